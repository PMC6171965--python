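"""Artifact readers/writers: trajectory CSVs, snapshot tables, TIFF
stacks, divergence/kymograph exports and the run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import DivergenceMap, SyntheticFrame
from .dynamics import FrameSeries
from .state import NO_FILAMENT, SystemState

__all__ = [
    "write_series_csv",
    "write_snapshots_csv",
    "read_snapshot_states",
    "write_tiff_stack",
    "write_divergence",
    "write_kymograph",
    "write_manifest",
    "write_run_bundle",
]


def read_snapshot_states(path: Path, cfg) -> list[tuple[int, SystemState]]:
    """Rebuild (step, SystemState) pairs from a snapshot CSV.

    Positions/orientations (and motor walk coordinates / binding
    partners) round-trip; transient per-head binding metadata
    (bind-order steps) does not, so the result supports rendering and
    analysis, not bitwise resumption.
    """
    df = pd.read_csv(path)
    out = []
    for step, grp in df.groupby("step", sort=True):
        fil = grp[grp["kind"] == "filament"].sort_values("id")
        mot = grp[grp["kind"] == "motor"].sort_values("id")
        xl = grp[grp["kind"] == "crosslinker"].sort_values("id")
        state = SystemState.empty(len(fil), len(mot), len(xl))
        state.fil_center[:, 0] = fil["x"].to_numpy()
        state.fil_center[:, 1] = fil["y"].to_numpy()
        state.fil_angle[:] = fil["theta"].to_numpy()
        state.fil_mobile[:] = fil["mobile"].to_numpy(dtype=bool)
        if len(mot):
            state.mot_pos[:, 0] = mot["x"].to_numpy()
            state.mot_pos[:, 1] = mot["y"].to_numpy()
            for h, col_f, col_l in ((0, "bound_a", "len_a"), (1, "bound_b", "len_b")):
                f = mot[col_f].to_numpy(dtype=int)
                state.mot_fil[:, h] = f
                state.mot_bound[:, h] = f != NO_FILAMENT
                state.mot_len[:, h] = np.nan_to_num(mot[col_l].to_numpy())
        if len(xl):
            state.xl_pos[:, 0] = xl["x"].to_numpy()
            state.xl_pos[:, 1] = xl["y"].to_numpy()
            f = xl[["bound_a", "bound_b"]].to_numpy(dtype=int)
            state.xl_fil[:] = f
            state.xl_bound[:] = (f != NO_FILAMENT).all(axis=1)
            state.xl_len[:, 0] = np.nan_to_num(xl["len_a"].to_numpy())
            state.xl_len[:, 1] = np.nan_to_num(xl["len_b"].to_numpy())
        out.append((int(step), state))
    return out


def write_series_csv(frames: FrameSeries, path: Path) -> None:
    frames.series.to_csv(path, index=False)


def _snapshot_rows(step: int, state: SystemState) -> pd.DataFrame:
    rows = []
    for i in range(state.n_filaments):
        rows.append(
            dict(
                step=step, kind="filament", id=i,
                x=state.fil_center[i, 0], y=state.fil_center[i, 1],
                theta=state.fil_angle[i], len_a=np.nan, len_b=np.nan,
                bound_a=NO_FILAMENT, bound_b=NO_FILAMENT,
                mobile=bool(state.fil_mobile[i]),
            )
        )
    pos = state.motor_head_positions().mean(axis=1)
    for j in range(state.n_motors):
        rows.append(
            dict(
                step=step, kind="motor", id=j,
                x=pos[j, 0], y=pos[j, 1], theta=np.nan,
                len_a=state.mot_len[j, 0], len_b=state.mot_len[j, 1],
                bound_a=int(state.mot_fil[j, 0]), bound_b=int(state.mot_fil[j, 1]),
                mobile=not bool(state.mot_tethered[j]),
            )
        )
    xpos = state.xl_head_positions().mean(axis=1)
    for j in range(state.n_crosslinkers):
        rows.append(
            dict(
                step=step, kind="crosslinker", id=j,
                x=xpos[j, 0], y=xpos[j, 1], theta=np.nan,
                len_a=state.xl_len[j, 0], len_b=state.xl_len[j, 1],
                bound_a=int(state.xl_fil[j, 0]), bound_b=int(state.xl_fil[j, 1]),
                mobile=True,
            )
        )
    return pd.DataFrame(rows)


def write_snapshots_csv(frames: FrameSeries, path: Path) -> None:
    tables = [_snapshot_rows(s.step, s.state) for s in frames.snapshots]
    pd.concat(tables, ignore_index=True).to_csv(path, index=False)


def write_tiff_stack(images: list[SyntheticFrame], path: Path) -> None:
    """Multi-page 16-bit TIFF, one page per frame."""
    import tifffile

    stack = np.stack([f.intensity for f in images])
    stack = np.clip(stack, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, stack, photometric="minisblack")


def write_kymograph(kymo: np.ndarray, stem: Path) -> None:
    """Write a kymograph (position x time) as float32 TIFF and tidy CSV."""
    import tifffile

    tifffile.imwrite(stem.with_suffix(".tif"), np.asarray(kymo, dtype=np.float32))
    pos, t = np.meshgrid(
        np.arange(kymo.shape[0]), np.arange(kymo.shape[1]), indexing="ij"
    )
    pd.DataFrame(
        dict(position_px=pos.ravel(), frame=t.ravel(), intensity=np.asarray(kymo).ravel())
    ).to_csv(stem.with_suffix(".csv"), index=False)


def write_divergence(divmap: DivergenceMap, stem: Path) -> None:
    """Write a divergence map as TIFF (float32) and tidy CSV."""
    import tifffile

    tifffile.imwrite(stem.with_suffix(".tif"), divmap.div.astype(np.float32))
    cx, cy = divmap.box_centers()
    gx, gy = np.meshgrid(cx, cy)
    pd.DataFrame(
        dict(x=gx.ravel(), y=gy.ravel(), div=divmap.div.ravel(),
             divx=divmap.divx.ravel(), divy=divmap.divy.ravel())
    ).to_csv(stem.with_suffix(".csv"), index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir: Path, config_dict: dict, files: list[Path]) -> Path:
    from . import __version__

    manifest = {
        "package": "astersim",
        "version": __version__,
        "config": config_dict,
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=float))
    return path


def write_run_bundle(
    frames: FrameSeries,
    out_dir: str | Path,
    render: bool = True,
    pixel_size: float = 0.05,
) -> Path:
    """Write the standard artifact bundle for one run.

    Contents: resolved config copy, per-step series CSV, snapshot table,
    filament/motor TIFF stacks (optional), final divergence map, and a
    manifest with output checksums.
    """
    from .analysis import divergence_map, render_frame
    from .geometry import HexagonDomain

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = frames.config
    cfg.to_yaml(out / "config.yaml")
    write_series_csv(frames, out / "series.csv")
    write_snapshots_csv(frames, out / "snapshots.csv")
    files = [out / "config.yaml", out / "series.csv", out / "snapshots.csv"]
    if render:
        for channel in ("filament", "motor"):
            imgs = [
                render_frame(s.state, cfg, pixel_size=pixel_size, channel=channel)
                for s in frames.snapshots
            ]
            path = out / f"{channel}_stack.tif"
            write_tiff_stack(imgs, path)
            files.append(path)
    domain = HexagonDomain(cfg.hexagon_circumradius)
    final = frames.final_state
    dm = divergence_map(
        final.plus_ends(cfg.filament_length),
        final.fil_angle,
        domain,
        cfg.filament_length / 8.0,
    )
    write_divergence(dm, out / "divergence_final")
    files += [out / "divergence_final.tif", out / "divergence_final.csv"]
    write_manifest(out, cfg.to_dict(), files)
    return out
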