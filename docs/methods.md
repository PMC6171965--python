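# Model and methods

## The model

`astersim` simulates a thin patch of cell cortex as a two-dimensional
open hexagonal domain containing three kinds of agents:

* **Filaments** — rigid polar rods of fixed length `L` (default 1 µm)
  and diameter `di` (8 nm), described by their center `(x_i, y_i)` and
  orientation `θ_i`. The plus-end sits at `center + (L/2)(cos θ, sin θ)`;
  ends are always derived, never stored. Filaments are rigid because the
  domain is small compared to F-actin persistence length; they do not
  interact sterically and may pass through one another.
* **Motors** — bipolar myosin-II mini-filaments, modeled as two-headed
  Hookean springs with zero rest length and stiffness `k` (3 pN/µm).
  Each head independently binds filaments and walks toward the plus-end
  at constant speed `v` (1 µm/s). A motor exerts force only while it
  spans two attachments; the spring force on the filament under head
  `j` is `F_j = k (A_j − a_j)` where `(a_j, b_j)` is the head's
  attachment point and `(A_j, B_j)` the opposite head. A single length
  `r` (0.3 µm) is both the binding search radius and the maximum
  stretch.
* **Crosslinkers** — passive two-point springs of the CH-domain bundler
  class (fimbrin/fascin/α-actinin). They bind pairs of co-oriented
  filaments (orientation difference ≤ π/8, polarity-aware so
  anti-parallel rods never link) no farther apart than their 40 nm
  reach, at the mutually closest points of the pair, and then stay
  fixed: they never walk, and release only when a linked filament turns
  over or is boundary-re-inserted (over-stretch breakage and stochastic
  unbinding exist as optional channels, both off by default — a
  crosslinker that lets go the moment motors stretch it past 40 nm
  provides no lasting resistance at any abundance). Crosslinker
  stiffness defaults to 6 pN/µm: bundler proteins are much stiffer than
  the deliberately soft motor spring, and this value sits at the
  boundary that reproduces the observed mixture behavior — a 25%
  crosslinker / 75% motor mixture still forms asters while a 75%
  crosslinker mixture suppresses them; at the motor's 3 pN/µm the
  excess never inhibits, and at α-actinin-scale 30–100 pN/µm even the
  25% mixture is frozen. Chosen once on that phenotype and fixed.
  Motors pass through bound crosslinkers.

Filament motion is overdamped. Forces and lever-arm torques from all
connectors are summed per filament, rotated into the filament frame,
and divided by anisotropic slender-rod drag coefficients

```
Γ_perp = 4πηL / (ln p + 0.84)      p = L/di
Γ_par  = 2πηL / (ln p + 0.114)
Γ_rot  = (1/3)πηL³ / (ln p − 0.662)
```

with natural logarithms (the end-correction constants are defined for
ln) and dynamic viscosity `η` (1 pN s/µm²). The center advances by
`dt·F_par/Γ_par` along the axis and `dt·F_perp/Γ_perp` across it; the
angle by `dt·Σ len_j F_perp,j / Γ_rot`, where `len_j` is the signed
attachment coordinate. Units are µm, s, pN throughout; energies are in
pN µm.

Polymerization dynamics are lumped into whole-filament **turnover**: at
rate `p2` per filament (0.7/s) a rod is deleted and re-created at a
uniformly random position and orientation, severing every attached
head. Treadmilling is neglected; `treadmilling_displacement` documents
why (0.21 subunits/s × 4–7 nm ⇒ 8.4×10⁻⁶–1.47×10⁻⁵ µm per 10 ms step,
three orders below motor-driven motion).

## The per-step update

Each 10 ms step runs, in a fixed order: (1) free motors take one
isotropic 0.05 µm diffusion step; (2) free heads search and bind
(probability `p1·dt`, default `p1` = 10/s); (3) free crosslinkers
diffuse, search and bind; (4) bound heads walk (`len += v·dt`, capped
at the plus-end, arrivals flagged); (5) connector forces are
accumulated and recorded; (6) mobile filaments move against drag;
(7) release checks — stochastic at `p0·dt` (`p0` = 1/s), flagged
plus-end arrivals, and over-stretch (extension > `r`) on end-of-step
positions, which drops the more recently bound head (ties broken at
random); (8) turnover; (9) agents whose anchor point left the hexagon
are re-inserted uniformly at random (filaments keep their orientation
but lose their heads); (10) scheduled parameter switches apply;
(11) per-step scalars are recorded, full snapshots at the configured
stride.

Two ordering choices deserve note. Forces are computed **before**
motion and release, so a motor stretched past `r` by the current step's
walk exerts one final force — bounded by `k(r + 2 v dt)` — before
detaching; this keeps the extension check on end-of-step positions and
matches a force-first update of the equations of motion. And release
follows motion, so the recorded per-motor force can exceed `k·r`
(0.9 pN at standard parameters) by at most one step's walk-induced
extension (0.06 pN).

## Binding rules

A searching head considers every filament whose **segment** lies within
`r` of the head's position (a one-bound motor's free head searches from
its partner's position — the spring has zero rest length). Among the
candidates the head binds a **uniformly random** one
(`binding_choice="random"`), at the signed along-rod coordinate of the
closest point; a fully free motor that draws two successes takes two
distinct filaments. We also implement nearest-candidate selection
(`"nearest"`), but it is not the default: in dense disordered networks
nearest-selection creates near-zero initial spring extensions, which
suppresses the steady-state motor force exactly in the no-aster regimes
and inverts the observed ordering (steady force should be higher in
high-turnover networks that fail to form asters than in aster-forming
ones, and non-decreasing in `p2` over {0, 0.7, 5}/s). Random selection
restores both, along with the characteristic peak-then-decay force
transient of aster-forming runs. Crosslinkers, by contrast, bind the
*closest* eligible pair — that rule is part of their definition.

Both heads draw attachment Bernoullis at `p1·dt` each step
(`free_attach_deterministic=False`). The deterministic-on-discovery
variant for fully free motors is available as a flag; it raises the
sparse-ensemble force slightly but degrades the single-aster robustness
and the force ordering above, so it is off by default.

Neighbor search uses uniform-grid binning (cell size `r/2`, 5×5 scan)
with an exact distance filter; results are identical to brute-force
all-pairs search, which the test suite verifies indirectly through an
independent straight-line oracle of the full step.

## Domain size — the one calibrated quantity

The physical parameter set fixes every rate and modulus but not the
hexagon size, which sets the ratio of filament length to system size
and thereby the number of aster nucleation basins. Two sizes are used,
each calibrated once and then frozen:

* **Dense experiments** (1000 filaments, 5000 motors): circumradius
  **2.5 µm**. At this size the standard parameter set forms exactly one
  central aster by step 1000 in 9/10 seeds, via the transient
  ring intermediate; at 5 µm the same parameters produce several small
  asters (the phenotype otherwise associated with short filaments).
* **Sparse ensemble** (50 filaments, 250 motors): circumradius
  **1.25 µm**, at which the ensemble mean of the final-step mean motor
  force is ≈0.08 pN with ≈40% relative SD over replicates.

## Analysis

* **Divergence maps**: each filament adds its orientation unit vector to
  the `L/8` grid box containing its plus-end; divergence is the central
  difference of the summed field (one-sided at grid edges,
  `numpy.gradient`). Disordered networks give ≈0; an aster core is
  strongly negative with a positive surround.
* **Aster detection**: Gaussian-smooth the divergence (σ = 1 box);
  candidate cores are in-domain boxes below −2 σ_DIV; cores within 2
  boxes merge. A core counts as an aster only if it shows the
  sign-reversal signature (a > +2 σ_DIV box within two boxes — the
  dark-next-to-light dipole of a compact core — or a positive mean
  shell) *and* plus-end packing: some 3×3-box window on the core holds
  ≥5 plus-ends and ≥4× the count of an average-density window. The
  packing gate encodes the definition of an aster core and rejects
  divergence noise in disordered networks (0 false positives on uniform
  configurations across densities in the test suite).
* **Synthetic fluorescence**: filaments rasterize as 1-px Bresenham
  segments, motors as points, intensities adding; default pixel size
  0.05 µm (20 px per filament). ROI traces, kymographs
  (`skimage.measure.profile_line`) and the coarse hexagon segmentation
  (tile the domain with small hexagons, highlight tiles ≥1.7× the
  global spatiotemporal mean, merge adjacent tiles) operate on these
  rasters.
* **Plus-end connectedness**: fraction of plus-ends in the largest
  single-linkage cluster at radius 2r. The underlying trace in the
  source material is not defined operationally; this is our
  reconstruction and should be read as such.
* **Energy accounting**: elastic energy `Σ ½ k ext²` over two-attachment
  connectors; viscous dissipation as the drag work of realized filament
  displacements `Σ(Γ_par Δ_par² + Γ_perp Δ_perp² + Γ_rot Δθ²)/dt`. In
  overdamped dynamics this equals the work done by the applied forces,
  so it doubles as the power input of the motors.

## Patterned experiments

`patterning` builds the non-random initial conditions: orientation
windows (`init_aligned`), a microcontact-printing-style bar with a
chosen fraction of filaments wholly inside and the rest minus-end-in /
plus-end-out (`init_bar`, bar filaments stabilized against turnover),
one-head-anchored motors in a region (`tether_motors`), and immobilized
filament subsets (`fix_filaments`). "Bottom eighth/fourth" regions are
horizontal slices of the hexagon's bounding box; for the bottom eighth
this tethers ≈9% of uniformly seeded motors (the area fraction of that
slice in a hexagon). Mid-run parameter switches (`switch_schedule`)
apply after the scheduled step completes; a filament-length switch
rescales rods about their centers and releases heads stranded beyond
the new tip, and drag coefficients are recomputed whenever geometry or
viscosity changes.

## What the generator emulates — and what it does not

The synthetic configurations reproduce the *in silico* study
conditions: counts, rates and modulus values of the standard parameter
set, and the patterned variants above. They do not model filament
bending or severing, steric interactions, explicit polymerization,
motor catch-bond kinetics, thermal forces on filaments, or the
signaling dynamics of living cortex; conclusions from passing tests
therefore concern the minimal rigid-rod/Hookean-motor model, not real
cortical imaging data.

## Problem sizes used by the test suite

Full-size dense runs (1000 filaments/5000 motors, 1000 steps) take
about a minute each, so the acceptance tests exercise the emergent
phenomenology on a density-matched scaled domain — circumradius 1.5 µm
with 360 filaments and 1800 motors (identical filament and motor
densities, identical L/domain ratio to within 17%) — and on the sparse
ensemble at reduced replicate counts. The full-size behavior reported
above (single-aster rate, force ordering, switch outcomes) was
established with the package's own orchestration tools and can be
reproduced with `astersim run`/`sweep`/`ensemble`.

## Numerical choices and degenerate inputs

Rates convert to per-step probabilities as `rate·dt`, clipped to 1; all
standard rates satisfy `rate·dt ≤ 0.1`, where the difference from
`1 − exp(−rate·dt)` is under 0.5%. A single `numpy` PCG64 stream,
seeded from the config, drives every stochastic draw in a fixed
documented order, making whole trajectories bit-reproducible. Aspect
ratios with `ln(L/di) ≤ 0.662` make `Γ_rot` non-positive and are
rejected. Motors that lose both heads re-enter the diffusing pool at
the midpoint of their final head positions. A motor's two heads may
never hold the same filament (a zero-rest-length spring on one rigid
rod exerts no net force and cannot remodel anything).

## Known limitations

* Aster detection on *sparse* networks (tens of filaments) is
  borderline: with turnover at 0.7/s only a handful of plus-ends occupy
  the core at any instant, near the packing gate's floor.
* The tethered fraction for the bottom-eighth experiment is set by slice
  geometry (~9%), not exactly the 12.5% quoted for the original
  experiment, whose slicing convention is not fully specified.
* The free-motor diffusion step (0.05 µm per 10 ms) is a modeling
  choice — no measured coefficient is given for the mini-filament pool;
  it is sized so a free motor explores its own search radius within
  about a second.
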