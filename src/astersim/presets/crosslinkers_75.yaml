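n_filaments: 1000
n_motors: 1250
n_crosslinkers: 3750
filament_length: 1.0
filament_diameter: 0.008
motor_stiffness: 3.0
motor_velocity: 1.0
motor_attach_rate: 10.0
motor_detach_rate: 1.0
filament_turnover_rate: 0.7
motor_reach: 0.3
dynamic_viscosity: 1.0
timestep: 0.01
n_steps: 1000
hexagon_circumradius: 2.5
free_motor_diffusion_step: 0.05
seed: 0
snapshot_stride: 100
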