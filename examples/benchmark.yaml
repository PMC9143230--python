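# Synthetic slab + solvent benchmark: a corrugated polymer-slab stand-in
# under SPC-geometry waters whose diffusion coefficient, dipole law and
# shell kinetics are known by construction.  All analysis parameters are
# the library defaults (0.4 nm surface grid, 0.5 nm hydration shell,
# |q| <= 0.2 e hydrophobicity cutoff, 0.14 nm probe).
seed: 1
output_dir: hydralyze_out
synth:
  kind: benchmark
  box: [6.0, 6.0, 12.0]
  slab_z_range: [1.0, 3.0]
  corrugation_mode: sinusoid
  corrugation_amplitude: 0.5
  corrugation_wavelength: 3.0
  atom_spacing: 0.2
  charge_pattern: [-0.5, 0.3, 0.1, 0.1]
  n_waters: 200
  true_D: 2.5
  n_frames: 200
  dt: 2.0
selections:
  membrane: "molname MEM"
  water: "molname SOL"
  water_oxygen: "molname SOL and name OW"
frames: all
stages:
  surface:
    cell_size: 0.4
    sides: [up, down]
  density:
    bin_width: 0.1
    symmetrize: true
  sasa:
    probe: 0.14
    n_points: 240
    charge_cutoff: 0.2
    frames: "last:2"
  orientation:
    bin_width: 0.2
    reference: grid
  residence:
    cutoff: 0.5
    gap_tolerance: 0
  diffusion:
    fit: [0.2, 0.8]
    max_lag: 80.0
    n_blocks: 5
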