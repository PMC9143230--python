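# Methods

Conventions: lengths nm, times ps, masses amu, charges e (the GRO unit
system); PDB input is converted from Å on read. Atom ids are 0-based in the
library and 1-based in files. Only orthorhombic periodic boxes are
supported; all pair distances use the minimum-image convention. Diffusion
coefficients convert between nm²/ps and the customary 10⁻⁵ cm²/s scale by
the single factor 10⁻³ (1 × 10⁻⁵ cm²/s = 10⁻³ nm²/ps); mass densities by
1 amu/nm³ = 1.66054 × 10⁻³ g/cm³. Both constants live in `units.py`.

## Surface extraction and roughness

The xy plane is tiled with square cells (default 0.4 nm); within each cell
the extreme-z selection atom defines the face height (max z for the upper
face, min z for the lower). Cells are half-open `[i·s, (i+1)·s)`; a box
length not divisible by the cell size leaves a final narrower cell rather
than a wrapped one, keeping cells disjoint and deterministic. RMS roughness
is `R = sqrt(Σ (Zᵢ − Z̄)²/N)` over occupied cells only — unoccupied cells
are flagged and excluded, never interpolated, and their count is reported.
`N` defaults to one height per occupied cell; the `all_top_atoms` variant
implements the per-atom reading (every atom within `top_layer` of its
cell's extreme height contributes), since either reading of "atoms exposed
in the outermost layer in each grid point" is defensible. Frame series
report per-frame R averaged over frames with both SEM (headline) and SD.
Slabs straddling the periodic z-boundary must pass through
`recenter_slab`, which centres the selection's circular-mean z at the box
midpoint.

## Density profiles

Mass-weighted histogram of wrapped z coordinates, divided by the bin slab
volume `Lx·Ly·dz` and averaged over frames; default bin width 0.1 nm
(configurable), whole molecules included. Mass is conserved exactly:
Σ value·bin volume equals the selected mass per frame up to float
summation. Symmetrization returns `½[ρ(z) + ρ(2c − z)]` with linear
interpolation at reflected positions (zero outside the range; reflections
that miss the outermost bin centre by float rounding are snapped). It is
idempotent and even about the centre up to interpolation error, exactly so
on a grid-aligned centre. The `auto` centre is the membrane selection's
mass-weighted mean z.

## SASA and hydrophilicity

Shrake–Rupley sampling with a deterministic Fibonacci sphere (default 960
points — reproducible across platforms, error ~n⁻½). Each selection atom's
solvent-expanded sphere (Bondi radius by atom-name first letter, shipped
table, overridable + probe, default 0.14 nm) is sampled; a point is buried
if inside any neighbour's expanded sphere, with periodic images as
occluders. A point exactly on a neighbour's surface is assigned to the
lower-index atom, so coincident identical atoms expose exactly one
sphere's area between them. Only selection atoms occlude: membrane SASA is
the membrane's own surface whether or not solvent is present, which is
what a dry-vs-hydrated comparison needs. The hydrophilic/hydrophobic split
is by partial charge with a closed hydrophobic interval |q| ≤ 0.2 e
(boundary charges are hydrophobic); the two totals sum to the total area
by construction. The SASA algorithm, probe and radii set are package
choices — all three are configurable because the observable is defined
only up to them.

## Dipole orientation

A molecule's dipole is `Σ qᵢ·min_image(rᵢ − r_ref)` with the heaviest atom
(the water oxygen) as reference; for neutral molecules the direction is
reference-independent, and for rigid 3-site water it is the H–H bisector.
Profiles bin each water by the height of its oxygen above the surface
reference — per-cell grid heights from the surface module by default, or a
fixed z-plane — and average cos θ (θ against +z) per bin over frames.
Waters below the surface get negative distances and are counted
separately; waters over unoccupied cells are dropped and counted. The
uniform-orientation null gives ⟨cos θ⟩ = 0 with sampling error 1/√(3n) per
bin (the variance of cos θ for a uniform direction is 1/3).

## Hydration-shell dynamics

Occupancy: a water is in the shell when the minimum-image distance from
its oxygen to the nearest membrane atom is ≤ cutoff (default 0.5 nm) —
proximity to membrane atoms, not to the extracted surface grid, which is
the direct reading of a distance-to-surface cutoff for a corrugated
surface. Residence events are maximal in-shell runs with gaps up to
`gap_tolerance` frames bridged (default 0, strict); duration is run length
(bridged gaps included) × frame spacing. Events touching the first or last
frame are censored — only a lower bound on their true duration is observed
— and the headline mean excludes them; when every event is censored (a
shell nothing ever leaves) the mean falls back to the censored durations
and is flagged. `mean_over("all")` gives the unfiltered mean for direct
hand-count comparisons.

MSD averages squared displacements of minimum-image-unwrapped coordinates
over molecules and all sliding time origins, computed with the standard
FFT decomposition; origin weights implement both origin strides and the
hydration-layer variant (origins restricted to frames where the molecule
is in the shell, displacements tracked after it leaves — restricting to
continuously-in-shell molecules would bias the MSD down). Unwrapping
requires per-frame displacements below half the box on every axis; a jump
at half the box is ambiguous and is a hard error naming the frame. The
Einstein relation gives `D = slope/6` from a least-squares fit over a
lag-fraction window, default 10–50 % of the maximum lag — late lags have
few independent origins, so analyses here fit short-lag windows (e.g.
max lag 200 ps of a 4 ns series) where the estimator variance is smallest.
The uncertainty is the SD of D refit on ≥ 3 contiguous trajectory blocks
(default 5), which shrinks as ~n⁻½ in the particle count.

## RDF, coordination number and SDF

g(r) counts reference–target pairs per spherical shell (exact shell
volumes, periodic KD-tree), normalised by the mean target density
N_target/V over the whole box — the convention under which an ideal gas
gives exactly 1, appropriate for the bulk solution systems this targets.
Self pairs are always excluded; pairs within one molecule are excluded by
molecule id (switchable). n(r) is the raw cumulative pair count per
reference, so a constructed shell of 6 neighbours gives a plateau of
exactly 6. `r_max` may not exceed half the smallest box length.
`first_minimum()` locates the first local minimum of g after its first
peak; coordination numbers can be read there or at any explicit radius,
since fixed-radius and first-minimum conventions both appear in practice.

The SDF histograms water oxygens in the molecular frame of three
user-specified anchor atoms (first at the origin, second on +x, third in
the xy-plane; collinear anchors are an error), normalised by the mean
water density so bulk is 1, and exports OpenDX. Rigid whole-system motion
leaves the grid unchanged.

## Synthetic generators

All generators are seeded (`numpy.random.default_rng`), bit-reproducible,
and record their ground truth in `Trajectory.metadata`. They emulate the
geometry and statistics the estimators consume, not physical dynamics:
particles do not interact, orientations are resampled per frame without
rotational dynamics, and shell exchange teleports particles. Passing tests
therefore validate the estimators (normalisation, censoring, unwrapping,
frame transforms), not force-field realism; correlated noise, slab
fluctuations and genuinely interacting water are absent by design.

- `make_slab`: lattice slab (default spacing 0.2 nm) whose top layer
  follows a flat / two-level / sinusoid height field with analytic RMS
  roughness 0, h, A/√2; the bulk lattice stays strictly below the
  corrugation's lowest point so surface extraction always sees the top
  layer. Optional rigid z-jitter exercises frame series.
- `make_brownian_solvent`: independent Gaussian walks with per-axis step
  variance 2·D·dt; unwrapped paths kept in metadata.
- `make_oriented_waters`: rigid 3-site waters (O–H 0.1 nm, H–O–H 109.47°,
  charges −0.82/+0.41 e) with uniform, fixed-cos θ, or exponentially
  decaying ⟨cos θ⟩(z) dipole laws imposed per frame by construction;
  oxygens optionally perform the same Brownian walk so one system carries
  both a known orientation law and a known D.
- `make_exchange_shell`: in-shell/out-of-shell episode lengths drawn as
  geometric numbers of frames with mean τ/dt — the discrete-time law whose
  dt→0 limit is exponential exchange — so the run-length × dt estimator is
  unbiased at any frame spacing; τ < 2·dt is rejected as unresolvable,
  τ = ∞ yields a fully censored shell.
- `make_ideal_gas` / `make_coordination_lattice`: the g = 1 null and an
  exact-coordination first shell for RDF/SDF checks.

Default study conditions for parameter-recovery checks: 500 particles,
2000 frames at dt = 2 ps (the frame spacing typical of stored production
trajectories), diffusion coefficients spanning 0.5–4 × 10⁻⁵ cm²/s and
residence times 10–50 ps — the range bracketing hydration-layer and bulk
water at room temperature.

## Pipeline

A YAML config validated against a strict pydantic schema (unknown keys get
close-match suggestions; cross-field checks cover positivity and required
selections) drives the stages in dependency order: surface before
orientation and occupancy; occupancy shared between residence and
hydration-layer diffusion. Each stage writes a TSV (or .dx) whose comment
header records its generating parameters; the run ends with a fixed-order,
fixed-format `summary.tsv`, so one config + seed is byte-reproducible.
Stage failures abort with the stage name, keeping earlier outputs. The
shipped `examples/benchmark.yaml` runs a 200-frame sinusoidal slab with
200 diffusing, randomly oriented waters — small enough to complete in
seconds while exercising every stage. The per-analysis shell commands are
deliberately folded into the config-driven `run`; each analysis remains a
first-class library function, and the CLI stays a thin wrapper.

## Known limitations

- No triclinic boxes, no binary trajectory formats (XTC/TRR/DCD); convert
  upstream or wrap an external reader.
- Density profiles assume a constant box over the averaged frames (no NPT
  box-fluctuation reweighting).
- The RDF bulk-density normalisation is box-volume based; for interfacial
  (slab) geometries g(r) plateaus below 1 and only relative peak heights
  are meaningful.
- Residence censoring is detected only at the trajectory ends; gap
  tolerance does not model re-entry statistics.
- SASA radii resolution by atom-name first letter misassigns two-letter
  elements that collide with common organics (e.g. Br → B table entry);
  supply an explicit radii table for such systems.
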