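# hydralyze

Quantitative analysis of the **hydration layer** above polymer membrane
surfaces in slab molecular-dynamics trajectories. Antifouling performance of
zwitterionic and anionic polymer coatings correlates with how tightly the
surface binds its first layers of water; `hydralyze` computes the standard
observables used to rank such surfaces:

- **surface structure** — per-cell surface extraction on a lateral grid
  (default 0.4 nm × 0.4 nm), RMS roughness
  `R = sqrt(Σᵢ (Zᵢ − Z̄)² / N)`, and contour maps;
- **density profiles** ρ(z) in g/cm³, symmetrized about the membrane centre;
- **hydrophilicity** — Shrake–Rupley solvent-accessible surface area split
  into hydrophilic and hydrophobic parts by partial charge
  (|q| ≤ 0.2 e → hydrophobic);
- **water ordering** — dipole-orientation profiles ⟨cos θ⟩(d) against the
  surface normal, with ⟨cos θ⟩ = 0 the disordered (bulk) reference;
- **hydration dynamics** — shell occupancy within a 0.5 nm cutoff, residence
  times from maximal in-shell runs, mean-square displacement with the
  Einstein relation `D = slope/6` (reported in 10⁻⁵ cm²/s);
- **solvation structure** — radial distribution functions g(r) with running
  coordination numbers n(r), and spatial distribution functions (SDF) in a
  solute-fixed frame, exported as OpenDX.

Because hydration observables are easy to get subtly wrong (normalisation,
periodic images, censoring), the package ships seeded **synthetic-trajectory
generators with closed-form ground truth** for every estimator: corrugated
slabs with known analytic roughness, Brownian solvents with a set true
diffusion coefficient, waters with imposed dipole-orientation laws,
exponential shell-exchange kinetics with known mean residence time, and
ideal-gas / lattice reference fluids for RDF and SDF.

The primary interface is the Python API plus the narrative scripts under
`examples/`; a thin CLI (`hydralyze run|validate|synth|convert|inspect`)
covers the config-driven pipeline.

## Worked example

```sh
python examples/05_residence_and_diffusion.py
```

prints

```
mean residence time :  25.01 ps   (true 25.00 ps)
events              : 40294 (752 censored at the trajectory boundaries)

diffusion coefficient: 2.560 +/- 0.065 x1e-5 cm^2/s (true 2.570, fit r^2 = 1.00000)
```

The residence estimator recovers the exchange generator's mean in-shell
episode of 25 ps from 40k events (runs touching either end of the trajectory
are censored and excluded from the mean); the MSD slope over the 20–100 ps
lag window recovers the Brownian generator's diffusion coefficient of
2.57 × 10⁻⁵ cm²/s within the block uncertainty. The other examples
demonstrate roughness (`01`), densities (`02`), SASA partitioning (`03`),
orientation profiles (`04`), RDF/coordination (`06`), SDF export (`07`) and
the full pipeline on the shipped benchmark config (`08`).

## Layout

```
src/hydralyze/     core, io, select, synth, surface, density, sasa,
                   structure, dynamics, pipeline, cli, units
examples/          one short script per capability + benchmark.yaml
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    models, estimators, defaults and limitations
```
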