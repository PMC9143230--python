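"""Solvent-accessible surface area of a charged slab, partitioned into
hydrophilic and hydrophobic parts by the |q| <= 0.2 e rule."""

import hydralyze as hz
from hydralyze.synth import SlabSpec, make_slab

# charge pattern mimicking a polymer with one strongly charged site
# (|q| > 0.2 e -> hydrophilic) per four atoms
top, traj = make_slab(
    SlabSpec(box=(4.0, 4.0, 8.0), charge_pattern=(-0.5, 0.3, 0.1, 0.1)), seed=0
)
membrane = hz.select(top, "molname MEM")
areas = hz.sasa(traj, top, membrane, probe=0.14, n_points=960)
result = hz.partition_sasa(areas, top.charges[membrane.atom_ids],
                           membrane.atom_ids, cutoff=0.2)

print(f"total SASA        : {result.total:8.2f} nm^2")
print(f"hydrophilic (|q|>0.2e): {result.hydrophilic:8.2f} nm^2")
print(f"hydrophobic (|q|<=0.2e): {result.hydrophobic:8.2f} nm^2")
print(f"hydrophilic fraction  : {result.hydrophilic_fraction:.3f}")

# Half the charge pattern is the -0.5/+0.3 pair, so about half the exposed
# area is hydrophilic; a larger hydrophilic fraction means a surface that
# hydrogen-bonds more water and hydrates more strongly.
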