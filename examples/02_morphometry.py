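"""Measure one cell: volumes, surface areas, sphericity, dry mass, N/C ratios.

Renders a phantom at the wild-type group means, segments it with the
rule-based segmenter, and compares measurements on the ground-truth vs the
rule-based mask.
"""

from tomoblast import generate_phantom, measure_cell, segment_rule_based
from tomoblast.phantom import PhantomSpec

spec = PhantomSpec(
    cell_volume_fl=446.24, cell_sphericity=0.804,
    nucleus_volume_fl=0.400 * 446.24, nucleus_sphericity=0.501,
    nucleolus_count=2, nucleolus_total_volume_fl=14.48,
    mean_ri_cytoplasm=1.3635, mean_ri_nucleoplasm=1.3692,
    mean_ri_nucleolus=1.3764,
)
tomo, gt_mask = generate_phantom(spec, grid_shape=(48, 96, 96),
                                 voxel_spacing=(0.35, 0.2, 0.2), rng=3)

for name, mask in [("ground truth", gt_mask), ("rule-based", segment_rule_based(tomo))]:
    m = measure_cell(tomo, mask, alpha=0.185)
    cell, nuc = m.regions["cell"], m.regions["nucleus"]
    print(f"[{name}]")
    print(f"  cell: V {cell.volume_fl:7.1f} fL   A {cell.surface_area_um2:7.1f} um^2  "
          f"psi {cell.sphericity:.3f}  dry mass {cell.dry_mass_pg:6.1f} pg")
    print(f"  nucleus: V {nuc.volume_fl:6.1f} fL  psi {nuc.sphericity:.3f}  "
          f"N/C 3D {m.nc_volume_ratio:.3f}  N/C 2D {m.nc_area_ratio_2d:.3f}")
# the ground-truth row recovers the configured parameters (V 446 fL,
# psi 0.804/0.501, N/C 0.400); the rule-based row shows the segmentation
# error budget of the deterministic thresholds.  The dry mass follows from
# c = (n - n_m)/alpha with alpha = 0.185 mL/g: an RI contrast of 0.001 is
# 5.4 fg/fL of biomolecular mass.
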