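"""Build a synthetic myeloblast cohort and inspect its design.

Generates the default two-genotype cohort manifest (no tomograms rendered:
the manifest, patient table and ground-truth parameter draws are enough to
see the study design), then renders one phantom to show the tomogram.
"""

import numpy as np

from tomoblast import generate_cohort, generate_phantom, sample_specs, mut_default_params

# the full cohort design: 1,173 mutant images from 22 patients and 900
# wild-type images from 26 patients, split into training (optimization +
# generalization) and a patient-disjoint validation set
manifest, specs = generate_cohort(rng=1)
print(manifest.images.groupby(["genotype", "split"]).size())
print(f"\npatients: {len(manifest.patients)}  "
      f"validation patients: {int(manifest.patients.is_validation.sum())}")

# ground-truth parameter draws follow the published group statistics
mut_specs = specs.merge(manifest.images[["image_id", "genotype"]], on="image_id") \
    .query("genotype == 'MUT'")
print(f"\nMUT draws: cell volume {mut_specs.cell_volume_fl.mean():.1f} fL "
      f"(printed 462.18), nucleus sphericity "
      f"{mut_specs.nucleus_sphericity.mean():.3f} (printed 0.538)")

# render one phantom: an RI tomogram plus its ground-truth label map
spec = sample_specs(mut_default_params(), 1, rng=7)[0]
tomo, mask = generate_phantom(spec, grid_shape=(48, 96, 96),
                              voxel_spacing=(0.35, 0.2, 0.2), rng=7)
print(f"\nphantom: grid {tomo.shape}, RI range "
      f"[{tomo.ri.min():.4f}, {tomo.ri.max():.4f}] over medium {tomo.medium_ri}")
print("voxels per region:", mask.counts())
# the RI range spans the medium (1.337) up through cytoplasm (~1.363),
# nucleoplasm (~1.369) and the bright nucleoli (~1.376)
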