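"""Phantom generator: shape synthesis, single-phantom rendering, sampling
and cohort construction."""

import numpy as np
import pytest
from scipy import ndimage

from tomoblast import (SegmentationMask, generate_cohort, generate_phantom,
                       mut_default_params, sample_specs, synthesize_shape,
                       wt_default_params)
from tomoblast.morphometry import LABELS, region_mask
from tomoblast.phantom import (GridTooSmallError, PhantomSpec, ParamDist,
                               SphericityUnreachableError, _patient_shifts)

SPACING = (0.35, 0.2, 0.2)


def canonical_spec(**over):
    base = dict(
        cell_volume_fl=446.24, cell_sphericity=0.804,
        nucleus_volume_fl=0.400 * 446.24, nucleus_sphericity=0.501,
        nucleolus_count=2, nucleolus_total_volume_fl=14.48,
        mean_ri_cytoplasm=1.3635, mean_ri_nucleoplasm=1.3692,
        mean_ri_nucleolus=1.3764,
    )
    base.update(over)
    return PhantomSpec(**base)


class TestSynthesizeShape:
    def test_sphere_limit(self):
        res = synthesize_shape(450.0, 1.0, SPACING, rng=1)
        assert res.sphericity >= 0.98
        assert abs(res.volume_fl - 450.0) / 450.0 < 0.03

    @pytest.mark.parametrize("target_psi,volume", [(0.80, 450.0), (0.50, 190.0)])
    def test_calibrated_sphericity_and_volume(self, target_psi, volume):
        res = synthesize_shape(volume, target_psi, SPACING, rng=2)
        assert abs(res.sphericity - target_psi) <= 0.02
        assert abs(res.volume_fl - volume) / volume <= 0.03

    def test_single_connected_component(self):
        res = synthesize_shape(300.0, 0.55, SPACING, rng=3)
        _, n = ndimage.label(res.mask)
        assert n == 1

    def test_seeded_determinism(self):
        a = synthesize_shape(450.0, 0.8, SPACING, rng=42)
        b = synthesize_shape(450.0, 0.8, SPACING, rng=42)
        assert np.array_equal(a.mask, b.mask)

    def test_unreachable_sphericity_reports_range(self):
        with pytest.raises(SphericityUnreachableError) as exc:
            synthesize_shape(190.0, 0.05, SPACING, rng=4)
        lo, hi = exc.value.achievable
        assert 0.0 < lo < hi <= 1.0
        assert "achievable range" in str(exc.value)

    def test_too_small_for_grid_resolution(self):
        with pytest.raises(ValueError, match="fewer than"):
            synthesize_shape(5.0, 0.9, (1.0, 1.0, 1.0), rng=5)


class TestGeneratePhantom:
    def test_ground_truth_region_means_noiseless(self):
        spec = canonical_spec()
        tomo, mask = generate_phantom(spec, grid_shape=(48, 96, 96),
                                      voxel_spacing=SPACING, noise_sd=0.0, rng=7)
        for region, want in [("cytoplasm", 1.3635), ("nucleoplasm", 1.3692),
                             ("nucleolus", 1.3764)]:
            got = tomo.ri[region_mask(mask.labels, region)].mean()
            assert abs(got - want) <= 1e-4

    def test_zero_nucleolus_count(self):
        spec = canonical_spec(nucleolus_count=0, nucleolus_total_volume_fl=0.0)
        _, mask = generate_phantom(spec, grid_shape=(48, 96, 96),
                                   voxel_spacing=SPACING, rng=8)
        assert not (mask.labels == LABELS["nucleolus"]).any()

    def test_partition_is_exact(self):
        spec = canonical_spec(lipid_droplet_count=1, lipid_total_volume_fl=2.0)
        _, mask = generate_phantom(spec, grid_shape=(48, 96, 96),
                                   voxel_spacing=SPACING, rng=9)
        counts = mask.counts()
        assert counts["cell"] == (counts["cytoplasm"] + counts["nucleoplasm"]
                                  + counts["nucleolus"] + counts["lipid"])
        nuc = region_mask(mask.labels, "nucleus")
        cell = region_mask(mask.labels, "cell")
        assert not (nuc & ~cell).any()

    def test_cell_fits_default_grid_with_margin(self):
        spec = canonical_spec(cell_volume_fl=450.0)
        _, mask = generate_phantom(spec, grid_shape=(72, 160, 160),
                                   voxel_spacing=(0.312, 0.156, 0.156), rng=10)
        idx = np.nonzero(region_mask(mask.labels, "cell"))
        for ax, dim in zip(range(3), (72, 160, 160)):
            assert idx[ax].min() >= 2 and idx[ax].max() <= dim - 3

    def test_invalid_spec_rejected_before_compute(self):
        spec = canonical_spec(nucleolus_total_volume_fl=1e4)
        with pytest.raises(ValueError, match="nucleolus"):
            generate_phantom(spec, grid_shape=(48, 96, 96), voxel_spacing=SPACING,
                             rng=11)
        with pytest.raises(ValueError, match="sphericit"):
            canonical_spec(cell_sphericity=1.4).validate()

    def test_noise_floor_respected(self):
        spec = canonical_spec()
        tomo, _ = generate_phantom(spec, grid_shape=(48, 96, 96),
                                   voxel_spacing=SPACING, noise_sd=0.002, rng=12)
        assert tomo.ri.min() >= tomo.medium_ri - 3 * 0.002 - 1e-12

    def test_grid_too_small_raises(self):
        spec = canonical_spec(cell_volume_fl=450.0)
        with pytest.raises(GridTooSmallError):
            generate_phantom(spec, grid_shape=(16, 40, 40), voxel_spacing=SPACING,
                             rng=13)


class TestSampling:
    def test_spec_invariants_hold_over_draws(self):
        for group, seed in ((wt_default_params(), 1), (mut_default_params(), 2)):
            specs = sample_specs(group, 500, rng=seed)
            for sp in specs:
                sp.validate()
                assert sp.mean_ri_nucleolus > sp.mean_ri_nucleoplasm
                assert 0 < sp.nucleus_volume_fl < sp.cell_volume_fl

    def test_truncated_sampler_mean_matches_expected(self):
        d = ParamDist(462.18, 187.43, lo=120.0)
        rng = np.random.default_rng(0)
        draws = d.sample(rng, 200_000)
        assert abs(draws.mean() - d.expected_mean()) < 1.5
        assert draws.min() >= d.mean - d.k_trunc() * d.sd - 1e-9

    def test_hierarchy_collapses_without_patient_variance(self):
        g = wt_default_params()
        g.icc = 0.0
        assert _patient_shifts(g, np.random.default_rng(0)) == {}
        a = sample_specs(g, 5, rng=3, patient_shifts={})
        b = sample_specs(g, 5, rng=3)
        assert a == b

    def test_patient_shifts_bounded(self):
        g = mut_default_params()
        shifts = _patient_shifts(g, np.random.default_rng(5))
        assert abs(shifts["nucleus_sphericity"]) <= 1.5 * g.nucleus_sphericity.sd


class TestCohort:
    def test_default_manifest_counts(self):
        man, specs = generate_cohort(rng=11)
        img = man.images
        assert len(img) == 2073
        assert (img.genotype == "MUT").sum() == 1173
        assert (img.genotype == "WT").sum() == 900
        val = img[img.split == "validation"]
        assert len(val) == 333 and len(img) - len(val) == 1740
        assert val.groupby("genotype").patient_id.nunique().to_dict() == {"MUT": 4, "WT": 4}
        train_pat = set(img[img.split != "validation"].patient_id)
        assert train_pat.isdisjoint(set(val.patient_id))
        assert len(specs) == 2073

    def test_optimization_generalization_proportions(self):
        man, _ = generate_cohort(rng=11)
        counts = man.images[man.images.split != "validation"] \
            .groupby(["genotype", "split"]).size().to_dict()
        assert counts[("MUT", "optimization")] == 574
        assert counts[("MUT", "generalization")] == 410
        assert counts[("WT", "optimization")] + counts[("WT", "generalization")] == 756

    def test_same_seed_same_manifest(self):
        a, sa = generate_cohort(rng=21)
        b, sb = generate_cohort(rng=21)
        assert a.images.equals(b.images) and a.patients.equals(b.patients)
        assert sa.equals(sb)

    def test_wt_patients_have_zero_vaf(self):
        man, _ = generate_cohort(rng=11)
        wt = man.patients[man.patients.genotype == "WT"]
        mut = man.patients[man.patients.genotype == "MUT"]
        assert (wt.vaf == 0).all()
        assert ((mut.vaf >= 0.2) & (mut.vaf <= 0.5)).all()


class TestRoundTrip:
    """Parameter recovery: generator + morphometry agree in distribution."""

    @pytest.mark.parametrize("group_name", ["WT", "MUT"])
    def test_measured_means_recover_configured_means(self, roundtrip_tables, group_name):
        df = roundtrip_tables[group_name]
        group = wt_default_params() if group_name == "WT" else mut_default_params()
        checks = [
            ("cell_volume", group.cell_volume.expected_mean()),
            ("cell_sphericity", group.cell_sphericity.expected_mean()),
            ("nucleus_sphericity", group.nucleus_sphericity.expected_mean()),
            ("nc_ratio", group.nc_volume_ratio.expected_mean()),
            ("ri_nucleolus", group.ri_nucleolus.expected_mean()),
            ("nucleolus_volume", group.nucleolus_total_volume.expected_mean()),
        ]
        for col, expected in checks:
            vals = df[col].to_numpy()
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - expected) <= 3 * sem, \
                f"{group_name} {col}: {vals.mean():.4f} vs {expected:.4f} (3 SEM {3*sem:.4f})"

    def test_per_phantom_volume_pinned(self, roundtrip_tables):
        df = roundtrip_tables["MUT"]
        rel = np.abs(df.cell_volume - df.spec_cell_volume) / df.spec_cell_volume
        assert rel.max() < 0.03
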