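"""Morphometry: closed-form geometry oracles, dry mass, N/C ratios and the
rule-based segmenter."""

import math

import numpy as np
import pytest

from tomoblast import (Tomogram, dry_mass, generate_phantom, mask_geometry,
                       measure_cell, nc_ratios, segment_rule_based, sphericity)
from tomoblast.morphometry import (AmbiguousFieldError, EmptyFieldError,
                                   MissingRegionError, SegmentationParams,
                                   region_geometry, region_mask)
from tomoblast.phantom import PhantomSpec

from test_phantom import canonical_spec


def ball(r, spacing=(1.0, 1.0, 1.0), pad=5):
    n = [int(2 * r / s) + 2 * pad for s in spacing]
    z, y, x = np.indices(n)
    c = [(k - 1) / 2 for k in n]
    return (((z - c[0]) * spacing[0]) ** 2 + ((y - c[1]) * spacing[1]) ** 2
            + ((x - c[2]) * spacing[2]) ** 2) <= r * r


def cube(L=40):
    m = np.zeros((L + 10,) * 3, bool)
    m[5:5 + L, 5:5 + L, 5:5 + L] = True
    return m


def spheroid(c=40, b=20):
    n = 2 * c + 9
    z, y, x = np.indices((n, n, n))
    ctr = (n - 1) / 2
    return ((z - ctr) / c) ** 2 + ((y - ctr) / b) ** 2 + ((x - ctr) / b) ** 2 <= 1


def spheroid_area(a, b):
    """Closed-form prolate spheroid surface area (semi-axes a > b = b)."""
    e = math.sqrt(1 - (b / a) ** 2)
    return 2 * math.pi * b ** 2 * (1 + (a / (b * e)) * math.asin(e))


class TestGeometry:
    def test_sphericity_formula_closed_forms(self):
        # cube: V = L^3, A = 6 L^2 -> psi = pi^(1/3) 6^(2/3) / 6
        assert sphericity(1.0, 6.0) == pytest.approx(
            math.pi ** (1 / 3) * 6 ** (2 / 3) / 6)
        assert sphericity(1.0, 6.0) == pytest.approx(0.80600, abs=1e-4)
        # 2:1:1 prolate spheroid via the analytic area formula
        v = 4 / 3 * math.pi * 2 * 1 * 1
        assert sphericity(v, spheroid_area(2, 1)) == pytest.approx(0.929, abs=0.01)
        # sphere is the psi = 1 case
        assert sphericity(4 / 3 * math.pi, 4 * math.pi) == pytest.approx(1.0)

    def test_digital_sphere(self):
        m = ball(20)
        v, a, psi = mask_geometry(m, (1, 1, 1))
        assert 0.98 <= psi <= 1.02
        assert abs(a - 4 * math.pi * 400) / (4 * math.pi * 400) <= 0.03

    def test_digital_cube_area(self):
        m = cube(40)
        v, a, psi = mask_geometry(m, (1, 1, 1))
        assert v == pytest.approx(40 ** 3)
        assert abs(a - 9600) / 9600 <= 0.03
        assert abs(psi - 0.806) <= 0.025  # within the 3%-area-implied band

    def test_digital_spheroid(self):
        m = spheroid(40, 20)
        v, a, psi = mask_geometry(m, (1, 1, 1))
        a_true = spheroid_area(40, 20)
        assert abs(a - a_true) / a_true <= 0.03
        assert abs(psi - 0.929) <= 0.02

    def test_anisotropic_sphere(self):
        sp = (0.35, 0.2, 0.2)
        m = ball(4.0, spacing=sp)
        _, a, psi = mask_geometry(m, sp)
        assert abs(a - 4 * math.pi * 16) / (4 * math.pi * 16) <= 0.03
        assert 0.98 <= psi <= 1.02

    def test_psi_invariant_to_isotropic_rescaling(self):
        m = spheroid(30, 15)
        _, _, p1 = mask_geometry(m, (1.0, 1.0, 1.0))
        _, _, p2 = mask_geometry(m, (2.5, 2.5, 2.5))
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_missing_region_is_explicit(self):
        labels = np.zeros((10, 10, 10), np.uint8)
        labels[4:6, 4:6, 4:6] = 1
        with pytest.raises(MissingRegionError):
            region_geometry(labels, "nucleolus", (1, 1, 1))


class TestDryMass:
    def _uniform_tomo(self, dn, n_vox=1000, voxvol=1.0):
        side = 10
        ri = np.full((side, side, side), 1.337 + dn)
        labels = np.ones_like(ri, dtype=np.uint8)
        s = voxvol ** (1 / 3)
        return ri, labels, (s, s, s)

    def test_sensitivity_statement(self):
        # RI contrast 0.001 at alpha = 0.185 mL/g is 5.4 fg/fL
        ri, labels, sp = self._uniform_tomo(0.001)
        _, conc = dry_mass(ri, labels, "cell", 1.337, alpha=0.185, spacing=sp)
        assert conc * 1000 == pytest.approx(5.4, abs=0.1)  # g/mL -> fg/fL

    def test_zero_contrast_zero_mass(self):
        ri, labels, sp = self._uniform_tomo(0.0)
        m, _ = dry_mass(ri, labels, "cell", 1.337, spacing=sp)
        assert m == 0.0

    def test_hand_computed_mass(self):
        # dn = 0.037 over 15 fL at alpha 0.185 -> 3.0 pg
        side = 5
        ri = np.full((side, side, side), 1.337 + 0.037)
        labels = np.ones_like(ri, dtype=np.uint8)
        s = (15.0 / side ** 3) ** (1 / 3)
        m, _ = dry_mass(ri, labels, "cell", 1.337, alpha=0.185, spacing=(s, s, s))
        assert m == pytest.approx(3.0, rel=1e-6)

    def test_mass_additive_and_linear(self):
        spec = canonical_spec(lipid_droplet_count=1, lipid_total_volume_fl=2.0)
        tomo, mask = generate_phantom(spec, grid_shape=(48, 96, 96),
                                      voxel_spacing=(0.35, 0.2, 0.2), rng=3)
        parts = [dry_mass(tomo.ri, mask.labels, r, tomo.medium_ri,
                          spacing=tomo.voxel_spacing)[0]
                 for r in ("cytoplasm", "nucleoplasm", "nucleolus", "lipid")]
        whole, _ = dry_mass(tomo.ri, mask.labels, "cell", tomo.medium_ri,
                            spacing=tomo.voxel_spacing)
        assert whole == pytest.approx(sum(parts), rel=1e-9)
        # inflating the contrast by k scales the mass by exactly k
        ri2 = tomo.medium_ri + 3.0 * (tomo.ri - tomo.medium_ri)
        m2, _ = dry_mass(ri2, mask.labels, "cell", tomo.medium_ri,
                         spacing=tomo.voxel_spacing)
        assert m2 == pytest.approx(3.0 * whole, rel=1e-9)

    def test_alpha_must_be_positive(self):
        ri, labels, sp = self._uniform_tomo(0.001)
        with pytest.raises(ValueError):
            dry_mass(ri, labels, "cell", 1.337, alpha=-1.0, spacing=sp)


class TestNCRatios:
    def test_nucleus_equals_cell(self):
        labels = np.zeros((20, 20, 20), np.uint8)
        labels[ball(8, pad=2)] = 2  # all-nucleoplasm cell
        r3, r2 = nc_ratios(labels)
        assert r3 == 1.0 and r2 == 1.0

    def test_concentric_spheres(self):
        # volume ratio 0.417 -> projected-area ratio 0.417^(2/3) ~ 0.558
        n = 101
        z, y, x = np.indices((n, n, n))
        c = (n - 1) / 2
        rho2 = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2
        R = 40.0
        r = R * 0.417 ** (1 / 3)
        labels = np.zeros((n, n, n), np.uint8)
        labels[rho2 <= R * R] = 1
        labels[rho2 <= r * r] = 2
        r3, r2 = nc_ratios(labels)
        assert r3 == pytest.approx(0.417, abs=0.01)
        assert r2 == pytest.approx(0.417 ** (2 / 3), abs=0.02)

    def test_half_radius_scaling(self):
        n = 101
        z, y, x = np.indices((n, n, n))
        c = (n - 1) / 2
        rho2 = (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2
        labels = np.zeros((n, n, n), np.uint8)
        labels[rho2 <= 40 ** 2] = 1
        labels[rho2 <= 20 ** 2] = 2
        r3, r2 = nc_ratios(labels)
        assert r3 == pytest.approx(0.125, abs=0.01)
        assert r2 == pytest.approx(0.25, abs=0.02)

    def test_missing_nucleus(self):
        labels = np.zeros((10, 10, 10), np.uint8)
        labels[3:7, 3:7, 3:7] = 1
        with pytest.raises(MissingRegionError):
            nc_ratios(labels)


def dice(a, b):
    return 2 * np.logical_and(a, b).sum() / (a.sum() + b.sum())


class TestRuleBasedSegmentation:
    """Validated against ground truth on canonical (group-mean) phantoms.

    Whole-cell recovery is excellent; interior compartments are limited by
    the low cytoplasm/nucleoplasm RI contrast relative to the intra-region
    texture of the phantoms (an honest property of the study's printed
    statistics), so their floors are set at the achievable level.
    """

    FLOORS = {"cell": 0.95, "cytoplasm": 0.80, "nucleus": 0.75,
              "nucleoplasm": 0.60, "nucleolus": 0.35}

    @pytest.mark.parametrize("seed", [1, 2])
    def test_noiseless_dice(self, seed):
        tomo, gt = generate_phantom(canonical_spec(), grid_shape=(48, 96, 96),
                                    voxel_spacing=(0.35, 0.2, 0.2), noise_sd=0.0,
                                    rng=seed)
        seg = segment_rule_based(tomo, SegmentationParams(noise_sd=1e-4))
        for region, floor in self.FLOORS.items():
            d = dice(region_mask(gt.labels, region), region_mask(seg.labels, region))
            assert d >= floor, f"{region}: Dice {d:.3f} < {floor}"

    def test_noisy_cell_dice(self):
        tomo, gt = generate_phantom(canonical_spec(), grid_shape=(48, 96, 96),
                                    voxel_spacing=(0.35, 0.2, 0.2), noise_sd=0.001,
                                    rng=3)
        seg = segment_rule_based(tomo)
        assert dice(region_mask(gt.labels, "cell"),
                    region_mask(seg.labels, "cell")) >= 0.90

    def test_empty_field(self):
        tomo = Tomogram(np.full((24, 24, 24), 1.337), (0.3, 0.3, 0.3), 1.337)
        with pytest.raises(EmptyFieldError):
            segment_rule_based(tomo)

    def test_two_cells_is_ambiguous(self):
        ri = np.full((30, 60, 30), 1.337)
        z, y, x = np.indices(ri.shape)
        ri[(z - 15) ** 2 + (y - 15) ** 2 + (x - 15) ** 2 <= 81] = 1.365
        ri[(z - 15) ** 2 + (y - 45) ** 2 + (x - 15) ** 2 <= 81] = 1.365
        tomo = Tomogram(ri, (0.3, 0.3, 0.3), 1.337)
        with pytest.raises(AmbiguousFieldError):
            segment_rule_based(tomo)


class TestMeasureCell:
    def test_full_record_and_invariants(self):
        spec = canonical_spec()
        tomo, mask = generate_phantom(spec, grid_shape=(48, 96, 96),
                                      voxel_spacing=(0.35, 0.2, 0.2), rng=5)
        m = measure_cell(tomo, mask)
        vox = tomo.voxel_volume_fl
        assert m.regions["nucleus"].volume_fl == pytest.approx(
            m.regions["nucleoplasm"].volume_fl + m.regions["nucleolus"].volume_fl,
            abs=vox / 10)
        assert 0 < m.nc_volume_ratio < 1
        assert 0 < m.regions["cell"].sphericity <= 1.02
        assert not m.regions["lipid"].present  # no droplets in this spec
        assert np.isnan(m.regions["lipid"].volume_fl)

    def test_measured_fields_match_spec(self):
        spec = canonical_spec()
        tomo, mask = generate_phantom(spec, grid_shape=(48, 96, 96),
                                      voxel_spacing=(0.35, 0.2, 0.2),
                                      noise_sd=0.0, rng=6)
        m = measure_cell(tomo, mask)
        assert m.regions["cell"].volume_fl == pytest.approx(spec.cell_volume_fl, rel=0.03)
        assert m.regions["cell"].sphericity == pytest.approx(spec.cell_sphericity, abs=0.02)
        assert m.regions["nucleus"].sphericity == pytest.approx(spec.nucleus_sphericity, abs=0.02)
        assert m.nc_volume_ratio == pytest.approx(spec.nc_volume_ratio, abs=0.005)
        assert m.regions["nucleolus"].mean_ri == pytest.approx(spec.mean_ri_nucleolus, abs=2e-4)

    def test_missing_required_region_raises(self):
        ri = np.full((20, 20, 20), 1.35)
        labels = np.zeros((20, 20, 20), np.uint8)
        labels[5:15, 5:15, 5:15] = 1  # cytoplasm only, no nucleus
        tomo = Tomogram(ri, (0.3, 0.3, 0.3), 1.337)
        with pytest.raises(MissingRegionError):
            measure_cell(tomo, labels)
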