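"""Subcellular segmentation and morphometric parameters from RI tomograms.

A refractive-index (RI) tomogram assigns each voxel the local optical density,
which is linearly related to the biomolecular mass concentration through the
specific refractive increment alpha:  c = (n - n_m) / alpha.  From a labelled
partition of the cell into cytoplasm, nucleoplasm, nucleolus and lipid
droplets, this module computes the standard quantitative-phase parameters per
region: volume, surface area, sphericity, mean RI, dry mass and mean
concentration, plus the 3D and 2D (projected-area) nucleus-to-cell ratios.

Conventions
-----------
* Volumes are numpy arrays indexed ``(z, y, x)``; ``spacing`` is the matching
  ``(dz, dy, dx)`` physical voxel pitch in micrometres.
* 1 um^3 == 1 fL; concentrations in g/mL; dry mass in pg (1 g/mL * 1 fL = 1 pg).
* Sphericity: psi = pi^(1/3) (6 V)^(2/3) / A, unity for a sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure
from skimage.filters import threshold_otsu

__all__ = [
    "LABELS",
    "REGION_LABELS",
    "SegmentationMask",
    "SegmentationParams",
    "RegionMetrics",
    "CellMorphometry",
    "MissingRegionError",
    "EmptyFieldError",
    "AmbiguousFieldError",
    "region_mask",
    "mask_geometry",
    "region_geometry",
    "sphericity",
    "mean_ri",
    "dry_mass",
    "nc_ratios",
    "segment_rule_based",
    "measure_cell",
    "measure_batch",
]

#: Voxel label codes of the segmentation partition.
LABELS = {"background": 0, "cytoplasm": 1, "nucleoplasm": 2, "nucleolus": 3, "lipid": 4}

#: Composite regions as tuples of label codes.  The nucleus is the union of
#: nucleoplasm and nucleolus; the cell is everything that is not background.
REGION_LABELS: Mapping[str, tuple[int, ...]] = {
    "cell": (1, 2, 3, 4),
    "nucleus": (2, 3),
    "nucleoplasm": (2,),
    "nucleolus": (3,),
    "cytoplasm": (1,),
    "lipid": (4,),
}

#: Default specific refractive increment (mL/g).  With alpha = 0.185 mL/g an
#: RI contrast of 0.001 corresponds to 5.4 fg/fL of biomolecular mass.
DEFAULT_ALPHA = 0.185


class MissingRegionError(ValueError):
    """Requested region has no voxels in the mask."""

    def __init__(self, region: str):
        self.region = region
        super().__init__(f"region {region!r} is absent from the segmentation mask")


class EmptyFieldError(ValueError):
    """No voxels above the background threshold: nothing to segment."""


class AmbiguousFieldError(ValueError):
    """More than one similarly sized cell candidate in the field of view."""


@dataclass
class SegmentationMask:
    """Voxel label map over {background, cytoplasm, nucleoplasm, nucleolus, lipid}."""

    labels: np.ndarray
    provenance: str = "rule_based"  # or "ground_truth"

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if self.provenance not in ("rule_based", "ground_truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def region(self, name: str) -> np.ndarray:
        return region_mask(self.labels, name)

    def counts(self) -> dict[str, int]:
        return {name: int(region_mask(self.labels, name).sum()) for name in REGION_LABELS}


def region_mask(labels: np.ndarray, region: str) -> np.ndarray:
    """Boolean mask of a named (possibly composite) region."""
    try:
        codes = REGION_LABELS[region]
    except KeyError:
        raise KeyError(f"unknown region {region!r}; expected one of {sorted(REGION_LABELS)}")
    return np.isin(labels, codes)


def sphericity(volume: float, area: float) -> float:
    """psi = pi^(1/3) (6V)^(2/3) / A for V in um^3 and A in um^2."""
    if area <= 0:
        return math.nan
    return math.pi ** (1.0 / 3.0) * (6.0 * volume) ** (2.0 / 3.0) / area


def _crop_pad(mask: np.ndarray, pad: int = 1) -> np.ndarray:
    """Crop to the bounding box and zero-pad so iso-surfaces close at borders."""
    idx = np.nonzero(mask)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    return np.pad(sub, pad)


#: Scale (in units of the finest voxel pitch) of the smoothed normal field
#: used for the staircase correction of marching-cubes areas; see
#: :func:`mask_geometry`.
NORMAL_SMOOTH_VOX = 1.0


def mask_geometry(mask: np.ndarray, spacing: tuple[float, float, float],
                  normal_smooth_vox: float = NORMAL_SMOOTH_VOX) -> tuple[float, float, float]:
    """Volume (fL), surface area (um^2) and sphericity of a boolean mask.

    The volume is the voxel count times the physical voxel volume.  The
    surface area is measured on the marching-cubes iso-surface of the binary
    mask with a facet-normal projection correction: each triangle contributes
    ``A_t |n_t . n̂(x_t)|`` where ``n̂`` is the unit gradient of the Gaussian-
    smoothed mask at the triangle centroid.  For a staircase approximation of
    any plane this equals the projected (true) area exactly, removing the
    ~8-10% overestimation of raw marching-cubes areas on oblique and curved
    digital surfaces; the residual bias on closed-form solids (sphere, cube,
    2:1:1 spheroid) is validated to be below 3% in the test suite.
    """
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    spacing = np.asarray(spacing, dtype=np.float64)
    voxvol = float(np.prod(spacing))
    volume = n * voxvol
    pad = max(2, int(math.ceil(3 * normal_smooth_vox)))
    sub = _crop_pad(mask, pad=pad).astype(np.float32)
    verts, faces, _, _ = _skmeasure.marching_cubes(sub, level=0.5, spacing=tuple(spacing))
    tri = verts[faces]
    nvec = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    tri_area = 0.5 * np.linalg.norm(nvec, axis=1)
    if normal_smooth_vox <= 0:
        area = float(tri_area.sum())
        return volume, area, sphericity(volume, area)
    nf = nvec / np.maximum(np.linalg.norm(nvec, axis=1, keepdims=True), 1e-12)
    sig = [normal_smooth_vox * spacing.min() / s for s in spacing]
    smooth = ndimage.gaussian_filter(sub, sigma=sig)
    grads = np.gradient(smooth, *spacing)
    cent = (tri.mean(axis=1) / spacing).T
    g = np.stack([ndimage.map_coordinates(q, cent, order=1) for q in grads], axis=1)
    gn = np.linalg.norm(g, axis=1)
    ok = gn > 1e-8
    w = np.abs((nf[ok] * (g[ok] / gn[ok, None])).sum(axis=1))
    area = float((tri_area[ok] * w).sum() + tri_area[~ok].sum())
    return volume, area, sphericity(volume, area)


def region_geometry(
    mask_or_labels: np.ndarray | SegmentationMask,
    region: str,
    spacing: tuple[float, float, float],
) -> tuple[float, float, float]:
    """Volume (fL), surface area (um^2) and sphericity of a named region."""
    labels = mask_or_labels.labels if isinstance(mask_or_labels, SegmentationMask) else mask_or_labels
    mask = region_mask(labels, region)
    if not mask.any():
        raise MissingRegionError(region)
    return mask_geometry(mask, spacing)


def mean_ri(ri: np.ndarray, labels: np.ndarray, region: str) -> float:
    mask = region_mask(labels, region)
    if not mask.any():
        raise MissingRegionError(region)
    return float(ri[mask].mean())


def dry_mass(
    ri: np.ndarray,
    labels: np.ndarray,
    region: str,
    medium_ri: float,
    alpha: float = DEFAULT_ALPHA,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> tuple[float, float]:
    """Dry mass (pg) and mean concentration (g/mL) of a region.

    Per voxel ``c = (n - n_m) / alpha``; the region mass is the concentration
    integrated over the region volume.  Voxels below the medium RI contribute
    negatively (they are kept, matching the linear model).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    mask = region_mask(labels, region)
    if not mask.any():
        raise MissingRegionError(region)
    voxvol = float(np.prod(spacing))
    conc = (ri[mask].astype(np.float64) - medium_ri) / alpha  # g/mL
    mass = float(conc.sum() * voxvol)  # g/mL * fL = pg
    return mass, float(conc.mean())


def nc_ratios(labels: np.ndarray | SegmentationMask) -> tuple[float, float]:
    """3D volume and 2D projected-area nucleus-to-cell ratios.

    The 2D ratio uses axial (z) projections of the nucleus and cell masks,
    matching the en-face view of conventional microscopy; the contrast between
    the two ratios is exactly the 2D-vs-3D distinction that separates the
    genotype groups in volumetric analysis only.
    """
    if isinstance(labels, SegmentationMask):
        labels = labels.labels
    cell = region_mask(labels, "cell")
    nuc = region_mask(labels, "nucleus")
    if not nuc.any():
        raise MissingRegionError("nucleus")
    if not cell.any():
        raise MissingRegionError("cell")
    ratio3d = float(nuc.sum() / cell.sum())
    cell2d = cell.any(axis=0)
    nuc2d = nuc.any(axis=0)
    ratio2d = float(nuc2d.sum() / cell2d.sum())
    return ratio3d, ratio2d


# ---------------------------------------------------------------------------
# Rule-based segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    """Deterministic thresholds replacing interactive pixel classification.

    background_k
        Cell/background cut at ``n_m + background_k * noise_sd``.
    nucleolus_k
        Nucleoli are connected components brighter than the sigma-clipped
        nucleoplasm mean plus ``nucleolus_k`` standard deviations.
    lipid_ri
        Fixed RI cutoff for high-RI particulate (lipid-like) droplets in the
        cytoplasm.
    """

    noise_sd: float = 0.001
    background_k: float = 2.0
    smooth_sigma_um: float = 0.25
    interior_margin_um: float = 0.5
    closing_radius: int = 2
    nucleolus_k: float = 2.0
    nucleolus_min_fl: float = 1.0
    lipid_ri: float = 1.39
    lipid_min_fl: float = 0.2
    ambiguity_fraction: float = 0.5


def _largest_component(mask: np.ndarray, ambiguity_fraction: float | None = None) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        raise EmptyFieldError("no voxels above the background threshold")
    sizes = ndimage.sum_labels(np.ones_like(lab, dtype=np.int64), lab, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    if ambiguity_fraction is not None and n > 1 and sizes[order[1]] >= ambiguity_fraction * sizes[order[0]]:
        raise AmbiguousFieldError(
            f"two cell candidates of comparable size ({int(sizes[order[0]])} and "
            f"{int(sizes[order[1]])} voxels); expected a single cell in the field"
        )
    return lab == (order[0] + 1)


def segment_rule_based(tomogram, params: SegmentationParams | None = None) -> SegmentationMask:
    """Segment a single-cell tomogram into subcellular regions by fixed rules.

    Pipeline: Gaussian smoothing in physical units; cell = largest connected
    component above the background cut, morphologically closed and hole-filled;
    nucleus = largest hole-filled component of the brighter (Otsu) class inside
    the cell; nucleoli = bright outliers inside the nucleus (sigma-clipped
    nucleoplasm statistics); lipid droplets = components above a fixed RI
    cutoff in the cytoplasm.
    """
    p = params or SegmentationParams()
    ri = np.asarray(tomogram.ri, dtype=np.float64)
    spacing = tomogram.voxel_spacing
    n_m = tomogram.medium_ri
    sigma_vox = [p.smooth_sigma_um / s for s in spacing]
    smooth = ndimage.gaussian_filter(ri, sigma=sigma_vox)

    # floor the background cut at n_m + k*noise_sd, but when the field holds a
    # cell the whole-volume Otsu threshold separates it far more sharply than
    # the noise floor (smoothing otherwise bleeds the cell boundary outward)
    t_bg = n_m + p.background_k * p.noise_sd
    if (smooth > t_bg).any():
        try:
            t_bg = max(t_bg, float(threshold_otsu(smooth)))
        except ValueError:
            pass
    fg = smooth > t_bg
    if not fg.any():
        raise EmptyFieldError("no voxels above the background threshold")
    struct = ndimage.generate_binary_structure(3, 1)
    fg = ndimage.binary_closing(fg, structure=struct, iterations=p.closing_radius)
    cell = _largest_component(fg, p.ambiguity_fraction)
    cell = ndimage.binary_fill_holes(cell)

    # the cytoplasm/nucleus threshold is initialized on the cell interior only
    # (smoothing blends boundary voxels with the medium, which would otherwise
    # dominate the intensity histogram) and then refined by two-means
    # iteration: threshold at the midpoint of the class means, re-estimate
    # the means, repeat until stable
    depth = ndimage.distance_transform_edt(cell, sampling=spacing)
    interior = depth > p.interior_margin_um
    if not interior.any():
        interior = cell
    nucleus = np.zeros_like(cell)
    try:
        t = float(threshold_otsu(smooth[interior]))
    except ValueError:  # constant-intensity cell
        t = np.inf
    if np.isfinite(t):
        for _ in range(10):
            hi = interior & (smooth >= t)
            lo = interior & ~hi
            if not hi.any() or not lo.any():
                break
            t_new = 0.5 * (float(smooth[hi].mean()) + float(smooth[lo].mean()))
            if abs(t_new - t) < 1e-7:
                t = t_new
                break
            t = t_new
        nuc_cand = cell & (smooth >= t)
        if nuc_cand.any():
            close_r = max(1, int(round(0.3 / float(np.min(spacing)))))
            nuc_cand = ndimage.binary_closing(nuc_cand, structure=struct,
                                              iterations=close_r)
            try:
                nucleus = _largest_component(nuc_cand)
                nucleus = ndimage.binary_fill_holes(nucleus) & cell
            except EmptyFieldError:
                nucleus = np.zeros_like(cell)

    labels = np.zeros(ri.shape, dtype=np.uint8)
    labels[cell] = LABELS["cytoplasm"]
    labels[nucleus] = LABELS["nucleoplasm"]

    voxvol = float(np.prod(spacing))
    if nucleus.any():
        # sigma-clipped nucleoplasm statistics, then bright-outlier components
        nv = smooth[nucleus]
        mu, sd = float(nv.mean()), float(nv.std())
        for _ in range(8):
            keep = nv <= mu + p.nucleolus_k * sd
            if keep.all() or not keep.any():
                break
            mu2, sd2 = float(nv[keep].mean()), float(nv[keep].std())
            if abs(mu2 - mu) < 1e-7 and abs(sd2 - sd) < 1e-7:
                mu, sd = mu2, sd2
                break
            mu, sd = mu2, sd2
        if sd > 0:
            cand = nucleus & (smooth > mu + p.nucleolus_k * sd)
            cand = ndimage.binary_closing(cand, structure=struct)
            lab, ncomp = ndimage.label(cand)
            min_vox = max(1, int(round(p.nucleolus_min_fl / voxvol)))
            for i in range(1, ncomp + 1):
                comp = lab == i
                if comp.sum() >= min_vox:
                    comp = ndimage.binary_fill_holes(comp) & nucleus
                    labels[comp] = LABELS["nucleolus"]

    cyto = labels == LABELS["cytoplasm"]
    lip_cand = cyto & (smooth > p.lipid_ri)
    if lip_cand.any():
        lab, ncomp = ndimage.label(lip_cand)
        min_vox = max(1, int(round(p.lipid_min_fl / voxvol)))
        for i in range(1, ncomp + 1):
            comp = lab == i
            if comp.sum() >= min_vox:
                labels[comp] = LABELS["lipid"]

    return SegmentationMask(labels, provenance="rule_based")


# ---------------------------------------------------------------------------
# Full per-cell measurement
# ---------------------------------------------------------------------------

@dataclass
class RegionMetrics:
    present: bool
    volume_fl: float = math.nan
    surface_area_um2: float = math.nan
    sphericity: float = math.nan
    mean_ri: float = math.nan
    dry_mass_pg: float = math.nan
    concentration_g_ml: float = math.nan


#: Regions always required in a valid single-cell mask.
_REQUIRED = ("cell", "nucleus", "nucleoplasm", "cytoplasm")
#: Regions that may legitimately be absent.
_OPTIONAL = ("nucleolus", "lipid")


@dataclass
class CellMorphometry:
    """All numerical parameters of one cell (one tomogram)."""

    regions: dict[str, RegionMetrics] = field(default_factory=dict)
    nc_volume_ratio: float = math.nan
    nc_area_ratio_2d: float = math.nan

    def to_row(self) -> dict[str, float]:
        row: dict[str, float] = {}
        for name, m in self.regions.items():
            row[f"{name}_volume_fl"] = m.volume_fl
            row[f"{name}_surface_area_um2"] = m.surface_area_um2
            row[f"{name}_sphericity"] = m.sphericity
            row[f"{name}_mean_ri"] = m.mean_ri
            row[f"{name}_dry_mass_pg"] = m.dry_mass_pg
            row[f"{name}_concentration_g_ml"] = m.concentration_g_ml
        row["nc_volume_ratio"] = self.nc_volume_ratio
        row["nc_area_ratio_2d"] = self.nc_area_ratio_2d
        return row


def measure_cell(
    tomogram,
    mask: SegmentationMask | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    regions: Iterable[str] | None = None,
    with_geometry: bool = True,
) -> CellMorphometry:
    """Compute :class:`CellMorphometry` for one tomogram/mask pair.

    ``regions`` restricts the per-region metrics (the N/C ratios are always
    computed); geometry (surface area / sphericity) can be skipped for speed
    when only volumes, RIs and masses are needed.
    """
    labels = mask.labels if isinstance(mask, SegmentationMask) else np.asarray(mask)
    if labels.shape != tomogram.ri.shape:
        raise ValueError("mask and tomogram shapes differ")
    spacing = tomogram.voxel_spacing
    voxvol = float(np.prod(spacing))
    wanted = tuple(regions) if regions is not None else tuple(REGION_LABELS)

    out = CellMorphometry()
    for name in wanted:
        m = region_mask(labels, name)
        n = int(m.sum())
        if n == 0:
            if name in _REQUIRED:
                raise MissingRegionError(name)
            out.regions[name] = RegionMetrics(present=False)
            continue
        met = RegionMetrics(present=True, volume_fl=n * voxvol)
        if with_geometry:
            _, met.surface_area_um2, met.sphericity = region_geometry(labels, name, spacing)
        met.mean_ri = float(tomogram.ri[m].mean())
        met.dry_mass_pg, met.concentration_g_ml = dry_mass(
            tomogram.ri, labels, name, tomogram.medium_ri, alpha, spacing
        )
        out.regions[name] = met

    out.nc_volume_ratio, out.nc_area_ratio_2d = nc_ratios(labels)
    return out


def measure_batch(pairs, alpha: float = DEFAULT_ALPHA, regions=None, with_geometry=True):
    """Measure an iterable of ``(tomogram, mask)`` pairs into a DataFrame."""
    import pandas as pd

    rows = []
    for tomo, mask in pairs:
        rows.append(measure_cell(tomo, mask, alpha=alpha, regions=regions,
                                 with_geometry=with_geometry).to_row())
    return pd.DataFrame(rows)
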