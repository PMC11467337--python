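"""Core container types shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Tomogram", "DEFAULT_MEDIUM_RI", "DEFAULT_SPACING", "block_downsample"]

#: Refractive index of the phosphate-buffered-saline mounting medium (n_m).
DEFAULT_MEDIUM_RI = 1.337

#: Default physical voxel pitch in micrometres, array order (dz, dy, dx):
#: 0.312 um axial, 0.156 um lateral (typical for commercial holotomography).
DEFAULT_SPACING = (0.312, 0.156, 0.156)


@dataclass
class Tomogram:
    """A 3D refractive-index map: the unit of analysis.

    ``ri`` is indexed ``(z, y, x)``; ``voxel_spacing`` is the matching
    ``(dz, dy, dx)`` pitch in micrometres, and ``medium_ri`` the refractive
    index of the surrounding medium (n_m).  Physical units are attached here
    and at I/O boundaries only; all coordinates elsewhere are voxel indices.
    """

    ri: np.ndarray
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    medium_ri: float = DEFAULT_MEDIUM_RI
    image_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ri = np.asarray(self.ri)
        if self.ri.ndim != 3:
            raise ValueError("ri volume must be 3D (z, y, x)")
        if any(d <= 0 for d in self.ri.shape):
            raise ValueError("grid dimensions must be positive")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be three positive lengths (dz, dy, dx)")
        if not np.isfinite(self.ri).all():
            raise ValueError("ri volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ri.shape

    @property
    def voxel_volume_fl(self) -> float:
        return float(np.prod(self.voxel_spacing))


def block_downsample(volume: np.ndarray, factors: tuple[int, int, int]) -> np.ndarray:
    """Average-pool a (z, y, x) volume by integer factors per axis.

    Used to feed high-resolution tomograms to classifiers with smaller input
    grids: partial-volume averaging preserves sub-voxel morphology as gray
    values (trailing voxels that do not fill a block are dropped).
    """
    volume = np.asarray(volume)
    d, h, w = [s // f * f for s, f in zip(volume.shape, factors)]
    v = volume[:d, :h, :w]
    fz, fy, fx = factors
    return v.reshape(d // fz, fz, h // fy, fy, w // fx, fx).mean(axis=(1, 3, 5))
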