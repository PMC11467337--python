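"""Label-preserving augmentation of RI volumes.

Gaussian noise, random integer-voxel translation, horizontal (in-plane)
flips and rotation about the optical axis.  Translation and rotation pad
with the fill value (the medium RI, or 0 for medium-subtracted inputs);
the axial (z) axis is never flipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentParams", "augment_volume", "augment_batch"]


@dataclass
class AugmentParams:
    noise_sd: float = 0.002          # RI units (or normalized units)
    max_translation: tuple[int, int, int] = (2, 6, 6)  # voxels per (z, y, x)
    flip_axes: tuple[int, ...] = (1, 2)  # in-plane (y, x); z never flipped
    rotation_deg: float = 180.0      # uniform in [-r, r] about the z axis


def _translate(vol: np.ndarray, shift: tuple[int, int, int], fill: float) -> np.ndarray:
    out = np.full_like(vol, fill)
    src = [slice(max(0, -s), vol.shape[i] - max(0, s)) for i, s in enumerate(shift)]
    dst = [slice(max(0, s), vol.shape[i] - max(0, -s)) for i, s in enumerate(shift)]
    out[tuple(dst)] = vol[tuple(src)]
    return out


def augment_volume(vol: np.ndarray, params: AugmentParams,
                   rng: np.random.Generator, fill: float = 0.0) -> np.ndarray:
    """One random augmentation of a (D, H, W) volume."""
    out = vol
    if params.rotation_deg > 0:
        angle = float(rng.uniform(-params.rotation_deg, params.rotation_deg))
        out = ndimage.rotate(out, angle, axes=(1, 2), reshape=False, order=1,
                             mode="constant", cval=fill)
    if any(params.max_translation):
        limits = []
        for i, m in enumerate(params.max_translation):
            if m >= vol.shape[i]:
                warnings.warn(
                    f"translation limit {m} exceeds axis size {vol.shape[i]}; clipping",
                    stacklevel=2,
                )
                m = vol.shape[i] - 1
            limits.append(m)
        shift = tuple(int(rng.integers(-m, m + 1)) if m else 0 for m in limits)
        out = _translate(out, shift, fill)
    for ax in params.flip_axes:
        if rng.random() < 0.5:
            out = np.flip(out, axis=ax)
    if params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, size=out.shape)
    return np.ascontiguousarray(out, dtype=vol.dtype)


def augment_batch(batch: np.ndarray, params: AugmentParams,
                  rng: np.random.Generator, fill: float = 0.0) -> np.ndarray:
    """Augment each volume of a (N, D, H, W) batch independently."""
    return np.stack([augment_volume(v, params, rng, fill) for v in batch])
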