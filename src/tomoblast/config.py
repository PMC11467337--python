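"""Single-file YAML configuration for the end-to-end pipeline.

A :class:`PipelineConfig` captures every knob of a run -- phantom group
statistics, grid geometry, segmentation mode, classifier architecture,
training recipe, screening options and the master seed -- and round-trips
losslessly through YAML (``load(save(c)) == c``).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .core import DEFAULT_MEDIUM_RI, DEFAULT_SPACING
from .nn.augment import AugmentParams
from .nn.network import ArchConfig, FULL_ARCH, TINY_ARCH
from .nn.train import TrainConfig
from .phantom import (GroupParams, ParamDist, SplitConfig, mut_default_params,
                      wt_default_params)

__all__ = ["PipelineConfig", "load_config", "save_config", "preset"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "tomoblast_run"
    alpha: float = 0.185                     # specific refractive increment, mL/g
    medium_ri: float = DEFAULT_MEDIUM_RI
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    grid_shape: tuple[int, int, int] = (72, 160, 160)
    noise_sd: float = 0.001
    segmentation: str = "rule_based"         # or "ground_truth"
    min_voxel_span: float = 10.0             # smallest acceptable body span, voxels
    wt: GroupParams = field(default_factory=wt_default_params)
    mut: GroupParams = field(default_factory=mut_default_params)
    split: SplitConfig = field(default_factory=SplitConfig)
    arch: ArchConfig = field(default_factory=lambda: FULL_ARCH)
    train: TrainConfig = field(default_factory=TrainConfig)
    screen_split: str = "validation"         # which images feed the screen

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.segmentation not in ("rule_based", "ground_truth"):
            raise ValueError(f"unknown segmentation mode {self.segmentation!r}")
        if tuple(self.arch.input_shape) != tuple(self.grid_shape):
            raise ValueError(
                f"classifier input {self.arch.input_shape} != grid {self.grid_shape}"
            )
        for g in (self.wt, self.mut):
            for dist_field in ("cell_sphericity", "nucleus_sphericity"):
                d = getattr(g, dist_field)
                if not (0.0 < d.mean <= 1.0):
                    raise ValueError(
                        f"{g.name} {dist_field} mean {d.mean} outside (0, 1]"
                    )
                d.k_trunc()  # raises if bounds exclude the mean
        self.arch.validate()
        self.train.validate()


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


_TUPLE_FIELDS = {"voxel_spacing", "grid_shape", "input_shape", "max_translation",
                 "flip_axes", "nucleolus_count_range", "vaf_range", "ri_correlation"}


def _build(cls, data):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        t = f.type if isinstance(f.type, type) else None
        if f.name == "ri_correlation" and v is not None:
            v = tuple(tuple(row) for row in v)
        elif f.name in _TUPLE_FIELDS and v is not None:
            v = tuple(v)
        elif isinstance(v, dict) and f.name in _NESTED:
            v = _build(_NESTED[f.name], v)
        kwargs[f.name] = v
    return cls(**kwargs)


_NESTED = {"wt": GroupParams, "mut": GroupParams, "split": SplitConfig,
           "arch": ArchConfig, "train": TrainConfig, "augment": AugmentParams,
           "cell_volume": ParamDist, "cell_sphericity": ParamDist,
           "nc_volume_ratio": ParamDist, "nucleus_sphericity": ParamDist,
           "nucleolus_total_volume": ParamDist, "ri_cytoplasm": ParamDist,
           "ri_nucleoplasm": ParamDist, "ri_nucleolus": ParamDist}


def _build_nested(cls, data):
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name in _NESTED and isinstance(v, dict):
            v = _build_nested(_NESTED[f.name], v)
        elif f.name == "ri_correlation" and v is not None:
            v = tuple(tuple(row) for row in v)
        elif f.name in _TUPLE_FIELDS and v is not None:
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def save_config(config: PipelineConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    plain = _to_plain(config)
    path.write_text(yaml.safe_dump(plain, sort_keys=False))
    return path


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    return _build_nested(PipelineConfig, data)


def preset(name: str) -> PipelineConfig:
    """Built-in configurations.

    ``full``
        Published cohort sizes and grid (160x160x72 at 0.156/0.312 um);
        training at this scale needs GPU-class hardware and is not exercised
        by the test suite.
    ``tiny``
        A CPU-scale toy: 200 cells at 32x32x16 (0.45/0.7 um voxels), reduced
        cell volumes so phantoms fit the small grid, thin classifier, and a
        relaxed minimum voxel span (coarse toy resolution).
    """
    if name == "full":
        return PipelineConfig()
    if name == "tiny":
        wt = wt_default_params(image_count=87, patient_count=6)
        mut = mut_default_params(image_count=113, patient_count=6)
        for g in (wt, mut):
            g.cell_volume = ParamDist(140.0, 20.0, lo=105.0, hi=175.0)
            g.cell_sphericity = ParamDist(g.cell_sphericity.mean, 0.03, lo=0.72, hi=0.92)
            g.nucleolus_total_volume = ParamDist(6.0, 2.0, lo=1.5)
            g.nc_volume_ratio = ParamDist(g.nc_volume_ratio.mean, 0.05, lo=0.3, hi=0.55)
        split = SplitConfig(val_patients_per_group=2)
        return PipelineConfig(
            grid_shape=(16, 32, 32), voxel_spacing=(0.75, 0.45, 0.45),
            wt=wt, mut=mut, split=split, arch=TINY_ARCH,
            segmentation="ground_truth", min_voxel_span=5.0,
            train=TrainConfig(epochs=8),
        )
    raise KeyError(f"unknown preset {name!r} (expected 'tiny' or 'full')")
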