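"""NIfTI volume I/O and YAML run configuration.

Arrays are written in index order with a diagonal affine built from the
voxel spacing, so a round trip preserves both values (float32) and spacing.
2D slices are stored as single-slice 3D volumes and can be squeezed back on
read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml


def write_volume(volume: np.ndarray, path, spacing=None) -> Path:
    """Write a 2D/3D array as NIfTI; 2D input becomes a single-slice 3D."""
    arr = np.asarray(volume)
    if arr.ndim == 2:
        arr = arr[:, :, None]
        if spacing is not None and len(spacing) == 2:
            spacing = (*spacing, 1.0)
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D or 3D array, got ndim={arr.ndim}")
    if spacing is None:
        spacing = (1.0, 1.0, 1.0)
    affine = np.diag([*map(float, spacing), 1.0])
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    elif arr.dtype not in (np.uint8, np.int16, np.int32):
        arr = arr.astype(np.float32)
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms(tuple(map(float, spacing)))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, path)
    return path


def read_volume(path, squeeze: bool = False):
    """Read a NIfTI volume; returns (array, spacing in mm per axis).

    ``squeeze=True`` drops trailing singleton axes so a stored 2D slice
    comes back as 2D (with 2-tuple spacing).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume not found: {path}")
    try:
        img = nib.load(path)
        arr = np.asanyarray(img.dataobj)
    except Exception as exc:  # corrupt file
        raise IOError(f"cannot read NIfTI volume {path}: {exc}") from exc
    spacing = tuple(float(z) for z in img.header.get_zooms()[:arr.ndim])
    if squeeze:
        while arr.ndim > 2 and arr.shape[-1] == 1:
            arr = arr[..., 0]
            spacing = spacing[:-1]
    return arr, spacing


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    phantom: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    loss: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    _SECTIONS = ("phantom", "artifacts", "network", "loss", "train",
                 "gamma", "paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls._SECTIONS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**{k: raw.get(k, {}) for k in cls._SECTIONS})

    def resolve(self):
        """Instantiate the typed configs (validates every field name)."""
        from .losses import LossConfig
        from .metrics import GammaConfig
        from .phantom import ArtifactParams, PhantomConfig
        from .training import TrainConfig
        from .transformer import NetworkConfig

        def build(cls_, d, name):
            try:
                return cls_.from_dict(d) if hasattr(cls_, "from_dict") \
                    else cls_(**d)
            except TypeError as exc:
                raise ValueError(f"bad key in [{name}]: {exc}") from exc

        return {
            "phantom": build(PhantomConfig, self.phantom, "phantom"),
            "artifacts": build(ArtifactParams, self.artifacts, "artifacts"),
            "network": build(NetworkConfig, self.network, "network"),
            "loss": build(LossConfig, self.loss, "loss"),
            "train": build(TrainConfig, self.train, "train"),
            "gamma": build(GammaConfig, self.gamma, "gamma"),
        }

    def dump(self, path):
        data = {k: getattr(self, k) for k in self._SECTIONS}
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
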