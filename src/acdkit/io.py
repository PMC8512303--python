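"""File formats and pipeline configuration.

Label images are integer TIFF (one label per cell, background 0);
intensity images 16-bit TIFF; tables CSV; fitted parameters and ground
truth JSON; configuration YAML.  Pixel size is configuration, never read
from file metadata.  All lengths are um, areas um^2, times minutes,
angles degrees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml


class FormatError(ValueError):
    pass


def read_label_image(path) -> np.ndarray:
    """Read an integer-labelled TIFF; rejects float-valued files."""
    arr = tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"{path}: label images must be integer-valued, got {arr.dtype}")
    return arr.astype(np.int32)


def read_intensity_image(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_label_image(path, labels) -> None:
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise FormatError("label image must be integer-valued")
    tifffile.imwrite(path, labels.astype(np.int32))


def write_intensity_image(path, intensity) -> None:
    arr = np.clip(np.asarray(intensity, dtype=float), 0, 65535)
    tifffile.imwrite(path, arr.astype(np.uint16))


def check_paired_shapes(label_image, intensity_image) -> None:
    if np.asarray(label_image).shape != np.asarray(intensity_image).shape:
        raise FormatError("label and intensity images differ in shape")


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, (np.bool_,)):
        return bool(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_json_default) + "\n")


@dataclass
class PipelineConfig:
    """Parameters of an end-to-end run.

    The defaults are the study conventions: 120 um^2 small-cell threshold,
    clusters of four or more cells, a 60-degree polarization cut-off and
    alpha = 0.05.  Each stage block (``tissue``, ``profiles``, ``lineage``,
    ``pairs``) is either a dict of synthetic-generator parameters or
    ``{"path": ...}`` pointing at input files.
    """

    pixel_size_um: float = 1.0
    small_threshold_um2: float = 120.0
    min_cluster_size: int = 4
    polarity_cutoff_deg: float = 60.0
    frame_interval_min: float = 40.0
    alpha: float = 0.05
    seeds: dict = field(default_factory=lambda: {
        "tissue": 1, "profiles": 2, "lineage": 3, "pairs": 4, "permutation": 5})
    tissue: Optional[dict] = field(default_factory=dict)
    profiles: Optional[dict] = field(default_factory=dict)
    lineage: Optional[dict] = field(default_factory=dict)
    pairs: Optional[dict] = field(default_factory=dict)
    n_perm: int = 999

    def __post_init__(self):
        for name in ("pixel_size_um", "small_threshold_um2",
                     "polarity_cutoff_deg", "frame_interval_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
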