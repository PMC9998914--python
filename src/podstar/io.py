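"""Volume and table I/O plus run configuration.

Volumes are multi-page TIFF stacks, one 2D slice per page, axis order
(Z, Y, X): the page index is the slice (Z) coordinate.  Seed reports are
RFC-4180 CSV with a fixed column order: the location block (bounding box
and centroid per axis), the size/shape block, and the valve block.
Bounding boxes are half-open [min, max) per axis and all voxel
coordinates are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "PipelineConfig",
    "SEED_TABLE_COLUMNS",
    "read_volume",
    "write_volume",
    "write_seed_table",
    "read_seed_table",
]


@dataclass
class ImageVolume:
    """3D grayscale intensity volume, axis order (Z, Y, X)."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("image volume must be 3D with all dimensions >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """3D instance-label volume: 0 = background, k > 0 = instance k."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label volume must be integer-typed")
        if self.data.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def ids(self) -> np.ndarray:
        ids = np.unique(self.data)
        return ids[ids > 0]


@dataclass
class PipelineConfig:
    """Run configuration shared by the CLI subcommands.

    threshold_mode is either "otsu" or a fixed intensity value given as
    threshold_value.  score_threshold and nms_threshold control candidate
    pruning; taus is the IoU-threshold grid for evaluation; n_rays and
    anisotropy parameterize the ray lattice; lowess_f overrides the
    smoother span for valve sorting (None = automatic); seed drives every
    random choice.
    """

    threshold_mode: str = "otsu"
    threshold_value: float | None = None
    score_threshold: float = 0.4
    nms_threshold: float = 0.4
    taus: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    n_rays: int = 96
    anisotropy: tuple[float, float, float] = (1.0, 1.0, 1.0)
    min_volume: int = 30
    lowess_f: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("score_threshold", "nms_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_rays < 4:
            raise ValueError("n_rays must be >= 4")
        a = tuple(float(v) for v in self.anisotropy)
        if min(a) < 1.0 or abs(min(a) - 1.0) > 1e-9:
            raise ValueError("anisotropy components must be >= 1 with min exactly 1")
        self.anisotropy = a

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a plain-text key=value file; keyword overrides win."""
        values: dict = {}
        names = {f.name: f for f in fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key = key.strip()
            if key not in names:
                raise ValueError(f"unknown configuration key: {key}")
            values[key] = _parse_value(key, val.strip())
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


def _parse_value(key: str, text: str):
    if key == "threshold_mode":
        return text
    if key in ("taus", "anisotropy"):
        return tuple(float(t) for t in text.split(","))
    if key in ("n_rays", "min_volume", "seed"):
        return int(text)
    if text.lower() in ("none", ""):
        return None
    return float(text)


def read_volume(path: str | Path, as_labels: bool = False) -> ImageVolume | LabelVolume:
    """Read a multi-page TIFF stack as a (Z, Y, X) volume.

    With as_labels=True the data must be integer-typed and is returned as a
    LabelVolume.
    """
    try:
        data = tifffile.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - surface a uniform error
        raise OSError(f"could not read TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None, ...]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a stack of 2D pages, got ndim={data.ndim}")
    if as_labels:
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"{path}: label volume must be integer-typed, got {data.dtype}")
        return LabelVolume(data)
    return ImageVolume(data)


def write_volume(volume: ImageVolume | LabelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF, one page per Z slice."""
    # photometric is explicit so 3-slice stacks are not guessed to be RGB
    tifffile.imwrite(str(path), np.asarray(volume.data), photometric="minisblack")


# Location block mirrors the per-seed report's bounding-box/centroid schema;
# size/shape block follows; valve block is appended by valve sorting.
SEED_TABLE_COLUMNS = [
    "Seed ID Number",
    "Z-axis minimum",
    "Y-axis minimum",
    "X-axis minimum",
    "Z-axis maximum",
    "Y-axis maximum",
    "X-axis maximum",
    "Z-axis centroid",
    "Y-axis centroid",
    "X-axis centroid",
    "Volume",
    "Bounding box volume",
    "Sphericity",
    "Surface area",
    "Convex volume",
    "Equivalent diameter",
    "Extent",
    "Major axis length",
    "Minor axis length",
    "Solidity",
    "valve",
    "sequence_in_valve",
    "spacing_to_previous",
]


def write_seed_table(records: list[dict], path: str | Path) -> None:
    """Write seed records as CSV with the fixed column order.

    Missing fields (e.g. valve columns before sorting) are left empty.  An
    empty record list writes a header-only file.
    """
    frame = pd.DataFrame(records, columns=SEED_TABLE_COLUMNS)
    frame.to_csv(path, index=False)


def read_seed_table(path: str | Path) -> pd.DataFrame:
    """Read a seed-record CSV back into a DataFrame."""
    return pd.read_csv(path)
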