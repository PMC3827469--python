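"""Readers, writers, configuration, and provenance helpers.

Conventions: all tables are TSV with a header row (UTF-8, '.' decimal);
models and stratifications are JSON; images are PNG or TIFF (8/16-bit
grayscale for intensities, 16-bit for label maps).  Every pipeline run logs
its resolved configuration and a hash of it, so outputs are traceable to
their parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from nucleomorph.cohort import IntervalSpec
from nucleomorph.scoring import ScoreModel
from nucleomorph.segmentation import SegmentationConfig

__all__ = [
    "PipelineConfig",
    "load_config",
    "config_hash",
    "read_image",
    "write_image",
    "read_label_map",
    "write_label_map",
    "read_table",
    "write_table",
    "write_model",
    "read_model",
    "write_json",
    "read_json",
]

FLOAT_FORMAT = "%.10g"


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    segmentation: SegmentationConfig = dataclasses.field(default_factory=SegmentationConfig)
    intervals: IntervalSpec = dataclasses.field(default_factory=IntervalSpec)
    weight_function: str = "bisquare"
    k: int | str = "auto"
    k_max: int = 16
    kmeans_seeds: int = 10000
    seed: int = 0
    tile_size: int = 4096

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["intervals"] = {"low": list(self.intervals.low), "high": list(self.intervals.high)}
        return d


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional TOML file + overrides.

    TOML sections ``[segmentation]`` and ``[intervals]`` map onto the nested
    configs; top-level keys map onto the remaining fields.  Unknown keys
    raise, so typos never pass silently.
    """
    data: dict = {}
    if path is not None:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    data.update(overrides)
    seg = SegmentationConfig(**data.pop("segmentation", {}))
    iv_raw = data.pop("intervals", {})
    iv = IntervalSpec(
        low=tuple(iv_raw.get("low", (1.0, 2.0))),
        high=tuple(iv_raw.get("high", (6.0, 10.0))),
    )
    known = {f.name for f in dataclasses.fields(PipelineConfig)} - {"segmentation", "intervals"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
    return PipelineConfig(segmentation=seg, intervals=iv, **data)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the resolved configuration (changes iff any parameter does)."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --- images ---------------------------------------------------------------


def write_image(path: str | Path, image: np.ndarray, bits: int = 8) -> None:
    """Write a [0, 1] float image as 8- or 16-bit grayscale PNG/TIFF."""
    path = Path(path)
    scale = 255 if bits == 8 else 65535
    arr = np.clip(np.asarray(image, dtype=float), 0, 1)
    arr = (arr * scale + 0.5).astype(np.uint8 if bits == 8 else np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF image as float in [0, 1] (RGB kept as 3 channels)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
    arr = arr.astype(float)
    return arr / info.max if info is not None else arr


def write_label_map(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map as 16-bit PNG/TIFF (labels must fit in uint16)."""
    path = Path(path)
    labels = np.asarray(labels)
    if labels.max() > 65535:
        raise ValueError("label map exceeds 16-bit range")
    arr = labels.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_label_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    return arr.astype(np.int32)


# --- tables and models ----------------------------------------------------


def write_table(path: str | Path, table: pd.DataFrame, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_model(path: str | Path, model: ScoreModel) -> None:
    Path(path).write_text(model.to_json())


def read_model(path: str | Path) -> ScoreModel:
    return ScoreModel.from_json(Path(path).read_text())


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
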