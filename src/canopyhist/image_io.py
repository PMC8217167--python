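"""Reading and writing canopy photographs, sample tables and feature tables.

The package treats a canopy photograph as a plain 8-bit RGB raster
(row-major, origin top-left); no geometric or radiometric calibration is
attempted.  Sample metadata travels in a flat CSV with one row per image.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import os
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_TABLE_COLUMNS = (
    "sample_id",
    "image_path",
    "cultivar",
    "stage",
    "n_level",
    "leaf_n",
    "yield",
)


class Stage(str, enum.Enum):
    """Growth stage of winter wheat at image acquisition."""

    REVIVING = "reviving"
    JOINTING = "jointing"

    @classmethod
    def parse(cls, token: str) -> "Stage":
        try:
            return cls(str(token).strip().lower())
        except ValueError:
            valid = ", ".join(s.value for s in cls)
            raise ValueError(
                f"unknown growth stage {token!r}; expected one of: {valid}"
            ) from None


@dataclasses.dataclass
class CanopyImage:
    """An 8-bit RGB canopy photograph plus sample metadata.

    ``pixels`` has shape (height, width, 3) and dtype uint8.
    """

    pixels: np.ndarray
    sample_id: str = ""
    cultivar: str = ""
    stage: Optional[Stage] = None
    n_level: float = 0.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(
                f"canopy image must be an (H, W, 3) raster, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("canopy image must contain at least one pixel")
        if px.dtype != np.uint8:
            raise ValueError(f"canopy image must be 8-bit, got dtype {px.dtype}")
        if self.n_level < 0:
            raise ValueError("n_level must be nonnegative")
        self.pixels = px

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclasses.dataclass
class SampleRecord:
    """One row of the sample table: an image and its agronomic measurements.

    ``leaf_n`` (% of leaf dry mass) and ``grain_yield`` (kg ha^-1) may be
    None for prediction-only samples.
    """

    sample_id: str
    image_path: str
    cultivar: str
    stage: Stage
    n_level: float
    leaf_n: Optional[float] = None
    grain_yield: Optional[float] = None

    def __post_init__(self) -> None:
        if self.leaf_n is not None and not self.leaf_n > 0:
            raise ValueError(
                f"sample {self.sample_id!r}: leaf_n must be positive when present"
            )
        if self.grain_yield is not None and not self.grain_yield > 0:
            raise ValueError(
                f"sample {self.sample_id!r}: yield must be positive when present"
            )

    @property
    def has_targets(self) -> bool:
        return self.leaf_n is not None and self.grain_yield is not None

    def target(self, name: str) -> Optional[float]:
        if name == "leaf_n":
            return self.leaf_n
        if name == "yield":
            return self.grain_yield
        raise KeyError(f"unknown target {name!r}; expected 'leaf_n' or 'yield'")


def read_image(path: os.PathLike | str, **metadata) -> CanopyImage:
    """Read a PNG/JPEG/TIFF photograph into a :class:`CanopyImage`.

    Grayscale input is replicated across the three channels, an alpha
    channel is dropped, and 16-bit sources are rescaled to 0-255 by the
    factor 257 (65535/255).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # codec errors vary by backend
        raise IOError(f"cannot decode image file {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.size == 0:
        raise ValueError(f"image {path} is empty")
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise IOError(f"image {path} is not a 2-D raster (shape {arr.shape})")
    if arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise IOError(f"image {path} has {arr.shape[2]} channels; expected 1, 3 or 4")
    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(np.float64) / 257.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise IOError(f"image {path} has unsupported dtype {arr.dtype}")
    return CanopyImage(pixels=arr, **metadata)


def write_image(image: CanopyImage, path: os.PathLike | str) -> None:
    """Write a canopy image losslessly (PNG recommended)."""
    iio.imwrite(Path(path), image.pixels)


def _parse_optional(value, row: int, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: cannot parse {column}={value!r} as a number")


def read_sample_table(path: os.PathLike | str) -> list[SampleRecord]:
    """Read the sample CSV into a list of :class:`SampleRecord`, in file order."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "cultivar": str, "stage": str})
    missing = [c for c in SAMPLE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample table {path} is missing columns: {missing}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample_id values in {path}: {sorted(set(dup))}")
    records = []
    for i, row in enumerate(df.to_dict(orient="records")):
        try:
            stage = Stage.parse(row["stage"])
        except ValueError as exc:
            raise ValueError(f"row {i} (sample {row['sample_id']!r}): {exc}") from None
        rec = SampleRecord(
            sample_id=str(row["sample_id"]),
            image_path=str(row["image_path"]),
            cultivar=str(row["cultivar"]),
            stage=stage,
            n_level=float(row["n_level"]),
            leaf_n=_parse_optional(row["leaf_n"], i, "leaf_n"),
            grain_yield=_parse_optional(row["yield"], i, "yield"),
        )
        records.append(rec)
    n_untargeted = sum(not r.has_targets for r in records)
    if n_untargeted:
        logger.info("%d of %d samples lack targets (prediction-only)", n_untargeted, len(records))
    return records


def write_sample_table(records: Sequence[SampleRecord], path: os.PathLike | str) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "image_path": r.image_path,
            "cultivar": r.cultivar,
            "stage": r.stage.value,
            "n_level": r.n_level,
            "leaf_n": r.leaf_n if r.leaf_n is not None else "",
            "yield": r.grain_yield if r.grain_yield is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_TABLE_COLUMNS)).to_csv(path, index=False)


@dataclasses.dataclass
class Cohort:
    """A set of samples sharing one growth stage: records plus their images.

    ``images`` maps sample_id to the in-memory :class:`CanopyImage`;
    ``ground_truth`` (optional) carries the latent state of simulated
    cohorts.
    """

    records: list[SampleRecord]
    images: dict[str, CanopyImage]
    ground_truth: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        missing = [r.sample_id for r in self.records if r.sample_id not in self.images]
        if missing:
            raise ValueError(f"samples missing their image: {missing}")

    @property
    def stage(self) -> Stage:
        stages = {r.stage for r in self.records}
        if len(stages) != 1:
            raise ValueError(f"cohort mixes growth stages: {sorted(s.value for s in stages)}")
        return next(iter(stages))


def load_cohort(directory: os.PathLike | str) -> Cohort:
    """Load a cohort directory written by the simulator or assembled by hand.

    Expects ``samples.csv`` with image paths relative to the directory, and
    optionally ``ground_truth.csv``.
    """
    directory = Path(directory)
    records = read_sample_table(directory / "samples.csv")
    images = {}
    for rec in records:
        img_path = directory / rec.image_path
        images[rec.sample_id] = read_image(
            img_path,
            sample_id=rec.sample_id,
            cultivar=rec.cultivar,
            stage=rec.stage,
            n_level=rec.n_level,
        )
    gt_path = directory / "ground_truth.csv"
    gt = pd.read_csv(gt_path) if gt_path.exists() else None
    return Cohort(records=records, images=images, ground_truth=gt)
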