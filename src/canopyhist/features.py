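"""Feature extraction from color-index rasters.

Two feature families are produced from each canopy photograph:

* **IIMV** (index-image mean value): the mean of a color-index raster over
  the vegetation component — one number per index, the traditional feature.
* **IIH** (index-image histogram): per-bin pixel percentages of an index
  raster over a fixed range — a curve that encodes both the hue of the
  vegetation (position of the crop peak) and the fractional plant coverage
  (relative mass of the soil and crop peaks).

A bimodal index histogram has a left peak (*a*, soil pixels) and a right
peak (*b*, crop pixels).  Informative histogram regions are selected by
correlating each bin's percentage with the diagnosis target across
samples, inside a window centred on the crop peak of a cohort-template
histogram.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .color_index import INDEX_NAMES, IndexRaster, compute_index
from .image_io import CanopyImage, SampleRecord

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 256


@dataclasses.dataclass
class VegetationMask:
    """Boolean vegetation raster plus the fractional coverage it implies."""

    mask: np.ndarray
    coverage: float
    threshold: float


@dataclasses.dataclass
class HistogramFeature:
    """Normalized index-image histogram with optional soil/crop peak bins."""

    bin_edges: np.ndarray          # n_bins + 1 ascending edges
    percentages: np.ndarray        # n_bins values summing to 100
    index_name: str
    peak_a_bin: Optional[int] = None   # left (soil) peak
    peak_b_bin: Optional[int] = None   # right (crop) peak
    smoothed: Optional[np.ndarray] = None
    flat: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.percentages)

    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclasses.dataclass
class BinSelection:
    """The histogram bins retained as model inputs, with their correlations."""

    index_name: str
    bin_indices: list[int]
    per_bin_correlation: list[float]
    target_name: str
    bin_edges: np.ndarray
    policy: str = "peak_window_corr"
    params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bin_indices:
            raise ValueError("bin selection must be nonempty")
        if any(b >= a for a, b in zip(self.bin_indices[1:], self.bin_indices[:-1])):
            raise ValueError("bin_indices must be strictly increasing")
        if any(abs(r) > 1 + 1e-12 for r in self.per_bin_correlation):
            raise ValueError("correlations must lie in [-1, 1]")

    def to_json(self, path) -> None:
        payload = {
            "index_name": self.index_name,
            "bin_indices": [int(b) for b in self.bin_indices],
            "per_bin_correlation": [float(r) for r in self.per_bin_correlation],
            "target_name": self.target_name,
            "bin_edges": [float(e) for e in self.bin_edges],
            "policy": self.policy,
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "BinSelection":
        with open(path) as fh:
            payload = json.load(fh)
        payload["bin_edges"] = np.asarray(payload["bin_edges"])
        return cls(**payload)


@dataclasses.dataclass
class SelectionPolicy:
    """How histogram bins are filtered into model inputs.

    ``peak_window_corr`` (default): keep bins within a ``window``-bin span
    centred on the template's crop peak whose |r| exceeds ``r_min``; if
    fewer than ``k_min`` survive, fall back to the ``k_min`` largest-|r|
    bins inside the window; if more than ``k_max`` survive, keep the
    ``k_max`` largest-|r| of them, so the network input stays modest
    relative to a 60-sample training set (adjacent bins are strongly
    collinear and add little).  ``global_corr``: the ``top_k`` largest-|r|
    bins anywhere.
    """

    policy: str = "peak_window_corr"
    window: int = 41
    r_min: float = 0.5
    k_min: int = 8
    k_max: int = 12
    top_k: int = 20


@dataclasses.dataclass
class FeatureMatrix:
    """Samples x features matrix aligned with per-sample targets."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    targets: pd.DataFrame  # index sample_id, columns leaf_n / yield (may hold NaN)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")

    def rows(self, sample_ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.values[[pos[s] for s in sample_ids]]

    def target_vector(self, name: str, sample_ids: Sequence[str]) -> np.ndarray:
        return self.targets.loc[list(sample_ids), name].to_numpy(dtype=np.float64)


def segment_vegetation(
    image: CanopyImage, threshold: Optional[float] = None
) -> VegetationMask:
    """Split the frame into vegetation and background pixels.

    The split is made on the normalized green-minus-red index GMRN, which
    highlights vegetation: pixels above the threshold are vegetation.  By
    default the threshold is Otsu's bimodal split of the valid GMRN values;
    pass ``threshold`` to override with a fixed cut.
    """
    raster = compute_index(image, "GMRN")
    valid = raster.valid_mask
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError(
            f"sample {image.sample_id!r}: no valid pixels to segment (all black)"
        )
    vals = raster.values[valid]
    if threshold is None:
        if np.ptp(vals) == 0.0:
            # constant raster: no soil/vegetation contrast; call it all vegetation
            logger.info(
                "sample %s: constant GMRN raster, treating whole frame as vegetation",
                image.sample_id,
            )
            threshold = vals[0] - 1.0
        else:
            threshold = float(threshold_otsu(vals))
    mask = valid & (raster.values > threshold)
    coverage = int(mask.sum()) / n_valid
    return VegetationMask(mask=mask, coverage=coverage, threshold=float(threshold))


def iimv(index_raster: IndexRaster, mask: Optional[VegetationMask] = None) -> float:
    """Index-image mean value: mean of the raster over the vegetation pixels.

    With ``mask=None`` the mean is over all valid pixels (whole-frame mode).
    An empty vegetation mask falls back to all valid pixels, with a log
    notice, so a fully vegetated or fully bare frame still yields a value.
    """
    valid = index_raster.valid_mask
    if not valid.any():
        raise ValueError(f"index {index_raster.index_name}: no valid pixels")
    if mask is None:
        sel = valid
    else:
        sel = valid & mask.mask
        if not sel.any():
            logger.info(
                "index %s: empty vegetation mask, falling back to all valid pixels",
                index_raster.index_name,
            )
            sel = valid
    return float(index_raster.values[sel].mean())


def histogram(index_raster: IndexRaster, n_bins: int = DEFAULT_N_BINS) -> HistogramFeature:
    """Equal-width percentage histogram of an index raster over its fixed range.

    Bins are right-open except the last (closed); values outside the range
    (possible only for the clipped GR/GB indices) are counted in the end
    bins.  Percentages sum to 100 over the valid pixels.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = index_raster.valid_values()
    if vals.size == 0:
        raise ValueError(f"index {index_raster.index_name}: no valid pixels to histogram")
    lo, hi = index_raster.theoretical_range
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.clip(vals, lo, hi), bins=edges)
    percentages = 100.0 * counts / counts.sum()
    return HistogramFeature(
        bin_edges=edges, percentages=percentages, index_name=index_raster.index_name
    )


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window % 2 != 1 or window < 1:
        raise ValueError("smooth_window must be a positive odd integer")
    if window == 1:
        return x.astype(np.float64)
    pad = window // 2
    padded = np.pad(x.astype(np.float64), pad, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _local_maxima(s: np.ndarray) -> list[int]:
    """Indices of local maxima; an endpoint counts only if it strictly
    dominates its single neighbor, and zero-height bins never qualify."""
    n = len(s)
    out = []
    for i in range(n):
        if s[i] <= 0.0:
            continue
        if i == 0:
            if n > 1 and s[0] > s[1]:
                out.append(i)
        elif i == n - 1:
            if s[i] > s[i - 1]:
                out.append(i)
        elif s[i] >= s[i - 1] and s[i] >= s[i + 1] and (
            s[i] > s[i - 1] or s[i] > s[i + 1]
        ):
            out.append(i)
    return out


def detect_peaks(
    hist: HistogramFeature, smooth_window: int = 5, min_separation: int = 20
) -> HistogramFeature:
    """Locate the soil (*a*) and crop (*b*) peaks of an index histogram.

    The curve is smoothed with a centred moving average, local maxima are
    ranked by height, and the two tallest maxima at least
    ``min_separation`` bins apart become peak *a* (smaller bin index) and
    peak *b* (larger).  A single detectable maximum is assigned by its
    position relative to the range midpoint.  A flat histogram has no
    peaks and is flagged.
    """
    smoothed = _moving_average(hist.percentages, smooth_window)
    out = dataclasses.replace(hist, smoothed=smoothed)
    if np.ptp(smoothed) == 0.0:
        out.flat = True
        out.peak_a_bin = out.peak_b_bin = None
        logger.info("index %s: flat histogram, no peaks detected", hist.index_name)
        return out
    maxima = _local_maxima(smoothed)
    maxima.sort(key=lambda i: (-smoothed[i], i))
    first = maxima[0]
    second = next((i for i in maxima[1:] if abs(i - first) >= min_separation), None)
    if second is None:
        midpoint = hist.n_bins / 2.0
        if first < midpoint:
            out.peak_a_bin, out.peak_b_bin = first, None
        else:
            out.peak_a_bin, out.peak_b_bin = None, first
    else:
        out.peak_a_bin, out.peak_b_bin = sorted((first, second))
    return out


def bin_correlations(hist_matrix: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Pearson correlation of each histogram bin with the target, across samples.

    Bins whose percentage is constant across samples get r = 0 by
    convention (rather than NaN).
    """
    H = np.asarray(hist_matrix, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    if H.ndim != 2 or H.shape[0] != y.shape[0]:
        raise ValueError("hist_matrix rows must align with target samples")
    if H.shape[0] < 3:
        raise ValueError("need at least 3 samples for bin correlations")
    yc = y - y.mean()
    sy = np.sqrt((yc ** 2).sum())
    if sy == 0.0:
        raise ValueError("target has zero variance")
    Hc = H - H.mean(axis=0)
    sx = np.sqrt((Hc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Hc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0.0] = 0.0
    return np.clip(r, -1.0, 1.0)


def select_region(
    correlations: np.ndarray,
    hist_template: HistogramFeature,
    policy: Optional[SelectionPolicy] = None,
    target_name: str = "leaf_n",
) -> BinSelection:
    """Pick the histogram bins used as model inputs.

    The default policy intersects a window centred on the template's crop
    peak with a correlation filter; see :class:`SelectionPolicy`.
    """
    policy = policy or SelectionPolicy()
    r = np.asarray(correlations, dtype=np.float64)
    n_bins = hist_template.n_bins
    if r.shape != (n_bins,):
        raise ValueError("correlations must have one entry per template bin")
    if policy.policy == "global_corr":
        order = np.argsort(-np.abs(r), kind="stable")
        chosen = np.sort(order[: policy.top_k])
    elif policy.policy == "peak_window_corr":
        if hist_template.peak_b_bin is None:
            raise ValueError(
                "template histogram has no crop peak; rerun detect_peaks or "
                "switch to the 'global_corr' selection policy"
            )
        half = policy.window // 2
        lo = max(0, hist_template.peak_b_bin - half)
        hi = min(n_bins, hist_template.peak_b_bin + half + 1)
        window_bins = np.arange(lo, hi)
        passing = window_bins[np.abs(r[window_bins]) >= policy.r_min]
        if len(passing) > policy.k_max:
            order = passing[np.argsort(-np.abs(r[passing]), kind="stable")]
            chosen = np.sort(order[: policy.k_max])
        elif len(passing) >= policy.k_min:
            chosen = passing
        else:
            logger.info(
                "selection fallback: only %d window bins reach |r|>=%.2f, "
                "taking top %d by |r|", len(passing), policy.r_min, policy.k_min,
            )
            order = window_bins[np.argsort(-np.abs(r[window_bins]), kind="stable")]
            chosen = np.sort(order[: policy.k_min])
    else:
        raise ValueError(f"unknown selection policy {policy.policy!r}")
    return BinSelection(
        index_name=hist_template.index_name,
        bin_indices=[int(b) for b in chosen],
        per_bin_correlation=[float(x) for x in r[chosen]],
        target_name=target_name,
        bin_edges=hist_template.bin_edges,
        policy=policy.policy,
        params=dataclasses.asdict(policy),
    )


def _targets_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "leaf_n": [r.leaf_n if r.leaf_n is not None else np.nan for r in records],
            "yield": [r.grain_yield if r.grain_yield is not None else np.nan
                      for r in records],
        },
        index=[r.sample_id for r in records],
    )


def histogram_matrix(
    records: Sequence[SampleRecord],
    images: Mapping[str, CanopyImage],
    index_name: str = "GMRN",
    n_bins: int = DEFAULT_N_BINS,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample histograms stacked into a samples x n_bins matrix.

    Returns (matrix, bin_edges); rows follow the order of ``records``.
    """
    _require_images(records, images)
    rows, edges = [], None
    for rec in records:
        h = histogram(compute_index(images[rec.sample_id], index_name), n_bins)
        rows.append(h.percentages)
        edges = h.bin_edges
    return np.vstack(rows), edges


def _require_images(records, images) -> None:
    missing = [r.sample_id for r in records if r.sample_id not in images]
    if missing:
        raise ValueError(f"samples missing their image: {missing}")


def build_feature_matrix(
    records: Sequence[SampleRecord],
    images: Mapping[str, CanopyImage],
    mode: str,
    selection: Optional[BinSelection] = None,
    index_set: Sequence[str] = INDEX_NAMES,
    n_bins: int = DEFAULT_N_BINS,
    vegetation_threshold: Optional[float] = None,
    use_vegetation_mask: bool = True,
) -> FeatureMatrix:
    """Assemble the model input matrix for one feature family.

    ``mode='iimv'``: one column per index in ``index_set``, the mean over
    the vegetation component of each image.  ``mode='iih'``: one column
    per selected histogram bin of ``selection.index_name``.
    """
    mode = mode.lower()
    _require_images(records, images)
    ids = [r.sample_id for r in records]
    if mode == "iimv":
        cols = list(index_set)
        values = np.empty((len(records), len(cols)))
        for i, rec in enumerate(records):
            img = images[rec.sample_id]
            mask = segment_vegetation(img, vegetation_threshold) if use_vegetation_mask else None
            for j, name in enumerate(cols):
                values[i, j] = iimv(compute_index(img, name), mask)
        names = [f"IIMV_{c}" for c in cols]
    elif mode == "iih":
        if selection is None:
            raise ValueError("mode='iih' requires a BinSelection")
        H, _ = histogram_matrix(records, images, selection.index_name, n_bins)
        if max(selection.bin_indices) >= H.shape[1]:
            raise ValueError("bin selection refers to bins beyond n_bins")
        values = H[:, selection.bin_indices]
        names = [f"IIH_{selection.index_name}_bin{b:03d}" for b in selection.bin_indices]
    else:
        raise ValueError(f"unknown feature mode {mode!r}; expected 'iimv' or 'iih'")
    return FeatureMatrix(
        sample_ids=ids, feature_names=names, values=values,
        targets=_targets_frame(records),
    )


def write_feature_table(features: FeatureMatrix, path) -> None:
    """Write a feature matrix as CSV: sample_id, targets, then features.

    Values round-trip through :func:`read_feature_table` at better than
    12 significant digits.
    """
    if len(features.feature_names) == 0:
        raise ValueError("cannot write an empty feature set")
    if not np.all(np.isfinite(features.values)):
        raise ValueError("feature matrix contains non-finite entries")
    df = pd.DataFrame(features.values, columns=features.feature_names,
                      index=pd.Index(features.sample_ids, name="sample_id"))
    out = pd.concat([features.targets.rename_axis("sample_id"), df], axis=1)
    out.to_csv(path, float_format="%.17g")


def read_feature_table(path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col="sample_id", dtype={"sample_id": str})
    targets = df[["leaf_n", "yield"]]
    feats = df.drop(columns=["leaf_n", "yield"])
    return FeatureMatrix(
        sample_ids=[str(s) for s in df.index],
        feature_names=list(feats.columns),
        values=feats.to_numpy(dtype=np.float64),
        targets=targets,
    )
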