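"""Synthetic canopy cohorts with the statistical structure the method assumes.

A simulated photograph is a two-population pixel mixture: a soil background
and a vegetation canopy whose greenness and fractional coverage both rise
with the plot's leaf nitrogen status.  The layout of vegetation is a
thresholded smoothed noise field, so canopies look patchy rather than
salt-and-pepper; only the color statistics matter to the diagnosis method.

Per plot (cultivar x N rate x replicate):

* leaf N (%) follows a saturating response to the N rate plus a cultivar
  offset and plot noise;
* each plot carries a tillering (stand-density) deviation on top of its
  cultivar offset: coverage follows a logistic curve in the latent N
  status plus this deviation, so coverage is a reading of the N status
  that is independent of the instantaneous leaf color;
* grain yield (kg ha^-1) rises linearly with the same stand-density
  status (the N response of yield is mediated by canopy establishment:
  better-established plots both cover more ground and yield more) minus a
  quadratic over-application penalty in the N rate, so the combined
  response peaks at an intermediate rate;
* vegetation RGB is (R0 - redness_loss * leaf_n, G0 + greenness_gain *
  leaf_n, B0) plus a per-cultivar color cast and pixel noise.  The
  cultivar color cast biases any purely color-based reading of leaf N,
  while coverage remains an unconfounded second signal — the structural
  reason a histogram feature can beat a mean-value feature.

Camera transforms (per-channel gain, gamma, offset) emulate the color
tuning differences between phone brands.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .color_index import compute_index
from .image_io import CanopyImage, Cohort, SampleRecord, Stage, write_image, write_sample_table

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ScenarioConfig:
    """Study-design and response-curve parameters of a simulated cohort.

    Defaults reproduce the field design: 6 cultivars x 5 N rates
    (0-360 kg N ha^-1) x 3 replicate images = 90 samples per stage.
    """

    n_cultivars: int = 6
    n_levels: tuple[float, ...] = (0.0, 120.0, 180.0, 240.0, 360.0)
    replicates: int = 3
    image_size: tuple[int, int] = (96, 96)   # (height, width)
    stage: str = "reviving"

    # leaf N response (% of dry mass): baseline + gain*(1 - exp(-N/tau))
    leaf_n_baseline: float = 2.9
    leaf_n_gain: float = 1.3
    leaf_n_tau: float = 180.0
    leaf_n_noise: float = 0.12
    cultivar_leaf_n_sd: float = 0.2

    # yield response (kg ha^-1): canopy-status-mediated gain minus a
    # quadratic over-application penalty, peaking at an intermediate rate
    yield_base: float = 5600.0          # yield at baseline canopy status
    yield_status_gain: float = 1500.0   # kg ha^-1 per leaf-N-equivalent status unit
    yield_opt: float = 190.0            # rates above this incur the penalty
    yield_curvature: float = 0.02       # over-application penalty curvature
    # residual variation NOT mediated by canopy status: most cultivar yield
    # differences track their canopy vigor, so the independent offset and
    # the harvest/plot noise are modest
    yield_noise: float = 150.0
    cultivar_yield_sd: float = 150.0

    # coverage: logistic in (latent leaf-N status + stand-density deviation)
    coverage_lo: float = 0.20
    coverage_hi: float = 0.65
    coverage_mid: float = 3.4
    coverage_scale: float = 0.45
    tiller_dev_sd: float = 0.15     # stand-density deviation, leaf-N-equivalent units
    coverage_noise: float = 0.02    # additive noise on the coverage fraction

    # colors (8-bit DN)
    soil_rgb: tuple[float, float, float] = (120.0, 100.0, 85.0)
    soil_spread: float = 6.0
    veg_rgb_base: tuple[float, float, float] = (90.0, 80.0, 60.0)
    greenness_gain: float = 18.0    # dG per % leaf N
    redness_loss: float = 8.0       # -dR per % leaf N
    cultivar_color_sd: float = 6.0  # per-cultivar RGB cast on vegetation
    image_color_jitter_sd: float = 5.0  # per-photo whole-frame RGB offset
    pixel_noise: float = 8.0
    blur_sigma: float = 2.5         # patchiness scale of the coverage field

    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage_lo <= self.coverage_hi < 1.0):
            raise ValueError("coverage curve must stay inside (0, 1)")
        if self.leaf_n_baseline <= 0:
            raise ValueError("leaf_n baseline must be positive")
        if self.n_cultivars < 1 or self.replicates < 1 or not self.n_levels:
            raise ValueError("design must have >=1 cultivar, level and replicate")
        if min(self.image_size) < 1:
            raise ValueError("image size must be positive")


def reviving_scenario(**overrides) -> ScenarioConfig:
    """Low-coverage early-season preset (sparse canopy over bare soil)."""
    return ScenarioConfig(stage="reviving", **overrides)


def jointing_scenario(**overrides) -> ScenarioConfig:
    """High-coverage stem-elongation preset (canopy dominates the frame)."""
    defaults = dict(
        stage="jointing", coverage_lo=0.5, coverage_hi=0.9,
        leaf_n_baseline=2.8, leaf_n_gain=1.5,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def color_only_scenario(**overrides) -> ScenarioConfig:
    """Constant-coverage control: leaf color is the only image signal."""
    defaults = dict(coverage_lo=0.45, coverage_hi=0.45 + 1e-9, coverage_noise=0.0)
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def null_scenario(**overrides) -> ScenarioConfig:
    """No-signal control: vegetation color and coverage ignore leaf N."""
    defaults = dict(
        greenness_gain=0.0, redness_loss=0.0,
        coverage_lo=0.45, coverage_hi=0.45 + 1e-9, coverage_noise=0.0,
        veg_rgb_base=(62.0, 135.0, 60.0),
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


def _coverage_curve(leaf_n: float, cfg: ScenarioConfig) -> float:
    span = cfg.coverage_hi - cfg.coverage_lo
    z = (leaf_n - cfg.coverage_mid) / cfg.coverage_scale
    return cfg.coverage_lo + span / (1.0 + np.exp(-z))


def _paint_image(
    rng: np.random.Generator,
    cfg: ScenarioConfig,
    coverage: float,
    veg_rgb: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Render one canopy frame; returns (pixels, realized coverage)."""
    h, w = cfg.image_size
    field = gaussian_filter(rng.standard_normal((h, w)), cfg.blur_sigma)
    n_veg = int(round(coverage * h * w))
    order = np.argsort(field, axis=None, kind="stable")
    veg_mask = np.zeros(h * w, dtype=bool)
    if n_veg > 0:
        veg_mask[order[-n_veg:]] = True
    veg_mask = veg_mask.reshape(h, w)
    # per-photo illumination / white-balance offset hits the whole frame
    jitter = rng.normal(0.0, cfg.image_color_jitter_sd, 3)
    soil = (np.asarray(cfg.soil_rgb) + jitter
            + cfg.soil_spread * rng.standard_normal((h, w, 3)))
    veg = veg_rgb + jitter + cfg.pixel_noise * rng.standard_normal((h, w, 3))
    px = np.where(veg_mask[:, :, None], veg, soil)
    px = np.clip(np.round(px), 0, 255).astype(np.uint8)
    return px, n_veg / (h * w)


def generate_cohort(config: ScenarioConfig) -> Cohort:
    """Simulate one full cohort (images, sample records, ground truth).

    Deterministic for a given config (including its seed): identical
    outputs across runs.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    stage = Stage.parse(cfg.stage)
    cultivars = [f"CV{i + 1:02d}" for i in range(cfg.n_cultivars)]
    leaf_offsets = rng.normal(0.0, cfg.cultivar_leaf_n_sd, cfg.n_cultivars)
    yield_offsets = rng.normal(0.0, cfg.cultivar_yield_sd, cfg.n_cultivars)
    color_casts = rng.normal(0.0, cfg.cultivar_color_sd, (cfg.n_cultivars, 3))
    records, images, gt_rows = [], {}, []
    for ci, cultivar in enumerate(cultivars):
        for n_rate in cfg.n_levels:
            for rep in range(cfg.replicates):
                sample_id = f"{cultivar}_N{int(n_rate):03d}_r{rep + 1}"
                latent = (cfg.leaf_n_baseline
                          + cfg.leaf_n_gain * (1.0 - np.exp(-n_rate / cfg.leaf_n_tau))
                          + leaf_offsets[ci])
                leaf_n = latent + rng.normal(0.0, cfg.leaf_n_noise)
                leaf_n = max(leaf_n, 0.5)
                tiller_dev = rng.normal(0.0, cfg.tiller_dev_sd)
                stand_status = latent + tiller_dev  # drives coverage and yield
                grain_yield = (cfg.yield_base
                               + cfg.yield_status_gain * (stand_status - cfg.leaf_n_baseline)
                               - cfg.yield_curvature * max(n_rate - cfg.yield_opt, 0.0) ** 2
                               + yield_offsets[ci]
                               + rng.normal(0.0, cfg.yield_noise))
                grain_yield = max(grain_yield, 500.0)
                coverage = _coverage_curve(stand_status, cfg)
                coverage += rng.normal(0.0, cfg.coverage_noise)
                coverage = float(np.clip(coverage, 0.02, 0.98))
                veg_rgb = np.array([
                    cfg.veg_rgb_base[0] - cfg.redness_loss * leaf_n,
                    cfg.veg_rgb_base[1] + cfg.greenness_gain * leaf_n,
                    cfg.veg_rgb_base[2],
                ]) + color_casts[ci]
                px, realized = _paint_image(rng, cfg, coverage, veg_rgb)
                img = CanopyImage(pixels=px, sample_id=sample_id,
                                  cultivar=cultivar, stage=stage, n_level=n_rate)
                images[sample_id] = img
                records.append(SampleRecord(
                    sample_id=sample_id,
                    image_path=f"images/{sample_id}.png",
                    cultivar=cultivar, stage=stage, n_level=float(n_rate),
                    leaf_n=float(leaf_n), grain_yield=float(grain_yield),
                ))
                gt_rows.append({
                    "sample_id": sample_id, "cultivar": cultivar,
                    "n_level": float(n_rate), "latent_leaf_n": float(latent),
                    "leaf_n": float(leaf_n), "yield": float(grain_yield),
                    "true_coverage": float(realized),
                    "cultivar_leaf_n_offset": float(leaf_offsets[ci]),
                    "cultivar_yield_offset": float(yield_offsets[ci]),
                    "camera": "native",
                })
    return Cohort(records=records, images=images,
                  ground_truth=pd.DataFrame(gt_rows))


def write_cohort(cohort: Cohort, directory, config: Optional[ScenarioConfig] = None) -> None:
    """Write a cohort to disk: PNGs, samples.csv, ground_truth.csv, scenario.yaml."""
    directory = Path(directory)
    (directory / "images").mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        write_image(cohort.images[rec.sample_id], directory / rec.image_path)
    write_sample_table(cohort.records, directory / "samples.csv")
    if cohort.ground_truth is not None:
        cohort.ground_truth.to_csv(directory / "ground_truth.csv", index=False,
                                   float_format="%.17g")
    if config is not None:
        with open(directory / "scenario.yaml", "w") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


@dataclasses.dataclass
class CameraTransform:
    """Per-channel gain, shared gamma, per-channel offset (in 8-bit DN)."""

    gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gamma: float = 1.0
    offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.gains) or self.gamma <= 0:
            raise ValueError("gains and gamma must be positive")


def apply_camera_transform(image: CanopyImage, transform: CameraTransform) -> CanopyImage:
    """Emulate a different camera: v -> clip(round(255*(gain*v/255)^gamma + offset))."""
    v = image.pixels.astype(np.float64) / 255.0
    gains = np.asarray(transform.gains)
    offsets = np.asarray(transform.offsets)
    out = 255.0 * (gains * v) ** transform.gamma + offsets
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return dataclasses.replace(image, pixels=out)


def _gmrn_of(rgb: Sequence[float]) -> float:
    r, g, b = rgb
    return (g - r) / (r + g + b)


def equal_mean_distinct_coverage_pair(
    image_size: tuple[int, int] = (64, 64),
    coverages: tuple[float, float] = (0.3, 0.6),
    soil_rgb: tuple[int, int, int] = (120, 100, 85),
    veg_rgb: tuple[int, int, int] = (60, 150, 55),
    mean_tol: float = 1e-3,
) -> tuple[CanopyImage, CanopyImage]:
    """Two frames with equal whole-frame GMRN means but different coverages.

    The second frame's vegetation greenness is solved analytically to
    compensate its larger coverage, then realized by mixing two adjacent
    integer green levels among its vegetation pixels.  Constructive core
    of the mean-vs-histogram information argument: a whole-frame mean
    cannot tell the two frames apart, their histograms can.
    """
    c1, c2 = coverages
    if abs(c2 - c1) < 0.2:
        raise ValueError("coverages must differ by at least 0.2")
    h, w = image_size
    npix = h * w
    g_soil = _gmrn_of(soil_rgb)
    g_veg1 = _gmrn_of(veg_rgb)

    def build(n_veg: int, veg_colors: np.ndarray) -> CanopyImage:
        px = np.empty((npix, 3), dtype=np.uint8)
        px[:] = np.asarray(soil_rgb, dtype=np.uint8)
        px[:n_veg] = veg_colors
        return CanopyImage(pixels=px.reshape(h, w, 3))

    n_v1 = int(round(c1 * npix))
    n_v2 = int(round(c2 * npix))
    img1 = build(n_v1, np.tile(np.asarray(veg_rgb, dtype=np.uint8), (n_v1, 1)))
    mean1 = (n_v1 * g_veg1 + (npix - n_v1) * g_soil) / npix
    target_sum = mean1 * npix - (npix - n_v2) * g_soil
    g2 = target_sum / n_v2
    r0, b0 = veg_rgb[0], veg_rgb[2]
    if not -1.0 < g2 < 1.0:
        raise ValueError("requested coverages cannot be mean-compensated")
    g_exact = (g2 * (r0 + b0) + r0) / (1.0 - g2)
    g_floor = int(np.floor(g_exact))
    if not 0 <= g_floor < 255:
        raise ValueError(
            "compensating green level falls outside [0, 255]; adjust colors"
        )
    g_lo = _gmrn_of((r0, g_floor, b0))
    g_hi = _gmrn_of((r0, g_floor + 1, b0))
    k = int(round((target_sum - n_v2 * g_lo) / (g_hi - g_lo)))
    k = int(np.clip(k, 0, n_v2))
    veg_colors = np.tile(np.array([r0, g_floor, b0], dtype=np.uint8), (n_v2, 1))
    veg_colors[:k, 1] = g_floor + 1
    img2 = build(n_v2, veg_colors)

    m1 = float(np.mean(compute_index(img1, "GMRN").valid_values()))
    m2 = float(np.mean(compute_index(img2, "GMRN").valid_values()))
    if abs(m1 - m2) > mean_tol:
        raise ValueError(
            f"mean compensation failed: |{m1:.6f} - {m2:.6f}| > {mean_tol}"
        )
    return img1, img2
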