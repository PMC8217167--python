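"""Experimental protocol and error reporting for the IIMV-vs-IIH comparison.

For each growth stage the cohort of 90 samples is split 60/30 into a
training and a validation set (stratified by cultivar and N rate, so every
plot condition is represented in training).  For each feature family
(IIMV, IIH) and each target (leaf N content in %, grain yield in
kg ha^-1) one MLP is trained on the 60 training samples; histogram-bin
selection for IIH is fitted on the training split only and frozen before
validation, to avoid selection leakage.  Errors are reported as RMSE (in
target units) and MAPE (in percent) on both splits.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import features as ft
from . import nn_model as nn
from .color_index import INDEX_NAMES
from .image_io import Cohort, SampleRecord

logger = logging.getLogger(__name__)


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root-mean-square error, in the units of the target."""
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("y and yhat must be nonempty and of equal length")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("inputs must be finite")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mape(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute percentage error, in percent; undefined when any y = 0."""
    y = np.asarray(y, dtype=np.float64).ravel()
    yhat = np.asarray(yhat, dtype=np.float64).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("y and yhat must be nonempty and of equal length")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValueError("inputs must be finite")
    if np.any(y == 0.0):
        raise ValueError("MAPE is undefined when a measured value is zero")
    return float(100.0 * np.mean(np.abs((y - yhat) / y)))


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample coefficient of variation, 100*sd/mean (sd with n-1 denominator)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2 or not np.all(np.isfinite(v)):
        raise ValueError("need at least 2 finite values")
    m = v.mean()
    if m == 0.0:
        raise ValueError("coefficient of variation is undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / m)


def split_samples(
    records: Sequence[SampleRecord],
    n_train: int,
    seed: int,
    stratify_by: Optional[Sequence[str]] = ("cultivar", "n_level"),
) -> tuple[list[str], list[str]]:
    """Seeded random train/validation split, stratified so every stratum trains.

    Training quotas per stratum follow largest-remainder apportionment of
    ``n_train`` over the stratum sizes, with a floor of one training sample
    per stratum.  Strata with fewer than 2 samples are pooled (with a
    warning) so they cannot force an empty validation side.
    """
    n = len(records)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}); got {n_train}")
    rng = np.random.default_rng(seed)
    if stratify_by:
        key = lambda r: tuple(getattr(r, f) if f != "n_level" else r.n_level
                              for f in stratify_by)
    else:
        key = lambda r: ("all",)
    strata: dict[tuple, list[str]] = {}
    for r in records:
        strata.setdefault(key(r), []).append(r.sample_id)
    small = [k for k, ids in strata.items() if len(ids) < 2]
    if small and len(strata) > 1:
        warnings.warn(
            f"{len(small)} strata have fewer than 2 samples; pooling them",
            stacklevel=2,
        )
        pooled = []
        for k in small:
            pooled.extend(strata.pop(k))
        if pooled:
            strata.setdefault(("__pooled__",), []).extend(pooled)
    keys = sorted(strata.keys(), key=str)
    sizes = np.array([len(strata[k]) for k in keys])
    exact = n_train * sizes / n
    quota = np.floor(exact).astype(int)
    quota = np.maximum(quota, 1)  # every stratum appears in training
    while quota.sum() > n_train:
        i = int(np.argmax(quota - exact))
        if quota[i] <= 1:
            break
        quota[i] -= 1
    frac_order = np.argsort(-(exact - quota), kind="stable")
    j = 0
    while quota.sum() < n_train:
        i = frac_order[j % len(keys)]
        if quota[i] < sizes[i]:
            quota[i] += 1
        j += 1
    train_ids, val_ids = [], []
    for k, q in zip(keys, quota):
        ids = sorted(strata[k])
        perm = rng.permutation(len(ids))
        shuffled = [ids[i] for i in perm]
        train_ids.extend(shuffled[:q])
        val_ids.extend(shuffled[q:])
    return sorted(train_ids), sorted(val_ids)


@dataclasses.dataclass
class EvalConfig:
    """Knobs of the comparison protocol; defaults follow the study design."""

    n_train: int = 60
    seed: int = 0
    n_bins: int = ft.DEFAULT_N_BINS
    iih_index: str = "GMRN"
    smooth_window: int = 5
    min_separation: int = 20
    selection: ft.SelectionPolicy = dataclasses.field(default_factory=ft.SelectionPolicy)
    mlp: nn.MLPConfig = dataclasses.field(default_factory=nn.MLPConfig)
    modes: tuple[str, ...] = ("iimv", "iih")
    targets: tuple[str, ...] = ("leaf_n", "yield")
    iimv_index_set: tuple[str, ...] = INDEX_NAMES
    use_vegetation_mask: bool = True


@dataclasses.dataclass
class ReportRow:
    mode: str
    stage: str
    target: str
    mape_train: float
    rmse_train: float
    mape_validation: float
    rmse_validation: float


@dataclasses.dataclass
class EvaluationReport:
    """All error cells of the comparison plus the artifacts needed to redo it."""

    rows: list[ReportRow]
    predictions: pd.DataFrame      # sample_id, stage, mode, target, measured, estimated, split
    split_manifest: dict           # stage -> {train: [...], validation: [...]}
    selections: dict               # (stage, target) -> BinSelection
    models: dict                   # (mode, stage, target) -> DiagnosisModel
    config: EvalConfig

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.rows])
        return df[["mode", "stage", "target", "mape_train", "rmse_train",
                   "mape_validation", "rmse_validation"]]

    def formatted_frame(self) -> pd.DataFrame:
        """Presentation table: MAPE to one decimal (%), RMSE to three decimals."""
        df = self.to_frame().copy()
        for c in ("mape_train", "mape_validation"):
            df[c] = df[c].map(lambda v: f"{v:.1f}%")
        for c in ("rmse_train", "rmse_validation"):
            df[c] = df[c].map(lambda v: f"{v:.3f}")
        return df

    def cell(self, mode: str, stage: str, target: str) -> ReportRow:
        for r in self.rows:
            if (r.mode, r.stage, r.target) == (mode, stage, target):
                return r
        raise KeyError((mode, stage, target))

    def write(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "report.csv", index=False,
                               float_format="%.17g")
        self.predictions.to_csv(directory / "predictions.csv", index=False,
                                float_format="%.17g")
        for (stage, target), sel in self.selections.items():
            sel.to_json(directory / f"selection_{stage}_{target}.json")
        for (mode, stage, target), model in self.models.items():
            model.to_json(directory / f"model_{mode}_{stage}_{target}.json")


def _model_seed(base: int, counter: int) -> int:
    # deterministic, well-spread per-model seeds below 2**31
    return int((base * 2654435761 + 97 * counter + 13) % (2 ** 31))


def run_comparison(
    cohorts: Mapping[str, Cohort],
    config: Optional[EvalConfig] = None,
) -> EvaluationReport:
    """Run the full IIMV-vs-IIH protocol on one cohort per growth stage.

    Every sample must carry both targets.  Returns the 4-cell error table
    for each (mode, stage, target) plus predicted-vs-measured pairs for
    1:1 scatter plots.
    """
    config = config or EvalConfig()
    rows: list[ReportRow] = []
    pred_rows = []
    manifest, selections, models = {}, {}, {}
    pair_counter = 0
    for stage in sorted(cohorts.keys()):
        cohort = cohorts[stage]
        records = cohort.records
        missing = [r.sample_id for r in records if not r.has_targets]
        if missing:
            raise ValueError(f"stage {stage}: samples missing targets: {missing}")
        ids = [r.sample_id for r in records]
        pos = {s: i for i, s in enumerate(ids)}
        train_ids, val_ids = split_samples(records, config.n_train, config.seed)
        manifest[stage] = {"train": train_ids, "validation": val_ids}
        tr = np.array([pos[s] for s in train_ids])
        va = np.array([pos[s] for s in val_ids])

        # per-sample features, computed once per stage
        feats: dict[str, ft.FeatureMatrix] = {}
        if "iimv" in config.modes:
            feats["iimv"] = ft.build_feature_matrix(
                records, cohort.images, "iimv",
                index_set=config.iimv_index_set,
                use_vegetation_mask=config.use_vegetation_mask,
            )
        H, edges = ft.histogram_matrix(
            records, cohort.images, config.iih_index, config.n_bins
        )
        if "iih" in config.modes:
            template = ft.HistogramFeature(
                bin_edges=edges, percentages=H[tr].mean(axis=0),
                index_name=config.iih_index,
            )
            template = ft.detect_peaks(
                template, config.smooth_window, config.min_separation
            )
            for target in config.targets:
                y_tr = np.array([records[i].target(target) for i in tr])
                r = ft.bin_correlations(H[tr], y_tr)
                selections[(stage, target)] = ft.select_region(
                    r, template, config.selection, target_name=target
                )

        for target in config.targets:
            y = np.array([rec.target(target) for rec in records])
            # one training seed per (stage, target), shared by both feature
            # modes: the IIMV-vs-IIH contrast is paired, so restart luck
            # cancels out of the comparison
            pair_seed = _model_seed(config.seed, pair_counter)
            pair_counter += 1
            for mode in config.modes:
                if mode == "iih":
                    sel = selections[(stage, target)]
                    fm = ft.build_feature_matrix(
                        records, cohort.images, "iih", selection=sel,
                        n_bins=config.n_bins,
                    )
                    recipe = {
                        "mode": "iih", "index": sel.index_name,
                        "n_bins": config.n_bins,
                        "bin_indices": list(sel.bin_indices),
                    }
                else:
                    fm = feats["iimv"]
                    recipe = {
                        "mode": "iimv",
                        "indices": list(config.iimv_index_set),
                        "use_vegetation_mask": config.use_vegetation_mask,
                    }
                mlp_cfg = dataclasses.replace(config.mlp, seed=pair_seed)
                model = nn.fit(
                    fm.values[tr], y[tr], mlp_cfg,
                    feature_names=fm.feature_names, target_name=target,
                    recipe=recipe,
                )
                models[(mode, stage, target)] = model
                yhat_tr = nn.predict(model, fm.values[tr], fm.feature_names)
                yhat_va = nn.predict(model, fm.values[va], fm.feature_names)
                rows.append(ReportRow(
                    mode=mode, stage=stage, target=target,
                    mape_train=mape(y[tr], yhat_tr),
                    rmse_train=rmse(y[tr], yhat_tr),
                    mape_validation=mape(y[va], yhat_va),
                    rmse_validation=rmse(y[va], yhat_va),
                ))
                for split_name, idx, yhat in (
                    ("train", tr, yhat_tr), ("validation", va, yhat_va)
                ):
                    for i, p in zip(idx, yhat):
                        pred_rows.append({
                            "sample_id": records[i].sample_id, "stage": stage,
                            "mode": mode, "target": target,
                            "measured": records[i].target(target),
                            "estimated": float(p), "split": split_name,
                        })
    predictions = pd.DataFrame(
        pred_rows,
        columns=["sample_id", "stage", "mode", "target", "measured",
                 "estimated", "split"],
    )
    return EvaluationReport(
        rows=rows, predictions=predictions, split_manifest=manifest,
        selections=selections, models=models, config=config,
    )


def compare_over_seeds(
    make_cohorts: Callable[[int], Mapping[str, Cohort]],
    seeds: Sequence[int],
    config: Optional[EvalConfig] = None,
) -> pd.DataFrame:
    """Run the comparison once per seed and collect all error cells.

    ``make_cohorts(seed)`` must build the stage->cohort mapping for that
    seed (typically via the synthetic generator); the same seed also
    drives the split and training.  Single-split results at n=90 are
    noisy, so verdicts should use the median over seeds.
    """
    base = config or EvalConfig()
    frames = []
    for s in seeds:
        cfg = dataclasses.replace(base, seed=int(s))
        rep = run_comparison(make_cohorts(int(s)), cfg)
        df = rep.to_frame()
        df.insert(0, "seed", int(s))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def median_cells(trials: pd.DataFrame) -> pd.DataFrame:
    """Median error cells over seeds, indexed by (mode, stage, target)."""
    return trials.groupby(["mode", "stage", "target"], as_index=True)[
        ["mape_train", "rmse_train", "mape_validation", "rmse_validation"]
    ].median()
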