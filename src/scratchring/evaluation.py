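"""Leave-one-subject-out evaluation, metrics, and clinical-scale analyses.

Metrics follow the study conventions for the 0-600 mW power scale:

* MAE(mW)   = mean |y - yhat|,
* MAPE(%)   = MAE / 600 x 100 (normalized by the scale maximum, not the
  conventional per-sample percentage error),
* accuracy  = percent of matching binary calls.

LOSO-CV holds out each participant in turn; the min-max scaler and the
model are fitted on the training folds only, and aggregate metrics are
the unweighted mean +- sd across folds.  Power maps onto a 0-10
clinical-style scale either linearly (divide by 60) or through a square
root (10 sqrt(p/600)); both send 0 mW to 0 and 600 mW to 10.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from . import models as _models
from .wearable_features import apply_scaler, feature_slices, fit_scaler

POWER_SCALE_MAX_MW = 600.0
LINEAR_MW_PER_UNIT = 60.0


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# metrics


def _paired(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size == 0 or y.size != yhat.size:
        raise EvaluationError("need equal-length, nonempty label/prediction arrays")
    return y, yhat


def mae(y, yhat) -> float:
    """Mean absolute error in mW."""
    y, yhat = _paired(y, yhat)
    return float(np.mean(np.abs(y - yhat)))


def mape(y, yhat) -> float:
    """MAE normalized by the 600 mW scale maximum, in percent."""
    return mae(y, yhat) / POWER_SCALE_MAX_MW * 100.0


def accuracy(y, yhat) -> float:
    """Percent agreement of binary calls."""
    y, yhat = _paired(y, yhat)
    return float(np.mean(np.asarray(y, bool) == np.asarray(yhat, bool)) * 100.0)


class NaiveBaseline:
    """Constant predictor: always the training-label mean."""

    def __init__(self, constant: float):
        self.constant = float(constant)

    def predict(self, n_or_features) -> np.ndarray:
        n = n_or_features if np.isscalar(n_or_features) else np.shape(n_or_features)[0]
        return np.full(int(n), self.constant)


def naive_baseline(train_labels) -> NaiveBaseline:
    labels = np.asarray(train_labels, dtype=float)
    if labels.size == 0:
        raise EvaluationError("cannot build a baseline from no labels")
    return NaiveBaseline(labels.mean())


# ---------------------------------------------------------------------------
# 0-10 clinical-style scale


@dataclass
class ScaleMap:
    """mW -> 0-10 scale conversion (linear p/60, or 10 sqrt(p/600))."""

    kind: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "sqrt"):
            raise EvaluationError(f"unknown scale kind {self.kind!r}")


def to_scale(power_mw, scale_map: Optional[ScaleMap] = None, clip: bool = True):
    """Convert power in mW to 0-10 scale units."""
    scale_map = scale_map or ScaleMap()
    p = np.asarray(power_mw, dtype=float)
    if clip:
        p = np.clip(p, 0.0, POWER_SCALE_MAX_MW)
    elif np.any(p < 0):
        raise EvaluationError("negative power with clipping disabled")
    if scale_map.kind == "linear":
        out = p / LINEAR_MW_PER_UNIT
    else:
        out = 10.0 * np.sqrt(p / POWER_SCALE_MAX_MW)
    return float(out) if np.isscalar(power_mw) else out


# ---------------------------------------------------------------------------
# LOSO folds


def loso_folds(participant_ids: Sequence[str]) -> List[Tuple[List[str], List[str]]]:
    """One fold per participant: ([everyone else], [held out])."""
    seen = list(dict.fromkeys(participant_ids))
    if len(seen) < 2:
        raise EvaluationError("LOSO requires at least 2 participants")
    return [([p for p in seen if p != held], [held]) for held in seen]


@dataclass
class FoldReport:
    """Metrics for one held-out participant."""

    held_out_participant: str
    n_test: int
    mae_mw: float = float("nan")
    mape_percent: float = float("nan")
    accuracy_percent: float = float("nan")
    rank_correlation: float = float("nan")
    baseline_mae_mw: float = float("nan")
    per_interaction_accuracy: Dict[str, float] = field(default_factory=dict)
    scaler_fitted_on: str = ""


@dataclass
class LOSOReport:
    task: str
    modality: str
    folds: List[FoldReport]

    def _agg(self, attr: str) -> Tuple[float, float]:
        vals = np.array([getattr(f, attr) for f in self.folds], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    @property
    def mae_mw(self) -> Tuple[float, float]:
        return self._agg("mae_mw")

    @property
    def mape_percent(self) -> Tuple[float, float]:
        return self._agg("mape_percent")

    @property
    def accuracy_percent(self) -> Tuple[float, float]:
        return self._agg("accuracy_percent")

    @property
    def per_interaction_accuracy(self) -> Dict[str, float]:
        """Per-interaction accuracy averaged across folds."""
        keys: Dict[str, List[float]] = {}
        for f in self.folds:
            for k, v in f.per_interaction_accuracy.items():
                keys.setdefault(k, []).append(v)
        return {k: float(np.mean(v)) for k, v in keys.items()}


@dataclass
class FeatureDataset:
    """Raw (unnormalized) feature matrix with labels and provenance."""

    X: np.ndarray
    y: np.ndarray
    participants: np.ndarray
    task: str
    interactions: Optional[np.ndarray] = None
    truth_power: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=float)
        self.participants = np.asarray(self.participants)
        n = self.X.shape[0]
        if self.y.size != n or self.participants.size != n:
            raise EvaluationError("X, y, participants must align")


def evaluate_loso(
    dataset: FeatureDataset,
    config=None,
    modality: str = "both",
    seed: int = 0,
    threshold: float = 0.5,
) -> LOSOReport:
    """Full LOSO cross-validation of the task model on a feature dataset.

    ``modality`` restricts the feature columns ('mic', 'acc' or 'both'),
    flowing the ablated matrix through the identical scaler + model
    pipeline.  Per fold, the scaler is fitted on the training rows only.
    """
    task = dataset.task
    sl = feature_slices(task)
    if modality == "both":
        X = dataset.X
    elif modality in sl:
        X = dataset.X[:, sl[modality]]
    else:
        raise EvaluationError(f"unknown modality {modality!r}")

    reports: List[FoldReport] = []
    for train_ids, test_ids in loso_folds(list(dataset.participants)):
        tr = np.isin(dataset.participants, train_ids)
        te = np.isin(dataset.participants, test_ids)
        assert not np.any(tr & te), "participant leakage across the fold split"
        scaler = fit_scaler(X[tr], fitted_on="train:" + ",".join(sorted(train_ids)))
        Xtr, Xte = apply_scaler(scaler, X[tr]), apply_scaler(scaler, X[te])
        held = test_ids[0]
        rep = FoldReport(held, int(te.sum()), scaler_fitted_on=scaler.fitted_on)
        if task == "intensity":
            model = _models.train_intensity(
                Xtr, dataset.y[tr], config=config, seed=seed, scaler=scaler
            )
            pred = _models.predict_intensity(model, Xte)
            rep.mae_mw = mae(dataset.y[te], pred)
            rep.mape_percent = mape(dataset.y[te], pred)
            rep.baseline_mae_mw = mae(
                dataset.y[te], naive_baseline(dataset.y[tr]).predict(Xte)
            )
            ref = dataset.truth_power[te] if dataset.truth_power is not None else dataset.y[te]
            if np.unique(ref).size > 1:
                rep.rank_correlation = float(stats.spearmanr(ref, pred).statistic)
        else:
            model = _models.train_detection(
                Xtr, dataset.y[tr], config=config, seed=seed, scaler=scaler
            )
            _, call = _models.predict_scratch(model, Xte, threshold=threshold)
            rep.accuracy_percent = accuracy(dataset.y[te], call)
            if dataset.interactions is not None:
                inter = dataset.interactions[te]
                for kind in np.unique(inter):
                    m = inter == kind
                    rep.per_interaction_accuracy[str(kind)] = accuracy(
                        dataset.y[te][m], call[m]
                    )
        reports.append(rep)
    return LOSOReport(task=task, modality=modality, folds=reports)


# ---------------------------------------------------------------------------
# validation-study analyses


@dataclass
class LevelAnalysis:
    levels: np.ndarray
    means: np.ndarray
    adjacent_p: np.ndarray  # p-value for levels[i] vs levels[i+1]


def _wilcoxon_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p; zeros dropped; exact for
    n <= 25, normal approximation above; identical groups give p = 1."""
    d = np.asarray(a, float) - np.asarray(b, float)
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    method = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue)


def level_analysis(values: np.ndarray, levels: Optional[Sequence] = None) -> LevelAnalysis:
    """Group means and adjacent-level paired Wilcoxon tests.

    ``values`` is an (n_pairs, n_levels) array: each row is one paired
    observation unit (participant x set), each column one instructed
    intensity level (ascending).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise EvaluationError("need a 2-D (pairs x levels) array with >= 2 levels")
    if np.isnan(values).any():
        raise EvaluationError("unpaired (NaN) observations are not supported")
    n_levels = values.shape[1]
    levels = np.asarray(levels if levels is not None else np.arange(1, n_levels + 1))
    means = values.mean(axis=0)
    pvals = np.array(
        [_wilcoxon_paired(values[:, i + 1], values[:, i]) for i in range(n_levels - 1)]
    )
    return LevelAnalysis(levels=levels, means=means, adjacent_p=pvals)


def normalized_spearman(set_values: np.ndarray) -> Tuple[float, float]:
    """Spearman correlation of level vs per-set min-max-normalized value.

    ``set_values`` is (n_sets, n_levels): each row holds one
    participant-set's mean regressed intensity per ascending level.  Rows
    are min-max normalized individually (constant rows are excluded with
    a warning), then all (level, value) points are pooled.
    """
    V = np.atleast_2d(np.asarray(set_values, dtype=float))
    spans = V.max(axis=1) - V.min(axis=1)
    keep = spans > 0
    if not keep.all():
        warnings.warn(f"excluding {int((~keep).sum())} constant set(s) from normalization")
    V = V[keep]
    if V.shape[0] == 0:
        raise EvaluationError("no non-degenerate sets")
    norm = (V - V.min(axis=1, keepdims=True)) / (
        V.max(axis=1, keepdims=True) - V.min(axis=1, keepdims=True)
    )
    levels = np.tile(np.arange(1, V.shape[1] + 1), V.shape[0])
    res = stats.spearmanr(levels, norm.ravel())
    return float(res.statistic), float(res.pvalue)


@dataclass
class ParticipantScaleFit:
    """Least-squares line through (instructed scale value, power in mW)."""

    participant_id: str
    slope_mw_per_unit: float
    intercept_mw: float


def participant_scale_fit(
    scale_values: Sequence[float],
    power_mw: Sequence[float],
    participant_id: str = "",
) -> ParticipantScaleFit:
    """OLS fit of ground-truth power against instructed scale value."""
    x = np.asarray(scale_values, dtype=float)
    y = np.asarray(power_mw, dtype=float)
    if np.unique(x).size < 2:
        raise EvaluationError("need >= 2 distinct scale values to fit a line")
    res = stats.linregress(x, y)
    return ParticipantScaleFit(participant_id, float(res.slope), float(res.intercept))


def report_to_dict(report: LOSOReport, decimals: int = 2) -> dict:
    """JSON-serializable summary (rounded headline + raw per-fold values)."""
    agg = {}
    for name in ("mae_mw", "mape_percent", "accuracy_percent"):
        mean, sd = getattr(report, name)
        if not np.isnan(mean):
            agg[name] = {"mean": round(mean, decimals), "sd": round(sd, decimals)}
    return {
        "schema_version": 1,
        "task": report.task,
        "modality": report.modality,
        "aggregate": agg,
        "per_interaction_accuracy": {
            k: round(v, decimals) for k, v in report.per_interaction_accuracy.items()
        },
        "folds": [dataclasses.asdict(f) for f in report.folds],
    }
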