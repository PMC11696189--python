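"""Evaluation: repeated cross-validation, discrimination, calibration,
ordinal explanation and bootstrap bias-corrected confidence intervals.

Predictions are pooled over the test folds of 20x5 repeated
cross-validation and summarised at the days directly preceding a TIL
assessment day.  Confidence intervals come from the bootstrap
bias-corrected cross-validation (BBC-CV) construction: each patient-level
bootstrap resample selects the best model configuration on in-resample
rows and evaluates it on out-of-resample rows, so the interval accounts
for configuration-selection optimism.  With a single configuration this
reduces to an ordinary patient-level percentile bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.api import Logit, add_constant
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import ModelConfig, prediction_frame, train_model
from .scoring import EVALUATION_DAYS
from .tokenizer import VariableSet, fit_vocabulary, tokenize_stay

__all__ = [
    "CVPartition",
    "MetricEstimate",
    "UndefinedMetricError",
    "make_partitions",
    "auc",
    "threshold_auc",
    "change_auc",
    "calibration_slope",
    "calibration_curve_error",
    "somers_dxy",
    "carry_forward_reference",
    "bbc_cv_interval",
    "cross_validate",
]


class UndefinedMetricError(ValueError):
    """Metric not defined on the given sample (e.g. single-class input)."""


@dataclass(frozen=True)
class CVPartition:
    repeat: int  # 1-based
    fold: int  # 1-based
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]  # internal validation, subset of training set
    test_ids: tuple[str, ...]

    @property
    def partition_id(self) -> str:
        return f"r{self.repeat:02d}f{self.fold}"


@dataclass(frozen=True)
class MetricEstimate:
    metric: str
    day: Optional[int]
    point: float
    lo: float
    hi: float
    variable_set: str = "full"

    def __post_init__(self) -> None:
        if not (self.lo <= self.point + 1e-9 and self.point <= self.hi + 1e-9):
            raise ValueError("CI must bracket the point estimate")


def make_partitions(
    patient_ids: Sequence[str],
    strata: Optional[Sequence] = None,
    repeats: int = 20,
    folds: int = 5,
    val_frac: float = 0.15,
    seed: int = 0,
) -> list[CVPartition]:
    """repeats x folds partitions with stratified test folds and a 15%
    internal validation split (floor convention) inside each training set.

    ``strata`` (e.g. each patient's TIL-Basic median) stabilises the fold
    distribution; unstratified when omitted.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    ids = np.asarray(patient_ids)
    if len(ids) < folds:
        raise ValueError(f"need at least {folds} patients for {folds}-fold CV")
    rng = np.random.default_rng(seed)
    out: list[CVPartition] = []
    for rep in range(1, repeats + 1):
        state = int(rng.integers(2**31 - 1))
        if strata is not None:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=state)
            splits = splitter.split(ids, np.asarray(strata))
        else:
            splitter = KFold(n_splits=folds, shuffle=True, random_state=state)
            splits = splitter.split(ids)
        for fold, (train_idx, test_idx) in enumerate(splits, start=1):
            train = ids[train_idx]
            n_val = int(np.floor(val_frac * len(train)))
            val = rng.choice(train, size=n_val, replace=False) if n_val else np.array([])
            val_set = set(val.tolist())
            out.append(
                CVPartition(
                    repeat=rep,
                    fold=fold,
                    train_ids=tuple(t for t in train if t not in val_set),
                    val_ids=tuple(sorted(val_set)),
                    test_ids=tuple(ids[test_idx]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Metrics

def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 0.5."""
    from scipy.stats import rankdata

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC requires both classes")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _at_day(pooled: pd.DataFrame, day: Optional[int]) -> pd.DataFrame:
    return pooled if day is None else pooled[pooled["day"] == day]


def threshold_auc(pooled: pd.DataFrame, threshold: int, day: Optional[int] = None) -> float:
    """AUC of Pr(Y > threshold) against the observed next-day indicator."""
    df = _at_day(pooled, day).dropna(subset=["y_next"])
    score = df[[f"p{j}" for j in range(threshold + 1, 5)]].sum(axis=1).values
    return auc(score, (df["y_next"] > threshold).values)


def change_auc(pooled: pd.DataFrame, direction: str, day: Optional[int] = None) -> float:
    """AUC for next-day (de-)escalation among assessed day pairs."""
    if direction not in ("escalation", "de-escalation"):
        raise ValueError("direction must be 'escalation' or 'de-escalation'")
    df = _at_day(pooled, day).dropna(subset=["change", "p_inc"])
    if direction == "escalation":
        return auc(df["p_inc"].values, (df["change"] > 0).values)
    return auc(df["p_dec"].values, (df["change"] < 0).values)


def calibration_slope(pred_probs: np.ndarray, outcomes: np.ndarray) -> float:
    """Logistic-recalibration slope: coefficient of logit(p) in a logistic
    refit of the outcomes.  1 = well calibrated, < 1 = overfitted."""
    p = np.clip(np.asarray(pred_probs, dtype=float), 1e-9, 1 - 1e-9)
    y = np.asarray(outcomes).astype(int)
    if y.min() == y.max():
        raise UndefinedMetricError("calibration requires both outcomes")
    lp = np.log(p / (1 - p))
    if np.ptp(lp) < 1e-12:
        raise UndefinedMetricError("constant predictions: slope is unidentified")
    fit = Logit(y, add_constant(lp)).fit(disp=0, maxiter=200)
    return float(fit.params[1])


def calibration_curve_error(
    pred_probs: np.ndarray,
    outcomes: np.ndarray,
    frac: float = 0.75,
    grid_size: int = 101,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Smoothed (lowess) calibration curve and its sup-norm distance to the
    diagonal, evaluated only within the observed prediction range."""
    p = np.asarray(pred_probs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(p) < 10:
        raise UndefinedMetricError("too few observations for a smoothed curve")
    if np.ptp(p) < 1e-12:  # degenerate: flat curve at the outcome mean
        grid = np.full(1, p[0])
        curve = np.full(1, y.mean())
        return grid, curve, float(abs(y.mean() - p[0]))
    grid = np.linspace(p.min(), p.max(), grid_size)
    # it=0: robustness reweighting is biased for binary outcomes
    curve = lowess(y, p, frac=frac, it=0, xvals=grid)
    return grid, curve, float(np.max(np.abs(curve - grid)))


def somers_dxy(outputs: np.ndarray, outcomes: np.ndarray) -> float:
    """Somers' D_xy of a scalar model output against an ordinal outcome.

    D_xy = (C - D) / (C + D + T_x) over all pairs with distinct outcomes,
    where T_x are pairs tied on the output; equivalently 2*(c - 0.5).
    Interpreted as the proportion of ordinal variation in the outcome
    explained by variation in the output.
    """
    x = np.asarray(outputs, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if len(x) < 2 or np.ptp(y) == 0:
        raise UndefinedMetricError("Somers' D_xy needs non-identical outcomes")
    gx = np.sign(x[:, None] - x[None, :])
    gy = np.sign(y[:, None] - y[None, :])
    informative = gy != 0
    C = int(((gx == gy) & informative).sum())
    D = int(((gx == -gy) & (gx != 0) & informative).sum())
    Tx = int(((gx == 0) & informative).sum())
    return float((C - D) / (C + D + Tx))


def somers_dxy_change(pooled: pd.DataFrame, day: Optional[int] = None) -> float:
    """D_xy of the expected-change score against observed ordinal change."""
    df = _at_day(pooled, day).dropna(subset=["change"])
    return somers_dxy((df["expected"] - df["last_til"]).values, df["change"].values)


def carry_forward_reference(tokenized_stays: Sequence) -> pd.DataFrame:
    """Reference predictor: all probability mass on the last available
    TIL-Basic score.  Emits the same table schema as model predictions so
    both run through identical metric code; patient-days with no prior
    score are skipped."""
    rows = []
    for stay in tokenized_stays:
        for t, day in enumerate(stay.days):
            last = stay.last_til[t]
            if last is None:
                continue
            p = np.zeros(5)
            p[last] = 1.0
            y = stay.labels[t]
            rows.append(
                {
                    "patient_id": stay.patient_id,
                    "day": day,
                    **{f"p{k}": p[k] for k in range(5)},
                    "expected": float(last),
                    "last_til": last,
                    "y_next": np.nan if y is None else y,
                    "p_dec": 0.0,
                    "p_same": 1.0,
                    "p_inc": 0.0,
                    "change": np.nan if y is None else y - last,
                }
            )
    return pd.DataFrame(rows)


def bbc_cv_interval(
    pooled: pd.DataFrame,
    metric_fn: Callable[[pd.DataFrame], float],
    metric_name: str = "metric",
    day: Optional[int] = None,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    variable_set: str = "full",
    max_retries_factor: int = 5,
) -> MetricEstimate:
    """BBC-CV point estimate and percentile CI for one metric.

    ``pooled`` must carry a ``config_id`` column when several
    configurations compete; each bootstrap resample of patients selects
    the best configuration on in-resample rows and evaluates it on
    out-of-resample rows.  With one configuration the procedure is an
    ordinary patient-level percentile bootstrap.  Resamples on which the
    metric is undefined are redrawn up to a retry cap.
    """
    df = _at_day(pooled, day)
    configs = sorted(df["config_id"].unique()) if "config_id" in df else [None]
    by_config = (
        {c: df[df["config_id"] == c] for c in configs} if configs != [None] else {None: df}
    )
    patients = np.asarray(sorted(df["patient_id"].unique()))
    if len(patients) == 0:
        raise UndefinedMetricError(f"no rows for metric {metric_name!r}")
    rng = np.random.default_rng(seed)

    values = np.empty(n_boot)
    max_draws = n_boot * max_retries_factor
    draws = 0
    got = 0
    while got < n_boot:
        if draws >= max_draws:
            raise UndefinedMetricError(
                f"metric {metric_name!r} undefined on too many bootstrap resamples"
            )
        draws += 1
        sample = rng.choice(patients, size=len(patients), replace=True)
        in_set = set(sample.tolist())
        try:
            if configs == [None]:
                counts = pd.Series(sample).value_counts()
                sub = by_config[None]
                rows = sub[sub["patient_id"].isin(in_set)]
                weights = counts.reindex(rows["patient_id"]).values
                values[got] = _weighted_metric(metric_fn, rows, weights)
            else:
                best_c, best_v = None, -np.inf
                for c in configs:
                    sub = by_config[c]
                    v = metric_fn(sub[sub["patient_id"].isin(in_set)])
                    if v > best_v:
                        best_c, best_v = c, v
                out_rows = by_config[best_c][
                    ~by_config[best_c]["patient_id"].isin(in_set)
                ]
                values[got] = metric_fn(out_rows)
        except UndefinedMetricError:
            continue
        got += 1

    if configs == [None]:
        point = metric_fn(df)
    else:
        point = float(values.mean())
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return MetricEstimate(
        metric=metric_name,
        day=day,
        point=float(np.clip(point, lo, hi)),
        lo=float(lo),
        hi=float(hi),
        variable_set=variable_set,
    )


def _weighted_metric(metric_fn, rows: pd.DataFrame, weights: np.ndarray) -> float:
    """Replicate multiply-sampled patients' rows per bootstrap weight."""
    rep = rows.loc[rows.index.repeat(weights)]
    return metric_fn(rep)


# ---------------------------------------------------------------------------
# Cross-validated pooled predictions

def cross_validate(
    stays: Sequence,
    manifest: pd.DataFrame,
    configs: Sequence[ModelConfig],
    partitions: Sequence[CVPartition],
    variable_set: VariableSet = "full",
) -> pd.DataFrame:
    """Train per partition (and per candidate config) and pool test-set
    predictions.  The vocabulary is refit on each partition's training
    patients only, so no test information leaks into bin edges."""
    by_id = {s.patient_id: s for s in stays}
    frames = []
    for part in partitions:
        train = [by_id[i] for i in part.train_ids]
        val = [by_id[i] for i in part.val_ids] or train[:1]
        test = [by_id[i] for i in part.test_ids]
        for ci, cfg in enumerate(configs):
            vocab = fit_vocabulary(
                train, manifest, embed_dim=cfg.embed_dim,
                partition_id=part.partition_id, seed=cfg.seed,
            )
            tok = lambda ss: [tokenize_stay(s, vocab, variable_set) for s in ss]
            net, _ = train_model(tok(train), tok(val), cfg, vocab)
            df = prediction_frame(net, tok(test))
            df["partition_id"] = part.partition_id
            df["config_id"] = f"cfg{ci}"
            frames.append(df)
    return pd.concat(frames, ignore_index=True)


def evaluation_day_table(
    pooled: pd.DataFrame,
    metric_fn: Callable[[pd.DataFrame], float],
    metric_name: str,
    n_boot: int = 200,
    seed: int = 0,
    variable_set: str = "full",
    days: Sequence[int] = EVALUATION_DAYS,
) -> list[MetricEstimate]:
    """BBC-CV estimates of one metric at each evaluation day; days where
    the metric is undefined are reported as missing (skipped)."""
    out = []
    for day in days:
        if not (pooled["day"] == day).any():
            continue
        try:
            out.append(
                bbc_cv_interval(
                    pooled, metric_fn, metric_name=metric_name, day=day,
                    n_boot=n_boot, seed=seed + day, variable_set=variable_set,
                )
            )
        except UndefinedMetricError:
            continue
    return out
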