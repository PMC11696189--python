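"""Kernel-weighted Shapley attribution over tokens and daily windows.

Features are token-within-window units of the recent (unpruned) windows,
plus a single group feature for the low-contributing distant past
(temporal coalition pruning).  The explained model output is the expected
next-day TIL-Basic score.  The baseline event replaces every token by its
variable's missing token — the model's native representation of "no
information".  A consequence is that missing-value tokens are exact null
players (masking them is a no-op), so their Shapley values are zero by
construction and they are reported separately from value tokens.

The Shapley values are obtained by a kernel-weighted linear regression on
binary coalition masks under the efficiency constraint
``sum(phi) = f(observed) - f(baseline)`` (enforced exactly by variable
elimination).  With full coalition enumeration the solution equals the
exact Shapley values.

ΔTimeSHAP: for an observed change in TIL-Basic between days t-1 and t
(after day two of the stay), each token's Shapley value in the final
window is computed at day t-1 and at day t-2; the difference is the
token's contribution to the shift in predicted treatment intensity over
the two days preceding the change.  A token absent from a day's window
contributes zero for that day.  Positive Δ associates with escalation,
negative with de-escalation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import expected_score
from .rnn import SequenceNet
from .tokenizer import TokenizedStay

__all__ = [
    "Attribution",
    "DeltaRecord",
    "kernel_weight",
    "solve_shapley",
    "prune_temporal",
    "timeshap_for_day",
    "delta_timeshap",
    "population_ranking",
]

ENUM_LIMIT = 12  # full coalition enumeration up to this many features
PRUNED_GROUP = "<pruned_past>"


@dataclass
class Attribution:
    """Shapley attribution of one patient-day model output."""

    patient_id: str
    day: int
    features: list[tuple[int, str]]  # (window day, token string)
    phi: np.ndarray
    phi_pruned: float
    baseline_output: float
    observed_output: float
    null_tokens: list[tuple[int, str]]  # exact null players (phi = 0)

    def __post_init__(self) -> None:
        gap = abs(
            self.phi.sum() + self.phi_pruned
            - (self.observed_output - self.baseline_output)
        )
        if gap > 1e-6:
            raise AssertionError(f"efficiency violated by {gap:.2e}")

    def token_phi(self, day: int, token: str) -> float:
        for (d, tok), p in zip(self.features, self.phi):
            if d == day and tok == token:
                return float(p)
        return 0.0


@dataclass(frozen=True)
class DeltaRecord:
    """Per-token ΔTimeSHAP contribution to one observed TIL-Basic change."""

    patient_id: str
    transition_day: int  # change occurred between transition_day-1 and it
    token: str
    variable: str
    delta_phi: float
    direction: str  # observed change: 'escalation' or 'de-escalation'
    is_missing_token: bool = False


def kernel_weight(M: int, s: int) -> float:
    """Shapley kernel weight for a size-s coalition of M features.

    w = (M-1) / (C(M,s) * s * (M-s)).  Empty and full coalitions are
    handled as exact constraints, not weights.
    """
    if not 0 < s < M:
        raise ValueError("empty/full coalitions are constraints, not weighted")
    return (M - 1) / (comb(M, s) * s * (M - s))


def solve_shapley(
    value_fn: Callable[[np.ndarray], float],
    M: int,
    n_coalitions: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Shapley values via constrained kernel-weighted least squares.

    ``value_fn`` maps a boolean inclusion mask of length M to the model
    output.  All 2^M coalitions are enumerated when M <= 12 (exact
    Shapley values); otherwise ``n_coalitions`` masks are sampled with
    probability proportional to the kernel weight of their size (default
    budget 2M + 2048).  Efficiency holds exactly by construction.
    """
    if M == 0:
        return np.zeros(0)
    f0 = value_fn(np.zeros(M, dtype=bool))
    f1 = value_fn(np.ones(M, dtype=bool))
    delta = f1 - f0
    if M == 1:
        return np.array([delta])

    if M <= ENUM_LIMIT:
        masks = np.array(
            [[(i >> j) & 1 for j in range(M)] for i in range(1, 2**M - 1)],
            dtype=bool,
        )
        sizes = masks.sum(axis=1)
        weights = np.array([kernel_weight(M, int(s)) for s in sizes])
    else:
        if n_coalitions is None:
            n_coalitions = 2 * M + 2048
        if n_coalitions < M + 2:
            raise ValueError("n_coalitions must be at least M + 2")
        rng = np.random.default_rng(seed)
        size_w = np.array([kernel_weight(M, s) * comb(M, s) for s in range(1, M)])
        size_p = size_w / size_w.sum()
        sizes = rng.choice(np.arange(1, M), size=n_coalitions, p=size_p)
        masks = np.zeros((n_coalitions, M), dtype=bool)
        for r, s in enumerate(sizes):
            masks[r, rng.choice(M, size=int(s), replace=False)] = True
        # paired (antithetic) sampling stabilises the estimate
        masks = np.vstack([masks, ~masks])
        weights = np.ones(len(masks))

    y = np.array([value_fn(m) for m in masks], dtype=float) - f0
    Z = masks.astype(float)
    # eliminate the last feature through the efficiency constraint
    y_adj = y - Z[:, -1] * delta
    X = Z[:, :-1] - Z[:, -1:]
    sw = np.sqrt(weights)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y_adj * sw, rcond=None)
    phi = np.empty(M)
    phi[:-1] = coef
    phi[-1] = delta - coef.sum()
    return phi


# ---------------------------------------------------------------------------
# Model-side value functions

def _token_str(net: SequenceNet, idx: int) -> str:
    if not hasattr(net.vocab, "_rev"):
        net.vocab._rev = {i: t for t, i in net.vocab.index.items()}  # type: ignore[attr-defined]
    return net.vocab._rev[int(idx)]  # type: ignore[attr-defined]


def _baseline_window(net: SequenceNet, toks: np.ndarray) -> np.ndarray:
    """All-missing counterpart of a window (same variables)."""
    vocab = net.vocab
    out = {
        vocab.index[vocab.missing_token(vocab.token_variable(_token_str(net, t)))]
        for t in toks
    }
    return np.fromiter(sorted(out), dtype=np.int64)


def _mask_token(net: SequenceNet, toks: np.ndarray, drop_idx: int) -> np.ndarray:
    """Remove one token, substituting its variable's missing token."""
    vocab = net.vocab
    var = vocab.token_variable(_token_str(net, drop_idx))
    missing = vocab.index[vocab.missing_token(var)]
    out = {int(t) for t in toks if int(t) != int(drop_idx)}
    if not any(vocab.token_variable(_token_str(net, t)) == var for t in out):
        out.add(missing)
    return np.fromiter(sorted(out), dtype=np.int64)


def _output(net: SequenceNet, windows: Sequence[np.ndarray]) -> float:
    probs = net.forward(windows)
    return expected_score(probs[-1])


def prune_temporal(
    net: SequenceNet,
    stay: TokenizedStay,
    output_day: int,
    tolerance: float = 0.05,
) -> tuple[list[int], list[int]]:
    """Split window indices into (kept, pruned-past group).

    Scans earliest-first: the longest contiguous prefix of windows whose
    *joint* replacement by the all-missing baseline changes the
    expected-score output by less than ``tolerance`` becomes the single
    pruned-past group.  The output-day window is never pruned.
    ``tolerance = 0`` prunes nothing.
    """
    t_idx = stay.days.index(output_day)
    windows = list(stay.token_sets[: t_idx + 1])
    full = _output(net, windows)
    pruned_upto = 0
    for k in range(1, len(windows)):  # keep at least the final window
        masked = [
            _baseline_window(net, w) if i < k else w for i, w in enumerate(windows)
        ]
        if abs(_output(net, masked) - full) < tolerance:
            pruned_upto = k
        else:
            break
    return list(range(pruned_upto, len(windows))), list(range(pruned_upto))


def timeshap_for_day(
    net: SequenceNet,
    stay: TokenizedStay,
    day: int,
    tolerance: float = 0.05,
    n_coalitions: Optional[int] = None,
    seed: int = 0,
) -> Attribution:
    """Shapley attribution of the expected next-day TIL-Basic score at
    ``day`` over token-within-window units of unpruned windows plus the
    pruned-past group.  Missing-value tokens are exact null players under
    the all-missing baseline and are reported with phi = 0."""
    if day not in stay.days:
        raise ValueError(f"day {day} outside the tokenised stay")
    t_idx = stay.days.index(day)
    windows = [w.copy() for w in stay.token_sets[: t_idx + 1]]
    kept, pruned = prune_temporal(net, stay, day, tolerance=tolerance)

    units: list[tuple[int, int]] = []  # (window index, token index)
    null_tokens: list[tuple[int, str]] = []
    vocab = net.vocab
    for w in kept:
        for tok in windows[w]:
            s = _token_str(net, int(tok))
            if vocab.is_missing_token(s):
                null_tokens.append((stay.days[w], s))
            else:
                units.append((w, int(tok)))
    has_group = len(pruned) > 0
    M = len(units) + (1 if has_group else 0)

    def value_fn(mask: np.ndarray) -> float:
        ws = [w.copy() for w in windows]
        for on, (wi, tok) in zip(mask[: len(units)], units):
            if not on:
                ws[wi] = _mask_token(net, ws[wi], tok)
        if has_group and not mask[-1]:
            for wi in pruned:
                ws[wi] = _baseline_window(net, ws[wi])
        return _output(net, ws)

    phi = solve_shapley(value_fn, M, n_coalitions=n_coalitions, seed=seed)
    baseline = value_fn(np.zeros(M, dtype=bool))
    observed = value_fn(np.ones(M, dtype=bool))
    return Attribution(
        patient_id=stay.patient_id,
        day=day,
        features=[(stay.days[w], _token_str(net, tok)) for w, tok in units],
        phi=phi[: len(units)],
        phi_pruned=float(phi[-1]) if has_group else 0.0,
        baseline_output=baseline,
        observed_output=observed,
        null_tokens=null_tokens,
    )


def delta_timeshap(
    net: SequenceNet,
    stay: TokenizedStay,
    transition_day: int,
    tolerance: float = 0.05,
    n_coalitions: Optional[int] = None,
    seed: int = 0,
) -> list[DeltaRecord]:
    """ΔTimeSHAP records for one observed change in TIL-Basic.

    The change occurs between ``transition_day - 1`` and
    ``transition_day``; changes on or before day two of the stay are
    excluded (an empty list is returned), since two prior days of
    information are required.
    """
    t = transition_day
    if t - 1 <= 1:
        return []
    d1, d2 = t - 1, t - 2
    if d1 not in stay.days or d2 not in stay.days:
        return []
    i1, i2 = stay.days.index(d1), stay.days.index(d2)
    y_prev = stay.labels[i1]  # TIL at transition_day
    last = stay.last_til[i1]
    if y_prev is None or last is None or y_prev == last:
        return []
    direction = "escalation" if y_prev > last else "de-escalation"

    att1 = timeshap_for_day(net, stay, d1, tolerance=tolerance,
                            n_coalitions=n_coalitions, seed=seed)
    att2 = timeshap_for_day(net, stay, d2, tolerance=tolerance,
                            n_coalitions=n_coalitions, seed=seed + 1)

    vocab = net.vocab
    tokens_d1 = {tok for (d, tok) in att1.features if d == d1}
    tokens_d2 = {tok for (d, tok) in att2.features if d == d2}
    missing_d1 = {tok for (d, tok) in att1.null_tokens if d == d1}
    missing_d2 = {tok for (d, tok) in att2.null_tokens if d == d2}
    records = []
    for tok in sorted(tokens_d1 | tokens_d2 | missing_d1 | missing_d2):
        phi1 = att1.token_phi(d1, tok)
        phi2 = att2.token_phi(d2, tok)
        records.append(
            DeltaRecord(
                patient_id=stay.patient_id,
                transition_day=t,
                token=tok,
                variable=vocab.token_variable(tok),
                delta_phi=phi1 - phi2,
                direction=direction,
                is_missing_token=vocab.is_missing_token(tok),
            )
        )
    return records


def population_ranking(
    records: Sequence[DeltaRecord] | pd.DataFrame,
    n_top: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population-level variable ranking from ΔTimeSHAP records.

    Records are first averaged per (patient, transition day, token)
    across cross-validation partitions, then summarised per variable by
    the median Δ over value (non-missing) tokens.  The table lists the
    ``n_top`` most-negative-median variables (de-escalation block)
    followed by the ``n_top`` most-positive among the remainder
    (escalation block).  Median ties break by record count, then name.
    Missing-value tokens are summarised in a separate table.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "patient_id": r.patient_id,
                    "transition_day": r.transition_day,
                    "token": r.token,
                    "variable": r.variable,
                    "delta_phi": r.delta_phi,
                    "is_missing_token": r.is_missing_token,
                }
                for r in records
            ]
        )
    if df.empty:
        empty = pd.DataFrame(
            columns=["variable", "median_delta", "n_records", "block"]
        )
        return empty, empty.copy()

    agg = (
        df.groupby(["patient_id", "transition_day", "token", "variable",
                    "is_missing_token"], as_index=False)["delta_phi"].mean()
    )

    def summarise(sub: pd.DataFrame) -> pd.DataFrame:
        g = sub.groupby("variable")["delta_phi"]
        out = pd.DataFrame(
            {"median_delta": g.median(), "n_records": g.size()}
        ).reset_index()
        return out

    value = summarise(agg[~agg["is_missing_token"]])
    missing = summarise(agg[agg["is_missing_token"]])
    missing["block"] = "missing"

    value = value.sort_values(
        ["median_delta", "n_records", "variable"], ascending=[True, False, True]
    ).reset_index(drop=True)
    neg = value.head(n_top).copy()
    neg["block"] = "de-escalation"
    rest = value.iloc[len(neg):]
    pos = rest.sort_values(
        ["median_delta", "n_records", "variable"], ascending=[False, False, True]
    ).head(n_top).copy()
    pos["block"] = "escalation"
    ranking = pd.concat([neg, pos], ignore_index=True)
    return ranking, missing.reset_index(drop=True)
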