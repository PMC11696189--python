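"""Ordinal next-day TIL-Basic model: configuration, prediction views,
training, tuning, and a Model/Results front end.

The central object is :class:`NextDayTILModel`, built from a cohort of
stays plus a variable manifest; ``fit()`` trains the token-embedding
recurrent network and returns a :class:`NextDayTILResults` carrying the
trained network, its validation trajectory, held-out predictions and a
``summary()`` table.

Prediction views derived from the 5-category probability vector p:

* threshold probabilities  Pr(Y > k) = sum_{j>k} p_j          (k = 0..3)
* change triple relative to the last available score L:
  p_dec = sum_{j<L} p_j,  p_same = p_L,  p_inc = sum_{j>L} p_j
* expected score  E[Y] = sum_k k p_k
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rnn import N_CLASSES, SequenceNet, TrainingError
from .tokenizer import (
    TokenizedStay,
    TokenVocabulary,
    VariableSet,
    fit_vocabulary,
    tokenize_stay,
)

__all__ = [
    "ModelConfig",
    "OrdinalPrediction",
    "threshold_probabilities",
    "change_probabilities",
    "expected_score",
    "embed_window",
    "forward_stay",
    "train_model",
    "tune_hyperparameters",
    "ordinal_concordance",
    "prediction_frame",
    "permutation_importance",
    "NextDayTILModel",
    "NextDayTILResults",
]

_EMBED_DIMS = (128, 256, 512, 1024)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the sequence model.

    ``embed_dim`` is restricted to the searched grid {128, 256, 512,
    1024}.  ``learning_rate`` must be non-negative; zero is permitted so
    that deliberately broken candidates can be used in tuning tests.
    """

    embed_dim: int = 128
    rnn_type: str = "GRU"
    hidden_dim: int = 32
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 5
    batch_size: int = 32
    weight_decay: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embed_dim not in _EMBED_DIMS:
            raise ValueError(f"embed_dim must be one of {_EMBED_DIMS}")
        if self.rnn_type not in ("GRU", "LSTM"):
            raise ValueError("rnn_type must be 'GRU' or 'LSTM'")
        if self.hidden_dim <= 0 or self.max_epochs <= 0 or self.patience <= 0:
            raise ValueError("dims and epoch counts must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


# ---------------------------------------------------------------------------
# Prediction views

def threshold_probabilities(p: np.ndarray) -> np.ndarray:
    """(Pr(Y>0), Pr(Y>1), Pr(Y>2), Pr(Y>3)) — non-increasing partial sums."""
    p = np.asarray(p, dtype=float)
    return np.cumsum(p[::-1])[::-1][1:]


def change_probabilities(p: np.ndarray, last_til: int) -> tuple[float, float, float]:
    """(p_dec, p_same, p_inc) relative to the last available score."""
    if last_til not in (0, 1, 2, 3, 4):
        raise ValueError("last_til must be an observed score in 0..4")
    p = np.asarray(p, dtype=float)
    return float(p[:last_til].sum()), float(p[last_til]), float(p[last_til + 1:].sum())


def expected_score(p: np.ndarray) -> float:
    """E[Y] = sum_k k p_k, in [0, 4]."""
    p = np.asarray(p, dtype=float)
    return float(np.arange(N_CLASSES) @ p)


@dataclass(frozen=True)
class OrdinalPrediction:
    """One patient-day probability vector over next-day TIL-Basic 0-4."""

    patient_id: str
    day: int
    p: np.ndarray
    last_til: Optional[int] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_CLASSES,) or (p < -1e-9).any() or abs(p.sum() - 1) > 1e-6:
            raise ValueError("p must be a length-5 probability vector")

    @property
    def thresholds(self) -> np.ndarray:
        return threshold_probabilities(self.p)

    @property
    def change(self) -> tuple[float, float, float]:
        if self.last_til is None:
            raise ValueError("no last available TIL-Basic score for this day")
        return change_probabilities(self.p, self.last_til)

    @property
    def expected(self) -> float:
        return expected_score(self.p)


# ---------------------------------------------------------------------------
# Forward / training wrappers

def embed_window(token_idx: np.ndarray, net: SequenceNet) -> np.ndarray:
    """Relevance-weighted mean embedding of one window's unique tokens."""
    return net.embed_window(np.asarray(token_idx, dtype=np.int64))


def forward_stay(stay: TokenizedStay, net: SequenceNet) -> list[OrdinalPrediction]:
    """One causal prediction per daily window of a tokenised stay."""
    probs = net.forward(stay.token_sets)
    return [
        OrdinalPrediction(
            patient_id=stay.patient_id, day=d, p=probs[t], last_til=stay.last_til[t]
        )
        for t, d in enumerate(stay.days)
    ]


def train_model(
    train_stays: Sequence[TokenizedStay],
    val_stays: Sequence[TokenizedStay],
    config: ModelConfig,
    vocab: TokenVocabulary,
) -> tuple[SequenceNet, list[float]]:
    """Train a sequence net; returns (net, validation-loss trajectory)."""
    if vocab.embed_dim != config.embed_dim:
        raise ValueError("vocabulary embed_dim does not match the model config")
    net = SequenceNet(
        vocab=vocab,
        rnn_type=config.rnn_type,
        hidden_dim=config.hidden_dim,
        seed=config.seed,
    )
    trajectory = net.fit(
        train_stays,
        val_stays,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        patience=config.patience,
        batch_size=config.batch_size,
        weight_decay=config.weight_decay,
        seed=config.seed,
    )
    return net, trajectory


def ordinal_concordance(net: SequenceNet, stays: Sequence[TokenizedStay]) -> float:
    """c-index of the expected next-day score against observed labels.

    Pairs of labelled patient-days with distinct observed scores; ties on
    the model output count one half.
    """
    scores, labels = [], []
    for stay in stays:
        probs = net.forward(stay.token_sets)
        for t, y in enumerate(stay.labels):
            if y is not None:
                scores.append(expected_score(probs[t]))
                labels.append(y)
    x = np.asarray(scores)
    y = np.asarray(labels)
    gy = np.sign(y[:, None] - y[None, :])
    gx = np.sign(x[:, None] - x[None, :])
    informative = gy != 0
    n = informative.sum()
    if n == 0:
        return 0.5
    conc = (gx == gy) & informative
    tied = (gx == 0) & informative
    return float((conc.sum() + 0.5 * tied.sum()) / n)


def tune_hyperparameters(
    configs: Sequence[ModelConfig],
    train_stays: Sequence[TokenizedStay],
    internal_val_stays: Sequence[TokenizedStay],
    vocabs: Sequence[TokenVocabulary] | TokenVocabulary,
    return_trace: bool = False,
):
    """Select the config with the best internal-validation ordinal
    concordance; exact ties go to the first listed candidate.
    """
    if not configs:
        raise ValueError("at least one candidate config is required")
    if isinstance(vocabs, TokenVocabulary):
        vocabs = [vocabs] * len(configs)
    trace = []
    best: Optional[tuple[float, int]] = None
    for i, (cfg, vocab) in enumerate(zip(configs, vocabs)):
        net, _ = train_model(train_stays, internal_val_stays, cfg, vocab)
        c = ordinal_concordance(net, internal_val_stays)
        trace.append({"config": cfg, "concordance": c})
        if best is None or c > best[0] + 1e-12:
            best = (c, i)
    assert best is not None
    chosen = configs[best[1]]
    if return_trace:
        return chosen, trace
    return chosen


# ---------------------------------------------------------------------------
# Pooled prediction table

def prediction_frame(
    net: SequenceNet, stays: Sequence[TokenizedStay]
) -> pd.DataFrame:
    """Tidy per-patient-day predictions with observed outcomes.

    Columns: patient_id, day, p0..p4, p_dec, p_same, p_inc, expected,
    last_til, y_next (observed next-day TIL-Basic, NaN if unassessed),
    change (y_next - last_til) — rows for every window of every stay.
    """
    rows = []
    for stay in stays:
        probs = net.forward(stay.token_sets)
        for t, day in enumerate(stay.days):
            p = probs[t]
            last = stay.last_til[t]
            y = stay.labels[t]
            rec = {
                "patient_id": stay.patient_id,
                "day": day,
                **{f"p{k}": p[k] for k in range(N_CLASSES)},
                "expected": expected_score(p),
                "last_til": np.nan if last is None else last,
                "y_next": np.nan if y is None else y,
            }
            if last is not None:
                rec["p_dec"], rec["p_same"], rec["p_inc"] = change_probabilities(p, last)
                rec["change"] = np.nan if y is None else y - last
            else:
                rec["p_dec"] = rec["p_same"] = rec["p_inc"] = np.nan
                rec["change"] = np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Permutation importance (ground-truth recovery diagnostics)

def permutation_importance(
    net: SequenceNet,
    stays: Sequence[TokenizedStay],
    vocab: TokenVocabulary,
    variable: str,
    n_permutations: int = 20,
    seed: int = 0,
) -> dict:
    """Drop in ordinal concordance when a variable's per-window tokens are
    shuffled across all windows of the evaluation set.

    Returns {'baseline', 'permuted' (array), 'importance', 'p_value'};
    p_value = (1 + #{permuted >= baseline}) / (n + 1).
    """
    rng = np.random.default_rng(seed)
    var_token_ids = np.array(
        [i for tok, i in vocab.index.items() if vocab.token_variable(tok) == variable]
    )
    id_set = set(var_token_ids.tolist())

    positions: list[tuple[int, int]] = []
    current: list[int] = []
    for si, stay in enumerate(stays):
        for ti, toks in enumerate(stay.token_sets):
            hit = [x for x in toks.tolist() if x in id_set]
            if hit:
                positions.append((si, ti))
                current.append(hit[0])
    baseline = ordinal_concordance(net, stays)
    permuted = np.empty(n_permutations)
    cur = np.array(current)
    for k in range(n_permutations):
        perm = rng.permutation(cur)
        shuffled = [
            TokenizedStay(
                patient_id=s.patient_id,
                days=s.days,
                token_sets=[ts.copy() for ts in s.token_sets],
                labels=s.labels,
                last_til=s.last_til,
            )
            for s in stays
        ]
        for (si, ti), new_tok in zip(positions, perm):
            ts = shuffled[si].token_sets[ti]
            keep = np.array([x for x in ts.tolist() if x not in id_set] + [int(new_tok)])
            shuffled[si].token_sets[ti] = np.sort(np.unique(keep))
        permuted[k] = ordinal_concordance(net, shuffled)
    p_value = (1 + int((permuted >= baseline).sum())) / (n_permutations + 1)
    return {
        "baseline": baseline,
        "permuted": permuted,
        "importance": float(baseline - permuted.mean()),
        "p_value": float(p_value),
    }


# ---------------------------------------------------------------------------
# Model / Results front end

class NextDayTILModel:
    """Next-day TIL-Basic sequence model bound to a cohort.

    Parameters
    ----------
    stays : sequence of PatientStay
        Cohort including TIL series (see :mod:`tildyn.simulate` or
        :func:`from_frames`).
    manifest : DataFrame
        Variable manifest (name/category/timing/flavor/flag columns).
    config : ModelConfig
    variable_set : {'full', 'no_treatment_impression', 'static_only'}
    val_frac : float
        Fraction of training patients set aside for internal validation.
    """

    def __init__(
        self,
        stays: Sequence,
        manifest: pd.DataFrame,
        config: ModelConfig = ModelConfig(),
        variable_set: VariableSet = "full",
        val_frac: float = 0.15,
        seed: int = 0,
    ) -> None:
        self.stays = list(stays)
        self.manifest = manifest
        self.config = config
        self.variable_set: VariableSet = variable_set
        self.val_frac = val_frac
        self.seed = seed

    @classmethod
    def from_frames(
        cls,
        observations: pd.DataFrame,
        treatments: pd.DataFrame,
        stay_meta: pd.DataFrame,
        manifest: pd.DataFrame,
        **kwargs,
    ) -> "NextDayTILModel":
        """Build from long-format tables (observations: patient_id/day/
        variable/value; treatments: patient_id/day/treatment_code;
        stay_meta: patient_id/centre_id/last_day/wlst_day)."""
        from .scoring import score_stay
        from .simulate import PatientStay

        obs_by = {k: g for k, g in observations.groupby("patient_id")}
        trt_by = {k: g for k, g in treatments.groupby("patient_id")}
        stays = []
        for _, row in stay_meta.iterrows():
            pid = row["patient_id"]
            wlst = row.get("wlst_day")
            wlst_day = None if pd.isna(wlst) or wlst == "" else int(wlst)
            trt = [
                (int(r["day"]), str(r["treatment_code"]))
                for _, r in trt_by.get(pid, pd.DataFrame(columns=["day", "treatment_code"])).iterrows()
            ]
            til = score_stay(trt, last_day=int(row["last_day"]), wlst_day=wlst_day)
            og = obs_by.get(pid)
            obs = (
                [(int(r["day"]), str(r["variable"]), r["value"]) for _, r in og.iterrows()]
                if og is not None
                else []
            )
            stays.append(
                PatientStay(
                    patient_id=str(pid),
                    centre_id=str(row.get("centre_id", "C00")),
                    observations=obs,
                    treatments=trt,
                    wlst_day=wlst_day,
                    last_day=int(row["last_day"]),
                    til_series=til,
                )
            )
        return cls(stays, manifest, **kwargs)

    def fit(self) -> "NextDayTILResults":
        """Fit vocabulary + network on an internal train/validation split."""
        rng = np.random.default_rng(self.seed)
        idx = rng.permutation(len(self.stays))
        n_val = max(1, int(self.val_frac * len(self.stays)))
        val_ids = set(idx[:n_val].tolist())
        train = [s for i, s in enumerate(self.stays) if i not in val_ids]
        val = [s for i, s in enumerate(self.stays) if i in val_ids]
        vocab = fit_vocabulary(
            train, self.manifest, embed_dim=self.config.embed_dim,
            partition_id="fit", seed=self.config.seed,
        )
        tok_train = [tokenize_stay(s, vocab, self.variable_set) for s in train]
        tok_val = [tokenize_stay(s, vocab, self.variable_set) for s in val]
        net, trajectory = train_model(tok_train, tok_val, self.config, vocab)
        return NextDayTILResults(self, net, vocab, trajectory, tok_train, tok_val)


class NextDayTILResults:
    """Fit results: trained network, diagnostics and prediction methods."""

    def __init__(
        self,
        model: NextDayTILModel,
        net: SequenceNet,
        vocab: TokenVocabulary,
        val_trajectory: list[float],
        tok_train: list[TokenizedStay],
        tok_val: list[TokenizedStay],
    ) -> None:
        self.model = model
        self.net = net
        self.vocab = vocab
        self.val_trajectory = val_trajectory
        self._tok_train = tok_train
        self._tok_val = tok_val

    def tokenize(self, stays: Sequence) -> list[TokenizedStay]:
        return [tokenize_stay(s, self.vocab, self.model.variable_set) for s in stays]

    def predict(self, stays: Optional[Sequence] = None) -> pd.DataFrame:
        """Per-patient-day prediction table (internal validation set by
        default; pass raw stays for new data)."""
        tok = self._tok_val if stays is None else self.tokenize(stays)
        return prediction_frame(self.net, tok)

    def attribute(self, stay, day: int, **kwargs):
        """Temporal Shapley attribution of one patient-day (see
        :mod:`tildyn.attribution`)."""
        from .attribution import timeshap_for_day

        tok = self.tokenize([stay])[0]
        return timeshap_for_day(self.net, tok, day, **kwargs)

    def summary(self) -> str:
        """Text summary: fit configuration plus internal-validation
        discrimination at each next-day TIL-Basic threshold."""
        from .evaluate import auc, somers_dxy

        df = self.predict()
        lines = [
            "Next-day TIL-Basic sequence model",
            "=" * 48,
            f"RNN type:        {self.net.rnn_type}",
            f"Embedding dim:   {self.vocab.embed_dim}",
            f"Hidden dim:      {self.net.hidden_dim}",
            f"Variable set:    {self.model.variable_set}",
            f"Vocabulary size: {len(self.vocab)}",
            f"Epochs run:      {len(self.val_trajectory)}"
            f" (best val loss {min(self.val_trajectory):.4f})",
            "",
            "Internal-validation discrimination",
            "-" * 48,
        ]
        labelled = df.dropna(subset=["y_next"])
        for k in range(4):
            y = (labelled["y_next"] > k).astype(int)
            score = labelled[[f"p{j}" for j in range(k + 1, N_CLASSES)]].sum(axis=1)
            if y.nunique() == 2:
                lines.append(f"AUC  Pr(Y>{k}):   {auc(score.values, y.values):.3f}")
            else:
                lines.append(f"AUC  Pr(Y>{k}):   undefined (single class)")
        ch = labelled.dropna(subset=["change"])
        if len(ch) >= 2 and ch["change"].nunique() > 1:
            d = somers_dxy(
                (ch["expected"] - ch["last_til"]).values, ch["change"].values
            )
            lines.append(f"Somers' Dxy (change): {d:.3f}")
        return "\n".join(lines)
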