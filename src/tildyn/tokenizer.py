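"""Tokenisation of mixed-type daily ICU observations.

Every (variable, value) observation becomes one discrete token:

* categorical — variable name + ``=`` + value,
* numeric — variable name + quantile-bin suffix, bins fitted on the
  training partition only (20 quantile bins by default),
* free text — variable name + lower-cased alphanumerics of the text,
* missing — a dedicated per-variable ``<NA>`` token, emitted whenever a
  variable is unobserved in a window, so models can learn patterns of
  missingness instead of relying on imputation,
* unseen value at test time — a per-variable ``<UNK>`` token.

A daily window is represented by its *set* of unique tokens.  Static
variables are carried forward into every window.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

__all__ = [
    "TokenVocabulary",
    "TokenizedStay",
    "VariableSet",
    "fit_vocabulary",
    "discretise_numeric",
    "normalise_text",
    "tokenize_stay",
]

VariableSet = Literal["full", "no_treatment_impression", "static_only"]

_NA = "<NA>"
_UNK = "<UNK>"
_NON_ALNUM = re.compile(r"[^a-z0-9]")


class ManifestError(KeyError):
    """An observation refers to a variable absent from the manifest."""


class FitError(ValueError):
    """Vocabulary fitting failed (e.g. empty training set)."""


def normalise_text(raw: object) -> str:
    """Lower-case alphanumerics of free text ('' for empty/whitespace)."""
    if raw is None:
        return ""
    return _NON_ALNUM.sub("", str(raw).lower())


def discretise_numeric(value: float, bin_edges: Sequence[float]) -> int:
    """Quantile-bin index (1-based) for a numeric value.

    Half-open right-exclusive intervals: a value equal to a cut point is
    assigned to the higher bin.  Values below/above the fitted range are
    clamped to the first/last bin.  Non-finite values are the caller's
    responsibility (they are tokenised as missing upstream).
    """
    edges = np.asarray(bin_edges, dtype=float)
    return int(np.searchsorted(edges, value, side="right")) + 1


@dataclass
class TokenVocabulary:
    """Training-partition-derived token index.

    ``embeddings`` (n_tokens x d) and ``relevance`` free parameters
    (softplus-transformed to positive weights) are initialised here and
    trained by the sequence model in place.
    """

    index: dict[str, int]
    bin_edges: dict[str, list[float]]
    variables: dict[str, dict]  # name -> manifest row (flavor/timing/flags)
    embed_dim: int
    partition_id: str = "all"
    embeddings: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    relevance_raw: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.index)

    def token_variable(self, token: str) -> str:
        """Recover the variable a token encodes (round-trip guarantee)."""
        if "=" in token:
            return token.split("=", 1)[0]
        return token.rsplit("|", 1)[0]

    def is_missing_token(self, token: str) -> bool:
        return token.endswith(f"={_NA}")

    def missing_token(self, variable: str) -> str:
        return f"{variable}={_NA}"

    def lookup(self, variable: str, token: str) -> int:
        """Index of a token, falling back to the variable's unknown token."""
        idx = self.index.get(token)
        if idx is None:
            idx = self.index[f"{variable}={_UNK}"]
        return idx

    def init_parameters(self, rng: np.random.Generator) -> None:
        n, d = len(self.index), self.embed_dim
        self.embeddings = rng.normal(0.0, 1.0 / np.sqrt(d), size=(n, d))
        self.relevance_raw = np.zeros(n)  # softplus(0) = log 2 > 0

    # -- serialisation -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "index": self.index,
                "bin_edges": self.bin_edges,
                "variables": self.variables,
                "embed_dim": self.embed_dim,
                "partition_id": self.partition_id,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TokenVocabulary":
        d = json.loads(text)
        return cls(
            index=d["index"],
            bin_edges=d["bin_edges"],
            variables=d["variables"],
            embed_dim=d["embed_dim"],
            partition_id=d["partition_id"],
        )


@dataclass
class TokenizedStay:
    """Per-day unique token-index sets plus next-day TIL-Basic labels."""

    patient_id: str
    days: list[int]
    token_sets: list[np.ndarray]  # int arrays, aligned with ``days``
    labels: list[Optional[int]]  # next-day TIL-Basic, None if unassessed
    last_til: list[Optional[int]]  # last available score up to each day

    def __post_init__(self) -> None:
        assert len(self.days) == len(self.token_sets) == len(self.labels)


def _token_for_value(vocab_vars: dict, variable: str, value: object,
                     bin_edges: dict[str, list[float]]) -> str:
    """Raw token string for one observed value (no vocabulary filtering)."""
    spec = vocab_vars[variable]
    flavor = spec["flavor"]
    if flavor == "numeric":
        try:
            x = float(value)
        except (TypeError, ValueError):
            x = float("nan")
        if not np.isfinite(x):
            return f"{variable}={_NA}"
        b = discretise_numeric(x, bin_edges.get(variable, []))
        return f"{variable}|bin{b:02d}"
    if flavor == "text":
        norm = normalise_text(value)
        if not norm:
            return f"{variable}={_NA}"
        return f"{variable}|{norm}"
    # categorical
    sval = str(value).strip()
    if not sval:
        return f"{variable}={_NA}"
    return f"{variable}={sval}"


def fit_vocabulary(
    training_stays: Iterable,
    manifest,
    n_bins: int = 20,
    embed_dim: int = 128,
    partition_id: str = "all",
    seed: int = 0,
) -> TokenVocabulary:
    """Fit token vocabulary (bin edges, token index) on training stays only.

    ``manifest`` is a DataFrame with columns name / category / timing /
    flavor / is_treatment_or_impression.  ``training_stays`` are
    ``PatientStay`` objects.  Heavily-tied numeric distributions can yield
    duplicate cut points; duplicates are merged so fewer than ``n_bins``
    effective bins may result, with bin numbering preserved.
    """
    stays = list(training_stays)
    if not stays:
        raise FitError("cannot fit a vocabulary on an empty training set")

    variables = {
        str(row["name"]): {
            "category": str(row["category"]),
            "timing": str(row["timing"]),
            "flavor": str(row["flavor"]),
            "is_treatment_or_impression": bool(row["is_treatment_or_impression"]),
        }
        for _, row in manifest.iterrows()
    }

    # gather training values per variable
    observed: dict[str, list] = {v: [] for v in variables}
    for stay in stays:
        for day, var, value in stay.observations:
            if var not in variables:
                raise ManifestError(f"variable {var!r} not in manifest")
            observed[var].append(value)

    # numeric bin edges: 19 interior quantile cut points for 20 bins
    qs = np.arange(1, n_bins) / n_bins
    bin_edges: dict[str, list[float]] = {}
    for var, spec in variables.items():
        if spec["flavor"] != "numeric":
            continue
        vals = np.asarray(
            [float(x) for x in observed[var]
             if _is_finite_number(x)], dtype=float
        )
        if vals.size == 0:
            bin_edges[var] = []
        else:
            edges = np.quantile(vals, qs)
            bin_edges[var] = np.unique(edges).tolist()

    # token universe
    tokens: list[str] = []
    for var, spec in variables.items():
        tokens.append(f"{var}={_NA}")
        tokens.append(f"{var}={_UNK}")
        if spec["flavor"] == "numeric":
            n_eff = len(bin_edges.get(var, [])) + 1
            tokens.extend(f"{var}|bin{b:02d}" for b in range(1, n_eff + 1))
        else:
            seen = sorted(
                {
                    _token_for_value(variables, var, v, bin_edges)
                    for v in observed[var]
                }
            )
            tokens.extend(t for t in seen if not t.endswith(f"={_NA}"))

    index = {tok: i for i, tok in enumerate(dict.fromkeys(tokens))}
    vocab = TokenVocabulary(
        index=index,
        bin_edges=bin_edges,
        variables=variables,
        embed_dim=embed_dim,
        partition_id=partition_id,
    )
    vocab.init_parameters(np.random.default_rng(seed))
    return vocab


def _is_finite_number(x: object) -> bool:
    try:
        return np.isfinite(float(x))
    except (TypeError, ValueError):
        return False


def eligible_variables(vocab: TokenVocabulary, variable_set: VariableSet) -> list[str]:
    """Variables retained under an ablation filter."""
    out = []
    for var, spec in vocab.variables.items():
        if variable_set == "static_only" and spec["timing"] != "static":
            continue
        if variable_set == "no_treatment_impression" and spec["is_treatment_or_impression"]:
            continue
        out.append(var)
    return out


def tokenize_stay(
    stay,
    vocab: TokenVocabulary,
    variable_set: VariableSet = "full",
) -> TokenizedStay:
    """Convert one stay into per-day unique token-index sets with labels.

    Static tokens are carried into every window; every eligible variable
    unobserved in a window contributes its missing token; values unseen in
    training map to the variable's unknown token.  The label at day t is
    the TIL-Basic score at day t+1 when assessed (absent otherwise, and
    absent on/after WLST).  Windows on/after the WLST day are dropped.
    """
    eligible = eligible_variables(vocab, variable_set)
    eligible_set = set(eligible)

    last = stay.last_day
    if stay.wlst_day is not None:
        last = min(last, stay.wlst_day - 1)
    days = list(range(1, last + 1))

    static_tokens: dict[str, str] = {}
    dynamic_by_day: dict[int, dict[str, str]] = {d: {} for d in days}
    for day, var, value in stay.observations:
        if var not in vocab.variables:
            raise ManifestError(f"variable {var!r} not in manifest")
        if var not in eligible_set:
            continue
        tok = _token_for_value(vocab.variables, var, value, vocab.bin_edges)
        if vocab.variables[var]["timing"] == "static":
            static_tokens[var] = tok
        elif day in dynamic_by_day:
            dynamic_by_day[day][var] = tok

    token_sets: list[np.ndarray] = []
    labels: list[Optional[int]] = []
    last_til: list[Optional[int]] = []
    til = stay.til_series
    for day in days:
        toks: set[int] = set()
        for var in eligible:
            timing = vocab.variables[var]["timing"]
            if timing == "static":
                tok = static_tokens.get(var, vocab.missing_token(var))
            else:
                tok = dynamic_by_day[day].get(var, vocab.missing_token(var))
            toks.add(vocab.lookup(var, tok))
        token_sets.append(np.fromiter(sorted(toks), dtype=np.int64))
        nxt = til.get(day + 1)
        labels.append(nxt)
        last_til.append(til.last_available(day + 1))

    return TokenizedStay(
        patient_id=stay.patient_id,
        days=days,
        token_sets=token_sets,
        labels=labels,
        last_til=last_til,
    )
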