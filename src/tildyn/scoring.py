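"""Daily TIL-Basic scoring from ICP-targeting treatments.

TIL-Basic condenses the 38-point Therapy Intensity Level scale into five
ordered categories of intracranial-pressure (ICP) treatment intensity:

    0  none      no ICP-targeting treatment
    1  basic     positioning, low-dose sedation
    2  mild      CSF drainage (low volume), mild hyperventilation, CPP support
    3  moderate  high-volume drainage, stronger osmotherapy, cooling >= 35 C
    4  extreme   metabolic suppression, hypothermia < 35 C, surgery

A calendar day's score is the *highest* class among all treatments given
that day.  Two special rules apply:

* A decompressive craniectomy performed as a last resort for refractory
  intracranial hypertension scores 4 on the day of the operation **and on
  every subsequent day** of the ICU stay (carry-forward).  Other
  intracranial operations score 4 on the day only.
* Scores are excluded on or after the day of any decision to withdraw
  life-sustaining therapies (WLST).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

__all__ = [
    "TreatmentCatalogue",
    "TilSeries",
    "DEFAULT_CATALOGUE",
    "ASSESSMENT_DAYS",
    "EVALUATION_DAYS",
    "score_day",
    "score_stay",
    "til_basic_median",
    "change_series",
]

#: Days of ICU stay on which TIL treatments are assessed.
ASSESSMENT_DAYS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 10, 14, 21, 28)

#: Days directly preceding an assessment day — the days at which next-day
#: predictions can be evaluated.
EVALUATION_DAYS: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 9, 13, 20, 27)


class CatalogueError(KeyError):
    """A treatment code is not present in the catalogue."""


class UndefinedSummaryError(ValueError):
    """No assessed days available for a summary statistic."""


@dataclass(frozen=True)
class TreatmentCatalogue:
    """Maps treatment codes to their ICP-control class (1-4).

    Exactly one code — the refractory-hypertension decompressive
    craniectomy — carries the carry-forward flag.
    """

    classes: Mapping[str, int]
    refractory_dc_code: str

    def __post_init__(self) -> None:
        for code, cls in self.classes.items():
            if cls not in (1, 2, 3, 4):
                raise ValueError(f"class for {code!r} must be 1-4, got {cls}")
        if self.refractory_dc_code not in self.classes:
            raise ValueError("refractory-DC code must be in the catalogue")
        if self.classes[self.refractory_dc_code] != 4:
            raise ValueError("refractory-DC must be class 4 (extreme)")

    def icp_class(self, code: str) -> int:
        try:
            return self.classes[code]
        except KeyError:
            raise CatalogueError(f"unknown treatment code: {code!r}") from None


#: The published treatment-to-class assignment.  Temperature boundary:
#: cooling at >= 35 C is moderate, therapeutic hypothermia < 35 C is extreme.
DEFAULT_CATALOGUE = TreatmentCatalogue(
    classes={
        # (1) basic
        "head_elevation": 1,
        "nursed_flat": 1,
        "low_dose_sedation": 1,
        # (2) mild
        "higher_dose_sedation": 2,
        "low_volume_csf_drainage": 2,
        "fluid_loading_cpp": 2,
        "vasopressor_therapy_cpp": 2,
        "mild_hyperventilation": 2,
        "low_dose_mannitol": 2,
        "low_dose_hypertonic_saline": 2,
        # (3) moderate
        "high_volume_csf_drainage": 3,
        "moderate_hyperventilation": 3,
        "high_dose_mannitol": 3,
        "high_dose_hypertonic_saline": 3,
        "cooling_for_icp": 3,
        # (4) extreme
        "metabolic_suppression": 4,
        "intensive_hyperventilation": 4,
        "therapeutic_hypothermia": 4,
        "intracranial_operation_mass_lesion": 4,
        "decompressive_craniectomy_refractory": 4,
    },
    refractory_dc_code="decompressive_craniectomy_refractory",
)


@dataclass
class TilSeries:
    """Daily TIL-Basic scores for one patient, honouring WLST censoring."""

    scores: dict[int, int] = field(default_factory=dict)
    wlst_day: Optional[int] = None

    def __post_init__(self) -> None:
        for day, s in self.scores.items():
            if s not in (0, 1, 2, 3, 4):
                raise ValueError(f"TIL-Basic score must be 0-4, got {s}")
            if self.wlst_day is not None and day >= self.wlst_day:
                raise ValueError("no score allowed on/after the WLST day")

    def get(self, day: int) -> Optional[int]:
        return self.scores.get(day)

    def last_available(self, before_day: int) -> Optional[int]:
        """Last assessed score strictly before ``before_day``."""
        prior = [d for d in self.scores if d < before_day]
        return self.scores[max(prior)] if prior else None


def score_day(
    treatments_on_day: Iterable[str],
    prior_refractory_dc: bool,
    catalogue: TreatmentCatalogue = DEFAULT_CATALOGUE,
) -> int:
    """TIL-Basic for one calendar day: max class over given treatments.

    ``prior_refractory_dc`` pins the score at 4 regardless of treatments.
    """
    if prior_refractory_dc:
        return 4
    classes = [catalogue.icp_class(c) for c in treatments_on_day]
    return max(classes, default=0)


def score_stay(
    treatments: Iterable[tuple[int, str]],
    last_day: int,
    wlst_day: Optional[int] = None,
    catalogue: TreatmentCatalogue = DEFAULT_CATALOGUE,
) -> TilSeries:
    """Score every day 1..last_day of a stay.

    The refractory-DC flag becomes true from the day of that operation
    onward.  Days on/after the WLST decision are left unscored.
    """
    by_day: dict[int, set[str]] = {}
    for day, code in treatments:
        catalogue.icp_class(code)  # validate early
        by_day.setdefault(int(day), set()).add(code)

    dc_days = [d for d, codes in by_day.items() if catalogue.refractory_dc_code in codes]
    dc_from = min(dc_days) if dc_days else None

    scores: dict[int, int] = {}
    for day in range(1, last_day + 1):
        if wlst_day is not None and day >= wlst_day:
            break
        flag = dc_from is not None and day >= dc_from
        scores[day] = score_day(by_day.get(day, ()), flag, catalogue)
    return TilSeries(scores=scores, wlst_day=wlst_day)


def til_basic_median(series: TilSeries) -> int:
    """Median of the daily scores over days 1-7 (available days only).

    Uses the lower median for an even number of available days so the
    summary stays on the ordinal 0-4 scale.
    """
    vals = sorted(series.scores[d] for d in range(1, 8) if d in series.scores)
    if not vals:
        raise UndefinedSummaryError("no TIL-Basic scores on days 1-7")
    return statistics.median_low(vals)


def change_series(series: TilSeries) -> list[tuple[int, str]]:
    """Day-to-day change directions over consecutive assessed day pairs.

    Returns ``(day, direction)`` where the change is day -> day+1 and
    direction is 'de-escalation', 'none' or 'escalation'.  Pairs with
    either score missing are skipped.
    """
    out: list[tuple[int, str]] = []
    for day in sorted(series.scores):
        a, b = series.scores.get(day), series.scores.get(day + 1)
        if a is None or b is None:
            continue
        direction = "escalation" if b > a else ("de-escalation" if b < a else "none")
        out.append((day, direction))
    return out
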