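"""PERCIST response classification and tumor-burden change metrics.

The PERCIST category is assigned from the SUL_max of the hottest single
lesion at each timepoint — the follow-up hottest lesion need not be the
same lesion as at baseline:

* PMD: development of a new lesion, or dSUL > +30%;
* CMR: complete resolution (no measurable lesion on follow-up);
* PMR: dSUL <= -30%;
* SMD: none of the above.

Precedence is new-lesion PMD > dSUL PMD > CMR > PMR > SMD.  Metabolic
responders (MR) are CMR or PMR; nonresponders (nMR) are SMD or PMD.  This
follows the percentage-only rule set; the additional 0.8-SUL-unit absolute
change that strict PERCIST 1.0 requires for PMR/PMD is available behind
``strict_percist``.

Burden change metrics are percentage changes of the target-lesion sums
(dsumSUL, dsumMTV, dsumTLG); lesions that resolved completely contribute 0
to the follow-up sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .lesions import TargetLesionSet


class PercistCategory(str, Enum):
    CMR = "CMR"
    PMR = "PMR"
    SMD = "SMD"
    PMD = "PMD"


class RecistGroup(str, Enum):
    NPD = "nPD"
    PD = "PD"


@dataclass(frozen=True)
class PercistAssessment:
    baseline_hottest_sul: float
    followup_hottest_sul: Optional[float]
    delta_sul_pct: Optional[float]
    new_lesion: bool
    category: PercistCategory

    @property
    def responder(self) -> bool:
        return self.category in (PercistCategory.CMR, PercistCategory.PMR)


@dataclass(frozen=True)
class BurdenSummary:
    bsum_sul: float
    bsum_mtv_cm3: float
    bsum_tlg_g: float
    dsum_sul_pct: float
    dsum_mtv_pct: float
    dsum_tlg_pct: float


def delta_percent(baseline: float, followup: float) -> float:
    """Percentage change 100 * (followup - baseline) / baseline."""
    if baseline <= 0:
        raise ValueError("baseline value must be positive")
    if followup < 0:
        raise ValueError("follow-up value must be non-negative")
    return 100.0 * (followup - baseline) / baseline


def classify_percist(baseline_hottest_sul: float,
                     followup_hottest_sul: Optional[float],
                     new_lesion: bool = False,
                     strict_percist: bool = False,
                     min_absolute_change: float = 0.8,
                     ) -> PercistAssessment:
    """Assign the PERCIST category from hottest-lesion SULs.

    ``followup_hottest_sul=None`` means no measurable lesion remains on the
    follow-up scan (complete resolution).  Boundary handling: dSUL of
    exactly -30% is PMR, exactly +30% is SMD.
    """
    if baseline_hottest_sul is None or baseline_hottest_sul <= 0:
        raise ValueError("baseline hottest-lesion SUL is required and must be positive")

    delta: Optional[float] = None
    abs_change = None
    if followup_hottest_sul is not None:
        delta = delta_percent(baseline_hottest_sul, followup_hottest_sul)
        abs_change = abs(followup_hottest_sul - baseline_hottest_sul)

    def _abs_ok() -> bool:
        return (not strict_percist) or (abs_change is not None and abs_change >= min_absolute_change)

    if new_lesion:
        category = PercistCategory.PMD
    elif delta is not None and delta > 30.0 and _abs_ok():
        category = PercistCategory.PMD
    elif followup_hottest_sul is None:
        category = PercistCategory.CMR
    elif delta is not None and delta <= -30.0 and _abs_ok():
        category = PercistCategory.PMR
    else:
        category = PercistCategory.SMD

    return PercistAssessment(
        baseline_hottest_sul=float(baseline_hottest_sul),
        followup_hottest_sul=None if followup_hottest_sul is None else float(followup_hottest_sul),
        delta_sul_pct=delta,
        new_lesion=bool(new_lesion),
        category=category,
    )


def summarize_burden(baseline: TargetLesionSet,
                     followup_matched: TargetLesionSet) -> BurdenSummary:
    """Baseline sums and percentage changes of the target-lesion burden.

    ``followup_matched`` holds the follow-up measurements of the matched
    baseline target lesions only; a baseline lesion with no match (resolved)
    is simply absent and thus contributes 0 to every follow-up sum.
    """
    if len(baseline) == 0:
        raise ValueError("baseline target lesion set is empty")
    return BurdenSummary(
        bsum_sul=baseline.sum_sul,
        bsum_mtv_cm3=baseline.sum_mtv_cm3,
        bsum_tlg_g=baseline.sum_tlg_g,
        dsum_sul_pct=delta_percent(baseline.sum_sul, followup_matched.sum_sul),
        dsum_mtv_pct=delta_percent(baseline.sum_mtv_cm3, followup_matched.sum_mtv_cm3),
        dsum_tlg_pct=delta_percent(baseline.sum_tlg_g, followup_matched.sum_tlg_g),
    )


def dichotomize_recist(recist_label: str) -> RecistGroup:
    """Collapse a RECIST 1.1 label to the PD / non-PD dichotomy.

    CR, PR and SD all count as non-PD — the decision boundary that governs
    whether therapy continues.
    """
    label = str(recist_label).strip().upper()
    if label == "PD":
        return RecistGroup.PD
    if label in ("CR", "PR", "SD"):
        return RecistGroup.NPD
    raise ValueError(f"unknown RECIST label {recist_label!r}")
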