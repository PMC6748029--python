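"""Reference demographic count tables and proportion reporting.

These are the published headcounts of the case cohort (and its three
cytokine-ratio subgroups) whose structure the synthetic generator emulates.
They serve as worked examples for the frequency reporting used throughout
the pipeline: every percentage is recomputed from the affected/total counts
rather than transcribed.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CohortCounts:
    """Affected/total headcounts for one cohort column."""

    n: int
    male: int
    female: int
    cognitive_below_1pct: int
    disturbed_sleep: int
    gi_symptoms: int
    nfa_history: int
    seizure_disorders: int
    antibody_deficiency: int
    allergic_rhinitis: int
    asthma: int


#: Full case cohort (N = 105 subjects).
ASD_COHORT = CohortCounts(
    n=105, male=88, female=17, cognitive_below_1pct=78, disturbed_sleep=36,
    gi_symptoms=73, nfa_history=64, seizure_disorders=13,
    antibody_deficiency=20, allergic_rhinitis=21, asthma=14)

#: Cytokine-ratio subgroups of the case cohort (classified subjects).
SUBGROUP_COHORTS: dict[str, CohortCounts] = {
    "high": CohortCounts(
        n=46, male=39, female=7, cognitive_below_1pct=33, disturbed_sleep=14,
        gi_symptoms=29, nfa_history=26, seizure_disorders=4,
        antibody_deficiency=8, allergic_rhinitis=11, asthma=8),
    "normal": CohortCounts(
        n=37, male=30, female=7, cognitive_below_1pct=29, disturbed_sleep=11,
        gi_symptoms=27, nfa_history=20, seizure_disorders=5,
        antibody_deficiency=6, allergic_rhinitis=8, asthma=4),
    "low": CohortCounts(
        n=22, male=19, female=3, cognitive_below_1pct=16, disturbed_sleep=11,
        gi_symptoms=17, nfa_history=18, seizure_disorders=4,
        antibody_deficiency=6, allergic_rhinitis=2, asthma=2),
}


def percent(numerator: int, denominator: int, digits: int = 1) -> float:
    """Percentage of ``numerator`` in ``denominator``, rounded."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    return round(100.0 * numerator / denominator, digits)


def feature_percent(cohort: CohortCounts, feature: str, digits: int = 1) -> float:
    """Percentage of a cohort affected by ``feature`` (a counts field)."""
    return percent(getattr(cohort, feature), cohort.n, digits)


def male_percent(cohort: CohortCounts, digits: int = 1) -> float:
    """Percentage of males from the male:female split."""
    return percent(cohort.male, cohort.male + cohort.female, digits)
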