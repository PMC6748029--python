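"""Threshold-rule classification of subjects by IL-1b/IL-10 ratios.

Per-subject, per-condition ratios are compared against control-derived
mean/SD reference statistics. A subject is **high** when the ratio exceeds
mean + 2 SD under at least one condition or mean + 1 SD under at least
three conditions; **low** when the ratio falls below mean - 1 SD under at
least one condition; **normal** when every condition sits strictly inside
the +/-1 SD band, or exactly one condition sits in the (+1 SD, +2 SD) band
with the rest inside. Patterns covered by none of the three rules (e.g.
exactly two conditions in the +1..+2 SD band) are resolved by the
configured gap policy; simultaneous high and low firings by the conflict
policy. All thresholds use strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import RuleConfig
from .errors import DegenerateReferenceError, ParseError, UnclassifiableError
from .simulate import CohortDataset


@dataclass
class ControlReference:
    """Per-condition mean/SD (sample SD, n-1 denominator) of control ratios."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_control: dict[str, int]

    @property
    def conditions(self) -> list[str]:
        return list(self.mean)


@dataclass
class SubgroupLabel:
    value: str  # high | normal | low | ambiguous
    fired_rules: list[tuple[str, str]] = field(default_factory=list)
    rule_gap: bool = False
    conflict: bool = False


def compute_ratio_table(
    cytokine_table: pd.DataFrame,
    il1b: str = "IL-1b",
    il10: str = "IL-10",
) -> pd.DataFrame:
    """Cell-wise IL-1b/IL-10 ratios in long format.

    Returns columns subject_id, sample_id, timepoint, condition, ratio,
    valid. A cell is invalid when IL-10 is zero or censored (no silent
    infinities); IL-1b = 0 with positive IL-10 gives a valid ratio of 0.
    """
    for col in ("subject_id", "condition", "cytokine", "pg_ml"):
        if col not in cytokine_table.columns:
            raise ParseError(f"cytokine table: missing required column {col!r}")
    present = set(cytokine_table["cytokine"])
    for needed in (il1b, il10):
        if needed not in present:
            raise ParseError(f"cytokine table: no rows for cytokine {needed!r}")

    table = cytokine_table.copy()
    if "sample_id" not in table.columns:
        table["sample_id"] = table["subject_id"]
    if "timepoint" not in table.columns:
        table["timepoint"] = 0
    if "censored" not in table.columns:
        table["censored"] = False

    keys = ["subject_id", "sample_id", "timepoint", "condition"]
    sub = table[table["cytokine"].isin([il1b, il10])]
    wide = sub.pivot_table(index=keys, columns="cytokine", values="pg_ml",
                           aggfunc="first")
    cens = sub.pivot_table(index=keys, columns="cytokine", values="censored",
                           aggfunc="first").astype(bool)

    num = wide[il1b]
    den = wide[il10]
    valid = den.notna() & num.notna() & (den > 0) & ~cens[il10]
    ratio = pd.Series(np.where(valid, num / den.replace(0, np.nan), np.nan),
                      index=wide.index)
    out = ratio.rename("ratio").reset_index()
    out["valid"] = valid.to_numpy()
    return out


def control_reference(
    ratio_table: pd.DataFrame,
    control_ids: Iterable[str],
    conditions: Optional[Sequence[str]] = None,
    min_controls: int = 5,
) -> ControlReference:
    """Mean and sample SD of valid control ratios per condition.

    Raises :class:`DegenerateReferenceError` when any used condition has
    fewer than ``min_controls`` valid control ratios or zero SD.
    """
    control_ids = set(control_ids)
    sub = ratio_table[ratio_table["subject_id"].isin(control_ids) & ratio_table["valid"]]
    if conditions is None:
        conditions = list(dict.fromkeys(ratio_table["condition"]))
    mean, sd, n = {}, {}, {}
    for cond in conditions:
        vals = sub.loc[sub["condition"] == cond, "ratio"].to_numpy(dtype=float)
        if len(vals) < min_controls:
            raise DegenerateReferenceError(
                f"condition {cond!r}: only {len(vals)} valid control ratios "
                f"(minimum {min_controls})")
        s = float(np.std(vals, ddof=1))
        if s == 0.0:
            raise DegenerateReferenceError(
                f"condition {cond!r}: control ratios have zero standard deviation")
        mean[cond] = float(np.mean(vals))
        sd[cond] = s
        n[cond] = int(len(vals))
    return ControlReference(mean=mean, sd=sd, n_control=n)


def classify_subject(
    subject_ratios: Mapping[str, Optional[float]],
    reference: ControlReference,
    rules: Optional[RuleConfig] = None,
) -> SubgroupLabel:
    """Apply the three-band threshold rule to one subject-timepoint.

    ``subject_ratios`` maps condition -> ratio, with ``None`` (or NaN)
    marking invalid cells; invalid cells are excluded from every count.
    """
    rules = rules or RuleConfig()
    rules.validate()
    conds = rules.conditions_used or tuple(reference.conditions)
    usable = {}
    for cond in conds:
        if cond not in reference.mean:
            continue
        r = subject_ratios.get(cond)
        if r is None or (isinstance(r, float) and np.isnan(r)):
            continue
        usable[cond] = float(r)
    if not usable:
        raise UnclassifiableError("no valid ratio under any usable culture condition")

    hi2, hi1, lo1, band, inside, boundary = [], [], [], [], [], []
    z = {}
    for cond, r in usable.items():
        mu, sigma = reference.mean[cond], reference.sd[cond]
        z[cond] = (r - mu) / sigma
        if r > mu + 2 * sigma:
            hi2.append(cond)
            hi1.append(cond)
        elif r > mu + sigma:
            hi1.append(cond)
            band.append(cond)
        elif r < mu - sigma:
            lo1.append(cond)
        elif mu - sigma < r < mu + sigma:
            inside.append(cond)
        else:
            boundary.append(cond)  # exactly on a threshold: matches no rule

    fired: list[tuple[str, str]] = []
    fired += [(c, ">+2SD") for c in hi2]
    fired += [(c, ">+1SD") for c in hi1 if c not in hi2]
    fired += [(c, "<-1SD") for c in lo1]

    high = len(hi2) >= rules.high_2sd_min_conditions or \
        len(hi1) >= rules.high_1sd_min_conditions
    low = len(lo1) >= rules.low_1sd_min_conditions
    normal = (not high and not low and not boundary
              and len(lo1) == 0 and len(hi2) == 0 and len(band) <= 1)

    if high and low:
        if rules.conflict_policy == "strict":
            return SubgroupLabel("ambiguous", fired, conflict=True)
        # max_abs_z tiebreak
        top = max(z.values(), key=abs)
        return SubgroupLabel("high" if top > 0 else "low", fired, conflict=True)
    if high:
        return SubgroupLabel("high", fired)
    if low:
        return SubgroupLabel("low", fired)
    if normal:
        return SubgroupLabel("normal", fired)
    # pattern covered by none of the three rules
    return SubgroupLabel("normal", fired, rule_gap=True)


def reconcile_timepoints(labels: Sequence[SubgroupLabel]) -> SubgroupLabel:
    """Collapse per-timepoint labels into one subject label.

    Identical labels keep that label; normal+low -> low; normal+high ->
    high (by symmetry); any high+low combination, or any ambiguous input,
    -> ambiguous.
    """
    if not labels:
        raise ValueError("reconcile_timepoints: empty label list")
    values = {lab.value for lab in labels}
    fired = [fr for lab in labels for fr in lab.fired_rules]
    gap = any(lab.rule_gap for lab in labels)
    conflict = any(lab.conflict for lab in labels)
    if "ambiguous" in values or {"high", "low"} <= values:
        return SubgroupLabel("ambiguous", fired, rule_gap=gap, conflict=True)
    for tail in ("high", "low"):
        if tail in values:
            return SubgroupLabel(tail, fired, rule_gap=gap, conflict=conflict)
    return SubgroupLabel("normal", fired, rule_gap=gap, conflict=conflict)


def classify_cohort(
    dataset: CohortDataset,
    rules: Optional[RuleConfig] = None,
) -> tuple[pd.DataFrame, list[dict]]:
    """Classify every case subject; returns (labels table, audit log).

    The audit log holds one record per case subject-timepoint with the
    rules that fired and any gap/conflict flags; the labels table has one
    reconciled row per case subject.
    """
    rules = rules or RuleConfig()
    ratio_table = compute_ratio_table(dataset.cytokine_table)
    reference = control_reference(ratio_table, dataset.control_subject_ids,
                                  min_controls=rules.min_controls)

    case_ids = list(dataset.subjects.loc[
        dataset.subjects["diagnosis"] != "control", "subject_id"])
    audit: list[dict] = []
    rows = []
    for sid in case_ids:
        sub = ratio_table[ratio_table["subject_id"] == sid]
        per_tp: list[SubgroupLabel] = []
        for tp, tp_rows in sub.groupby("timepoint"):
            ratios = {
                row["condition"]: (row["ratio"] if row["valid"] else None)
                for _, row in tp_rows.iterrows()
            }
            label = classify_subject(ratios, reference, rules)
            per_tp.append(label)
            audit.append(dict(
                subject_id=sid, timepoint=int(tp), label=label.value,
                fired_rules=[list(fr) for fr in label.fired_rules],
                rule_gap=label.rule_gap, conflict=label.conflict))
        final = reconcile_timepoints(per_tp)
        rows.append(dict(
            subject_id=sid, label=final.value, n_timepoints=len(per_tp),
            rule_gap=final.rule_gap, conflict=final.conflict,
            fired_rules=";".join(f"{c}:{r}" for c, r in final.fired_rules)))
    labels_df = pd.DataFrame(
        rows, columns=["subject_id", "label", "n_timepoints", "rule_gap",
                       "conflict", "fired_rules"])
    return labels_df, audit
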