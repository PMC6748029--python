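"""Bioenergetic parameters from 4-phase sequential-injection OCR traces.

Phase protocol: baseline -> oligomycin -> FCCP -> antimycin A + rotenone,
three measurements per phase. Derived quantities (all pMol/min):

- non-mitochondrial = antimycin/rotenone OCR
- basal             = baseline - non-mitochondrial
- ALR (ATP-linked)  = baseline - oligomycin
- PLR (proton leak) = oligomycin - non-mitochondrial
- MRC (maximal)     = FCCP - non-mitochondrial
- RC (reserve)      = MRC - basal

plus the efficiency ratios ALR/PLR and MRC/PLR (undefined when PLR <= 0).
Negative derived values are reported with QC flags, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .config import OCR_PHASES
from .errors import MissingPhaseError

SUMMARY_RULES = ("mean", "median", "last")


@dataclass
class RespirationParams:
    non_mito: float
    basal: float
    alr: float
    plr: float
    mrc: float
    rc: float
    alr_over_plr: float  # NaN when PLR <= 0
    mrc_over_plr: float
    qc_flags: list[str] = field(default_factory=list)


def phase_summaries(
    trace: pd.DataFrame,
    summary_rule: str = "mean",
) -> tuple[dict[str, float], list[str]]:
    """One summary OCR value per phase plus structural QC flags.

    ``trace`` needs columns phase and ocr_pmol_min (one subject's rows).
    """
    if summary_rule not in SUMMARY_RULES:
        raise ValueError(f"summary_rule must be one of {SUMMARY_RULES}")
    flags: list[str] = []
    values: dict[str, float] = {}
    for phase in OCR_PHASES:
        vals = trace.loc[trace["phase"] == phase, "ocr_pmol_min"].to_numpy(dtype=float)
        if len(vals) == 0:
            raise MissingPhaseError(f"trace has no measurements for phase {phase!r}")
        if len(vals) != 3:
            flags.append(f"replicate_count:{phase}:{len(vals)}")
        if summary_rule == "mean":
            values[phase] = float(np.mean(vals))
        elif summary_rule == "median":
            values[phase] = float(np.median(vals))
        else:
            values[phase] = float(vals[-1])
    return values, flags


def derive_parameters(phase_values: Mapping[str, float]) -> RespirationParams:
    """Derive all respiration parameters from the four phase summaries.

    The identities basal = ALR + PLR and RC = MRC - basal hold exactly by
    construction.
    """
    missing = [p for p in OCR_PHASES if p not in phase_values]
    if missing:
        raise MissingPhaseError(f"phase values missing {missing}")
    baseline = float(phase_values["baseline"])
    oligo = float(phase_values["oligomycin"])
    fccp = float(phase_values["FCCP"])
    non_mito = float(phase_values["antimycin_rotenone"])

    alr = baseline - oligo
    plr = oligo - non_mito
    basal = alr + plr  # == baseline - non_mito; identity exact by construction
    mrc = fccp - non_mito
    rc = mrc - basal

    flags = []
    for name, v in (("basal", basal), ("ALR", alr), ("PLR", plr),
                    ("MRC", mrc), ("RC", rc)):
        if v < 0:
            flags.append(f"negative_{name}")
    if plr > 0:
        alr_over_plr = alr / plr
        mrc_over_plr = mrc / plr
    else:
        alr_over_plr = float("nan")
        mrc_over_plr = float("nan")
        flags.append("ratios_undefined_plr_nonpositive")
    return RespirationParams(
        non_mito=non_mito, basal=basal, alr=alr, plr=plr, mrc=mrc, rc=rc,
        alr_over_plr=alr_over_plr, mrc_over_plr=mrc_over_plr, qc_flags=flags)


def qc_trace(trace: pd.DataFrame, cv_threshold: float = 0.25) -> list[str]:
    """Quality flags for one subject's trace (never raises).

    Flags: wrong replicate counts, missing phases, no oligomycin response
    (oligomycin mean >= baseline mean), no FCCP response (FCCP mean <=
    baseline mean), antimycin above oligomycin, negative raw readings, and
    noisy phases (within-phase CV above ``cv_threshold``).
    """
    flags: list[str] = []
    means: dict[str, float] = {}
    for phase in OCR_PHASES:
        vals = trace.loc[trace["phase"] == phase, "ocr_pmol_min"].to_numpy(dtype=float)
        if len(vals) == 0:
            flags.append(f"missing_phase:{phase}")
            continue
        if len(vals) != 3:
            flags.append(f"replicate_count:{phase}:{len(vals)}")
        if (vals < 0).any():
            flags.append(f"negative_raw_ocr:{phase}")
        m = float(np.mean(vals))
        means[phase] = m
        if m != 0 and len(vals) > 1:
            cv = float(np.std(vals, ddof=1)) / abs(m)
            if cv > cv_threshold:
                flags.append(f"noisy_phase:{phase}")
    if {"baseline", "oligomycin"} <= means.keys() and \
            means["oligomycin"] >= means["baseline"]:
        flags.append("no_oligomycin_response")
    if {"baseline", "FCCP"} <= means.keys() and means["FCCP"] <= means["baseline"]:
        flags.append("no_fccp_response")
    if {"oligomycin", "antimycin_rotenone"} <= means.keys() and \
            means["antimycin_rotenone"] >= means["oligomycin"]:
        flags.append("no_antimycin_response")
    return flags


def respiration_table(
    ocr_traces: pd.DataFrame,
    summary_rule: str = "mean",
    cv_threshold: float = 0.25,
) -> pd.DataFrame:
    """Per-subject respiration parameters from a long OCR trace table."""
    rows = []
    for sid, trace in ocr_traces.groupby("subject_id", sort=False):
        values, structural = phase_summaries(trace, summary_rule)
        params = derive_parameters(values)
        flags = structural + qc_trace(trace, cv_threshold) + params.qc_flags
        rows.append(dict(
            subject_id=sid, non_mito=params.non_mito, basal=params.basal,
            ALR=params.alr, PLR=params.plr, MRC=params.mrc, RC=params.rc,
            alr_over_plr=params.alr_over_plr, mrc_over_plr=params.mrc_over_plr,
            qc_flags=";".join(dict.fromkeys(flags))))
    return pd.DataFrame(rows)
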