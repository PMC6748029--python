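"""Seeded synthetic cohort generator.

Produces cohorts with the statistical structure the downstream stages
assume: log-normal cytokine production under four culture conditions with
subgroup-dependent IL-1b/IL-10 ratio shifts, 4-phase OCR traces with three
measurements per phase, negative-binomial miRNA counts with a planted
differential-expression pattern, and rank correlations planted through a
Gaussian copula. Every draw flows from one :class:`numpy.random.Generator`
seeded from the config, so identical configs give identical datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .config import OCR_PHASES, SUBGROUPS, CorrelationPlanEntry, SimulationConfig
from .errors import ConfigurationError

SUBJECT_COLUMNS = [
    "subject_id", "diagnosis", "age", "gender", "severity",
    "neuroleptics", "adhd_meds", "aed", "ssri",
    "nfa", "seizure", "sad", "ar", "asthma", "gi", "sleep",
]

SAMPLE_COLUMNS = ["sample_id", "subject_id", "timepoint"]

# clinical-feature frequencies used to dress synthetic case subjects; they
# mirror the reference demographic counts in :mod:`immunomir.demographics`.
_CASE_FLAG_RATES = {
    "nfa": 0.61, "seizure": 0.124, "sad": 0.19, "ar": 0.20,
    "asthma": 0.133, "gi": 0.695, "sleep": 0.343,
    "neuroleptics": 0.20, "adhd_meds": 0.20, "aed": 0.29, "ssri": 0.15,
}


@dataclass
class MiRNACountMatrix:
    """Raw miRNA counts (features x samples) plus per-sample library sizes.

    ``library_sizes`` are total mapped reads and are stored independently of
    the column sums (they may exceed the miRNA-assigned totals).
    """

    counts: pd.DataFrame
    library_sizes: pd.Series

    def validate(self) -> None:
        if list(self.counts.columns) != list(self.library_sizes.index):
            raise ValueError("count columns and library_sizes index disagree")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.library_sizes < 1).any():
            raise ValueError("library sizes must be >= 1")


@dataclass
class CohortDataset:
    """Bundled cohort tables with optional simulation ground truth."""

    subjects: pd.DataFrame
    samples: pd.DataFrame
    cytokine_table: pd.DataFrame
    ocr_traces: pd.DataFrame
    mirna_counts: MiRNACountMatrix
    truth: Optional[dict] = None

    def validate(self) -> None:
        known = set(self.subjects["subject_id"])
        for name, frame in (
            ("samples", self.samples),
            ("cytokine_table", self.cytokine_table),
            ("ocr_traces", self.ocr_traces),
        ):
            unknown = set(frame["subject_id"]) - known
            if unknown:
                raise ValueError(f"{name} references unknown subjects: {sorted(unknown)[:5]}")
        if (self.cytokine_table["pg_ml"] < 0).any():
            raise ValueError("cytokine concentrations must be >= 0")
        self.mirna_counts.validate()
        sample_ids = set(self.samples["sample_id"])
        unknown_cols = set(self.mirna_counts.counts.columns) - sample_ids
        if unknown_cols:
            raise ValueError(f"count columns not in samples table: {sorted(unknown_cols)[:5]}")

    @property
    def control_subject_ids(self) -> list[str]:
        mask = self.subjects["diagnosis"] == "control"
        return list(self.subjects.loc[mask, "subject_id"])


def _make_subjects(config: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, pd.Series]:
    """Subject roster plus planted per-subject labels (control or subgroup)."""
    rows = []
    labels = {}
    idx = 1
    for _ in range(config.n_control):
        sid = f"C{idx:03d}"
        rows.append(
            dict(subject_id=sid, diagnosis="control",
                 age=round(float(rng.uniform(4.0, 30.0)), 1),
                 gender="M" if rng.random() < 0.77 else "F",
                 severity="not_applicable",
                 **{k: False for k in _CASE_FLAG_RATES}))
        labels[sid] = "control"
        idx += 1
    idx = 1
    for grp in SUBGROUPS:
        for _ in range(config.n_per_subgroup.get(grp, 0)):
            sid = f"A{idx:03d}"
            sev = rng.choice(["severe", "moderate", "mild"], p=[0.58, 0.21, 0.21])
            rows.append(
                dict(subject_id=sid, diagnosis="ASD",
                     age=round(float(rng.uniform(2.0, 22.0)), 1),
                     gender="M" if rng.random() < 0.84 else "F",
                     severity=str(sev),
                     **{k: bool(rng.random() < p) for k, p in _CASE_FLAG_RATES.items()}))
            labels[sid] = grp
            idx += 1
    subjects = pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
    return subjects, pd.Series(labels, name="label")


def _make_samples(subjects: pd.DataFrame, labels: pd.Series,
                  config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for sid in subjects["subject_id"]:
        rows.append(dict(sample_id=sid, subject_id=sid, timepoint=0))
    case_ids = [s for s in subjects["subject_id"] if labels[s] != "control"]
    n_rep = min(config.n_repeat_timepoints, len(case_ids))
    for sid in rng.choice(case_ids, size=n_rep, replace=False) if n_rep else []:
        rows.append(dict(sample_id=f"{sid}_t1", subject_id=str(sid), timepoint=1))
    samples = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    samples["label"] = samples["subject_id"].map(labels)
    return samples


def simulate_cytokine_profiles(
    samples: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    latent: Optional[dict[tuple[str, str, str], float]] = None,
) -> pd.DataFrame:
    """Long-format cytokine table (sample x condition x cytokine, pg/ml).

    Concentrations are log-normal; subgroup ratio shifts apply only to
    IL-1b and IL-10 in the configured shift conditions. Values below
    ``detection_limit`` (when set) are substituted by the limit and flagged.

    ``latent`` maps (sample_id, condition, cytokine) -> standard-normal
    draw; missing entries are drawn from ``rng`` (the generator fills the
    full grid up front so draw order is deterministic).
    """
    known = set(("control",) + SUBGROUPS)
    bad = set(samples["label"]) - known
    if bad:
        raise ConfigurationError(f"unknown subgroup labels: {sorted(bad)}")

    latent = dict(latent or {})
    rows = []
    for _, srow in samples.iterrows():
        sample_id, subject_id, tp, label = (
            srow["sample_id"], srow["subject_id"], srow["timepoint"], srow["label"])
        shift = config.ratio_shift.get(label, 1.0) if label != "control" else 1.0
        shift_conditions = (config.shift_conditions or {}).get(label, config.conditions) \
            if label != "control" else ()
        sd_scale = config.subgroup_ratio_sd_scale.get(label, 1.0) if label != "control" else 1.0
        for cond in config.conditions:
            for cyt in config.cytokines:
                key = (sample_id, cond, cyt)
                z = latent.get(key)
                if z is None:
                    z = float(rng.standard_normal())
                logmean = config.cytokine_logmean[(cond, cyt)]
                logsd = config.cytokine_logsd[(cond, cyt)]
                if cyt in ("IL-1b", "IL-10"):
                    logsd = logsd * sd_scale
                val = math.exp(logmean + logsd * z)
                if cond in shift_conditions:
                    if cyt == "IL-1b":
                        val *= math.sqrt(shift)
                    elif cyt == "IL-10":
                        val /= math.sqrt(shift)
                censored = False
                if config.detection_limit is not None and val < config.detection_limit:
                    val = config.detection_limit
                    censored = True
                rows.append(
                    dict(subject_id=subject_id, sample_id=sample_id, timepoint=tp,
                         condition=cond, cytokine=cyt, pg_ml=val, censored=censored))
    return pd.DataFrame(rows)


def simulate_ocr_traces(
    subjects_or_samples: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    subject_effects: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """4-phase OCR traces, three measurements per phase, per subject.

    Each subject carries a multiplicative level effect exp(subject_sd * z)
    shared across phases; Gaussian measurement noise is added on top.
    """
    config.ocr_params.validate()
    subject_ids = list(dict.fromkeys(subjects_or_samples["subject_id"]))
    if subject_effects is None:
        subject_effects = pd.Series(rng.standard_normal(len(subject_ids)), index=subject_ids)
    params = config.ocr_params
    rows = []
    for sid in subject_ids:
        level = math.exp(params.subject_sd * float(subject_effects[sid]))
        for phase_idx, phase in enumerate(OCR_PHASES):
            mean = params.phase_means[phase] * level
            for rep in (1, 2, 3):
                noise = float(rng.standard_normal()) * params.noise_sd
                rows.append(
                    dict(subject_id=sid, phase=phase, replicate=rep,
                         minutes=phase_idx * 18 + rep * 6,
                         ocr_pmol_min=mean + noise))
    return pd.DataFrame(rows)


def _nb_quantile(u: np.ndarray, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Inverse CDF of NB(mean, variance = mean + dispersion * mean^2)."""
    u = np.clip(u, 1e-12, 1 - 1e-12)
    if dispersion <= 0:
        return stats.poisson.ppf(u, mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return stats.nbinom.ppf(u, r, p)


def simulate_mirna_counts(
    samples: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    target_latents: Optional[dict[int, pd.Series]] = None,
) -> MiRNACountMatrix:
    """Negative-binomial count matrix with planted fold changes.

    counts[g, s] ~ NB(mean = abundance_g * library_size_s * 2^log2FC,
    dispersion) where the fold change applies when sample s belongs to a
    subgroup listing miRNA g in its effect table. Planted correlations are
    realised through a Gaussian copula: for a planned (miRNA, target,
    stratum) triple, the miRNA's latent normal in that stratum is
    rho * z_target + sqrt(1 - rho^2) * noise, then mapped through the NB
    quantile function (rank correlation survives the monotone maps).
    """
    n_genes = config.n_mirna
    sample_ids = list(samples["sample_id"])
    n_samples = len(sample_ids)
    labels = samples.set_index("sample_id")["label"]

    abundance = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    # planted signals must be expressed: floor the abundance of every
    # effect-table / correlation-plan miRNA at the 60th percentile so the
    # low-count CPM filter cannot silently drop the ground truth.
    planted = {i for table in (config.effect_table or {}).values()
               for direction in ("up", "down")
               for i, _ in table.get(direction, [])}
    planted |= {e.mirna_index for e in config.correlation_plan}
    if planted:
        floor = float(np.quantile(abundance, 0.6))
        idx = np.fromiter(planted, dtype=int)
        abundance[idx] = np.maximum(abundance[idx], floor)
    abundance /= abundance.sum()
    lo, hi = config.library_size_range
    lib_sizes = rng.integers(lo, hi + 1, size=n_samples)

    log2fc = np.zeros((n_genes, n_samples))
    for grp, table in (config.effect_table or {}).items():
        cols = np.asarray(labels.to_numpy() == grp)
        for direction in ("up", "down"):
            for gi, fc in table.get(direction, []):
                log2fc[gi, cols] = fc

    mean = abundance[:, None] * lib_sizes[None, :] * np.exp2(log2fc)

    if config.nb_dispersion > 0:
        r = 1.0 / config.nb_dispersion
        p = r / (r + mean)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mean)
    counts = counts.astype(np.int64)

    # copula overwrite for planned correlations; draw order is fixed by the
    # plan order so the dataset stays deterministic.
    for entry in config.correlation_plan:
        zt = None if target_latents is None else target_latents.get(id(entry))
        if zt is None:
            continue
        in_stratum = labels.reindex(sample_ids).to_numpy() == entry.stratum
        if not in_stratum.any():
            continue
        eps = rng.standard_normal(int(in_stratum.sum()))
        z = entry.rho * zt.reindex(np.asarray(sample_ids)[in_stratum]).to_numpy() \
            + math.sqrt(max(0.0, 1 - entry.rho ** 2)) * eps
        u = ndtr(z)
        gi = entry.mirna_index
        counts[gi, in_stratum] = _nb_quantile(
            u, mean[gi, in_stratum], config.nb_dispersion).astype(np.int64)

    counts_df = pd.DataFrame(
        counts, index=[f"mir-{i:04d}" for i in range(n_genes)], columns=sample_ids)
    counts_df.index.name = "mirna_id"
    lib = pd.Series(lib_sizes, index=sample_ids, name="library_size")
    return MiRNACountMatrix(counts=counts_df, library_sizes=lib)


def generate_cohort(config: SimulationConfig) -> CohortDataset:
    """Generate a full synthetic cohort from a validated config.

    Deterministic for a fixed seed. The returned ``truth`` bundle carries
    the planted subgroup labels, per-subgroup differential-expression sets,
    and the correlation plan.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    subjects, labels = _make_subjects(config, rng)
    samples = _make_samples(subjects, labels, config, rng)

    # pre-draw every latent the correlation plan may need, in fixed order
    sample_ids = list(samples["sample_id"])
    cyt_latent: dict[tuple[str, str, str], float] = {}
    for sample_id in sample_ids:
        for cond in config.conditions:
            for cyt in config.cytokines:
                cyt_latent[(sample_id, cond, cyt)] = float(rng.standard_normal())
    subject_ids = list(subjects["subject_id"])
    ocr_latent = pd.Series(rng.standard_normal(len(subject_ids)), index=subject_ids)

    target_latents: dict[int, pd.Series] = {}
    subj_of = samples.set_index("sample_id")["subject_id"]
    for entry in config.correlation_plan:
        if entry.target_kind == "ratio":
            z = pd.Series({
                s: (cyt_latent[(s, entry.condition, "IL-1b")]
                    - cyt_latent[(s, entry.condition, "IL-10")]) / math.sqrt(2.0)
                for s in sample_ids})
        elif entry.target_kind == "cytokine":
            if entry.target not in config.cytokines:
                raise ConfigurationError(f"plan targets unknown cytokine {entry.target!r}")
            z = pd.Series({s: cyt_latent[(s, entry.condition, entry.target)]
                           for s in sample_ids})
        else:  # respiration
            z = pd.Series({s: float(ocr_latent[subj_of[s]]) for s in sample_ids})
        target_latents[id(entry)] = z

    cytokine_table = simulate_cytokine_profiles(samples, config, rng, latent=cyt_latent)
    ocr_traces = simulate_ocr_traces(subjects, config, rng, subject_effects=ocr_latent)
    mirna_counts = simulate_mirna_counts(samples, config, rng, target_latents=target_latents)

    mirna_ids = list(mirna_counts.counts.index)
    truth = {
        "seed": config.seed,
        "labels": {str(k): str(v) for k, v in labels.items()},
        "de_sets": {
            grp: {
                direction: [[mirna_ids[i], float(fc)] for i, fc in table.get(direction, [])]
                for direction in ("up", "down")
            }
            for grp, table in (config.effect_table or {}).items()
        },
        "correlation_plan": [
            {
                "mirna_id": mirna_ids[e.mirna_index],
                "mirna_index": e.mirna_index,
                "target_kind": e.target_kind,
                "target": e.target,
                "condition": e.condition,
                "stratum": e.stratum,
                "rho": e.rho,
            }
            for e in config.correlation_plan
        ],
    }

    dataset = CohortDataset(
        subjects=subjects, samples=samples, cytokine_table=cytokine_table,
        ocr_traces=ocr_traces, mirna_counts=mirna_counts, truth=truth)
    dataset.validate()
    return dataset
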