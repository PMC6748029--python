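"""End-to-end orchestration: simulate/read -> classify -> respiration ->
differential expression -> association screens -> report bundle.

Every stage writes its tables under the run's output directory and logs
parameters and row counts; ``summary.json`` collects the machine-readable
outcome. All randomness flows from the run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import de as de_mod
from . import io as io_mod
from . import screen as screen_mod
from .config import RuleConfig, SimulationConfig
from .errors import ConfigurationError
from .respiration import respiration_table
from .simulate import CohortDataset, generate_cohort
from .subgroups import classify_cohort, compute_ratio_table

logger = logging.getLogger("immunomir")

RESPIRATION_TARGETS = ("PLR", "ALR", "MRC", "RC")
CYTOKINE_TARGETS = ("IL-10", "TNF-a", "CCL2")


@dataclass
class RunConfig:
    """One pipeline run: exactly one of input_dir / sim_config."""

    output_dir: Path
    input_dir: Optional[Path] = None
    sim_config: Optional[SimulationConfig] = None
    rules: RuleConfig = field(default_factory=RuleConfig)
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.05
    alpha: float = 0.05
    seed: int = 0
    #: None = screen only miRNAs significant in some DE comparison
    screen_all_mirnas: bool = False

    def validate(self) -> None:
        if (self.input_dir is None) == (self.sim_config is None):
            raise ConfigurationError(
                "provide exactly one of input_dir or sim_config")


def _build_targets(dataset: CohortDataset, resp: pd.DataFrame) -> pd.DataFrame:
    """Long target table: ratio and cytokine targets per condition plus
    respiration parameters (condition '-')."""
    ratio = compute_ratio_table(dataset.cytokine_table)
    rows = []
    for _, r in ratio.iterrows():
        rows.append(dict(sample_id=r["sample_id"], target="IL-1b/IL-10",
                         condition=r["condition"],
                         value=r["ratio"] if r["valid"] else np.nan))
    cyt = dataset.cytokine_table
    for target in CYTOKINE_TARGETS:
        sub = cyt[cyt["cytokine"] == target]
        for _, r in sub.iterrows():
            rows.append(dict(sample_id=r["sample_id"], target=target,
                             condition=r["condition"], value=r["pg_ml"]))
    resp_idx = resp.set_index("subject_id")
    sample_subject = dataset.samples.set_index("sample_id")["subject_id"]
    for sample_id, subject_id in sample_subject.items():
        if subject_id not in resp_idx.index:
            continue
        for target in RESPIRATION_TARGETS:
            rows.append(dict(sample_id=sample_id, target=target, condition="-",
                             value=float(resp_idx.loc[subject_id, target])))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the summary dict (also written as JSON)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # --- stage 1: data -----------------------------------------------------
    if config.sim_config is not None:
        sim = config.sim_config
        sim.seed = config.seed
        dataset = generate_cohort(sim)
        io_mod.write_cohort(dataset, out / "cohort")
        logger.info("simulated cohort: %d subjects, %d samples, %d miRNAs",
                    len(dataset.subjects), len(dataset.samples),
                    dataset.mirna_counts.counts.shape[0])
    else:
        dataset = io_mod.read_cohort(config.input_dir)
        logger.info("read cohort from %s: %d subjects", config.input_dir,
                    len(dataset.subjects))
    summary["n_subjects"] = int(len(dataset.subjects))
    summary["n_samples"] = int(len(dataset.samples))

    # --- stage 2: subgroup classification ----------------------------------
    labels_df, audit = classify_cohort(dataset, config.rules)
    labels_df.to_csv(out / "subgroups.tsv", sep="\t", index=False)
    with open(out / "classification_audit.jsonl", "w") as fh:
        for record in audit:
            fh.write(json.dumps(record) + "\n")
    subgroup_sizes = labels_df["label"].value_counts().to_dict()
    summary["subgroup_sizes"] = {k: int(v) for k, v in subgroup_sizes.items()}
    logger.info("classification: %s", summary["subgroup_sizes"])

    # sample-level stratum labels: controls keep 'control'
    subject_label = dict(zip(labels_df["subject_id"], labels_df["label"]))
    for cid in dataset.control_subject_ids:
        subject_label[cid] = "control"
    strata = dataset.samples.set_index("sample_id")["subject_id"].map(subject_label)

    # --- stage 3: respiration ----------------------------------------------
    resp = respiration_table(dataset.ocr_traces)
    resp.to_csv(out / "respiration.tsv", sep="\t", index=False)
    summary["n_respiration_subjects"] = int(len(resp))

    # --- stage 4: differential expression ----------------------------------
    counts = dataset.mirna_counts.counts
    lib = dataset.mirna_counts.library_sizes
    group_of = strata.reindex(counts.columns)
    de_labels = group_of.copy()
    de_labels[de_labels.isin(["high", "normal", "low", "ambiguous"])] = \
        "ASD_" + de_labels[de_labels.isin(["high", "normal", "low", "ambiguous"])]

    comparisons: dict[str, de_mod.DEComparison] = {}
    for grp in ("high", "normal", "low"):
        name = f"{grp}_vs_control"
        grouping = group_of.where(group_of.isin([grp, "control"]))
        try:
            comparisons[name] = de_mod.de_comparison(
                counts, lib, grouping, group=grp, reference_group="control",
                fc_threshold=config.fc_threshold,
                fdr_threshold=config.fdr_threshold)
        except ValueError as exc:
            logger.warning("comparison %s skipped: %s", name, exc)
    all_asd = group_of.map(
        lambda v: "ASD" if v in ("high", "normal", "low", "ambiguous")
        else ("control" if v == "control" else np.nan))
    comparisons["all_ASD_vs_control"] = de_mod.de_comparison(
        counts, lib, all_asd, group="ASD", reference_group="control",
        fc_threshold=config.fc_threshold, fdr_threshold=config.fdr_threshold)

    for name, comp in comparisons.items():
        frame = comp.results.rename_axis("mirna_id").reset_index()
        frame.to_csv(out / f"de_{name}.tsv", sep="\t", index=False)
        volcano = frame[["mirna_id", "log2_fc", "fdr"]].copy()
        volcano["neg_log10_fdr"] = -np.log10(volcano["fdr"].clip(lower=1e-300))
        volcano.to_csv(out / f"volcano_{name}.tsv", sep="\t", index=False)
    summary_table = de_mod.de_summary(comparisons)
    summary_table.to_csv(out / "de_summary.tsv", sep="\t", index=False)
    summary["de"] = {
        row["comparison"]: {"n_up": int(row["n_up"]), "n_down": int(row["n_down"]),
                            "n_tested": int(row["n_tested"])}
        for _, row in summary_table.iterrows()
    }
    logger.info("differential expression: %s", summary["de"])

    # --- stage 5: association screens --------------------------------------
    all_factors = de_mod.tmm_factors(counts, lib)
    norm = de_mod.normalized_cpm(counts, all_factors)
    if config.screen_all_mirnas:
        screen_ids = list(norm.index)
    else:
        selected = {
            mid for comp in comparisons.values()
            for mid in comp.results.index[comp.results["direction"] != "ns"]}
        if dataset.truth:  # keep any planted correlation targets screenable
            selected |= {e["mirna_id"] for e in
                         dataset.truth.get("correlation_plan", [])}
        screen_ids = sorted(selected & set(norm.index))
        if not screen_ids:
            screen_ids = list(norm.index)
    targets = _build_targets(dataset, resp)
    full, significant = screen_mod.correlation_screen(
        norm.loc[screen_ids], targets, strata, alpha=config.alpha)
    full.to_csv(out / "correlations.tsv", sep="\t", index=False)
    significant.to_csv(out / "correlations_significant.tsv", sep="\t", index=False)
    summary["screen"] = {"n_mirnas": len(screen_ids),
                         "n_records": int(len(full)),
                         "n_significant": int(len(significant))}

    # --- stage 6: covariate screen ------------------------------------------
    age = dataset.subjects.set_index("subject_id")["age"]
    sample_age = dataset.samples.set_index("sample_id")["subject_id"].map(age)
    diag = dataset.samples.set_index("sample_id")["subject_id"].map(
        dataset.subjects.set_index("subject_id")["diagnosis"])
    cov = screen_mod.covariate_screen(
        norm.loc[screen_ids], diag, sample_age, covariate_name="age",
        alpha=config.alpha)
    cov.to_csv(out / "covariate_screen.tsv", sep="\t", index=False)
    summary["covariate_screen"] = {
        "n_retained": int((cov["verdict"] == "group_effect_retained").sum()),
        "n_tested": int(len(cov))}

    params = {
        "alpha": config.alpha, "fc_threshold": config.fc_threshold,
        "fdr_threshold": config.fdr_threshold, "seed": config.seed,
        "rules": {
            "high_2sd_min_conditions": config.rules.high_2sd_min_conditions,
            "high_1sd_min_conditions": config.rules.high_1sd_min_conditions,
            "low_1sd_min_conditions": config.rules.low_1sd_min_conditions,
            "conflict_policy": config.rules.conflict_policy,
        },
    }
    summary["parameters"] = params
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def make_report(summary: dict) -> str:
    """Human-readable run report from a summary dict (idempotent)."""
    lines = ["# Pipeline report", ""]
    sizes = summary.get("subgroup_sizes", {})
    lines.append("Subgroup sizes: " + (", ".join(
        f"{k}={v}" for k, v in sorted(sizes.items())) or "none"))
    de = summary.get("de")
    if de:
        lines.append("")
        lines.append("Differential expression (up / down):")
        for name, row in de.items():
            lines.append(f"  {name}: {row['n_up']} up / {row['n_down']} down "
                         f"(of {row['n_tested']} tested)")
    else:
        lines.append("WARNING: no differential-expression stage output")
    screen = summary.get("screen")
    if screen:
        lines.append("")
        lines.append(
            f"Correlation screen: {screen['n_significant']} significant of "
            f"{screen['n_records']} records over {screen['n_mirnas']} miRNAs")
    else:
        lines.append("WARNING: no correlation-screen output")
    return "\n".join(lines) + "\n"
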