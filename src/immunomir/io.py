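"""Reading and writing cohort datasets as plain TSV + JSON.

Layout written by :func:`write_cohort`:

- ``subjects.tsv``        one row per subject
- ``samples.tsv``         sample_id -> subject_id, timepoint
- ``cytokines.tsv``       long format: subject_id, sample_id, timepoint,
                          condition, cytokine, pg_ml, censored
- ``ocr.tsv``             subject_id, phase, replicate, minutes, ocr_pmol_min
- ``counts.tsv``          miRNA rows x sample columns, first column mirna_id
- ``library_sizes.tsv``   sample_id, library_size
- ``truth.json``          optional ground-truth bundle (seed recorded here)

Readers are tolerant: unknown extra columns are preserved; missing required
columns raise :class:`~immunomir.errors.ParseError` naming file and column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .errors import ParseError
from .simulate import CohortDataset, MiRNACountMatrix

_FLOAT_FORMAT = "%.17g"  # lossless for float64 -> round-trip identity

_REQUIRED = {
    "subjects.tsv": ["subject_id", "diagnosis"],
    "samples.tsv": ["sample_id", "subject_id", "timepoint"],
    "cytokines.tsv": ["subject_id", "sample_id", "condition", "cytokine", "pg_ml"],
    "ocr.tsv": ["subject_id", "phase", "replicate", "minutes", "ocr_pmol_min"],
    "library_sizes.tsv": ["sample_id", "library_size"],
}


def _read_tsv(path: Path, required: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"{path}: file not found")
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: failed to parse ({exc})") from exc
    for col in required:
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    return frame


def write_cohort(dataset: CohortDataset, directory: str | Path) -> Path:
    """Write every cohort table under ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    dataset.subjects.to_csv(directory / "subjects.tsv", sep="\t", index=False,
                            float_format=_FLOAT_FORMAT)
    dataset.samples.to_csv(directory / "samples.tsv", sep="\t", index=False,
                           float_format=_FLOAT_FORMAT)
    dataset.cytokine_table.to_csv(directory / "cytokines.tsv", sep="\t", index=False,
                                  float_format=_FLOAT_FORMAT)
    dataset.ocr_traces.to_csv(directory / "ocr.tsv", sep="\t", index=False,
                              float_format=_FLOAT_FORMAT)
    dataset.mirna_counts.counts.to_csv(directory / "counts.tsv", sep="\t")
    dataset.mirna_counts.library_sizes.rename("library_size").rename_axis(
        "sample_id").reset_index().to_csv(
        directory / "library_sizes.tsv", sep="\t", index=False)
    if dataset.truth is not None:
        (directory / "truth.json").write_text(
            json.dumps(dataset.truth, indent=1, sort_keys=True))
    return directory


def read_cohort(directory: str | Path) -> CohortDataset:
    """Read a cohort previously written by :func:`write_cohort`."""
    directory = Path(directory)

    subjects = _read_tsv(directory / "subjects.tsv", _REQUIRED["subjects.tsv"])
    samples = _read_tsv(directory / "samples.tsv", _REQUIRED["samples.tsv"])
    cytokines = _read_tsv(directory / "cytokines.tsv", _REQUIRED["cytokines.tsv"])
    ocr = _read_tsv(directory / "ocr.tsv", _REQUIRED["ocr.tsv"])
    lib = _read_tsv(directory / "library_sizes.tsv", _REQUIRED["library_sizes.tsv"])

    counts_path = directory / "counts.tsv"
    if not counts_path.exists():
        raise ParseError(f"{counts_path}: file not found")
    counts = pd.read_csv(counts_path, sep="\t")
    if "mirna_id" not in counts.columns:
        raise ParseError(f"{counts_path}: missing required column 'mirna_id'")
    counts = counts.set_index("mirna_id")

    library_sizes = lib.set_index("sample_id")["library_size"]
    library_sizes = library_sizes.reindex(counts.columns)
    if library_sizes.isna().any():
        missing = list(library_sizes[library_sizes.isna()].index)[:5]
        raise ParseError(
            f"{directory / 'library_sizes.tsv'}: no library size for samples {missing}")

    truth: Optional[dict] = None
    truth_path = directory / "truth.json"
    if truth_path.exists():
        try:
            truth = json.loads(truth_path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{truth_path}: invalid JSON at line {exc.lineno}") from exc

    # restore the truth-derived sample labels if present (tolerant otherwise)
    if "label" not in samples.columns and truth and "labels" in truth:
        samples = samples.copy()
        samples["label"] = samples["subject_id"].map(truth["labels"])

    dataset = CohortDataset(
        subjects=subjects, samples=samples, cytokine_table=cytokines,
        ocr_traces=ocr,
        mirna_counts=MiRNACountMatrix(counts=counts, library_sizes=library_sizes),
        truth=truth)
    dataset.validate()
    return dataset
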