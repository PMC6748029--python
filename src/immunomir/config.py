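"""Configuration dataclasses for simulation, classification, and pipeline runs.

All configurations are plain dataclasses that can be round-tripped through
YAML/JSON mappings via :func:`simulation_config_from_mapping` and
:meth:`SimulationConfig.to_mapping`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .errors import ConfigurationError

#: Culture conditions in protocol order: unstimulated medium plus three
#: TLR-agonist stimulations.
DEFAULT_CONDITIONS: tuple[str, ...] = ("medium", "LPS", "zymosan", "CL097")

#: Cytokines measured in culture supernatants (pro-inflammatory and
#: counter-regulatory panels).
DEFAULT_CYTOKINES: tuple[str, ...] = (
    "IL-1b", "IL-10", "TNF-a", "IL-6", "IL-12p40", "CCL2", "TGF-b", "sTNFRII",
)

SUBGROUPS: tuple[str, ...] = ("high", "normal", "low")

OCR_PHASES: tuple[str, ...] = ("baseline", "oligomycin", "FCCP", "antimycin_rotenone")


def default_cytokine_logmeans(
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    cytokines: Sequence[str] = DEFAULT_CYTOKINES,
) -> dict[tuple[str, str], float]:
    """Natural-log means (log pg/ml) per condition x cytokine.

    Unstimulated medium sits low; TLR-stimulated conditions induce higher
    production, with cytokine-specific baselines chosen to span the typical
    ELISA dynamic range.
    """
    import math

    base = {
        "IL-1b": 120.0, "IL-10": 60.0, "TNF-a": 300.0, "IL-6": 800.0,
        "IL-12p40": 150.0, "CCL2": 900.0, "TGF-b": 400.0, "sTNFRII": 250.0,
    }
    out: dict[tuple[str, str], float] = {}
    for cond in conditions:
        for cyt in cytokines:
            level = base.get(cyt, 100.0)
            if cond == "medium":
                level = level / 8.0
            out[(cond, cyt)] = math.log(level)
    return out


def default_cytokine_logsds(
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    cytokines: Sequence[str] = DEFAULT_CYTOKINES,
) -> dict[tuple[str, str], float]:
    return {(cond, cyt): 0.5 for cond in conditions for cyt in cytokines}


def default_effect_table(n_mirna: int = 500) -> dict[str, dict[str, list[tuple[int, float]]]]:
    """Planted differential-expression pattern per subgroup.

    Default: high 8 up + 9 down, normal 0 up + 10 down, low 0 up + 18 down,
    with |log2FC| = 2 throughout. Index blocks are disjoint across sets so a
    recovery test can count hits unambiguously; the down-set of the low
    subgroup deliberately overlaps the normal subgroup's down-set (shared
    signature) as in the shape of the headline summary.
    """
    if n_mirna < 48:
        raise ConfigurationError("default effect table needs n_mirna >= 48")
    high_up = [(i, 2.0) for i in range(0, 8)]
    high_down = [(i, -2.0) for i in range(8, 17)]
    normal_down = [(i, -2.0) for i in range(17, 27)]
    low_down = [(i, -2.0) for i in range(27, 37)] + [(i, -2.0) for i in range(37, 45)]
    return {
        "high": {"up": high_up, "down": high_down},
        "normal": {"up": [], "down": normal_down},
        "low": {"up": [], "down": low_down},
    }


@dataclass
class CorrelationPlanEntry:
    """One planted rank correlation between a miRNA and a target variable.

    target_kind is one of ``ratio`` (IL-1b/IL-10 ratio in ``condition``),
    ``cytokine`` (named cytokine in ``condition``) or ``respiration``
    (derived OCR parameter; condition ignored).
    """

    mirna_index: int
    target_kind: str
    target: str
    stratum: str
    rho: float
    condition: Optional[str] = None

    def validate(self, n_mirna: int, conditions: Sequence[str]) -> None:
        if not (0 <= self.mirna_index < n_mirna):
            raise ConfigurationError(
                f"correlation plan miRNA index {self.mirna_index} outside [0, {n_mirna})"
            )
        if self.target_kind not in ("ratio", "cytokine", "respiration"):
            raise ConfigurationError(f"unknown target_kind {self.target_kind!r}")
        if not (-1.0 <= self.rho <= 1.0):
            raise ConfigurationError(f"target rho {self.rho} outside [-1, 1]")
        if self.target_kind in ("ratio", "cytokine"):
            if self.condition not in conditions:
                raise ConfigurationError(
                    f"correlation plan condition {self.condition!r} not in {conditions}"
                )
        if self.stratum not in ("control",) + SUBGROUPS:
            raise ConfigurationError(f"unknown stratum {self.stratum!r}")


@dataclass
class OCRParams:
    """Phase means (pMol/min) and noise for simulated 4-phase OCR traces."""

    phase_means: dict[str, float] = field(
        default_factory=lambda: {
            "baseline": 100.0, "oligomycin": 40.0, "FCCP": 160.0,
            "antimycin_rotenone": 10.0,
        }
    )
    noise_sd: float = 4.0
    #: log-scale SD of a per-subject multiplicative level effect; this is
    #: the latent that planted respiration correlations couple to.
    subject_sd: float = 0.15

    def validate(self) -> None:
        missing = [p for p in OCR_PHASES if p not in self.phase_means]
        if missing:
            raise ConfigurationError(f"ocr_params missing phase means for {missing}")
        for phase, mean in self.phase_means.items():
            if mean < 0:
                raise ConfigurationError(f"negative OCR phase mean for {phase!r}: {mean}")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ConfigurationError("OCR noise parameters must be >= 0")


@dataclass
class SimulationConfig:
    """Full specification of a synthetic cohort.

    Defaults emulate the structure of the cohort the pipeline was designed
    for: 35 controls, three case subgroups (high/normal/low cytokine-ratio),
    four culture conditions, an eight-cytokine panel, negative-binomial
    miRNA counts with a planted differential-expression pattern, and
    4-phase OCR traces.
    """

    n_control: int = 35
    n_per_subgroup: dict[str, int] = field(
        default_factory=lambda: {"high": 48, "normal": 43, "low": 25}
    )
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    cytokines: tuple[str, ...] = DEFAULT_CYTOKINES
    cytokine_logmean: Optional[dict[tuple[str, str], float]] = None
    cytokine_logsd: Optional[dict[tuple[str, str], float]] = None
    #: multiplicative shift of the IL-1b/IL-10 ratio per subgroup, applied
    #: symmetrically (IL-1b up by sqrt(shift), IL-10 down by sqrt(shift)).
    ratio_shift: dict[str, float] = field(
        default_factory=lambda: {"high": 10.0, "normal": 1.0, "low": 0.1}
    )
    #: conditions in which the subgroup shift applies (default: all).
    shift_conditions: Optional[dict[str, tuple[str, ...]]] = None
    #: per-subgroup scale on the IL-1b / IL-10 log-noise of case subjects;
    #: < 1 tightens a subgroup around its planted ratio so that label purity
    #: against the simulated control reference meets ``target_purity``.
    subgroup_ratio_sd_scale: dict[str, float] = field(
        default_factory=lambda: {"high": 0.5, "normal": 0.3, "low": 0.5}
    )
    target_purity: float = 0.9
    n_mirna: int = 500
    library_size_range: tuple[int, int] = (30_000, 60_000)
    nb_dispersion: float = 0.2
    effect_table: Optional[dict[str, dict[str, list[tuple[int, float]]]]] = None
    correlation_plan: list[CorrelationPlanEntry] = field(default_factory=list)
    ocr_params: OCRParams = field(default_factory=OCRParams)
    detection_limit: Optional[float] = None
    #: number of case subjects sampled at a second timepoint.
    n_repeat_timepoints: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cytokine_logmean is None:
            self.cytokine_logmean = default_cytokine_logmeans(self.conditions, self.cytokines)
        if self.cytokine_logsd is None:
            self.cytokine_logsd = default_cytokine_logsds(self.conditions, self.cytokines)
        if self.effect_table is None:
            self.effect_table = default_effect_table(self.n_mirna)

    def validate(self) -> None:
        if self.n_control < 0 or any(n < 0 for n in self.n_per_subgroup.values()):
            raise ConfigurationError("cohort sizes must be >= 0")
        if self.n_mirna <= 0:
            raise ConfigurationError("n_mirna must be > 0")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ConfigurationError("library_size_range must satisfy 1 <= lo <= hi")
        if "IL-1b" not in self.cytokines or "IL-10" not in self.cytokines:
            raise ConfigurationError("cytokine panel must include IL-1b and IL-10")
        for grp, shift in self.ratio_shift.items():
            if shift <= 0:
                raise ConfigurationError(
                    f"ratio_shift for {grp!r} must be > 0 (got {shift}); "
                    "a non-positive shift cannot produce valid concentrations"
                )
        for grp, table in (self.effect_table or {}).items():
            up = {i for i, _ in table.get("up", [])}
            down = {i for i, _ in table.get("down", [])}
            if up & down:
                raise ConfigurationError(
                    f"effect_table for {grp!r}: up and down index sets overlap: {sorted(up & down)}"
                )
            for i in up | down:
                if not (0 <= i < self.n_mirna):
                    raise ConfigurationError(
                        f"effect_table index {i} outside [0, {self.n_mirna})"
                    )
        for entry in self.correlation_plan:
            entry.validate(self.n_mirna, self.conditions)
        if self.n_repeat_timepoints < 0:
            raise ConfigurationError("n_repeat_timepoints must be >= 0")
        if self.detection_limit is not None and self.detection_limit < 0:
            raise ConfigurationError("detection_limit must be >= 0")
        self.ocr_params.validate()

    def to_mapping(self) -> dict:
        d = asdict(self)
        d["cytokine_logmean"] = {f"{c}|{k}": v for (c, k), v in self.cytokine_logmean.items()}
        d["cytokine_logsd"] = {f"{c}|{k}": v for (c, k), v in self.cytokine_logsd.items()}
        d["conditions"] = list(self.conditions)
        d["cytokines"] = list(self.cytokines)
        d["library_size_range"] = list(self.library_size_range)
        d["correlation_plan"] = [asdict(e) for e in self.correlation_plan]
        return d


def simulation_config_from_mapping(mapping: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML/JSON-style mapping."""
    m = dict(mapping)
    if "cytokine_logmean" in m and m["cytokine_logmean"] is not None:
        m["cytokine_logmean"] = {
            tuple(k.split("|", 1)): float(v) for k, v in m["cytokine_logmean"].items()
        }
    if "cytokine_logsd" in m and m["cytokine_logsd"] is not None:
        m["cytokine_logsd"] = {
            tuple(k.split("|", 1)): float(v) for k, v in m["cytokine_logsd"].items()
        }
    if "conditions" in m:
        m["conditions"] = tuple(m["conditions"])
    if "cytokines" in m:
        m["cytokines"] = tuple(m["cytokines"])
    if "library_size_range" in m:
        m["library_size_range"] = tuple(int(x) for x in m["library_size_range"])
    if "ocr_params" in m and isinstance(m["ocr_params"], dict):
        m["ocr_params"] = OCRParams(**m["ocr_params"])
    if "correlation_plan" in m:
        m["correlation_plan"] = [
            e if isinstance(e, CorrelationPlanEntry) else CorrelationPlanEntry(**e)
            for e in m["correlation_plan"]
        ]
    if "effect_table" in m and m["effect_table"] is not None:
        m["effect_table"] = {
            grp: {
                direction: [(int(i), float(fc)) for i, fc in entries]
                for direction, entries in table.items()
            }
            for grp, table in m["effect_table"].items()
        }
    cfg = SimulationConfig(**m)
    cfg.validate()
    return cfg


@dataclass
class RuleConfig:
    """Parameters of the ratio-threshold subgroup classification rule."""

    conditions_used: Optional[tuple[str, ...]] = None  # None = all available
    high_2sd_min_conditions: int = 1
    high_1sd_min_conditions: int = 3
    low_1sd_min_conditions: int = 1
    conflict_policy: str = "strict"  # strict | max_abs_z
    gap_policy: str = "assign_normal_flagged"
    min_controls: int = 5

    def validate(self) -> None:
        if self.conflict_policy not in ("strict", "max_abs_z"):
            raise ConfigurationError(f"unknown conflict_policy {self.conflict_policy!r}")
        if self.gap_policy not in ("assign_normal_flagged",):
            raise ConfigurationError(f"unknown gap_policy {self.gap_policy!r}")
        for name in ("high_2sd_min_conditions", "high_1sd_min_conditions",
                     "low_1sd_min_conditions"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
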