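"""Statistical battery: rank tests, frequency tests, stratified Spearman
correlation screens with tiered reporting, and a covariate (general linear
model) screen.

Correlation records mirror the structure of the study-style report tables:
stratum x condition x miRNA x target variable, with rho, nominal p, a
significance tier, and the direction of association. No multiplicity
correction is applied inside the screen (nominal tiers); a BH column is
emitted alongside in the full table.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .de import bh_adjust

TIERS = (0.0001, 0.0005, 0.001, 0.005, 0.01, 0.05)


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    n_per_group: tuple[int, ...]
    groups: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------

import functools


@functools.lru_cache(maxsize=8)
def _permutation_indices(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray) -> float:
    """Exact two-sided permutation p for the rank correlation.

    Under permutation the rank SDs are fixed, so the |rho| ordering equals
    the ordering of |sum(rx * perm(ry)) - n*mean_rx*mean_ry|; enumerate all
    permutations of the (possibly tied) y mid-ranks.
    """
    n = len(rx)
    perms = ry[_permutation_indices(n)]
    dots = perms @ rx
    center = n * rx.mean() * ry.mean()
    obs = abs(float(np.dot(rx, ry)) - center)
    count = int(np.sum(np.abs(dots - center) >= obs - 1e-9))
    return count / len(perms)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Tie-corrected Spearman rho with exact p for n <= 9, t-approx above.

    Pairs with non-finite entries are dropped; needs >= 4 complete pairs.
    Zero variance in either vector gives (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"spearman needs >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        p = _spearman_exact_p(rx, ry)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(1.0, p))


def tier_pvalue(p: float) -> str:
    """Smallest reporting tier containing p, or "ns" above 0.05."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value {p} outside [0, 1]")
    for cut in TIERS:
        if p < cut:
            return f"<{cut:g}"
    return "ns"


# ---------------------------------------------------------------------------
# rank and frequency tests
# ---------------------------------------------------------------------------

def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of x against y (ties counted half)."""
    u = 0.0
    for xi in x:
        u += float(np.sum(xi > y)) + 0.5 * float(np.sum(xi == y))
    return u


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney test.

    Exact for combined n <= 10 (classical distribution when there are no
    ties, full permutation enumeration with ties), normal approximation
    with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney: empty group")
    n1, n2 = len(x), len(y)
    u = _mw_u(x, y)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if n1 + n2 <= 10:
        if not has_ties:
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            p = float(res.pvalue)
        else:
            # permutation null: P(|U - n1 n2 / 2| >= observed)
            mu = n1 * n2 / 2.0
            obs = abs(u - mu)
            count = total = 0
            for idx in itertools.combinations(range(n1 + n2), n1):
                mask = np.zeros(n1 + n2, dtype=bool)
                mask[list(idx)] = True
                u_perm = _mw_u(pooled[mask], pooled[~mask])
                total += 1
                if abs(u_perm - mu) >= obs - 1e-9:
                    count += 1
            p = count / total
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return TestResult("mann_whitney", float(u), float(min(1.0, p)), (n1, n2))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("kruskal_wallis: empty group")
    stat, p = stats.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(stat), float(p),
                      tuple(len(a) for a in arrays))


def fisher_exact(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher exact test by hypergeometric enumeration.

    Sums P(a') over every table with the same margins whose probability is
    no larger than the observed table's.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("fisher_exact needs a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("fisher_exact: degenerate margins (zero row or column)")
    a = int(t[0, 0])
    r1 = int(t[0].sum())
    c1 = int(t[:, 0].sum())
    n = int(t.sum())
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(stats.hypergeom.pmf(a, n, r1, c1))
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return TestResult("fisher_exact", float(a), min(1.0, p),
                      (r1, n - r1))


def chi_square(table: Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square for an r x c table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("chi_square: negative cell")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi_square: degenerate margins (zero row or column)")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return TestResult("chi_square", float(stat), float(p),
                      tuple(int(v) for v in t.sum(axis=1)))


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

def correlation_screen(
    mirna_cpm: pd.DataFrame,
    targets: pd.DataFrame,
    strata: pd.Series,
    alpha: float = 0.05,
    min_stratum_n: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum Spearman screen of every miRNA against every target.

    ``mirna_cpm``: features x samples (TMM CPM). ``targets``: long table
    with columns sample_id, target, condition (may be "-"), value.
    ``strata``: sample_id -> stratum label. Returns (full table,
    significant records at nominal ``alpha``); the full table carries an
    auxiliary BH-adjusted column.
    """
    for col in ("sample_id", "target", "condition", "value"):
        if col not in targets.columns:
            raise ValueError(f"targets table missing column {col!r}")
    records = []
    strata = strata.dropna()
    for stratum in strata.unique():
        samples = [s for s in strata.index[strata == stratum]
                   if s in mirna_cpm.columns]
        if len(samples) < min_stratum_n:
            import warnings
            warnings.warn(
                f"stratum {stratum!r}: only {len(samples)} samples, skipped")
            continue
        tsub = targets[targets["sample_id"].isin(samples)]
        for (target, condition), tgrp in tsub.groupby(["target", "condition"]):
            series = tgrp.set_index("sample_id")["value"].reindex(samples)
            vals = series.to_numpy(dtype=float)
            if np.isfinite(vals).sum() < max(4, min_stratum_n):
                continue
            for mirna_id, row in mirna_cpm.loc[:, samples].iterrows():
                x = row.to_numpy(dtype=float)
                rho, p = spearman(x, vals)
                if not np.isfinite(rho):
                    continue
                records.append(dict(
                    stratum=stratum, condition=condition, mirna_id=mirna_id,
                    target=target, n=int((np.isfinite(x) & np.isfinite(vals)).sum()),
                    rho=rho, p=p, tier=tier_pvalue(p),
                    direction="positive" if rho > 0 else "negative"))
    full = pd.DataFrame(records, columns=[
        "stratum", "condition", "mirna_id", "target", "n", "rho", "p",
        "tier", "direction"])
    if len(full):
        full["fdr_bh"] = bh_adjust(full["p"].to_numpy())
        significant = full[full["p"] < alpha].reset_index(drop=True)
    else:
        full["fdr_bh"] = pd.Series(dtype=float)
        significant = full.copy()
    return full, significant


# ---------------------------------------------------------------------------
# covariate screen
# ---------------------------------------------------------------------------

def covariate_screen(
    mirna_cpm: pd.DataFrame,
    group_labels: pd.Series,
    covariate: pd.Series,
    covariate_name: str = "covariate",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group effect on log2(CPM + 1) adjusted for one covariate.

    Fits ``log2(cpm + 1) ~ C(group) + covariate`` per feature; the group
    effect p comes from the partial (type-II) F test. Verdict is
    ``group_effect_retained`` when that p < alpha. A constant covariate is
    dropped (one-way model); a covariate collinear with group raises.
    """
    samples = [s for s in mirna_cpm.columns
               if s in group_labels.index and s in covariate.index]
    groups = group_labels.reindex(samples)
    cov = pd.to_numeric(covariate.reindex(samples), errors="raise")
    if groups.nunique() < 2:
        raise ValueError("covariate_screen needs >= 2 groups")

    drop_cov = cov.nunique() == 1
    if not drop_cov:
        # confounded design: covariate fully determined by group membership
        within_sd = cov.groupby(groups).transform(lambda v: v.std(ddof=0))
        if (within_sd.fillna(0) == 0).all() and cov.groupby(groups).mean().nunique() > 1:
            raise ValueError(
                f"covariate {covariate_name!r} is collinear with group labels "
                "(constant within each group): group effect not identifiable")

    rows = []
    for mirna_id, row in mirna_cpm.loc[:, samples].iterrows():
        frame = pd.DataFrame({
            "expr": np.log2(row.to_numpy(dtype=float) + 1.0),
            "group": groups.to_numpy(),
            "cov": cov.to_numpy(),
        })
        formula = "expr ~ C(group)" + ("" if drop_cov else " + cov")
        fit = smf.ols(formula, data=frame).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        p_group = float(anova.loc["C(group)", "PR(>F)"])
        rows.append(dict(
            mirna_id=mirna_id, covariate=covariate_name, p_group_adjusted=p_group,
            verdict="group_effect_retained" if p_group < alpha else "group_effect_lost"))
    return pd.DataFrame(rows, columns=["mirna_id", "covariate",
                                       "p_group_adjusted", "verdict"])
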