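"""Count normalization and negative-binomial exact-test differential expression.

The full path is re-implemented here rather than delegated: CPM, low-count
filtering anchored to the smallest library, trimmed-mean-of-M-values (TMM)
between-sample normalization with inverse-variance weights, library-size
equalization, common-dispersion estimation by maximizing the conditional
(given group totals) NB log-likelihood, the conditional exact test on group
sums, and Benjamini-Hochberg step-up adjustment.

Count matrices are pandas DataFrames (features x samples); library sizes
are a Series aligned to the columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """Counts per million mapped reads: counts / library_size * 1e6."""
    lib = library_sizes.reindex(counts.columns)
    if lib.isna().any():
        missing = list(lib[lib.isna()].index)[:5]
        raise ValueError(f"no library size for samples {missing}")
    if (lib <= 0).any():
        bad = list(lib[lib <= 0].index)[:5]
        raise ValueError(f"non-positive library size for samples {bad}")
    return counts.div(lib, axis=1) * 1e6


def filter_low_expression(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    min_raw: int = 5,
    min_samples_frac: float = 1.0,
    group_labels: Optional[pd.Series] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop features below a CPM floor anchored to the smallest library.

    The CPM threshold is ``min_raw / min(library_size) * 1e6``; a feature is
    kept when its CPM reaches the threshold in at least
    ``ceil(min_samples_frac * n_small)`` samples, where ``n_small`` is the
    size of the smaller comparison group (all samples when no labels are
    given). Returns (filtered counts, per-feature kept/dropped report).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to filter")
    lib = library_sizes.reindex(counts.columns)
    threshold = min_raw / float(lib.min()) * 1e6
    if group_labels is not None:
        sizes = group_labels.reindex(counts.columns).value_counts()
        n_small = int(sizes.min())
    else:
        n_small = counts.shape[1]
    required = max(1, math.ceil(min_samples_frac * n_small))
    mat = cpm(counts, library_sizes)
    passing = (mat >= threshold).sum(axis=1)
    keep = passing >= required
    report = pd.DataFrame({
        "samples_passing": passing,
        "required": required,
        "cpm_threshold": threshold,
        "kept": keep,
    })
    return counts.loc[keep], report


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors (geometric mean 1) and effective sizes."""

    factors: pd.Series
    reference: str
    effective_library_sizes: pd.Series


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        raise ValueError("sample shares no positive-count feature with the reference")
    o = obs[keep] / n_obs
    r = ref[keep] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    # asymptotic (binomial) variance of M; weight = 1/variance
    var = (n_obs - obs[keep]) / (n_obs * obs[keep]) + \
          (n_ref - ref[keep]) / (n_ref * ref[keep])
    if np.allclose(m, m[0]):
        return float(m[0])
    n = len(m)
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    w = 1.0 / var[keep2]
    return float(np.sum(w * m[keep2]) / np.sum(w))


def tmm_factors(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormalizationFactors:
    """Trimmed mean of M-values normalization factors.

    Reference sample: the one whose 75th-percentile CPM is closest to the
    mean 75th percentile. M (log-ratio) and A (log-abundance) values are
    computed over features positive in both sample and reference, doubly
    trimmed (``trim_m`` on M, ``trim_a`` on A, symmetric tails), and the
    factor is 2 to the inverse-variance-weighted mean of the surviving M.
    Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples for TMM")
    lib = library_sizes.reindex(counts.columns).astype(float)
    q75 = cpm(counts, lib).quantile(0.75, axis=0)
    ref_sample = (q75 - q75.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(dtype=float)
    n_ref = float(lib[ref_sample])

    log2f = {}
    for sample in counts.columns:
        if sample == ref_sample:
            log2f[sample] = 0.0
            continue
        log2f[sample] = _tmm_pair(
            counts[sample].to_numpy(dtype=float), ref, float(lib[sample]),
            n_ref, trim_m, trim_a)
    factors = pd.Series({s: 2.0 ** v for s, v in log2f.items()}).reindex(counts.columns)
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    return NormalizationFactors(
        factors=factors, reference=str(ref_sample),
        effective_library_sizes=lib * factors)


def normalized_cpm(counts: pd.DataFrame, factors: NormalizationFactors) -> pd.DataFrame:
    """CPM computed against TMM effective library sizes."""
    return cpm(counts, factors.effective_library_sizes)


# ---------------------------------------------------------------------------
# library-size equalization
# ---------------------------------------------------------------------------

@dataclass
class EqualizedCounts:
    pseudo: pd.DataFrame
    common_library_size: float
    method: str  # "proportional" | "quantile"


def equalize_library_sizes(
    counts: pd.DataFrame,
    effective_library_sizes: pd.Series,
    dispersion: float = 0.1,
    ratio_tolerance: float = 0.20,
) -> EqualizedCounts:
    """Map counts to a common library size (geometric mean of effectives).

    Proportional scaling with rounding when all effective sizes are within
    ``ratio_tolerance`` of each other; otherwise each count is pushed
    through its NB mid-quantile at the sample's fitted mean and pulled back
    at the common-library mean (Poisson when dispersion is 0).
    """
    lib = effective_library_sizes.reindex(counts.columns).astype(float)
    common = float(np.exp(np.log(lib).mean()))
    spread = float(lib.max() / lib.min()) - 1.0
    mat = counts.to_numpy(dtype=float)

    if spread < ratio_tolerance:
        pseudo = np.rint(mat * (common / lib.to_numpy())[None, :])
        method = "proportional"
    else:
        lam = mat.sum(axis=1) / lib.sum()  # per-feature rate
        mu = lam[:, None] * lib.to_numpy()[None, :]
        mu_common = lam[:, None] * common
        mu = np.maximum(mu, 1e-10)
        mu_common = np.maximum(mu_common, 1e-10)
        if dispersion > 0:
            r = 1.0 / dispersion
            p = r / (r + mu)
            u = stats.nbinom.cdf(mat, r, p) - 0.5 * stats.nbinom.pmf(mat, r, p)
            u = np.clip(u, 1e-10, 1 - 1e-10)
            p_c = r / (r + mu_common)
            pseudo = stats.nbinom.ppf(u, r, p_c)
        else:
            u = stats.poisson.cdf(mat, mu) - 0.5 * stats.poisson.pmf(mat, mu)
            u = np.clip(u, 1e-10, 1 - 1e-10)
            pseudo = stats.poisson.ppf(u, mu_common)
        method = "quantile"
    pseudo = pd.DataFrame(np.maximum(pseudo, 0).astype(np.int64),
                          index=counts.index, columns=counts.columns)
    return EqualizedCounts(pseudo=pseudo, common_library_size=common, method=method)


# ---------------------------------------------------------------------------
# common dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionEstimate:
    dispersion: float
    log_likelihood: float
    converged: bool
    grid_bounds: tuple[float, float] = (1e-4, 4.0)
    equalization_method: str = "proportional"
    metadata: dict = field(default_factory=dict)


def _group_matrix(counts: pd.DataFrame, group_labels: pd.Series) -> dict[str, np.ndarray]:
    labels = group_labels.reindex(counts.columns)
    if labels.isna().any():
        missing = list(labels[labels.isna()].index)[:5]
        raise ValueError(f"no group label for samples {missing}")
    return {g: counts.loc[:, labels == g].to_numpy(dtype=float)
            for g in labels.unique()}


def _conditional_loglik(groups: Sequence[np.ndarray], phi: float) -> float:
    """Summed per-feature log-likelihood conditional on each group's total.

    For a group of n samples with equal per-sample NB size r = 1/phi, the
    split of the group total t across samples is Dirichlet-multinomial:
    P(y | t) = [prod_j C(y_j + r - 1, y_j)] / C(t + n*r - 1, t).
    The phi -> 0 limit is the equiprobable multinomial.
    """
    total = 0.0
    for mat in groups:
        n = mat.shape[1]
        if n < 2:
            continue
        t = mat.sum(axis=1)
        if phi <= 0:
            total += float(np.sum(
                gammaln(t + 1) - gammaln(mat + 1).sum(axis=1) - t * math.log(n)))
        else:
            r = 1.0 / phi
            total += float(np.sum(
                gammaln(mat + r).sum(axis=1) - n * gammaln(r)
                - gammaln(mat + 1).sum(axis=1)
                + gammaln(t + 1) + gammaln(n * r) - gammaln(t + n * r)))
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame,
    group_labels: pd.Series,
    effective_library_sizes: Optional[pd.Series] = None,
    grid_bounds: tuple[float, float] = (1e-4, 4.0),
    grid_points: int = 25,
) -> DispersionEstimate:
    """Maximize the conditional log-likelihood over a common dispersion.

    Counts are first equalized to a common library size (two passes: an
    initial guess, then re-equalization at the estimate). The search is a
    log-grid over ``grid_bounds`` refined by bounded scalar optimization;
    the Poisson boundary (phi = 0) is checked explicitly.
    """
    groups_all = _group_matrix(counts, group_labels)
    if all(mat.shape[1] < 2 for mat in groups_all.values()):
        raise ValueError("dispersion estimation needs >= 2 samples in some group")

    if effective_library_sizes is None:
        effective_library_sizes = counts.sum(axis=0).astype(float)

    method = "proportional"
    phi_hat = 0.1
    result: Optional[DispersionEstimate] = None
    for _pass in range(2):
        eq = equalize_library_sizes(counts, effective_library_sizes, dispersion=phi_hat)
        method = eq.method
        groups = list(_group_matrix(eq.pseudo, group_labels).values())

        grid = np.logspace(math.log10(grid_bounds[0]), math.log10(grid_bounds[1]),
                           grid_points)
        lls = np.array([_conditional_loglik(groups, phi) for phi in grid])
        ll0 = _conditional_loglik(groups, 0.0)
        best = int(np.argmax(lls))
        if ll0 >= lls[best]:
            result = DispersionEstimate(0.0, ll0, True, grid_bounds, method,
                                        {"boundary": True})
            phi_hat = 0.0
            break
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        opt = optimize.minimize_scalar(
            lambda lp: -_conditional_loglik(groups, math.exp(lp)),
            bounds=(math.log(lo), math.log(hi)), method="bounded")
        phi_hat = float(math.exp(opt.x))
        result = DispersionEstimate(phi_hat, float(-opt.fun), bool(opt.success),
                                    grid_bounds, method, {"boundary": False})
    assert result is not None
    return result


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

def _conditional_split_logpmf(t: int, r1: float, r2: float) -> np.ndarray:
    """log P(first-group sum = a | total = t) for a = 0..t (NB group sums)."""
    a = np.arange(t + 1, dtype=float)
    lp = (gammaln(a + r1) - gammaln(a + 1)
          + gammaln(t - a + r2) - gammaln(t - a + 1))
    return lp - logsumexp(lp)


def _binomial_split_logpmf(t: int, n1: int, n2: int) -> np.ndarray:
    a = np.arange(t + 1, dtype=float)
    q1 = n1 / (n1 + n2)
    q2 = n2 / (n1 + n2)
    lp = (gammaln(t + 1) - gammaln(a + 1) - gammaln(t - a + 1)
          + a * math.log(q1) + (t - a) * math.log(q2))
    return lp


def exact_test_pvalue(y1: int, y2: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided conditional exact p for one feature.

    Conditions on the total t = y1 + y2; under the null the two group sums
    are NB with sizes n1/phi and n2/phi (binomial split when phi = 0), and
    the p-value sums the probabilities of all splits no more likely than
    the observed one (the "small-p" two-sided rule).
    """
    t = y1 + y2
    if t == 0:
        return 1.0
    if dispersion > 0:
        lp = _conditional_split_logpmf(t, n1 / dispersion, n2 / dispersion)
    else:
        lp = _binomial_split_logpmf(t, n1, n2)
    obs = lp[y1]
    return float(min(1.0, np.exp(logsumexp(lp[lp <= obs + 1e-10]))))


def exact_test_de(
    counts: pd.DataFrame,
    group_labels: pd.Series,
    dispersion: float,
) -> pd.Series:
    """Per-feature two-sided conditional exact p-values.

    ``counts`` must already be equalized to a common library size; exactly
    two groups are required. Features with total 0 get p = 1.
    """
    groups = _group_matrix(counts, group_labels)
    if len(groups) != 2:
        raise ValueError(f"exact test needs exactly two groups, got {len(groups)}")
    (name1, g1), (name2, g2) = groups.items()
    n1, n2 = g1.shape[1], g2.shape[1]
    y1 = g1.sum(axis=1).astype(np.int64)
    y2 = g2.sum(axis=1).astype(np.int64)
    pvals = np.array([
        exact_test_pvalue(int(a), int(b), n1, n2, dispersion)
        for a, b in zip(y1, y2)
    ])
    return pd.Series(pvals, index=counts.index, name="p")


def bh_adjust(pvalues: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    if isinstance(pvalues, pd.Series):
        return pd.Series(out, index=pvalues.index, name="fdr")
    return out


# ---------------------------------------------------------------------------
# full comparison
# ---------------------------------------------------------------------------

@dataclass
class DEComparison:
    """Full result of one two-group differential-expression comparison."""

    results: pd.DataFrame  # mirna_id index; group means, log2_fc, p, fdr, direction
    dispersion: DispersionEstimate
    factors: NormalizationFactors
    group: str
    reference_group: str
    fc_threshold: float
    fdr_threshold: float
    filter_report: pd.DataFrame


def de_comparison(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    group_labels: pd.Series,
    group: str,
    reference_group: str,
    min_raw: int = 5,
    min_samples_frac: float = 1.0,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> DEComparison:
    """Filter, TMM-normalize and exact-test ``group`` against ``reference_group``.

    Fold change is the ratio of TMM-normalized group mean CPM with a
    0.5-count prior (at the mean effective library size) added to both
    means. ``direction`` is up/down when |fold change| clears
    ``fc_threshold`` and FDR clears ``fdr_threshold``, else ns.
    """
    labels = group_labels.reindex(library_sizes.index)
    use = labels.isin([group, reference_group])
    sub = counts.loc[:, counts.columns[use.reindex(counts.columns).fillna(False)]]
    sub_lib = library_sizes[use]
    sub_labels = labels[use]
    if (sub_labels == group).sum() < 2 or (sub_labels == reference_group).sum() < 2:
        raise ValueError("each compared group needs >= 2 samples")

    filtered, report = filter_low_expression(
        sub, sub_lib, min_raw=min_raw, min_samples_frac=min_samples_frac,
        group_labels=sub_labels)
    factors = tmm_factors(filtered, sub_lib)
    disp = estimate_common_dispersion(
        filtered, sub_labels, effective_library_sizes=factors.effective_library_sizes)
    eq = equalize_library_sizes(filtered, factors.effective_library_sizes,
                                dispersion=disp.dispersion)
    pvals = exact_test_de(eq.pseudo, sub_labels, disp.dispersion)
    fdr = bh_adjust(pvals)

    norm = normalized_cpm(filtered, factors)
    mean_g = norm.loc[:, sub_labels == group].mean(axis=1)
    mean_r = norm.loc[:, sub_labels == reference_group].mean(axis=1)
    prior = 0.5 / float(factors.effective_library_sizes.mean()) * 1e6
    log2_fc = np.log2((mean_g + prior) / (mean_r + prior))

    significant = fdr < fdr_threshold
    up = significant & (log2_fc > math.log2(fc_threshold))
    down = significant & (log2_fc < -math.log2(fc_threshold))
    direction = pd.Series("ns", index=filtered.index)
    direction[up] = "up"
    direction[down] = "down"

    results = pd.DataFrame({
        f"mean_cpm_{group}": mean_g,
        f"mean_cpm_{reference_group}": mean_r,
        "log2_fc": log2_fc,
        "p": pvals,
        "fdr": fdr,
        "direction": direction,
    })
    return DEComparison(results=results, dispersion=disp, factors=factors,
                        group=group, reference_group=reference_group,
                        fc_threshold=fc_threshold, fdr_threshold=fdr_threshold,
                        filter_report=report)


def de_summary(comparisons: dict[str, DEComparison]) -> pd.DataFrame:
    """Up/down-regulated feature counts per comparison (headline table shape)."""
    rows = []
    for name, comp in comparisons.items():
        d = comp.results["direction"]
        rows.append(dict(comparison=name, n_up=int((d == "up").sum()),
                         n_down=int((d == "down").sum()),
                         n_tested=len(d),
                         fc_threshold=comp.fc_threshold,
                         fdr_threshold=comp.fdr_threshold))
    return pd.DataFrame(rows, columns=["comparison", "n_up", "n_down", "n_tested",
                                       "fc_threshold", "fdr_threshold"])
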