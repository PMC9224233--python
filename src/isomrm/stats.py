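"""Statistical dispatch: normality-gated tests, rank correlation, groups.

The decision procedure mirrors common practice in small-n physiology
studies: Shapiro-Wilk gates the choice between a parametric test and its
rank-based fallback (paired t vs Wilcoxon signed-rank for paired designs;
one-way ANOVA vs Kruskal-Wallis for multi-group contrasts, with Bartlett's
test additionally gating homoscedasticity). Every result records which
branch fired and the gate p-values, so the dispatch is auditable.
Percentages are arcsine-square-root transformed before parametric testing.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

DEFAULT_ALPHA_NORMALITY = 0.05

#: Sample size at or below which the Spearman p-value is computed by exact
#: permutation enumeration rather than the t approximation.
SPEARMAN_EXACT_N = 9


@dataclass
class PairedTestResult:
    """Outcome of the normality-gated paired comparison."""

    label: str
    test_name: str  # "paired_t" | "wilcoxon_signed_rank"
    statistic: float
    p_value: float
    normality_p: float  # Shapiro-Wilk on paired differences; NaN if degenerate
    n: int
    degenerate: bool = False
    notes: str = ""


@dataclass
class CorrelationResult:
    """Spearman rank correlation of group abundance vs a phenotype."""

    label: str
    variable: str
    rho: float | None
    p_value: float | None
    n: int
    method: str = ""
    reason: str = ""  # non-empty when rho is undefined


@dataclass
class GroupComparisonResult:
    """Omnibus multi-group comparison with pairwise fold ratios."""

    label: str
    test_name: str  # "one_way_anova" | "kruskal_wallis"
    statistic: float
    p_value: float
    normality_p: float
    bartlett_p: float
    category_means: dict[str, float] = field(default_factory=dict)
    fold_ratios: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False
    notes: str = ""


def paired_compare(x, y, alpha_normality: float = DEFAULT_ALPHA_NORMALITY,
                   label: str = "") -> PairedTestResult:
    """Compare paired measurements x and y.

    Shapiro-Wilk is applied to the paired differences (the quantity the
    paired t-test assumes normal). If its p-value clears
    ``alpha_normality`` the paired t-test runs, otherwise the Wilcoxon
    signed-rank test (Pratt handling of zero differences). All-zero
    differences are a degenerate no-signal case reported as p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError(f"paired comparison needs n >= 3, got {n}")
    d = x - y
    if np.all(d == 0):
        return PairedTestResult(
            label=label, test_name="wilcoxon_signed_rank", statistic=0.0,
            p_value=1.0, normality_p=float("nan"), n=n, degenerate=True,
            notes="all paired differences zero; no signal to test")
    if np.ptp(d) == 0:
        # constant non-zero differences: normality test undefined, the
        # t statistic diverges; the signed-rank test is still meaningful
        stat, p = sps.wilcoxon(d, zero_method="pratt")
        return PairedTestResult(
            label=label, test_name="wilcoxon_signed_rank",
            statistic=float(stat), p_value=float(p),
            normality_p=float("nan"), n=n, degenerate=True,
            notes="constant differences; normality gate undefined")
    norm_p = float(sps.shapiro(d).pvalue)
    if norm_p >= alpha_normality:
        stat, p = sps.ttest_rel(x, y)
        return PairedTestResult(label=label, test_name="paired_t",
                                statistic=float(stat), p_value=float(p),
                                normality_p=norm_p, n=n)
    stat, p = sps.wilcoxon(d, zero_method="pratt")
    return PairedTestResult(label=label, test_name="wilcoxon_signed_rank",
                            statistic=float(stat), p_value=float(p),
                            normality_p=norm_p, n=n)


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all n! permutations of one rank vector (feasible for the
    small n of donor-level designs). Ties are handled through average
    ranks; the observed |rho| is compared with a small numerical slack so
    exact ties count as at least as extreme.
    """
    n = xr.size
    obs = abs(_rank_corr(xr, yr))
    perms = np.fromiter(
        itertools.chain.from_iterable(itertools.permutations(range(n))),
        dtype=np.intp).reshape(-1, n)
    ymat = yr[perms]
    yc = ymat - ymat.mean(axis=1, keepdims=True)
    xc = xr - xr.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=1))
    rhos = (yc @ xc) / denom
    return float(np.mean(np.abs(rhos) >= obs - 1e-12))


def _rank_corr(xr: np.ndarray, yr: np.ndarray) -> float:
    """Pearson correlation of two rank vectors."""
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    return float((xc * yc).sum() / denom)


def correlate(abundance, phenotype, variable: str = "",
              label: str = "") -> CorrelationResult:
    """Spearman rank correlation between abundance and a phenotype.

    Average ranks are used for ties. For n <= 9 the p-value is exact by
    permutation enumeration; above that the usual t approximation is used.
    Constant input makes rho undefined; this is reported (with a reason),
    not raised, so a screening loop over many groups keeps going.
    """
    x = np.asarray(abundance, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    n = x.size
    if n < 4:
        raise ValueError(f"correlation needs n >= 4, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        which = "abundance" if np.ptp(x) == 0 else "phenotype"
        return CorrelationResult(label=label, variable=variable, rho=None,
                                 p_value=None, n=n,
                                 reason=f"constant {which}: rho undefined")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = _rank_corr(xr, yr)
    if n <= SPEARMAN_EXACT_N:
        p = _spearman_exact_p(xr, yr)
        method = "exact_permutation"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "t_approximation"
    return CorrelationResult(label=label, variable=variable, rho=rho,
                             p_value=p, n=n, method=method)


def group_compare(values, categories,
                  alpha_normality: float = DEFAULT_ALPHA_NORMALITY,
                  label: str = "") -> GroupComparisonResult:
    """Omnibus comparison of Ln abundances across >= 2 labeled categories.

    Gates: Shapiro-Wilk on the pooled within-category residuals and
    Bartlett across categories. Both must clear ``alpha_normality`` for
    one-way ANOVA; failing either routes to Kruskal-Wallis (the notes
    field records which gate fired). A category of size 1 forces the
    non-parametric branch since its dispersion is undefined.

    Because abundances live on the Ln scale, the pairwise fold ratio
    between categories i and j is exp(mean_i - mean_j), reported for every
    ordered pair "i/j" with i before j in sorted category order.
    """
    v = np.asarray(values, dtype=float)
    cats = np.asarray(categories)
    if v.shape != cats.shape or v.ndim != 1:
        raise ValueError("values and categories must be equal-length 1-D")
    levels = sorted(set(cats.tolist()))
    if len(levels) < 2:
        raise ValueError("need >= 2 categories")
    by_cat = {c: v[cats == c] for c in levels}
    means = {c: float(g.mean()) for c, g in by_cat.items()}
    ratios = {f"{a}/{b}": math.exp(means[a] - means[b])
              for a, b in itertools.combinations(levels, 2)}

    if np.ptp(v) == 0:
        return GroupComparisonResult(
            label=label, test_name="kruskal_wallis", statistic=float("nan"),
            p_value=float("nan"), normality_p=float("nan"),
            bartlett_p=float("nan"), category_means=means,
            fold_ratios=ratios, degenerate=True,
            notes="all values identical; comparison degenerate")

    singleton = [c for c, g in by_cat.items() if g.size < 2]
    if singleton:
        stat, p = sps.kruskal(*by_cat.values())
        return GroupComparisonResult(
            label=label, test_name="kruskal_wallis", statistic=float(stat),
            p_value=float(p), normality_p=float("nan"),
            bartlett_p=float("nan"), category_means=means,
            fold_ratios=ratios,
            notes=f"categories {singleton} have n=1; non-parametric forced")

    residuals = np.concatenate([g - g.mean() for g in by_cat.values()])
    if np.ptp(residuals) == 0:
        norm_p = float("nan")
        gate_normal = False
        gate_note = "zero residual spread; normality gate undefined"
    else:
        norm_p = float(sps.shapiro(residuals).pvalue)
        gate_normal = norm_p >= alpha_normality
        gate_note = ""
    if any(np.ptp(g) == 0 for g in by_cat.values()):
        bart_p = float("nan")  # a zero-spread category breaks Bartlett
    else:
        bart_p = float(sps.bartlett(*by_cat.values()).pvalue)
    gate_homosc = not math.isnan(bart_p) and bart_p >= alpha_normality

    if gate_normal and gate_homosc:
        stat, p = sps.f_oneway(*by_cat.values())
        name = "one_way_anova"
        notes = ""
    else:
        stat, p = sps.kruskal(*by_cat.values())
        name = "kruskal_wallis"
        fired = gate_note or ("normality" if not gate_normal
                              else "homoscedasticity")
        notes = f"parametric branch rejected by {fired} gate"
    return GroupComparisonResult(
        label=label, test_name=name, statistic=float(stat),
        p_value=float(p), normality_p=norm_p, bartlett_p=bart_p,
        category_means=means, fold_ratios=ratios, notes=notes)


def arcsine_percent(p):
    """Arcsine-square-root transform of a percentage in [0, 100].

    Maps 0 -> 0, 50 -> pi/4, 100 -> pi/2; strictly increasing. The
    standard variance-stabilising transform applied to percentage
    variables before parametric testing.
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    out = np.arcsin(np.sqrt(arr / 100.0))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def bh_adjust(p_values):
    """Benjamini-Hochberg adjusted p-values (off by default upstream:
    screening reports raw p across isoforms unless explicitly requested)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float))
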