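"""Guideline classification and method-comparison statistics.

Implements the validation machinery for comparing LDL-C estimates against
direct measurement: NCEP-ATP III category classification, concordance /
discordance accounting, exact McNemar and Wilcoxon signed-rank tests,
difference-distribution summaries, Mood's median test, one-way ANOVA with
Tamhane T2 letter grouping, and an OLS variance decomposition of VLDL-C.
"""

from __future__ import annotations

import enum
import itertools
import math
import string
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import LipidPanel, band_labels, compute_derived

# ---------------------------------------------------------------------------
# NCEP-ATP III classification

#: Guideline cutoffs, mg/dL; a value equal to a cutoff joins the upper band.
NCEP_CUTOFFS = (70.0, 100.0, 130.0, 160.0, 190.0)


class GuidelineCategory(enum.IntEnum):
    """Ordered NCEP-ATP III LDL-C risk categories (mg/dL bands)."""

    LT_70 = 0
    FROM_70_TO_99 = 1
    FROM_100_TO_129 = 2
    FROM_130_TO_159 = 3
    FROM_160_TO_189 = 4
    GE_190 = 5

    @property
    def label(self) -> str:
        return ("< 70", "70 to 99", "100 to 129", "130 to 159",
                "160 to 189", ">= 190")[self.value]


def classify_ncep(ldl: float) -> GuidelineCategory:
    """NCEP-ATP III category of an LDL-C value (negative estimates -> '< 70')."""
    if not math.isfinite(ldl):
        raise ValueError(f"LDL-C must be finite, got {ldl}")
    return GuidelineCategory(int(np.searchsorted(NCEP_CUTOFFS, ldl, side="right")))


# ---------------------------------------------------------------------------
# Concordance accounting

#: TG strata used for concordance reporting, mg/dL: <100, 100-149, 150-199, 200-399.
CONCORDANCE_TG_EDGES = (100.0, 150.0, 200.0)


def format_rate(c: int, t: int) -> str:
    """Concordance rate C/T as the printed one-decimal percentage string."""
    if t <= 0:
        raise ValueError("total must be positive")
    return f"{100.0 * c / t:.1f}"


def proportion_ci(c: int, t: int) -> tuple[float, float]:
    """95% Wald interval for 100*c/t, in percent, truncated to [0, 100]."""
    if t <= 0:
        raise ValueError("total must be positive")
    if not (0 <= c <= t):
        raise ValueError(f"need 0 <= c <= t, got c={c}, t={t}")
    p = c / t
    half = 1.96 * math.sqrt(p * (1.0 - p) / t)
    return (max(0.0, 100.0 * (p - half)), min(100.0, 100.0 * (p + half)))


@dataclass(frozen=True)
class ConcordanceReport:
    """Concordant/total accounting for one estimator against direct LDL-C.

    Rows keyed by the ESTIMATE's category carry the C/T pairs (the
    denominator is the number of subjects the estimate placed in that
    category); ``by_direct_category_n`` carries the direct-measurement
    category sizes printed alongside.  The partition identities

        sum_k C_k (by category) = sum_s C_s (by TG stratum) = overall C
        sum_k T_k = overall T = sum by_direct_category_n
        under + over + overall C = overall T

    hold for every input.
    """

    overall: tuple[int, int]
    by_estimate_category: tuple[tuple[int, int], ...]
    by_direct_category_n: tuple[int, ...]
    by_tg_stratum: tuple[tuple[str, int, int], ...]
    under_count: int
    over_count: int

    def rate(self, c: int, t: int) -> dict:
        lo, hi = proportion_ci(c, t) if t else (math.nan, math.nan)
        return {
            "c": c, "t": t,
            "pct": 100.0 * c / t if t else math.nan,
            "pct_str": format_rate(c, t) if t else "",
            "ci": (lo, hi),
        }

    def to_dict(self) -> dict:
        cats = list(GuidelineCategory)
        return {
            "overall": self.rate(*self.overall),
            "by_estimate_category": {
                cats[k].label: self.rate(c, t) if t else {"c": c, "t": t}
                for k, (c, t) in enumerate(self.by_estimate_category)
            },
            "by_direct_category_n": {
                cats[k].label: n for k, n in enumerate(self.by_direct_category_n)
            },
            "by_tg_stratum": {
                lab: self.rate(c, t) if t else {"c": c, "t": t}
                for lab, c, t in self.by_tg_stratum
            },
            "under_count": self.under_count,
            "over_count": self.over_count,
            "under_pct_str": format_rate(self.under_count, self.overall[1]),
            "over_pct_str": format_rate(self.over_count, self.overall[1]),
        }


def concordance_report(
    estimates: Sequence[float],
    direct: Sequence[float],
    tg: Sequence[float],
) -> ConcordanceReport:
    """Guideline-classification concordance of estimates vs direct LDL-C.

    Initial classification is defined by the estimate; concordance is
    determined according to direct LDL-C.  Under/over counts are subjects
    whose estimate category is ordinally below/above their direct category.
    """
    est = np.asarray(estimates, dtype=float)
    dir_ = np.asarray(direct, dtype=float)
    tg_arr = np.asarray(tg, dtype=float)
    if not (est.shape == dir_.shape == tg_arr.shape):
        raise ValueError(
            f"length mismatch: estimates {est.shape}, direct {dir_.shape}, "
            f"tg {tg_arr.shape}"
        )
    if np.any(tg_arr >= 400.0):
        raise ValueError("concordance is defined for TG < 400 mg/dL only")
    est_cat = np.searchsorted(NCEP_CUTOFFS, est, side="right")
    dir_cat = np.searchsorted(NCEP_CUTOFFS, dir_, side="right")
    match = est_cat == dir_cat
    total = est.size
    overall_c = int(match.sum())
    by_cat = tuple(
        (int(match[est_cat == k].sum()), int((est_cat == k).sum())) for k in range(6)
    )
    by_dir_n = tuple(int((dir_cat == k).sum()) for k in range(6))
    strat = np.searchsorted(CONCORDANCE_TG_EDGES, tg_arr, side="right")
    labels = band_labels(CONCORDANCE_TG_EDGES, upper_cap=400.0)
    by_tg = tuple(
        (labels[s], int(match[strat == s].sum()), int((strat == s).sum()))
        for s in range(len(labels))
    )
    return ConcordanceReport(
        overall=(overall_c, int(total)),
        by_estimate_category=by_cat,
        by_direct_category_n=by_dir_n,
        by_tg_stratum=by_tg,
        under_count=int((est_cat < dir_cat).sum()),
        over_count=int((est_cat > dir_cat).sum()),
    )


# ---------------------------------------------------------------------------
# Paired exact tests

def mcnemar_exact(n01: int, n10: int) -> float:
    """Two-sided exact McNemar p-value from the discordant-pair counts.

    Exact binomial: p = min(1, 2 * P(X <= min(n01, n10))) with
    X ~ Binomial(n01 + n10, 1/2).  Symmetric in its arguments.
    """
    if n01 < 0 or n10 < 0:
        raise ValueError("discordant counts must be non-negative")
    n = n01 + n10
    if n == 0:
        warnings.warn("no discordant pairs; McNemar p-value is 1 by convention")
        return 1.0
    return float(min(1.0, 2.0 * stats.binom.cdf(min(n01, n10), n, 0.5)))


@dataclass(frozen=True)
class SignedRankResult:
    """Wilcoxon signed-rank outcome with the positive/negative rank sums.

    ``sp + sn == n_nonzero * (n_nonzero + 1) / 2``.  ``direction`` follows
    the rank-sum rule: 'positive' when SP > SN (x tends to exceed y),
    'negative' when SN > SP, 'none' on equality.
    """

    sp: float
    sn: float
    n_nonzero: int
    p_two_sided: float
    exact: bool

    @property
    def direction(self) -> str:
        if self.sp > self.sn:
            return "positive"
        if self.sn > self.sp:
            return "negative"
        return "none"


def _wilcoxon_exact_p(ranks: np.ndarray, w_min: float) -> float:
    """Exact two-sided tail by convolution over +/- rank assignments.

    Ranks are midranks, so doubled to integers; counts subsets of ranks
    whose sum is <= w_min (the smaller of SP, SN); the null distribution is
    symmetric, so the two-sided p is twice that tail, capped at 1.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r]
    counts /= 2.0 ** len(r2)
    w2 = int(round(2.0 * w_min))
    tail = float(counts[: w2 + 1].sum())
    return min(1.0, 2.0 * tail)


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_limit: int = 25
) -> SignedRankResult:
    """Wilcoxon signed-rank test for paired samples, reporting SP and SN.

    Zero differences are dropped before ranking; ties get midranks.  The
    null distribution is enumerated exactly for up to ``exact_limit``
    non-zero differences, and approximated by a tie-corrected normal (no
    continuity correction) above that.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size == 0:
        raise ValueError("x and y must be equal-length 1-D sequences, length >= 1")
    d = xa - ya
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; degenerate Wilcoxon result")
        return SignedRankResult(sp=0.0, sn=0.0, n_nonzero=0, p_two_sided=1.0, exact=True)
    ranks = stats.rankdata(np.abs(d))
    sp = float(ranks[d > 0].sum())
    sn = float(ranks[d < 0].sum())
    if n <= exact_limit:
        p = _wilcoxon_exact_p(ranks, min(sp, sn))
        return SignedRankResult(sp=sp, sn=sn, n_nonzero=n, p_two_sided=p, exact=True)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var == 0:
        warnings.warn("zero variance in signed-rank statistic; p = 1")
        return SignedRankResult(sp=sp, sn=sn, n_nonzero=n, p_two_sided=1.0, exact=False)
    z = (sp - mean) / math.sqrt(var)
    p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return SignedRankResult(sp=sp, sn=sn, n_nonzero=n, p_two_sided=p, exact=False)


# ---------------------------------------------------------------------------
# Difference-distribution summaries

def difference_summary(
    estimates: Sequence[float], direct: Sequence[float]
) -> dict[str, float | tuple[float, float]]:
    """Median, IQR, 5th-95th and 1st-99th percentiles of estimate - direct.

    Quantiles use linear interpolation between order statistics.  Values
    keep the sign convention estimate minus direct (positive =
    overestimation), mg/dL.
    """
    e = np.asarray(estimates, dtype=float)
    m = np.asarray(direct, dtype=float)
    if e.shape != m.shape or e.size == 0:
        raise ValueError("estimates and direct must be equal-length, non-empty")
    d = e - m
    q = np.quantile(d, [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99])
    return {
        "median": float(q[3]),
        "iqr": (float(q[2]), float(q[4])),
        "p5_p95": (float(q[1]), float(q[5])),
        "p1_p99": (float(q[0]), float(q[6])),
    }


# ---------------------------------------------------------------------------
# Group comparison tests

def mood_median_test(groups: Sequence[Sequence[float]]) -> float:
    """Mood's median test across k groups.

    Dichotomizes every value at the pooled grand median (above vs at-or-
    below) and tests the resulting 2 x k table with a Pearson chi-square
    without continuity correction; a 2 x 2 table with any expected count
    below 5 falls back to Fisher's exact test.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group must be non-empty")
    grand = np.median(np.concatenate(arrs))
    above = np.array([(a > grand).sum() for a in arrs], dtype=int)
    below = np.array([(a <= grand).sum() for a in arrs], dtype=int)
    table = np.vstack([above, below])
    if above.sum() == 0 or below.sum() == 0:
        raise ValueError(
            "degenerate median test: every value ties the grand median on one side"
        )
    if table.shape[1] == 2:
        expected = stats.contingency.expected_freq(table)
        if (expected < 5).any():
            return float(stats.fisher_exact(table)[1])
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


@dataclass(frozen=True)
class TamhaneResult:
    """One-way ANOVA omnibus plus Tamhane T2 pairwise letter grouping."""

    f_statistic: float
    p_omnibus: float
    pairwise_p: dict[tuple[int, int], float]  # Sidak-adjusted Welch p-values
    letters: tuple[str, ...]  # groups sharing a letter: not sig. different
    # letters run A, B, ... in descending group-mean order


def _welch_t_p(a: np.ndarray, b: np.ndarray) -> float:
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p)


def _letter_display(k: int, different: set[tuple[int, int]], order: Sequence[int]) -> tuple[str, ...]:
    """Compact letter display: maximal cliques of the 'not different' graph.

    Groups are lettered following ``order`` (ascending mean); each maximal
    set of mutually non-different groups gets one letter.
    """
    not_diff = {
        frozenset((i, j))
        for i in range(k) for j in range(i + 1, k)
        if (i, j) not in different
    }
    # maximal cliques by inclusion over subsets containing each seed, k is tiny
    cliques: list[frozenset[int]] = []
    for size in range(k, 0, -1):
        for combo in itertools.combinations(range(k), size):
            cset = frozenset(combo)
            if any(cset <= c for c in cliques):
                continue
            if all(frozenset(p) in not_diff for p in itertools.combinations(combo, 2)):
                cliques.append(cset)
    pos = {g: i for i, g in enumerate(order)}
    cliques.sort(key=lambda c: min(pos[g] for g in c))
    labels = [""] * k
    for letter, clique in zip(string.ascii_uppercase, cliques):
        for g in clique:
            labels[g] += letter
    return tuple(labels)


def anova_with_tamhane(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> TamhaneResult:
    """One-way ANOVA F-test with Tamhane T2 post-hoc letter grouping.

    Tamhane T2 performs all pairwise Welch t-tests (no equal-variance
    assumption) and applies a Sidak adjustment 1 - (1-p)^m over the m
    comparisons; groups not significantly different at ``alpha`` share a
    letter, lettered in descending-mean order.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrs):
        raise ValueError("every group needs n >= 2")
    if all(a.var(ddof=1) == 0 for a in arrs):
        raise ValueError("zero within-group variance everywhere; ANOVA undefined")
    f_stat, p_omni = stats.f_oneway(*arrs)
    m = k * (k - 1) // 2
    pairwise: dict[tuple[int, int], float] = {}
    different: set[tuple[int, int]] = set()
    for i, j in itertools.combinations(range(k), 2):
        p_raw = _welch_t_p(arrs[i], arrs[j])
        p_adj = float(min(1.0, 1.0 - (1.0 - p_raw) ** m))
        pairwise[(i, j)] = p_adj
        if p_adj < alpha:
            different.add((i, j))
    order = sorted(range(k), key=lambda g: -arrs[g].mean())
    letters = _letter_display(k, different, order)
    return TamhaneResult(
        f_statistic=float(f_stat), p_omnibus=float(p_omni),
        pairwise_p=pairwise, letters=letters,
    )


# ---------------------------------------------------------------------------
# Regression variance decomposition

PREDICTOR_NAMES = ("tg", "non_hdl", "hdl", "age")


@dataclass(frozen=True)
class RegressionSummary:
    """OLS of VLDL-C on lipid predictors, with correlation decomposition."""

    predictors: tuple[str, ...]
    b: dict[str, float]
    b_ci: dict[str, tuple[float, float]]
    zero_order_r: dict[str, float]
    partial_r: dict[str, float]
    intercept: float
    intercept_ci: tuple[float, float]
    adjusted_r2: float
    r2: float
    n: int


def variance_decomposition(
    cohort: Sequence[LipidPanel],
    predictors: Sequence[str] = ("tg", "non_hdl"),
    tg_max: float = 400.0,
) -> RegressionSummary:
    """OLS of computed VLDL-C on a subset of {tg, non_hdl, hdl, age}.

    Reports per-predictor unstandardized coefficients with 95% CI, the
    zero-order correlation with VLDL-C, and the partial correlation
    (correlation of residuals after regressing both VLDL-C and the
    predictor on the remaining predictors), plus the model's adjusted R².
    Subjects with TG >= ``tg_max`` or without direct LDL-C are excluded.
    """
    preds = tuple(predictors)
    unknown = set(preds) - set(PREDICTOR_NAMES)
    if unknown:
        raise ValueError(f"unknown predictors: {sorted(unknown)}")
    if len(set(preds)) != len(preds) or not preds:
        raise ValueError("predictors must be a non-empty set of distinct names")
    rows = []
    for p in cohort:
        if p.ldl_direct is None or p.tg >= tg_max:
            continue
        d = compute_derived(p)
        rows.append(
            {"tg": p.tg, "non_hdl": d.non_hdl, "hdl": p.hdl, "age": p.age,
             "vldl": d.vldl}
        )
    df = pd.DataFrame(rows)
    if len(df) < len(preds) + 2:
        raise ValueError(
            f"need at least {len(preds) + 2} eligible subjects, have {len(df)}"
        )
    X = df[list(preds)]
    for a, b_name in itertools.combinations(preds, 2):
        r = np.corrcoef(X[a], X[b_name])[0, 1]
        if abs(r) > 1 - 1e-12:
            raise ValueError(f"collinear predictors: {a} and {b_name}")
    y = df["vldl"].to_numpy()
    model = sm.OLS(y, sm.add_constant(X)).fit()
    ci = model.conf_int(alpha=0.05)
    zero_order = {v: float(np.corrcoef(X[v], y)[0, 1]) for v in preds}
    partial = {}
    for v in preds:
        others = [w for w in preds if w != v]
        if not others:
            partial[v] = zero_order[v]
            continue
        Z = sm.add_constant(X[others])
        res_y = sm.OLS(y, Z).fit().resid
        res_x = sm.OLS(X[v].to_numpy(), Z).fit().resid
        partial[v] = float(np.corrcoef(res_x, res_y)[0, 1])
    return RegressionSummary(
        predictors=preds,
        b={v: float(model.params[v]) for v in preds},
        b_ci={v: (float(ci.loc[v, 0]), float(ci.loc[v, 1])) for v in preds},
        zero_order_r=zero_order,
        partial_r=partial,
        intercept=float(model.params["const"]),
        intercept_ci=(float(ci.loc["const", 0]), float(ci.loc["const", 1])),
        adjusted_r2=float(model.rsquared_adj),
        r2=float(model.rsquared),
        n=int(len(df)),
    )
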