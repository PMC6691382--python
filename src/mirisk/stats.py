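"""Self-contained statistical primitives reused across the pipeline.

Implements, from first principles: Spearman rank correlation with exact
(small-n permutation) or t-approximation P-values, the one/two-sided
Mann-Whitney/Wilcoxon rank-sum test (exact enumeration for small tie-free
samples, tie- and continuity-corrected normal approximation otherwise),
Benjamini-Hochberg step-up FDR, ROC curves with the rank-sum AUC identity and
DeLong confidence intervals, and a Wilcoxon signed-rank test for paired
designs.  scipy is used only for reference distribution functions
(t / normal / chi-square tails).

P-values are floored at machine epsilon and never reported as exactly zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _spdist

_EPS = float(np.finfo(float).eps)

# branch thresholds: exact Spearman permutation below this n, exact rank-sum
# enumeration up to this pooled size (tie-free only)
SPEARMAN_EXACT_MAX_N = 9
RANKSUM_EXACT_MAX_N = 12


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined for these inputs (n too small,
    zero variance, single-class labels, ...)."""


def _clip_p(p: float) -> float:
    return float(min(1.0, max(_EPS, p)))


def midranks(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties given their average (mid) rank."""
    x = np.asarray(x, dtype=float)
    n = x.size
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(n, dtype=float)
    sx = x[order]
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    sidedness: str  # "two" | "negative-one-sided"


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def spearman(x, y, sidedness: str = "two") -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of the mid-ranks.  The P-value uses the
    exact permutation distribution (all n! orderings of one rank vector) for
    n < 10 and the t approximation with n-2 degrees of freedom otherwise.
    ``sidedness="negative-one-sided"`` reports P(rho* <= rho_obs) under the
    null, the direction-constrained test the target-integration cascade uses.
    """
    if sidedness not in ("two", "negative-one-sided"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n < 3:
        raise UndefinedStatisticError(f"need n >= 3 complete pairs, got {n}")
    rx = midranks(x)
    ry = midranks(y)
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    sx = math.sqrt(float(cx @ cx))
    sy = math.sqrt(float(cy @ cy))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError("zero variance in ranks")
    rho = float(np.clip((cx @ cy) / (sx * sy), -1.0, 1.0))
    if abs(abs(rho) - 1.0) < 4 * _EPS:  # identical/reversed rankings
        rho = math.copysign(1.0, rho)

    if n <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(cx, cy, sx * sy, rho, sidedness)
    else:
        df = n - 2
        denom = max(1.0 - rho * rho, _EPS)
        t = rho * math.sqrt(df / denom)
        if sidedness == "two":
            p = 2.0 * float(_spdist.t.sf(abs(t), df))
        else:
            p = float(_spdist.t.cdf(t, df))
    return CorrelationResult(rho=rho, p_value=_clip_p(p), n=n, sidedness=sidedness)


def _spearman_exact_p(cx, cy, norm, rho_obs, sidedness) -> float:
    """Exact permutation P by complete enumeration of orderings of y's ranks."""
    n = cx.size
    tol = 1e-12
    count = 0
    total = 0
    cy_t = tuple(cy)
    for perm in itertools.permutations(cy_t):
        r = float(np.dot(cx, perm)) / norm
        if sidedness == "two":
            if abs(r) >= abs(rho_obs) - tol:
                count += 1
        else:
            if r <= rho_obs + tol:
                count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# Mann-Whitney / rank-sum test
# ---------------------------------------------------------------------------


def rank_sum_test(a, b, alternative: str = "two_sided") -> tuple[float, float]:
    """Mann-Whitney U test on mid-ranks; returns (U_a, p).

    U_a counts pairs (i, j) with a_i > b_j (ties half).  Exact P by complete
    enumeration of group labelings when the pooled size is <= 12 and tie-free;
    otherwise the normal approximation with tie correction and a 0.5
    continuity correction.  ``alternative``: "a_greater", "a_less" or
    "two_sided".
    """
    if alternative not in ("a_greater", "a_less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        raise UndefinedStatisticError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n = na + nb
    ranks = midranks(pooled)
    ra = float(ranks[:na].sum())
    u_a = ra - na * (na + 1) / 2.0

    has_ties = np.unique(pooled).size < n
    if n <= RANKSUM_EXACT_MAX_N and not has_ties:
        p = _ranksum_exact_p(ranks, na, u_a, alternative)
        return float(u_a), _clip_p(p)

    mu = na * nb / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (12.0 * n * (n - 1)) if n > 1 else 0.0
    var = na * nb * ((n + 1) / 12.0 - tie_term)
    if var <= 0:
        # completely tied pooled sample: U is degenerate at its mean
        return float(u_a), 1.0
    sd = math.sqrt(var)
    if alternative == "a_greater":
        z = (u_a - mu - 0.5) / sd
        p = float(_spdist.norm.sf(z))
    elif alternative == "a_less":
        z = (u_a - mu + 0.5) / sd
        p = float(_spdist.norm.cdf(z))
    else:
        z = max(abs(u_a - mu) - 0.5, 0.0) / sd
        p = 2.0 * float(_spdist.norm.sf(z))
    return float(u_a), _clip_p(p)


def _ranksum_exact_p(ranks, na, u_obs, alternative) -> float:
    """Exact U null distribution by enumerating all C(n, na) labelings."""
    n = ranks.size
    offset = na * (na + 1) / 2.0
    tol = 1e-9
    ge = 0
    le = 0
    total = 0
    for combo in itertools.combinations(range(n), na):
        u = sum(ranks[i] for i in combo) - offset
        if u >= u_obs - tol:
            ge += 1
        if u <= u_obs + tol:
            le += 1
        total += 1
    if alternative == "a_greater":
        return ge / total
    if alternative == "a_less":
        return le / total
    return min(1.0, 2.0 * min(ge, le) / total)


def wilcoxon_signed_rank(a, b=None, alternative: str = "two_sided") -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples (or differences directly).

    W is the sum of ranks of positive differences; zero differences are
    dropped.  Exact enumeration of the 2^n sign assignments when n <= 12 and
    |differences| are tie-free, else the tie-corrected normal approximation
    with continuity correction.  ``alternative="a_greater"`` tests for a > b.
    """
    if alternative not in ("a_greater", "a_less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    a = np.asarray(a, dtype=float)
    d = a - np.asarray(b, dtype=float) if b is not None else a
    d = d[~np.isnan(d)]
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise UndefinedStatisticError("no non-zero paired differences")
    r = midranks(np.abs(d))
    w_pos = float(r[d > 0].sum())

    has_ties = np.unique(np.abs(d)).size < n
    if n <= 12 and not has_ties:
        tol = 1e-9
        ge = le = 0
        total = 1 << n
        for mask in range(total):
            w = 0.0
            for i in range(n):
                if mask >> i & 1:
                    w += r[i]
            if w >= w_pos - tol:
                ge += 1
            if w <= w_pos + tol:
                le += 1
        if alternative == "a_greater":
            return w_pos, _clip_p(ge / total)
        if alternative == "a_less":
            return w_pos, _clip_p(le / total)
        return w_pos, _clip_p(min(1.0, 2.0 * min(ge, le) / total))

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((counts**3 - counts).sum()) / 48.0
    if var <= 0:
        return w_pos, 1.0
    sd = math.sqrt(var)
    if alternative == "a_greater":
        p = float(_spdist.norm.sf((w_pos - mu - 0.5) / sd))
    elif alternative == "a_less":
        p = float(_spdist.norm.cdf((w_pos - mu + 0.5) / sd))
    else:
        z = max(abs(w_pos - mu) - 0.5, 0.0) / sd
        p = 2.0 * float(_spdist.norm.sf(z))
    return w_pos, _clip_p(p)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR
# ---------------------------------------------------------------------------


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending; thresholds[0] = +inf (no calls)
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci95: tuple[float, float]

    @property
    def n_points(self) -> int:
        return self.fpr.size


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve of a score against boolean labels.

    AUC uses the rank-sum identity U/(n_pos * n_neg) with tied
    positive-negative pairs counted 1/2; the 95% CI is DeLong's nonparametric
    interval.  The curve starts at (0,0), ends at (1,1), and its trapezoidal
    area equals the AUC (tied scores collapse to a single diagonal segment).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    npos = int(labels.sum())
    nneg = int((~labels).sum())
    if npos == 0 or nneg == 0:
        raise UndefinedStatisticError("both classes must be present")

    r_all = midranks(scores)
    auc = (float(r_all[labels].sum()) - npos * (npos + 1) / 2.0) / (npos * nneg)

    # curve over descending unique thresholds
    thr = np.unique(scores)[::-1]
    tps = np.array([(labels & (scores >= t)).sum() for t in thr], dtype=float)
    fps = np.array([(~labels & (scores >= t)).sum() for t in thr], dtype=float)
    tpr = np.concatenate([[0.0], tps / npos])
    fpr = np.concatenate([[0.0], fps / nneg])
    thresholds = np.concatenate([[np.inf], thr])

    ci = _delong_ci(scores, labels, auc, npos, nneg)
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(auc), ci95=ci)


def _delong_ci(scores, labels, auc, npos, nneg) -> tuple[float, float]:
    r_all = midranks(scores)
    pos = scores[labels]
    neg = scores[~labels]
    # placements: V10_i = fraction of negatives a positive beats (ties half)
    v10 = (r_all[labels] - midranks(pos)) / nneg
    v01 = 1.0 - (r_all[~labels] - midranks(neg)) / npos
    s10 = float(np.var(v10, ddof=1)) if npos > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if nneg > 1 else 0.0
    se = math.sqrt(s10 / npos + s01 / nneg)
    z = 1.959963984540054
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def roc_auc_rank_pvalue(scores, labels) -> float:
    """P-value for AUC != 0.5 via the equivalent two-sided rank-sum test of
    scores in positives vs negatives (the Wilcoxon reading of an ROC test)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    _, p = rank_sum_test(scores[labels], scores[~labels], "two_sided")
    return p


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial (Clopper-Pearson) confidence interval for k/n."""
    if n == 0:
        raise UndefinedStatisticError("empty denominator")
    lo = 0.0 if k == 0 else float(_spdist.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(_spdist.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi
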