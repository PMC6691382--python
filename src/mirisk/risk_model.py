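"""Metastatic-risk classification: per-series dichotomization, stepwise
logistic modelling, the miR-SDHB 0-3 score, and ROC evaluation.

To pool sub-series profiled on different platforms, each miRNA is first
turned into a binary high/low indicator at its *within-series* median (a
batch-aware cut: pooled medians would let platform baselines leak into the
indicator).  The model is a maximum-likelihood logistic regression with
forward/backward stepwise term selection by likelihood-ratio tests, with the
series indicator covariates forced in; a stratum-conditional likelihood
variant (series as strata, no intercept) is available via ``mode``.

The miR-SDHB score is the integer count of three risk features: miR-21-3p
high, miR-183-5p high, SDHB mutated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize as _spopt
from scipy import stats as _spdist

from .datamodel import ExpressionMatrix, SampleSheet, ValidationError
from .stats import RocCurve, clopper_pearson, roc_auc

logger = logging.getLogger(__name__)

ENTRY_ALPHA = 0.05
REMOVAL_ALPHA = 0.10


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class DichotomizedDesign:
    """Pooled binary design: miRNA high/low indicators, SDHB, series dummies,
    metastatic outcome.  ``frame`` is indexed by sample_id; ``series_terms``
    names the k-1 series indicator columns (first series is the reference)."""

    frame: pd.DataFrame
    mirna_terms: list[str]
    series_terms: list[str]
    sdhb_term: str | None

    @property
    def outcome(self) -> np.ndarray:
        return self.frame["outcome"].to_numpy(dtype=float)


def dichotomize(
    exprs: Sequence[ExpressionMatrix], mirna_ids: Sequence[str]
) -> pd.DataFrame:
    """Binary high/low indicators at the within-series median, then pooled.

    indicator = 1 iff value strictly above the median of that miRNA *in that
    series*; computed independently per series before pooling so that series
    baseline shifts cannot bias the split.  A miRNA constant within a series
    is an error (no meaningful median split exists).
    """
    frames = []
    for expr in exprs:
        cols = {}
        for mid in mirna_ids:
            v = expr.row(mid)
            if np.any(np.isnan(v)):
                raise ValidationError(
                    f"miRNA {mid!r} has missing values in series {expr.series_id!r}"
                )
            if np.all(v == v[0]):
                raise ValidationError(
                    f"miRNA {mid!r} constant in series {expr.series_id!r}"
                )
            cols[f"{mid}_high"] = (v > np.median(v)).astype(int)
        df = pd.DataFrame(cols, index=pd.Index(expr.sample_ids, name="sample_id"))
        df["series_id"] = expr.series_id
        frames.append(df)
    out = pd.concat(frames)
    if out.index.duplicated().any():
        raise ValidationError("duplicate sample IDs across series")
    return out


def build_design(
    indicators: pd.DataFrame,
    sheet: SampleSheet,
    include_sdhb: bool = True,
) -> DichotomizedDesign:
    """Join indicators with clinical data into a model-ready design.

    Samples with unknown SDHB status are excluded (with a log entry) when
    SDHB enters the design; unknown status is never imputed.
    """
    mirna_terms = [c for c in indicators.columns if c != "series_id"]
    rows = []
    kept_idx = []
    for sid in indicators.index:
        if sid not in sheet:
            raise ValidationError(f"sample {sid!r} missing from sample sheet")
        rec = sheet[sid]
        if include_sdhb and rec.sdhb_mutated is None:
            logger.info("sample %s excluded: unknown SDHB status", sid)
            continue
        row = {t: int(indicators.at[sid, t]) for t in mirna_terms}
        if include_sdhb:
            row["sdhb_mutated"] = int(rec.sdhb_mutated)
        row["outcome"] = int(rec.metastatic)
        rows.append(row)
        kept_idx.append(sid)
    frame = pd.DataFrame(rows, index=pd.Index(kept_idx, name="sample_id"))
    series = indicators.loc[kept_idx, "series_id"]
    series_levels = list(dict.fromkeys(series))
    series_terms = []
    for lvl in series_levels[1:]:
        col = f"series_{lvl}"
        frame[col] = (series == lvl).astype(int).to_numpy()
        series_terms.append(col)
    frame["series_id"] = series.to_numpy()
    return DichotomizedDesign(
        frame=frame,
        mirna_terms=mirna_terms,
        series_terms=series_terms,
        sdhb_term="sdhb_mutated" if include_sdhb else None,
    )


# ---------------------------------------------------------------------------
# logistic fits
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    llf: float
    converged: bool
    n_iter: int


def logistic_fit(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by iteratively reweighted least
    squares (Newton-Raphson on the log-likelihood).

    Converges when the log-likelihood moves by less than ``tol``.  Under
    perfect separation the likelihood has no maximum: the fit is flagged
    ``converged=False`` and the coefficients from the last stable iteration
    are returned; callers may retry with ``ridge > 0`` (an L2 penalty) as the
    documented fallback.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    ll_old = -math.inf
    last_stable = beta.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        # clip to keep weights finite; |eta| this large means separation
        eta_c = np.clip(eta, -35.0, 35.0)
        mu = 1.0 / (1.0 + np.exp(-eta_c))
        ll = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
        if ridge > 0:
            ll -= 0.5 * ridge * float(beta @ beta)
        w = mu * (1.0 - mu)
        if not np.isfinite(ll):
            break
        if abs(ll - ll_old) < tol:
            converged = True
            break
        ll_old = ll
        last_stable = beta.copy()
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        if ridge > 0:
            grad -= ridge * beta
            hess += ridge * np.eye(k)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0 and ridge == 0.0:
            # diverging coefficients: (quasi-)separation
            break
    if not converged:
        beta = last_stable
        logger.warning(
            "logistic fit did not converge after %d iterations "
            "(possible perfect separation); returning last stable iterate",
            it,
        )
        eta_c = np.clip(X @ beta, -35.0, 35.0)
        ll_old = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
    return LogisticFit(coefficients=beta, llf=ll_old if converged else ll_old,
                       converged=converged, n_iter=it)


def _esp_dp(w: np.ndarray, k: int) -> float:
    """log of the elementary symmetric polynomial e_k over weights exp(eta),
    computed by the stable O(n*k) recursion in log space."""
    # dp[j] = log e_j of the prefix processed so far
    dp = np.full(k + 1, -math.inf)
    dp[0] = 0.0
    for eta in w:
        dp[1 : k + 1] = np.logaddexp(dp[1 : k + 1], dp[0:k] + eta)
    return float(dp[k])


def conditional_logistic_fit(
    X: np.ndarray, y: np.ndarray, strata: Sequence, tol: float = 1e-8
) -> LogisticFit:
    """Stratum-conditional logistic regression (series as strata).

    Maximises the exact conditional likelihood: within each stratum, the
    probability of the observed case set given its size, so intercepts and
    stratum-constant covariates drop out of the model.  The denominator
    (a sum over all case sets of the stratum) is computed with the elementary
    symmetric polynomial recursion, so large strata stay tractable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    strata = np.asarray(strata)
    groups = [np.where(strata == s)[0] for s in pd.unique(strata)]

    def nll(beta: np.ndarray) -> float:
        eta = X @ beta
        total = 0.0
        for idx in groups:
            k = int(y[idx].sum())
            if k == 0 or k == idx.size:
                continue  # uninformative stratum
            total += float(eta[idx][y[idx] > 0].sum()) - _esp_dp(eta[idx], k)
        return -total

    res = _spopt.minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                          options={"gtol": 1e-7})
    return LogisticFit(
        coefficients=res.x, llf=float(-res.fun), converged=bool(res.success),
        n_iter=int(res.nit),
    )


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------


@dataclass
class RiskModelFit:
    selected_terms: list[str]
    coefficients: dict[str, float]
    intercept: float
    probabilities: np.ndarray | None
    convergence: bool
    llf: float
    mode: str = "unconditional"
    sample_ids: list[str] = field(default_factory=list)


def stepwise_logistic(
    design: DichotomizedDesign,
    candidate_terms: Sequence[str],
    forced_terms: Sequence[str] = (),
    entry_alpha: float = ENTRY_ALPHA,
    removal_alpha: float = REMOVAL_ALPHA,
    mode: str = "unconditional",
    ridge: float = 0.0,
) -> RiskModelFit:
    """Forward selection / backward elimination by likelihood-ratio tests.

    Terms enter at ``entry_alpha`` (LR chi-square, 1 df) and leave at
    ``removal_alpha``; forced terms (typically the series indicators, and
    optionally SDHB) are always retained regardless of significance.
    ``mode="conditional"`` swaps in the stratum-conditional likelihood with
    series as strata (series indicators then drop out automatically).
    """
    if mode not in ("unconditional", "conditional"):
        raise ValueError(f"unknown mode {mode!r}")
    frame = design.frame
    y = design.outcome
    if y.min() == y.max():
        raise ValidationError("outcome has a single class")
    forced = [t for t in forced_terms]
    if mode == "conditional":
        forced = [t for t in forced if t not in design.series_terms]
        strata = frame["series_id"].to_numpy()
    candidates = [t for t in candidate_terms if t not in forced]

    def fit(terms: list[str]) -> LogisticFit:
        if mode == "conditional":
            if not terms:
                return LogisticFit(np.zeros(0), 0.0, True, 0)
            X = frame[terms].to_numpy(dtype=float)
            return conditional_logistic_fit(X, y, strata)
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[t].to_numpy(dtype=float) for t in terms]
        )
        return logistic_fit(X, y, ridge=ridge)

    selected: list[str] = list(forced)
    current = fit(selected)
    changed = True
    while changed:
        changed = False
        # forward step
        best_term, best_p, best_fit = None, 1.0, None
        for t in candidates:
            if t in selected:
                continue
            trial = fit(selected + [t])
            lr = 2.0 * (trial.llf - current.llf)
            p = float(_spdist.chi2.sf(max(lr, 0.0), 1))
            if p < best_p:
                best_term, best_p, best_fit = t, p, trial
        if best_term is not None and best_p < entry_alpha:
            selected.append(best_term)
            current = best_fit
            changed = True
        # backward step over non-forced terms
        removable = [t for t in selected if t not in forced]
        worst_term, worst_p, worst_fit = None, -1.0, None
        for t in removable:
            reduced = [s for s in selected if s != t]
            trial = fit(reduced)
            lr = 2.0 * (current.llf - trial.llf)
            p = float(_spdist.chi2.sf(max(lr, 0.0), 1))
            if p > worst_p:
                worst_term, worst_p, worst_fit = t, p, trial
        if worst_term is not None and worst_p > removal_alpha:
            selected.remove(worst_term)
            current = worst_fit
            changed = True

    if mode == "conditional":
        coefs = dict(zip(selected, current.coefficients))
        probs = None
        intercept = 0.0
    else:
        intercept = float(current.coefficients[0])
        coefs = dict(zip(selected, current.coefficients[1:]))
        eta = np.clip(
            intercept
            + sum(
                coefs[t] * frame[t].to_numpy(dtype=float) for t in selected
            ),
            -35.0,
            35.0,
        ) if selected else np.full(len(frame), np.clip(intercept, -35, 35))
        probs = 1.0 / (1.0 + np.exp(-eta))
    return RiskModelFit(
        selected_terms=selected,
        coefficients={t: float(c) for t, c in coefs.items()},
        intercept=intercept,
        probabilities=probs,
        convergence=current.converged,
        llf=float(current.llf),
        mode=mode,
        sample_ids=list(frame.index),
    )


# ---------------------------------------------------------------------------
# miR-SDHB score
# ---------------------------------------------------------------------------


@dataclass
class MirSdhbScore:
    sample_id: str
    score: int  # 0..3
    components: tuple[int, int, int]  # (mir21_high, mir183_high, sdhb_mut)


def mir_sdhb_score(
    design: DichotomizedDesign,
    mir21_term: str | None = None,
    mir183_term: str | None = None,
) -> list[MirSdhbScore]:
    """Integer 0-3 risk score: miR-21-3p high + miR-183-5p high + SDHB mutated.

    Score 3 means all three risk features, score 0 none; the score is the
    plain sum of the three indicators (symmetric in its components).
    """
    frame = design.frame
    if design.sdhb_term is None:
        raise ValidationError("design was built without SDHB status")

    def _find(term: str | None, token: str) -> str:
        if term is not None:
            if term not in frame.columns:
                raise ValidationError(f"indicator column {term!r} missing")
            return term
        matches = [c for c in design.mirna_terms if token in c]
        if len(matches) != 1:
            raise ValidationError(
                f"cannot locate unique indicator for {token!r}: {matches}"
            )
        return matches[0]

    c21 = _find(mir21_term, "miR-21-3p")
    c183 = _find(mir183_term, "miR-183-5p")
    out = []
    for sid in frame.index:
        comp = (
            int(frame.at[sid, c21]),
            int(frame.at[sid, c183]),
            int(frame.at[sid, design.sdhb_term]),
        )
        out.append(MirSdhbScore(sample_id=sid, score=sum(comp), components=comp))
    return out


def stratify_by_score(
    scores: Sequence[MirSdhbScore], sheet: SampleSheet
) -> pd.DataFrame:
    """Metastatic fraction per score level with exact Clopper-Pearson 95% CIs.

    Empty score levels report a missing fraction (NaN), never zero.
    """
    rows = []
    for level in range(4):
        members = [s for s in scores if s.score == level]
        n = len(members)
        if n == 0:
            rows.append(dict(score=level, n=0, n_metastatic=0,
                             fraction=np.nan, ci_low=np.nan, ci_high=np.nan))
            continue
        k = sum(int(sheet[s.sample_id].metastatic) for s in members)
        lo, hi = clopper_pearson(k, n)
        rows.append(dict(score=level, n=n, n_metastatic=k,
                         fraction=k / n, ci_low=lo, ci_high=hi))
    return pd.DataFrame(rows).set_index("score")


def evaluate_classifier(
    fit_or_scores: RiskModelFit | Sequence[MirSdhbScore], outcome
) -> RocCurve:
    """Apparent (training-data) ROC of a fitted model or of the integer score."""
    if isinstance(fit_or_scores, RiskModelFit):
        if fit_or_scores.probabilities is None:
            raise ValidationError(
                "conditional-mode fits have no per-sample probabilities"
            )
        scores = np.asarray(fit_or_scores.probabilities, dtype=float)
    else:
        scores = np.array([s.score for s in fit_or_scores], dtype=float)
    return roc_auc(scores, np.asarray(outcome, dtype=bool))
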