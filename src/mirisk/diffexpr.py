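"""Differential miRNA expression between metastatic and non-metastatic tumors.

Run per sub-series (discovery is batch-aware: each series is tested and
FDR-corrected on its own), then combined by a direction-consistent consensus
across series.  A separate one-sided, direction-constrained test confirms
candidates in an independent validation series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .datamodel import ExpressionMatrix, SampleSheet, ValidationError
from .stats import bh_fdr, rank_sum_test

logger = logging.getLogger(__name__)

DEFAULT_FDR_CUT = 0.05
DEFAULT_LFC_CUT = 0.75


@dataclass
class DEResult:
    mirna_id: str
    series_id: str
    log2fc: float  # mean(metastatic) - mean(non-metastatic), log2 units
    p_value: float
    q_value: float
    direction: str  # "up" iff log2fc > 0
    passed: bool


@dataclass
class ConsensusCall:
    mirna_id: str
    series_hits: frozenset[str]
    direction: str
    direction_consistent: bool = True


def _split_groups(
    expr: ExpressionMatrix, sheet: SampleSheet
) -> tuple[np.ndarray, np.ndarray]:
    missing = [s for s in expr.sample_ids if s not in sheet]
    if missing:
        raise ValidationError(f"samples not in sheet: {missing[:5]}")
    is_met = np.array([sheet[s].metastatic for s in expr.sample_ids], dtype=bool)
    return is_met, ~is_met


def differential_expression(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    fdr_cut: float = DEFAULT_FDR_CUT,
    lfc_cut: float = DEFAULT_LFC_CUT,
) -> list[DEResult]:
    """Two-sided rank-sum test per miRNA, BH-corrected within the series.

    A miRNA passes iff q < ``fdr_cut`` and |log2 fold change| >= ``lfc_cut``,
    with log2FC the difference of group means on the log2 scale.
    """
    met, nonmet = _split_groups(expr, sheet)
    if met.sum() < 2 or nonmet.sum() < 2:
        raise ValidationError(
            f"series {expr.series_id!r}: need >= 2 samples per group "
            f"(metastatic={int(met.sum())}, non-metastatic={int(nonmet.sum())})"
        )
    lfc = np.empty(len(expr.feature_ids))
    pvals = np.empty(len(expr.feature_ids))
    for i, _ in enumerate(expr.feature_ids):
        vm = expr.values[i, met]
        vn = expr.values[i, nonmet]
        vm = vm[~np.isnan(vm)]
        vn = vn[~np.isnan(vn)]
        if vm.size < 2 or vn.size < 2:
            raise ValidationError(
                f"feature {expr.feature_ids[i]!r}: < 2 non-missing values in a group"
            )
        lfc[i] = float(vm.mean() - vn.mean())
        _, pvals[i] = rank_sum_test(vm, vn, "two_sided")
    qvals = bh_fdr(pvals)
    out = []
    for i, mid in enumerate(expr.feature_ids):
        out.append(
            DEResult(
                mirna_id=mid,
                series_id=expr.series_id,
                log2fc=float(lfc[i]),
                p_value=float(pvals[i]),
                q_value=float(qvals[i]),
                direction="up" if lfc[i] > 0 else "down",
                passed=bool(qvals[i] < fdr_cut and abs(lfc[i]) >= lfc_cut),
            )
        )
    return out


def consensus(
    de_lists: Sequence[Sequence[DEResult]], min_series: int = 2
) -> list[ConsensusCall]:
    """Direction-consistent consensus over per-series passing calls.

    A miRNA is called iff it passes in >= ``min_series`` series with the same
    direction in every hit series; miRNAs hitting in conflicting directions
    are excluded and logged, never silently merged.
    """
    hits: dict[str, dict[str, str]] = {}
    for de in de_lists:
        for r in de:
            if r.passed:
                hits.setdefault(r.mirna_id, {})[r.series_id] = r.direction
    calls = []
    for mid in sorted(hits):
        per_series = hits[mid]
        if len(per_series) < min_series:
            continue
        directions = set(per_series.values())
        if len(directions) > 1:
            logger.warning(
                "miRNA %s excluded from consensus: conflicting directions %s",
                mid,
                dict(per_series),
            )
            continue
        calls.append(
            ConsensusCall(
                mirna_id=mid,
                series_hits=frozenset(per_series),
                direction=directions.pop(),
            )
        )
    return calls


def validate_direction(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    expected_direction: Mapping[str, str],
) -> list[tuple[str, float]]:
    """One-sided confirmation of pre-specified candidates in a new series.

    Each candidate is tested with the rank-sum alternative oriented by its
    expected direction from discovery ("up": metastatic greater).  No
    multiplicity adjustment: the candidate set is small and pre-specified.
    """
    met, nonmet = _split_groups(expr, sheet)
    out = []
    for mid in expected_direction:
        direction = expected_direction[mid]
        if direction not in ("up", "down"):
            raise ValidationError(f"miRNA {mid!r}: bad expected direction {direction!r}")
        if mid not in expr:
            raise ValidationError(f"miRNA {mid!r} not present in validation matrix")
        v = expr.row(mid)
        vm = v[met]
        vn = v[nonmet]
        vm = vm[~np.isnan(vm)]
        vn = vn[~np.isnan(vn)]
        alt = "a_greater" if direction == "up" else "a_less"
        _, p = rank_sum_test(vm, vn, alt)
        out.append((mid, float(p)))
    return out


def paired_expression_test(
    primary, metastasis, alternative: str = "two_sided"
) -> tuple[float, float]:
    """Wilcoxon signed-rank comparison of paired primary/metastatic samples.

    Thin wrapper for the paired primary-vs-metastasis design; returns
    (W, p).  ``alternative="a_greater"`` tests metastasis > primary.
    """
    from .stats import wilcoxon_signed_rank

    primary = np.asarray(primary, dtype=float)
    metastasis = np.asarray(metastasis, dtype=float)
    # orient so "a_greater" means higher in metastases
    return wilcoxon_signed_rank(metastasis, primary, alternative)
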