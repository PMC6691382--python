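"""miRNA-mRNA negative-correlation integration ("targetome" cascade) and
multi-cohort correlation screens.

The cascade proceeds in three steps: (1) a candidate target list per miRNA
from validated-interaction databases; (2) restriction of each sub-series mRNA
matrix to those candidates; (3) Spearman correlation of every candidate probe
against the miRNA within each sub-series, followed by a replication filter:
a gene survives only if some series shows a strong significant negative
correlation (rho below a cut, P below alpha) AND that signal is supported
either by significant negative correlations in every other series or by at
least two probes of the gene within the triggering series.  An optional
user-supplied allowlist models the downstream literature-based biology
filter without hard-coding any gene list.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .datamodel import (
    ExpressionMatrix,
    ProbeMap,
    TargetCatalog,
    ValidationError,
)
from .stats import CorrelationResult, spearman

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_STRONG_RHO = -0.4
MIN_PAIRWISE_N = 10
_LOG10_FLOOR = 1e-300


@dataclass
class CorrelationRecord:
    mirna_id: str
    gene_symbol: str
    probe_id: str
    series_id: str
    rho: float
    p_value: float
    n: int


@dataclass
class CascadeResult:
    gene_symbol: str
    trigger_series: list[str]
    support: set[str]  # nonempty; subset of {"cross-series", "multi-probe"}
    records: list[CorrelationRecord]
    passed_allowlist: bool


@dataclass
class CohortCorrelationSummary:
    cohort_id: str
    n: int
    rho: float
    p_value: float
    neg_log10_p: float


def build_targetome_matrix(
    mrna: ExpressionMatrix,
    catalog: TargetCatalog,
    mirna_id: str,
    probe_map: ProbeMap | None = None,
) -> ExpressionMatrix:
    """Restrict an mRNA matrix to the candidate targets of one miRNA.

    All probes of a retained gene are kept.  On single-probe (gene-level)
    platforms the probe map defaults to the identity.  Candidate genes absent
    from the matrix are silently omitted (logged); an empty intersection
    yields an empty matrix with a warning, not an error.
    """
    if probe_map is None:
        probe_map = ProbeMap.identity(mrna.feature_ids)
    candidates = catalog.genes_for(mirna_id)
    keep = [
        f for f in mrna.feature_ids if probe_map.gene_or_none(f) in candidates
    ]
    present_genes = {probe_map.gene(f) for f in keep}
    absent = candidates - present_genes
    if absent:
        logger.info(
            "series %s: %d candidate genes of %s absent from matrix",
            mrna.series_id, len(absent), mirna_id,
        )
    if not keep:
        logger.warning(
            "series %s: no candidate targets of %s on this platform",
            mrna.series_id, mirna_id,
        )
    return mrna.subset_features(keep)


def correlate_targetome(
    targetome: ExpressionMatrix,
    mirna_vector,
    mirna_id: str,
    probe_map: ProbeMap | None = None,
    min_n: int = MIN_PAIRWISE_N,
) -> list[CorrelationRecord]:
    """Two-sided Spearman of every candidate probe against the miRNA.

    ``mirna_vector`` must be aligned to the targetome's sample IDs (pass a
    dict/Series keyed by sample ID, or an array in matrix sample order).
    Probes with fewer than ``min_n`` pairwise-complete observations are
    skipped with a warning.
    """
    if probe_map is None:
        probe_map = ProbeMap.identity(targetome.feature_ids)
    if isinstance(mirna_vector, Mapping) or hasattr(mirna_vector, "reindex"):
        try:
            mv = np.array(
                [float(mirna_vector[s]) for s in targetome.sample_ids]
            )
        except KeyError as e:
            raise ValidationError(f"miRNA vector missing sample {e}") from None
    else:
        mv = np.asarray(mirna_vector, dtype=float)
        if mv.shape != (len(targetome.sample_ids),):
            raise ValidationError(
                "miRNA vector length does not match targetome samples"
            )
    out: list[CorrelationRecord] = []
    for i, probe in enumerate(targetome.feature_ids):
        row = targetome.values[i]
        ok = ~(np.isnan(row) | np.isnan(mv))
        n = int(ok.sum())
        if n < min_n:
            logger.warning(
                "probe %s in series %s: only %d complete pairs, skipped",
                probe, targetome.series_id, n,
            )
            continue
        res = spearman(row[ok], mv[ok], "two")
        out.append(
            CorrelationRecord(
                mirna_id=mirna_id,
                gene_symbol=probe_map.gene(probe),
                probe_id=probe,
                series_id=targetome.series_id,
                rho=res.rho,
                p_value=res.p_value,
                n=res.n,
            )
        )
    return out


def cascade_filter(
    records: Iterable[CorrelationRecord],
    alpha: float = DEFAULT_ALPHA,
    strong_rho: float = DEFAULT_STRONG_RHO,
    allowlist: set[str] | None = None,
    multiprobe_rule: str = "strict",
) -> list[CascadeResult]:
    """Replication filter over per-series correlation records.

    A gene survives iff
      (A) some series has a record with p < ``alpha`` and rho < ``strong_rho``
          (the trigger), AND
      (B) either every *other* series has at least one record of the gene
          with rho < 0 and p < ``alpha`` (cross-series replication), or the
          triggering series has at least two distinct probes of the gene
          each individually significant and negative (``strict``; the
          ``lenient`` reading only requires two probes present, one passing).

    Genes observed in a single series with a single probe cannot satisfy (B)
    and are excluded, not errored.  ``allowlist`` marks (does not enforce)
    membership in a user-supplied biology shortlist.
    """
    if multiprobe_rule not in ("strict", "lenient"):
        raise ValueError(f"unknown multiprobe_rule {multiprobe_rule!r}")
    records = list(records)
    all_series = sorted({r.series_id for r in records})
    if len(all_series) < 2:
        raise ValidationError("cascade needs records from >= 2 series")
    by_gene: dict[str, list[CorrelationRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_symbol, []).append(r)

    out: list[CascadeResult] = []
    for gene in sorted(by_gene):
        recs = by_gene[gene]
        per_series: dict[str, list[CorrelationRecord]] = {}
        for r in recs:
            per_series.setdefault(r.series_id, []).append(r)
        triggers = [
            s
            for s, rs in per_series.items()
            if any(r.p_value < alpha and r.rho < strong_rho for r in rs)
        ]
        if not triggers:
            continue
        support: set[str] = set()
        fired: list[str] = []
        for s in triggers:
            others = [t for t in all_series if t != s]
            replicated = all(
                any(
                    r.rho < 0 and r.p_value < alpha
                    for r in per_series.get(t, [])
                )
                for t in others
            )
            series_recs = per_series[s]
            probes = {r.probe_id for r in series_recs}
            if multiprobe_rule == "strict":
                passing_probes = {
                    r.probe_id
                    for r in series_recs
                    if r.rho < 0 and r.p_value < alpha
                }
                multiprobe = len(passing_probes) >= 2
            else:
                multiprobe = len(probes) >= 2 and any(
                    r.rho < 0 and r.p_value < alpha for r in series_recs
                )
            if replicated or multiprobe:
                fired.append(s)
                if replicated:
                    support.add("cross-series")
                if multiprobe:
                    support.add("multi-probe")
        if not fired:
            continue
        out.append(
            CascadeResult(
                gene_symbol=gene,
                trigger_series=sorted(fired),
                support=support,
                records=recs,
                passed_allowlist=(gene in allowlist) if allowlist is not None else True,
            )
        )
    return out


def cohort_screen(
    pairs: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    target_kind: str = "mRNA",
) -> tuple[list[CohortCorrelationSummary], float]:
    """Per-cohort Spearman screen of a (miRNA, target) pair.

    ``pairs`` maps cohort ID to (miRNA vector, target vector) — the target
    being an mRNA, a protein (RPPA) level, or a numeric signature score.
    Cohorts with fewer than 10 complete pairs are skipped with a warning.
    Returns the summaries and the fraction of screened cohorts with a
    significant negative correlation (rho < 0, p < 0.05).
    """
    if target_kind not in ("mRNA", "protein", "signature_score"):
        raise ValueError(f"unknown target_kind {target_kind!r}")
    out: list[CohortCorrelationSummary] = []
    for cohort_id in pairs:
        x, y = pairs[cohort_id]
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if int(ok.sum()) < MIN_PAIRWISE_N:
            logger.warning("cohort %s: n < %d, skipped", cohort_id, MIN_PAIRWISE_N)
            continue
        res = spearman(x[ok], y[ok], "two")
        out.append(
            CohortCorrelationSummary(
                cohort_id=cohort_id,
                n=res.n,
                rho=res.rho,
                p_value=res.p_value,
                neg_log10_p=-math.log10(max(res.p_value, _LOG10_FLOOR)),
            )
        )
    if not out:
        return out, float("nan")
    neg = sum(1 for s in out if s.rho < 0 and s.p_value < 0.05)
    return out, neg / len(out)


def sensitivity_signature_correlation(
    mirna_vector, signature_scores
) -> CorrelationResult:
    """Spearman (two-sided) of miRNA expression vs a drug-sensitivity
    signature score supplied as a precomputed numeric column."""
    return spearman(mirna_vector, signature_scores, "two")
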