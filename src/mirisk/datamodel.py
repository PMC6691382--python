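"""Typed containers shared by every stage of the pipeline.

The pipeline moves four kinds of objects between stages: log2 expression
matrices (miRNA or mRNA, one per sub-series), per-sample clinical records,
miRNA -> candidate-target catalogs (the union of validated-interaction
databases), and probe -> gene maps for multi-probe array platforms.  All of
them validate their invariants at construction time so downstream code can
assume well-formed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

FEATURE_KINDS = ("miRNA", "mRNA-probe", "mRNA-gene")
SERUM_GROUPS = ("H", "B", "Ms", "Mp")


class ValidationError(ValueError):
    """An input violates a structural invariant of the data model."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Log2 expression values, features x samples, for one sub-series.

    Missing values are explicit NaNs (never silent zeros); every consumer
    that correlates or tests works pairwise-complete on that mask.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    series_id: str
    feature_kind: str = "miRNA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.feature_ids, "feature ID")
        _check_unique(self.sample_ids, "sample ID")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"({len(self.feature_ids)} features, {len(self.sample_ids)} samples)"
            )
        if self.feature_kind not in FEATURE_KINDS:
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        self._feature_index = {f: i for i, f in enumerate(self.feature_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._feature_index

    def row(self, feature_id: str) -> np.ndarray:
        """Expression vector of one feature across samples (copy)."""
        try:
            i = self._feature_index[feature_id]
        except KeyError:
            raise KeyError(
                f"feature {feature_id!r} not in matrix for series {self.series_id!r}"
            ) from None
        return self.values[i].copy()

    def subset_features(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return ExpressionMatrix(
            values=self.values[idx],
            feature_ids=[self.feature_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            series_id=self.series_id,
            feature_kind=self.feature_kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.feature_ids, name="feature_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, series_id: str, feature_kind: str = "miRNA"
    ) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            feature_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            series_id=series_id,
            feature_kind=feature_kind,
        )


@dataclass
class SampleRecord:
    """One patient/sample: clinical outcome, genotype and series membership.

    ``sdhb_mutated`` is tri-state: True/False/None (unknown); unknown is never
    imputed, models requiring SDHB exclude it explicitly.  ``serum_group`` is
    "none" for tumor samples and one of H (healthy), B (non-metastatic
    patient), Ms (stable metastatic) or Mp (progressive metastatic) for serum
    panel samples.  Times are in days throughout.
    """

    sample_id: str
    series_id: str
    metastatic: bool
    sdhb_mutated: bool | None = None
    followup_days: int = 0
    event: bool = False
    serum_group: str = "none"
    metastatic_burden: float | None = None

    def __post_init__(self) -> None:
        self.followup_days = int(self.followup_days)
        if self.followup_days < 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: negative followup_days"
            )
        if self.event and self.followup_days <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: event=True requires followup_days > 0"
            )
        if self.serum_group not in SERUM_GROUPS + ("none",):
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown serum_group {self.serum_group!r}"
            )
        if self.serum_group == "H" and self.metastatic:
            raise ValidationError(
                f"sample {self.sample_id!r}: healthy controls cannot be metastatic"
            )
        if self.metastatic_burden is not None:
            self.metastatic_burden = float(self.metastatic_burden)
            if math.isnan(self.metastatic_burden):
                self.metastatic_burden = None
            elif self.metastatic_burden < 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: negative metastatic_burden"
                )


class SampleSheet:
    """Collection of :class:`SampleRecord` with unique sample IDs."""

    def __init__(self, records: Iterable[SampleRecord]):
        self.records: list[SampleRecord] = list(records)
        _check_unique([r.sample_id for r in self.records], "sample ID")
        self._by_id = {r.sample_id: r for r in self.records}

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        return SampleSheet(self._by_id[s] for s in sample_ids)

    @property
    def series_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.series_id not in out:
                out.append(r.series_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                dict(
                    sample_id=r.sample_id,
                    series_id=r.series_id,
                    metastatic=int(r.metastatic),
                    sdhb_mutated="" if r.sdhb_mutated is None else int(r.sdhb_mutated),
                    followup_days=r.followup_days,
                    event=int(r.event),
                    serum_group=r.serum_group,
                    metastatic_burden=(
                        "" if r.metastatic_burden is None else r.metastatic_burden
                    ),
                )
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CatalogEntry:
    mirna_id: str
    gene_symbol: str
    source_db: str


class TargetCatalog:
    """miRNA -> candidate target genes, as the union of interaction databases.

    Entries are unique on (miRNA, gene, source); the candidate set of a miRNA
    is the union over sources, deduplicated on gene symbol.
    """

    def __init__(self, entries: Iterable[CatalogEntry | tuple[str, str, str]]):
        norm = []
        for e in entries:
            if not isinstance(e, CatalogEntry):
                e = CatalogEntry(*e)
            norm.append(e)
        self.entries: frozenset[CatalogEntry] = frozenset(norm)

    def __len__(self) -> int:
        return len(self.entries)

    def __or__(self, other: "TargetCatalog") -> "TargetCatalog":
        return TargetCatalog(self.entries | other.entries)

    @property
    def mirna_ids(self) -> set[str]:
        return {e.mirna_id for e in self.entries}

    def genes_for(self, mirna_id: str) -> set[str]:
        """Deduplicated candidate gene set of one miRNA (union of sources)."""
        return {e.gene_symbol for e in self.entries if e.mirna_id == mirna_id}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (e.mirna_id, e.gene_symbol, e.source_db) for e in self.entries
        )
        return pd.DataFrame(rows, columns=["mirna_id", "gene_symbol", "source_db"])


class ProbeMap:
    """Probe -> gene symbol map; a probe maps to exactly one gene."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = {str(p): str(g) for p, g in mapping.items()}
        self._by_gene: dict[str, list[str]] = {}
        for p, g in self.mapping.items():
            self._by_gene.setdefault(g, []).append(p)

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "ProbeMap":
        """Gene-level platform: each feature is its own probe and gene."""
        return cls({i: i for i in ids})

    def gene(self, probe_id: str) -> str:
        return self.mapping[probe_id]

    def gene_or_none(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)

    def probes_of(self, gene_symbol: str) -> list[str]:
        return sorted(self._by_gene.get(gene_symbol, []))

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)
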