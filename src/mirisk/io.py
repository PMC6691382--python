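"""Readers/writers for the delimited tables and FASTA files the pipeline uses.

Formats:

* expression: TSV/CSV, header row = sample IDs, first column = feature IDs,
  blank or ``NA`` cells are missing values;
* sample sheet: TSV/CSV with the fixed clinical columns;
* target catalog: TSV/CSV with columns mirna_id, gene_symbol, source_db;
* 3'UTRs: plain FASTA (record id = gene symbol), U normalised to T.

The delimiter is auto-detected between tab and comma from the header line;
files mixing both are rejected rather than guessed at.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .datamodel import (
    CatalogEntry,
    ExpressionMatrix,
    ProbeMap,
    SampleRecord,
    SampleSheet,
    TargetCatalog,
    ValidationError,
)

logger = logging.getLogger(__name__)

NA_TOKENS = {"", "NA", "NaN", "nan", "na", "N/A", "null", "None"}

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "series_id",
    "metastatic",
    "sdhb_mutated",
    "followup_days",
    "event",
    "serum_group",
    "metastatic_burden",
]


def sniff_delimiter(path: str | Path) -> str:
    """Detect tab vs comma from the header line; mixed delimiters are an error."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                header = line.rstrip("\n")
                break
        else:
            raise ValidationError(f"{path}: empty file")
    has_tab = "\t" in header
    has_comma = "," in header
    if has_tab and has_comma:
        raise ValidationError(f"{path}: mixed tab/comma delimiters in header")
    if has_comma:
        return ","
    return "\t"


def _header_fields(path: str | Path, sep: str) -> list[str]:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.rstrip("\n").split(sep)
    raise ValidationError(f"{path}: empty file")


def read_expression(
    path: str | Path, series_id: str, feature_kind: str = "miRNA"
) -> ExpressionMatrix:
    """Parse a features x samples log2 expression table.

    Duplicate feature or sample IDs and non-numeric cells are hard errors
    naming the offender; blank/``NA`` cells become explicit missing values.
    """
    sep = sniff_delimiter(path)
    header = _header_fields(path, sep)
    sample_ids = [h.strip() for h in header[1:]]
    seen: set[str] = set()
    for s in sample_ids:
        if s in seen:
            raise ValidationError(f"{path}: duplicate sample column {s!r}")
        seen.add(s)

    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    feature_ids = [str(i).strip() for i in df.index]
    dup = pd.Index(feature_ids).duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate feature ID {feature_ids[int(np.argmax(dup))]!r}"
        )

    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy(dtype=object)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell in NA_TOKENS:
                values[i, j] = np.nan
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric cell {cell!r} at feature "
                    f"{feature_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None

    return ExpressionMatrix(
        values=values,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        series_id=series_id,
        feature_kind=feature_kind,
    )


def write_expression(matrix: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write a matrix so that a re-read reproduces finite values bit-identically."""
    df = matrix.to_frame()
    # repr-based float formatting round-trips doubles exactly
    df.to_csv(path, sep=sep, na_rep="NA")


def _parse_bool(cell: str, where: str) -> bool:
    c = cell.strip().lower()
    if c in {"1", "true", "t", "yes"}:
        return True
    if c in {"0", "false", "f", "no"}:
        return False
    raise ValidationError(f"{where}: cannot parse boolean from {cell!r}")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Parse the clinical sample sheet into typed records.

    Unknown SDHB status (blank/``NA``/``unknown``) is preserved as a third
    state; a blank metastatic_burden is missing, never zero.
    """
    sep = sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_SHEET_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        where = f"{path}: sample {sid!r}"
        sdhb_raw = str(row["sdhb_mutated"]).strip()
        if sdhb_raw in NA_TOKENS or sdhb_raw.lower() == "unknown":
            sdhb: bool | None = None
        else:
            sdhb = _parse_bool(sdhb_raw, where)
        burden_raw = str(row.get("metastatic_burden", "")).strip()
        burden = None if burden_raw in NA_TOKENS else float(burden_raw)
        serum_raw = str(row.get("serum_group", "none")).strip()
        records.append(
            SampleRecord(
                sample_id=sid,
                series_id=str(row["series_id"]).strip(),
                metastatic=_parse_bool(str(row["metastatic"]), where),
                sdhb_mutated=sdhb,
                followup_days=int(float(row["followup_days"])),
                event=_parse_bool(str(row["event"]), where),
                serum_group=serum_raw if serum_raw else "none",
                metastatic_burden=burden,
            )
        )
    return SampleSheet(records)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, sep: str = "\t") -> None:
    sheet.to_frame().to_csv(path, sep=sep, index=False)


def read_target_catalog(
    paths: Sequence[str | Path] | str | Path,
    mirna_ids: Iterable[str] | None = None,
) -> TargetCatalog:
    """Union one or more interaction-database exports into a catalog.

    Requested miRNAs absent from every file yield empty candidate sets with a
    logged warning (never an error: catalogs legitimately lack some miRNAs).
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    entries: list[CatalogEntry] = []
    for p in paths:
        sep = sniff_delimiter(p)
        df = pd.read_csv(p, sep=sep, dtype=str, keep_default_na=False)
        for col in ("mirna_id", "gene_symbol", "source_db"):
            if col not in df.columns:
                raise ValidationError(f"{p}: missing catalog column {col!r}")
        for _, row in df.iterrows():
            entries.append(
                CatalogEntry(
                    str(row["mirna_id"]).strip(),
                    str(row["gene_symbol"]).strip(),
                    str(row["source_db"]).strip(),
                )
            )
    cat = TargetCatalog(entries)
    if mirna_ids is not None:
        wanted = list(mirna_ids)
        for m in wanted:
            if m not in cat.mirna_ids:
                logger.warning("catalog has no entries for miRNA %r", m)
        cat = TargetCatalog(e for e in cat.entries if e.mirna_id in set(wanted))
    return cat


def write_target_catalog(catalog: TargetCatalog, path: str | Path, sep: str = "\t") -> None:
    catalog.to_frame().to_csv(path, sep=sep, index=False)


def read_probe_map(path: str | Path) -> ProbeMap:
    sep = sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("probe_id", "gene_symbol"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing probe-map column {col!r}")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        p = str(row["probe_id"]).strip()
        if p in mapping:
            raise ValidationError(f"{path}: probe {p!r} mapped more than once")
        mapping[p] = str(row["gene_symbol"]).strip()
    return ProbeMap(mapping)


def write_probe_map(pm: ProbeMap, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        sorted(pm.mapping.items()), columns=["probe_id", "gene_symbol"]
    )
    df.to_csv(path, sep=sep, index=False)


_UTR_ALPHABET = set("ACGTN")


def read_utr_fasta(path: str | Path) -> dict[str, str]:
    """Read 3'UTR sequences keyed by gene symbol; uppercased, U -> T."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate FASTA record {rec.id!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - _UTR_ALPHABET
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id!r} has invalid characters {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
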