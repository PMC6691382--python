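"""3'UTR seed-site scanner for miRNA binding sites.

Canonical site classes follow the TargetScan convention: a 6mer is a UTR
match to the reverse complement of miRNA positions 2-7; 7mer-m8 extends the
match to position 8 (on the 5' side of the UTR site, since the duplex is
antiparallel); 7mer-A1 adds an adenosine in the UTR opposite miRNA position
1 (the 3' end of the UTR site); 8mer has both.  A separate scan finds
imperfect 6mers — exactly one seed mismatch — rescued by a short exact match
to the miRNA's 3'-supplementary region (positions 13-16 by default) located
a few nucleotides 5' of the seed site on the UTR, the compensatory-site
geometry proposed for the TSC2/miR-21-3p interaction.

Coordinates are 0-based half-open on the UTR; scanning is case- and
U/T-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

SITE_TYPES = ("6mer", "7mer-m8", "7mer-A1", "8mer", "6mer-1mm-compensated")

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class SequenceError(ValueError):
    """A sequence contains characters outside the nucleotide alphabet."""


def normalize_seq(seq: str, allow_n: bool = False, what: str = "sequence") -> str:
    """Uppercase, U -> T, and validate the alphabet."""
    s = seq.upper().replace("U", "T")
    allowed = set("ACGTN") if allow_n else set("ACGT")
    bad = set(s) - allowed
    if bad:
        raise SequenceError(f"invalid characters {sorted(bad)} in {what}")
    return s


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


@dataclass
class SeedSite:
    gene_symbol: str
    site_type: str
    utr_start: int  # 0-based inclusive
    utr_end: int  # 0-based exclusive
    mismatch_offset: int | None = None  # position within the 6mer window
    compensatory_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        expected_len = {"6mer": 6, "7mer-m8": 7, "7mer-A1": 7, "8mer": 8,
                        "6mer-1mm-compensated": 6}[self.site_type]
        if self.utr_end - self.utr_start != expected_len:
            raise ValueError(
                f"{self.site_type} span must be {expected_len} nt, got "
                f"[{self.utr_start}, {self.utr_end})"
            )
        if self.site_type == "6mer-1mm-compensated":
            if self.mismatch_offset is None or not 0 <= self.mismatch_offset < 6:
                raise ValueError("compensated site needs mismatch_offset in [0, 6)")
            if self.compensatory_span is None:
                raise ValueError("compensated site needs a compensatory_span")


def find_seed_sites(
    mirna_seq: str,
    utr_seq: str,
    gene_symbol: str = "",
    maximal_only: bool = True,
) -> list[SeedSite]:
    """Scan a 3'UTR for canonical seed-match sites of one miRNA.

    By default each match location reports only its maximal class (an 8mer is
    not additionally listed as its nested 7mers/6mer); pass
    ``maximal_only=False`` for all applicable classes.  Overlapping sites at
    different locations are all reported, ordered by UTR position.
    """
    m = normalize_seq(mirna_seq, allow_n=False, what="miRNA")
    if len(m) < 8:
        raise SequenceError("miRNA must be at least 8 nt")
    u = normalize_seq(utr_seq, allow_n=True, what="3'UTR")
    seed6 = reverse_complement(m[1:7])  # miRNA positions 2-7
    m8_base = _COMPLEMENT[m[7]]  # UTR base pairing miRNA position 8

    sites: list[SeedSite] = []
    for i in range(0, len(u) - 5):
        if u[i : i + 6] != seed6:
            continue
        has_m8 = i >= 1 and u[i - 1] == m8_base
        has_a1 = i + 6 < len(u) and u[i + 6] == "A"
        if maximal_only:
            if has_m8 and has_a1:
                sites.append(SeedSite(gene_symbol, "8mer", i - 1, i + 7))
            elif has_m8:
                sites.append(SeedSite(gene_symbol, "7mer-m8", i - 1, i + 6))
            elif has_a1:
                sites.append(SeedSite(gene_symbol, "7mer-A1", i, i + 7))
            else:
                sites.append(SeedSite(gene_symbol, "6mer", i, i + 6))
        else:
            sites.append(SeedSite(gene_symbol, "6mer", i, i + 6))
            if has_m8:
                sites.append(SeedSite(gene_symbol, "7mer-m8", i - 1, i + 6))
            if has_a1:
                sites.append(SeedSite(gene_symbol, "7mer-A1", i, i + 7))
            if has_m8 and has_a1:
                sites.append(SeedSite(gene_symbol, "8mer", i - 1, i + 7))
    sites.sort(key=lambda s: (s.utr_start, s.utr_end, s.site_type))
    return sites


def find_compensated_6mer(
    mirna_seq: str,
    utr_seq: str,
    gene_symbol: str = "",
    max_gap: int = 8,
    comp_len: int = 4,
    supp_start: int = 12,
) -> list[SeedSite]:
    """Find single-mismatch 6mer seed sites rescued by 3'-supplementary pairing.

    A 6-nt UTR window matching the seed reverse complement at exactly 5 of 6
    positions qualifies when an exact ``comp_len``-nt match to the reverse
    complement of the miRNA's supplementary region (positions
    ``supp_start+1``..``supp_start+comp_len``, default 13-16) lies 5' of the
    window on the UTR — where the miRNA 3' arm reaches in the antiparallel
    duplex — separated by at most ``max_gap`` nt.  One site is reported per
    qualifying window, with the nearest patch recorded.
    """
    m = normalize_seq(mirna_seq, allow_n=False, what="miRNA")
    if len(m) < supp_start + comp_len:
        raise SequenceError(
            f"miRNA must span the supplementary region "
            f"(>= {supp_start + comp_len} nt)"
        )
    u = normalize_seq(utr_seq, allow_n=True, what="3'UTR")
    seed6 = reverse_complement(m[1:7])
    patch = reverse_complement(m[supp_start : supp_start + comp_len])

    sites: list[SeedSite] = []
    for i in range(0, len(u) - 5):
        window = u[i : i + 6]
        mism = [k for k in range(6) if window[k] != seed6[k]]
        if len(mism) != 1:
            continue
        # search patches 5' of the window, nearest first
        found = None
        for j in range(i - comp_len, i - comp_len - max_gap - 1, -1):
            if j < 0:
                break
            if u[j : j + comp_len] == patch:
                found = (j, j + comp_len)
                break
        if found is not None:
            sites.append(
                SeedSite(
                    gene_symbol,
                    "6mer-1mm-compensated",
                    i,
                    i + 6,
                    mismatch_offset=mism[0],
                    compensatory_span=found,
                )
            )
    return sites
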