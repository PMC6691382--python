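"""Circulating (serum / conditioned-media) miRNA panel statistics.

Samples belong to four groups: H (healthy controls), B (non-metastatic
patients), Ms (stable metastatic) and Mp (progressive metastatic).  The
analyses are one-sided rank-sum contrasts with the direction fixed a priori
(the more-diseased side hypothesised higher — never inferred from the data
under test), patient-vs-control ROC discrimination, and the correlation of a
miRNA's level with metastatic burden.

Undetected miRNAs are kept as zero levels and handled by the tie correction,
not dropped.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _spdist

from .datamodel import SERUM_GROUPS, SampleSheet, ValidationError
from .stats import (
    CorrelationResult,
    RocCurve,
    bh_fdr,
    rank_sum_test,
    roc_auc,
    spearman,
)

#: the five pre-specified directional contrasts: (name, hypothesised-greater
#: groups, lesser groups)
DEFAULT_CONTRASTS: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = [
    ("patients_vs_H", ("B", "Ms", "Mp"), ("H",)),
    ("B_vs_H", ("B",), ("H",)),
    ("metastatic_vs_B", ("Ms", "Mp"), ("B",)),
    ("Mp_vs_B", ("Mp",), ("B",)),
    ("Mp_vs_Ms", ("Mp",), ("Ms",)),
]


class SerumPanel:
    """Long-format serum panel: one level (copies/ul) per (sample, miRNA)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"sample_id", "group", "mirna_id", "level"}
        missing = required - set(frame.columns)
        if missing:
            raise ValidationError(f"serum panel missing columns {sorted(missing)}")
        frame = frame.copy()
        frame["level"] = frame["level"].astype(float)
        if (frame["level"] < 0).any():
            raise ValidationError("serum levels must be nonnegative")
        bad = set(frame["group"]) - set(SERUM_GROUPS)
        if bad:
            raise ValidationError(f"unknown serum groups {sorted(bad)}")
        if frame.duplicated(["sample_id", "mirna_id"]).any():
            dup = frame[frame.duplicated(["sample_id", "mirna_id"])].iloc[0]
            raise ValidationError(
                f"duplicate level for sample {dup['sample_id']!r}, "
                f"miRNA {dup['mirna_id']!r}"
            )
        self.frame = frame.reset_index(drop=True)

    @property
    def mirna_ids(self) -> list[str]:
        return sorted(self.frame["mirna_id"].unique())

    def levels(self, mirna_id: str, groups: Sequence[str]) -> np.ndarray:
        sub = self.frame[
            (self.frame["mirna_id"] == mirna_id)
            & self.frame["group"].isin(groups)
        ]
        return sub["level"].to_numpy(dtype=float)

    def sample_levels(self, mirna_id: str) -> pd.Series:
        sub = self.frame[self.frame["mirna_id"] == mirna_id]
        return sub.set_index("sample_id")["level"]


def group_comparisons(
    panel: SerumPanel,
    contrasts: Sequence[tuple[str, tuple[str, ...], tuple[str, ...]]] | None = None,
    adjust: bool = False,
) -> pd.DataFrame:
    """One-sided rank-sum tests for each (miRNA, contrast).

    The alternative is always "greater-side higher" as declared in the
    contrast.  P-values are unadjusted by default (pre-specified small panel);
    ``adjust=True`` adds a BH q-value column across all tests.
    """
    if contrasts is None:
        contrasts = DEFAULT_CONTRASTS
    rows = []
    for mirna in panel.mirna_ids:
        for name, greater, lesser in contrasts:
            a = panel.levels(mirna, greater)
            b = panel.levels(mirna, lesser)
            if a.size == 0 or b.size == 0:
                raise ValidationError(
                    f"contrast {name!r}: empty group for miRNA {mirna!r}"
                )
            u, p = rank_sum_test(a, b, "a_greater")
            rows.append(
                dict(mirna_id=mirna, contrast=name, n_greater=a.size,
                     n_lesser=b.size, U=u, p_value=p)
            )
    out = pd.DataFrame(rows)
    if adjust:
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    return out


def patient_control_auc(panel: SerumPanel, mirna_id: str) -> RocCurve:
    """ROC of one miRNA's serum level for patients ({B, Ms, Mp}) vs healthy."""
    sub = panel.frame[panel.frame["mirna_id"] == mirna_id]
    if sub.empty:
        raise ValidationError(f"no serum levels for miRNA {mirna_id!r}")
    labels = sub["group"].isin(["B", "Ms", "Mp"]).to_numpy()
    return roc_auc(sub["level"].to_numpy(dtype=float), labels)


def burden_correlation(
    panel: SerumPanel,
    sheet: SampleSheet,
    mirna_id: str,
    method: str = "spearman",
) -> CorrelationResult:
    """Correlate a miRNA's serum level with metastatic burden.

    Runs over metastatic patients with a recorded burden.  ``method`` is
    "spearman" (rank-based, default) or "pearson" — the appropriate reading
    of a plain "r" is cohort-dependent, so both are exposed.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    levels = panel.sample_levels(mirna_id)
    xs, ys = [], []
    for sid, level in levels.items():
        if sid not in sheet:
            continue
        rec = sheet[sid]
        if rec.metastatic and rec.metastatic_burden is not None:
            xs.append(float(level))
            ys.append(rec.metastatic_burden)
    if len(xs) < 3:
        raise ValidationError(
            f"need >= 3 metastatic samples with burden, got {len(xs)}"
        )
    if method == "spearman":
        return spearman(xs, ys, "two")
    r, p = _spdist.pearsonr(xs, ys)
    return CorrelationResult(rho=float(r), p_value=float(p), n=len(xs), sidedness="two")
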