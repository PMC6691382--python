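"""Synthetic multi-cohort generator for every input the pipeline consumes.

Emulates the structure the analyses assume: three sub-series of different
sizes and platforms (probe multiplicity differs per series), a metastatic
subgroup with shifted levels of a small planted miRNA signature, candidate
target genes rank-coupled to their miRNA through a Gaussian copula among
independent decoys, SDHB genotype driving metastasis odds, right-censored
time-to-progression with metachronous timing, and a serum panel with
group-ordered levels.

The planted truth travels in a separate :class:`SimTruth` object that no
analysis module consumes; identical configs produce identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize as _spopt
from scipy import stats as _spdist

from .circulating import SerumPanel
from .datamodel import (
    CatalogEntry,
    ExpressionMatrix,
    ProbeMap,
    SampleRecord,
    SampleSheet,
    TargetCatalog,
    ValidationError,
)
from .risk_model import DichotomizedDesign
from .survival import SurvivalCohort

# mature sequences (miRBase) of the two classifier miRNAs; used as seed-scan
# defaults for the synthetic UTRs
MIR21_3P_SEQ = "CAACACCAGUCGAUGGGCUGU"
MIR183_5P_SEQ = "UAUGGCACUGGUAGAAUUCACU"

SIGNATURE_MIRNAS = (
    "hsa-miR-21-3p",
    "hsa-miR-183-5p",
    "hsa-miR-182-5p",
    "hsa-miR-96-5p",
    "hsa-miR-551b-3p",
    "hsa-miR-202-5p",
)

CATALOG_SOURCES = ("miRTarBase", "TarBase", "OncomiRDB")


def _default_planted_prognostic() -> tuple[tuple[str, float], ...]:
    # five up-shifted signature members and one down-shifted, 1.2 log2 units
    return tuple(
        (m, -1.2 if m == "hsa-miR-202-5p" else 1.2) for m in SIGNATURE_MIRNAS
    )


def _default_planted_targets() -> tuple[tuple[str, str, float], ...]:
    out = []
    for i in range(10):
        out.append(("hsa-miR-21-3p", f"TG21_{i + 1:02d}", -0.5))
    for i in range(10):
        out.append(("hsa-miR-183-5p", f"TG183_{i + 1:02d}", -0.5))
    return tuple(out)


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohorts (all expression in log2)."""

    n_series: int = 3
    samples_per_series: tuple[int, ...] = (150, 100, 80)
    metastatic_fraction: float = 0.25
    n_mirnas: int = 200
    planted_prognostic: tuple[tuple[str, float], ...] = field(
        default_factory=_default_planted_prognostic
    )
    sdhb_fraction: float = 0.3
    sdhb_metastasis_or: float = 3.0
    n_genes: int = 320  # includes the planted targets
    planted_targets: tuple[tuple[str, str, float], ...] = field(
        default_factory=_default_planted_targets
    )
    decoy_candidates_per_mirna: int = 150
    probes_per_gene: tuple[tuple[int, float], ...] = ((1, 0.7), (2, 0.3))
    probe_noise_sd: float = 0.3
    noise_sd: float = 0.5  # miRNA residual sd
    gene_sd: float = 1.0
    series_offsets: tuple[float, ...] = (0.0, 0.9, -0.7)
    event_median_days: float = 1000.0
    sdhb_hazard_multiplier: float = 1.5
    censor_min_days: int = 400
    censor_horizon_days: int = 3650
    serum_group_sizes: tuple[tuple[str, int], ...] = (
        ("H", 10), ("B", 12), ("Ms", 7), ("Mp", 7)
    )
    serum_group_shifts: tuple[tuple[str, float], ...] = (
        ("H", 0.0), ("B", 1.5), ("Ms", 2.8), ("Mp", 4.4)
    )
    serum_sd: float = 0.8
    serum_base_log2: float = 3.0
    burden_rho: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.metastatic_fraction < 1.0:
            raise ValidationError("metastatic_fraction must lie in (0, 1)")
        if not 0.0 < self.sdhb_fraction < 1.0:
            raise ValidationError("sdhb_fraction must lie in (0, 1)")
        if len(self.samples_per_series) != self.n_series:
            raise ValidationError("samples_per_series must match n_series")
        if len(self.series_offsets) < self.n_series:
            raise ValidationError("need a series offset per series")
        for _, _, rho in self.planted_targets:
            if not -0.96 < rho < 0.0:
                raise ValidationError(
                    f"planted target rho must be in (-0.96, 0), got {rho}"
                )
        for _, shift in self.planted_prognostic:
            if abs(shift) > 20:
                raise ValidationError("implausible planted shift")
        probs = [p for _, p in self.probes_per_gene]
        if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
            raise ValidationError("probes_per_gene probabilities must sum to 1")
        planted_genes = [g for _, g, _ in self.planted_targets]
        if len(planted_genes) > self.n_genes:
            raise ValidationError("more planted targets than genes")


@dataclass
class SimTruth:
    """Planted ground truth; emitted beside the data, never consumed by the
    analysis modules."""

    planted_prognostic: dict[str, float]
    planted_targets: list[tuple[str, str, float]]
    serum_group_shifts: dict[str, float]
    latent_risk: dict[str, float]  # per tumor sample: metastasis probability


@dataclass
class SimResult:
    mirna: dict[str, ExpressionMatrix]
    mrna: dict[str, ExpressionMatrix]
    sheet: SampleSheet
    catalog: TargetCatalog
    probe_map: ProbeMap
    serum: SerumPanel
    truth: SimTruth


def spearman_to_pearson_latent(rho_s: float) -> float:
    """Latent Gaussian correlation giving population Spearman ``rho_s``
    (bivariate-normal rank identity r = 2 sin(pi * rho_s / 6))."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Map values to latent standard-normal scores through their ranks."""
    order = np.argsort(np.argsort(values, kind="mergesort"), kind="mergesort")
    u = (order + 0.5) / values.size
    return _spdist.norm.ppf(u)


def _solve_base_logit(target: float, frac_mut: float, log_or: float) -> float:
    """Intercept so that the marginal metastatic fraction matches target."""

    def f(l0: float) -> float:
        p0 = 1.0 / (1.0 + math.exp(-l0))
        p1 = 1.0 / (1.0 + math.exp(-(l0 + log_or)))
        return (1 - frac_mut) * p0 + frac_mut * p1 - target

    return float(_spopt.brentq(f, -30.0, 30.0))


def simulate_cohorts(config: SimConfig | None = None, seed: int | None = None) -> SimResult:
    """Generate the full multi-cohort input bundle from a config.

    ``seed`` overrides ``config.seed``; identical configurations produce
    byte-identical outputs.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    mirna_names = _mirna_names(config)
    gene_names = _gene_names(config)
    planted_shift = dict(config.planted_prognostic)
    targets_by_gene = {g: (m, r) for m, g, r in config.planted_targets}

    # per-feature baselines shared across series
    mirna_base = {m: 6.0 + rng.normal(0.0, 1.0) for m in mirna_names}
    gene_base = {g: 9.0 + rng.normal(0.0, 1.0) for g in gene_names}

    log_or = math.log(config.sdhb_metastasis_or)
    base_logit = _solve_base_logit(
        config.metastatic_fraction, config.sdhb_fraction, log_or
    )

    probe_counts = np.array([k for k, _ in config.probes_per_gene])
    probe_probs = np.array([p for _, p in config.probes_per_gene])

    records: list[SampleRecord] = []
    latent_risk: dict[str, float] = {}
    mirna_mats: dict[str, ExpressionMatrix] = {}
    mrna_mats: dict[str, ExpressionMatrix] = {}
    probe_map: dict[str, str] = {}

    for s_idx in range(config.n_series):
        series = f"S{s_idx + 1}"
        n = config.samples_per_series[s_idx]
        offset = config.series_offsets[s_idx]
        sample_ids = [f"{series}_{i + 1:03d}" for i in range(n)]

        sdhb = rng.random(n) < config.sdhb_fraction
        p_met = 1.0 / (1.0 + np.exp(-(base_logit + log_or * sdhb)))
        metastatic = rng.random(n) < p_met

        # miRNA matrix
        vals = np.empty((len(mirna_names), n))
        for i, m in enumerate(mirna_names):
            shift = planted_shift.get(m, 0.0)
            vals[i] = (
                mirna_base[m]
                + offset
                + shift * metastatic
                + rng.normal(0.0, config.noise_sd, n)
            )
        mirna_mats[series] = ExpressionMatrix(
            values=vals, feature_ids=list(mirna_names), sample_ids=sample_ids,
            series_id=series, feature_kind="miRNA",
        )

        # mRNA matrix: gene-level signal, then platform probes
        mirna_scores = {
            m: _normal_scores(mirna_mats[series].row(m))
            for m in {m for m, _ in targets_by_gene.values()}
        }
        probe_ids: list[str] = []
        probe_rows: list[np.ndarray] = []
        for g in gene_names:
            if g in targets_by_gene:
                m, rho_t = targets_by_gene[g]
                r = spearman_to_pearson_latent(rho_t)
                latent = r * mirna_scores[m] + math.sqrt(1 - r * r) * rng.normal(
                    0.0, 1.0, n
                )
            else:
                latent = rng.normal(0.0, 1.0, n)
            signal = gene_base[g] + offset + config.gene_sd * latent
            k = int(rng.choice(probe_counts, p=probe_probs))
            for j in range(k):
                pid = f"{g}:{series}:p{j + 1}"
                probe_ids.append(pid)
                probe_map[pid] = g
                probe_rows.append(
                    signal + rng.normal(0.0, config.probe_noise_sd, n)
                )
        mrna_mats[series] = ExpressionMatrix(
            values=np.vstack(probe_rows), feature_ids=probe_ids,
            sample_ids=sample_ids, series_id=series, feature_kind="mRNA-probe",
        )

        # clinical records with TTP
        base_rate = math.log(2.0) / config.event_median_days
        for i, sid in enumerate(sample_ids):
            latent_risk[sid] = float(p_met[i])
            if metastatic[i]:
                rate = base_rate * (
                    config.sdhb_hazard_multiplier if sdhb[i] else 1.0
                )
                t = max(1, int(round(rng.exponential(1.0 / rate))))
                records.append(
                    SampleRecord(
                        sample_id=sid, series_id=series, metastatic=True,
                        sdhb_mutated=bool(sdhb[i]), followup_days=t, event=True,
                    )
                )
            else:
                c = int(rng.integers(config.censor_min_days,
                                     config.censor_horizon_days + 1))
                records.append(
                    SampleRecord(
                        sample_id=sid, series_id=series, metastatic=False,
                        sdhb_mutated=bool(sdhb[i]), followup_days=c, event=False,
                    )
                )

    catalog = _build_catalog(config, gene_names, rng)
    serum_panel, serum_records = simulate_serum_panel(
        group_sizes=dict(config.serum_group_sizes),
        group_shifts=dict(config.serum_group_shifts),
        sd=config.serum_sd,
        base_log2=config.serum_base_log2,
        mirna_ids=[m for m, _ in config.planted_prognostic],
        burden_rho=config.burden_rho,
        rng=rng,
    )
    records.extend(serum_records)

    truth = SimTruth(
        planted_prognostic=dict(config.planted_prognostic),
        planted_targets=list(config.planted_targets),
        serum_group_shifts=dict(config.serum_group_shifts),
        latent_risk=latent_risk,
    )
    return SimResult(
        mirna=mirna_mats,
        mrna=mrna_mats,
        sheet=SampleSheet(records),
        catalog=catalog,
        probe_map=ProbeMap(probe_map),
        serum=serum_panel,
        truth=truth,
    )


def _mirna_names(config: SimConfig) -> list[str]:
    planted = [m for m, _ in config.planted_prognostic]
    decoys = [f"hsa-miR-dec-{i + 1:03d}" for i in range(config.n_mirnas - len(planted))]
    return planted + decoys


def _gene_names(config: SimConfig) -> list[str]:
    planted = [g for _, g, _ in config.planted_targets]
    decoys = [f"DEC{i + 1:03d}" for i in range(config.n_genes - len(planted))]
    return planted + decoys


def _build_catalog(
    config: SimConfig, gene_names: Sequence[str], rng: np.random.Generator
) -> TargetCatalog:
    """Candidate catalog: planted targets plus random decoy candidates, with
    database provenance and some entries duplicated across sources."""
    planted_by_mirna: dict[str, list[str]] = {}
    for m, g, _ in config.planted_targets:
        planted_by_mirna.setdefault(m, []).append(g)
    decoy_pool = [g for g in gene_names if not any(
        g in v for v in planted_by_mirna.values())]
    entries: list[CatalogEntry] = []
    for m in planted_by_mirna:
        genes = list(planted_by_mirna[m])
        k = min(config.decoy_candidates_per_mirna, len(decoy_pool))
        genes += list(rng.choice(decoy_pool, size=k, replace=False))
        for g in genes:
            src = CATALOG_SOURCES[int(rng.integers(0, len(CATALOG_SOURCES)))]
            entries.append(CatalogEntry(m, g, src))
            if rng.random() < 0.2:  # cross-database duplication
                other = CATALOG_SOURCES[int(rng.integers(0, len(CATALOG_SOURCES)))]
                entries.append(CatalogEntry(m, g, other))
    return TargetCatalog(entries)


def simulate_serum_panel(
    group_sizes: Mapping[str, int] | None = None,
    group_shifts: Mapping[str, float] | None = None,
    sd: float = 0.8,
    base_log2: float = 3.0,
    mirna_ids: Sequence[str] = SIGNATURE_MIRNAS,
    burden_rho: float = 0.5,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[SerumPanel, list[SampleRecord]]:
    """Serum panel with group-ordered log-normal levels (copies/ul).

    Metastatic samples get a metastatic-burden value rank-coupled (Gaussian
    copula) to their first-listed miRNA's level at Spearman ``burden_rho``.
    Returns the panel and the matching sample-sheet records.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    group_sizes = dict(group_sizes or {"H": 10, "B": 12, "Ms": 7, "Mp": 7})
    group_shifts = dict(
        group_shifts or {"H": 0.0, "B": 1.5, "Ms": 2.8, "Mp": 4.4}
    )
    rows = []
    records: list[SampleRecord] = []
    met_ids: list[str] = []
    for grp in group_sizes:
        for i in range(group_sizes[grp]):
            sid = f"SER_{grp}_{i + 1:02d}"
            metastatic = grp in ("Ms", "Mp")
            if metastatic:
                met_ids.append(sid)
            records.append(
                SampleRecord(
                    sample_id=sid, series_id="serum", metastatic=metastatic,
                    sdhb_mutated=None, followup_days=0, event=False,
                    serum_group=grp,
                )
            )
            for m in mirna_ids:
                level = 2.0 ** (base_log2 + group_shifts[grp] + rng.normal(0.0, sd))
                rows.append(dict(sample_id=sid, group=grp, mirna_id=m, level=level))
    panel = SerumPanel(
        pd.DataFrame(rows, columns=["sample_id", "group", "mirna_id", "level"])
    )
    # burden rank-coupled to the first miRNA's level among metastatic samples
    if met_ids and mirna_ids:
        levels = panel.sample_levels(mirna_ids[0]).loc[met_ids].to_numpy()
        r = spearman_to_pearson_latent(burden_rho)
        z = _normal_scores(levels)
        latent = r * z + math.sqrt(1 - r * r) * rng.normal(0.0, 1.0, len(met_ids))
        burden = np.exp(1.0 + 0.8 * latent)  # lesion-volume-like, arbitrary units
        by_id = dict(zip(met_ids, burden))
        records = [
            SampleRecord(
                sample_id=r_.sample_id, series_id=r_.series_id,
                metastatic=r_.metastatic, sdhb_mutated=r_.sdhb_mutated,
                followup_days=r_.followup_days, event=r_.event,
                serum_group=r_.serum_group,
                metastatic_burden=by_id.get(r_.sample_id),
            )
            for r_ in records
        ]
    return panel, records


def simulate_risk_cohort(
    n: int = 500,
    component_or: float = 3.0,
    baseline_p: float = 0.05,
    sdhb_fraction: float = 0.3,
    seed: int | None = None,
) -> DichotomizedDesign:
    """Single-series cohort with three binary risk components driving
    metastasis at a common per-component odds ratio.

    The two miRNA-high indicators are balanced (median-split-like), SDHB
    mutation has its own prevalence; the outcome follows a logistic model
    with ``log(component_or)`` per active component on a ``baseline_p``
    score-zero risk.
    """
    rng = np.random.default_rng(seed)
    mir21 = (rng.random(n) < 0.5).astype(int)
    mir183 = (rng.random(n) < 0.5).astype(int)
    sdhb = (rng.random(n) < sdhb_fraction).astype(int)
    score = mir21 + mir183 + sdhb
    logit0 = math.log(baseline_p / (1 - baseline_p))
    p = 1.0 / (1.0 + np.exp(-(logit0 + math.log(component_or) * score)))
    outcome = (rng.random(n) < p).astype(int)
    frame = pd.DataFrame(
        {
            "hsa-miR-21-3p_high": mir21,
            "hsa-miR-183-5p_high": mir183,
            "sdhb_mutated": sdhb,
            "outcome": outcome,
            "series_id": "R1",
        },
        index=pd.Index([f"R1_{i + 1:03d}" for i in range(n)], name="sample_id"),
    )
    return DichotomizedDesign(
        frame=frame,
        mirna_terms=["hsa-miR-21-3p_high", "hsa-miR-183-5p_high"],
        series_terms=[],
        sdhb_term="sdhb_mutated",
    )


def simulate_survival_cohort(
    n: int = 200,
    event_odds_ratio: float = 3.0,
    baseline_event_p: float = 0.3,
    event_median_days: float = 900.0,
    censor_min_days: int = 500,
    censor_horizon_days: int = 3650,
    seed: int | None = None,
    mirna_id: str = "hsa-miR-21-3p",
) -> tuple[ExpressionMatrix, SurvivalCohort]:
    """Cohort with a continuous expression marker whose above-median half has
    elevated event odds; returns the 1-feature matrix and the TTP cohort."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    high = x > np.median(x)
    logit0 = math.log(baseline_event_p / (1 - baseline_event_p))
    p = 1.0 / (1.0 + np.exp(-(logit0 + math.log(event_odds_ratio) * high)))
    event = rng.random(n) < p
    times = np.where(
        event,
        np.maximum(1, np.round(rng.exponential(
            event_median_days / math.log(2.0), n))),
        rng.integers(censor_min_days, censor_horizon_days + 1, n),
    ).astype(int)
    ids = [f"V{i + 1:03d}" for i in range(n)]
    expr = ExpressionMatrix(
        values=x[None, :], feature_ids=[mirna_id], sample_ids=ids,
        series_id="V", feature_kind="miRNA",
    )
    cohort = SurvivalCohort(sample_ids=ids, time_days=times, event=event)
    return expr, cohort


# ---------------------------------------------------------------------------
# worked toy
# ---------------------------------------------------------------------------


def worked_toy() -> tuple[SimResult, dict]:
    """Hand-auditable fixture: 12 tumor patients, 4 miRNAs, 10 genes, 2
    series, plus a 24-sample serum panel.

    All values are small integers chosen so each module's expected output can
    be derived by hand; the second return value freezes those expectations:

    * Kaplan-Meier on the assembled TTP cohort (P06 synchronous and P07
      short-follow-up excluded; 10 patients, events at days 365/500/800/
      1000/2500): survival 0.9, 0.7875, 0.65625, 0.525, 0.2625 by direct
      product-limit arithmetic.
    * Cascade: G01 is antitone to miR-21-3p on two probes in series T1 only
      (multi-probe support); G02 is antitone in both series (cross-series
      support); G03 is antitone in T1 on one probe only (trigger without
      support -> excluded); G06 is antitone to miR-183-5p in both series.
    * miR-SDHB score counts 4/2/3/3 for levels 0-3, with metastatic
      fractions 0, 0, 1, 1 by direct counting.
    * Serum levels are fully separated between patients and controls
      (patient-vs-healthy AUC = 1).
    """
    t1 = ["P01", "P02", "P03", "P04", "P05", "P06"]
    t2 = ["P07", "P08", "P09", "P10", "P11", "P12"]
    # metastatic: last three of each series
    mir21_t1 = [1.0, 2.0, 3.0, 5.0, 6.0, 7.0]
    mir183_t1 = [2.0, 1.0, 3.0, 6.0, 7.0, 5.0]
    mir21_t2 = [2.0, 1.0, 3.0, 6.0, 5.0, 7.0]
    mir183_t2 = [1.0, 3.0, 2.0, 5.0, 7.0, 6.0]
    # decoy miRNAs: a low-correlation rank pattern
    decoy = [3.0, 6.0, 1.0, 5.0, 2.0, 4.0]
    mirna_t1 = ExpressionMatrix(
        values=np.array([mir21_t1, mir183_t1, decoy, decoy[::-1]]),
        feature_ids=["hsa-miR-21-3p", "hsa-miR-183-5p", "hsa-miR-7-5p",
                     "hsa-miR-9-5p"],
        sample_ids=t1, series_id="T1", feature_kind="miRNA",
    )
    mirna_t2 = ExpressionMatrix(
        values=np.array([mir21_t2, mir183_t2, decoy[::-1], decoy]),
        feature_ids=["hsa-miR-21-3p", "hsa-miR-183-5p", "hsa-miR-7-5p",
                     "hsa-miR-9-5p"],
        sample_ids=t2, series_id="T2", feature_kind="miRNA",
    )

    def anti(v: Sequence[float]) -> list[float]:
        return [8.0 - x for x in v]

    noise = [5.0, 8.0, 3.0, 7.0, 4.0, 6.0]  # same rank pattern as `decoy`
    genes = [f"G{i + 1:02d}" for i in range(10)]
    # series T1 platform: two probes for G01, one for the others
    t1_probe_ids = ["G01:a", "G01:b"] + [g for g in genes[1:]]
    t1_rows = [
        anti(mir21_t1),            # G01:a  rho = -1 vs miR-21
        [x + 0.5 for x in anti(mir21_t1)],  # G01:b  rho = -1 vs miR-21
        anti(mir21_t1),            # G02    rho = -1 vs miR-21
        anti(mir21_t1),            # G03    rho = -1 vs miR-21 (T1 only)
        noise,                     # G04
        noise[::-1],               # G05
        anti(mir183_t1),           # G06    rho = -1 vs miR-183
        noise,                     # G07
        noise[::-1],               # G08
        noise,                     # G09 (not a candidate)
        noise[::-1],               # G10 (not a candidate)
    ]
    mrna_t1 = ExpressionMatrix(
        values=np.array(t1_rows), feature_ids=t1_probe_ids, sample_ids=t1,
        series_id="T1", feature_kind="mRNA-probe",
    )
    t2_rows = [
        noise,                     # G01: uncorrelated in T2
        anti(mir21_t2),            # G02: replicates in T2
        noise[::-1],               # G03: does not replicate
        noise,                     # G04
        noise[::-1],               # G05
        anti(mir183_t2),           # G06: replicates
        noise,                     # G07
        noise[::-1],               # G08
        noise,                     # G09
        noise[::-1],               # G10
    ]
    mrna_t2 = ExpressionMatrix(
        values=np.array(t2_rows), feature_ids=list(genes), sample_ids=t2,
        series_id="T2", feature_kind="mRNA-probe",
    )
    probe_map = ProbeMap(
        {"G01:a": "G01", "G01:b": "G01", **{g: g for g in genes}}
    )
    catalog = TargetCatalog(
        [("hsa-miR-21-3p", g, "miRTarBase") for g in genes[:5]]
        + [("hsa-miR-183-5p", g, "TarBase") for g in genes[5:8]]
    )

    sdhb = {"P03": True, "P04": True, "P05": True, "P09": True, "P10": True}
    clinical = {
        # sample: (metastatic, followup_days, event)
        "P01": (False, 400, False),
        "P02": (False, 2000, False),
        "P03": (False, 1290, False),
        "P04": (True, 500, True),
        "P05": (True, 800, True),
        "P06": (True, 200, True),    # synchronous -> excluded from TTP
        "P07": (False, 300, False),  # short follow-up -> excluded
        "P08": (False, 3000, False),
        "P09": (False, 1500, False),
        "P10": (True, 1000, True),
        "P11": (True, 365, True),    # metachronous boundary, included
        "P12": (True, 2500, True),
    }
    records = [
        SampleRecord(
            sample_id=sid, series_id="T1" if sid in t1 else "T2",
            metastatic=met, sdhb_mutated=sdhb.get(sid, False),
            followup_days=days, event=ev,
        )
        for sid, (met, days, ev) in clinical.items()
    ]

    serum_rows = []
    level = 1.0
    for grp, n_grp in (("H", 3), ("B", 3), ("Ms", 3), ("Mp", 3)):
        for i in range(n_grp):
            sid = f"SER_{grp}_{i + 1}"
            serum_rows.append(
                dict(sample_id=sid, group=grp, mirna_id="hsa-miR-21-3p",
                     level=level)
            )
            metastatic = grp in ("Ms", "Mp")
            records.append(
                SampleRecord(
                    sample_id=sid, series_id="serum", metastatic=metastatic,
                    sdhb_mutated=None, followup_days=0, event=False,
                    serum_group=grp,
                    metastatic_burden=level - 6.0 if metastatic else None,
                )
            )
            level += 1.0
    serum = SerumPanel(pd.DataFrame(serum_rows))

    result = SimResult(
        mirna={"T1": mirna_t1, "T2": mirna_t2},
        mrna={"T1": mrna_t1, "T2": mrna_t2},
        sheet=SampleSheet(records),
        catalog=catalog,
        probe_map=probe_map,
        serum=serum,
        truth=SimTruth(
            planted_prognostic={"hsa-miR-21-3p": 4.0, "hsa-miR-183-5p": 4.0},
            planted_targets=[
                ("hsa-miR-21-3p", "G01", -1.0),
                ("hsa-miR-21-3p", "G02", -1.0),
                ("hsa-miR-183-5p", "G06", -1.0),
            ],
            serum_group_shifts={"H": 0, "B": 3, "Ms": 6, "Mp": 9},
            latent_risk={},
        ),
    )
    expected = {
        "ttp_included": ["P01", "P02", "P03", "P04", "P05", "P08", "P09",
                          "P10", "P11", "P12"],
        "ttp_excluded": {"P06": "synchronous_metastasis",
                          "P07": "short_followup"},
        "km_times": [365.0, 500.0, 800.0, 1000.0, 2500.0],
        "km_survival": [0.9, 0.7875, 0.675, 0.5625, 0.28125],
        "km_at_risk": [10, 8, 7, 6, 2],
        "cascade_mir21": {"G01", "G02"},
        "cascade_mir183": {"G06"},
        "cascade_mir21_support": {"G01": {"multi-probe"},
                                   "G02": {"cross-series"}},
        "score_counts": {0: 4, 1: 2, 2: 3, 3: 3},
        "score_metastatic_fraction": {0: 0.0, 1: 0.0, 2: 1.0, 3: 1.0},
        "mir21_high": {"P04", "P05", "P06", "P10", "P11", "P12"},
        "serum_patient_auc": 1.0,
    }
    return result, expected
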