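"""Dichotomization, stepwise logistic selection and the miR-SDHB score."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mirisk.datamodel import ExpressionMatrix, SampleRecord, SampleSheet, ValidationError
from mirisk.risk_model import (
    DichotomizedDesign,
    build_design,
    conditional_logistic_fit,
    dichotomize,
    evaluate_classifier,
    logistic_fit,
    mir_sdhb_score,
    stepwise_logistic,
    stratify_by_score,
)
from mirisk.simulate import simulate_risk_cohort
from mirisk.stats import roc_auc


def _expr(series, ids, values_by_mirna):
    names = list(values_by_mirna)
    vals = np.array([values_by_mirna[m] for m in names], dtype=float)
    return ExpressionMatrix(vals, names, ids, series)


class TestDichotomize:
    def test_median_split_small_example(self):
        e = _expr("S1", ["a", "b", "c", "d"], {"m": [1, 2, 3, 4]})
        ind = dichotomize([e], ["m"])
        assert list(ind["m_high"]) == [0, 0, 1, 1]

    def test_odd_n_distinct_values_floor_half_high(self, rng):
        n = 9
        e = _expr("S1", [f"s{i}" for i in range(n)],
                  {"m": rng.permutation(np.arange(n, dtype=float))})
        ind = dichotomize([e], ["m"])
        assert ind["m_high"].sum() == n // 2

    def test_per_series_split_differs_from_pooled(self):
        # same pooled values, but series medians differ: batch-aware split
        e1 = _expr("S1", ["a", "b", "c", "d"], {"m": [1, 2, 3, 4]})
        e2 = _expr("S2", ["e", "f", "g", "h"], {"m": [5, 6, 7, 8]})
        ind = dichotomize([e1, e2], ["m"])
        per_series = ind["m_high"].to_numpy()
        pooled = (np.array([1, 2, 3, 4, 5, 6, 7, 8]) > 4.5).astype(int)
        assert list(per_series) == [0, 0, 1, 1, 0, 0, 1, 1]
        assert list(per_series) != list(pooled)

    def test_invariant_under_increasing_transform(self, rng):
        vals = rng.normal(size=12)
        e1 = _expr("S1", [f"s{i}" for i in range(12)], {"m": vals})
        e2 = _expr("S1", [f"s{i}" for i in range(12)], {"m": np.exp(vals)})
        assert dichotomize([e1], ["m"])["m_high"].equals(
            dichotomize([e2], ["m"])["m_high"]
        )

    def test_constant_mirna_rejected(self):
        e = _expr("S1", ["a", "b", "c"], {"m": [2, 2, 2]})
        with pytest.raises(ValidationError):
            dichotomize([e], ["m"])


class TestLogisticFit:
    def test_matches_statsmodels_mle(self, rng):
        import statsmodels.api as sm

        X = np.column_stack([np.ones(200), rng.normal(size=(200, 3))])
        eta = X @ np.array([-0.5, 1.0, -0.7, 0.3])
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = logistic_fit(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit.converged
        assert np.allclose(fit.coefficients, ref.params, atol=1e-6)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-8)

    def test_perfect_separation_flagged_and_ridge_rescues(self):
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = logistic_fit(X, y)
        assert not fit.converged
        assert np.all(np.isfinite(fit.coefficients))
        ridge = logistic_fit(X, y, ridge=1.0)
        assert ridge.converged

    def test_conditional_fit_matches_statsmodels(self, rng):
        from statsmodels.discrete.conditional_models import ConditionalLogit

        n = 120
        strata = np.repeat([0, 1, 2], n // 3)
        x = rng.normal(size=(n, 2))
        eta = x @ np.array([0.8, -0.5]) + 0.5 * strata  # stratum effects
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = conditional_logistic_fit(x, y, strata)
        ref = ConditionalLogit(y, x, groups=strata).fit(disp=0)
        assert np.allclose(fit.coefficients, ref.params, atol=1e-4)


class TestStepwise:
    CANDS = ["hsa-miR-21-3p_high", "hsa-miR-183-5p_high"]

    def test_forced_terms_always_retained(self, rng):
        d = simulate_risk_cohort(n=300, component_or=1.0, seed=5)
        fit = stepwise_logistic(d, self.CANDS, forced_terms=["sdhb_mutated"])
        assert "sdhb_mutated" in fit.selected_terms

    def test_strong_effect_selected_in_most_replicates(self):
        hits = 0
        for i in range(100):
            d = simulate_risk_cohort(n=400, component_or=6.0, seed=4000 + i)
            fit = stepwise_logistic(d, ["hsa-miR-21-3p_high"],
                                    forced_terms=["sdhb_mutated"])
            hits += "hsa-miR-21-3p_high" in fit.selected_terms
        assert hits >= 95

    def test_null_selection_rate_matches_permuted_outcome(self, rng):
        # pure-noise candidates: the familywise rate of selecting >= 1 term
        # should match a permuted-outcome replicate within binomial noise
        def run(shuffle, seed):
            r = np.random.default_rng(seed)
            n = 200
            frame = pd.DataFrame(
                {f"noise{k}": (r.random(n) < 0.5).astype(int) for k in range(10)}
            )
            frame["outcome"] = (r.random(n) < 0.3).astype(int)
            if shuffle:
                frame["outcome"] = r.permutation(frame["outcome"].to_numpy())
            frame["series_id"] = "S1"
            frame.index = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
            d = DichotomizedDesign(frame=frame, mirna_terms=[f"noise{k}" for k in range(10)],
                                   series_terms=[], sdhb_term=None)
            fit = stepwise_logistic(d, d.mirna_terms)
            return int(len(fit.selected_terms) > 0)

        n_rep = 120
        rate_null = np.mean([run(False, 6000 + i) for i in range(n_rep)])
        rate_perm = np.mean([run(True, 7000 + i) for i in range(n_rep)])
        se = np.sqrt(2 * 0.4 * 0.6 / n_rep)  # generous bound on diff SE
        assert abs(rate_null - rate_perm) < 3 * se

    def test_single_class_outcome_rejected(self):
        d = simulate_risk_cohort(n=50, seed=1)
        d.frame["outcome"] = 0
        with pytest.raises(ValidationError):
            stepwise_logistic(d, self.CANDS)

    def test_conditional_mode_drops_series_terms(self):
        d = simulate_risk_cohort(n=200, component_or=4.0, seed=11)
        fit = stepwise_logistic(d, self.CANDS, forced_terms=["sdhb_mutated"],
                                mode="conditional")
        assert fit.probabilities is None
        assert fit.mode == "conditional"
        assert "sdhb_mutated" in fit.selected_terms


class TestMirSdhbScore:
    def test_exhaustive_component_enumeration(self):
        rows = []
        ids = []
        for i, combo in enumerate(itertools.product([0, 1], repeat=3)):
            ids.append(f"s{i}")
            rows.append(dict(zip(
                ["hsa-miR-21-3p_high", "hsa-miR-183-5p_high", "sdhb_mutated"],
                combo)))
        frame = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
        frame["outcome"] = 0
        frame["series_id"] = "S1"
        d = DichotomizedDesign(frame=frame,
                               mirna_terms=["hsa-miR-21-3p_high",
                                            "hsa-miR-183-5p_high"],
                               series_terms=[], sdhb_term="sdhb_mutated")
        scores = mir_sdhb_score(d)
        for s, combo in zip(scores, itertools.product([0, 1], repeat=3)):
            assert s.score == sum(combo)
            assert s.components == combo

    def test_score_extremes_match_definitions(self, toy):
        result, expected = toy
        ind = dichotomize(
            [result.mirna["T1"], result.mirna["T2"]],
            ["hsa-miR-21-3p", "hsa-miR-183-5p"],
        )
        design = build_design(ind, result.sheet)
        scores = mir_sdhb_score(design)
        counts = {k: sum(1 for s in scores if s.score == k) for k in range(4)}
        assert counts == expected["score_counts"]

    def test_unknown_sdhb_excluded_from_design(self):
        ids = ["a", "b", "c", "d"]
        e = _expr("S1", ids, {"hsa-miR-21-3p": [1, 2, 3, 4],
                              "hsa-miR-183-5p": [4, 3, 2, 1]})
        sheet = SampleSheet([
            SampleRecord("a", "S1", False, sdhb_mutated=None),
            SampleRecord("b", "S1", False, sdhb_mutated=True),
            SampleRecord("c", "S1", True, sdhb_mutated=False),
            SampleRecord("d", "S1", True, sdhb_mutated=True),
        ])
        design = build_design(dichotomize([e], ["hsa-miR-21-3p",
                                                "hsa-miR-183-5p"]), sheet)
        assert list(design.frame.index) == ["b", "c", "d"]


class TestStratifyAndRoc:
    def test_hand_counting_oracle(self, toy):
        result, expected = toy
        ind = dichotomize(
            [result.mirna["T1"], result.mirna["T2"]],
            ["hsa-miR-21-3p", "hsa-miR-183-5p"],
        )
        design = build_design(ind, result.sheet)
        scores = mir_sdhb_score(design)
        table = stratify_by_score(scores, result.sheet)
        for k, frac in expected["score_metastatic_fraction"].items():
            assert table.loc[k, "fraction"] == pytest.approx(frac)
            assert (table.loc[k, "ci_low"] <= frac <= table.loc[k, "ci_high"])

    def test_empty_level_reported_missing(self):
        d = simulate_risk_cohort(n=40, seed=3)
        scores = mir_sdhb_score(d)
        scores = [s for s in scores if s.score != 3]
        sheet = SampleSheet([
            SampleRecord(s.sample_id, "R1",
                         bool(d.frame.at[s.sample_id, "outcome"]))
            for s in scores
        ])
        table = stratify_by_score(scores, sheet)
        assert np.isnan(table.loc[3, "fraction"]) and table.loc[3, "n"] == 0

    def test_perfectly_ordered_score_auc_one(self):
        d = simulate_risk_cohort(n=60, seed=9)
        scores = mir_sdhb_score(d)
        outcome = np.array([s.score >= 2 for s in scores])
        assert evaluate_classifier(scores, outcome).auc == 1.0

    def test_integer_score_roc_equals_pair_counting(self, rng):
        scores_int = rng.integers(0, 4, size=12)
        outcome = rng.random(12) < 0.5
        if outcome.all() or not outcome.any():
            outcome[0] = ~outcome[0]
        curve = roc_auc(scores_int.astype(float), outcome)
        pos = scores_int[outcome]
        neg = scores_int[~outcome]
        expect = np.mean([
            1.0 if p > q else (0.5 if p == q else 0.0)
            for p in pos for q in neg
        ])
        assert curve.auc == pytest.approx(expect, abs=1e-12)

    def test_nested_model_auc_ordering(self):
        for i in range(20):
            d = simulate_risk_cohort(n=400, seed=8000 + i)
            full = stepwise_logistic(
                d, ["hsa-miR-21-3p_high", "hsa-miR-183-5p_high"],
                forced_terms=["sdhb_mutated"],
            )
            sdhb_only = stepwise_logistic(d, [], forced_terms=["sdhb_mutated"])
            a_full = evaluate_classifier(full, d.outcome).auc
            a_sdhb = evaluate_classifier(sdhb_only, d.outcome).auc
            assert a_full >= a_sdhb
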