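import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from siltriage import reference
from siltriage.diagnostics import (
    AucEstimate,
    ConfusionCounts,
    Stratum,
    StratumTable,
    accuracy_report,
    auc_ci,
    chi_square_2x2,
    compare_auc,
    dichotomize,
    empirical_auc,
    expected_vs_found,
    odds_ratio_2x2,
    prevalence_adjusted_pv,
    sens_spec,
    stratum_mortality,
    youden_cutoff,
)
from siltriage.errors import InvalidInputError, UndefinedValueError

from conftest import brute_force_auc, random_cohort

#: AUC of the published stratum table, frozen from the brute-force pair
#: oracle: (9463 concordant + 2652/2 tied) / (61 * 238).
STUDY_AUC = 10789 / 14518


class TestDichotomize:
    def test_perfect_separation(self):
        c = dichotomize([0, 6], [0, 1], cutoff=3)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 1)

    def test_all_below_cutoff(self):
        c = dichotomize([0, 1, 2], [1, 0, 0], cutoff=5)
        assert c.tp == 0 and c.fp == 0
        assert c.fn == 1 and c.tn == 2

    def test_study_fixture_at_cutoff_3(self, study_records):
        scores, outcomes = study_records
        c = dichotomize(scores, outcomes, cutoff=3)
        assert (c.tp, c.fp, c.fn, c.tn) == (29, 27, 32, 211)

    def test_counts_partition_cohort(self, study_records):
        scores, outcomes = study_records
        for cutoff in range(8):
            c = dichotomize(scores, outcomes, cutoff)
            assert c.n == len(scores)
            assert c.deaths == outcomes.sum()

    def test_roc_endpoints(self, study_records):
        scores, outcomes = study_records
        lo = dichotomize(scores, outcomes, -np.inf)
        assert lo.fn == 0 and lo.tn == 0  # sensitivity 1, specificity 0
        hi = dichotomize(scores, outcomes, np.inf)
        assert hi.tp == 0 and hi.fp == 0  # sensitivity 0, specificity 1

    def test_errors(self):
        with pytest.raises(InvalidInputError):
            dichotomize([], [], 1)
        with pytest.raises(InvalidInputError):
            dichotomize([1, 2], [1], 1)


class TestSensSpec:
    def test_perfect(self):
        sens, _, spec, _ = sens_spec(ConfusionCounts(1, 0, 0, 1))
        assert sens == 1.0 and spec == 1.0

    def test_study_counts(self):
        sens, sens_ci, spec, spec_ci = sens_spec(ConfusionCounts(29, 27, 32, 211))
        assert sens == pytest.approx(29 / 61, abs=1e-12)
        assert spec == pytest.approx(211 / 238, abs=1e-12)
        assert round(sens, 3) == 0.475
        assert round(spec, 3) == 0.887
        assert sens_ci[0] <= sens <= sens_ci[1]
        assert spec_ci[0] <= spec <= spec_ci[1]

    def test_degenerate(self):
        sens, _, spec, _ = sens_spec(ConfusionCounts(0, 0, 5, 5))
        assert sens == 0.0 and spec == 1.0

    def test_wald_ci_clipped(self):
        _, sens_ci, _, spec_ci = sens_spec(ConfusionCounts(10, 0, 0, 10))
        assert sens_ci == (1.0, 1.0)
        assert spec_ci == (1.0, 1.0)

    def test_wilson_available(self):
        sens, ci, _, _ = sens_spec(ConfusionCounts(10, 0, 0, 10), ci_method="wilson")
        assert ci[0] < 1.0 <= ci[1]

    def test_zero_denominator(self):
        with pytest.raises(UndefinedValueError):
            sens_spec(ConfusionCounts(0, 5, 0, 5))


class TestPrevalenceAdjustedPV:
    def test_perfect(self):
        assert prevalence_adjusted_pv(1.0, 1.0, 0.5) == (1.0, 1.0)

    def test_published_sil_row(self):
        ppv, npv = prevalence_adjusted_pv(0.694, 0.678, 61 / 299)
        assert ppv == pytest.approx(0.356, abs=0.001)
        assert npv == pytest.approx(0.896, abs=0.001)

    def test_published_news_row(self):
        ppv, npv = prevalence_adjusted_pv(0.628, 0.595, 61 / 299)
        assert ppv == pytest.approx(0.284, abs=0.001)
        assert npv == pytest.approx(0.862, abs=0.001)

    def test_undefined_denominator(self):
        with pytest.raises(UndefinedValueError):
            prevalence_adjusted_pv(0.0, 1.0, 1.0)

    @given(st.data())
    def test_reduces_to_raw_count_formula_at_sample_prevalence(self, data):
        tp = data.draw(st.integers(1, 30))
        fp = data.draw(st.integers(1, 30))
        fn = data.draw(st.integers(1, 30))
        tn = data.draw(st.integers(1, 30))
        c = ConfusionCounts(tp, fp, fn, tn)
        sens, _, spec, _ = sens_spec(c)
        ppv, npv = prevalence_adjusted_pv(sens, spec, c.deaths / c.n)
        assert ppv == pytest.approx(tp / (tp + fp), abs=1e-12)
        assert npv == pytest.approx(tn / (tn + fn), abs=1e-12)


class TestEmpiricalAuc:
    def test_perfect_separation(self):
        t = StratumTable([Stratum(0, 10, 0), Stratum(1, 5, 5)])
        assert empirical_auc(t) == 1.0

    def test_single_stratum_pure_ties(self):
        t = StratumTable([Stratum(2, 10, 4)])
        assert empirical_auc(t) == 0.5

    def test_study_fixture(self, study_strata):
        assert empirical_auc(study_strata) == pytest.approx(STUDY_AUC, abs=1e-12)
        assert round(empirical_auc(study_strata), 4) == 0.7431

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            scores, outcomes = random_cohort(rng)
            assert empirical_auc(scores, outcomes) == pytest.approx(
                brute_force_auc(scores, outcomes), abs=1e-12
            )

    def test_label_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            scores, outcomes = random_cohort(rng)
            assert empirical_auc(-scores, outcomes) == pytest.approx(
                1 - empirical_auc(scores, outcomes), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            scores, outcomes = random_cohort(rng)
            transformed = np.exp(scores) + 3
            assert empirical_auc(transformed, outcomes) == pytest.approx(
                empirical_auc(scores, outcomes), abs=1e-12
            )

    def test_all_one_class(self):
        with pytest.raises(UndefinedValueError):
            empirical_auc([1, 2, 3], [1, 1, 1])


class TestAucCi:
    def test_delong_perfect_separation_clipped(self):
        est = auc_ci([0, 0, 1, 1], [0, 0, 1, 1], method="delong")
        assert est.auc == 1.0
        assert est.ci_high == 1.0
        assert 0.0 <= est.ci_low <= 1.0

    def test_constant_score(self):
        est = auc_ci([2, 2, 2, 2], [0, 1, 0, 1], method="delong")
        assert est.auc == 0.5

    def test_delong_ci_brackets_point(self, study_records):
        est = auc_ci(*study_records, method="delong")
        assert est.ci_low <= est.auc <= est.ci_high
        assert est.ci_high - est.ci_low < 0.2

    def test_bootstrap_seeded_and_reproducible(self, study_records):
        scores, outcomes = study_records
        a = auc_ci(scores, outcomes, method="bootstrap", reps=200, seed=5)
        b = auc_ci(scores, outcomes, method="bootstrap", reps=200, seed=5)
        assert a == b
        assert a.ci_low <= a.auc <= a.ci_high

    def test_large_synthetic_cohort_ci_contains_generator_auc(self):
        rng = np.random.default_rng(11)
        probs = np.array([n for _, n, _, _ in reference.SIL_STRATA], float)
        probs /= probs.sum()
        mort = np.array([d / n for _, n, d, _ in reference.SIL_STRATA])
        strata = rng.choice(7, size=4000, p=probs)
        outcomes = (rng.random(4000) < mort[strata]).astype(int)
        est = auc_ci(strata.astype(float), outcomes, method="delong")
        assert est.ci_low <= STUDY_AUC <= est.ci_high

    def test_bad_method(self, study_records):
        with pytest.raises(InvalidInputError):
            auc_ci(*study_records, method="jackknife")


class TestCompareAuc:
    def test_identical_scores(self, study_records):
        scores, outcomes = study_records
        assert compare_auc(scores, scores, outcomes) == 1.0

    def test_extreme_separation(self):
        rng = np.random.default_rng(3)
        outcomes = rng.integers(0, 2, size=400)
        perfect = outcomes.astype(float)
        noise = np.full(400, 1.0)
        noise[:200] += 1e-9  # not constant, but uninformative
        assert compare_auc(perfect, noise, outcomes) < 0.001

    def test_null_p_values_roughly_uniform(self):
        # two independent noisy copies of one latent score under H0
        rng = np.random.default_rng(19)
        pvals = []
        for _ in range(200):
            latent = rng.normal(size=300)
            outcomes = (rng.random(300) < 1 / (1 + np.exp(-latent))).astype(int)
            if outcomes.min() == outcomes.max():
                continue
            a = latent + rng.normal(0, 1, 300)
            b = latent + rng.normal(0, 1, 300)
            pvals.append(compare_auc(a, b, outcomes))
        pvals = np.asarray(pvals)
        # coarse uniformity: mean near 0.5, rejection rate near nominal
        assert abs(pvals.mean() - 0.5) < 0.08
        assert abs((pvals < 0.05).mean() - 0.05) < 0.05


class TestOddsRatio:
    def test_symmetric_table(self):
        r = odds_ratio_2x2(1, 1, 1, 1)
        assert r.odds_ratio == pytest.approx(1.0)

    def test_renal_insufficiency_row(self):
        r = odds_ratio_2x2(14, 16, 47, 222)
        assert r.odds_ratio == pytest.approx(4.13, abs=0.01)
        assert r.ci_low == pytest.approx(1.87, abs=0.05)
        assert r.ci_high == pytest.approx(9.13, abs=0.15)

    def test_septic_shock_row(self):
        r = odds_ratio_2x2(42, 64, 19, 174)
        assert r.odds_ratio == pytest.approx(6.01, abs=0.01)

    def test_haldane_correction_on_zero_cell(self):
        r = odds_ratio_2x2(5, 0, 3, 7)
        assert math.isfinite(r.odds_ratio)
        assert r.ci_low <= r.odds_ratio <= r.ci_high

    def test_zero_margin_rejected(self):
        with pytest.raises(UndefinedValueError):
            odds_ratio_2x2(0, 0, 3, 7)

    @given(
        a=st.integers(1, 50), b=st.integers(1, 50),
        c=st.integers(1, 50), d=st.integers(1, 50),
    )
    def test_invariance_properties(self, a, b, c, d):
        base = odds_ratio_2x2(a, b, c, d)
        # swapping both rows and both columns leaves the OR unchanged
        flipped = odds_ratio_2x2(d, c, b, a)
        assert flipped.odds_ratio == pytest.approx(base.odds_ratio, rel=1e-9)
        # swapping exposure labels reciprocates it
        swapped = odds_ratio_2x2(c, d, a, b)
        assert swapped.odds_ratio == pytest.approx(1 / base.odds_ratio, rel=1e-9)


class TestChiSquare:
    def test_balanced_table(self):
        assert chi_square_2x2(10, 10, 10, 10) == pytest.approx(1.0)

    def test_septic_shock_row(self):
        assert chi_square_2x2(42, 64, 19, 174) < 0.001

    def test_correction_is_conservative(self):
        p_corrected = chi_square_2x2(8, 4, 3, 9)
        p_raw = chi_square_2x2(8, 4, 3, 9, correction=False)
        assert p_corrected >= p_raw

    def test_zero_margin(self):
        with pytest.raises(UndefinedValueError):
            chi_square_2x2(0, 0, 5, 5)


class TestStratumMortality:
    def test_study_values(self, study_strata):
        mort = stratum_mortality(study_strata)
        assert mort["per_stratum"][3] == pytest.approx(47.2, abs=0.05)
        assert mort["per_stratum"][6] == pytest.approx(100.0)
        assert mort["overall"] == pytest.approx(20.4, abs=0.05)

    def test_subgroups(self, study_strata):
        mort = stratum_mortality(
            study_strata,
            subgroups={
                "sepsis_only": (reference.SEPSIS_ONLY_DEATHS, reference.SEPSIS_ONLY_N),
                "septic_shock": (reference.SEPTIC_SHOCK_DEATHS, reference.SEPTIC_SHOCK_N),
            },
        )
        assert mort["sepsis_only"] == pytest.approx(9.8, abs=0.05)
        assert mort["septic_shock"] == pytest.approx(39.6, abs=0.05)

    def test_all_zero_deaths(self):
        t = StratumTable([Stratum(v, 10, 0) for v in range(3)])
        mort = stratum_mortality(t)
        assert all(v == 0 for v in mort["per_stratum"].values())
        assert mort["overall"] == 0

    def test_empty_table_rejected(self):
        with pytest.raises(InvalidInputError):
            stratum_mortality(StratumTable([]))


class TestExpectedVsFound:
    def test_reproduces_found_column(self, study_strata):
        frame = expected_vs_found(study_strata)
        found = dict(zip(frame["score_value"], frame["found_pct"].round(1)))
        assert found == {0: 6.9, 1: 14.4, 2: 21.2, 3: 47.2, 4: 53.3, 5: 50.0, 6: 100.0}

    def test_zero_difference_when_equal(self):
        t = StratumTable([Stratum(0, 10, 5, expected_mortality=50.0)])
        frame = expected_vs_found(t)
        assert frame["difference_pct"].iloc[0] == pytest.approx(0.0)

    def test_tiny_stratum_has_wide_ci(self):
        t = StratumTable([Stratum(5, 2, 1, expected_mortality=85.4)])
        frame = expected_vs_found(t)
        width = frame["found_ci_high_pct"].iloc[0] - frame["found_ci_low_pct"].iloc[0]
        assert width >= 50.0

    def test_missing_expected_rejected(self):
        t = StratumTable([Stratum(0, 10, 5)])
        with pytest.raises(InvalidInputError):
            expected_vs_found(t)


class TestAccuracyReport:
    def test_youden_default_cutoff(self, study_records):
        scores, outcomes = study_records
        rep = accuracy_report(scores, outcomes)
        assert rep.cutoff == youden_cutoff(scores, outcomes)
        assert 0 <= rep.sensitivity <= 1 and 0 <= rep.specificity <= 1
        assert rep.prevalence == pytest.approx(61 / 299)

    def test_explicit_cutoff_and_prevalence(self, study_records):
        scores, outcomes = study_records
        rep = accuracy_report(scores, outcomes, cutoff=3, prevalence=0.18)
        assert rep.counts.tp == 29
        ppv, npv = prevalence_adjusted_pv(rep.sensitivity, rep.specificity, 0.18)
        assert rep.ppv == ppv and rep.npv == npv


class TestStratumTableType:
    def test_expand_round_trips(self, study_strata):
        scores, outcomes = study_strata.expand()
        rebuilt = StratumTable.from_records(scores, outcomes)
        assert [(s.score_value, s.n_total, s.n_deaths) for s in rebuilt] == [
            (s.score_value, s.n_total, s.n_deaths) for s in study_strata
        ]

    def test_invariants(self):
        with pytest.raises(InvalidInputError):
            Stratum(0, 5, 6)
        with pytest.raises(InvalidInputError):
            AucEstimate(0.7, 0.8, 0.9, "delong")
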