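import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as lifelines_logrank

from urosig.signature import ScoreTable
from urosig.survival import (cox_ph, cox_score_test,
                             gehan_breslow_wilcoxon, hazard_ratio,
                             km_estimate, logrank_test)
from urosig.synthetic_data import generate_cohort, generate_survival
from .conftest import make_clinical


def hand_two_group_tables(ta, ea, tb, eb):
    """Independent per-event-time 2x2 table computation."""
    times = sorted(set(list(ta[ea == 1]) + list(tb[eb == 1])))
    O = E = V = 0.0
    rows = []
    for t in times:
        na = (ta >= t).sum()
        nb = (tb >= t).sum()
        da = ((ta == t) & (ea == 1)).sum()
        db = ((tb == t) & (eb == 1)).sum()
        n, d = na + nb, da + db
        e = na * d / n
        v = na * nb * d * (n - d) / (n ** 2 * (n - 1)) if n > 1 else 0.0
        O += da
        E += e
        V += v
        rows.append((n, da, e, v))
    return O, E, V, rows


class TestKaplanMeier:
    def test_hand_product_limit(self, clinical_factory):
        km = km_estimate(clinical_factory([1, 2, 3], [1, 0, 1]))
        np.testing.assert_allclose(km.survival, [2 / 3, 0.0])
        assert km.at(1) == pytest.approx(2 / 3)
        assert km.at(0.5) == 1.0

    def test_empirical_survival_without_censoring(self, clinical_factory):
        km = km_estimate(clinical_factory([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(km.survival, [0.75, 0.5, 0.25, 0.0])

    def test_all_censored_is_flat_one(self, clinical_factory):
        km = km_estimate(clinical_factory([5, 6, 7], [0, 0, 0]))
        assert km.event_times.size == 0
        assert km.at(100) == 1.0

    def test_curve_monotone_and_risk_decreasing(self, rng, clinical_factory):
        t = rng.exponential(10, 50)
        e = rng.integers(0, 2, 50)
        km = km_estimate(clinical_factory(t, e))
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all(np.diff(km.n_at_risk) <= 0)


class TestTwoGroupTests:
    def _groups(self, rng, n=60, scale_b=6.0, horizon=12.0):
        ta = np.minimum(rng.exponential(10.0, n), horizon)
        tb = np.minimum(rng.exponential(scale_b, n), horizon)
        ea = (ta < horizon).astype(int)
        eb = (tb < horizon).astype(int)
        a = make_clinical(ta, ea, [f"a{i}" for i in range(n)])
        b = make_clinical(tb, eb, [f"b{i}" for i in range(n)])
        return a, b

    def test_identical_groups_null(self, clinical_factory):
        a = clinical_factory([1, 2, 3, 4], [1, 1, 0, 1])
        b = clinical_factory([1, 2, 3, 4], [1, 1, 0, 1],
                             ids=[f"b{i}" for i in range(4)])
        for test in (logrank_test, gehan_breslow_wilcoxon):
            res = test(a, b)
            assert res.chi_square == pytest.approx(0.0, abs=1e-12)
            assert res.p_value == pytest.approx(1.0)

    def test_hand_table_oracle(self, clinical_factory):
        ta, ea = np.array([1.0, 2, 3]), np.array([1, 1, 1])
        tb, eb = np.array([4.0, 5, 6]), np.array([1, 1, 1])
        a = clinical_factory(ta, ea)
        b = clinical_factory(tb, eb, ids=["x", "y", "z"])
        O, E, V, rows = hand_two_group_tables(ta, ea, tb, eb)
        res = logrank_test(a, b)
        assert res.chi_square == pytest.approx((O - E) ** 2 / V, abs=1e-10)
        gw = gehan_breslow_wilcoxon(a, b)
        num = sum(n * (da - e) for n, da, e, v in rows)
        den = sum(n * n * v for n, da, e, v in rows)
        assert gw.chi_square == pytest.approx(num ** 2 / den, abs=1e-10)

    def test_label_swap_invariance(self, rng):
        a, b = self._groups(rng)
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.chi_square == pytest.approx(r2.chi_square, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)

    def test_matches_lifelines(self, rng):
        a, b = self._groups(rng)
        mine = logrank_test(a, b)
        ref = lifelines_logrank(a.time, b.time, a.event, b.event)
        assert mine.chi_square == pytest.approx(ref.test_statistic, rel=1e-9)
        assert mine.p_value == pytest.approx(ref.p_value, rel=1e-9)

    def test_single_event_time_weights_cancel(self, clinical_factory):
        a = clinical_factory([3, 5, 6], [1, 0, 0])
        b = clinical_factory([3, 7, 8], [1, 0, 0],
                             ids=["x", "y", "z"])
        lr = logrank_test(a, b)
        gw = gehan_breslow_wilcoxon(a, b)
        assert lr.chi_square == pytest.approx(gw.chi_square, abs=1e-12)

    def test_wilcoxon_emphasises_early_separation(self, clinical_factory):
        # group a fails early then matches b; Wilcoxon weights the
        # early tables by the large number at risk
        early_a = clinical_factory([1, 1, 2, 9, 10, 11], [1, 1, 1, 0, 0, 0])
        early_b = clinical_factory([8, 9, 10, 11, 12, 13], [1, 1, 1, 0, 0, 0],
                                   ids=[f"b{i}" for i in range(6)])
        lr = logrank_test(early_a, early_b)
        gw = gehan_breslow_wilcoxon(early_a, early_b)
        assert gw.chi_square > lr.chi_square

    def test_time_shift_invariance(self, rng):
        a, b = self._groups(rng)
        shift_a = make_clinical(a.time + 5.0, a.event, a.patient_ids)
        shift_b = make_clinical(b.time + 5.0, b.event, b.patient_ids)
        assert logrank_test(a, b).chi_square == pytest.approx(
            logrank_test(shift_a, shift_b).chi_square, abs=1e-12)


class TestHazardRatio:
    def test_identical_groups_unit_hr(self, clinical_factory):
        a = clinical_factory([1, 2, 3, 4], [1, 1, 1, 0])
        b = clinical_factory([1, 2, 3, 4], [1, 1, 1, 0],
                             ids=[f"b{i}" for i in range(4)])
        for method in ("mantel_haenszel", "logrank_oe"):
            est = hazard_ratio(a, b, method)
            assert est.hr == pytest.approx(1.0)
            assert est.ci95[0] <= est.hr <= est.ci95[1]

    def test_group_swap_inverts(self, rng):
        ta = np.minimum(rng.exponential(5, 80), 12)
        tb = np.minimum(rng.exponential(15, 80), 12)
        a = make_clinical(ta, (ta < 12).astype(int),
                          [f"a{i}" for i in range(80)])
        b = make_clinical(tb, (tb < 12).astype(int),
                          [f"b{i}" for i in range(80)])
        for method in ("mantel_haenszel", "logrank_oe"):
            ab = hazard_ratio(a, b, method).hr
            ba = hazard_ratio(b, a, method).hr
            assert ab == pytest.approx(1 / ba, rel=1e-9)

    def test_recovers_planted_hr_three(self, rng):
        n = 2000
        ta = np.minimum(rng.exponential(1 / 0.09, n), 20)
        tb = np.minimum(rng.exponential(1 / 0.03, n), 20)
        a = make_clinical(ta, (ta < 20).astype(int),
                          [f"a{i}" for i in range(n)])
        b = make_clinical(tb, (tb < 20).astype(int),
                          [f"b{i}" for i in range(n)])
        for method in ("mantel_haenszel", "logrank_oe"):
            est = hazard_ratio(a, b, method)
            assert est.hr == pytest.approx(3.0, rel=0.15)


class TestCox:
    def test_constant_covariate_rejected(self, clinical_factory):
        rec = clinical_factory([1, 2, 3, 4], [1, 1, 1, 0])
        with pytest.raises(ValueError, match="constant"):
            cox_ph(rec, np.ones(4))

    def test_score_test_equals_logrank_no_ties(self, rng):
        t = rng.exponential(8, 100)
        horizon = 10.0
        e = (t < horizon).astype(int)
        t = np.minimum(t, horizon)
        x = (np.arange(100) < 50).astype(float)
        rec = make_clinical(t, e, [f"p{i}" for i in range(100)])
        a = make_clinical(t[x == 1], e[x == 1], [f"a{i}" for i in range(50)])
        b = make_clinical(t[x == 0], e[x == 0], [f"b{i}" for i in range(50)])
        chi, _ = cox_score_test(rec, x)
        assert chi == pytest.approx(logrank_test(a, b).chi_square, rel=1e-6)

    def test_efron_equals_breslow_without_ties(self, rng):
        t = rng.exponential(8, 60)
        e = (t < 10).astype(int)
        t = np.minimum(t, 10)
        x = rng.normal(size=60)
        rec = make_clinical(t, e, [f"p{i}" for i in range(60)])
        fe = cox_ph(rec, x, ties="efron")
        fb = cox_ph(rec, x, ties="breslow")
        assert fe.beta == pytest.approx(fb.beta, abs=1e-12)

    def test_matches_lifelines_with_ties(self, rng):
        t = rng.integers(1, 8, 80).astype(float)  # heavy ties
        e = rng.integers(0, 2, 80)
        while e.sum() < 2:
            e = rng.integers(0, 2, 80)
        x = rng.normal(size=80)
        rec = make_clinical(t, e, [f"p{i}" for i in range(80)])
        fit = cox_ph(rec, x)
        df = pd.DataFrame({"T": t, "E": e, "x": x})
        ref = CoxPHFitter().fit(df, "T", "E")
        assert fit.beta == pytest.approx(ref.params_["x"], abs=1e-5)
        assert fit.se == pytest.approx(ref.standard_errors_["x"], abs=1e-5)

    def test_planted_beta_recovery(self):
        n = 2000
        scores = ScoreTable([f"P{i:04d}" for i in range(n)],
                            np.zeros(n), (np.arange(n) % 2).astype(float))
        _, truth = generate_cohort(n_patients=4, seed=1, planted_hr=3.0)
        truth.latent_activity = pd.Series(np.zeros(n),
                                          index=scores.patient_ids)
        clin = generate_survival(truth, scores, baseline_hazard=0.03,
                                 seed=5, contrast="unit")
        fit = cox_ph(clin, np.asarray(scores.score))
        assert fit.converged
        assert fit.beta == pytest.approx(-np.log(3.0), rel=0.15)
        assert fit.ci95[0] < fit.hr < fit.ci95[1]

    def test_wald_p_consistent_with_ci(self, rng):
        t = rng.exponential(8, 120)
        e = (t < 10).astype(int)
        t = np.minimum(t, 10)
        x = rng.normal(size=120)
        fit = cox_ph(make_clinical(t, e, [f"p{i}" for i in range(120)]), x)
        crosses_one = fit.ci95[0] <= 1.0 <= fit.ci95[1]
        assert crosses_one == (fit.wald_p > 0.05)
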