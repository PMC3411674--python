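import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from vakgbm import ConvergenceError, cox_fit, km_curve, km_median, logrank, lr_compare


def brute_logrank_chi2(timesA, eventsA, timesB, eventsB):
    """Independent oracle: recompute O, E, V from explicit risk-set tables."""
    rows = [(t, e, 0) for t, e in zip(timesA, eventsA)] + [
        (t, e, 1) for t, e in zip(timesB, eventsB)
    ]
    o = e = v = 0.0
    for t in sorted({t for t, ev, _ in rows if ev == 1}):
        risk = [r for r in rows if r[0] >= t]
        died = [r for r in rows if r[0] == t and r[1] == 1]
        n, n_a = len(risk), sum(1 for r in risk if r[2] == 0)
        d, d_a = len(died), sum(1 for r in died if r[2] == 0)
        o += d_a
        e += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v if v > 0 else 0.0


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_curve([2, 4, 6, 8], [1, 1, 1, 1])
        assert curve.survival_probs == pytest.approx([0.75, 0.5, 0.25, 0.0])
        assert list(curve.at_risk) == [4, 3, 2, 1]
        assert km_median(curve) == 4.0

    def test_single_subject_drops_to_zero(self):
        curve = km_curve([5.0], [1])
        assert curve.survival_at(4.9) == 1.0
        assert curve.survival_at(5.0) == 0.0
        assert km_median(curve) == 5.0

    def test_all_censored_stays_at_one(self):
        curve = km_curve([3, 6, 9], [0, 0, 0])
        assert curve.event_times.size == 0
        assert km_median(curve) is None

    def test_censoring_keeps_subject_at_risk_at_own_time(self):
        # event and censoring tied at t=2: censored subject still in risk set
        curve = km_curve([2, 2, 4], [1, 0, 1])
        assert curve.survival_probs == pytest.approx([2 / 3, 0.0])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 40).round(1)
        curve = km_curve(times, np.ones(40, dtype=int))
        for t in np.unique(times):
            assert curve.survival_at(t) == pytest.approx((times > t).mean())
        # first-crossing sample median
        med = km_median(curve)
        assert curve.survival_at(med) <= 0.5
        prev = curve.event_times[curve.event_times < med]
        if prev.size:
            assert curve.survival_at(prev[-1]) > 0.5

    def test_matches_lifelines(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(12, 60)
        e = (rng.random(60) < 0.7).astype(int)
        curve = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for et, s in zip(curve.event_times, curve.survival_probs):
            assert s == pytest.approx(kmf.predict(et), abs=1e-9)

    @pytest.mark.parametrize("bad", [([], []), ([-1.0], [1])])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            km_curve(*bad)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        res = logrank([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p == 1.0

    def test_hand_hypergeometric_fixture(self):
        res = logrank([1, 2], [1, 1], [3, 4], [1, 1])
        assert res.chi2 == pytest.approx(49 / 17)
        assert res.observed == pytest.approx((2.0, 2.0))
        assert res.expected[0] == pytest.approx(5 / 6)

    def test_label_swap_symmetry(self):
        a = ([1, 5, 7], [1, 0, 1], [2, 3, 9], [1, 1, 0])
        r1 = logrank(*a)
        r2 = logrank(a[2], a[3], a[0], a[1])
        assert r1.chi2 == pytest.approx(r2.chi2)
        assert r1.p == pytest.approx(r2.p)

    @pytest.mark.parametrize("seed", range(5))
    def test_small_inputs_match_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        nA, nB = rng.integers(2, 5, 2)
        tA = rng.integers(1, 9, nA).astype(float)
        tB = rng.integers(1, 9, nB).astype(float)
        eA, eB = np.ones(nA, dtype=int), np.ones(nB, dtype=int)
        res = logrank(tA, eA, tB, eB)
        assert res.chi2 == pytest.approx(brute_logrank_chi2(tA, eA, tB, eB))

    def test_matches_lifelines(self):
        rng = np.random.default_rng(21)
        tA = rng.exponential(10, 40)
        tB = rng.exponential(20, 35)
        eA = (rng.random(40) < 0.8).astype(int)
        eB = (rng.random(35) < 0.8).astype(int)
        res = logrank(tA, eA, tB, eB)
        ref = logrank_test(tA, tB, eA, eB)
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            logrank([1, 2], [0, 0], [3], [0])


def simulate_two_group(seed, n=500, hr=2.0, cens=3.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / np.where(x == 1, hr, 1.0))
    c = rng.uniform(0, cens, n)
    return x, np.minimum(t, c), (t <= c).astype(int)


class TestCox:
    def test_binary_covariate_recovers_log_hazard_ratio(self):
        x, t, e = simulate_two_group(seed=42)
        fit = cox_fit(x, t, e)
        # oracle: closed-form exponential MLE of the rate ratio
        d1, d0 = e[x == 1].sum(), e[x == 0].sum()
        T1, T0 = t[x == 1].sum(), t[x == 0].sum()
        mle = np.log((d1 / T1) / (d0 / T0))
        assert fit.coefficients[0] == pytest.approx(np.log(2), abs=0.15)
        assert fit.coefficients[0] == pytest.approx(mle, abs=0.1)
        assert fit.lr_p < 1e-6

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_lifelines(self, ties):
        x, t, e = simulate_two_group(seed=9, n=150)
        z = np.random.default_rng(10).normal(size=150)
        fit = cox_fit(np.column_stack([x, z]), t, e, ties=ties)
        df = pd.DataFrame({"x": x, "z": z, "t": t, "e": e})
        ref = CoxPHFitter().fit(df, "t", "e")  # lifelines default is efron
        if ties == "efron":
            assert fit.coefficients == pytest.approx(ref.params_.values, abs=1e-6)
            assert fit.standard_errors == pytest.approx(ref.standard_errors_.values, abs=1e-6)
            assert fit.log_likelihood == pytest.approx(ref.log_likelihood_, abs=1e-6)
        else:
            assert fit.coefficients == pytest.approx(ref.params_.values, abs=0.05)

    def test_constant_covariate_carries_no_information(self):
        _, t, e = simulate_two_group(seed=3, n=80)
        fit = cox_fit(np.ones(80), t, e)
        assert fit.coefficients[0] == 0.0
        assert fit.lr_stat == pytest.approx(0.0, abs=1e-9)

    def test_permutation_invariance(self):
        x, t, e = simulate_two_group(seed=4, n=100)
        fit1 = cox_fit(x, t, e)
        perm = np.random.default_rng(0).permutation(100)
        fit2 = cox_fit(x[perm], t[perm], e[perm])
        assert fit1.coefficients == pytest.approx(fit2.coefficients, abs=1e-8)
        assert fit1.log_likelihood == pytest.approx(fit2.log_likelihood, abs=1e-8)

    def test_lr_stat_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=200)
        t = rng.exponential(1.0 / np.exp(0.5 * z))
        e = np.ones(200, dtype=int)
        f1 = cox_fit(z, t, e)
        f2 = cox_fit(13.0 * z + 7.0, t, e)
        assert f1.lr_stat == pytest.approx(f2.lr_stat, rel=1e-6)

    def test_sign_agrees_with_km_median_direction(self):
        for seed in range(6):
            x, t, e = simulate_two_group(seed=seed, n=300)
            m1 = km_median(km_curve(t[x == 1], e[x == 1]))
            m0 = km_median(km_curve(t[x == 0], e[x == 0]))
            if m1 is None or m0 is None or m1 == m0:
                continue
            fit = cox_fit(x, t, e)
            # shorter survival in group 1 <=> positive log hazard ratio
            assert (fit.coefficients[0] > 0) == (m1 < m0)

    def test_separation_raises_naming_covariate(self):
        # covariate perfectly ordered with event times: monotone likelihood
        t = np.arange(1.0, 21.0)
        x = np.arange(20.0)
        with pytest.raises(ConvergenceError, match="covariate 0"):
            cox_fit(x, t, np.ones(20, dtype=int))

    def test_nested_lr_comparison(self):
        x, t, e = simulate_two_group(seed=12, n=200)
        z = np.random.default_rng(13).normal(size=200)
        full = cox_fit(np.column_stack([x, z]), t, e)
        reduced = cox_fit(x, t, e)
        stat, p = lr_compare(full, reduced, df=1)
        assert stat >= 0 and 0 < p <= 1
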