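"""Survival analysis: keyword classifier, KM hand tables, Efron grid-search oracle."""

import numpy as np
import pandas as pd
import pytest

from aneuscope import simulate
from aneuscope.survival import (
    classify_treatment,
    cox_hr,
    km_curve,
    stratified_survival_analysis,
)


class TestClassifyTreatment:
    @pytest.mark.parametrize(
        "drugs, expected",
        [
            (["Oxaliplatin"], "chemo"),          # "platin" substring
            (["Doxorubicin"], "chemo"),          # "dox" / "rubicin"
            (["letrozole"], "non_chemo"),
            (["tamoxifen"], "non_chemo"),
            (["paclitaxel"], "non_chemo"),       # "ac" must NOT fire inside
            (["AC"], "chemo"),                   # whole-token short code
            (["5-FU"], "chemo"),
            (["gemzar", "letrozole"], "chemo"),  # any match suffices
            (["capecetabine"], "chemo"),
            (["methotrexate"], "chemo"),         # "trexate"
        ],
    )
    def test_keyword_matching(self, drugs, expected):
        cls, _ = classify_treatment(drugs)
        assert cls == expected

    def test_empty_list_is_untreated_non_chemo(self):
        cls, note = classify_treatment([])
        assert cls == "non_chemo" and note == "untreated"

    def test_substring_mode_replicates_raw_search_strings(self):
        # the raw published substring behaviour does fire on paclitaxel via "ac"
        cls, _ = classify_treatment(["paclitaxel"], match_mode="substring")
        assert cls == "chemo"


class TestKMCurve:
    def test_no_events_survival_stays_one(self, caplog):
        with caplog.at_level("WARNING"):
            km = km_curve([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at(5.0) == pytest.approx(1.0)
        assert "no events" in caplog.text

    def test_hand_product_limit_table(self):
        # times 1(event), 2(censor), 3(event):
        # S(1) = 2/3; at t=3 risk set {3}, so S(3) = 2/3 * 0 = 0
        km = km_curve([1.0, 2.0, 3.0], [1, 0, 1])
        assert km.survival_at(1.0) == pytest.approx(2 / 3)
        assert km.survival_at(2.5) == pytest.approx(2 / 3)
        assert km.survival_at(3.0) == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(2.0, 40)
        km = km_curve(times, np.ones(40, dtype=int))
        for t in [0.5, 1.0, 2.0, 4.0]:
            empirical = np.mean(times > t)
            assert km.survival_at(t) == pytest.approx(empirical)

    def test_greenwood_variance_hand_value(self):
        # single event among n=4 at t=1: Var = S^2 * d/(n(n-d)) = (3/4)^2 * 1/12
        km = km_curve([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0])
        i = np.where(km.times == 1.0)[0][0]
        assert km.variance[i] == pytest.approx((0.75**2) * (1 / 12))

    def test_simulated_cohort_recovers_true_five_year_survival(self):
        kms = []
        for seed in range(20):
            coh, _ = simulate.simulate_survival_cohort(
                500, baseline_5yr_survival=0.95, two_groups=False,
                random_censor_frac=0.2, seed=seed,
            )
            kms.append(km_curve(coh["time"], coh["event"]).survival_at(5.0))
        assert np.mean(kms) == pytest.approx(0.95, abs=0.02)


def efron_partial_loglik(beta: float, time, event, x) -> float:
    """Independent oracle: Efron partial log-likelihood for one binary covariate."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        d_mask = (time == t) & (event == 1)
        r_mask = time >= t
        d = int(d_mask.sum())
        sum_x_d = x[d_mask].sum()
        theta_r = np.exp(beta * x[r_mask]).sum()
        theta_d = np.exp(beta * x[d_mask]).sum()
        ll += beta * sum_x_d
        for j in range(d):
            ll -= np.log(theta_r - (j / d) * theta_d)
    return ll


class TestCoxHR:
    def test_identical_groups_give_unit_hazard_ratio(self, rng):
        t = rng.exponential(2.0, 200)
        df = pd.DataFrame({"time": np.concatenate([t, t]),
                           "event": 1,
                           "group": ["a"] * 200 + ["b"] * 200})
        fit = cox_hr(df)
        assert fit.hr == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_grid_search_of_efron_partial_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        x = np.array([0] * 5 + [1] * 5)
        time = np.round(rng.exponential(2.0, n) * np.where(x == 1, 0.5, 1.0), 1) + 0.1
        event = rng.random(n) < 0.8
        if event.sum() == 0 or event[x == 0].sum() == 0 or event[x == 1].sum() == 0:
            pytest.skip("degenerate draw")
        df = pd.DataFrame({"time": time, "event": event.astype(int),
                           "group": np.where(x == 1, "g2", "g1")})
        fit = cox_hr(df, reference="g1")

        grid = np.arange(-4.0, 4.0, 1e-4)
        ll = np.array([efron_partial_loglik(b, time, event, x) for b in grid])
        beta_star = grid[np.argmax(ll)]
        assert fit.coef == pytest.approx(beta_star, abs=2e-4)

    def test_label_swap_inverts_hazard_ratio(self):
        coh, _ = simulate.simulate_survival_cohort(400, true_hr=2.0, seed=5)
        fwd = cox_hr(coh, reference="baseline")
        rev = cox_hr(coh, reference="exposed")
        assert fwd.hr == pytest.approx(1 / rev.hr)

    def test_monotone_likelihood_reported_as_divergence(self, caplog):
        df = pd.DataFrame({"time": [1, 2, 3, 4.0],
                           "event": [1, 1, 0, 0],
                           "group": ["a", "a", "b", "b"]})
        with caplog.at_level("WARNING"):
            fit = cox_hr(df)
        assert fit.diverged and np.isnan(fit.hr)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "group": ["a", "b"]})
        with pytest.raises(ValueError, match="no events"):
            cox_hr(df)

    def test_log_hr_bias_small_at_large_n(self):
        # planted log-HR recovered with bias < 0.05 at n=2000 over 20 replicates
        true_hr = 2.67
        coefs = []
        for seed in range(20):
            coh, _ = simulate.simulate_survival_cohort(
                2000, true_hr=true_hr, baseline_5yr_survival=0.8, seed=seed
            )
            coefs.append(cox_hr(coh, reference="baseline").coef)
        assert abs(np.mean(coefs) - np.log(true_hr)) < 0.05


class TestStratifiedAnalysis:
    def _cohort(self, chemo_hr, non_chemo_hr, n=800, seed=0):
        chemo, _ = simulate.simulate_survival_cohort(
            n, true_hr=chemo_hr, baseline_5yr_survival=0.9,
            group_labels=("net_gain", "net_loss"), seed=seed,
        )
        chemo["treatment_class"] = "chemo"
        nc, _ = simulate.simulate_survival_cohort(
            n, true_hr=non_chemo_hr, baseline_5yr_survival=0.9,
            group_labels=("net_gain", "net_loss"), seed=seed + 1000,
        )
        nc["treatment_class"] = "non_chemo"
        out = pd.concat([chemo, nc], ignore_index=True)
        return out.rename(columns={"group": "burden_class"})

    def test_effect_only_in_chemo_stratum_recovered(self):
        log_hrs = {"chemo": [], "non_chemo": []}
        for seed in range(8):
            res = stratified_survival_analysis(
                self._cohort(2.5, 1.0, n=3000, seed=seed * 7)
            )
            for t in log_hrs:
                log_hrs[t].append(res["cox"][t].coef)
        assert np.mean(log_hrs["chemo"]) == pytest.approx(np.log(2.5), abs=0.1)
        assert np.mean(log_hrs["non_chemo"]) == pytest.approx(0.0, abs=0.1)

    def test_relabeling_burden_classes_inverts_hazard_ratios(self):
        coh = self._cohort(2.0, 0.5, seed=3)
        res = stratified_survival_analysis(coh)
        swapped = coh.copy()
        swapped["burden_class"] = swapped["burden_class"].map(
            {"net_gain": "net_loss", "net_loss": "net_gain"}
        )
        res_sw = stratified_survival_analysis(swapped)
        for t in ("chemo", "non_chemo"):
            assert res_sw["cox"][t].hr == pytest.approx(1 / res["cox"][t].hr)

    def test_single_stratum_cohort_yields_partial_output(self, caplog):
        coh = self._cohort(1.0, 1.0, n=100, seed=1)
        only = coh[(coh["treatment_class"] == "chemo") & (coh["burden_class"] == "net_gain")]
        with caplog.at_level("WARNING"):
            res = stratified_survival_analysis(only)
        assert list(res["km"]) == [("chemo", "net_gain")]
        assert res["cox"] == {}
        assert "partial" in caplog.text or "lacks" in caplog.text

    def test_missing_burden_classes_rejected(self):
        df = pd.DataFrame({"time": [1.0], "event": [1],
                           "burden_class": ["balanced"], "treatment_class": ["chemo"]})
        with pytest.raises(ValueError, match="net_gain"):
            stratified_survival_analysis(df)
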