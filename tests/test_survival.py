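"""Endpoints, Cox/Kaplan-Meier fits, hazard screening, cutpoints, LR gain."""

import numpy as np
import pandas as pd
import pytest

from sarcomics.survival import (
    CoxFit,
    build_endpoints,
    cox_fit,
    km_fit,
    lr_gain,
    martingale_cutpoint,
    screen_features,
)


def _clinical(rows: dict) -> pd.DataFrame:
    df = pd.DataFrame(rows).T
    df.columns = [
        "time_to_local_recurrence",
        "time_to_metastasis",
        "time_to_death",
        "last_followup",
    ]
    return df


class TestBuildEndpoints:
    def test_death_counts_for_all_composite_endpoints(self):
        clin = _clinical({"a": [np.nan, np.nan, 4.0, 4.0]})
        rec = build_endpoints(clin)
        lrfs = rec[(rec["sample"] == "a") & (rec["endpoint"] == "LRFS")]
        assert lrfs.iloc[0]["time"] == 4.0
        assert lrfs.iloc[0]["event"] == 1

    def test_event_free_capped_at_five_years(self):
        clin = _clinical({"a": [np.nan, np.nan, np.nan, 6.2]})
        rec = build_endpoints(clin)
        assert (rec["time"] == 5.0).all()
        assert (rec["event"] == 0).all()

    def test_first_component_event_wins(self):
        clin = _clinical({"a": [np.nan, 1.2, 3.0, 3.0]})
        rec = build_endpoints(clin)
        mfs = rec[rec["endpoint"] == "MFS"].iloc[0]
        assert mfs["time"] == 1.2 and mfs["event"] == 1
        os_ = rec[rec["endpoint"] == "OS"].iloc[0]
        assert os_["time"] == 3.0 and os_["event"] == 1

    def test_event_after_cap_is_censored(self):
        clin = _clinical({"a": [np.nan, np.nan, 6.5, 7.0]})
        rec = build_endpoints(clin)
        assert (rec["time"] == 5.0).all()
        assert (rec["event"] == 0).all()

    def test_non_positive_followup_rejected(self, caplog):
        clin = _clinical({"a": [np.nan, np.nan, np.nan, 0.0],
                          "b": [np.nan, np.nan, 1.0, 2.0]})
        with caplog.at_level("WARNING"):
            rec = build_endpoints(clin)
        assert set(rec["sample"]) == {"b"}


def _simulated_records(n=200, hr=1.0, seed=0, censor=None):
    r = np.random.default_rng(seed)
    x = r.integers(0, 2, n).astype(float)
    t = r.exponential(1.0 / (0.3 * hr**x))
    followup = np.full(n, np.inf) if censor is None else r.exponential(censor, n)
    clin = pd.DataFrame(
        {
            "time_to_local_recurrence": np.nan,
            "time_to_metastasis": np.nan,
            "time_to_death": np.where(t <= followup, t, np.nan),
            "last_followup": np.minimum(followup, 100.0),
        },
        index=[f"s{i}" for i in range(n)],
    )
    rec = build_endpoints(clin, cap=100.0)
    return rec, pd.Series(x, index=clin.index, name="x")


class TestCoxFit:
    def test_null_covariate_estimates_near_zero(self):
        rec, x = _simulated_records(n=1000, hr=1.0, seed=1)
        fit = cox_fit(rec, x.to_frame(), endpoint="OS")
        assert abs(np.log(fit.hazard_ratios["x"])) < 0.15

    def test_planted_hazard_ratio_recovered(self):
        rec, x = _simulated_records(n=500, hr=2.0, seed=2)
        fit = cox_fit(rec, x.to_frame(), endpoint="OS")
        assert 1.7 <= fit.hazard_ratios["x"] <= 2.35
        assert fit.summary.loc["x", "p"] < 0.001

    def test_ci_contains_hr(self):
        rec, x = _simulated_records(n=300, hr=1.5, seed=3)
        fit = cox_fit(rec, x.to_frame(), endpoint="OS")
        row = fit.summary.loc["x"]
        assert row["HR_lower95"] <= row["HR"] <= row["HR_upper95"]

    def test_constant_covariate_rejected(self):
        rec, x = _simulated_records(n=50, seed=4)
        with pytest.raises(ValueError, match="constant"):
            cox_fit(rec, pd.DataFrame({"c": np.ones(50)}, index=x.index),
                    endpoint="OS")

    def test_llr_invariant_to_affine_rescaling(self):
        rec, x = _simulated_records(n=200, hr=2.0, seed=5)
        f1 = cox_fit(rec, x.to_frame(), endpoint="OS")
        f2 = cox_fit(rec, (10 * x + 3).to_frame(), endpoint="OS")
        assert f1.llr_chi2 == pytest.approx(f2.llr_chi2, rel=1e-6)


class TestKmFit:
    def test_no_events_flat_curve(self):
        rec = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0], "event": [0, 0, 0]},
            index=["a", "b", "c"],
        )
        km = km_fit(rec, pd.Series("g", index=rec.index))
        assert (km.fitters["g"].survival_function_["g"] == 1.0).all()

    def test_hand_product_limit(self):
        rec = pd.DataFrame(
            {"time": [1.0, 2.0], "event": [1, 1]}, index=["a", "b"]
        )
        km = km_fit(rec, pd.Series("g", index=rec.index))
        sf = km.fitters["g"].survival_function_["g"]
        assert sf.loc[1.0] == pytest.approx(0.5)
        assert sf.loc[2.0] == pytest.approx(0.0)

    def test_hand_product_limit_with_censoring(self):
        # events at 1 and 3, censored at 2: S = 1/2 at 1, then 1/2 * 0 at 3
        rec = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0], "event": [1, 0, 1, 0]},
            index=list("abcd"),
        )
        km = km_fit(rec, pd.Series("g", index=rec.index))
        sf = km.fitters["g"].survival_function_["g"]
        assert sf.loc[1.0] == pytest.approx(3 / 4)
        assert sf.loc[3.0] == pytest.approx(3 / 4 * 1 / 2)

    def test_identical_groups_logrank_null(self):
        pvals = []
        for seed in range(30):
            rec, x = _simulated_records(n=80, hr=1.0, seed=seed)
            groups = pd.Series(np.where(x > 0, "a", "b"), index=x.index)
            km = km_fit(rec, groups, endpoint="OS")
            pvals.append(km.logrank_p)
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_group_rejected(self):
        rec = pd.DataFrame({"time": [1.0], "event": [1]}, index=["a"])
        with pytest.raises(ValueError):
            km_fit(rec, pd.Series({"a": "g", "zz": "h"}))


class TestScreenFeatures:
    def _records_three_endpoints(self, n=150, seed=0):
        r = np.random.default_rng(seed)
        risk = r.normal(size=n)
        rows = []
        samples = [f"s{i}" for i in range(n)]
        for ep, beta in (("OS", 1.2), ("LRFS", 1.2), ("MFS", 0.0)):
            t = r.exponential(1.0 / (0.3 * np.exp(beta * risk)))
            rows.append(
                pd.DataFrame(
                    {"sample": samples, "endpoint": ep,
                     "time": np.minimum(t, 5.0),
                     "event": (t <= 5.0).astype(int)}
                )
            )
        matrix = pd.DataFrame(
            np.vstack([risk, r.normal(size=(3, n))]),
            index=["risk", "n1", "n2", "n3"],
            columns=samples,
        )
        return pd.concat(rows, ignore_index=True), matrix

    def test_partial_endpoint_significance_excluded_from_intersection(self):
        rec, matrix = self._records_three_endpoints()
        table, sig, all_ep = screen_features(matrix, rec)
        assert "risk" in sig["OS"] and "risk" in sig["LRFS"]
        assert "risk" not in sig["MFS"]
        assert all_ep == set()

    def test_null_features_rarely_pass_hr_bounds(self):
        rates = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 120
            samples = [f"s{i}" for i in range(n)]
            t = r.exponential(1 / 0.3, n)
            rec = pd.DataFrame(
                {"sample": samples, "endpoint": "OS",
                 "time": np.minimum(t, 5.0), "event": (t <= 5.0).astype(int)}
            )
            matrix = pd.DataFrame(
                r.normal(size=(40, n)),
                index=[f"f{i}" for i in range(40)],
                columns=samples,
            )
            _, sig, _ = screen_features(matrix, rec, endpoints=("OS",))
            rates.append(len(sig["OS"]) / 40)
        assert np.mean(rates) < 0.02


class TestMartingaleCutpoint:
    def _threshold_records(self, n=400, c=2.0, seed=0):
        r = np.random.default_rng(seed)
        x = r.lognormal(np.log(c), 0.6, n)
        hazard = np.where(x > c, 1.2, 0.25)
        t = r.exponential(1.0 / hazard)
        rec = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(n)], "endpoint": "OS",
             "time": np.minimum(t, 8.0), "event": (t <= 8.0).astype(int)}
        )
        return rec, pd.Series(x, index=rec["sample"].to_numpy())

    def test_jump_location_recovered(self):
        errs = []
        for seed in range(10):
            rec, x = self._threshold_records(seed=seed)
            res = martingale_cutpoint(rec, x, endpoint="OS")
            errs.append(abs(res.cutpoint - 2.0) / 2.0)
        assert np.median(errs) <= 0.10

    def test_independent_covariate_falls_back_to_median(self):
        r = np.random.default_rng(42)
        n = 200
        t = r.exponential(2.0, n)
        rec = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(n)], "endpoint": "OS",
             "time": t, "event": np.ones(n, dtype=int)}
        )
        x = pd.Series(r.lognormal(0, 1, n), index=rec["sample"].to_numpy())
        with pytest.warns(UserWarning):
            res = martingale_cutpoint(rec, x, endpoint="OS")
        assert res.used_fallback
        assert res.cutpoint == pytest.approx(float(np.median(x)))

    def test_too_few_distinct_values_rejected(self):
        rec = pd.DataFrame(
            {"sample": [f"s{i}" for i in range(20)], "endpoint": "OS",
             "time": np.arange(1, 21, dtype=float), "event": 1}
        )
        x = pd.Series([1.0, 2.0] * 10, index=rec["sample"].to_numpy())
        with pytest.raises(ValueError, match="distinct"):
            martingale_cutpoint(rec, x, endpoint="OS")


class TestLrGain:
    def test_identical_models_zero_gain(self):
        rec, x = _simulated_records(n=150, hr=2.0, seed=6)
        fit = cox_fit(rec, x.to_frame(), endpoint="OS")
        gain = lr_gain(fit, fit)
        assert gain.delta_chi2 == 0.0
        assert gain.gain_pct == 0.0

    def test_printed_pair_consistency(self):
        """A base LR chi2 of 7.125 extended to 15.895 is a change of 8.77,
        i.e. a 123.1% relative gain in prognostic information."""
        base = CoxFit(pd.DataFrame(), -100.0, 7.125, 3, 25, 20, ["g"])
        ext = CoxFit(pd.DataFrame(), -95.0, 15.895, 4, 25, 20, ["g", "c"])
        gain = lr_gain(base, ext)
        assert gain.delta_chi2 == pytest.approx(8.77)
        assert gain.gain_pct == pytest.approx(123.1, abs=0.1)

    def test_added_true_risk_factor_gains(self):
        rec, x = _simulated_records(n=300, hr=2.5, seed=7)
        noise = pd.Series(
            np.random.default_rng(8).normal(size=300), index=x.index, name="z"
        )
        base = cox_fit(rec, noise.to_frame(), endpoint="OS")
        ext = cox_fit(rec, pd.concat([noise, x], axis=1), endpoint="OS")
        gain = lr_gain(base, ext)
        assert gain.gain_pct > 0
        assert gain.p < 0.05

    def test_non_nested_rejected(self):
        rec, x = _simulated_records(n=100, hr=1.5, seed=9)
        f1 = cox_fit(rec, x.to_frame(), endpoint="OS")
        other = pd.DataFrame(
            {"y": np.random.default_rng(1).normal(size=100)}, index=x.index
        )
        f2 = cox_fit(rec, other, endpoint="OS")
        with pytest.raises(ValueError, match="nested"):
            lr_gain(f1, f2)
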