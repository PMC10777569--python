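"""Survival: product-limit and log-rank hand oracles, Cox grid oracle, HR curve."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import rloopsc as r
from rloopsc.survival import ConvergenceError, natural_spline_basis


def _surv(times, events, groups=None, **extra):
    df = pd.DataFrame({"time": times, "event": events})
    df["group"] = groups if groups is not None else "all"
    for k, v in extra.items():
        df[k] = v
    return df


def test_km_no_events_flat():
    surv = _surv([1.0, 2.0, 3.0], [0, 0, 0])
    curves = r.km_estimate(surv)
    assert np.allclose(curves["all"].survival, 1.0)


def test_km_all_events_closed_form():
    surv = _surv([1.0, 2.0, 3.0], [1, 1, 1])
    km = r.km_estimate(surv)["all"]
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])


def test_km_hand_computed_with_censoring():
    # times 1,2+,3,4,5+,6 -> steps at 1,3,4,6
    surv = _surv([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
    km = r.km_estimate(surv)["all"]
    expected = {1: 5 / 6, 3: 5 / 6 * 3 / 4, 4: 5 / 6 * 3 / 4 * 2 / 3, 6: 0.0}
    for t, s in expected.items():
        row = km[km.time == t].iloc[0]
        assert row.survival == pytest.approx(s, abs=1e-12)
    # Greenwood variance at t=1: S^2 * d/(n(n-d)) = (5/6)^2 * 1/30
    assert km[km.time == 1].greenwood_var.iloc[0] == pytest.approx((5 / 6) ** 2 / 30)


def test_km_survival_non_increasing_starts_at_one(normalized_sim):
    surv = r.generate_survival(
        pd.Series(["high"] * 40 + ["low"] * 40), hr=2, censor_rate=0.3, seed=0
    )
    for km in r.km_estimate(surv).values():
        s = km.survival.to_numpy()
        assert s[0] <= 1.0
        assert (np.diff(s) <= 1e-12).all()


def test_logrank_identical_groups():
    surv = _surv([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1], ["a"] * 3 + ["b"] * 3)
    chi2, p = r.logrank_test(surv)
    assert chi2 == pytest.approx(0.0, abs=1e-10)
    assert p == pytest.approx(1.0, abs=1e-10)


def test_logrank_hand_computed_six_subjects():
    # group a: 1 (event), 3 (event); group b: 2 (event), 4 (censored)
    surv = _surv([1, 3, 2, 4], [1, 1, 1, 0], ["a", "a", "b", "b"])
    # hand O-E and hypergeometric variance over event times 1, 2, 3:
    # t=1: n=4 (2a,2b), d=1 in a -> E_a = 1*2/4 = 0.5, V = 2*2*1*3/(16*3) = 0.25
    # t=2: n=3 (1a,2b), d=1 in b -> E_a = 1/3, V = 1*2*1*2/(9*2) = 2/9
    # t=3: n=2 (1a,1b), d=1 in a -> E_a = 0.5, V = 1*1*1*1/(4*1) = 0.25
    O_a, E_a = 2.0, 0.5 + 1 / 3 + 0.5
    V = 0.25 + 2 / 9 + 0.25
    expected_chi2 = (O_a - E_a) ** 2 / V
    chi2, _ = r.logrank_test(surv)
    assert chi2 == pytest.approx(expected_chi2, rel=1e-10)


def test_logrank_no_events_errors():
    surv = _surv([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])
    with pytest.raises(ValueError):
        r.logrank_test(surv)


def grid_oracle_coef(times, events, x):
    """1-D Breslow partial likelihood maximized by golden-section search."""
    times, events, x = map(np.asarray, (times, events, x))

    def neg_loglik(beta):
        ll = 0.0
        for i in np.flatnonzero(events == 1):
            risk = times >= times[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
        return -ll

    res = minimize_scalar(neg_loglik, bounds=(-5, 5), method="bounded",
                          options={"xatol": 1e-10})
    return res.x


def test_cox_matches_grid_search_oracle():
    times = [1.0, 2.0, 3.0, 4.0, 5.0]
    events = [1, 1, 0, 1, 1]
    x = [0.0, 1.0, 0.0, 1.0, 0.0]
    surv = _surv(times, events, x=x)
    fit = r.cox_ph(surv, "x")
    assert fit.coef.iloc[0] == pytest.approx(grid_oracle_coef(times, events, x), abs=1e-6)


def test_cox_agrees_with_lifelines_on_tie_free_data():
    """Independent route: lifelines' Efron fit equals Breslow without ties."""
    from lifelines import CoxPHFitter

    surv = r.generate_survival(
        pd.Series(["high"] * 100 + ["low"] * 100), hr=2, censor_rate=0.2, seed=7
    )
    surv["x"] = (surv.group == "low").astype(float)
    mine = r.cox_ph(surv, "x")
    cph = CoxPHFitter().fit(surv[["time", "event", "x"]], "time", "event")
    assert mine.coef.iloc[0] == pytest.approx(cph.params_["x"], abs=1e-6)
    assert mine.p.iloc[0] == pytest.approx(cph.summary.loc["x", "p"], rel=1e-3)


def test_cox_hr_equivariance_under_negation():
    surv = r.generate_survival(
        pd.Series(["high"] * 80 + ["low"] * 80), hr=2, censor_rate=0.2, seed=8
    )
    surv["x"] = (surv.group == "low").astype(float)
    surv["negx"] = 1.0 - surv.x
    a = r.cox_ph(surv, "x")
    b = r.cox_ph(surv, "negx")
    assert a.hr.iloc[0] == pytest.approx(1 / b.hr.iloc[0], rel=1e-8)


def test_cox_separation_errors():
    # covariate perfectly orders survival times -> monotone likelihood
    surv = _surv(np.arange(1, 21, dtype=float), [1] * 20, x=np.arange(20, dtype=float))
    with pytest.raises((ConvergenceError, ValueError)):
        r.cox_ph(surv, "x")


def test_cox_too_few_events_errors():
    surv = _surv([1.0, 2.0, 3.0], [1, 0, 0], x=[0.0, 1.0, 0.5])
    with pytest.raises(ValueError):
        r.cox_ph(surv, ["x", "time"])


def test_spline_basis_shape_and_linearity_outside_knots():
    x = np.linspace(0, 1, 50)
    B = natural_spline_basis(x, np.quantile(x, [0, 0.33, 0.66, 1.0]))
    assert B.shape == (50, 3)
    assert np.allclose(B[:, 0], x)


def test_hr_curve_zero_at_median_and_monotone_for_linear_hazard():
    rng = np.random.default_rng(9)
    n = 400
    score = rng.normal(size=n)
    times = rng.exponential(1.0 / np.exp(0.8 * score))
    surv = pd.DataFrame({"time": times, "event": 1, "score": score})
    curve = r.hr_score_curve(surv, "score")
    med = np.median(score)
    at_med = curve[np.isclose(curve.score, med)]
    assert len(at_med) == 1
    assert at_med.ln_hr.iloc[0] == 0.0
    # positive log-hazard slope recovered, curve increasing overall
    assert curve.ln_hr.iloc[-1] > 0 > curve.ln_hr.iloc[0]


def test_hr_curve_df_exceeding_distinct_scores_errors():
    surv = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1],
                         "score": [0.0, 0.0, 1.0, 1.0]})
    with pytest.raises(ValueError):
        r.hr_score_curve(surv, "score", df=4)
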