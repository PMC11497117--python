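"""Ratio covariates, KM estimation, log-rank and Mantel-Haenszel HR."""

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from spatialniche import synthetic_data as sd
from spatialniche import survival as sv


def two_arm(times_a, times_b, events_a=None, events_b=None):
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea = np.ones(len(ta), int) if events_a is None else np.asarray(events_a)
    eb = np.ones(len(tb), int) if events_b is None else np.asarray(events_b)
    return (
        np.concatenate([ta, tb]),
        np.concatenate([ea, eb]),
        np.array(["high"] * len(ta) + ["low"] * len(tb)),
    )


# ----------------------------------------------------------------- ratios

def test_sample_ratio_values():
    cells = pd.DataFrame(
        {
            "level_nos2": ["strong"] * 50 + ["negative"] * 25,
            "phenotype": [2] * 50 + [4] * 25,
        }
    )
    assert sv.sample_ratio(cells, "nos2s") == pytest.approx(2.0)
    cells2 = pd.DataFrame({"level_nos2": ["negative"] * 10,
                           "phenotype": [4] * 10})
    assert sv.sample_ratio(cells2, "nos2s") == 0.0
    none_cd8 = pd.DataFrame({"level_nos2": ["strong"], "phenotype": [2]})
    with pytest.raises(ZeroDivisionError):
        sv.sample_ratio(none_cd8, "nos2s")
    assert sv.sample_ratio(none_cd8, "nos2s", pseudocount=1.0) == 1.0


def test_deceased_cohort_has_elevated_ratios():
    """Planted NOS2s-up / CD8-down structure shows in the sample ratios."""
    hits = 0
    for seed in range(5):
        cells, meta, _ = sd.simulate_cohort(2, 2, seed=seed)
        phen = sd.canonical_rule()
        from spatialniche.phenotyping import phenotype_cells

        ratios = sv.cohort_ratios(
            phenotype_cells(cells, phen), "nos2s", pseudocount=1.0
        )
        by_group = ratios.groupby(
            meta.set_index("sample_id")["group"]
        ).median()
        hits += by_group["deceased"] > by_group["alive"]
    assert hits == 5


# ----------------------------------------------------------- dichotomize

def test_dichotomize_median_conventions():
    assert sv.dichotomize_median([1, 2, 3, 4]).tolist() == [
        "low", "low", "high", "high"]
    assert sv.dichotomize_median([1, 2, 2, 3]).tolist() == [
        "low", "low", "low", "high"]  # ties at the median go low
    assert sv.dichotomize_median([5, 1]).tolist() == ["high", "low"]
    with pytest.raises(ValueError):
        sv.dichotomize_median([2, 2, 2])


# ------------------------------------------------------------------- KM

def test_km_closed_form_two_subjects():
    kmf = sv.km_estimate([1.0, 2.0], [1, 1])
    assert kmf.predict(1.0) == pytest.approx(0.5)
    assert kmf.predict(2.0) == pytest.approx(0.0)
    assert kmf.predict(0.5) == pytest.approx(1.0)


def test_km_all_censored_stays_at_one():
    kmf = sv.km_estimate([1, 2, 3], [0, 0, 0])
    assert kmf.predict(3.0) == pytest.approx(1.0)


def test_km_exponential_survival_value():
    rng = np.random.default_rng(0)
    t = rng.exponential(5.0, 1000)  # rate 0.2 -> S(5) = e^-1
    kmf = sv.km_estimate(t, np.ones(1000, int))
    assert abs(kmf.predict(5.0) - np.exp(-1)) < 0.05


def test_km_curve_monotone_nonincreasing():
    rec = sd.simulate_survival_cohort(200, 2.0, censor_rate=0.3, seed=1)
    kmf = sv.km_estimate(rec.time_years, rec.event)
    vals = kmf.survival_function_.iloc[:, 0].to_numpy()
    assert vals[0] == 1.0 and (np.diff(vals) <= 1e-12).all()

    with pytest.raises(ValueError, match="negative"):
        sv.km_estimate([-1.0, 2.0], [1, 1])


# -------------------------------------------------------------- log-rank

def test_logrank_identical_strata_is_null():
    t, e, g = two_arm([1, 2, 3], [1, 2, 3])
    chi2, p = sv.logrank_mantel_cox(t, e, g)
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_logrank_matches_hand_tabulated_oe():
    """Fully separated event times: O-E computed by hand over the pooled
    risk tables."""
    t, e, g = two_arm([1, 2, 3], [10, 20, 30])
    # risk sets at t=1,2,3: n=(6,5,4), n_high=(3,2,1), one death each (high)
    e_high = 3 / 6 + 2 / 5 + 1 / 4
    # at t=10,20,30: n=(3,2,1) all low, expected contribution 0 for high
    v = sum(
        d * nh / n * (1 - nh / n) * (n - d) / (n - 1)
        for nh, n, d in [(3, 6, 1), (2, 5, 1), (1, 4, 1)]
    )
    chi2, _ = sv.logrank_mantel_cox(t, e, g)
    assert chi2 == pytest.approx((3 - e_high) ** 2 / v, abs=1e-9)


def test_logrank_agrees_with_lifelines():
    for seed in range(5):
        rec = sd.simulate_survival_cohort(150, 2.5, censor_rate=0.2,
                                          seed=seed)
        chi2, p = sv.logrank_mantel_cox(rec.time_years, rec.event,
                                        rec.stratum)
        hi = rec.stratum == "high"
        ref = logrank_test(rec.time_years[hi], rec.time_years[~hi],
                           rec.event[hi], rec.event[~hi])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)


def test_logrank_invariant_to_time_rescaling():
    rec = sd.simulate_survival_cohort(100, 3.0, seed=2)
    a = sv.logrank_mantel_cox(rec.time_years, rec.event, rec.stratum)
    b = sv.logrank_mantel_cox(rec.time_years * 37.5, rec.event, rec.stratum)
    assert a == pytest.approx(b)


def test_logrank_requires_events_per_stratum():
    t, e, g = two_arm([1, 2], [3, 4], events_b=[0, 0])
    with pytest.raises(ValueError, match="low"):
        sv.logrank_mantel_cox(t, e, g)


# ------------------------------------------------------------------- HR

def test_hr_identity_and_reciprocity():
    t, e, g = two_arm([1, 2, 5, 7], [1, 2, 5, 7])
    assert sv.hazard_ratio_mh(t, e, g).hr == pytest.approx(1.0)

    rec = sd.simulate_survival_cohort(100, 3.0, seed=4)
    fwd = sv.hazard_ratio_mh(rec.time_years, rec.event, rec.stratum).hr
    flipped = np.where(rec.stratum == "high", "low", "high")
    rev = sv.hazard_ratio_mh(rec.time_years, rec.event, flipped).hr
    assert fwd == pytest.approx(1 / rev)


def test_hr_ci_contains_point_estimate_and_is_positive():
    rec = sd.simulate_survival_cohort(200, 2.0, censor_rate=0.1, seed=5)
    res = sv.hazard_ratio_mh(rec.time_years, rec.event, rec.stratum)
    assert 0 < res.ci_low < res.hr < res.ci_high


@pytest.mark.parametrize("true_hr", [1.0, 2.0, 5.0])
def test_hr_recovers_planted_values(true_hr):
    """Recovery under the cohort's 5-year-horizon study conditions (the
    O/E estimator attenuates when nearly all subjects have events)."""
    hrs = [
        sv.hazard_ratio_mh(*(lambda r: (r.time_years, r.event, r.stratum))(
            sd.simulate_survival_cohort(600, true_hr, horizon_years=5.0,
                                        seed=s)
        )).hr
        for s in range(30)
    ]
    log_err = abs(np.log(np.mean(hrs)) - np.log(true_hr))
    assert log_err < 0.15


def test_horizon_truncation():
    t, e = sv.truncate_at_horizon([2.0, 7.0], [1, 1], 5.0)
    assert t.tolist() == [2.0, 5.0] and e.tolist() == [1, 0]


# ------------------------------------------------- expression-ratio module

def synth_geo(n=120, hr=3.0, seed=0):
    """Expression + survival tables where the high NOS2/CD8A-ratio half has
    a planted hazard ratio."""
    rng = np.random.default_rng(seed)
    samples = [f"g{i}" for i in range(n)]
    ratio = np.concatenate([rng.uniform(0.2, 0.9, n // 2),
                            rng.uniform(1.1, 4.0, n // 2)])
    cd8a = rng.uniform(1.0, 3.0, n)
    expr = pd.DataFrame(
        {
            s: {"NOS2": ratio[i] * cd8a[i], "PTGS2": ratio[i] * cd8a[i],
                "CD8A": cd8a[i]}
            for i, s in enumerate(samples)
        }
    )
    rate = np.where(ratio > np.median(ratio), 0.08 * hr, 0.08)
    time = rng.exponential(1 / rate)
    surv = pd.DataFrame(
        {"sample_id": samples, "time_years": time,
         "event": np.ones(n, int)}
    )
    return expr, surv


def test_geo_ratio_survival_recovers_planted_hr():
    hrs = []
    for seed in range(20):
        expr, surv = synth_geo(n=200, hr=3.0, seed=seed)
        res = sv.geo_ratio_survival(expr, surv)
        hrs.append(res["nos2_cd8a"].hr)
    assert 2.3 <= np.mean(hrs) <= 3.9


def test_geo_constant_cd8a_preserves_numerator_order():
    expr, surv = synth_geo(n=40, seed=3)
    expr.loc["CD8A"] = 1.0
    ratios = (expr.loc["NOS2"] / expr.loc["CD8A"]).to_numpy()
    assert (np.argsort(ratios) == np.argsort(expr.loc["NOS2"].to_numpy())).all()
    res = sv.geo_ratio_survival(expr, surv)
    assert res["nos2_cd8a"].hr > 0


def test_geo_missing_gene_raises():
    expr, surv = synth_geo(n=20)
    with pytest.raises(KeyError, match="ACTB"):
        sv.geo_ratio_survival(expr, surv, nos2_gene="ACTB")
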