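"""Ratio covariates and dichotomized survival analysis.

Builds per-sample marker/CD8 ratios (cell-count based for imaging cohorts,
expression based for transcriptomic cohorts), splits samples at the median
ratio, and compares the high vs low strata with the Kaplan-Meier estimator,
the log-rank (Mantel-Cox) test and the Mantel-Haenszel hazard ratio.

The log-rank machinery is a single pooled O/E tabulation over distinct
event times: with ``n_gj`` at risk and ``d_gj`` events in stratum ``g`` at
time ``t_j`` (``n_j``, ``d_j`` pooled),

    E_gj = d_j * n_gj / n_j
    V_j  = d_j * (n_1j/n_j) * (1 - n_1j/n_j) * (n_j - d_j) / (n_j - 1)

    chi-square = (O_1 - E_1)^2 / V,   1 df
    HR         = (O_1/E_1) / (O_2/E_2)   (Mantel-Haenszel / Pike)
    CI         = exp(log HR +/- 1.96 * sqrt(1/E_1 + 1/E_2))

Orientation is high vs low: HR > 1 means the high-ratio stratum fares
worse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


@dataclass
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    chi_square: float
    p_value: float
    observed: tuple  # (O_high, O_low)
    expected: tuple  # (E_high, E_low)
    variance: float  # summed hypergeometric variance
    table: pd.DataFrame  # per-event-time risk/event tabulation


def sample_ratio(
    cells: pd.DataFrame,
    numerator: str = "nos2s",
    pseudocount: float = 0.0,
) -> float:
    """Marker/CD8 ratio of one phenotyped sample.

    ``numerator="nos2s"`` counts cells with *strong* NOS2 signal;
    ``"cox2"`` counts COX2+ cells (moderate-or-above by the default rule).
    The denominator is the CD8+ cell count (phenotype code bit 4).  A zero
    denominator raises unless ``pseudocount`` > 0.
    """
    if numerator == "nos2s":
        num = int((cells["level_nos2"] == "strong").sum())
    elif numerator == "cox2":
        num = int((cells["phenotype"].to_numpy(int) & 1 > 0).sum())
    elif numerator == "nos2":
        num = int((cells["phenotype"].to_numpy(int) & 2 > 0).sum())
    else:
        raise ValueError(f"unknown numerator {numerator!r}")
    den = int((cells["phenotype"].to_numpy(int) & 4 > 0).sum())
    if den == 0 and pseudocount == 0:
        raise ZeroDivisionError(
            "no CD8+ cells in sample and pseudocount disabled"
        )
    return num / (den + pseudocount)


def cohort_ratios(
    cells: pd.DataFrame, numerator: str = "nos2s", pseudocount: float = 0.0
) -> pd.Series:
    """Per-sample ratios for a multi-sample phenotyped cell table."""
    return cells.groupby("sample_id", sort=False).apply(
        lambda g: sample_ratio(g, numerator, pseudocount),
        include_groups=False,
    )


def dichotomize_median(values) -> np.ndarray:
    """Label values 'low' (<= median) or 'high' (> median).

    Ties at the median go to 'low'.  All-identical input raises (no split
    is possible).
    """
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need at least 2 values")
    med = np.median(v)
    labels = np.where(v > med, "high", "low")
    if (labels == "low").all() or (labels == "high").all():
        raise ValueError("all values identical at the median; cannot split")
    return labels


def km_estimate(time, event, label: str | None = None) -> KaplanMeierFitter:
    """Product-limit survival curve for one stratum (lifelines fitter)."""
    time = np.asarray(time, float)
    if (time < 0).any():
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, np.asarray(event, int), label=label)
    return kmf


def _oe_table(time, event, group) -> pd.DataFrame:
    """Pooled per-event-time tabulation for two strata ('high' first)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    rows = []
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        n1 = int((at_risk & (group == "high")).sum())
        n2 = int((at_risk & (group == "low")).sum())
        d1 = int((dead & (group == "high")).sum())
        d2 = int((dead & (group == "low")).sum())
        n, d = n1 + n2, d1 + d2
        e1 = d * n1 / n
        var = (
            d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        )
        rows.append(
            {"time": t, "n_high": n1, "n_low": n2, "d_high": d1,
             "d_low": d2, "e_high": e1, "variance": var}
        )
    return pd.DataFrame(rows)


def logrank_mantel_cox(time, event, group):
    """Log-rank (Mantel-Cox) chi-square and two-sided p, 1 df.

    ``group`` holds 'high'/'low' labels.  Identical strata give
    chi-square 0, p 1.
    """
    event = np.asarray(event, int)
    group = np.asarray(group)
    for g in ("high", "low"):
        if event[group == g].sum() < 1:
            raise ValueError(f"stratum {g!r} has no events")
    tab = _oe_table(time, event, group)
    o1 = tab["d_high"].sum()
    e1 = tab["e_high"].sum()
    v = tab["variance"].sum()
    if v == 0:
        return 0.0, 1.0
    chi2 = (o1 - e1) ** 2 / v
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def hazard_ratio_mh(time, event, group) -> HazardRatioResult:
    """Mantel-Haenszel hazard ratio of the high vs low strata."""
    event = np.asarray(event, int)
    group = np.asarray(group)
    tab = _oe_table(time, event, group)
    if len(tab) == 0:
        raise ValueError("no events in either stratum")
    o1, o2 = tab["d_high"].sum(), tab["d_low"].sum()
    e1 = tab["e_high"].sum()
    e2 = (tab["d_high"] + tab["d_low"] - tab["e_high"]).sum()
    v = tab["variance"].sum()
    if e1 == 0 or e2 == 0:
        raise ValueError("zero expected events in a stratum")
    if o1 == 0 or o2 == 0:
        raise ValueError("a stratum has no observed events")
    hr = (o1 / e1) / (o2 / e2)
    se = np.sqrt(1 / e1 + 1 / e2)
    ci = (hr * np.exp(-1.96 * se), hr * np.exp(1.96 * se))
    chi2 = (o1 - e1) ** 2 / v if v > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if v > 0 else 1.0
    return HazardRatioResult(
        hr=float(hr),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        chi_square=float(chi2),
        p_value=p,
        observed=(float(o1), float(o2)),
        expected=(float(e1), float(e2)),
        variance=float(v),
        table=tab,
    )


def truncate_at_horizon(time, event, horizon_years: float):
    """Administratively censor records beyond the horizon (default policy
    for '5-year survival' analyses)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int).copy()
    over = time > horizon_years
    time = np.where(over, horizon_years, time)
    event[over] = 0
    return time, event


def ratio_survival(
    ratios: pd.Series,
    survival: pd.DataFrame,
    horizon_years: float | None = 5.0,
) -> HazardRatioResult:
    """Median-dichotomized ratio survival analysis for one covariate.

    ``ratios`` is indexed by sample_id; ``survival`` has sample_id,
    time_years and event columns.  Records beyond the horizon are censored
    there.
    """
    surv = survival.set_index("sample_id").loc[ratios.index]
    strata = dichotomize_median(ratios.to_numpy())
    time = surv["time_years"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    if horizon_years is not None:
        time, event = truncate_at_horizon(time, event, horizon_years)
    return hazard_ratio_mh(time, event, strata)


def geo_ratio_survival(
    expression: pd.DataFrame,
    survival: pd.DataFrame,
    nos2_gene: str = "NOS2",
    cox2_gene: str = "PTGS2",
    cd8_gene: str = "CD8A",
    horizon_years: float = 5.0,
):
    """Expression-ratio survival analysis (transcriptomic validation).

    ``expression`` is genes x samples; ``survival`` has sample_id,
    time_years, event.  Per-sample NOS2/CD8A and COX2/CD8A expression
    ratios are median-dichotomized and each is tested by log-rank with a
    Mantel-Haenszel HR, events censored at the horizon.

    Returns ``{"nos2_cd8a": HazardRatioResult, "cox2_cd8a": ...}``.
    """
    for g in (nos2_gene, cox2_gene, cd8_gene):
        if g not in expression.index:
            raise KeyError(f"gene {g!r} missing from expression table")
    samples = [
        s for s in survival["sample_id"] if s in expression.columns
    ]
    missing = set(survival["sample_id"]) - set(samples)
    if missing:
        raise KeyError(f"samples missing from expression table: {sorted(missing)}")
    results = {}
    for key, gene in (("nos2_cd8a", nos2_gene), ("cox2_cd8a", cox2_gene)):
        ratios = (
            expression.loc[gene, samples] / expression.loc[cd8_gene, samples]
        ).astype(float)
        ratios.index.name = "sample_id"
        results[key] = ratio_survival(
            ratios, survival, horizon_years=horizon_years
        )
    return results
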