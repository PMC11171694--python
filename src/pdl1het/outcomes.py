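"""Survival and clinicopathological association analyses.

Overall survival runs from the date of diagnosis; the headline analyses
are 5-year analyses, so observation is administratively censored at 60
months. Patients are stratified by PD-L1 positivity of the lesion type
under study (score >= 1 vs < 1 by default), compared with Kaplan-Meier
curves and the log-rank test, and modeled with Cox proportional hazards,
univariately and adjusted for UICC stage (and p16 status in oropharyngeal
subsets).

Treatment response (RECIST, CR/PR = response vs SD/PD = no response) is
related to binary PD-L1 positivity through the contingency coefficient on
the 2x2 table rather than logistic regression, reflecting the small size
of the primary radio(chemo)therapy subgroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "SurvivalResult",
    "AssociationResult",
    "OutcomesError",
    "administrative_censor",
    "km_logrank",
    "cox_regression",
    "cox_table_by_site",
    "response_association",
]

DEFAULT_HORIZON_MONTHS = 60.0


class OutcomesError(ValueError):
    """Invalid input to a survival/association analysis."""


@dataclass
class SurvivalResult:
    """Hazard ratio (exposed vs unexposed) with CI, p and group summaries."""

    grouping: tuple[str, float]  # (scheme/column, threshold)
    model: str  # km_logrank | cox_uni | cox_multi
    hr: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    n_by_group: dict = field(default_factory=dict)
    events_by_group: dict = field(default_factory=dict)
    median_os_by_group: dict = field(default_factory=dict)
    covariates: tuple = ()
    status: str = "ok"  # ok | no_events | failed


@dataclass
class AssociationResult:
    coefficient: float
    chi2: float
    p_value: float
    n: int
    table: pd.DataFrame | None = None
    status: str = "ok"  # ok | undefined


def administrative_censor(
    times: np.ndarray, events: np.ndarray, horizon: float
) -> tuple[np.ndarray, np.ndarray]:
    """Censor follow-up at ``horizon``; never increases the event count."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    return np.minimum(t, horizon), e & (t <= horizon)


_BINARY_LEVELS = {"positive": 1.0, "negative": 0.0, True: 1.0, False: 0.0}


def _coerce_covariate(series: pd.Series) -> pd.Series:
    """Numeric view of a covariate; positive/negative and booleans map to
    1/0, anything unmappable becomes NaN and is dropped from the model."""
    if series.dtype == object:
        mapped = series.map(lambda v: _BINARY_LEVELS.get(v, v))
        return pd.to_numeric(mapped, errors="coerce")
    if series.dtype == bool:
        return series.astype(float)
    return pd.to_numeric(series, errors="coerce")


def _exposure(df: pd.DataFrame, value_col: str, threshold: float) -> pd.Series:
    if value_col not in df.columns:
        raise OutcomesError(f"missing score column {value_col!r}")
    return (df[value_col] >= threshold).astype(int)


def km_logrank(
    df: pd.DataFrame,
    value_col: str = "cps",
    threshold: float = 1.0,
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    time_col: str = "os_months",
    event_col: str = "event",
) -> tuple[SurvivalResult, pd.DataFrame]:
    """Kaplan-Meier curves and log-rank test for score-positive vs -negative.

    Returns the test summary (with the univariate HR at the same horizon
    for the headline numbers) and the KM curve coordinates per stratum.
    An empty stratum is an error naming the stratum; zero events after
    censoring yields a no-test result instead of a crash.
    """
    exposed = _exposure(df, value_col, threshold)
    times, events = administrative_censor(df[time_col].to_numpy(), df[event_col].to_numpy(), horizon_months)

    result = SurvivalResult(grouping=(value_col, threshold), model="km_logrank")
    curves = []
    for flag, label in ((0, f"{value_col}<{threshold:g}"), (1, f"{value_col}>={threshold:g}")):
        mask = (exposed == flag).to_numpy()
        if mask.sum() == 0:
            raise OutcomesError(f"empty stratum: {label}")
        kmf = KaplanMeierFitter(label=label)
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time_months", "survival"]
        sf["stratum"] = label
        curves.append(sf)
        result.n_by_group[label] = int(mask.sum())
        result.events_by_group[label] = int(events[mask].sum())
        med = kmf.median_survival_time_
        result.median_os_by_group[label] = float(med) if np.isfinite(med) else float("nan")

    if events.sum() == 0:
        result.status = "no_events"
        return result, pd.concat(curves, ignore_index=True)

    lr = logrank_test(
        times[exposed == 1], times[exposed == 0], events[exposed == 1], events[exposed == 0]
    )
    result.p_value = float(lr.p_value)
    # headline HR from the univariate Cox fit at the same horizon
    cox = cox_regression(df, value_col, covariates=(), threshold=threshold, horizon_months=horizon_months)
    result.hr, result.ci_low, result.ci_high = cox.hr, cox.ci_low, cox.ci_high
    return result, pd.concat(curves, ignore_index=True)


def cox_regression(
    df: pd.DataFrame,
    value_col: str = "cps",
    covariates: tuple[str, ...] = (),
    threshold: float = 1.0,
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
    time_col: str = "os_months",
    event_col: str = "event",
) -> SurvivalResult:
    """Cox proportional-hazards model with binary score positivity.

    ``covariates`` may include ``uicc_stage`` (ordinal I-IV coded 1-4) and
    ``p16`` (binary; only meaningful in oropharyngeal subsets). Rows with
    missing covariates are dropped. Non-convergence or degenerate designs
    are reported as ``status='failed'``, never raised.
    """
    model = "cox_uni" if not covariates else "cox_multi"
    result = SurvivalResult(grouping=(value_col, threshold), model=model, covariates=tuple(covariates))

    data = pd.DataFrame({"exposed": _exposure(df, value_col, threshold).to_numpy()})
    for cov in covariates:
        if cov not in df.columns:
            raise OutcomesError(f"missing covariate column {cov!r}")
        data[cov] = _coerce_covariate(df[cov]).to_numpy()
    t, e = administrative_censor(df[time_col].to_numpy(), df[event_col].to_numpy(), horizon_months)
    data["time"], data["event"] = t, e.astype(int)
    data = data.dropna()

    result.n_by_group = {
        "exposed": int((data["exposed"] == 1).sum()),
        "unexposed": int((data["exposed"] == 0).sum()),
    }
    result.events_by_group = {
        "exposed": int(data.loc[data["exposed"] == 1, "event"].sum()),
        "unexposed": int(data.loc[data["exposed"] == 0, "event"].sum()),
    }
    if data["event"].sum() == 0:
        result.status = "no_events"
        return result
    if data["exposed"].nunique() < 2:
        result.status = "failed"
        return result
    # perfect collinearity of a covariate with the exposure -> singular design
    for cov in covariates:
        if data[cov].nunique() > 1 and abs(np.corrcoef(data["exposed"], data[cov])[0, 1]) > 0.9999:
            result.status = "failed"
            return result

    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col="time", event_col="event")
    except Exception:
        result.status = "failed"
        return result
    result.hr = float(np.exp(cph.params_["exposed"]))
    ci = cph.confidence_intervals_
    with np.errstate(over="ignore"):  # near-separation -> infinite upper CI
        result.ci_low = float(np.exp(ci.loc["exposed"].iloc[0]))
        result.ci_high = float(np.exp(ci.loc["exposed"].iloc[1]))
    result.p_value = float(cph.summary.loc["exposed", "p"])
    return result


def cox_table_by_site(
    patients: pd.DataFrame,
    value_col: str = "cps",
    threshold: float = 1.0,
    horizon_months: float = DEFAULT_HORIZON_MONTHS,
) -> pd.DataFrame:
    """Uni- and multivariate Cox results for the whole cohort and subsites.

    Rows mirror a hazard-ratio table: HNSCC (all sites, univariate and
    stage-adjusted), OPSCC (univariate and stage+p16-adjusted), OSCC
    (univariate and stage-adjusted).
    """
    specs = [
        ("HNSCC", None, ()),
        ("HNSCC", None, ("uicc_stage",)),
        ("OPSCC", "oropharynx", ()),
        ("OPSCC", "oropharynx", ("uicc_stage", "p16")),
        ("OSCC", "oral_cavity", ()),
        ("OSCC", "oral_cavity", ("uicc_stage",)),
    ]
    rows = []
    for label, site, covs in specs:
        sub = patients if site is None else patients[patients["site"] == site]
        sub = sub.dropna(subset=[value_col])
        res = cox_regression(sub, value_col, covariates=covs, threshold=threshold, horizon_months=horizon_months)
        rows.append(
            {
                "tumor_site": label,
                "covariates": "univariate" if not covs else "+".join(covs),
                "n": sum(res.n_by_group.values()),
                "hazard_ratio": res.hr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p_value": res.p_value,
                "status": res.status,
            }
        )
    return pd.DataFrame(rows)


def response_association(
    df: pd.DataFrame,
    value_col: str = "cps",
    threshold: float = 1.0,
    response_col: str = "response",
) -> AssociationResult:
    """Contingency coefficient between binary PD-L1 positivity and response.

    C = sqrt(chi2 / (chi2 + n)) with the Pearson chi-square (no continuity
    correction) on the 2x2 table. A zero margin leaves the coefficient
    undefined (status flag, no exception).
    """
    from scipy.stats import chi2_contingency

    sub = df.dropna(subset=[value_col, response_col])
    sub = sub[sub[response_col].isin(["response", "no_response"])]
    n = len(sub)
    if n == 0:
        return AssociationResult(float("nan"), float("nan"), float("nan"), 0, None, status="undefined")
    exposed = (sub[value_col] >= threshold).map({True: "positive", False: "negative"})
    table = pd.crosstab(exposed, sub[response_col]).reindex(
        index=["negative", "positive"], columns=["no_response", "response"], fill_value=0
    )
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return AssociationResult(float("nan"), float("nan"), float("nan"), n, table, status="undefined")
    chi2, p, _, _ = chi2_contingency(arr, correction=False)
    coef = math.sqrt(chi2 / (chi2 + n))
    return AssociationResult(float(coef), float(chi2), float(p), n, table)
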