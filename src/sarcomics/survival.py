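"""Survival endpoints, Cox/Kaplan-Meier modelling and prognostic screening.

Endpoints follow the composite definitions used in sarcoma outcome studies:
local recurrence-free survival (LRFS; local recurrence or death),
metastasis-free survival (MFS; metastasis or death) and overall survival
(OS; death), all timed from primary surgery and administratively censored
at five years. Model fitting delegates to lifelines; on top sit the
per-feature hazard-ratio screen (significant when p < alpha and HR > 2 or
< 0.5 on the per-SD scale), martingale-residual cutpoint search for
non-linear continuous covariates, and the likelihood-ratio gain statistic
quantifying added prognostic information of nested Cox models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

ENDPOINTS = ("LRFS", "MFS", "OS")
FOLLOWUP_CAP_YEARS = 5.0

# raw clinical columns consumed by build_endpoints
_EVENT_COLUMNS = {
    "LRFS": ("time_to_local_recurrence", "time_to_death"),
    "MFS": ("time_to_metastasis", "time_to_death"),
    "OS": ("time_to_death",),
}


def build_endpoints(
    clinical: pd.DataFrame, cap: float = FOLLOWUP_CAP_YEARS
) -> pd.DataFrame:
    """Construct tidy records (sample, endpoint, time, event) from raw events.

    Composite endpoints take the earliest component event; event-free
    samples are censored at last follow-up, administratively capped.
    Records with non-positive follow-up are rejected with a logged reason.
    """
    required = {"last_followup"} | {c for cols in _EVENT_COLUMNS.values() for c in cols}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table lacks columns: {sorted(missing)}")
    rows = []
    for sample, rec in clinical.iterrows():
        if not rec["last_followup"] > 0:
            logger.warning("sample %s rejected: non-positive follow-up", sample)
            continue
        for ep, cols in _EVENT_COLUMNS.items():
            times = [rec[c] for c in cols if pd.notna(rec[c])]
            if times and min(times) <= 0:
                logger.warning("sample %s rejected for %s: non-positive event time",
                               sample, ep)
                continue
            if times and min(times) <= cap:
                t, e = min(times), 1
            else:
                t, e = min(rec["last_followup"], cap), 0
            rows.append({"sample": sample, "endpoint": ep, "time": float(t),
                         "event": e})
    return pd.DataFrame(rows)


def endpoint_frame(records: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    sub = records[records["endpoint"] == endpoint]
    return sub.set_index("sample")[["time", "event"]]


@dataclass
class CoxFit:
    summary: pd.DataFrame  # coef, HR, CI bounds, Wald p per covariate
    log_likelihood: float
    llr_chi2: float
    df: int
    n: int
    n_events: int
    covariates: list[str]
    warnings_: list[str] = field(default_factory=list)

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.summary["HR"]


def cox_fit(
    records: pd.DataFrame,
    covariates: pd.DataFrame,
    endpoint: str | None = None,
    ties: str = "efron",
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) via lifelines.

    ``records`` is either tidy (with an ``endpoint`` column, select one) or
    already a (time, event) frame indexed by sample. Monotone-likelihood /
    separation problems surface as a flagged warning, mirroring screens
    where extreme hazard ratios make estimates unstable.
    """
    if "endpoint" in records.columns:
        if endpoint is None:
            raise ValueError("select an endpoint from the tidy records")
        records = endpoint_frame(records, endpoint)
    df = covariates.join(records[["time", "event"]], how="inner")
    if df["event"].sum() < 1:
        raise ValueError("need at least one event")
    for c in covariates.columns:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    cph = CoxPHFitter()
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as err:
            raise ValueError(f"Cox model did not converge: {err}") from err
        for w in wlist:
            caught.append(str(w.message))
    if any("infinite" in m or "convergence" in m.lower() for m in caught):
        logger.warning("possible monotone likelihood / extreme hazard ratio")

    summ = cph.summary
    out = pd.DataFrame(
        {
            "coef": summ["coef"],
            "HR": summ["exp(coef)"],
            "HR_lower95": summ["exp(coef) lower 95%"],
            "HR_upper95": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    llr = cph.log_likelihood_ratio_test()
    return CoxFit(
        summary=out,
        log_likelihood=float(cph.log_likelihood_),
        llr_chi2=float(llr.test_statistic),
        df=len(covariates.columns),
        n=len(df),
        n_events=int(df["event"].sum()),
        covariates=list(covariates.columns),
        warnings_=caught,
    )


@dataclass
class KmResult:
    fitters: dict[str, KaplanMeierFitter]
    logrank_chi2: float | None
    logrank_p: float | None


def km_fit(
    records: pd.DataFrame,
    groups: pd.Series,
    endpoint: str | None = None,
) -> KmResult:
    """Kaplan-Meier curves per group with a log-rank comparison."""
    if "endpoint" in records.columns:
        if endpoint is None:
            raise ValueError("select an endpoint from the tidy records")
        records = endpoint_frame(records, endpoint)
    declared = set(groups.dropna().unique())
    groups = groups.reindex(records.index)
    present = set(groups.dropna().unique())
    if declared - present:
        raise ValueError(f"empty group(s): {sorted(declared - present)}")
    fitters = {}
    for g in sorted(present):
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter(label=str(g))
        kmf.fit(records["time"][mask], records["event"][mask])
        fitters[str(g)] = kmf
    if len(fitters) >= 2:
        lr = multivariate_logrank_test(
            records["time"], groups.astype(str), records["event"]
        )
        return KmResult(fitters, float(lr.test_statistic), float(lr.p_value))
    return KmResult(fitters, None, None)


def _uni_cox(time, event, x) -> tuple[float, float, bool]:
    """Univariable Cox HR and Wald p; flag False when unstable."""
    df = pd.DataFrame({"time": time, "event": event, "x": x})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception:
        return np.nan, np.nan, False
    coef = float(cph.params_["x"])
    if abs(coef) > 15:  # monotone likelihood: HR astronomically large
        return np.exp(coef), float(cph.summary.loc["x", "p"]), False
    return float(np.exp(coef)), float(cph.summary.loc["x", "p"]), True


def screen_features(
    matrix: pd.DataFrame,
    records: pd.DataFrame,
    hr_bounds: tuple[float, float] = (0.5, 2.0),
    alpha: float = 0.05,
    endpoints: tuple[str, ...] = ENDPOINTS,
    standardize: bool = True,
) -> tuple[pd.DataFrame, dict[str, set[str]], set[str]]:
    """Univariable Cox screen of every feature row against each endpoint.

    Expression is standardised per feature (HR per SD) before fitting.
    Significant = converged, p < alpha and HR above/below the bounds.
    Returns the full table, per-endpoint significant sets, and the
    intersection across all endpoints.
    """
    lo, hi = hr_bounds
    X = matrix.copy()
    if standardize:
        mu, sd = X.mean(axis=1), X.std(axis=1, ddof=0)
        X = X.sub(mu, axis=0).div(sd.where(sd > 0, 1.0), axis=0)
    rows = []
    sig: dict[str, set[str]] = {ep: set() for ep in endpoints}
    for ep in endpoints:
        rec = endpoint_frame(records, ep)
        common = rec.index.intersection(X.columns)
        if len(common) == 0:
            raise ValueError("records and matrix share no samples")
        rec = rec.loc[common]
        for feat in X.index:
            hr, p, ok = _uni_cox(
                rec["time"].to_numpy(),
                rec["event"].to_numpy(),
                X.loc[feat, common].to_numpy(),
            )
            significant = bool(ok and p < alpha and (hr > hi or hr < lo))
            if significant:
                sig[ep].add(feat)
            rows.append(
                {"feature": feat, "endpoint": ep, "HR": hr, "p": p,
                 "converged": ok, "significant": significant}
            )
    table = pd.DataFrame(rows)
    all_ep = set.intersection(*(sig[ep] for ep in endpoints)) if endpoints else set()
    return table, sig, all_ep


@dataclass
class CutpointResult:
    cutpoint: float
    used_fallback: bool
    covariate_grid: np.ndarray
    smoothed_residuals: np.ndarray


def martingale_cutpoint(
    records: pd.DataFrame,
    covariate: pd.Series,
    endpoint: str | None = None,
    log_transform: bool = True,
    span: float = 0.5,
) -> CutpointResult:
    """Optimal split of a continuous covariate from null-model martingale
    residuals.

    Residuals (event indicator minus Nelson-Aalen cumulative hazard at the
    observed time) are smoothed against the (log-transformed) covariate
    with a running-line smoother; the cutpoint is the zero crossing nearest
    the steepest smoothed slope. Without a crossing the median is returned
    with a warning.
    """
    if "endpoint" in records.columns:
        if endpoint is None:
            raise ValueError("select an endpoint from the tidy records")
        records = endpoint_frame(records, endpoint)
    covariate = covariate.reindex(records.index).dropna()
    if covariate.nunique() < 10:
        raise ValueError("covariate needs at least 10 distinct values")
    rec = records.loc[covariate.index]

    naf = NelsonAalenFitter()
    naf.fit(rec["time"], rec["event"])
    cumhaz = naf.cumulative_hazard_at_times(rec["time"]).to_numpy()
    resid = rec["event"].to_numpy() - cumhaz

    x = covariate.to_numpy(float)
    xt = np.log(x) if log_transform else x

    # a cutpoint is only meaningful if residuals track the covariate at all
    rho, rho_p = stats.spearmanr(xt, resid)
    if np.isnan(rho) or rho_p >= 0.05:
        warnings.warn("covariate shows no association with martingale "
                      "residuals; falling back to the median", stacklevel=2)
        order0 = np.argsort(xt, kind="stable")
        return CutpointResult(
            float(np.median(x)), True, x[order0], np.zeros(x.size)
        )

    order = np.argsort(xt, kind="stable")
    xs, rs = xt[order], resid[order]
    n = xs.size
    half = max(int(span * n) // 2, 2)
    smooth = np.empty(n)
    slope = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        b, a = np.polyfit(xs[lo:hi], rs[lo:hi], 1)
        smooth[i] = b * xs[i] + a
        slope[i] = b

    crossings = np.where(np.diff(np.sign(smooth)) != 0)[0]
    raw_sorted = x[order]
    if crossings.size == 0:
        warnings.warn("no zero crossing in smoothed residuals; falling back "
                      "to the median", stacklevel=2)
        return CutpointResult(float(np.median(x)), True, raw_sorted, smooth)
    steep = crossings[np.argmax(np.abs(slope[crossings]))]
    cut = float((raw_sorted[steep] + raw_sorted[steep + 1]) / 2.0)
    return CutpointResult(cut, False, raw_sorted, smooth)


@dataclass
class LrGain:
    base_chi2: float
    extended_chi2: float
    delta_chi2: float
    gain_pct: float
    df_diff: int
    p: float


def lr_gain(base: CoxFit, extended: CoxFit) -> LrGain:
    """Relative gain in prognostic information of a nested Cox extension.

    gain% = 100 * (LRchi2_ext - LRchi2_base) / LRchi2_base; the added
    parameters give the chi-square df for the improvement test.
    """
    if not set(base.covariates) <= set(extended.covariates):
        raise ValueError("models are not nested")
    if base.n != extended.n or base.n_events != extended.n_events:
        raise ValueError("models must be fitted on the same records")
    delta = extended.llr_chi2 - base.llr_chi2
    df_diff = extended.df - base.df
    if base.llr_chi2 == 0 and delta == 0:
        gain = 0.0
    else:
        gain = 100.0 * delta / base.llr_chi2
    p = float(stats.chi2.sf(max(delta, 0.0), df_diff)) if df_diff > 0 else 1.0
    return LrGain(
        base_chi2=base.llr_chi2,
        extended_chi2=extended.llr_chi2,
        delta_chi2=delta,
        gain_pct=gain,
        df_diff=df_diff,
        p=p,
    )
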