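"""Kaplan-Meier, log-rank, and Cox proportional-hazards machinery.

All three estimators are implemented from first principles: the
product-limit estimator with Greenwood's variance, the two-group log-rank
test with hypergeometric variance, and Cox partial-likelihood maximisation
by Newton-Raphson with Efron's tie correction (Breslow optional).  These
are the core statistical engines of the pipeline; established
implementations serve only as cross-checks in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, NumericalError

Z95 = 1.959964  # normal quantile for the fixed 95% confidence level

CAUSE_SPECIFIC_DEFAULT = frozenset({"infections_parasites", "circulatory"})

COVARIATE_BLOCKS = {
    "age": ("age_30_40", "age_ge40"),
    "sex": ("female",),
    "chm": ("chm_user",),
    "cci": ("cci_1_2", "cci_ge3"),
}
ADJUSTED_COVARIATES = ("age_30_40", "age_ge40", "female", "chm_user",
                       "cci_1_2", "cci_ge3")


@dataclass
class SurvivalCurve:
    """Product-limit estimate over the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_var: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "at_risk": self.at_risk,
            "events": self.events,
            "survival": self.survival,
            "greenwood_var": self.greenwood_var,
        })

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class CoxFit:
    coefficients: dict[str, float]
    covariance: np.ndarray
    hr: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    p: dict[str, float]
    loglik0: float
    loglik: float
    ties_method: str
    n: int
    n_events: int
    iterations: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for cov, beta in self.coefficients.items():
            rows.append({
                "covariate": cov,
                "coef": beta,
                "hr": self.hr[cov],
                "ci_low": self.ci_low[cov],
                "ci_high": self.ci_high[cov],
                "p": self.p[cov],
            })
        return pd.DataFrame(rows)


def _check_survival_input(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if len(time) == 0:
        raise DataError("empty survival input")
    if np.any(time <= 0):
        raise DataError("follow-up times must be positive")
    return time, event


def km_estimate(time, event, label: str = "") -> SurvivalCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    Subjects censored exactly at an event time are counted at risk at that
    time (the usual convention).
    """
    time, event = _check_survival_input(time, event)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    ev_times = np.unique(time[event])
    n = len(time)
    at_risk = n - np.searchsorted(time, ev_times, side="left")
    te = np.sort(time[event])
    d = (np.searchsorted(te, ev_times, side="right")
         - np.searchsorted(te, ev_times, side="left"))
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.nan)
        gw = surv**2 * np.nancumsum(terms)
    gw = np.where(np.isnan(gw), 0.0, gw)
    return SurvivalCurve(ev_times, at_risk, d, surv, gw, label)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) on 1 df."""
    time, event = _check_survival_input(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise DataError(f"log-rank needs exactly two groups, got {len(labels)}")
    g1 = group == labels[1]
    ev_times = np.unique(time[event])

    def _counts(t_sorted, ev_sorted):
        at = len(t_sorted) - np.searchsorted(t_sorted, ev_times, side="left")
        d = (np.searchsorted(ev_sorted, ev_times, side="right")
             - np.searchsorted(ev_sorted, ev_times, side="left"))
        return at.astype(float), d.astype(float)

    n_at, d_tot = _counts(np.sort(time), np.sort(time[event]))
    n1_at, d1 = _counts(np.sort(time[g1]), np.sort(time[g1 & event]))
    keep = n_at > 1
    n_at, d_tot, n1_at, d1 = n_at[keep], d_tot[keep], n1_at[keep], d1[keep]
    frac1 = n1_at / n_at
    O_minus_E = float((d1 - d_tot * frac1).sum())
    V = float((d_tot * frac1 * (1 - frac1) * (n_at - d_tot) / (n_at - 1)).sum())
    if V <= 0:
        return 0.0, 1.0
    chi2 = O_minus_E**2 / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Cox proportional hazards


class _CoxData:
    """Time-sorted design with per-event-time group structure."""

    def __init__(self, time, event, X):
        order = np.argsort(time, kind="stable")
        self.t = time[order]
        self.e = event[order]
        self.x = X[order]
        ev_idx = np.flatnonzero(self.e)
        ev_t = self.t[ev_idx]
        starts = np.flatnonzero(np.r_[True, ev_t[1:] != ev_t[:-1]])
        self.ev_idx = ev_idx
        self.grp_start = starts
        bounds = np.r_[starts, len(ev_idx)]
        self.d = np.diff(bounds)
        # first row of each group's risk set in the sorted full array
        self.risk_pos = np.searchsorted(self.t, ev_t[starts], side="left")
        rep = np.repeat(np.arange(len(starts)), self.d)
        within = np.arange(len(ev_idx)) - starts[rep]
        self.rep = rep
        self.frac = within / self.d[rep]  # Efron fractions l/d
        self.xd = self.x[ev_idx]
        self.xd_sum = np.add.reduceat(self.xd, starts, axis=0).sum(axis=0)


def _cox_quantities(data: "_CoxData", beta, ties, want_derivs=True):
    """Log partial likelihood (and optionally score and information)."""
    x = data.x
    eta = x @ beta
    eta = eta - eta.max()  # common shift cancels in all ratios
    theta = np.exp(eta)
    S0 = np.cumsum(theta[::-1])[::-1][data.risk_pos]
    td = theta[data.ev_idx]
    s0d = np.add.reduceat(td, data.grp_start)
    frac = data.frac if ties == "efron" else np.zeros_like(data.frac)
    rep = data.rep
    den = S0[rep] - frac * s0d[rep]
    loglik = float(eta[data.ev_idx].sum() - np.log(den).sum())
    if not want_derivs:
        return loglik, None, None
    S1 = np.cumsum((theta[:, None] * x)[::-1], axis=0)[::-1][data.risk_pos]
    s1d = np.add.reduceat(td[:, None] * data.xd, data.grp_start, axis=0)
    z = (S1[rep] - frac[:, None] * s1d[rep]) / den[:, None]
    score = data.xd_sum - z.sum(axis=0)
    S2 = np.cumsum(
        (theta[:, None, None] * (x[:, :, None] * x[:, None, :]))[::-1], axis=0
    )[::-1][data.risk_pos]
    s2d = np.add.reduceat(
        td[:, None, None] * (data.xd[:, :, None] * data.xd[:, None, :]),
        data.grp_start, axis=0,
    )
    term1 = ((S2[rep] - frac[:, None, None] * s2d[rep])
             / den[:, None, None]).sum(axis=0)
    info = term1 - np.einsum("ep,eq->pq", z, z)
    return loglik, score, info


def cox_fit(
    data: pd.DataFrame,
    covariates,
    time_col: str = "time",
    event_col: str = "event",
    ties: str = "efron",
    tol: float = 1e-9,
    max_iter: int = 60,
) -> CoxFit:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``ties`` selects Efron's (default) or Breslow's handling of tied event
    times.  Wald confidence intervals and p-values use the fixed 95% normal
    quantile.
    """
    if ties not in ("efron", "breslow"):
        raise DataError(f"unknown ties method {ties!r}")
    covariates = list(covariates)
    time, event = _check_survival_input(data[time_col], data[event_col])
    if event.sum() == 0:
        raise DataError("no events in survival data")
    X = data[covariates].to_numpy(dtype=float)
    const = X.min(axis=0) == X.max(axis=0)
    if const.any():
        bad = [c for c, b in zip(covariates, const) if b]
        raise DataError(f"constant covariates: {bad}")
    scale = X.std(axis=0)
    center = X.mean(axis=0)
    Xs = (X - center) / scale
    p = Xs.shape[1]
    data = _CoxData(time, event, Xs)
    beta = np.zeros(p)
    loglik0, _, _ = _cox_quantities(data, beta, ties, want_derivs=False)
    ll = loglik0
    trace = [ll]
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        ll, score, info = _cox_quantities(data, beta, ties)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise NumericalError("singular information matrix in Cox fit") from exc
        # step-halving to keep the partial likelihood non-decreasing
        new_beta = beta + step
        new_ll, _, _ = _cox_quantities(data, new_beta, ties, want_derivs=False)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step = step / 2.0
            new_beta = beta + step
            new_ll, _, _ = _cox_quantities(data, new_beta, ties, want_derivs=False)
            halvings += 1
        beta = new_beta
        trace.append(new_ll)
    if not converged:
        ll, score, info = _cox_quantities(data, beta, ties)
        if np.max(np.abs(score)) >= 1e-5:
            raise NumericalError(
                f"Cox fit did not converge in {max_iter} iterations; "
                f"log-likelihood trace: {[round(v, 4) for v in trace[-5:]]}"
            )
    if np.max(np.abs(beta / scale.clip(1e-12))) > 50:
        worst = covariates[int(np.argmax(np.abs(beta)))]
        warnings.warn(
            f"possibly monotone partial likelihood for covariate {worst!r}",
            RuntimeWarning, stacklevel=2,
        )
    ll, score, info = _cox_quantities(data, beta, ties)
    cov_s = np.linalg.inv(info)
    # back-transform from the standardised scale
    beta_raw = beta / scale
    cov_raw = cov_s / np.outer(scale, scale)
    se = np.sqrt(np.diag(cov_raw))
    coef = dict(zip(covariates, beta_raw))
    hr = {c: float(np.exp(b)) for c, b in coef.items()}
    ci_lo = {c: float(np.exp(coef[c] - Z95 * s)) for c, s in zip(covariates, se)}
    ci_hi = {c: float(np.exp(coef[c] + Z95 * s)) for c, s in zip(covariates, se)}
    pvals = {
        c: float(2 * stats.norm.sf(abs(coef[c] / s)))
        for c, s in zip(covariates, se)
    }
    return CoxFit(
        coefficients={c: float(v) for c, v in coef.items()},
        covariance=cov_raw,
        hr=hr, ci_low=ci_lo, ci_high=ci_hi, p=pvals,
        loglik0=float(loglik0), loglik=float(ll),
        ties_method=ties, n=len(time), n_events=int(event.sum()),
        iterations=it,
    )


# ---------------------------------------------------------------------------
# Cohort-level analyses


def cause_specific_subset(
    cohort: pd.DataFrame,
    categories=CAUSE_SPECIFIC_DEFAULT,
) -> pd.DataFrame:
    """Restrict to the cause-specific mortality design.

    Deaths from the listed categories remain events; censored subjects
    remain censored; deaths from any other category are removed from the
    analysis set entirely (the study design, distinct from competing-risks
    censoring).
    """
    categories = set(categories)
    ev = cohort["event"].astype(bool)
    other = ev & ~cohort["cause_category"].isin(categories)
    return cohort.loc[~other].copy()


@dataclass
class MortalityAnalysis:
    outcome: str
    curves: dict[str, SurvivalCurve]
    logrank_chi2: float
    logrank_p: float
    crude: dict[str, CoxFit]
    adjusted: CoxFit
    n: int
    n_events: int
    subgroup: str | None = None


def _analysis_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    df["time"] = df["followup_days"].astype(float)
    df["age_30_40"] = (df["age_band"] == "30to40").astype(int)
    df["age_ge40"] = (df["age_band"] == "ge40").astype(int)
    df["cci_1_2"] = (df["cci_group"] == "1-2").astype(int)
    df["cci_ge3"] = (df["cci_group"] == ">=3").astype(int)
    return df


def run_mortality_analysis(
    cohort: pd.DataFrame,
    matched=None,
    outcome: str = "all_cause",
    extra_covariates: tuple[str, ...] = (),
    subgroup: str | None = None,
    ties: str = "efron",
) -> MortalityAnalysis:
    """Kaplan-Meier curves, log-rank test, per-block crude Cox fits, and
    the adjusted Cox model for one mortality outcome.

    ``matched`` (a :class:`~herbsurv.psm.MatchedSet`) restricts the analysis
    to the matched sample.  ``outcome`` is ``"all_cause"`` or
    ``"infect_circ"`` (infections/parasites and circulatory deaths, with
    other-cause deaths removed).  ``subgroup`` filters on a neurological
    subtype (e.g. ``"cns_infection"``); ``extra_covariates`` are appended to
    the adjusted model (e.g. ``("interval_days",)`` for the sensitivity
    model adjusting for the neuro-to-index interval).
    """
    df = cohort
    if matched is not None:
        keep = set(matched.user_ids) | set(matched.control_ids)
        df = df.loc[df["patient_id"].isin(keep)]
    if subgroup:
        df = df.loc[df["neuro_subtypes"].str.contains(subgroup, regex=False)]
    if outcome == "infect_circ":
        df = cause_specific_subset(df)
    elif outcome != "all_cause":
        raise DataError(f"unknown outcome {outcome!r}")
    df = _analysis_frame(df)

    curves = {
        "chm_user": km_estimate(
            df.loc[df["chm_user"] == 1, "time"],
            df.loc[df["chm_user"] == 1, "event"], label="chm_user"),
        "non_user": km_estimate(
            df.loc[df["chm_user"] == 0, "time"],
            df.loc[df["chm_user"] == 0, "event"], label="non_user"),
    }
    chi2, p = logrank_test(df["time"], df["event"], df["chm_user"])
    def _nonconstant(covs):
        kept = [c for c in covs if df[c].nunique() > 1]
        dropped = sorted(set(covs) - set(kept))
        if dropped:
            warnings.warn(
                f"dropping constant covariates {dropped} from the Cox model",
                RuntimeWarning, stacklevel=2)
        return kept

    crude = {}
    for block, covs in COVARIATE_BLOCKS.items():
        kept = _nonconstant(list(covs))
        if kept:
            crude[block] = cox_fit(df, kept, ties=ties)
    adjusted = cox_fit(
        df, _nonconstant(list(ADJUSTED_COVARIATES) + list(extra_covariates)),
        ties=ties)
    return MortalityAnalysis(
        outcome=outcome, curves=curves, logrank_chi2=chi2, logrank_p=p,
        crude=crude, adjusted=adjusted,
        n=len(df), n_events=int(df["event"].sum()), subgroup=subgroup,
    )
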