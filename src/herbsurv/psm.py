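"""Propensity-score estimation and 1:2 nearest-neighbour matching.

The exposure model is a maximum-likelihood logistic regression fitted by
Newton-Raphson (implemented here rather than delegated, so the matching
pipeline is self-contained and auditable).  Matching is greedy nearest
neighbour on the logit of the propensity score, without replacement, with a
caliper expressed as a multiple of the standard deviation of the logit
scores — the standard recommendation for claims studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, NumericalError

DEFAULT_COVARIATES = ("female", "age_30_40", "age_ge40", "cci_score",
                      "index_duration_days")


@dataclass
class PropensityModel:
    coefficients: dict[str, float]
    fitted_scores: pd.Series  # indexed by patient_id, values in (0,1)
    iterations: int
    gradient_norm: float
    covariates: tuple[str, ...]

    @property
    def logit_scores(self) -> pd.Series:
        p = self.fitted_scores
        return np.log(p / (1.0 - p))


@dataclass
class MatchedSet:
    triples: list[tuple[str, ...]]  # (user_id, control_1, ..., control_k)
    unmatched_users: list[str]
    caliper: float
    k: int = 2

    @property
    def user_ids(self) -> list[str]:
        return [t[0] for t in self.triples]

    @property
    def control_ids(self) -> list[str]:
        return [c for t in self.triples for c in t[1:]]

    def to_frame(self) -> pd.DataFrame:
        cols = ["user_id"] + [f"control_id_{i}" for i in range(1, self.k + 1)]
        return pd.DataFrame(self.triples, columns=cols)


def design_matrix(cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES):
    """Expand the matching covariates into a numeric design matrix.

    Age enters as band indicators; sex as a female indicator; Charlson
    score and index duration as continuous columns.
    """
    cols = {}
    for cov in covariates:
        if cov == "age_30_40":
            cols[cov] = (cohort["age_band"] == "30to40").astype(float)
        elif cov == "age_ge40":
            cols[cov] = (cohort["age_band"] == "ge40").astype(float)
        elif cov in ("cci_1_2", "cci_ge3"):
            label = "1-2" if cov == "cci_1_2" else ">=3"
            cols[cov] = (cohort["cci_group"] == label).astype(float)
        else:
            cols[cov] = cohort[cov].astype(float)
    X = pd.DataFrame(cols, index=cohort.index)
    if X.isna().any().any():
        raise DataError("missing covariate values in propensity design")
    return X


def _logistic_newton(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                     max_iter: int = 50):
    n, p = X.shape
    beta = np.zeros(p)
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            return beta, it, float(np.max(np.abs(score)))
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(
                "singular information matrix: collinear covariates among "
                f"{list(range(p))}"
            ) from exc
        beta = beta + step
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    gnorm = float(np.max(np.abs(X.T @ (y - mu))))
    if gnorm > 1e-4:
        raise NumericalError(
            f"logistic fit did not converge in {max_iter} iterations "
            f"(gradient norm {gnorm:.3g}); possible complete separation — "
            "consider exact matching without a propensity model"
        )
    return beta, it, gnorm


def fit_logistic_ps(
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    exposure_col: str = "chm_user",
) -> PropensityModel:
    """Fit the exposure propensity model by Newton-Raphson.

    Continuous covariates are standardised internally for numerical
    stability; reported coefficients are on the original scale.
    """
    y = cohort[exposure_col].astype(float).to_numpy()
    if y.min() == y.max():
        raise DataError("need at least one exposed and one unexposed subject")
    Xdf = design_matrix(cohort, covariates)
    X = Xdf.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale
    Xs = np.column_stack([np.ones(len(y)), Xs])
    beta_s, it, gnorm = _logistic_newton(Xs, y)
    # map back to the raw scale
    beta = beta_s[1:] / scale
    intercept = beta_s[0] - float(np.sum(beta_s[1:] * mean / scale))
    eta = intercept + X @ beta
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    coef = {"intercept": float(intercept)}
    coef.update({c: float(b) for c, b in zip(Xdf.columns, beta)})
    scores = pd.Series(p, index=cohort["patient_id"].to_numpy())
    return PropensityModel(coef, scores, it, gnorm, tuple(Xdf.columns))


def match_1_to_k(
    model: PropensityModel,
    exposure: pd.Series,
    k: int = 2,
    caliper_sd_mult: float = 0.2,
    seed: int = 0,
) -> MatchedSet:
    """Greedy 1:k nearest-neighbour matching on logit propensity.

    Users are processed in random order under ``seed``; controls are drawn
    without replacement; users with fewer than ``k`` in-caliper controls are
    dropped.  ``exposure`` is a 0/1 series indexed like the fitted scores.
    """
    logit = model.logit_scores
    exposure = exposure.reindex(logit.index)
    caliper = float(caliper_sd_mult * np.std(logit.to_numpy(), ddof=1)) \
        if caliper_sd_mult is not None else np.inf
    users = logit[exposure == 1]
    controls = logit[exposure == 0]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(users))

    c_ids = controls.index.to_numpy()
    c_vals = controls.to_numpy(dtype=float)
    sort = np.argsort(c_vals, kind="stable")
    c_ids, c_vals = c_ids[sort], c_vals[sort]
    used = np.zeros(len(c_ids), dtype=bool)

    triples: list[tuple[str, ...]] = []
    unmatched: list[str] = []
    for idx in order:
        uid = users.index[idx]
        uval = float(users.iloc[idx])
        pos = int(np.searchsorted(c_vals, uval))
        lo, hi = pos - 1, pos
        picks: list[int] = []
        while len(picks) < k:
            # advance pointers past consumed controls
            while lo >= 0 and used[lo]:
                lo -= 1
            while hi < len(c_vals) and used[hi]:
                hi += 1
            dl = uval - c_vals[lo] if lo >= 0 else np.inf
            dr = c_vals[hi] - uval if hi < len(c_vals) else np.inf
            if dl <= dr:
                if not np.isfinite(dl) or dl > caliper:
                    break
                picks.append(lo)
                lo -= 1
            else:
                if not np.isfinite(dr) or dr > caliper:
                    break
                picks.append(hi)
                hi += 1
        if len(picks) == k:
            for j in picks:
                used[j] = True
            triples.append((uid, *c_ids[picks]))
        else:
            unmatched.append(uid)
    if not triples:
        import logging
        logging.getLogger(__name__).warning(
            "matching produced no matched sets (caliper %.4f)", caliper)
    return MatchedSet(triples, unmatched, caliper, k)


def standardized_mean_differences(
    cohort: pd.DataFrame,
    user_ids,
    control_ids,
    covariates=DEFAULT_COVARIATES,
) -> pd.Series:
    """Absolute standardised mean differences between arms, the balance
    metric matched covariates are judged by (values < 0.1 indicate
    acceptable balance)."""
    X = design_matrix(cohort, covariates)
    X = X.set_index(cohort["patient_id"].to_numpy())
    xu = X.loc[X.index.intersection(pd.Index(user_ids))]
    xc = X.loc[X.index.intersection(pd.Index(control_ids))]
    mu, mc = xu.mean(), xc.mean()
    vu, vc = xu.var(ddof=1), xc.var(ddof=1)
    pooled = np.sqrt((vu + vc) / 2.0)
    smd = (mu - mc).abs() / pooled.replace(0.0, np.nan)
    return smd.fillna(0.0)


def balance_table(
    matched: MatchedSet,
    cohort: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-covariate arm summaries and SMDs for the matched sample."""
    if not matched.triples:
        raise DataError("empty matched set")
    by_id = cohort.set_index("patient_id")
    X = design_matrix(cohort, covariates).set_axis(
        cohort["patient_id"].to_numpy(), axis=0)
    xu = X.loc[matched.user_ids]
    xc = X.loc[matched.control_ids]
    smd = standardized_mean_differences(
        cohort, matched.user_ids, matched.control_ids, covariates)
    rows = []
    for cov in X.columns:
        rows.append({
            "covariate": cov,
            "user_mean": float(xu[cov].mean()),
            "user_sd": float(xu[cov].std(ddof=1)),
            "control_mean": float(xc[cov].mean()),
            "control_sd": float(xc[cov].std(ddof=1)),
            "smd": float(smd[cov]),
        })
    del by_id
    return pd.DataFrame(rows)
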