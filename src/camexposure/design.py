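"""Design-based weighted Poisson rate estimation.

Children are sampled in a stratified two-stage design (schools within
ethnicity x school-decile strata, children within schools) with unequal
sampling weights, so ordinary Poisson-GLM standard errors are invalid.
This module fits the weighted Poisson log-likelihood

    l(beta) = sum_i w_i [ y_i (x_i'beta + o_i) - exp(x_i'beta + o_i) ]

by iteratively reweighted least squares (IRLS), where ``o_i = log(exposure
time)`` is the offset, and estimates the covariance with the stratified
between-cluster linearised (Taylor/sandwich) estimator used by survey
software: weighted score residuals are summed within each cluster (school),
centred within stratum, and combined with the stratum factor
``n_h / (n_h - 1)``. Confidence intervals use a t reference with the design
degrees of freedom (number of clusters minus number of strata, by default;
the rule is configurable). Rate ratios are exponentiated coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .rates import DAY_SECONDS

__all__ = [
    "SurveyDesign",
    "ModelFit",
    "WaldTest",
    "fit_weighted_poisson",
    "estimate_margin_rates",
    "build_design_matrix",
    "fit_models",
    "wald_interaction_test",
    "stratified_rate_ratios",
]


class FitError(RuntimeError):
    pass


@dataclass
class SurveyDesign:
    """Stratum, cluster and weight for each analysis unit (child).

    Clusters must be nested in strata: one school cannot belong to two
    strata. ``df_rule`` selects the design degrees of freedom used for t
    intervals and Wald-F denominators: ``"clusters_minus_strata"`` (the
    standard survey rule) or ``"clusters_minus_one"``.
    """

    strata: np.ndarray
    clusters: np.ndarray
    weights: np.ndarray
    df_rule: str = "clusters_minus_strata"

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        self.clusters = np.asarray(self.clusters)
        self.weights = np.asarray(self.weights, float)
        if not (len(self.strata) == len(self.clusters) == len(self.weights)):
            raise ValueError("strata, clusters, weights must have equal length")
        if (self.weights <= 0).any():
            raise ValueError("weights must be positive")
        nesting = pd.DataFrame({"c": self.clusters, "s": self.strata})
        if (nesting.groupby("c", observed=True)["s"].nunique() > 1).any():
            raise ValueError("clusters must be nested within strata")
        if self.df_rule not in ("clusters_minus_strata", "clusters_minus_one"):
            raise ValueError(f"unknown df rule: {self.df_rule!r}")

    @classmethod
    def from_children(cls, children: pd.DataFrame, df_rule: str = "clusters_minus_strata") -> "SurveyDesign":
        strata = (
            children["ethnicity"].astype(str) + ":" + children["decile_group"].astype(str)
        ).to_numpy()
        return cls(
            strata=strata,
            clusters=children["school_id"].to_numpy(),
            weights=children["sampling_weight"].to_numpy(float),
            df_rule=df_rule,
        )

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        return SurveyDesign(
            self.strata[mask], self.clusters[mask], self.weights[mask], self.df_rule
        )

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.clusters))

    @property
    def n_strata(self) -> int:
        return len(np.unique(self.strata))

    @property
    def df(self) -> int:
        if self.df_rule == "clusters_minus_one":
            return self.n_clusters - 1
        return self.n_clusters - self.n_strata


@dataclass
class ModelFit:
    """A fitted design-based weighted Poisson model."""

    params: pd.Series  # log-rate scale
    cov: pd.DataFrame  # design-based covariance
    df: int
    n_obs: int
    converged: bool
    n_iter: int
    ci_level: float = 0.95
    separation: list = field(default_factory=list)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def conf_int(self) -> pd.DataFrame:
        """t-based CI on the log-rate scale with the design df."""
        tcrit = stats.t.ppf(0.5 + self.ci_level / 2, self.df)
        se = self.se
        return pd.DataFrame(
            {"ci_low": self.params - tcrit * se, "ci_high": self.params + tcrit * se}
        )

    def rate_ratios(self) -> pd.DataFrame:
        """Exponentiated coefficients with CIs (``rr, ci_low, ci_high``)."""
        ci = self.conf_int()
        out = pd.DataFrame(
            {
                "rr": np.exp(self.params),
                "ci_low": np.exp(ci["ci_low"]),
                "ci_high": np.exp(ci["ci_high"]),
            }
        )
        for name in self.separation:
            out.loc[name, ["ci_low", "ci_high"]] = [0.0, np.inf]
        return out

    def rate_per_day(self, day_seconds: float = DAY_SECONDS) -> tuple:
        """Intercept rate per reporting day with its CI (intercept-only fits)."""
        ci = self.conf_int()
        i = self.params.index[0]
        return (
            float(np.exp(self.params[i]) * day_seconds),
            float(np.exp(ci.loc[i, "ci_low"]) * day_seconds),
            float(np.exp(ci.loc[i, "ci_high"]) * day_seconds),
        )


@dataclass
class WaldTest:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def _cluster_sandwich(
    X: np.ndarray, resid_scores: np.ndarray, design: SurveyDesign, bread_inv: np.ndarray
) -> np.ndarray:
    """Stratified between-cluster linearised covariance.

    ``resid_scores`` are the per-unit weighted score residuals
    ``w_i (y_i - mu_i) x_i``. Cluster totals are centred within stratum and
    scaled by ``n_h / (n_h - 1)``; a stratum with a single cluster
    contributes its uncentred cluster total (no finite variance estimate
    exists within such a stratum).
    """
    p = X.shape[1]
    meat = np.zeros((p, p))
    strata = design.strata
    for h in np.unique(strata):
        in_h = strata == h
        z = (
            pd.DataFrame(resid_scores[in_h])
            .groupby(design.clusters[in_h])
            .sum()
            .to_numpy()
        )
        n_h = z.shape[0]
        if n_h == 1:
            meat += z.T @ z
            continue
        e = z - z.mean(axis=0, keepdims=True)
        meat += (n_h / (n_h - 1)) * e.T @ e
    return bread_inv @ meat @ bread_inv


def fit_weighted_poisson(
    y,
    X: pd.DataFrame,
    offset,
    design: SurveyDesign,
    ci_level: float = 0.95,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> ModelFit:
    """Fit a weighted Poisson rate model with design-based covariance.

    Parameters
    ----------
    y
        Non-negative counts per unit (child).
    X
        Design matrix (include an intercept column); column names label the
        coefficients.
    offset
        Log exposure time per unit, in seconds.
    design
        Strata, clusters and weights aligned with the rows of ``X``.

    Returns
    -------
    ModelFit
        Coefficients on the log-rate(-per-second) scale, the stratified
        cluster sandwich covariance, and the design df for t intervals.

    Notes
    -----
    The intercept-only fit has the closed form ``log(sum w y / sum w t)``;
    IRLS reproduces it to solver tolerance. A covariate level whose units
    have all-zero counts causes separation: the coefficient diverges to the
    boundary and is reported with an infinite CI, flagged in
    ``ModelFit.separation``.
    """
    y = np.asarray(y, float)
    offset = np.asarray(offset, float)
    w = design.weights
    names = list(X.columns)
    Xm = X.to_numpy(float)
    n, p = Xm.shape
    if len(y) != n or len(offset) != n or len(w) != n:
        raise ValueError("y, X, offset and design must align")
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if not np.isfinite(offset).all():
        raise ValueError("offsets must be finite")

    # detect separation: an indicator column whose support has zero counts
    separation = [
        names[j]
        for j in range(p)
        if set(np.unique(Xm[:, j])) <= {0.0, 1.0}
        and Xm[:, j].any()
        and y[Xm[:, j] > 0].sum() == 0
    ]

    beta = np.zeros(p)
    rate0 = max(w @ y, 0.5) / (w @ np.exp(offset))
    if "intercept" in names:
        beta[names.index("intercept")] = np.log(rate0)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Xm @ beta + offset
        mu = np.exp(eta)
        ww = w * mu
        z = eta - offset + (y - mu) / mu
        XtW = Xm.T * ww
        A = XtW @ Xm
        try:
            beta_new = np.linalg.solve(A, XtW @ z)
        except np.linalg.LinAlgError as err:
            raise FitError(f"singular working information at iteration {it}: {err}")
        if separation:
            # cap runaway boundary coefficients so the remaining ones converge
            beta_new = np.clip(beta_new, -30, 30)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    if not converged and not separation:
        raise FitError(f"IRLS did not converge in {max_iter} iterations")

    mu = np.exp(Xm @ beta + offset)
    A = (Xm.T * (w * mu)) @ Xm
    bread_inv = np.linalg.inv(A)
    scores = (w * (y - mu))[:, None] * Xm
    V = _cluster_sandwich(Xm, scores, design, bread_inv)
    V = (V + V.T) / 2

    return ModelFit(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(V, index=names, columns=names),
        df=design.df,
        n_obs=n,
        converged=converged or bool(separation),
        n_iter=it,
        ci_level=ci_level,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# margin rates (intercept-only fits per count column)


def estimate_margin_rates(
    summary: pd.DataFrame,
    design: SurveyDesign,
    count_columns=None,
    day_seconds: float = DAY_SECONDS,
) -> pd.DataFrame:
    """Per-day rate with design-based 95% CI for each count column.

    One intercept-only weighted Poisson fit per column of the per-child
    summary (totals and every setting/medium/product margin by default),
    with offset log(exposure time). A column with zero total count is
    reported as rate 0 with a degenerate CI and ``flag='zero_count'``.
    """
    if count_columns is None:
        count_columns = [
            c
            for c in summary.columns
            if c.endswith("_total")
            or "_setting_" in c
            or "_medium_" in c
            or "_product_" in c
        ]
    offset = np.log(summary["exposure_time"].to_numpy(float))
    X = pd.DataFrame({"intercept": np.ones(len(summary))}, index=summary.index)
    rows = []
    for col in count_columns:
        y = summary[col].to_numpy(float)
        if y.sum() == 0:
            rows.append((col, 0.0, 0.0, 0.0, "zero_count"))
            continue
        fit = fit_weighted_poisson(y, X, offset, design)
        rate, lo, hi = fit.rate_per_day(day_seconds)
        rows.append((col, rate, lo, hi, ""))
    return pd.DataFrame(
        rows, columns=["margin", "rate", "ci_low", "ci_high", "flag"]
    ).set_index("margin")


# ---------------------------------------------------------------------------
# adjusted rate-ratio models

ETH_LEVELS = ("NZE", "Maori", "Pacific")  # reference first
DECILE_LEVELS = ("medium", "low", "high")  # reference first
GENDER_REF = "female"


def build_design_matrix(children: pd.DataFrame, model: int) -> pd.DataFrame:
    """Design matrix for the adjusted models.

    Model 1: ethnicity + gender + age (years, linear).
    Model 2: model 1 + school-decile group.
    Model 3: model 2 + ethnicity x decile interaction.
    Reference levels: NZE ethnicity, female gender, medium decile.
    """
    if model not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    X = pd.DataFrame({"intercept": np.ones(len(children))}, index=children.index)
    for e in ETH_LEVELS[1:]:
        X[f"eth_{e}"] = (children["ethnicity"] == e).astype(float)
    X["male"] = (children["gender"] == "male").astype(float)
    X["age"] = children["age"].astype(float)
    if model >= 2:
        for d in DECILE_LEVELS[1:]:
            X[f"decile_{d}"] = (children["decile_group"] == d).astype(float)
    if model == 3:
        for e in ETH_LEVELS[1:]:
            for d in DECILE_LEVELS[1:]:
                X[f"eth_{e}:decile_{d}"] = X[f"eth_{e}"] * X[f"decile_{d}"]
    return X


def fit_models(
    summary: pd.DataFrame,
    children: pd.DataFrame,
    design: SurveyDesign,
    outcome: str = "noncore_total",
    models=(1, 2, 3),
) -> dict:
    """Fit the adjusted rate-ratio models for one outcome count.

    Children with missing demographics (age or gender) are dropped from
    these models (they stay in the overall/margin rates). Returns
    ``{model_number: ModelFit}``.
    """
    df = children.drop(
        columns=[c for c in ("exposure_time", outcome) if c in children.columns]
    ).merge(summary[["child_id", outcome, "exposure_time"]], on="child_id", how="inner")
    complete = df["age"].notna() & df["gender"].notna()
    df = df.loc[complete].reset_index(drop=True)
    mask = complete.to_numpy()
    sub = design.subset(mask)
    offset = np.log(df["exposure_time"].to_numpy(float))
    fits = {}
    for m in models:
        X = build_design_matrix(df, m)
        fits[m] = fit_weighted_poisson(df[outcome].to_numpy(float), X, offset, sub)
    return fits


def wald_interaction_test(
    fit: ModelFit, prefix: str = ":decile_", adjusted: bool = True
) -> WaldTest:
    """Design-based Wald F test that all interaction coefficients are zero.

    With ``W = (R b)' (R V R')^{-1} (R b)`` and ``q`` interaction terms, the
    default is the survey-adjusted Wald statistic
    ``F = (d - q + 1) / (d q) * W`` referred to ``F(q, d - q + 1)`` where
    ``d`` is the design df — the small-sample adjustment survey software
    applies, which markedly improves calibration when clusters are few.
    ``adjusted=False`` gives the unadjusted ``W / q ~ F(q, d)``.
    """
    terms = [n for n in fit.params.index if prefix in n]
    q = len(terms)
    if q == 0:
        raise ValueError(f"no coefficients match {prefix!r}")
    b = fit.params[terms].to_numpy()
    V = fit.cov.loc[terms, terms].to_numpy()
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        raise FitError(f"singular covariance among interaction terms {terms}")
    wald = float(b @ Vi @ b)
    d = fit.df
    if adjusted:
        if d - q + 1 <= 0:
            raise FitError(
                f"design df {d} too small for adjusted Wald with {q} constraints"
            )
        f_stat = wald * (d - q + 1) / (d * q)
        df_den = d - q + 1
    else:
        f_stat = wald / q
        df_den = d
    p = float(stats.f.sf(f_stat, q, df_den))
    return WaldTest(f_stat=f_stat, df_num=q, df_den=df_den, p_value=p)


def stratified_rate_ratios(fit: ModelFit) -> pd.DataFrame:
    """Ethnicity vs reference rate ratios within each decile group (model 3).

    The log rate ratio of ethnicity *e* vs the reference inside decile *d*
    is the linear combination ``eth_e + eth_e:decile_d`` (the interaction
    term vanishing in the reference decile); variances follow from the
    design covariance of that combination, CIs use the design-df t.
    """
    rows = []
    tcrit = stats.t.ppf(0.5 + fit.ci_level / 2, fit.df)
    idx = list(fit.params.index)
    V = fit.cov.to_numpy()
    for d in DECILE_LEVELS:
        for e in ETH_LEVELS:
            c = np.zeros(len(idx))
            if e != ETH_LEVELS[0]:
                c[idx.index(f"eth_{e}")] = 1.0
                inter = f"eth_{e}:decile_{d}"
                if inter in idx:
                    c[idx.index(inter)] = 1.0
            est = float(c @ fit.params.to_numpy())
            se = float(np.sqrt(c @ V @ c))
            rows.append(
                (
                    d,
                    e,
                    np.exp(est),
                    np.exp(est - tcrit * se),
                    np.exp(est + tcrit * se),
                )
            )
    return pd.DataFrame(
        rows, columns=["decile_group", "ethnicity", "rr", "ci_low", "ci_high"]
    )
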