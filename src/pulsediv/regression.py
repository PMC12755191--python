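"""Unweighted mixed-effects meta-regression and rank-correlation utilities.

The headline model relates community instability (OEV) to the mean species
response, response dissimilarity, and response divergence across
experiments:

    y_ij = beta0 + beta' x_ij + u_j + e_ij,   u_j ~ N(0, tau2),  e_ij ~ N(0, 1)

with a random intercept per experiment and *unit* sampling variances — the
standard reading of an unweighted mixed-effects meta-analysis (metafor's
``rma.mv(yi, V = 1, mods, random = ~1|id)``). Because the sampling variance
is fixed at 1 rather than estimated, the between-experiment variance tau2
remains identifiable even with one observation per experiment. tau2 is
estimated by restricted maximum likelihood (REML; ML optional), fixed
effects by GLS at the estimated tau2, and moderator tests are normal-theory
z-tests without multiplicity correction (each moderator is reported raw).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["MetaModelFit", "fit_mixed_model", "rank_correlation"]


@dataclass(frozen=True)
class CoefficientEstimate:
    estimate: float
    se: float
    zvalue: float
    pvalue: float


@dataclass
class MetaModelFit:
    """Result of the unweighted mixed-effects meta-regression."""

    coefficients: dict[str, CoefficientEstimate]
    tau2: float
    n_obs: int
    n_groups: int
    method: str

    def params(self) -> dict[str, float]:
        return {k: v.estimate for k, v in self.coefficients.items()}

    def confint(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        z = stats.norm.ppf(0.5 + level / 2.0)
        return {
            k: (v.estimate - z * v.se, v.estimate + z * v.se)
            for k, v in self.coefficients.items()
        }

    def to_json(self) -> str:
        payload = {
            "model": "unweighted mixed-effects meta-regression (unit sampling variance)",
            "method": self.method,
            "tau2": self.tau2,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
            "coefficients": {
                k: {
                    "estimate": v.estimate,
                    "se": v.se,
                    "zvalue": v.zvalue,
                    "pvalue": v.pvalue,
                }
                for k, v in self.coefficients.items()
            },
        }
        return json.dumps(payload, indent=2)


def _group_stats(X, y, sizes, starts, tau2):
    """X'V^-1X, X'V^-1y, y'V^-1y and log|V| for V = I + tau2 * ZZ'.

    V is block diagonal; by Sherman-Morrison each block inverse is
    I - (tau2 / (1 + n_g tau2)) * J.
    """
    XtVX = X.T @ X
    XtVy = X.T @ y
    ytVy = float(y @ y)
    logdet = 0.0
    for n_g, s in zip(sizes, starts):
        Xg = X[s : s + n_g]
        yg = y[s : s + n_g]
        c = tau2 / (1.0 + n_g * tau2)
        sx = Xg.sum(axis=0)
        sy = float(yg.sum())
        XtVX -= c * np.outer(sx, sx)
        XtVy -= c * sx * sy
        ytVy -= c * sy * sy
        logdet += np.log1p(n_g * tau2)
    return XtVX, XtVy, ytVy, logdet


def _neg_loglik(tau2, X, y, sizes, starts, reml):
    n, p = X.shape
    XtVX, XtVy, ytVy, logdet = _group_stats(X, y, sizes, starts, tau2)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - float(beta @ XtVy)  # y' P y at the GLS beta
    ll = -0.5 * (logdet + rss)
    if reml:
        sign, logdet_xvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        ll -= 0.5 * logdet_xvx
    return -ll


def fit_mixed_model(
    table: pd.DataFrame,
    response: str = "oev",
    moderators: tuple[str, ...] = ("mean_response", "dissimilarity", "divergence"),
    group: str = "experiment_id",
    method: str = "reml",
) -> MetaModelFit:
    """Fit the unweighted mixed-effects meta-regression.

    ``table`` holds one row per community/experiment observation with the
    response, the moderator columns, and a grouping column for the random
    intercept. Missing values in any used column are rejected. Rank-deficient
    moderator matrices raise rather than silently dropping terms.
    """
    if method not in {"reml", "ml"}:
        raise ValueError("method must be 'reml' or 'ml'")
    cols = [response, *moderators, group]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    sub = table[cols]
    if sub[[response, *moderators]].isna().any().any():
        raise ValueError("missing values in response or moderators")

    # sort rows by group so each random-effect block is contiguous; the fit
    # is invariant to the original row order and to group labels
    sub = sub.sort_values(group, kind="mergesort").reset_index(drop=True)
    y = sub[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[m].to_numpy(dtype=float) for m in moderators]
    )
    names = ["intercept", *moderators]
    n, p = X.shape
    if n < p:
        raise ValueError(f"need at least {p} observations, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(
            "moderator matrix is rank deficient (collinear moderators); "
            f"columns: {names}"
        )

    codes = sub[group].astype("category").cat.codes.to_numpy()
    # groups are contiguous after the sort
    _, starts, sizes = np.unique(codes, return_index=True, return_counts=True)
    n_groups = sizes.size

    reml = method == "reml"
    upper = max(10.0 * float(np.var(y)) + 1.0, 10.0)
    res = optimize.minimize_scalar(
        _neg_loglik,
        bounds=(0.0, upper),
        args=(X, y, sizes, starts, reml),
        method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(res.x)
    # the bounded optimizer never evaluates the exact boundary; snap to 0
    # when the criterion is no worse there
    if _neg_loglik(0.0, X, y, sizes, starts, reml) <= res.fun + 1e-10:
        tau2 = 0.0

    XtVX, XtVy, _, _ = _group_stats(X, y, sizes, starts, tau2)
    cov = np.linalg.inv(XtVX)
    beta = cov @ XtVy
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    coefficients = {
        name: CoefficientEstimate(float(b), float(s), float(zz), float(pp))
        for name, b, s, zz, pp in zip(names, beta, se, z, pvals)
    }
    return MetaModelFit(
        coefficients=coefficients,
        tau2=tau2,
        n_obs=n,
        n_groups=int(n_groups),
        method=method,
    )


def rank_correlation(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least three observations")
    return float(stats.spearmanr(x, y).statistic)
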