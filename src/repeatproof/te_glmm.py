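"""Random-intercept logistic model of perfect TE assembly.

Per TE copy the binary outcome (perfectly assembled or not) is modeled as

    logit P(y_ij = 1) = x_ij' beta + u_j,   u_j ~ N(0, sigma^2)

with one random intercept per TE family and fixed effects for copy length,
GC content of the copy plus 1 kbp flanks, divergence from the family
canonical sequence, the family's number of high-identity copies
(divergence < 0.01), and the divergence x high-identity-copies interaction.
All predictors are standardized to zero mean and unit variance before
fitting so coefficient magnitudes are comparable; the interaction is the
product of the two standardized columns.

The marginal likelihood integrates the family intercepts by the Laplace
approximation (one scalar integral per family, inner Newton for the mode);
standard errors come from the observed information of the marginal
log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .align_io import Feature
from .feature_eval import FeatureAssessment
from .gap_sim import gc_fraction
from .synthetic_data import GenomeBundle

FIXED_EFFECTS = ("length", "gc_flank", "divergence", "high_copies", "div_x_high")
HIGH_IDENTITY_DIVERGENCE = 0.01  # strict upper bound


class SeparationError(RuntimeError):
    pass


@dataclass
class TEGlmmData:
    X: np.ndarray  # n x 6 design (intercept + standardized predictors)
    y: np.ndarray  # n binary
    family_index: np.ndarray  # n integer codes
    family_labels: list[str]
    columns: tuple[str, ...] = ("intercept",) + FIXED_EFFECTS
    n_dropped_missing_divergence: int = 0
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.family_labels)


@dataclass
class TEGlmmFit:
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sigma_family: float
    loglik: float
    columns: tuple[str, ...]
    converged: bool = True

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se, "z": self.z, "p": self.p},
            index=list(self.columns),
        )


# ---------------------------------------------------------------------------
# Design construction


def build_design(
    assessments: Sequence[FeatureAssessment],
    tes: Sequence[Feature],
    genome: GenomeBundle,
    flank: int = 1000,
) -> TEGlmmData:
    """Assemble the standardized per-copy design matrix from assessments and
    annotation metadata. Copies without a divergence estimate are dropped
    and counted; flanks are truncated at scaffold ends."""
    by_id = {t.feature_id: t for t in tes}
    outcome = {
        a.feature_id: 1.0 if a.perfect else 0.0
        for a in assessments
        if a.feature_type == "TE"
    }
    rows = []
    dropped = 0
    for fid, y in outcome.items():
        te = by_id.get(fid)
        if te is None:
            continue
        if te.divergence is None:
            dropped += 1
            continue
        seq = genome.sequences[te.ref_id]
        lo = max(0, te.start - flank)
        hi = min(len(seq), te.end + flank)
        rows.append(
            {
                "feature_id": fid,
                "y": y,
                "length": float(te.length),
                "gc_flank": gc_fraction(seq[lo:hi]),
                "divergence": te.divergence,
                "family": te.family or "unknown",
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no assessable TE copies with divergence metadata")
    high = (
        df[df.divergence < HIGH_IDENTITY_DIVERGENCE].groupby("family").size()
    )
    df["high_copies"] = df["family"].map(high).fillna(0).astype(float)

    means, sds = {}, {}
    for col in ("length", "gc_flank", "divergence", "high_copies"):
        mu = float(df[col].mean())
        sd = float(df[col].std(ddof=0))
        if sd == 0:
            raise ValueError(f"zero-variance predictor: {col}")
        df[col + "_z"] = (df[col] - mu) / sd
        means[col], sds[col] = mu, sd
    df["div_x_high_z"] = df["divergence_z"] * df["high_copies_z"]

    fams = sorted(df["family"].unique())
    fam_code = {f: i for i, f in enumerate(fams)}
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["length_z"], df["gc_flank_z"], df["divergence_z"],
            df["high_copies_z"], df["div_x_high_z"],
        ]
    )
    return TEGlmmData(
        X=X,
        y=df["y"].to_numpy(),
        family_index=df["family"].map(fam_code).to_numpy(),
        family_labels=fams,
        n_dropped_missing_divergence=dropped,
        means=means,
        sds=sds,
    )


# ---------------------------------------------------------------------------
# Laplace-approximated marginal likelihood


def _family_slices(family_index: np.ndarray, n_families: int):
    order = np.argsort(family_index, kind="stable")
    sorted_idx = family_index[order]
    bounds = np.searchsorted(sorted_idx, np.arange(n_families + 1))
    return order, bounds


def _inner_modes(
    eta: np.ndarray, y: np.ndarray, order, bounds, n_fam: int, sigma2: float,
    tol: float = 1e-10, max_iter: int = 50,
):
    """Newton solve for the conditional mode u_j of each family."""
    u = np.zeros(n_fam)
    for j in range(n_fam):
        idx = order[bounds[j] : bounds[j + 1]]
        ej = eta[idx]
        yj = y[idx]
        uj = 0.0
        for _ in range(max_iter):
            p = special.expit(ej + uj)
            g = np.sum(yj - p) - uj / sigma2
            h = -np.sum(p * (1 - p)) - 1.0 / sigma2
            step = g / h
            uj -= step
            if abs(step) < tol:
                break
        u[j] = uj
    return u


def marginal_loglik(
    beta: np.ndarray, sigma: float, X: np.ndarray, y: np.ndarray,
    family_index: np.ndarray, n_fam: int,
) -> float:
    """Laplace-approximated marginal log-likelihood.

    Per family: l(u_hat) - u_hat^2/(2 sigma^2) - 0.5 log(1 + sigma^2 W),
    where W = sum p(1-p) at the conditional mode. At sigma = 0 this is the
    plain logistic log-likelihood.
    """
    eta = X @ beta
    if sigma < 1e-10:
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    order, bounds = _family_slices(family_index, n_fam)
    sigma2 = sigma * sigma
    u = _inner_modes(eta, y, order, bounds, n_fam, sigma2)
    ll = 0.0
    for j in range(n_fam):
        idx = order[bounds[j] : bounds[j + 1]]
        ej = eta[idx] + u[j]
        p = special.expit(ej)
        ll += float(np.sum(y[idx] * ej - np.logaddexp(0.0, ej)))
        ll -= u[j] ** 2 / (2 * sigma2)
        W = float(np.sum(p * (1 - p)))
        ll -= 0.5 * np.log1p(sigma2 * W)
    return ll


def marginal_loglik_quadrature(
    beta: np.ndarray, sigma: float, X: np.ndarray, y: np.ndarray,
    family_index: np.ndarray, n_fam: int, n_points: int = 51,
) -> float:
    """Adaptive Gauss-Hermite oracle for the marginal log-likelihood.

    Quadrature is centered and scaled at each family's conditional mode;
    with 51 points this is numerically exact for these one-dimensional
    integrals. Independent of the Laplace path (used to validate it).
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_points)
    eta = X @ beta
    if sigma < 1e-10:
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    order, bounds = _family_slices(family_index, n_fam)
    sigma2 = sigma * sigma
    u_hat = _inner_modes(eta, y, order, bounds, n_fam, sigma2)
    ll = 0.0
    for j in range(n_fam):
        idx = order[bounds[j] : bounds[j + 1]]
        ej = eta[idx]
        yj = y[idx]
        p = special.expit(ej + u_hat[j])
        tau = 1.0 / np.sqrt(np.sum(p * (1 - p)) + 1.0 / sigma2)
        us = u_hat[j] + tau * nodes

        def integrand_log(u):
            return (
                np.sum(
                    yj[:, None] * (ej[:, None] + u[None, :])
                    - np.logaddexp(0.0, ej[:, None] + u[None, :]),
                    axis=0,
                )
                - u * u / (2 * sigma2)
                - np.log(sigma)
                - 0.5 * np.log(2 * np.pi)
            )

        logf = integrand_log(us)
        # \int f(u) du = tau * sum_k w_k exp(nodes_k^2 / 2) f(u_k) for
        # Hermite-e weights; work in log space for stability
        logterms = np.log(weights) + nodes * nodes / 2.0 + logf + np.log(tau)
        ll += float(special.logsumexp(logterms))
    return ll


def fit_glmm(
    data: TEGlmmData,
    tol: float = 1e-8,
    max_iter: int = 500,
    fix_sigma: float | None = None,
) -> TEGlmmFit:
    """Maximize the Laplace marginal likelihood over (beta, sigma).

    Fixed starting values (beta = 0, sigma = 1); convergence on gradient
    norm; Wald standard errors from the observed information (numerical
    Hessian of the marginal log-likelihood at the optimum). With
    ``fix_sigma`` the random-intercept standard deviation is held fixed
    (``fix_sigma=0`` reduces the model to plain logistic regression).
    """
    if data.n_families < 2:
        raise ValueError("need >= 2 families to fit a family random intercept")
    if len(np.unique(data.y)) < 2:
        raise ValueError("outcome is constant; nothing to fit")
    X, y, fidx, n_fam = data.X, data.y, data.family_index, data.n_families
    k = X.shape[1]

    def negll(theta):
        beta = theta[:k]
        sigma = theta[k] if fix_sigma is None else fix_sigma
        return -marginal_loglik(beta, sigma, X, y, fidx, n_fam)

    theta0 = np.zeros(k + 1)
    theta0[k] = 1.0 if fix_sigma is None else fix_sigma
    sigma_bounds = (0.0, 50.0) if fix_sigma is None else (fix_sigma, fix_sigma)
    res = optimize.minimize(
        negll,
        theta0,
        method="L-BFGS-B",
        bounds=[(None, None)] * k + [sigma_bounds],
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
    )
    theta = res.x
    beta = theta[:k]
    sigma = float(theta[k]) if fix_sigma is None else float(fix_sigma)
    if np.any(np.abs(beta) > 30):
        raise SeparationError(
            "fixed-effect estimate diverged (|beta| > 30): likely complete separation"
        )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(f"GLMM fit did not converge: {res.message}; |grad|={np.linalg.norm(res.jac):.3g}")

    from statsmodels.tools.numdiff import approx_hess1

    if fix_sigma is not None:
        H = approx_hess1(beta, lambda b: negll(np.concatenate([b, [fix_sigma]])))
    else:
        H = approx_hess1(theta, negll)
    try:
        cov = np.linalg.inv(H)
        se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        # sigma at the boundary can make H singular; fall back to the beta block
        Hb = H[:k, :k]
        cov = np.linalg.inv(Hb)
        se_all = np.concatenate([np.sqrt(np.clip(np.diag(cov), 0, None)), [np.nan]])
    se = se_all[:k]
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        Hb = H[:k, :k]
        se = np.sqrt(np.clip(np.diag(np.linalg.inv(Hb)), 1e-300, None))
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return TEGlmmFit(
        beta=beta, se=se, z=z, p=np.clip(p, np.finfo(float).tiny, 1.0),
        sigma_family=sigma, loglik=-res.fun, columns=data.columns,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# Predicted-probability curves


def predict_curves(
    fit: TEGlmmFit,
    data: TEGlmmData,
    covariate: str,
    conditions: Mapping[str, float] | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Predicted probability over a grid of one standardized covariate.

    Other covariates sit at 0 (the standardized mean) and the random
    intercept at 0. ``conditions`` maps condition labels to fixed values of
    ``high_copies`` (standardized), e.g. low vs high high-identity copy
    number; the interaction column is recomputed along the grid.
    """
    if covariate not in FIXED_EFFECTS:
        raise ValueError(f"unknown covariate {covariate!r}; have {FIXED_EFFECTS}")
    if grid is None:
        grid = np.linspace(-2.0, 2.0, 41)
    conditions = dict(conditions or {"all": 0.0})
    cols = list(fit.columns)
    rows = []
    for label, high_val in conditions.items():
        for g in grid:
            xvec = np.zeros(len(cols))
            xvec[cols.index("intercept")] = 1.0
            xvec[cols.index(covariate)] = g
            if covariate != "high_copies":
                xvec[cols.index("high_copies")] = high_val
            div = xvec[cols.index("divergence")]
            high = xvec[cols.index("high_copies")]
            xvec[cols.index("div_x_high")] = div * high
            eta = float(xvec @ fit.beta)
            rows.append(
                {"condition": label, covariate: g,
                 "probability": float(special.expit(eta))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation helper (for validation and the parameter-recovery analyses)


def simulate_glmm_data(
    n: int,
    n_families: int,
    beta: Mapping[str, float],
    sigma: float,
    seed: int = 0,
) -> TEGlmmData:
    """Draw data from the model itself (standardized predictors, known
    coefficients); used to check that fitting recovers the truth."""
    rng = np.random.default_rng(seed)
    fidx = rng.integers(0, n_families, size=n)
    Z = rng.standard_normal((n, 4))
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    inter = Z[:, 2] * Z[:, 3]
    X = np.column_stack([np.ones(n), Z, inter])
    b = np.array(
        [beta.get("intercept", 0.0)]
        + [beta.get(c, 0.0) for c in FIXED_EFFECTS]
    )
    u = rng.normal(0.0, sigma, size=n_families)
    eta = X @ b + u[fidx]
    y = (rng.random(n) < special.expit(eta)).astype(float)
    return TEGlmmData(
        X=X, y=y, family_index=fidx,
        family_labels=[f"fam_{j}" for j in range(n_families)],
    )
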