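"""Two-part model estimation: probit participation + smokers-only log OLS.

The probit is fit by Newton ascent on the exact log-likelihood with
step-halving; standard errors come from the inverse observed information.
The conditional-demand part is ordinary least squares with classical
(homoskedastic) standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr, ndtr, ndtri

from .synthetic import (
    CONSUMPTION_TERMS,
    PARTICIPATION_TERMS,
    consumption_matrix,
    participation_matrix,
)

__all__ = [
    "ProbitFit",
    "OLSFit",
    "probit_loglik",
    "fit_probit",
    "fit_ols",
    "fit_two_part",
]

#: probabilities are clipped to [EPS, 1-EPS] inside the likelihood
EPS = 1e-10

#: designs with a larger condition number are rejected as collinear
MAX_CONDITION_NUMBER = 1e8


@dataclass(frozen=True)
class ProbitFit:
    """Fitted participation model."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    loglik: float
    converged: bool
    n: int
    mean_linear_index: float  # fitted index evaluated at covariate means
    participation_rate: float
    terms: tuple[str, ...] = PARTICIPATION_TERMS
    n_iter: int = 0

    def to_dict(self) -> dict:
        return {
            "kind": "probit",
            "terms": list(self.terms),
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n": self.n,
            "mean_linear_index": self.mean_linear_index,
            "participation_rate": self.participation_rate,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbitFit":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            standard_errors=np.asarray(d["standard_errors"], dtype=float),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n=int(d["n"]),
            mean_linear_index=float(d["mean_linear_index"]),
            participation_rate=float(d["participation_rate"]),
            terms=tuple(d["terms"]),
            n_iter=int(d.get("n_iter", 0)),
        )


@dataclass(frozen=True)
class OLSFit:
    """Fitted conditional-demand model (smokers only)."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    r_squared: float
    n: int
    terms: tuple[str, ...] = CONSUMPTION_TERMS

    def to_dict(self) -> dict:
        return {
            "kind": "ols",
            "terms": list(self.terms),
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "r_squared": self.r_squared,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OLSFit":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            standard_errors=np.asarray(d["standard_errors"], dtype=float),
            r_squared=float(d["r_squared"]),
            n=int(d["n"]),
            terms=tuple(d["terms"]),
        )


def _as_design(design) -> np.ndarray:
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _check_rank(X: np.ndarray, terms=None) -> None:
    if X.shape[0] == 0:
        return
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > MAX_CONDITION_NUMBER:
        # name the columns loading on the smallest singular direction
        _, _, vt = np.linalg.svd(X, full_matrices=False)
        v = np.abs(vt[-1])
        idx = np.flatnonzero(v > 0.3 * v.max())
        names = (
            [terms[i] for i in idx] if terms is not None else [f"col{i}" for i in idx]
        )
        raise ValueError(
            f"design is rank deficient or near-collinear (condition number "
            f"{cond:.3g}); offending columns: {', '.join(names)}"
        )


def probit_loglik(coefficients, design, outcome) -> float:
    """Probit log-likelihood Σ[z·lnΦ(w'a) + (1−z)·ln(1−Φ(w'a))].

    Probabilities are clipped to ``[EPS, 1-EPS]`` so the value stays finite
    for extreme indices.  An empty sample returns 0.
    """
    X = _as_design(design)
    z = np.asarray(outcome, dtype=float)
    if X.shape[0] != z.shape[0]:
        raise ValueError(
            f"design has {X.shape[0]} rows but outcome has {z.shape[0]}"
        )
    a = np.asarray(coefficients, dtype=float)
    if a.shape[0] != X.shape[1]:
        raise ValueError(
            f"coefficient length {a.shape[0]} does not match "
            f"{X.shape[1]} design columns"
        )
    if X.shape[0] == 0:
        return 0.0
    p = np.clip(ndtr(X @ a), EPS, 1.0 - EPS)
    return float(np.sum(z * np.log(p) + (1.0 - z) * np.log1p(-p)))


def _mills(t: np.ndarray) -> np.ndarray:
    """phi(t)/Phi(t), computed in log space for stability at t << 0."""
    return np.exp(-0.5 * t * t - 0.5 * np.log(2.0 * np.pi) - log_ndtr(t))


def fit_probit(
    design,
    outcome,
    terms: tuple[str, ...] = PARTICIPATION_TERMS,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> ProbitFit:
    """Maximum-likelihood probit via Newton ascent with step-halving.

    Convergence requires the max-abs score below ``tol``; standard errors are
    square roots of the diagonal of the inverse observed information.
    Separation (diverging coefficients) is flagged as not-converged rather
    than raised.
    """
    X = _as_design(design)
    z = np.asarray(outcome, dtype=float)
    if X.shape[0] != z.shape[0]:
        raise ValueError("design and outcome lengths differ")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    rate = float(z.mean())
    if rate in (0.0, 1.0):
        raise ValueError(
            f"outcome is single-class (participation rate {rate:.0%}); "
            "probit is not estimable"
        )
    _check_rank(X, terms)

    coef = np.zeros(p)
    # start the intercept-like column at the inverse-CDF of the base rate
    const_cols = np.flatnonzero(np.all(X == X[0], axis=0) & (X[0] != 0))
    if const_cols.size:
        coef[const_cols[0]] = ndtri(rate) / X[0, const_cols[0]]

    ll = probit_loglik(coef, X, z)
    converged = False
    it = 0
    q = 2.0 * z - 1.0
    for it in range(1, max_iter + 1):
        eta = X @ coef
        lam = _mills(q * eta)
        grad = X.T @ (q * lam)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = lam * (lam + q * eta)  # observed-information weights, > 0
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step-halve until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            new_coef = coef + scale * step
            new_ll = probit_loglik(new_coef, X, z)
            if new_ll >= ll - 1e-12:
                break
            scale *= 0.5
        coef = coef + scale * step
        ll = new_ll
        if np.max(np.abs(coef)) > 1e4:  # separation guard
            break
    else:
        it = max_iter

    eta = X @ coef
    lam = _mills(q * eta)
    if converged and np.max(np.abs(grad := X.T @ (q * lam))) >= tol:
        converged = False
    if np.all(q * eta > 0):
        # perfect classification: the true MLE diverges (separation) even
        # though the clipped likelihood plateaus
        converged = False
    w = lam * (lam + q * eta)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    if not converged:
        warnings.warn(
            "probit did not converge (possible separation); inspect the fit",
            stacklevel=2,
        )
    xbar = X.mean(axis=0)
    return ProbitFit(
        coefficients=coef,
        standard_errors=se,
        loglik=probit_loglik(coef, X, z),
        converged=converged,
        n=n,
        mean_linear_index=float(xbar @ coef),
        participation_rate=rate,
        terms=tuple(terms) if terms is not None else tuple(f"x{i}" for i in range(p)),
        n_iter=it,
    )


def fit_ols(
    design, ln_consumption, terms: tuple[str, ...] = CONSUMPTION_TERMS
) -> OLSFit:
    """Least squares with classical standard errors and centered R²."""
    X = _as_design(design)
    y = np.asarray(ln_consumption, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("design and response lengths differ")
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    _check_rank(X, terms)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    sigma2 = rss / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return OLSFit(
        coefficients=coef,
        standard_errors=se,
        r_squared=max(0.0, min(1.0, r2)),
        n=n,
        terms=tuple(terms) if terms is not None else tuple(f"x{i}" for i in range(p)),
    )


def fit_two_part(table: pd.DataFrame, quintile: int) -> tuple[ProbitFit, OLSFit]:
    """Fit both parts on one quintile of a household table.

    Part one uses every household of the quintile; part two only the smoker
    households, with the response ``ln(sticks_month)``.
    """
    sub = table[table["quintile"] == quintile]
    if len(sub) == 0:
        raise ValueError(f"no households in quintile {quintile}")
    n_smokers = int(sub["smoke"].sum())
    if n_smokers == 0 or n_smokers == len(sub):
        raise ValueError(
            f"quintile {quintile} is single-class: {n_smokers} smokers out of "
            f"{len(sub)} households"
        )
    W = participation_matrix(sub)
    probit = fit_probit(W, sub["smoke"].to_numpy())
    smokers = sub[sub["smoke"] == 1]
    X = consumption_matrix(smokers)
    # education levels absent among the smokers yield all-zero dummies;
    # drop them instead of failing the rank check
    keep = [j for j in range(X.shape[1]) if np.any(X[:, j] != 0)]
    terms = tuple(CONSUMPTION_TERMS[j] for j in keep)
    if len(keep) < X.shape[1]:
        dropped = [t for t in CONSUMPTION_TERMS if t not in terms]
        warnings.warn(
            f"quintile {quintile}: dropping empty education levels {dropped}",
            stacklevel=2,
        )
    ols = fit_ols(
        X[:, keep], np.log(smokers["sticks_month"].to_numpy(dtype=float)), terms=terms
    )
    return probit, ols
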