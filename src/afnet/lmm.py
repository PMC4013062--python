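"""Exact REML fits of the single-random-intercept linear mixed model.

Per-feature association models share one fixed-effect design ``X`` and one
pedigree grouping; only the outcome (a gene's expression vector) changes.
For the model

    y = X beta + b_ped + eps,   b_ped ~ N(0, sigma_f^2),  eps ~ N(0, sigma_e^2)

the marginal covariance is block diagonal by pedigree with blocks
``sigma_e^2 (I + lambda J)`` where ``lambda = sigma_f^2 / sigma_e^2`` and J is
the all-ones matrix.  Each block inverts in closed form,

    (I + lambda J)^{-1} = I - (lambda / (1 + n_j lambda)) J,

so the profiled REML criterion is a smooth scalar function of ``lambda``
that costs O(n_pedigrees * p^2) to evaluate.  Fitting thousands of genes
then reduces to thousands of cheap 1-D optimizations over a shared set of
precomputed group sums.  The result is numerically identical to a general
mixed-model fit (verified in the test suite against statsmodels MixedLM)
at a small fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, stats
from scipy.optimize import minimize_scalar

__all__ = ["RandomInterceptModel", "LMMFit"]

_LAMBDA_MAX = 1e4


@dataclass
class LMMFit:
    """Result of one REML fit: fixed effects and variance components."""

    beta: np.ndarray
    se: np.ndarray
    sigma_e2: float
    sigma_f2: float
    lam: float
    converged: bool

    def wald_p(self, index: int) -> float:
        """Two-sided Wald p-value (normal reference) for one coefficient."""
        z = self.beta[index] / self.se[index]
        return float(2.0 * stats.norm.sf(abs(z)))


class RandomInterceptModel:
    """REML machinery for many outcomes sharing one design and grouping.

    Parameters
    ----------
    X:
        Fixed-effect design matrix, shape (n, p), full column rank.
    groups:
        Integer codes of length n assigning each sample to a pedigree.
    """

    def __init__(self, X: np.ndarray, groups: np.ndarray):
        X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        if X.ndim != 2 or X.shape[0] != groups.shape[0]:
            raise ValueError("X and groups have incompatible shapes")
        self.n, self.p = X.shape
        if self.n <= self.p:
            raise ValueError("more parameters than samples")
        codes, self.group_index = np.unique(groups, return_inverse=True)
        self.m = codes.size
        self.X = X
        self.group_sizes = np.bincount(self.group_index, minlength=self.m).astype(float)
        # Group sums of X (m x p) and the Gram matrix, shared across outcomes.
        self._Gx = np.zeros((self.m, self.p))
        for j in range(self.p):
            self._Gx[:, j] = np.bincount(self.group_index, weights=X[:, j], minlength=self.m)
        self._Sxx = X.T @ X

    def _whitened_normal_eqs(self, lam: float, gy: np.ndarray, Sxy: np.ndarray, Syy: float):
        """Return (A, b, yOy) for GLS at ratio lam: A = X'O^-1 X etc."""
        c = lam / (1.0 + self.group_sizes * lam)
        A = self._Sxx - self._Gx.T @ (c[:, None] * self._Gx)
        b = Sxy - self._Gx.T @ (c * gy)
        yOy = Syy - float(np.dot(c * gy, gy))
        return A, b, yOy

    def _neg2_reml(self, lam: float, gy: np.ndarray, Sxy: np.ndarray, Syy: float) -> float:
        A, b, yOy = self._whitened_normal_eqs(lam, gy, Sxy, Syy)
        try:
            cf = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(cf, b)
        rss = yOy - float(np.dot(beta, b))
        if rss <= 0:
            return np.inf
        df = self.n - self.p
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        logdet_Omega = float(np.sum(np.log1p(self.group_sizes * lam)))
        return df * np.log(rss / df) + logdet_Omega + logdet_A

    def fit(self, y: np.ndarray) -> LMMFit:
        """REML fit for one outcome vector."""
        y = np.asarray(y, dtype=float)
        gy = np.bincount(self.group_index, weights=y, minlength=self.m)
        Sxy = self.X.T @ y
        Syy = float(np.dot(y, y))

        obj = lambda lam: self._neg2_reml(lam, gy, Sxy, Syy)
        res = minimize_scalar(obj, bounds=(0.0, _LAMBDA_MAX), method="bounded",
                              options={"xatol": 1e-10})
        lam = float(res.x)
        # The bounded minimizer never proposes the boundary itself; accept
        # lam = 0 (pure OLS) when it fits at least as well.
        if obj(0.0) <= res.fun:
            lam = 0.0
        A, b, yOy = self._whitened_normal_eqs(lam, gy, Sxy, Syy)
        cf = linalg.cho_factor(A, lower=True)
        beta = linalg.cho_solve(cf, b)
        rss = yOy - float(np.dot(beta, b))
        df = self.n - self.p
        sigma_e2 = rss / df
        cov = linalg.cho_solve(cf, np.eye(self.p)) * sigma_e2
        se = np.sqrt(np.diag(cov))
        return LMMFit(
            beta=beta,
            se=se,
            sigma_e2=float(sigma_e2),
            sigma_f2=float(lam * sigma_e2),
            lam=lam,
            converged=bool(np.isfinite(res.fun) or lam == 0.0),
        )
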