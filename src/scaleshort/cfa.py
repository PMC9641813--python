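"""One-factor confirmatory factor analysis with normal-theory ML.

Items are treated as continuous and the congeneric model Sigma = lambda
lambda' + Psi is fitted to the sample covariance matrix by minimizing the
ML discrepancy

    F = log|Sigma| + tr(S Sigma^-1) - log|S| - p ,

giving chi2 = (n - 1) * F.  The baseline (independence) model constrains
Sigma to diag(S).  Fit is summarized by CFI, TLI, and RMSEA.  The factor
variance is fixed at 1 for identification; reported loadings are
standardized (lambda_j / sqrt(lambda_j^2 + psi_j)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .data import ResponseMatrix, ScaleDefinition, ValidationError

__all__ = ["OneFactorCFA", "CFAFit", "FitIndices", "fit_one_factor", "fit_indices"]

_PSI_FLOOR = 1e-4


@dataclass(frozen=True)
class CFAFit:
    """Estimates and test statistics from a one-factor ML fit."""

    item_ids: tuple[str, ...]
    loadings: np.ndarray          # standardized
    uniquenesses: np.ndarray      # standardized residual variances
    chi2_model: float
    df_model: int
    chi2_baseline: float
    df_baseline: int
    n: int
    converged: bool
    heywood: bool

    def summary(self) -> str:
        idx = fit_indices(self)
        lines = [
            "One-factor CFA (normal-theory ML on covariances)",
            f"  n = {self.n}, items = {len(self.item_ids)}",
            f"  chi2(model) = {self.chi2_model:.3f} on {self.df_model} df; "
            f"chi2(baseline) = {self.chi2_baseline:.3f} on {self.df_baseline} df",
            f"  CFI = {idx.cfi:.3f}  TLI = {idx.tli:.3f}  RMSEA = {idx.rmsea:.3f}",
            "",
            f"  {'item':<8}{'loading':>9}{'uniqueness':>12}",
        ]
        for item, lam, psi in zip(self.item_ids, self.loadings, self.uniquenesses):
            lines.append(f"  {item:<8}{lam:>9.3f}{psi:>12.3f}")
        if self.heywood:
            lines.append("  warning: Heywood case (uniqueness at floor)")
        return "\n".join(lines)


@dataclass(frozen=True)
class FitIndices:
    cfi: float
    tli: float
    rmsea: float


def _ml_discrepancy(S: np.ndarray, lam: np.ndarray, psi: np.ndarray) -> float:
    p = S.shape[0]
    sigma = np.outer(lam, lam) + np.diag(psi)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet + np.trace(np.linalg.solve(sigma, S)) - logdet_s - p)


class OneFactorCFA:
    """Congeneric one-factor model for a set of Likert items.

    Parameters
    ----------
    data : ResponseMatrix
    subset : ScaleDefinition, optional
        Items entering the model (default: all).  At least 3 items are
        required for identification; with exactly 3 the model is saturated
        (df = 0).
    """

    def __init__(self, data, subset: ScaleDefinition | None = None):
        if isinstance(data, ResponseMatrix):
            self.subset = subset if subset is not None else data.full_scale()
            self.item_ids = tuple(self.subset.item_ids)
            x = data.subset_values(self.subset).astype(float)
        else:
            # any persons x items numeric matrix
            x = np.asarray(data, dtype=float)
            if subset is not None:
                raise ValidationError("subset selection requires a ResponseMatrix")
            self.subset = None
            self.item_ids = tuple(f"item{j + 1}" for j in range(x.shape[1]))
        if len(self.item_ids) < 3:
            raise ValidationError("one-factor CFA needs at least 3 items")
        self.n = x.shape[0]
        self.S = np.cov(x, rowvar=False, ddof=1)
        if np.any(np.diag(self.S) <= 0):
            raise ValidationError("an item has zero variance")
        eig = np.linalg.eigvalsh(self.S)
        if eig.min() <= 1e-10:
            raise ValidationError("sample covariance matrix is not positive definite")

    def fit(self, max_iter: int = 500) -> CFAFit:
        S = self.S
        p = S.shape[0]
        sd = np.sqrt(np.diag(S))
        # principal-component start
        w, v = np.linalg.eigh(S)
        lam0 = v[:, -1] * math.sqrt(max(w[-1], 1e-6))
        if lam0.sum() < 0:
            lam0 = -lam0
        psi0 = np.maximum(np.diag(S) - lam0 ** 2, 0.1 * np.diag(S))
        x0 = np.concatenate([lam0, np.log(psi0)])

        def objective(params):
            lam, logpsi = params[:p], params[p:]
            return _ml_discrepancy(S, lam, np.exp(logpsi))

        lo_psi = np.log(_PSI_FLOOR * np.diag(S))
        bounds = [(None, None)] * p + [(lo, None) for lo in lo_psi]
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10})
        lam = res.x[:p]
        psi = np.exp(res.x[p:])
        heywood = bool(np.any(psi <= 1.01 * _PSI_FLOOR * np.diag(S)))
        # orient the factor so the average loading is positive
        if lam.sum() < 0:
            lam = -lam

        F = _ml_discrepancy(S, lam, psi)
        df_model = p * (p + 1) // 2 - 2 * p
        # independence baseline: Sigma = diag(S)
        _, logdet_s = np.linalg.slogdet(S)
        F_base = float(np.sum(np.log(np.diag(S))) - logdet_s)
        df_base = p * (p - 1) // 2

        total_var = lam ** 2 + psi
        return CFAFit(
            item_ids=self.item_ids,
            loadings=lam / np.sqrt(total_var),
            uniquenesses=psi / total_var,
            chi2_model=max((self.n - 1) * F, 0.0),
            df_model=df_model,
            chi2_baseline=max((self.n - 1) * F_base, 0.0),
            df_baseline=df_base,
            n=self.n,
            converged=bool(res.success),
            heywood=heywood,
        )


def fit_one_factor(m: ResponseMatrix, subset: ScaleDefinition | None = None) -> CFAFit:
    """Convenience wrapper: build and fit a one-factor CFA."""
    return OneFactorCFA(m, subset).fit()


def fit_indices(f: CFAFit) -> FitIndices:
    """CFI, TLI, and RMSEA from the model and baseline chi-square statistics.

    With df_model = 0 (saturated model) RMSEA is defined as 0 and TLI is
    undefined, reported as NaN.
    """
    if f.df_baseline <= 0:
        raise ValidationError("baseline degrees of freedom must be positive")
    d_model = max(f.chi2_model - f.df_model, 0.0)
    d_base = max(f.chi2_baseline - f.df_baseline, d_model, 0.0)
    cfi = 1.0 if d_base == 0 else 1.0 - d_model / d_base
    if f.df_model == 0:
        tli = math.nan
        rmsea = 0.0
    else:
        base_ratio = f.chi2_baseline / f.df_baseline
        tli = (base_ratio - f.chi2_model / f.df_model) / (base_ratio - 1.0)
        rmsea = math.sqrt(d_model / (f.df_model * (f.n - 1)))
    return FitIndices(cfi=float(cfi), tli=float(tli), rmsea=float(rmsea))
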