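"""Permutation inference engines.

Two engines drive every hypothesis test in the pipeline:

1. A repeated-measures linear mixed model (LMM) — fixed effects for task
   stage, group and their stage x group interaction (covariates of
   interest, CI) plus nuisance covariates (CNI), and a random intercept per
   subject.  The balanced two-observations-per-subject design lets the
   model be fitted exactly by profiling the variance ratio on the
   orthogonal within-subject (difference) / between-subject (sum)
   decomposition, with the REML variance denominator so that in the
   covariate-free case the stage t-statistic is identical to the paired
   t-test.  Inference is by within-subject permutation of the tested CI:
   stage labels are flipped independently per subject (a sign flip of the
   within-subject contrast); the between-subject group CI uses a
   Freedman-Lane reduced-model residual permutation across subjects.

2. Robust regression with Tukey bisquare M-estimation (tuning constant
   c = 4.685, scale = MAD/0.6745 re-estimated per IRLS iteration, OLS
   start) and a permutation Wald test: the Wald statistic W of the CI
   block, computed from the standard Huber-corrected robust-regression
   covariance, is recomputed under permutation of the CI regressor after
   residualising it on the nuisance columns, so its reference distribution
   is taken from the data rather than from an asymptotic chi-square (a
   Freedman-Lane residual-permutation scheme is available as an option).
   For a single CI, W = t^2 identically.

Permutation p-values are (b + 1)/(B + 1) with b the number of permuted
statistics at least as extreme as the observed one (two-sided throughout);
exhaustive enumeration replaces sampling when the flip space is small.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator

__all__ = [
    "bonferroni_threshold",
    "effect_size_label",
    "standardized_beta",
    "robust_fit",
    "robust_permutation_wald",
    "fit_lmm_repeated",
    "permutation_p_lmm",
    "PermutationResult",
    "RobustFit",
    "RobustPermutationRegressor",
    "RepeatedMeasuresPermutationLMM",
    "BISQUARE_C",
]

BISQUARE_C = 4.685  # 95% Gaussian efficiency tuning of the Tukey biweight
_MAD_NORM = 0.6745  # Phi^-1(0.75): makes MAD consistent for a Gaussian sd


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error threshold ``alpha / n_tests``."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def effect_size_label(beta: float) -> str:
    """Categorise |beta|: < 0.2 weak, 0.2 <= |beta| < 0.5 moderate, else strong."""
    b = abs(float(beta))
    if not np.isfinite(b):
        raise ValueError("beta must be finite")
    if b < 0.2:
        return "weak"
    if b < 0.5:
        return "moderate"
    return "strong"


def standardized_beta(coef: float, x: np.ndarray, y: np.ndarray) -> float:
    """Standardise a raw coefficient by sd(predictor)/sd(outcome).

    Binary predictors are standardised identically (by their sample sd).
    Equals the coefficient a refit on fully z-scored data would return.
    """
    sx = np.std(np.asarray(x, dtype=float), ddof=1)
    sy = np.std(np.asarray(y, dtype=float), ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance predictor or outcome")
    return float(coef) * sx / sy


@dataclass
class PermutationResult:
    """One CI's inference summary from a permutation engine."""

    name: str
    coefficient: float
    t: float
    wald: float
    std_beta: float
    p_value: float
    effect_size: str
    n_permutations: int
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "name": self.name, "coefficient": self.coefficient, "t": self.t,
            "wald": self.wald, "std_beta": self.std_beta,
            "p_value": self.p_value, "effect_size": self.effect_size,
            "n_permutations": self.n_permutations, "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# Tukey bisquare IRLS
# ---------------------------------------------------------------------------

def _bisquare_weights(z: np.ndarray, c: float) -> np.ndarray:
    u = z / c
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    return w


def _psi(z: np.ndarray, c: float) -> np.ndarray:
    return z * _bisquare_weights(z, c)


def _psi_prime(z: np.ndarray, c: float) -> np.ndarray:
    u = (z / c) ** 2
    out = (1.0 - u) * (1.0 - 5.0 * u)
    out[u >= 1.0] = 0.0
    return out


def _h1_factor(z, scale, n, p, c):
    """Huber-corrected variance factor of the M-estimate (the H1 form).

    ``cov = k^2 * [sum psi(z)^2 s^2 / (n-p)] / mean(psi'(z))^2 * (X'X)^-1``
    with ``k = 1 + p/n * var(psi') / mean(psi')^2`` — the standard robust
    regression covariance (MASS ``rlm`` / MATLAB ``robustfit``), for which
    the printed Wald statistic equals the squared t exactly.
    """
    psi = _psi(z, c)
    dpsi = _psi_prime(z, c)
    m = dpsi.mean()
    if m <= 0:
        return np.inf
    k = 1.0 + (p / n) * dpsi.var() / m**2
    return k**2 * (np.sum(psi**2) * scale**2 / (n - p)) / m**2


@dataclass
class RobustFit:
    """Converged bisquare M-estimate with Huber-corrected covariance."""

    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    cov: np.ndarray
    weights: np.ndarray
    scale: float
    converged: bool
    n_iter: int


def _mad_scale(resid: np.ndarray, axis=None) -> np.ndarray:
    return np.median(np.abs(resid), axis=axis) / _MAD_NORM


def _zero_scale(y, axis=None):
    """Threshold below which a residual scale counts as a perfect fit."""
    return 1e-10 * (np.median(np.abs(y), axis=axis) + 1.0)


def robust_fit(
    y, X, c: float = BISQUARE_C, tol: float = 1e-8, max_iter: int = 50
) -> RobustFit:
    """IRLS bisquare M-estimation of ``y = X b + e``.

    The design must be full rank and include its own intercept column.
    The covariance is the Huber-corrected H1 form (see :func:`_h1_factor`).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    tiny = _zero_scale(y)
    converged = False
    n_iter = 0
    scale = 0.0
    for n_iter in range(1, max_iter + 1):
        resid = y - X @ coef
        scale = float(_mad_scale(resid))
        if scale <= tiny:  # perfect fit
            scale = 0.0
            converged = True
            break
        w = _bisquare_weights(resid / scale, c)
        sw = np.sqrt(w)
        new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        delta = np.max(np.abs(new - coef))
        coef = new
        if delta < tol:
            converged = True
            break
    resid = y - X @ coef
    scale = float(_mad_scale(resid))
    if scale <= tiny:
        scale = 0.0
        weights = np.ones(n)
        cov = np.zeros((p, p))
    else:
        z = resid / scale
        weights = _bisquare_weights(z, c)
        cov = _h1_factor(z, scale, n, p, c) * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    coef_tiny = 1e-10 * (1.0 + np.abs(coef).max())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se,
                     np.where(np.abs(coef) <= coef_tiny, 0.0, np.inf))
    return RobustFit(coef, se, t, cov, weights, scale, converged, n_iter)


def _batched_irls(
    X: np.ndarray, Y: np.ndarray, c: float, tol: float, max_iter: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """IRLS over a batch of regression problems.

    ``X`` is (n, p) (shared design) or (B, n, p) (per-problem designs);
    ``Y`` is (B, n).  Returns coefficients (B, p), residuals (B, n) and
    scales (B,).  Used to refit the robust model under every permutation.
    """
    if X.ndim == 2:
        Xb = np.broadcast_to(X, (Y.shape[0],) + X.shape)
    else:
        Xb = X
    nB, n, p = Xb.shape
    XT = np.swapaxes(Xb, 1, 2)  # (B, p, n)
    # OLS start
    A0 = XT @ Xb
    rhs0 = np.einsum("bpn,bn->bp", XT, Y)
    coefs = _batch_solve(A0, rhs0)
    active = np.ones(nB, dtype=bool)
    scales = np.zeros(nB)
    tiny = _zero_scale(Y, axis=1)
    for _ in range(max_iter):
        R = Y - np.einsum("bnp,bp->bn", Xb, coefs)
        s = _mad_scale(R, axis=1)
        scales = s
        zero = s <= tiny
        active &= ~zero
        if not active.any():
            break
        idx = np.flatnonzero(active)
        Z = R[idx] / (c * s[idx, None])
        W = (1.0 - Z**2) ** 2
        W[np.abs(Z) >= 1.0] = 0.0  # (b_active, n)
        XtW = XT[idx] * W[:, None, :]                  # (b, p, n)
        A = XtW @ Xb[idx]                               # (b, p, p)
        rhs = np.einsum("bpn,bn->bp", XtW, Y[idx])
        new = _batch_solve(A, rhs)
        delta = np.max(np.abs(new - coefs[idx]), axis=1)
        coefs[idx] = new
        done = delta < tol
        active[idx[done]] = False
        if not active.any():
            break
    R = Y - np.einsum("bnp,bp->bn", Xb, coefs)
    scales = _mad_scale(R, axis=1)
    scales[scales <= tiny] = 0.0
    return coefs, R, scales


def _batch_solve(A, rhs):
    try:
        return np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        return np.stack([np.linalg.lstsq(A[i], rhs[i], rcond=None)[0]
                         for i in range(A.shape[0])])


def _batched_wald(
    X: np.ndarray, coefs: np.ndarray, R: np.ndarray, scales: np.ndarray,
    ci_idx: np.ndarray, c: float,
) -> np.ndarray:
    """H1-covariance Wald statistic of the CI block for each batched fit.

    ``X`` is (n, p) or (B, n, p) matching :func:`_batched_irls`; ``R`` is
    (B, n).
    """
    shared = X.ndim == 2
    n, p = (X.shape if shared else X.shape[1:])
    nB = coefs.shape[0]
    W = np.empty(nB)
    ok = scales > 0
    W[~ok] = np.inf  # perfect fit: infinitely precise
    idx = np.flatnonzero(ok)
    if idx.size:
        Z = R[idx] / scales[idx, None]  # (b, n)
        u = (Z / c) ** 2
        psi = Z * (1.0 - u) ** 2
        psi[u >= 1.0] = 0.0
        dpsi = (1.0 - u) * (1.0 - 5.0 * u)
        dpsi[u >= 1.0] = 0.0
        m = dpsi.mean(axis=1)
        safe_m2 = np.where(m > 0, m**2, 1.0)
        k = 1.0 + (p / n) * dpsi.var(axis=1) / safe_m2
        factor = np.where(
            m > 0,
            k**2 * (np.sum(psi**2, axis=1) * scales[idx] ** 2 / (n - p))
            / safe_m2,
            np.inf,
        )
        b_ci = coefs[idx][:, ci_idx]
        if shared:
            xtx_inv_ci = np.linalg.pinv(X.T @ X)[np.ix_(ci_idx, ci_idx)]
            quad_mat = np.linalg.pinv(xtx_inv_ci)
            quad = np.einsum("bi,ij,bj->b", b_ci, quad_mat, b_ci)
        else:
            Xb = X[idx]
            xtx_inv = np.linalg.pinv(np.swapaxes(Xb, 1, 2) @ Xb)
            sub = xtx_inv[:, ci_idx[:, None], ci_idx[None, :]]
            quad_mat = np.linalg.pinv(sub)
            quad = np.einsum("bi,bij,bj->b", b_ci, quad_mat, b_ci)
        with np.errstate(divide="ignore", invalid="ignore"):
            W[idx] = np.where(np.isfinite(factor), quad / factor, 0.0)
    return W


class RobustPermutationRegressor(BaseEstimator):
    """Bisquare robust regression with a permutation Wald test for one CI block.

    Parameters
    ----------
    ci : sequence of column names or indices
        The covariate(s) of interest whose joint Wald statistic is tested;
        default is the first design column.
    n_permutations : int, default 1000
        Number of permutations B; p = (b+1)/(B+1).
    permute : {"regressor", "residuals"}, default "regressor"
        Null-generation scheme.  ``"regressor"`` permutes the CI columns
        after residualising them on the nuisance columns (the studentized
        regressor-permutation approach, valid under heteroscedastic
        errors); ``"residuals"`` is the Freedman-Lane scheme permuting
        reduced-model robust residuals.
    seed : int or numpy Generator, optional
    fit_intercept : bool, default True
        Append an intercept column (always part of the nuisance set).
    c, tol, max_iter : IRLS tuning (bisquare constant, coefficient
        convergence tolerance, iteration cap).

    Attributes
    ----------
    coef_, intercept_ : robust coefficient estimates.
    result_ : :class:`PermutationResult` for the CI block.
    fit_ : full :class:`RobustFit` on the observed data.
    """

    def __init__(self, ci=None, n_permutations: int = 1000, seed=None,
                 permute: str = "regressor", fit_intercept: bool = True,
                 c: float = BISQUARE_C, tol: float = 1e-8, max_iter: int = 50):
        self.ci = ci
        self.n_permutations = n_permutations
        self.seed = seed
        self.permute = permute
        self.fit_intercept = fit_intercept
        self.c = c
        self.tol = tol
        self.max_iter = max_iter

    def _design(self, X):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim == 1:
                values = values[:, None]
            names = list(range(values.shape[1]))
        if self.fit_intercept:
            values = np.column_stack([values, np.ones(len(values))])
            names = names + ["const"]
        return values, names

    def fit(self, X, y):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        y = np.asarray(y, dtype=float)
        design, names = self._design(X)
        ci = self.ci if self.ci is not None else [names[0]]
        ci_idx = np.array([names.index(c) if not isinstance(c, (int, np.integer))
                           else int(c) for c in np.atleast_1d(ci)])
        rng = np.random.default_rng(self.seed)

        fit = robust_fit(y, design, self.c, self.tol, self.max_iter)
        cov_ci = fit.cov[np.ix_(ci_idx, ci_idx)]
        b_ci = fit.coef[ci_idx]
        if np.all(cov_ci == 0):
            coef_tiny = 1e-10 * (1.0 + np.abs(fit.coef).max())
            w_obs = np.inf if np.any(np.abs(b_ci) > coef_tiny) else 0.0
        else:
            w_obs = float(b_ci @ np.linalg.solve(cov_ci, b_ci))

        n = len(y)
        B = int(self.n_permutations)
        exhaustive = math.factorial(n) <= B
        if exhaustive:
            perms = np.array(list(itertools.permutations(range(n))))  # (n!, n)
        else:
            perms = np.stack([rng.permutation(n) for _ in range(B)], axis=0)
        keep = np.setdiff1d(np.arange(design.shape[1]), ci_idx)
        if self.permute == "regressor":
            # residualise the CI block on the nuisance columns, permute it
            Znui = design[:, keep]
            xci = design[:, ci_idx]
            x_res = xci - Znui @ np.linalg.lstsq(Znui, xci, rcond=None)[0]
            Xb = np.broadcast_to(design, (perms.shape[0],) + design.shape).copy()
            Xb[:, :, ci_idx] = x_res[perms]
            Yb = np.broadcast_to(y, (perms.shape[0], n))
            coefs, R, scales = _batched_irls(Xb, Yb, self.c, self.tol,
                                             self.max_iter)
            w_null = _batched_wald(Xb, coefs, R, scales, ci_idx, self.c)
        elif self.permute == "residuals":
            # Freedman-Lane: permute reduced-model robust residuals
            reduced = robust_fit(y, design[:, keep], self.c, self.tol,
                                 self.max_iter)
            fitted_red = design[:, keep] @ reduced.coef
            resid_red = y - fitted_red
            Ystar = fitted_red[None, :] + resid_red[perms]
            coefs, R, scales = _batched_irls(design, Ystar, self.c, self.tol,
                                             self.max_iter)
            w_null = _batched_wald(design, coefs, R, scales, ci_idx, self.c)
        else:
            raise ValueError("permute must be 'regressor' or 'residuals'")
        w_tol = 1e-8 * (1.0 + abs(w_obs)) if np.isfinite(w_obs) else 0.0
        b_count = int(np.sum(w_null >= w_obs - w_tol))
        if exhaustive:  # identity permutation is in the enumeration
            B = perms.shape[0]
            p = b_count / B
        else:
            p = (b_count + 1) / (B + 1)

        j = ci_idx[0]
        if design[:, j].std(ddof=1) > 0 and y.std(ddof=1) > 0:
            beta = standardized_beta(fit.coef[j], design[:, j], y)
        else:
            beta = 0.0
        self.names_ = names
        self.ci_idx_ = ci_idx
        self.fit_ = fit
        self.coef_ = fit.coef[:-1] if self.fit_intercept else fit.coef
        self.intercept_ = fit.coef[-1] if self.fit_intercept else 0.0
        self.null_wald_ = w_null
        self.result_ = PermutationResult(
            name="+".join(str(names[i]) for i in ci_idx),
            coefficient=float(fit.coef[ci_idx[0]]),
            t=float(fit.t[ci_idx[0]]),
            wald=float(w_obs),
            std_beta=float(beta),
            p_value=float(p),
            effect_size=effect_size_label(beta),
            n_permutations=B,
            converged=fit.converged,
        )
        return self

    def predict(self, X):
        design, _ = self._design(X)
        full = np.append(self.coef_, self.intercept_) if self.fit_intercept \
            else self.coef_
        return design @ full


def robust_permutation_wald(
    y, design, ci_columns, n_permutations: int = 1000, seed=None, **kwargs
) -> PermutationResult:
    """Functional wrapper around :class:`RobustPermutationRegressor`.

    ``design`` must already include any intercept column.
    """
    est = RobustPermutationRegressor(
        ci=ci_columns, n_permutations=n_permutations, seed=seed,
        fit_intercept=False, **kwargs,
    )
    est.fit(design, y)
    return est.result_


# ---------------------------------------------------------------------------
# Balanced repeated-measures LMM
# ---------------------------------------------------------------------------

@dataclass
class LmmFit:
    """REML fit of the balanced two-observation random-intercept model."""

    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    names: list
    sigma2_resid: float
    sigma2_subject: float
    n_subjects: int

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "t": self.t}, index=self.names
        )


def _reml_balanced(Xd, Xs, yd, ys):
    """Profile-REML solve on the difference/sum decomposition.

    Rows of (Xd, yd) are within-subject contrasts (variance sigma_e^2),
    rows of (Xs, ys) between-subject sums (variance sigma_e^2 (1+2*lam))
    with lam = sigma_b^2 / sigma_e^2.  REML profile over lam is a 1-D
    bounded optimisation; every evaluation is one weighted least squares.
    """
    n = len(yd)
    X = np.vstack([Xd, Xs])
    y = np.concatenate([yd, ys])
    N, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design")

    def solve(lam):
        w = np.concatenate([np.ones(n), np.full(n, 1.0 / (1.0 + 2.0 * lam))])
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        yw = y * sw
        coef, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        rss = float(np.sum((yw - Xw @ coef) ** 2))
        return coef, rss, Xw

    def crit(log_lam):
        lam = np.exp(log_lam)
        _, rss, Xw = solve(lam)
        sigma2 = max(rss / (N - p), 1e-300)
        sign, logdet = np.linalg.slogdet(Xw.T @ Xw)
        return (N - p) * np.log(sigma2) + n * np.log1p(2.0 * lam) + logdet

    res = minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    if crit(-30.0) < res.fun:  # boundary sigma_b^2 -> 0
        lam = 0.0
    coef, rss, Xw = solve(lam)
    sigma2 = rss / (N - p)
    cov = sigma2 * np.linalg.pinv(Xw.T @ Xw)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, coef / se, 0.0)
    return coef, se, t, sigma2, lam * sigma2


class RepeatedMeasuresPermutationLMM(BaseEstimator):
    """Stage/group/interaction LMM with within-subject permutation tests.

    The long table must contain exactly two rows per subject (one per task
    stage).  Fixed effects: stage, group, stage x group (the CIs; the
    interaction regressor is the elementwise product of the 0/1 stage and
    group codings) plus the CNI columns and an intercept; a random
    intercept per subject absorbs each participant's average level.

    Permutation schemes (B draws, p = (b+1)/(B+1), two-sided on |t|):

    - ``stage``: flip the stage labels of each subject independently in the
      stage regressor and refit.
    - ``interaction``: rebuild the interaction regressor from
      independently flipped stage labels, keeping the observed stage main
      effect modelled, and refit.
    - ``group``: Freedman-Lane — permute reduced-model residuals at the
      subject level across subjects, refit the full model.

    When the flip space ``2^n_subjects`` does not exceed ``n_permutations``
    the stage/interaction tests enumerate it exhaustively, making the
    p-value seed-independent.
    """

    def __init__(self, n_permutations: int = 1000, seed=None,
                 ci=("stage", "group", "interaction")):
        self.n_permutations = n_permutations
        self.seed = seed
        self.ci = ci

    # -- model assembly -----------------------------------------------------

    def _assemble(self, data, outcome, subject, stage, group, cni):
        df = data.sort_values([subject, stage], kind="stable")
        counts = df.groupby(subject, sort=False).size()
        if not (counts == 2).all():
            raise ValueError("every subject needs exactly 2 stage rows")
        subj_ids = df[subject].to_numpy()[::2]
        y = df[outcome].to_numpy(dtype=float)
        st = df[stage].to_numpy(dtype=float)
        gr = df[group].to_numpy(dtype=float)
        cni = list(cni)
        if np.ptp(gr) == 0:  # single-group data: stage-only model
            cols = [st]
            names = ["stage"]
        else:
            cols = [st, gr, st * gr]
            names = ["stage", "group", "interaction"]
        for c in cni:
            cols.append(df[c].to_numpy(dtype=float))
            names.append(c)
        cols.append(np.ones(len(df)))
        names.append("const")
        X = np.column_stack(cols)
        return subj_ids, y, st, gr, X, names

    @staticmethod
    def _diff_sum(M: np.ndarray):
        a, b = M[0::2], M[1::2]
        inv = 1.0 / np.sqrt(2.0)
        return (b - a) * inv, (a + b) * inv

    def _fit_design(self, X, y):
        Xd, Xs = self._diff_sum(X)
        yd, ys = self._diff_sum(y)
        return _reml_balanced(Xd, Xs, yd, ys)

    def fit(self, data: pd.DataFrame, outcome: str, subject: str = "participant",
            stage: str = "stage", group: str = "group", cni=()):
        subj_ids, y, st, gr, X, names = self._assemble(
            data, outcome, subject, stage, group, cni)
        coef, se, t, s2e, s2b = _reml_balanced(*self._diff_sum(X),
                                               *self._diff_sum(y))
        n_sub = len(subj_ids)
        self.model_ = LmmFit(coef, se, t, names, s2e, s2b, n_sub)
        self.design_ = X
        self.names_ = names
        self.outcome_ = y
        self.stage_codes_ = st
        self.group_codes_ = gr
        self.subject_ids_ = subj_ids

        rng = np.random.default_rng(self.seed)
        B = int(self.n_permutations)
        if B < 1:
            raise ValueError("n_permutations must be >= 1")
        results = {}
        for ci_name in self.ci:
            results[ci_name] = self._permute_ci(ci_name, rng, B)
        self.results_ = results
        return self

    # -- permutation schemes ------------------------------------------------

    def _refit_t(self, X, y, col):
        coef, se, t, *_ = _reml_balanced(*self._diff_sum(X), *self._diff_sum(y))
        return t[col]

    def _permute_ci(self, ci_name, rng, B) -> PermutationResult:
        X, y, names = self.design_, self.outcome_, self.names_
        col = names.index(ci_name)
        t_obs = self.model_.t[col]
        n_sub = self.model_.n_subjects

        if ci_name in ("stage", "interaction"):
            exhaustive = n_sub <= 30 and 2**n_sub <= B
            if exhaustive:
                flip_sets = (
                    np.array(np.meshgrid(*([[0, 1]] * n_sub), indexing="ij"))
                    .reshape(n_sub, -1).T
                )
            else:
                flip_sets = rng.integers(0, 2, size=(B, n_sub))
            t_null = np.empty(len(flip_sets))
            for i, flips in enumerate(flip_sets):
                f = np.repeat(flips, 2)
                st_perm = np.where(f == 1, 1.0 - self.stage_codes_,
                                   self.stage_codes_)
                Xp = X.copy()
                if ci_name == "stage":
                    Xp[:, names.index("stage")] = st_perm
                else:
                    Xp[:, names.index("interaction")] = st_perm * self.group_codes_
                t_null[i] = self._refit_t(Xp, y, col)
            tol = 1e-6 * (1.0 + abs(t_obs))
            if exhaustive:
                p = float(np.mean(np.abs(t_null) >= abs(t_obs) - tol))
                n_real = len(flip_sets)
            else:
                b = int(np.sum(np.abs(t_null) >= abs(t_obs) - tol))
                p = (b + 1) / (B + 1)
                n_real = B
        else:  # group: Freedman-Lane across subjects
            keep = [i for i in range(X.shape[1]) if i != col]
            coef_r, *_ = _reml_balanced(*self._diff_sum(X[:, keep]),
                                        *self._diff_sum(y))
            fitted = X[:, keep] @ coef_r
            resid = y - fitted
            t_null = np.empty(B)
            for i in range(B):
                order = rng.permutation(n_sub)
                idx = np.empty(2 * n_sub, dtype=int)
                idx[0::2] = 2 * order
                idx[1::2] = 2 * order + 1
                ystar = fitted + resid[idx]
                t_null[i] = self._refit_t(X, ystar, col)
            tol = 1e-6 * (1.0 + abs(t_obs))
            b = int(np.sum(np.abs(t_null) >= abs(t_obs) - tol))
            p = (b + 1) / (B + 1)
            n_real = B

        xcol = X[:, col]
        beta = standardized_beta(self.model_.coef[col], xcol, y) \
            if xcol.std(ddof=1) > 0 and y.std(ddof=1) > 0 else 0.0
        return PermutationResult(
            name=ci_name,
            coefficient=float(self.model_.coef[col]),
            t=float(t_obs),
            wald=float(t_obs**2),
            std_beta=float(beta),
            p_value=float(p),
            effect_size=effect_size_label(beta),
            n_permutations=n_real,
        )


def fit_lmm_repeated(data, outcome, subject="participant", stage="stage",
                     group="group", cni=()) -> LmmFit:
    """Fit the repeated-measures LMM without permutation inference."""
    est = RepeatedMeasuresPermutationLMM(n_permutations=1, ci=())
    est.fit(data, outcome, subject=subject, stage=stage, group=group, cni=cni)
    return est.model_


def permutation_p_lmm(data, outcome, subject="participant", stage="stage",
                      group="group", cni=(), n_permutations=1000, seed=None,
                      ci=("stage", "group", "interaction")) -> dict:
    """Permutation results per CI of the repeated-measures LMM."""
    est = RepeatedMeasuresPermutationLMM(
        n_permutations=n_permutations, seed=seed, ci=ci)
    est.fit(data, outcome, subject=subject, stage=stage, group=group, cni=cni)
    return est.results_
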