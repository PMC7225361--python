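"""Two-stage genetic-risk-score test for gene-environment interaction.

Stage one regresses the phenotype on non-genetic covariates, takes the
response-scale residuals, and estimates per-SNP weights by penalized least
squares on the gene's dosage matrix:

    minimize  sum_i (eps_i - b0 - sum_j b_j G_ij)^2  +  lambda * P(b),

with P the ridge (sum b_j^2), lasso (sum |b_j|), or elastic-net
((1-a)/2 sum b_j^2 + a sum |b_j|, mixing a = 0.5 by default) penalty and an
unpenalized intercept.  lambda is chosen to minimize 10-fold cross-validated
MSE over a log-spaced grid.  The weighted allele-count score
GRS'_i = sum_j b_j G_ij is standardized to a Z-score.

Stage two fits the generalized linear model

    g[E(Y_i)] = g0 + gG GRS_i + gE E_i + gInt GRS_i x E_i + gC' X_i

and tests H0: gInt = 0 (two-sided Wald).  A significantly positive gInt
means the exposure exacerbates the gene's trait-increasing effect; negative
means it attenuates it.  Because the weights are estimated on the same
sample, validity rests on the asymptotic independence of marginal-effect
filtering and the interaction estimate under the null; the simulation
harness in :mod:`grsgxe.experiments` verifies the resulting calibration
empirically.

Both stages may legitimately use the whole sample — no data splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path

from ._glm import ConvergenceError, fit_glm
from .data_io import CohortTable, GenotypePanel

__all__ = [
    "AdjustedPhenotype",
    "PenalizedWeights",
    "GRSVector",
    "GxEResult",
    "DegenerateGRSError",
    "SingularDesignError",
    "InestimableInteractionError",
    "adjust_covariates",
    "fit_ols_weights",
    "fit_penalized_weights",
    "build_grs",
    "test_grs_by_e",
    "run_grs_pipeline",
    "PENALIZED_METHODS",
]

PENALIZED_METHODS = ("ridge", "lasso", "enet")


class DegenerateGRSError(ValueError):
    """All slope weights are exactly zero; the score carries no information."""


class SingularDesignError(np.linalg.LinAlgError):
    """The genotype design is rank-deficient where an exact solve is needed."""


class InestimableInteractionError(ValueError):
    """The interaction term cannot be estimated (e.g. constant exposure)."""


@dataclass
class AdjustedPhenotype:
    """Response-scale residuals from the covariate-only null model."""

    residuals: np.ndarray
    null_fit_coefficients: np.ndarray
    family: str = "gaussian"


@dataclass
class PenalizedWeights:
    """Estimated SNP weights beta_0..beta_L with the selection metadata."""

    beta_hat: np.ndarray          # length L+1; [0] is the intercept
    method: str                   # ols | ridge | lasso | enet
    lambda_: float                # on the total-RSS objective scale
    alpha_mix: float              # elastic-net mixing (1 = lasso, 0 = ridge)
    cv_mse_path: np.ndarray | None = None   # (n_lambda, 2): lambda, CV MSE

    @property
    def slopes(self) -> np.ndarray:
        return self.beta_hat[1:]

    def selected_snps(self) -> np.ndarray:
        """Indices with nonzero slope (the lasso/enet marginal filter)."""
        return np.flatnonzero(self.slopes != 0.0)


@dataclass
class GRSVector:
    """Raw and standardized (Z-score) genetic risk scores."""

    raw: np.ndarray
    standardized: np.ndarray


@dataclass
class GxEResult:
    """Outcome of the GRS-by-exposure interaction test."""

    gamma_int_hat: float
    se: float
    p_value: float
    direction: str                 # exacerbation | attenuation | none
    gamma_G_hat: float
    gamma_E_hat: float
    n: int
    L: int
    method: str
    family: str
    alpha: float = 0.05
    lambda_: float | None = None
    alpha_mix: float | None = None
    degenerate: bool = False
    selected: np.ndarray | None = None   # SNPs passing the marginal filter

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "selected"}
        d["selected"] = (None if self.selected is None
                         else [int(i) for i in self.selected])
        return d


# ---------------------------------------------------------------------------
# stage one: covariate adjustment and weight estimation
# ---------------------------------------------------------------------------

def adjust_covariates(cohort: CohortTable) -> AdjustedPhenotype:
    """Regress Y on covariates and return response-scale residuals.

    Gaussian: eps = Y - (a0 + a'X).  Binomial: eps = Y - expit(a0 + a'X).
    With no covariates this reduces to centering Y at its mean (gaussian) or
    at the prevalence (binomial).
    """
    X = np.column_stack([np.ones(cohort.n), cohort.covariates])
    res = fit_glm(cohort.y, X, cohort.family)
    mu = np.asarray(res.fittedvalues)  # response scale for both families
    return AdjustedPhenotype(residuals=cohort.y - mu,
                             null_fit_coefficients=np.asarray(res.params),
                             family=cohort.family)


def fit_ols_weights(eps: AdjustedPhenotype,
                    panel: GenotypePanel) -> PenalizedWeights:
    """Exact least-squares weights; fails loudly on a collinear gene.

    This is the lambda -> 0 limit of ridge and the reason penalization is
    needed at all: with strong LD the normal-equations matrix is singular.
    """
    G = panel.imputed_dosages()
    X = np.column_stack([np.ones(panel.n_samples), G])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise SingularDesignError(
            f"genotype design is rank-deficient (rank {rank} < {X.shape[1]}); "
            "use ridge/lasso/enet")
    beta, *_ = np.linalg.lstsq(X, eps.residuals, rcond=None)
    return PenalizedWeights(beta_hat=beta, method="ols", lambda_=0.0,
                            alpha_mix=0.0)


def _ridge_path_gram(gram: np.ndarray, xty: np.ndarray,
                     lambdas: np.ndarray) -> np.ndarray:
    """Ridge solutions for all penalties at once from the Gram matrix.

    One symmetric eigendecomposition of X'X gives the whole path:
    b(lambda) = V diag(1/(d + lambda)) V' X'y.  Returns (p, K).
    """
    d, V = np.linalg.eigh(gram)
    d = np.clip(d, 0.0, None)
    w = V.T @ xty
    return V @ (w[:, None] / (d[:, None] + lambdas[None, :]))


def _ridge_path(Xc: np.ndarray, yc: np.ndarray,
                lambdas: np.ndarray) -> np.ndarray:
    """Ridge solutions for the total-RSS objective ||yc - Xc b||^2 + lambda ||b||^2.

    ``Xc``/``yc`` are column-centered (or otherwise intercept-free); returns
    a (p, K) coefficient matrix.
    """
    return _ridge_path_gram(Xc.T @ Xc, Xc.T @ yc, lambdas)


def _lambda_grid(Xc: np.ndarray, yc: np.ndarray, method: str,
                 alpha_mix: float, n_lambda: int = 100,
                 ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced penalty grid on the total-RSS scale, descending.

    lambda_max is the smallest penalty nulling every slope for lasso/enet
    (2 max|Xc'yc| / alpha_mix); for ridge, which never reaches exact zero, a
    data-scaled cap of 1000 x the lasso lambda_max is used.
    """
    lmax_l1 = 2.0 * np.max(np.abs(Xc.T @ yc))
    if lmax_l1 <= 0:
        return np.array([])
    if method == "lasso":
        lmax = lmax_l1
    elif method == "enet":
        lmax = lmax_l1 / alpha_mix
    else:  # ridge
        lmax = 1000.0 * lmax_l1
    return np.geomspace(lmax, lmax * ratio, n_lambda)


def _cv_folds(n: int, folds: int, seed: int) -> list[np.ndarray]:
    perm = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def fit_penalized_weights(eps: AdjustedPhenotype, panel: GenotypePanel,
                          method: str = "ridge", alpha_mix: float = 0.5,
                          folds: int = 10, seed: int = 0,
                          n_lambda: int = 100) -> PenalizedWeights:
    """Penalized SNP weights with the penalty chosen by minimum CV MSE.

    Fold assignment is a seeded random permutation split as evenly as
    possible; the reported ``lambda_`` and the CV path are on the printed
    total-RSS scale, so solver-internal per-observation scalings (the
    scikit-learn coordinate-descent convention divides the RSS by 2n) are
    mapped back before reporting.  The minimum-MSE rule is deliberate: the
    more conservative one-standard-error rule tends to select zero SNPs for
    a single gene, which destroys the score.
    """
    if method not in PENALIZED_METHODS:
        raise ValueError(f"method must be one of {PENALIZED_METHODS}")
    if method == "lasso":
        alpha_mix = 1.0
    if not 0.0 <= alpha_mix <= 1.0:
        raise ValueError("alpha_mix must lie in [0, 1]")
    G = panel.imputed_dosages()
    y = np.asarray(eps.residuals, dtype=float)
    n = G.shape[0]
    if folds > n:
        raise ValueError(f"folds={folds} exceeds sample size {n}")

    xmean_full = G.mean(axis=0)
    ymean_full = y.mean()
    Xc_full = G - xmean_full
    yc_full = y - ymean_full
    grid = _lambda_grid(Xc_full, yc_full, method, alpha_mix, n_lambda)
    if grid.size == 0:  # constant residual: intercept-only model
        warnings.warn("adjusted phenotype is constant; all slopes set to 0")
        beta = np.concatenate([[ymean_full], np.zeros(G.shape[1])])
        return PenalizedWeights(beta_hat=beta, method=method, lambda_=0.0,
                                alpha_mix=alpha_mix)

    # full-sample sufficient statistics let each fold's centered Gram be
    # obtained by downdating instead of re-multiplying the training block
    gram_full = G.T @ G
    xty_raw = G.T @ y
    colsum = G.sum(axis=0)
    ysum = y.sum()

    sq_err = np.zeros(grid.size)
    for test_idx in _cv_folds(n, folds, seed):
        Xe, ye = G[test_idx], y[test_idx]
        n_t = n - test_idx.size
        xm = (colsum - Xe.sum(axis=0)) / n_t
        ym = (ysum - ye.sum()) / n_t
        gram_t = gram_full - Xe.T @ Xe - n_t * np.outer(xm, xm)
        xty_t = xty_raw - Xe.T @ ye - n_t * xm * ym
        if method == "ridge":
            B = _ridge_path_gram(gram_t, xty_t, grid)
        else:
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            alphas_sk = grid / (2.0 * n_t)
            Xtc = np.asfortranarray(G[mask] - xm)
            _, B, _ = enet_path(Xtc, np.ascontiguousarray(y[mask] - ym),
                                l1_ratio=alpha_mix, alphas=alphas_sk,
                                precompute=np.ascontiguousarray(gram_t),
                                Xy=np.ascontiguousarray(xty_t),
                                check_input=False)
        preds = (Xe - xm) @ B + ym
        sq_err += ((ye[:, None] - preds) ** 2).sum(axis=0)
    cv_mse = sq_err / n
    best = int(np.argmin(cv_mse))
    lam = float(grid[best])

    if method == "ridge":
        slopes = _ridge_path(Xc_full, yc_full, np.array([lam]))[:, 0]
    else:
        model = ElasticNet(alpha=lam / (2.0 * n), l1_ratio=alpha_mix,
                           fit_intercept=True, max_iter=10_000, tol=1e-8)
        model.fit(G, y)
        slopes = model.coef_
    intercept = ymean_full - xmean_full @ slopes
    return PenalizedWeights(
        beta_hat=np.concatenate([[intercept], slopes]),
        method=method, lambda_=lam, alpha_mix=alpha_mix,
        cv_mse_path=np.column_stack([grid, cv_mse]))


# ---------------------------------------------------------------------------
# stage two: score construction and the interaction test
# ---------------------------------------------------------------------------

def build_grs(panel: GenotypePanel, weights: PenalizedWeights) -> GRSVector:
    """Weighted allele-count score, standardized to mean 0 / SD 1 (ddof 1).

    The intercept is excluded: it shifts every subject equally and cancels
    in the standardization.  A larger score always means a larger expected
    phenotype, because each weight already carries the direction in which
    its minor allele moves the trait.
    """
    slopes = weights.slopes
    if slopes.shape[0] != panel.n_variants:
        raise ValueError("weight length must match panel variant count")
    if np.all(slopes == 0.0):
        raise DegenerateGRSError(
            "all slope weights are exactly zero; no score can be formed")
    raw = panel.imputed_dosages() @ slopes
    sd = raw.std(ddof=1)
    if sd == 0.0:
        raise DegenerateGRSError("risk score is constant across subjects")
    return GRSVector(raw=raw, standardized=(raw - raw.mean()) / sd)


def test_grs_by_e(cohort: CohortTable, grs: GRSVector,
                  alpha: float = 0.05, *, method: str = "grs",
                  L: int | None = None, lambda_: float | None = None,
                  alpha_mix: float | None = None) -> GxEResult:
    """Fit g[E(Y)] = g0 + gG GRS + gE E + gInt GRS x E + gC'X; Wald-test gInt.

    ``direction`` is "exacerbation" (significant, gInt > 0), "attenuation"
    (significant, gInt < 0) or "none".  For binomial traits exp(gInt) is the
    modifier of the per-SD score odds ratio between exposure levels.
    """
    e = cohort.exposure
    if np.ptp(e) == 0.0:
        raise InestimableInteractionError("exposure is constant")
    z = grs.standardized
    if np.ptp(z) == 0.0:
        raise InestimableInteractionError("risk score is constant")
    X = np.column_stack([np.ones(cohort.n), z, e, z * e, cohort.covariates])
    res = fit_glm(cohort.y, X, cohort.family)
    gamma_int = float(res.params[3])
    p = float(res.pvalues[3])
    if p < alpha:
        direction = "exacerbation" if gamma_int > 0 else "attenuation"
    else:
        direction = "none"
    return GxEResult(
        gamma_int_hat=gamma_int, se=float(res.bse[3]), p_value=p,
        direction=direction, gamma_G_hat=float(res.params[1]),
        gamma_E_hat=float(res.params[2]), n=cohort.n,
        L=L if L is not None else -1, method=method, family=cohort.family,
        alpha=alpha, lambda_=lambda_, alpha_mix=alpha_mix)


def run_grs_pipeline(cohort: CohortTable, panel: GenotypePanel,
                     method: str = "ridge", seed: int = 0,
                     alpha: float = 0.05, alpha_mix: float = 0.5,
                     folds: int = 10) -> GxEResult:
    """The full two-stage procedure on the whole sample.

    A degenerate score (all lasso/enet weights shrunk to zero) is reported
    as a non-finding — p = 1, direction "none", ``degenerate`` flag set —
    rather than raised, so that simulation loops can keep running.
    """
    if cohort.n != panel.n_samples:
        raise ValueError("cohort and panel sample counts differ")
    eps = adjust_covariates(cohort)
    weights = fit_penalized_weights(eps, panel, method=method,
                                    alpha_mix=alpha_mix, folds=folds,
                                    seed=seed)
    selected = weights.selected_snps() if method in ("lasso", "enet") else None
    try:
        grs = build_grs(panel, weights)
    except DegenerateGRSError:
        return GxEResult(
            gamma_int_hat=0.0, se=float("nan"), p_value=1.0, direction="none",
            gamma_G_hat=0.0, gamma_E_hat=0.0, n=cohort.n, L=panel.n_variants,
            method=method, family=cohort.family, alpha=alpha,
            lambda_=weights.lambda_, alpha_mix=weights.alpha_mix,
            degenerate=True, selected=selected)
    result = test_grs_by_e(cohort, grs, alpha=alpha, method=method,
                           L=panel.n_variants, lambda_=weights.lambda_,
                           alpha_mix=weights.alpha_mix)
    result.selected = selected
    return result
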