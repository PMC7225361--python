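"""Competing gene-by-environment interaction tests.

Three established set-based alternatives to the penalized-GRS test, under a
common in-memory interface:

* **SBERIA** — screens SNPs one at a time for marginal association
  (p < 0.1), builds a sign-only risk score ``w_j = I(p_j < 0.1) sign(b_j) + nu``
  (nu a tiny offset so the score is defined even when nothing passes), and
  Wald-tests the score-by-exposure term in a model that also keeps every
  individual SNP main effect.  Like the GRS tests it reports a direction.

* **Variance-component score test** (iSKAT-style) — treats the per-SNP
  interaction coefficients as random with variance tau and score-tests
  H0: tau = 0.  The null model contains the exposure, covariates, and all
  SNP main effects, fit with ridge regularization so that LD-induced
  collinearity cannot break it.  The statistic Q = ||S'r||^2 (S the centered
  SNP-by-exposure design, r the null residuals) is referred to its weighted
  chi-square null distribution by an exact-tail Imhof integral with a
  moment-matching fallback.

* **ADABF** — computes an approximate Bayes factor for every SNP x E
  interaction from its Wald summary, then adaptively aggregates the top-k
  log Bayes factors over all k = 1..L, taking the best (smallest) per-k
  resampling p-value as the statistic; overall significance comes from the
  same multivariate-normal resamples of the interaction z-scores, with
  sequential early stopping once the Monte-Carlo p-value is resolved.

The variance-component and ADABF tests give p-values only; they never claim
an interaction direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import stats
from scipy.special import expit

from ._glm import fit_glm
from ._quadform import quadform_pvalue
from .data_io import CohortTable, GenotypePanel
from .grs_gxe import (GxEResult, InestimableInteractionError,
                      SingularDesignError, _cv_folds, _ridge_path)

__all__ = [
    "MarginalScanResult",
    "VarianceComponentResult",
    "ADABFResult",
    "marginal_scan",
    "sberia_test",
    "iskat_test",
    "compute_interaction_bf",
    "adabf_test",
]


@dataclass
class MarginalScanResult:
    """Per-SNP marginal association estimates (one model per SNP)."""

    beta_hat: np.ndarray
    p_values: np.ndarray
    selected: np.ndarray          # boolean, p < threshold
    threshold: float


@dataclass
class VarianceComponentResult:
    """Score statistic for H0: tau = 0 and its weighted-chi-square p-value."""

    Q: float
    eigenvalues: np.ndarray
    p_value: float
    lambda_: float
    n: int
    L: int
    method: str = "iskat"


@dataclass
class ADABFResult:
    """Adaptive top-k Bayes-factor aggregation with resampled significance."""

    z_scores: np.ndarray
    se: np.ndarray
    bayes_factors: np.ndarray
    per_k_p: np.ndarray
    best_k: int
    p_value: float
    n_resamples_used: int
    at_resampling_floor: bool
    method: str = "adabf"


# ---------------------------------------------------------------------------
# marginal scan (one SNP at a time, covariate-adjusted)
# ---------------------------------------------------------------------------

def marginal_scan(cohort: CohortTable, panel: GenotypePanel,
                  p_threshold: float = 0.1) -> MarginalScanResult:
    """Fit Y ~ G_j + covariates separately for each SNP j.

    Gaussian fits use the Frisch-Waugh-Lovell identity (residualize Y and
    every G_j on the covariates once, then slope each pair), which is exact
    and avoids L separate dense solves.  Binomial fits loop over logistic
    models.
    """
    G = panel.imputed_dosages()
    n, L = G.shape
    W = np.column_stack([np.ones(n), cohort.covariates])
    if cohort.family == "gaussian":
        Wpinv = np.linalg.pinv(W)
        My = cohort.y - W @ (Wpinv @ cohort.y)
        MG = G - W @ (Wpinv @ G)
        den = (MG ** 2).sum(axis=0)
        den = np.where(den > 0, den, np.nan)
        beta = (MG * My[:, None]).sum(axis=0) / den
        dof = n - W.shape[1] - 1
        rss = (My @ My) - beta ** 2 * den
        se = np.sqrt(np.maximum(rss, 0.0) / dof / den)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        p = np.where(np.isfinite(p), p, 1.0)
        beta = np.nan_to_num(beta)
    else:
        beta = np.empty(L)
        p = np.empty(L)
        for j in range(L):
            res = fit_glm(cohort.y, np.column_stack([W, G[:, j]]),
                          "binomial")
            beta[j], p[j] = res.params[-1], res.pvalues[-1]
    return MarginalScanResult(beta_hat=beta, p_values=p,
                              selected=p < p_threshold, threshold=p_threshold)


# ---------------------------------------------------------------------------
# SBERIA
# ---------------------------------------------------------------------------

def _drop_aliased(protected: np.ndarray, candidates: np.ndarray,
                  tol: float = 1e-9) -> tuple[np.ndarray, list[int]]:
    """QR-with-pivoting rank filter: keep candidate columns up to full rank.

    Protected columns (intercept, exposure, score-by-exposure, covariates)
    must survive; the dropped candidate indices are returned for logging.
    """
    A = np.column_stack([protected, candidates])
    _, R, piv = sla.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int((diag > tol * diag[0]).sum()) if diag.size else 0
    keep = set(piv[:rank].tolist())
    n_prot = protected.shape[1]
    if not set(range(n_prot)) <= keep:
        raise SingularDesignError(
            "design remains rank-deficient after dropping aliased SNP columns")
    kept_idx = [j for j in range(candidates.shape[1]) if (n_prot + j) in keep]
    dropped = [j for j in range(candidates.shape[1]) if (n_prot + j) not in keep]
    return np.array(kept_idx, dtype=int), dropped


def sberia_test(cohort: CohortTable, panel: GenotypePanel,
                p_threshold: float = 0.1, nu: float = 1e-4,
                alpha: float = 0.05) -> GxEResult:
    """Screened sign-score interaction test.

    Stage one is :func:`marginal_scan`; stage two keeps all SNP main effects
    (dropping exactly aliased columns) alongside the standardized score-by-
    exposure product and Wald-tests that interaction.
    """
    if np.ptp(cohort.exposure) == 0.0:
        raise InestimableInteractionError("exposure is constant")
    scan = marginal_scan(cohort, panel, p_threshold)
    w = scan.selected * np.sign(scan.beta_hat) + nu
    G = panel.imputed_dosages()
    raw = G @ w
    sd = raw.std(ddof=1)
    if sd == 0.0:
        raise InestimableInteractionError("sign score is constant")
    z = (raw - raw.mean()) / sd

    protected = np.column_stack([np.ones(cohort.n), cohort.exposure,
                                 z * cohort.exposure, cohort.covariates])
    kept, _dropped = _drop_aliased(protected, G)
    X = np.column_stack([protected, G[:, kept]])
    res = fit_glm(cohort.y, X, cohort.family)
    gamma_int, p = float(res.params[2]), float(res.pvalues[2])
    direction = ("none" if p >= alpha
                 else "exacerbation" if gamma_int > 0 else "attenuation")
    return GxEResult(
        gamma_int_hat=gamma_int, se=float(res.bse[2]), p_value=p,
        direction=direction, gamma_G_hat=float("nan"),
        gamma_E_hat=float(res.params[1]), n=cohort.n, L=panel.n_variants,
        method="sberia", family=cohort.family, alpha=alpha,
        selected=np.flatnonzero(scan.selected))


# ---------------------------------------------------------------------------
# variance-component score test (iSKAT-style)
# ---------------------------------------------------------------------------

def _ridge_lambda_cv(Gt: np.ndarray, yt: np.ndarray, folds: int,
                     seed: int, n_lambda: int = 50) -> float:
    """CV-minimum ridge penalty for an already-projected design (no centering).

    The grid is capped at the lasso-scale lambda_max: the null-model ridge
    only needs to stabilize LD-induced near-singularity, and heavy shrinkage
    would leak genetic main effects into the score residuals and distort the
    score test's null distribution.
    """
    lmax = 2.0 * np.max(np.abs(Gt.T @ yt))
    if lmax <= 0:
        return 1.0
    grid = np.geomspace(lmax, lmax * 1e-4, n_lambda)
    n = Gt.shape[0]
    sq = np.zeros(n_lambda)
    for test_idx in _cv_folds(n, folds, seed):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        B = _ridge_path(Gt[mask], yt[mask], grid)
        sq += ((yt[test_idx, None] - Gt[test_idx] @ B) ** 2).sum(axis=0)
    return float(grid[int(np.argmin(sq))])


def iskat_test(cohort: CohortTable, panel: GenotypePanel, seed: int = 0,
               folds: int = 10) -> VarianceComponentResult:
    """Variance-component score test of any SNP-by-exposure interaction.

    Null model: intercept + covariates + exposure unpenalized, all SNP main
    effects under a ridge penalty (CV-chosen) so that LD cannot make the fit
    singular.  Q = r'SS'r with r the null residuals and S the column-centered
    G_j * E matrix; the null distribution is the matching weighted sum of
    one-degree chi-squares, with weights from the eigenvalues of the
    residual-projected kernel.
    """
    G = panel.imputed_dosages()
    n, L = G.shape
    q = cohort.covariates.shape[1] + 2
    if n <= q + L:
        raise ValueError(f"n={n} too small for L={L} SNPs plus {q} fixed terms")
    W = np.column_stack([np.ones(n), cohort.covariates, cohort.exposure])
    S = G * cohort.exposure[:, None]
    S = S - S.mean(axis=0)

    if cohort.family == "gaussian":
        Wpinv = np.linalg.pinv(W)
        My = cohort.y - W @ (Wpinv @ cohort.y)
        Gt = G - W @ (Wpinv @ G)          # SNPs residualized on fixed terms
        lam = _ridge_lambda_cv(Gt, My, folds, seed)
        A = Gt.T @ Gt + lam * np.eye(L)
        b = np.linalg.solve(A, Gt.T @ My)
        r = My - Gt @ b
        edf = float(np.trace(np.linalg.solve(A, Gt.T @ Gt)))
        sigma2 = float(r @ r) / max(n - W.shape[1] - edf, 1.0)
        # project the interaction columns off the whole null column space
        # (fixed terms AND SNP main effects): genetic main-effect signal that
        # ridge shrinkage leaves in r then cannot reach the score, and with
        # L = 1 the statistic reduces to the classical score test exactly
        MS = S - W @ (Wpinv @ S)
        S = MS - Gt @ (np.linalg.pinv(Gt) @ MS)
        kernel = sigma2 * (S.T @ S)
    else:
        lam = _ridge_lambda_cv(G - W @ (np.linalg.pinv(W) @ G),
                               cohort.y - cohort.y.mean(), folds, seed)
        X = np.column_stack([W, G])
        D = np.zeros(X.shape[1])
        D[W.shape[1]:] = lam
        beta = np.zeros(X.shape[1])
        for _ in range(30):  # penalized IRLS
            eta = X @ beta
            mu = expit(eta)
            v = np.clip(mu * (1.0 - mu), 1e-10, None)
            zwork = eta + (cohort.y - mu) / v
            XtV = X.T * v
            new = np.linalg.solve(XtV @ X + np.diag(D), XtV @ zwork)
            if np.max(np.abs(new - beta)) < 1e-8:
                beta = new
                break
            beta = new
        mu = expit(X @ beta)
        r = cohort.y - mu
        v = np.clip(mu * (1.0 - mu), 1e-10, None)
        # working-metric projection of the interaction columns off the whole
        # null design, mirroring the gaussian branch
        XtV = X.T * v
        B = np.linalg.solve(XtV @ X + 1e-8 * np.eye(X.shape[1]), XtV @ S)
        S = S - X @ B
        kernel = (S * v[:, None]).T @ S

    Q = float(np.sum((S.T @ r) ** 2))
    if not np.isfinite(Q):
        raise FloatingPointError("non-finite score statistic")
    eigs = np.linalg.eigvalsh((kernel + kernel.T) / 2.0)
    eigs = np.clip(eigs, 0.0, None)
    if eigs.max() <= 0:
        raise FloatingPointError("degenerate kernel: no positive eigenvalues")
    p = quadform_pvalue(Q, eigs)
    return VarianceComponentResult(Q=Q, eigenvalues=eigs, p_value=p,
                                   lambda_=lam, n=n, L=L)


# ---------------------------------------------------------------------------
# ADABF
# ---------------------------------------------------------------------------

def compute_interaction_bf(z: float, se: float, prior_var: float) -> float:
    """Approximate Bayes factor Pr(data|H1)/Pr(data|H0) from a Wald summary.

    With a N(0, psi) prior on the interaction coefficient and estimate
    b = z * se with sampling variance se^2, the marginal-likelihood ratio is

        BF = sqrt(se^2 / (se^2 + psi)) * exp(z^2 psi / (2 (se^2 + psi))).

    BF < 1 at z = 0, is strictly increasing in |z|, and tends to 1 as the
    prior collapses (psi -> 0).
    """
    if not (np.isfinite(z) and np.isfinite(se) and np.isfinite(prior_var)):
        raise ValueError("inputs must be finite")
    if se <= 0 or prior_var <= 0:
        raise ValueError("se and prior_var must be positive")
    shrink = se ** 2 / (se ** 2 + prior_var)
    return float(np.sqrt(shrink) * np.exp(z ** 2 * prior_var
                                          / (2.0 * (se ** 2 + prior_var))))


def _interaction_scan(cohort: CohortTable, panel: GenotypePanel
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP interaction Wald z, se, and residualized G_j*E columns.

    Each SNP gets its own model Y ~ G_j + E + G_j*E + covariates.  The third
    return value holds each interaction column residualized on that model's
    remaining terms — the ingredients of the null z-score correlation.
    """
    G = panel.imputed_dosages()
    n, L = G.shape
    e = cohort.exposure
    base = np.column_stack([np.ones(n), e, cohort.covariates])
    z_arr = np.empty(L)
    se_arr = np.empty(L)
    U = np.empty((n, L))
    if cohort.family == "gaussian":
        for j in range(L):
            gj = G[:, j]
            X0 = np.column_stack([base, gj])          # everything but G_j*E
            s = gj * e
            X0pinv = np.linalg.pinv(X0)
            u = s - X0 @ (X0pinv @ s)
            ry = cohort.y - X0 @ (X0pinv @ cohort.y)
            den = u @ u
            if den <= 1e-12:
                z_arr[j], se_arr[j], U[:, j] = 0.0, np.inf, 0.0
                continue
            beta = (u @ ry) / den
            dof = n - X0.shape[1] - 1
            rss = ry @ ry - beta ** 2 * den
            se = np.sqrt(max(rss, 0.0) / dof / den)
            z_arr[j], se_arr[j], U[:, j] = beta / se, se, u
    else:
        for j in range(L):
            gj = G[:, j]
            X = np.column_stack([base, gj, gj * e])
            res = fit_glm(cohort.y, X, "binomial")
            b, se = float(res.params[-1]), float(res.bse[-1])
            z_arr[j], se_arr[j] = b / se, se
            # working-scale residualization for the correlation estimate
            mu = np.asarray(res.fittedvalues)
            v = np.sqrt(np.clip(mu * (1 - mu), 1e-10, None))
            X0v = X[:, :-1] * v[:, None]
            sv = (gj * e) * v
            U[:, j] = sv - X0v @ (np.linalg.pinv(X0v) @ sv)
    return z_arr, se_arr, U


def adabf_test(cohort: CohortTable, panel: GenotypePanel,
               prior_var: float = 0.04, max_resamples: int = 1000,
               alpha_stop: float = 0.05, seed: int = 0,
               stop_exceedances: int = 50, chunk: int = 200) -> ADABFResult:
    """Adaptive combination of per-SNP interaction Bayes factors.

    The statistic is min over k of the resampling p-value of T_k = the sum
    of the k largest log Bayes factors; its own significance is read off the
    same null resamples (z-vectors drawn from a multivariate normal with the
    empirical correlation of the interaction-score contributions).  Resampling
    stops early once ``stop_exceedances`` null statistics at least as extreme
    as the observed one have accumulated, a conservative sequential rule with
    p-hat = (r + 1) / (B + 1).
    """
    if max_resamples < 100:
        raise ValueError("max_resamples must be at least 100")
    z, se, U = _interaction_scan(cohort, panel)
    L = z.size
    finite = np.isfinite(se)
    bf = np.ones(L)
    for j in np.flatnonzero(finite):
        bf[j] = compute_interaction_bf(z[j], se[j], prior_var)

    c = np.where(finite, prior_var / (2.0 * (se ** 2 + prior_var)), 0.0)
    const = np.where(finite,
                     0.5 * np.log(se ** 2 / (se ** 2 + prior_var)), 0.0)
    logbf_obs = const + c * z ** 2
    T_obs = np.cumsum(np.sort(logbf_obs)[::-1])

    # null correlation of the interaction z-scores
    norms = np.linalg.norm(U, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    R = (U / norms).T @ (U / norms)
    R = (R + R.T) / 2.0 + 1e-8 * np.eye(L)
    chol = np.linalg.cholesky(R)

    rng = np.random.default_rng(seed)
    pools: list[np.ndarray] = []
    n_used = 0
    while True:
        size = min(chunk, max_resamples - n_used)
        Z = rng.standard_normal((size, L)) @ chol.T
        pools.append(const + c * Z ** 2)
        n_used += size
        logbf_null = np.vstack(pools)
        T_null = np.cumsum(np.sort(logbf_null, axis=1)[:, ::-1], axis=1)
        B = T_null.shape[0]
        p_k_obs = (1.0 + (T_null >= T_obs).sum(axis=0)) / (B + 1.0)
        minp_obs = p_k_obs.min()
        p_null = stats.rankdata(-T_null, axis=0, method="max") / (B + 1.0)
        minp_null = p_null.min(axis=1)
        exceed = int((minp_null <= minp_obs).sum())
        if exceed >= stop_exceedances or n_used >= max_resamples:
            break
    p_value = (exceed + 1.0) / (n_used + 1.0)
    # floor: the observed statistic beat every resample at its best k, so the
    # p-value is only an upper bound set by the budget
    at_floor = (n_used >= max_resamples
                and minp_obs <= 1.0 / (n_used + 1.0) + 1e-12)
    return ADABFResult(
        z_scores=z, se=se, bayes_factors=bf, per_k_p=p_k_obs,
        best_k=int(np.argmin(p_k_obs)) + 1, p_value=float(p_value),
        n_resamples_used=n_used, at_resampling_floor=at_floor)
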