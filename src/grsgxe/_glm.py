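"""Small shared wrappers around statsmodels GLM fits."""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm


class ConvergenceError(RuntimeError):
    """A GLM fit failed to converge (e.g. separation in a logistic fit)."""


def fit_glm(y: np.ndarray, X: np.ndarray, family: str):
    """Fit an identity-link gaussian or logit-link binomial model.

    Returns the statsmodels results object.  Wald-type coefficient tests are
    available via ``params`` / ``bse`` / ``pvalues`` (t-based for gaussian,
    normal-based for binomial).
    """
    if family == "gaussian":
        return sm.OLS(y, X).fit()
    if family == "binomial":
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception as exc:  # pragma: no cover - statsmodels wraps errors
            raise ConvergenceError(f"logistic fit failed: {exc}") from exc
        if not np.all(np.isfinite(res.bse)):
            raise ConvergenceError(
                "logistic fit produced non-finite standard errors "
                "(possible separation)")
        return res
    raise ValueError(f"unknown family {family!r}")
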