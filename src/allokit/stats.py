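"""Shared statistical machinery for nested-model comparison and errors.

The extra-sum-of-squares F-test is the package's single arbiter for "is the
more complex model warranted": shared vs free plateaus, Hill slopes vs 1,
and the number of components in a multiphasic fit all go through
:func:`extra_ss_ftest` at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["FTestResult", "extra_ss_ftest", "covariance_from_jacobian"]


@dataclass(frozen=True)
class FTestResult:
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    ss_reduced: float
    ss_full: float

    @property
    def prefers_full(self) -> bool:
        """True when the richer model is justified at alpha = 0.05."""
        return self.p_value < 0.05


def extra_ss_ftest(ss_reduced: float, df_reduced: int,
                   ss_full: float, df_full: int) -> FTestResult:
    """Compare nested least-squares fits by the extra-sum-of-squares F-test.

    The *reduced* model is the constrained one (fewer parameters, more
    residual degrees of freedom).  A small p-value rejects the constraint.
    """
    if df_reduced <= df_full:
        raise ValueError("reduced model must have more residual dof than full")
    if df_full <= 0:
        raise ValueError("full model has no residual degrees of freedom")
    df_num = df_reduced - df_full
    # numerical guard: constrained SS can dip below full SS by round-off
    extra = max(ss_reduced - ss_full, 0.0)
    if ss_full <= 0:
        f = 0.0 if extra == 0 else np.inf
    else:
        f = (extra / df_num) / (ss_full / df_full)
    p = float(sps.f.sf(f, df_num, df_full)) if np.isfinite(f) else 0.0
    return FTestResult(float(f), p, df_num, df_full, float(ss_reduced), float(ss_full))


def covariance_from_jacobian(jac: np.ndarray, residuals: np.ndarray,
                             n_params: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Asymptotic covariance of least-squares estimates from the Jacobian.

    Returns ``(cov, stderr)`` where ``cov = s2 * (J'J)^-1`` with
    ``s2 = SS / dof``.  Singular directions get infinite standard errors
    rather than raising, so ill-conditioned fits stay inspectable.
    """
    n_obs = residuals.size
    p = n_params if n_params is not None else jac.shape[1]
    dof = max(n_obs - p, 1)
    s2 = float(residuals @ residuals) / dof
    jtj = jac.T @ jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.inf
    return cov, np.sqrt(diag)
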