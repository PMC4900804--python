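"""Saturation binding with a Hill slope, nonspecific binding and optional
receptor depletion.

Total binding at total radioligand concentration [P]_t follows

    B_obsd = B_sp + NS * ([P]_t - c * B_sp)

where specific binding B_sp satisfies the implicit relation

    B_sp = Bmax * ([P]_t - c*B_sp)^nH / (K^nH + ([P]_t - c*B_sp)^nH)

NS is the fraction of unbound radioligand appearing as nonspecific binding,
and c converts bound signal to molar so that [P]_t - c*B_sp is the free
concentration.  With the default c = 0 the free concentration equals the
total (no depletion) and B_sp has the familiar closed form; with c > 0 the
relation is solved per point by bracketed root-finding (the residual is
strictly monotone in B_sp, so the root is unique).

Replicate curves are fitted globally: log K, nH and NS are shared, maximal
binding Bmax is per experiment.  A fit with nH free is compared against the
nH = 1 constraint by an extra-sum-of-squares F-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .datasets import SaturationCurve
from .exceptions import (FitFailureError, InfeasibleParameterError,
                         InvalidParameterError, UnidentifiableError)
from .stats import FTestResult, covariance_from_jacobian, extra_ss_ftest

__all__ = ["eval_saturation", "SaturationModel", "SaturationResults"]


def _specific_binding(p_total: float, bmax: float, k: float, nh: float,
                      c: float) -> float:
    """Solve the implicit specific-binding relation for one concentration."""
    if c == 0.0:
        return bmax * p_total ** nh / (k ** nh + p_total ** nh)

    def resid(b):
        free = p_total - c * b
        if free <= 0:
            return b           # positive: beyond feasible occupancy
        return b - bmax * free ** nh / (k ** nh + free ** nh)

    hi = min(bmax, p_total / c)
    lo = 0.0
    f_lo, f_hi = resid(lo), resid(hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise InfeasibleParameterError(
            f"no root for B_sp in [0, {hi:.3g}] at [P]_t = {p_total:.3g}")
    return brentq(resid, lo, hi, xtol=1e-15, rtol=1e-14)


def eval_saturation(p_total, bmax: float, log_k: float, nh: float = 1.0,
                    ns: float = 0.0, signal_to_molar: float = 0.0):
    """Total binding (specific + nonspecific) at total concentrations ``p_total``."""
    p = np.atleast_1d(np.asarray(p_total, dtype=float))
    for name, v in (("bmax", bmax), ("log_k", log_k), ("nh", nh), ("ns", ns)):
        if not np.isfinite(v):
            raise InvalidParameterError(f"{name} must be finite")
    if bmax <= 0 or nh <= 0:
        raise InvalidParameterError("bmax and nh must be > 0")
    if not 0 <= ns < 1:
        raise InvalidParameterError("ns must lie in [0, 1)")
    if np.any(p <= 0):
        raise InvalidParameterError("p_total must be > 0")
    k = 10.0 ** log_k
    c = signal_to_molar
    b_sp = np.array([_specific_binding(pi, bmax, k, nh, c) for pi in p])
    out = b_sp + ns * (p - c * b_sp)
    return out if np.ndim(p_total) else float(out[0])


@dataclass(frozen=True)
class SaturationResults:
    """Global saturation fit: shared affinity/slope/NS, per-experiment Bmax."""

    log_k: float
    log_k_stderr: float
    nh: float
    nh_stderr: float | None
    nh_fixed: bool
    ns: float
    ns_stderr: float
    bmax: np.ndarray
    bmax_stderr: np.ndarray
    experiment_ids: list[str]
    ssr: float
    df_resid: int
    signal_to_molar: float
    nh_test: FTestResult | None = None
    _curves: tuple[SaturationCurve, ...] = field(default=(), repr=False)

    @property
    def k_molar(self) -> float:
        return 10.0 ** self.log_k

    def predict(self, p_total, experiment: int | str = 0) -> np.ndarray:
        idx = (self.experiment_ids.index(experiment)
               if isinstance(experiment, str) else experiment)
        return eval_saturation(p_total, self.bmax[idx], self.log_k, self.nh,
                               self.ns, self.signal_to_molar)

    def normalize_replicates(self) -> pd.DataFrame:
        from .replicates import normalize_replicates
        return normalize_replicates(self)

    def summary(self) -> str:
        nh_se = "fixed" if self.nh_stderr is None else f"{self.nh_stderr:.3f}"
        lines = ["Saturation binding fit", "=" * 60,
                 f"experiments: {len(self.experiment_ids)}    "
                 f"SSR: {self.ssr:.6g}    df_resid: {self.df_resid}",
                 f"log K  = {self.log_k:.3f} +/- {self.log_k_stderr:.3f}"
                 f"  (K = {self.k_molar:.3g} M)",
                 f"nH     = {self.nh:.3f} ({nh_se})",
                 f"NS     = {self.ns:.4f} +/- {self.ns_stderr:.4f}"]
        for i, eid in enumerate(self.experiment_ids):
            lines.append(f"Bmax[{eid}] = {self.bmax[i]:.4g} "
                         f"+/- {self.bmax_stderr[i]:.2g}")
        if self.nh_test is not None:
            lines.append(f"nH vs 1: F = {self.nh_test.f_stat:.3f}, "
                         f"p = {self.nh_test.p_value:.3f}")
        return "\n".join(lines)


class SaturationModel:
    """Global fit of saturation binding curves.

    ``nh_policy`` follows the modulation convention: ``"fixed"`` pins
    nH = 1, ``"free"`` fits it, ``"tested"`` fits it and keeps the
    constraint when the F-test against nH = 1 gives p >= 0.05.
    """

    def __init__(self, curves, nh_policy: str = "tested",
                 signal_to_molar: float = 0.0):
        curves = ([curves] if isinstance(curves, SaturationCurve)
                  else list(curves))
        if not curves:
            raise InvalidParameterError("at least one curve is required")
        for cu in curves:
            if np.unique(cu.ligand_conc_total).size < 6:
                raise InvalidParameterError(
                    "each curve needs >= 6 distinct concentrations")
        if nh_policy not in ("fixed", "free", "tested"):
            raise InvalidParameterError("nh_policy must be fixed|free|tested")
        # identifiability guard: a flat specific component cannot pin K
        for cu in curves:
            y = cu.bound
            if np.ptp(y) < 1e-12 * max(abs(y).max(), 1.0):
                raise UnidentifiableError(
                    f"curve {cu.experiment_id} is flat: K is unidentifiable")
        self.curves = curves
        self.nh_policy = nh_policy
        self.c = signal_to_molar
        # residuals are fitted on a unit data scale so convergence criteria
        # behave identically for molar-unit and arbitrary-unit signals
        self._yscale = max(float(np.abs(cu.bound).max()) for cu in curves) or 1.0

    # layout: [log_k, ns, (nh)] + [bmax_e]*E

    def _residuals(self, theta, free_nh):
        log_k, ns = theta[0], theta[1]
        nh = theta[2] if free_nh else 1.0
        bmaxes = theta[(3 if free_nh else 2):]
        res = []
        for bmax, cu in zip(bmaxes, self.curves):
            try:
                pred = eval_saturation(cu.ligand_conc_total, bmax, log_k, nh,
                                       ns, self.c)
            except InfeasibleParameterError:
                return np.full(sum(c.bound.size for c in self.curves), 1e6)

            res.append((pred - cu.bound) / self._yscale)
        return np.concatenate(res)

    def _solve(self, free_nh):
        all_p = np.concatenate([c.ligand_conc_total for c in self.curves])
        # seed NS from the linear tail slope and Bmax from the residual
        # plateau, so a dominant nonspecific component does not mislead the fit
        ns0s, bmax0s = [], []
        for cu in self.curves:
            order = np.argsort(cu.ligand_conc_total)
            p_s, y_s = cu.ligand_conc_total[order], cu.bound[order]
            if p_s[-1] > p_s[-2]:
                ns0s.append((y_s[-1] - y_s[-2]) / (p_s[-1] - p_s[-2]))
            bmax0s.append(float(np.max(y_s - np.clip(ns0s[-1] if ns0s else 0.0,
                                                     0, 0.999) * p_s)))
        ns0 = float(np.clip(np.median(ns0s) if ns0s else 0.01, 0.0, 0.5))
        log_k0 = float(np.median(np.log10(all_p)))
        theta0 = [log_k0, ns0]
        lb = [-15.0, 0.0]
        ub = [0.0, 0.999]
        if free_nh:
            theta0.append(1.0); lb.append(0.2); ub.append(5.0)
        for cu, bmax0 in zip(self.curves, bmax0s):
            theta0.append(max(bmax0, 0.5 * float(cu.bound.max()), 1e-12))
            lb.append(1e-12); ub.append(np.inf)
        sol = least_squares(self._residuals, theta0, args=(free_nh,),
                            bounds=(lb, ub), method="trf", x_scale="jac",
                            ftol=1e-13, xtol=1e-13, gtol=1e-13)
        if not (sol.success or sol.status > 0):
            raise FitFailureError("saturation fit did not converge",
                                  {"status": sol.status, "message": sol.message})
        return sol

    def fit(self) -> SaturationResults:
        n_obs = sum(c.bound.size for c in self.curves)
        e = len(self.curves)
        sol_fixed = self._solve(free_nh=False) if self.nh_policy != "free" else None
        sol_free = self._solve(free_nh=True) if self.nh_policy != "fixed" else None
        nh_test = None
        if self.nh_policy == "fixed":
            sol, free_nh = sol_fixed, False
        elif self.nh_policy == "free":
            sol, free_nh = sol_free, True
        else:
            nh_test = extra_ss_ftest(2 * sol_fixed.cost, n_obs - (2 + e),
                                     2 * sol_free.cost, n_obs - (3 + e))
            sol, free_nh = ((sol_free, True) if nh_test.prefers_full
                            else (sol_fixed, False))
        n_par = (3 if free_nh else 2) + e
        _, stderr = covariance_from_jacobian(sol.jac, sol.fun, n_par)
        off = 3 if free_nh else 2
        return SaturationResults(
            log_k=float(sol.x[0]), log_k_stderr=float(stderr[0]),
            nh=float(sol.x[2]) if free_nh else 1.0,
            nh_stderr=float(stderr[2]) if free_nh else None,
            nh_fixed=not free_nh,
            ns=float(sol.x[1]), ns_stderr=float(stderr[1]),
            bmax=sol.x[off:].copy(), bmax_stderr=stderr[off:].copy(),
            experiment_ids=[c.experiment_id for c in self.curves],
            ssr=2 * sol.cost * self._yscale ** 2, df_resid=n_obs - n_par,
            signal_to_molar=self.c, nh_test=nh_test,
            _curves=tuple(self.curves))
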