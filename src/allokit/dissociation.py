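"""Monoexponential dissociation kinetics with shared-plateau global fitting.

Net dissociation of a pre-bound radioligand follows

    B(t) = (B_t0 - B_inf) * exp(-k_obsd * t) + B_inf

Time courses at graded modulator concentrations are analysed in concert: each
trace has its own rate constant k_obsd and initial level B_t0, while the
asymptote B_inf may be shared across traces (the default, tested against the
free-plateau alternative by an extra-sum-of-squares F-test).  Rates are
normalised to the modulator-free control (k0) to give the relative rate
k_obsd/k0 that downstream modulation fits consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .datasets import DissociationTrace, ModulationCurve
from .exceptions import (FitFailureError, InvalidParameterError,
                         MissingControlError)
from .stats import FTestResult, covariance_from_jacobian, extra_ss_ftest

__all__ = ["eval_dissociation", "DissociationModel", "DissociationResults"]


def eval_dissociation(t, b_t0: float, b_inf: float, k_obsd: float):
    """Monoexponential decay from B_t0 toward B_inf with rate k_obsd (1/min)."""
    t = np.asarray(t, dtype=float)
    if not (np.isfinite(b_t0) and np.isfinite(b_inf) and np.isfinite(k_obsd)):
        raise InvalidParameterError("dissociation parameters must be finite")
    if k_obsd <= 0:
        raise InvalidParameterError("k_obsd must be > 0")
    if np.any(t < 0):
        raise InvalidParameterError("time must be >= 0")
    return (b_t0 - b_inf) * np.exp(-k_obsd * t) + b_inf


@dataclass(frozen=True)
class DissociationResults:
    """Global monoexponential fit over one or more dissociation traces."""

    k_obsd: np.ndarray
    k_obsd_stderr: np.ndarray
    b_t0: np.ndarray
    b_inf: np.ndarray            # one shared value broadcast, or per trace
    modulator_conc: np.ndarray
    shared_b_inf: bool
    k0: float | None
    relative_rates: np.ndarray | None
    ssr: float
    df_resid: int
    share_test: FTestResult | None = None
    _traces: tuple[DissociationTrace, ...] = field(default=(), repr=False)

    def predict(self, trace_index: int, t) -> np.ndarray:
        return eval_dissociation(t, self.b_t0[trace_index],
                                 self.b_inf[trace_index],
                                 self.k_obsd[trace_index])

    def rate_curve(self, experiment_id: str = "dissociation") -> ModulationCurve:
        """Relative rates vs modulator concentration, ready for modulation fits."""
        if self.relative_rates is None:
            raise MissingControlError(
                "no control trace: relative rates are unavailable")
        return ModulationCurve(modulator_conc=self.modulator_conc,
                               response=self.relative_rates,
                               experiment_id=experiment_id)

    def summary(self) -> str:
        lines = ["Dissociation kinetics fit", "=" * 60,
                 f"traces: {self.k_obsd.size}    shared B_inf: {self.shared_b_inf}",
                 f"SSR: {self.ssr:.6g}    df_resid: {self.df_resid}",
                 "-" * 60,
                 f"{'[A] (M)':>12}{'k_obsd (1/min)':>16}{'SE':>10}{'B_t0':>10}{'B_inf':>10}"]
        for i in range(self.k_obsd.size):
            lines.append(f"{self.modulator_conc[i]:>12.3g}{self.k_obsd[i]:>16.5g}"
                         f"{self.k_obsd_stderr[i]:>10.2g}{self.b_t0[i]:>10.4g}"
                         f"{self.b_inf[i]:>10.4g}")
        if self.relative_rates is not None:
            lines.append("-" * 60)
            lines.append("k_obsd/k0: " +
                         ", ".join(f"{r:.4g}" for r in self.relative_rates))
        if self.share_test is not None:
            lines.append(f"shared vs free B_inf: F = {self.share_test.f_stat:.3f}, "
                         f"p = {self.share_test.p_value:.3f}")
        return "\n".join(lines)


class DissociationModel:
    """Fit Eq-of-motion-free monoexponential dissociation, globally.

    ``share_b_inf=True`` (default) fits a single asymptote across traces and
    reports the F-test against trace-specific asymptotes.  Relative rates
    are computed whenever a control (modulator-free) trace is present;
    ``require_control=True`` turns their absence into an error.
    """

    def __init__(self, traces, share_b_inf: bool = True,
                 require_control: bool = False):
        traces = ([traces] if isinstance(traces, DissociationTrace)
                  else list(traces))
        if not traces:
            raise InvalidParameterError("at least one trace is required")
        for tr in traces:
            if tr.times.size < 4:
                raise InvalidParameterError(
                    "each trace needs >= 4 time points")
        self.traces = traces
        self.share_b_inf = share_b_inf
        self.require_control = require_control

    # layout (shared):  [k_i, b0_i]*m + [b_inf]
    # layout (free):    [k_i, b0_i, binf_i]*m

    def _residuals(self, theta, shared):
        m = len(self.traces)
        res = []
        for i, tr in enumerate(self.traces):
            if shared:
                k, b0 = theta[2 * i], theta[2 * i + 1]
                binf = theta[-1]
            else:
                k, b0, binf = theta[3 * i:3 * i + 3]
            res.append((b0 - binf) * np.exp(-k * tr.times) + binf - tr.bound)
        return np.concatenate(res)

    def _initial(self, shared):
        theta, binfs = [], []
        for tr in self.traces:
            binf = float(tr.bound.min())
            b0 = float(tr.bound[0])
            span = max(b0 - binf, 1e-12)
            # crude log-linear slope for the rate seed
            y = np.clip((tr.bound - binf) / span, 1e-6, None)
            with np.errstate(divide="ignore"):
                slope = np.polyfit(tr.times, np.log(y), 1)[0]
            k0 = max(-slope, 1e-6)
            theta.extend([k0, b0])
            if not shared:
                theta.append(binf)
            binfs.append(binf)
        if shared:
            theta.append(float(np.mean(binfs)))
        return np.asarray(theta)

    def _solve(self, shared):
        theta0 = self._initial(shared)
        lb = np.full(theta0.size, -np.inf)
        m = len(self.traces)
        if shared:
            lb[0:2 * m:2] = 1e-12      # rates positive
        else:
            lb[0::3] = 1e-12
        sol = least_squares(self._residuals, np.maximum(theta0, lb + 1e-15),
                            args=(shared,), bounds=(lb, np.inf),
                            method="trf", x_scale="jac")
        if not (sol.success or sol.status > 0):
            raise FitFailureError("dissociation fit did not converge",
                                  {"status": sol.status, "message": sol.message})
        return sol

    def fit(self) -> DissociationResults:
        m = len(self.traces)
        n_obs = sum(tr.times.size for tr in self.traces)
        share_test = None
        if self.share_b_inf and m > 1:
            sol_s = self._solve(shared=True)
            sol_f = self._solve(shared=False)
            share_test = extra_ss_ftest(2 * sol_s.cost, n_obs - (2 * m + 1),
                                        2 * sol_f.cost, n_obs - 3 * m)
            sol, shared = sol_s, True
            n_par = 2 * m + 1
        else:
            shared = self.share_b_inf and m == 1
            sol = self._solve(shared=shared)
            n_par = 2 * m + 1 if shared else 3 * m
        _, stderr = covariance_from_jacobian(sol.jac, sol.fun, n_par)
        if shared:
            k = sol.x[0:2 * m:2]
            k_se = stderr[0:2 * m:2]
            b0 = sol.x[1:2 * m:2]
            binf = np.full(m, sol.x[-1])
        else:
            k = sol.x[0::3]
            k_se = stderr[0::3]
            b0 = sol.x[1::3]
            binf = sol.x[2::3]
        conc = np.array([tr.modulator_conc for tr in self.traces])
        controls = np.flatnonzero(conc == 0.0)
        k0 = rel = None
        if controls.size:
            k0 = float(np.mean(k[controls]))
            rel = k / k0
        elif self.require_control:
            raise MissingControlError(
                "relative rates requested but no modulator-free trace present")
        return DissociationResults(
            k_obsd=k, k_obsd_stderr=k_se, b_t0=b0, b_inf=binf,
            modulator_conc=conc, shared_b_inf=shared, k0=k0,
            relative_rates=rel, ssr=2 * sol.cost, df_resid=n_obs - n_par,
            share_test=share_test, _traces=tuple(self.traces))
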