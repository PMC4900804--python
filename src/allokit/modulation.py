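"""Empirical multiphasic analysis of allosteric modulation curves.

The observed response Y (a normalised dissociation rate, or total binding at
a fixed read time) as a function of modulator concentration [A] is described
by a sum of one to three hyperbolic (optionally Hill-sloped) components::

    Y([A]) = Yinf + (Y0 - Yinf) * sum_j F_j * K_j^nH_j / (K_j^nH_j + [A]^nH_j)

with sum_j F_j = 1, so that Y(0) = Y0 and Y(inf) = Yinf.  K_j is the apparent
dissociation constant of component j (stored as log10 molar) and nH_j its
Hill coefficient, fixed at 1 unless the data demonstrably require otherwise.

Replicate curves are fitted globally: log K_j, nH_j and the component
fractions are shared across experiments while the plateaus Y0/Yinf are
per-experiment, absorbing scale differences between preparations.  Model
complexity (the number of components, and free vs unit Hill slopes) is
adjudicated by extra-sum-of-squares F-tests at alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datasets import ModulationCurve
from .exceptions import FitFailureError, InvalidParameterError
from .stats import FTestResult, covariance_from_jacobian, extra_ss_ftest

__all__ = [
    "eval_modulation",
    "ModulationModel",
    "ModulationResults",
    "ComponentSelection",
    "select_components",
]


def eval_modulation(a, y0: float, yinf: float, log_k, fractions, nh=None):
    """Evaluate the multiphasic modulation equation at concentrations ``a``.

    Parameters are one value per component; ``nh=None`` means unit Hill
    slopes.  Fractions must sum to 1 (checked to 1e-8) unless signed spans
    are deliberately in use, in which case pass them as given.
    """
    scalar = np.ndim(a) == 0
    a = np.atleast_1d(np.asarray(a, dtype=float))
    if np.any(a < 0):
        raise InvalidParameterError("modulator concentration must be >= 0")
    log_k = np.atleast_1d(np.asarray(log_k, dtype=float))
    fractions = np.atleast_1d(np.asarray(fractions, dtype=float))
    if nh is None:
        nh = np.ones_like(log_k)
    nh = np.atleast_1d(np.asarray(nh, dtype=float))
    for name, arr in (("log_k", log_k), ("fractions", fractions), ("nh", nh)):
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError(f"{name} contains non-finite values")
    if not (np.isfinite(y0) and np.isfinite(yinf)):
        raise InvalidParameterError("plateaus must be finite")
    k = 10.0 ** log_k
    # occupancy of the *unmodulated* state: K^nH / (K^nH + A^nH)
    with np.errstate(over="ignore"):
        knh = k[:, None] ** nh[:, None]
        anh = a[None, :] ** nh[:, None]
    s = (fractions[:, None] * knh / (knh + anh)).sum(axis=0)
    out = yinf + (y0 - yinf) * s
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class ModulationResults:
    """Global fit of the multiphasic modulation equation.

    Shared parameters (log K, fractions, Hill slopes) come with asymptotic
    standard errors; plateaus are per experiment.  Components are ordered by
    ascending log K (highest affinity first).
    """

    n_components: int
    log_k: np.ndarray
    log_k_stderr: np.ndarray
    fractions: np.ndarray
    fractions_stderr: np.ndarray
    nh: np.ndarray
    nh_stderr: np.ndarray | None
    nh_fixed: bool
    y0: np.ndarray           # per experiment
    yinf: np.ndarray         # per experiment
    experiment_ids: list[str]
    ssr: float
    df_resid: int
    n_obs: int
    cov: np.ndarray | None = None
    nh_test: FTestResult | None = None
    signed_fractions: bool = False
    _curves: tuple[ModulationCurve, ...] = field(default=(), repr=False)

    def predict(self, a, experiment: int | str | None = None) -> np.ndarray:
        """Model curve at concentrations ``a``; mean plateaus by default."""
        if experiment is None:
            y0, yinf = float(self.y0.mean()), float(self.yinf.mean())
        else:
            idx = (self.experiment_ids.index(experiment)
                   if isinstance(experiment, str) else experiment)
            y0, yinf = float(self.y0[idx]), float(self.yinf[idx])
        return eval_modulation(a, y0, yinf, self.log_k, self.fractions, self.nh)

    def normalize_replicates(self) -> pd.DataFrame:
        """Rescale each measured point onto the mean-plateau curve.

        Each Y is multiplied by f(x, a_bar, b)/f(x, a, b), where a are the
        per-experiment plateaus and b the shared parameters; points at the
        same concentration are then averaged to mean +/- SEM.
        """
        from .replicates import normalize_replicates
        return normalize_replicates(self)

    def summary(self) -> str:
        lines = [
            "Multiphasic modulation fit",
            "=" * 60,
            f"components: {self.n_components}    observations: {self.n_obs}"
            f"    experiments: {len(self.experiment_ids)}",
            f"SSR: {self.ssr:.6g}    df_resid: {self.df_resid}",
            f"Hill slopes: {'fixed at 1' if self.nh_fixed else 'free'}",
            "-" * 60,
            f"{'component':<10}{'log K':>12}{'SE':>10}{'F_j':>10}{'SE':>10}{'nH':>8}",
        ]
        for j in range(self.n_components):
            se_nh = "" if self.nh_stderr is None else f" ({self.nh_stderr[j]:.2f})"
            lines.append(
                f"{j + 1:<10}{self.log_k[j]:>12.3f}{self.log_k_stderr[j]:>10.3f}"
                f"{self.fractions[j]:>10.3f}{self.fractions_stderr[j]:>10.3f}"
                f"{self.nh[j]:>8.2f}{se_nh}")
        lines.append("-" * 60)
        for i, eid in enumerate(self.experiment_ids):
            lines.append(f"{eid}: Y0 = {self.y0[i]:.4g}, Yinf = {self.yinf[i]:.4g}")
        if self.nh_test is not None:
            lines.append(
                f"nH vs 1: F = {self.nh_test.f_stat:.3f}, p = {self.nh_test.p_value:.3f}"
                f" -> {'free' if self.nh_test.prefers_full else 'fixed at 1'}")
        return "\n".join(lines)


def _softmax_fractions(g: np.ndarray) -> np.ndarray:
    """Map n-1 free logits to n positive fractions summing to 1 (g_1 = 0)."""
    z = np.concatenate([[0.0], g])
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def _fraction_jacobian(g: np.ndarray) -> np.ndarray:
    """d fractions / d logits for the softmax parameterisation (n x (n-1))."""
    f = _softmax_fractions(g)
    n = f.size
    jac = np.zeros((n, n - 1))
    for j in range(1, n):
        for i in range(n):
            jac[i, j - 1] = f[i] * ((1.0 if i == j else 0.0) - f[j])
    return jac


class ModulationModel:
    """Global multiphasic fit of allosteric modulation curves.

    Parameters
    ----------
    curves
        Replicate log-dose curves; log K, fractions and Hill slopes are
        shared, plateaus are per curve.
    n_components
        Number of hyperbolic components (1-3).
    nh_policy
        ``"fixed"`` pins every Hill slope at 1; ``"free"`` fits them;
        ``"tested"`` fits them, compares against 1 by an F-test, and keeps
        the constrained model when p >= 0.05 (the conventional choice when
        slopes are statistically indistinguishable from 1).
    signed_fractions
        Allow component fractions of either sign (still summing to 1), an
        extension that can describe bell-shaped dose-response profiles.
        Off by default.
    n_starts
        Multistart count; each start jitters the log K seeds by up to
        +/- 1 log unit.
    """

    def __init__(self, curves, n_components: int = 1,
                 nh_policy: str = "fixed", signed_fractions: bool = False,
                 weights: str | None = None, n_starts: int = 8,
                 seed: int = 0):
        curves = [curves] if isinstance(curves, ModulationCurve) else list(curves)
        if not curves:
            raise InvalidParameterError("at least one curve is required")
        if n_components not in (1, 2, 3):
            raise InvalidParameterError("n_components must be 1, 2 or 3")
        if nh_policy not in ("fixed", "free", "tested"):
            raise InvalidParameterError("nh_policy must be fixed|free|tested")
        n_distinct = len(set(np.concatenate([c.modulator_conc for c in curves])))
        if n_distinct < 6:
            raise InvalidParameterError(
                "need >= 6 distinct modulator concentrations to fit")
        self.curves = curves
        self.n_components = n_components
        self.nh_policy = nh_policy
        self.signed_fractions = signed_fractions
        self.weights = weights
        self.n_starts = n_starts
        self.seed = seed

    # -- parameter vector layout -------------------------------------------------
    # [log_k (n)] [nh (n, only if free)] [frac params (n-1)] [y0_c yinf_c]*C

    def _unpack(self, theta, free_nh):
        n, c = self.n_components, len(self.curves)
        i = 0
        log_k = theta[i:i + n]; i += n
        if free_nh:
            nh = theta[i:i + n]; i += n
        else:
            nh = np.ones(n)
        gpars = theta[i:i + n - 1]; i += n - 1
        if self.signed_fractions:
            fr = np.concatenate([gpars, [1.0 - gpars.sum()]]) if n > 1 else np.ones(1)
        else:
            fr = _softmax_fractions(gpars)
        plateaus = theta[i:].reshape(c, 2)
        return log_k, nh, fr, plateaus

    def _residuals(self, theta, free_nh):
        log_k, nh, fr, plateaus = self._unpack(theta, free_nh)
        res = []
        for (y0, yinf), curve in zip(plateaus, self.curves):
            pred = eval_modulation(curve.modulator_conc, y0, yinf, log_k, fr, nh)
            r = pred - curve.response
            if self.weights == "1/y":
                r = r / np.maximum(np.abs(curve.response), 1e-12)
            res.append(r)
        return np.concatenate(res)

    def _n_params(self, free_nh):
        n, c = self.n_components, len(self.curves)
        return n + (n if free_nh else 0) + (n - 1) + 2 * c

    def _initial_guesses(self):
        all_a = np.concatenate([c.modulator_conc for c in self.curves])
        pos = all_a[all_a > 0]
        lo, hi = np.log10(pos.min()), np.log10(pos.max())
        n = self.n_components
        # seed the log K values at interior quantiles of the sampled range
        qs = (np.arange(1, n + 1)) / (n + 1)
        return lo + qs * (hi - lo)

    def _fit_once(self, free_nh, log_k0):
        n, c = self.n_components, len(self.curves)
        theta0 = [np.sort(log_k0)]
        if free_nh:
            theta0.append(np.ones(n))
        theta0.append(np.zeros(n - 1))
        for curve in self.curves:
            order = np.argsort(curve.modulator_conc)
            theta0.append([curve.response[order][0], curve.response[order][-1]])
        theta0 = np.concatenate(theta0)
        lb = np.full(theta0.size, -np.inf)
        ub = np.full(theta0.size, np.inf)
        lb[:n], ub[:n] = -15.0, 3.0
        if free_nh:
            lb[n:2 * n], ub[n:2 * n] = 0.1, 5.0
        sol = least_squares(self._residuals, theta0, args=(free_nh,),
                            bounds=(lb, ub), method="trf", x_scale="jac")
        return sol

    def _multistart(self, free_nh):
        rng = np.random.default_rng(self.seed)
        base = self._initial_guesses()
        best = None
        for start in range(self.n_starts):
            jitter = np.zeros_like(base) if start == 0 else rng.uniform(-1, 1, base.size)
            try:
                sol = self._fit_once(free_nh, base + jitter)
            except (ValueError, np.linalg.LinAlgError):
                continue
            if sol.success or sol.status > 0:
                ssr = 2.0 * sol.cost
                if best is None or ssr < best[1]:
                    best = (sol, ssr)
        if best is None:
            raise FitFailureError("all multistarts failed to converge",
                                  {"n_starts": self.n_starts})
        return best[0]

    def fit(self) -> ModulationResults:
        fixed_sol = self._multistart(free_nh=False)
        nh_test = None
        free_nh = False
        sol = fixed_sol
        if self.nh_policy in ("free", "tested"):
            free_sol = self._multistart(free_nh=True)
            if self.nh_policy == "free":
                sol, free_nh = free_sol, True
            else:
                n_obs = sum(c.response.size for c in self.curves)
                nh_test = extra_ss_ftest(
                    2 * fixed_sol.cost, n_obs - self._n_params(False),
                    2 * free_sol.cost, n_obs - self._n_params(True))
                if nh_test.prefers_full:
                    sol, free_nh = free_sol, True
        return self._package(sol, free_nh, nh_test)

    def _package(self, sol, free_nh, nh_test) -> ModulationResults:
        n = self.n_components
        n_obs = sum(c.response.size for c in self.curves)
        n_par = self._n_params(free_nh)
        df = n_obs - n_par
        log_k, nh, fr, plateaus = self._unpack(sol.x, free_nh)
        cov, stderr = covariance_from_jacobian(sol.jac, sol.fun, n_par)
        cond = np.linalg.cond(sol.jac.T @ sol.jac)
        if cond > 1e12:
            warnings.warn(
                f"ill-conditioned fit (condition number {cond:.2g}); "
                "the design may not resolve this many components",
                RuntimeWarning, stacklevel=2)
        span = plateaus[:, 0] - plateaus[:, 1]
        if np.all(np.abs(span) < 1e-8 * np.maximum(np.abs(plateaus[:, 0]), 1.0)):
            warnings.warn("degenerate amplitude: Y0 ~= Yinf, component "
                          "parameters are unconstrained", RuntimeWarning,
                          stacklevel=2)
        log_k_se = stderr[:n]
        i = n
        nh_se = None
        if free_nh:
            nh_se = stderr[i:i + n]
            i += n
        g = sol.x[i:i + n - 1]
        if self.signed_fractions or n == 1:
            fr_se = np.zeros(n)
            if n > 1:
                fr_se[:-1] = stderr[i:i + n - 1]
                fr_se[-1] = np.sqrt(cov[i:i + n - 1, i:i + n - 1].sum())
        else:
            jg = _fraction_jacobian(g)
            fr_cov = jg @ cov[i:i + n - 1, i:i + n - 1] @ jg.T
            fr_se = np.sqrt(np.maximum(np.diag(fr_cov), 0.0))
        # deterministic output: order components by ascending log K
        order = np.argsort(log_k)
        res = ModulationResults(
            n_components=n,
            log_k=log_k[order], log_k_stderr=log_k_se[order],
            fractions=fr[order], fractions_stderr=fr_se[order],
            nh=nh[order], nh_stderr=None if nh_se is None else nh_se[order],
            nh_fixed=not free_nh,
            y0=plateaus[:, 0].copy(), yinf=plateaus[:, 1].copy(),
            experiment_ids=[c.experiment_id for c in self.curves],
            ssr=2.0 * sol.cost, df_resid=df, n_obs=n_obs, cov=cov,
            nh_test=nh_test, signed_fractions=self.signed_fractions,
            _curves=tuple(self.curves))
        if not self.signed_fractions:
            assert abs(res.fractions.sum() - 1.0) < 1e-8
        return res


@dataclass(frozen=True)
class ComponentSelection:
    """Nested F-test selection of the number of modulation components."""

    chosen_n: int
    results: dict[int, ModulationResults]
    table: pd.DataFrame

    @property
    def best(self) -> ModulationResults:
        return self.results[self.chosen_n]


def select_components(curves, candidates=(1, 2, 3), **model_kwargs) -> ComponentSelection:
    """Choose the number of components by nested extra-SS F-tests.

    Starting from the smallest candidate, a larger model is accepted only
    when it improves the fit at p < 0.05 over the currently accepted one.
    """
    candidates = sorted(candidates)
    results: dict[int, ModulationResults] = {}
    rows = []
    chosen = None
    for n in candidates:
        try:
            res = ModulationModel(curves, n_components=n, **model_kwargs).fit()
        except FitFailureError:
            rows.append({"n": n, "ssr": np.nan, "df": np.nan,
                         "f_stat": np.nan, "p_value": np.nan, "accepted": False})
            continue
        results[n] = res
        if chosen is None:
            chosen = n
            rows.append({"n": n, "ssr": res.ssr, "df": res.df_resid,
                         "f_stat": np.nan, "p_value": np.nan, "accepted": True})
            continue
        ref = results[chosen]
        test = extra_ss_ftest(ref.ssr, ref.df_resid, res.ssr, res.df_resid)
        accepted = test.prefers_full
        if accepted:
            chosen = n
        rows.append({"n": n, "ssr": res.ssr, "df": res.df_resid,
                     "f_stat": test.f_stat, "p_value": test.p_value,
                     "accepted": accepted})
    if chosen is None:
        raise FitFailureError("no candidate model converged")
    return ComponentSelection(chosen_n=chosen, results=results,
                              table=pd.DataFrame(rows))
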