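"""Presentation of replicate experiments against a single fitted curve.

After a global fit that separates per-experiment parameters **a** (plateaus,
maximal binding) from shared parameters **b** (affinities, slopes), each
measured point is rescaled by

    Y' = Y * f(x_i, a_bar, b) / f(x_i, a, b)

where a_bar replaces the experiment-specific parameters by their means.
Points from different experiments then overlay one mean-parameter curve and
can be averaged at common x to mean +/- SEM.  Applied to already-normalised
data (whose per-experiment parameters all equal the mean) the adjustment is
the identity, so the operation is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import UndefinedScalingError

__all__ = ["NormalizedReplicates", "normalize_replicates"]


@dataclass(frozen=True)
class NormalizedReplicates:
    """Adjusted per-point data plus the mean +/- SEM profile."""

    points: pd.DataFrame     # experiment_id, x, y, y_adj
    means: pd.DataFrame      # x, mean, sem, n


def _mod_curves_xy(result):
    for i, curve in enumerate(result._curves):
        yield (curve.experiment_id, curve.modulator_conc, curve.response,
               (result.y0[i], result.yinf[i]))


def _sat_curves_xy(result):
    for i, curve in enumerate(result._curves):
        yield (curve.experiment_id, curve.ligand_conc_total, curve.bound,
               (result.bmax[i],))


def normalize_replicates(result) -> NormalizedReplicates:
    """Adjust every measured point onto the mean-parameter fitted curve.

    Accepts a :class:`~allokit.modulation.ModulationResults` or
    :class:`~allokit.saturation.SaturationResults` (any result exposing its
    source curves and per-experiment parameters).
    """
    from .modulation import ModulationResults, eval_modulation
    from .saturation import SaturationResults, eval_saturation

    if isinstance(result, ModulationResults):
        mean_par = (float(result.y0.mean()), float(result.yinf.mean()))

        def f(x, par):
            return eval_modulation(x, par[0], par[1], result.log_k,
                                   result.fractions, result.nh)
        iterator = _mod_curves_xy(result)
    elif isinstance(result, SaturationResults):
        mean_par = (float(result.bmax.mean()),)

        def f(x, par):
            return np.atleast_1d(eval_saturation(
                x, par[0], result.log_k, result.nh, result.ns,
                result.signal_to_molar))
        iterator = _sat_curves_xy(result)
    else:
        raise TypeError(f"cannot normalise a {type(result).__name__}")

    rows = []
    for exp_id, x, y, par in iterator:
        f_own = f(x, par)
        if np.any(f_own == 0):
            raise UndefinedScalingError(
                f"fitted curve is zero at a data point of {exp_id}")
        y_adj = y * f(x, mean_par) / f_own
        for xi, yi, yai in zip(x, y, y_adj):
            rows.append({"experiment_id": exp_id, "x": xi, "y": yi,
                         "y_adj": yai})
    points = pd.DataFrame(rows)
    grouped = points.groupby("x")["y_adj"]
    means = pd.DataFrame({
        "mean": grouped.mean(),
        "sem": grouped.sem(ddof=1).fillna(0.0),
        "n": grouped.size(),
    }).reset_index()
    return NormalizedReplicates(points=points, means=means)
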