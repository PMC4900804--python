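"""Synthetic-data generators with known ground truth.

Every input the fitters consume can be generated here under the designs the
analyses assume: multiphasic log-dose series with zero/saturating anchors,
replicate curves with per-experiment scale variability, lambda-scan spectra
with Gaussian noise, and TCSPC histograms with Poisson counting noise.
Defaults follow the study conditions (2%-of-span Gaussian noise on binding
and spectral data, 12.5-ns repetition period and ~16-ps bins for photon
counting); each generator returns the observations together with the
generating truth so parameter recovery can be tested directly.  All
randomness flows through a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .capping import MechanismParams, Protocol, dose_response
from .datasets import (SPECTRAL_GRID, DecayHistogram, DissociationTrace,
                       EmissionSpectrum, ModulationCurve, ReferenceSpectra,
                       SaturationCurve)
from .dissociation import eval_dissociation
from .exceptions import InvalidParameterError
from .fret import FretConfig
from .modulation import eval_modulation
from .saturation import eval_saturation
from .tcspc import DecayModel, convolve_with_irf, model_decays

__all__ = [
    "reference_spectra",
    "gen_modulation",
    "gen_dissociation",
    "gen_saturation",
    "gen_spectra",
    "gen_tcspc",
    "gen_capping_dataset",
]


# ---------------------------------------------------------------------------
# reference spectra

#: log-normal shape parameters (onset nm, mode offset nm, log-width) chosen
#: to peak at 530 nm (FlAsH-like), 610 nm (mCherry-like), 507 nm (eGFP-like)
#: with the red tail characteristic of fluorophore emission.
_SHAPES = {
    "donor": (470.0, 60.0, 0.28),
    "acceptor": (545.0, 65.0, 0.25),
    "third": (450.0, 57.0, 0.25),
}


def _lognormal_shape(wl: np.ndarray, onset: float, mode: float,
                     width: float) -> np.ndarray:
    x = wl - onset
    out = np.zeros_like(wl)
    pos = x > 0
    out[pos] = np.exp(-0.5 * ((np.log(x[pos] / mode)) / width) ** 2)
    return out / out.max()


def reference_spectra(wavelengths: np.ndarray | None = None,
                      include_third: bool = True) -> ReferenceSpectra:
    """Unit-peak donor/acceptor (and optional third-colour) references."""
    wl = SPECTRAL_GRID if wavelengths is None else np.asarray(wavelengths, float)
    em_d = _lognormal_shape(wl, *_SHAPES["donor"])
    em_a = _lognormal_shape(wl, *_SHAPES["acceptor"])
    em_b = _lognormal_shape(wl, *_SHAPES["third"]) if include_third else None
    return ReferenceSpectra(wavelengths=wl, em_d=em_d, em_a=em_a, em_b=em_b)


# ---------------------------------------------------------------------------
# binding designs


def _log_dose_design(log_lo: float, log_hi: float, n: int,
                     anchors: bool = True) -> np.ndarray:
    conc = np.logspace(log_lo, log_hi, n)
    if anchors:
        # zero- and saturating-concentration anchors as in log-dose figures
        conc = np.concatenate([[0.0], conc, [10.0 ** (log_hi + 3)]])
    return conc


@dataclass(frozen=True)
class ModulationTruth:
    log_k: np.ndarray
    fractions: np.ndarray
    nh: np.ndarray
    y0: float
    yinf: float


def gen_modulation(log_k, fractions=None, nh=None, y0: float = 1.0,
                   yinf: float = 0.0, design: np.ndarray | None = None,
                   log_range: tuple[float, float] = (-9.0, -1.0),
                   n_points: int = 16, anchors: bool = True,
                   noise: float = 0.02, scale_sd: float = 0.1,
                   replicates: int = 3, seed: int = 0):
    """Replicate multiphasic modulation curves plus the generating truth.

    Noise is Gaussian with SD ``noise`` times the response span; each
    replicate's plateaus are scaled by a log-normal factor of spread
    ``scale_sd`` to emulate between-experiment signal variability.
    """
    rng = np.random.default_rng(seed)
    log_k = np.atleast_1d(np.asarray(log_k, dtype=float))
    n = log_k.size
    fractions = (np.full(n, 1.0 / n) if fractions is None
                 else np.atleast_1d(np.asarray(fractions, float)))
    nh = np.ones(n) if nh is None else np.atleast_1d(np.asarray(nh, float))
    pos = log_k[log_k > -np.inf]
    span = np.asarray(
        _log_dose_design(*log_range, n_points, anchors) if design is None
        else design, dtype=float)
    finite = span[span > 0]
    if finite.size and (np.log10(finite.max()) - np.log10(finite.min())
                        < 1.5 * max(1, n)) and n > 1:
        # the design must straddle each transition to resolve it
        pass
    curves = []
    for rep in range(replicates):
        scale = float(np.exp(rng.normal(0.0, scale_sd))) if scale_sd else 1.0
        y0_r, yinf_r = y0 * scale, yinf * scale
        y = eval_modulation(span, y0_r, yinf_r, log_k, fractions, nh)
        y = y + rng.normal(0.0, noise * abs(y0_r - yinf_r), size=y.size)
        curves.append(ModulationCurve(modulator_conc=span, response=y,
                                      experiment_id=f"rep{rep + 1}"))
    truth = ModulationTruth(log_k=log_k, fractions=fractions, nh=nh,
                            y0=y0, yinf=yinf)
    return curves, truth


@dataclass(frozen=True)
class DissociationTruth:
    k_obsd: np.ndarray
    modulator_conc: np.ndarray
    b_t0: float
    b_inf: float


def gen_dissociation(k_obsd, modulator_conc, b_t0: float = 100.0,
                     b_inf: float = 5.0, times: np.ndarray | None = None,
                     noise: float = 0.01, seed: int = 0):
    """Dissociation traces at graded modulator concentrations (control first).

    ``k_obsd`` lists the true rate constant (1/min) at each concentration in
    ``modulator_conc``; a modulator-free control must be included when
    relative rates are wanted downstream.
    """
    rng = np.random.default_rng(seed)
    k_obsd = np.atleast_1d(np.asarray(k_obsd, float))
    conc = np.atleast_1d(np.asarray(modulator_conc, float))
    if k_obsd.size != conc.size:
        raise InvalidParameterError("k_obsd and modulator_conc differ in length")
    if times is None:
        t_char = 1.0 / k_obsd.min()
        times = np.linspace(0.0, 3.0 * t_char, 12)
    traces = []
    for k, a in zip(k_obsd, conc):
        y = eval_dissociation(times, b_t0, b_inf, k)
        y = y + rng.normal(0.0, noise * (b_t0 - b_inf), size=y.size)
        traces.append(DissociationTrace(times=times, bound=y,
                                        modulator_conc=float(a),
                                        experiment_id=f"A={a:g}"))
    truth = DissociationTruth(k_obsd=k_obsd, modulator_conc=conc,
                              b_t0=b_t0, b_inf=b_inf)
    return traces, truth


@dataclass(frozen=True)
class SaturationTruth:
    bmax: float
    log_k: float
    nh: float
    ns: float


def gen_saturation(log_k: float = -8.01, bmax: float = 1.0, nh: float = 1.0,
                   ns: float = 0.05, log_range: tuple[float, float] = (-10.0, -7.0),
                   n_points: int = 12, noise: float = 0.02,
                   scale_sd: float = 0.1, replicates: int = 5,
                   seed: int = 0, signal_to_molar: float = 0.0):
    """Replicate saturation curves around K with 2%-of-span noise defaults."""
    rng = np.random.default_rng(seed)
    conc = np.logspace(*log_range, n_points)
    curves = []
    for rep in range(replicates):
        scale = float(np.exp(rng.normal(0.0, scale_sd))) if scale_sd else 1.0
        y = eval_saturation(conc, bmax * scale, log_k, nh, ns, signal_to_molar)
        y = np.asarray(y) + rng.normal(0.0, noise * bmax * scale, size=conc.size)
        curves.append(SaturationCurve(ligand_conc_total=conc, bound=y,
                                      experiment_id=f"rep{rep + 1}"))
    return curves, SaturationTruth(bmax=bmax, log_k=log_k, nh=nh, ns=ns)


# ---------------------------------------------------------------------------
# spectra


def _coefficients_from_efficiency(e_pct: float, brightness: float,
                                  config: FretConfig) -> tuple[float, float]:
    """Invert the sensitized-emission formula: (k_d, raw k_a) for a target
    E_app, re-adding the direct-excitation fraction the pipeline removes."""
    if not 0 < e_pct < 100:
        raise InvalidParameterError("target efficiency must lie in (0, 100)%")
    k_a_corr = brightness
    ratio = (100.0 / e_pct - 1.0) / ((config.q_a / config.q_d) * config.w_ratio)
    k_d = ratio * k_a_corr
    k_a_raw = k_a_corr / (1.0 - config.direct_excitation_fraction)
    return k_d, k_a_raw


def gen_spectra(mu: float = 59.2, sigma: float = 7.7, n_cells: int = 31,
                e_values: np.ndarray | None = None,
                refs: ReferenceSpectra | None = None,
                config: FretConfig | None = None,
                brightness_mean: float = 100.0, brightness_sd: float = 0.3,
                k_b_mean: float = 0.0, noise: float = 0.01,
                condition: str = "none", seed: int = 0):
    """Per-cell two- (or three-) fluorophore spectra at target efficiencies.

    True per-cell efficiencies are drawn from N(mu, sigma) (percent) unless
    ``e_values`` is given.  Each cell gets a log-normal brightness, donor
    and acceptor coefficients consistent with its efficiency (including the
    direct-excitation contribution the analysis later removes), and
    Gaussian noise of SD ``noise`` times the spectral peak.
    Returns (spectra, true_efficiencies, refs).
    """
    rng = np.random.default_rng(seed)
    refs = refs or reference_spectra()
    config = config or FretConfig()
    if e_values is None:
        e_true = rng.normal(mu, sigma, size=n_cells)
        e_true = np.clip(e_true, 2.0, 98.0)
    else:
        e_true = np.asarray(e_values, dtype=float)
        n_cells = e_true.size
    spectra = []
    for i, e in enumerate(e_true):
        bright = brightness_mean * float(np.exp(rng.normal(0.0, brightness_sd)))
        k_d, k_a_raw = _coefficients_from_efficiency(float(e), bright, config)
        y = k_d * refs.em_d + k_a_raw * refs.em_a
        if k_b_mean > 0:
            k_b = k_b_mean * float(np.exp(rng.normal(0.0, brightness_sd)))
            y = y + k_b * refs.em_b
        y = y + rng.normal(0.0, noise * y.max(), size=y.size)
        spectra.append(EmissionSpectrum(wavelengths=refs.wavelengths,
                                        intensities=y, cell_id=f"cell{i + 1}",
                                        condition=condition))
    return spectra, e_true, refs


# ---------------------------------------------------------------------------
# photon counting


def gen_tcspc(model: DecayModel | None = None, total_counts: float = 1e6,
              n_bins: int = 781, period: float = 12.5,
              irf_fwhm: float = 0.1, irf_center: float = 1.0,
              poisson: bool = True, seed: int = 0):
    """Polarised TCSPC histograms from the reconvolution forward model.

    A Gaussian IRF (FWHM ``irf_fwhm`` ns at ``irf_center`` ns) is applied to
    both channels; the model amplitude is rescaled so the expected total is
    ``total_counts``, then Poisson noise is applied bin-wise.  Returns
    (DecayHistogram, DecayModel truth with the realised amplitude).
    """
    rng = np.random.default_rng(seed)
    model = model or DecayModel(tau=3.0, phi=18.0, r0=0.38)
    t = np.arange(n_bins) * (period / n_bins)
    sd = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    irf = np.exp(-0.5 * ((t - irf_center) / sd) ** 2)
    irf = irf / irf.sum() * total_counts / 10.0   # arbitrary recorded scale
    d_par, d_perp = model_decays(model, t, period)
    e_par = convolve_with_irf(d_par, irf, model.shift)
    e_perp = convolve_with_irf(d_perp, irf, model.shift)
    scale = total_counts / (e_par.sum() + e_perp.sum())
    e_par, e_perp = e_par * scale, e_perp * scale
    truth = replace(model, amplitude=model.amplitude * scale)
    if poisson:
        c_par = rng.poisson(e_par).astype(float)
        c_perp = rng.poisson(e_perp).astype(float)
    else:
        c_par, c_perp = e_par, e_perp
    hist = DecayHistogram(bin_times=t, counts_par=c_par, counts_perp=c_perp,
                          irf_par=irf, irf_perp=irf, period=period)
    return hist, truth


# ---------------------------------------------------------------------------
# mechanistic dose-response


def gen_capping_dataset(params: MechanismParams | None = None,
                        protocol: Protocol | None = None,
                        a_series: np.ndarray | None = None,
                        read_times=(5.0, 20.0, "equilibrium"),
                        noise: float = 0.0, seed: int = 0):
    """Simulated capping dose-response curves at several read times.

    Defaults emulate an inhibitory modulator acting on a pre-formed
    radioligand-receptor system read early (5 min), mid (20 min) and at
    equilibrium.  Returns ({read_time: ModulationCurve}, params).
    """
    rng = np.random.default_rng(seed)
    params = params or MechanismParams(k_l=1e-9, k_a=1e-5, alpha=10.0,
                                       k_off_l=0.02, k_off_a=10.0)
    protocol = protocol or Protocol(mode="simultaneous", l_conc=1e-8)
    if a_series is None:
        a_series = np.logspace(-8, -2, 12)
    curves = dose_response(params, protocol, a_series, read_times)
    if noise > 0:
        noisy = {}
        for t, curve in curves.items():
            span = np.ptp(curve.response) or 1.0
            y = curve.response + rng.normal(0.0, noise * span,
                                            size=curve.response.size)
            noisy[t] = ModulationCurve(modulator_conc=curve.modulator_conc,
                                       response=y,
                                       radioligand_conc=curve.radioligand_conc,
                                       experiment_id=curve.experiment_id)
        curves = noisy
    return curves, params
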