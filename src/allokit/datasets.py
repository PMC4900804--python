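"""Typed containers for the experimental designs the package analyses.

Units are fixed at construction: concentrations in molar, time in minutes for
binding kinetics and nanoseconds for photon counting, wavelengths in
nanometres.  Each container validates its invariants eagerly so that fitters
can assume well-formed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError, ParseError

__all__ = [
    "DissociationTrace",
    "ModulationCurve",
    "SaturationCurve",
    "EmissionSpectrum",
    "ReferenceSpectra",
    "DecayHistogram",
]

#: canonical lambda-scan grid: 495-640 nm in 5-nm steps, 30 points
SPECTRAL_GRID = np.arange(495.0, 645.0, 5.0)


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ParseError(f"{name} must be a non-empty 1-D array")
    if not np.all(np.isfinite(arr)):
        raise ParseError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class DissociationTrace:
    """A radioligand dissociation time course at one modulator concentration.

    ``modulator_conc = 0`` marks the control trace whose rate constant k0 is
    used to normalise the others.
    """

    times: np.ndarray
    bound: np.ndarray
    modulator_conc: float = 0.0
    experiment_id: str = "exp1"

    def __post_init__(self):
        t = _as_1d(self.times, "times")
        b = _as_1d(self.bound, "bound")
        if t.size != b.size:
            raise ParseError("times and bound must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ParseError("times must be strictly increasing")
        if t[0] < 0:
            raise ParseError("times must be non-negative")
        if self.modulator_conc < 0:
            raise ParseError("modulator_conc must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "bound", b)

    @property
    def is_control(self) -> bool:
        return self.modulator_conc == 0.0


@dataclass(frozen=True)
class ModulationCurve:
    """Log-dose allosteric modulation data: response vs modulator concentration.

    The response may be a normalised dissociation rate (k_obsd/k0) or total
    bound radioligand at a fixed read time; zero- and saturating-concentration
    anchor points are permitted.
    """

    modulator_conc: np.ndarray
    response: np.ndarray
    radioligand_conc: float | None = None
    experiment_id: str = "exp1"

    def __post_init__(self):
        a = _as_1d(self.modulator_conc, "modulator_conc")
        y = _as_1d(self.response, "response")
        if a.size != y.size:
            raise ParseError("modulator_conc and response must have equal length")
        if np.any(a < 0):
            raise ParseError("modulator_conc must be >= 0")
        object.__setattr__(self, "modulator_conc", a)
        object.__setattr__(self, "response", y)


@dataclass(frozen=True)
class SaturationCurve:
    """Total binding vs total radioligand concentration ([P]_t, molar)."""

    ligand_conc_total: np.ndarray
    bound: np.ndarray
    experiment_id: str = "exp1"

    def __post_init__(self):
        p = _as_1d(self.ligand_conc_total, "ligand_conc_total")
        b = _as_1d(self.bound, "bound")
        if p.size != b.size:
            raise ParseError("ligand_conc_total and bound must have equal length")
        if np.any(p <= 0):
            raise ParseError("ligand_conc_total must be > 0")
        object.__setattr__(self, "ligand_conc_total", p)
        object.__setattr__(self, "bound", b)


@dataclass(frozen=True)
class EmissionSpectrum:
    """A background-corrected per-cell lambda scan on the canonical grid."""

    wavelengths: np.ndarray
    intensities: np.ndarray
    cell_id: str = "cell1"
    condition: str = "none"

    def __post_init__(self):
        w = _as_1d(self.wavelengths, "wavelengths")
        y = _as_1d(self.intensities, "intensities")
        if w.size != y.size:
            raise ParseError("wavelengths and intensities must have equal length")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "intensities", y)


@dataclass(frozen=True)
class ReferenceSpectra:
    """Unit-peak-normalised fluorophore reference spectra on a common grid.

    ``em_d`` is the donor (FlAsH-like), ``em_a`` the acceptor (mCherry-like)
    and ``em_b`` an optional third colour (eGFP-like marker).
    """

    wavelengths: np.ndarray
    em_d: np.ndarray
    em_a: np.ndarray
    em_b: np.ndarray | None = None

    def __post_init__(self):
        w = _as_1d(self.wavelengths, "wavelengths")
        object.__setattr__(self, "wavelengths", w)
        for name in ("em_d", "em_a", "em_b"):
            ref = getattr(self, name)
            if ref is None:
                continue
            ref = _as_1d(ref, name)
            if ref.size != w.size:
                raise ParseError(f"{name} does not match the wavelength grid")
            if np.any(ref < 0):
                raise ParseError(f"{name} must be non-negative")
            if not np.isclose(ref.max(), 1.0, rtol=1e-6):
                raise ParseError(f"{name} must be normalised to unit peak")
            object.__setattr__(self, name, ref)

    def design_matrix(self, n_colors: int = 2) -> np.ndarray:
        if n_colors == 2:
            return np.column_stack([self.em_d, self.em_a])
        if n_colors == 3:
            if self.em_b is None:
                raise InvalidParameterError("3-colour unmixing requires em_b")
            return np.column_stack([self.em_d, self.em_a, self.em_b])
        raise InvalidParameterError("n_colors must be 2 or 3")

    def spectral_integral_ratio(self) -> float:
        """W_D/W_A by trapezoidal integration over the stored grid."""
        w_d = np.trapezoid(self.em_d, self.wavelengths)
        w_a = np.trapezoid(self.em_a, self.wavelengths)
        return float(w_d / w_a)


@dataclass(frozen=True)
class DecayHistogram:
    """Polarised TCSPC histograms with the matching instrument response.

    ``bin_times`` is a uniform grid (ns) covering one laser repetition period
    ``period`` (12.5 ns for an 80-MHz source).  Counts are non-negative; the
    IRF need not be normalised.
    """

    bin_times: np.ndarray
    counts_par: np.ndarray
    counts_perp: np.ndarray
    irf_par: np.ndarray
    irf_perp: np.ndarray
    period: float = 12.5
    experiment_id: str = field(default="tcspc1")

    def __post_init__(self):
        t = _as_1d(self.bin_times, "bin_times")
        dt = np.diff(t)
        if t.size < 8 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ParseError("bin_times must be a uniform grid of >= 8 bins")
        object.__setattr__(self, "bin_times", t)
        for name in ("counts_par", "counts_perp", "irf_par", "irf_perp"):
            arr = _as_1d(getattr(self, name), name)
            if arr.size != t.size:
                raise ParseError(f"{name} does not match bin_times")
            if np.any(arr < 0):
                raise ParseError(f"{name} must be non-negative")
            object.__setattr__(self, name, arr)
        if self.period <= t[-1] - t[0]:
            raise ParseError("period must exceed the histogram window")

    @property
    def bin_width(self) -> float:
        return float(self.bin_times[1] - self.bin_times[0])

    @property
    def total_counts(self) -> float:
        return float(self.counts_par.sum() + self.counts_perp.sum())
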