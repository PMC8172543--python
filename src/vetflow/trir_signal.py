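"""Forward model and analysis of transient-IR (TRIR) azide-band signals.

The sensor's azide stretch band red-shifts in proportion to the local excess
vibrational energy (anharmonic coupling to transiently populated low-frequency
modes). Because the shift is much smaller than the band width it is not
resolved directly; it produces a difference signal ΔA(ν, t) — induced
absorption on the low-wavenumber side, bleach on the high side — whose
amplitude is proportional to the shift. Summing |ΔA| over the pixels carrying
the signal gives the scalar VET transient whose peak time is the experimental
observable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._peaks import quadratic_peak


@dataclass
class BandModel:
    """Gaussian azide band with an energy-proportional red shift.

    ``shift_coeff`` is the red-shift magnitude in cm⁻¹ per unit sensor
    energy: at sensor energy E the band centre sits at ``center −
    shift_coeff·E``.
    """

    center: float = 2120.0       # cm⁻¹
    sigma: float = 10.0          # cm⁻¹ Gaussian width
    amplitude: float = 1.0       # mOD
    shift_coeff: float = 1.0     # cm⁻¹ per unit energy

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("band width sigma must be > 0")
        if self.amplitude <= 0:
            raise ValueError("band amplitude must be > 0")

    def profile(self, wavenumbers: np.ndarray, shift: float = 0.0) -> np.ndarray:
        nu = np.asarray(wavenumbers, dtype=float)
        return self.amplitude * np.exp(
            -0.5 * ((nu - (self.center - shift)) / self.sigma) ** 2)


@dataclass
class Spectrum2D:
    """Pixelated ΔA(ν, t) map in mOD."""

    wavenumbers: np.ndarray      # cm⁻¹, strictly monotone, ~32 pixels
    delays: np.ndarray           # ps
    delta_a: np.ndarray          # shape (n_delays, n_pixels)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        self.delta_a = np.asarray(self.delta_a, dtype=float)
        d = np.diff(self.wavenumbers)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")
        if self.delta_a.shape != (self.delays.size, self.wavenumbers.size):
            raise ValueError("delta_a must have shape (n_delays, n_pixels)")
        if not np.all(np.isfinite(self.delta_a)):
            raise ValueError("non-finite values in spectrum")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.delta_a,
                          columns=[f"{nu:.2f}" for nu in self.wavenumbers])
        df.insert(0, "delay_ps", self.delays)
        return df


@dataclass
class VETTransient:
    """Summed |ΔA| signal vs delay, with its interpolated peak time."""

    delays: np.ndarray
    signal: np.ndarray           # mOD, >= 0
    peak_time: float             # ps
    pixel_window: tuple[int, int]  # [start, stop) pixel indices used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"delay_ps": self.delays, "signal_mOD": self.signal})


def default_pixels(center: float = 2120.0, n_pixels: int = 32,
                   span: float = 64.0) -> np.ndarray:
    """Detector pixel wavenumbers around the azide band (cm⁻¹)."""
    return center + np.linspace(-span / 2, span / 2, n_pixels)


def synth_trir(band: BandModel, delays: np.ndarray,
               sensor_energy: np.ndarray,
               wavenumbers: np.ndarray | None = None,
               noise_sigma: float = 0.0, seed: int = 0) -> Spectrum2D:
    """Synthesize a TRIR difference spectrum from a sensor-energy transient.

    Each delay frame is the red-shifted band minus the unshifted band,
    ΔA(ν, t) = band(ν; shift = c_ν·E(t)) − band(ν; 0), sampled on the detector
    pixels, plus white Gaussian noise. Warns when the maximum shift leaves the
    small-shift regime (shift comparable to the band width).
    """
    delays = np.asarray(delays, dtype=float)
    sensor_energy = np.asarray(sensor_energy, dtype=float)
    if sensor_energy.shape != delays.shape:
        raise ValueError("sensor_energy and delays must align")
    nu = default_pixels(band.center) if wavenumbers is None \
        else np.asarray(wavenumbers, dtype=float)
    max_shift = band.shift_coeff * float(np.max(np.abs(sensor_energy), initial=0))
    if max_shift > 0.5 * band.sigma:
        warnings.warn("band shift is not small against the band width; the "
                      "difference signal is no longer shift-proportional",
                      stacklevel=2)
    base = band.profile(nu)
    da = np.empty((delays.size, nu.size))
    for k, e in enumerate(sensor_energy):
        da[k] = band.profile(nu, shift=band.shift_coeff * e) - base
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        da = da + rng.normal(0.0, noise_sigma, size=da.shape)
    return Spectrum2D(nu, delays, da)


def background_subtract(sample: Spectrum2D, reference: Spectrum2D,
                        scale: float = 1.0) -> Spectrum2D:
    """Subtract a scaled reference (e.g. pure-solvent) spectrum elementwise."""
    if not (np.array_equal(sample.wavenumbers, reference.wavenumbers)
            and np.array_equal(sample.delays, reference.delays)):
        raise ValueError("sample and reference grids do not match")
    return Spectrum2D(sample.wavenumbers, sample.delays,
                      sample.delta_a - scale * reference.delta_a)


def auto_pixel_window(spectrum: Spectrum2D, threshold: float = 0.1
                      ) -> tuple[int, int]:
    """Contiguous pixel range carrying the VET signal.

    Pixels whose time-averaged |ΔA| exceeds ``threshold`` times its maximum
    are selected; the window is the enclosing contiguous range.
    """
    mean_abs = np.mean(np.abs(spectrum.delta_a), axis=0)
    mask = mean_abs >= threshold * mean_abs.max()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("no pixels exceed the window threshold")
    return int(idx[0]), int(idx[-1] + 1)


def vet_transient(spectrum: Spectrum2D,
                  pixel_window: tuple[int, int] | None = None) -> VETTransient:
    """Scalar VET transient: summed |ΔA| over the signal-carrying pixels.

    ``pixel_window`` is a half-open pixel index range; by default it is chosen
    automatically (:func:`auto_pixel_window`). The peak time uses the same
    quadratic interpolation as the residue-energy peak metrics.
    """
    if pixel_window is None:
        pixel_window = auto_pixel_window(spectrum)
    a, b = pixel_window
    if b <= a or a < 0 or b > spectrum.wavenumbers.size:
        raise ValueError("empty or out-of-range pixel window")
    signal = np.sum(np.abs(spectrum.delta_a[:, a:b]), axis=1)
    peak_time, _ = quadratic_peak(spectrum.delays, signal)
    return VETTransient(spectrum.delays, signal, peak_time, (a, b))
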