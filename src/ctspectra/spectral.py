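"""Multitaper spectral estimation and aperiodic/periodic parameterization.

A power spectrum is decomposed, in log10-power space, into

* an aperiodic (Lorentzian) component ``L = b - log10(kappa + F**X)``
  with broadband offset ``b``, exponent ``X`` and optional knee ``kappa``
  (in the default *fixed* mode the knee is omitted and L is a straight
  line in log-log space, ``b - X * log10(F)``), and
* up to ``max_peaks`` Gaussian peaks
  ``G = a * exp(-(F - c)**2 / (2 * omega**2))`` with height ``a`` in
  log10-power units above the aperiodic fit, center ``c`` (Hz) and
  standard deviation ``omega`` (Hz).

The model of the full spectrum is ``log10 PSD = L + sum_n G_n``.  Fitting
is a robust two-pass aperiodic fit, iterative peak detection against a
noise threshold on the flattened spectrum, a joint Gaussian refit, and a
final aperiodic refit on the peak-subtracted spectrum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy import optimize, signal

__all__ = [
    "PowerSpectrum",
    "AperiodicComponent",
    "PeakComponent",
    "SpectralFit",
    "FitSettings",
    "detrend_epoch",
    "multitaper_psd",
    "fit_aperiodic",
    "extract_peaks",
    "fit_spectral_model",
    "select_alpha",
    "aperiodic_model",
    "gaussian_model",
]

ALPHA_BAND = (8.0, 12.0)


@dataclass
class PowerSpectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray      # Hz, ascending
    power: np.ndarray      # linear units^2/Hz, positive
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def crop(self, lo: float, hi: float) -> "PowerSpectrum":
        m = (self.freqs >= lo) & (self.freqs <= hi)
        return PowerSpectrum(self.freqs[m], self.power[m], dict(self.meta))


@dataclass(frozen=True)
class AperiodicComponent:
    """Lorentzian aperiodic fit: offset b (log10 power), exponent X,
    and knee kappa (None in fixed mode)."""

    offset: float
    exponent: float
    knee: float | None = None


@dataclass(frozen=True)
class PeakComponent:
    """Gaussian peak: height a (log10 power above the aperiodic fit),
    center c (Hz), standard deviation omega (Hz)."""

    power: float
    center: float
    width: float


@dataclass(frozen=True)
class FitSettings:
    """Settings of the spectral parameterization."""

    freq_range: tuple = (4.0, 40.0)
    max_peaks: int = 5
    min_peak_height: float = 0.0          # absolute log10 height floor
    peak_width_limits: tuple = (0.5, 12.0)
    peak_threshold: float = 2.0           # multiples of flattened-spectrum sd
    aperiodic_mode: str = "fixed"         # "fixed" or "knee"

    def __post_init__(self) -> None:
        lo, hi = self.freq_range
        if not (0 < lo < hi):
            raise ValueError("freq_range must be positive and ordered")
        wlo, whi = self.peak_width_limits
        if not (0 < wlo < whi):
            raise ValueError("peak_width_limits must be positive and ordered")
        if self.aperiodic_mode not in ("fixed", "knee"):
            raise ValueError("aperiodic_mode must be 'fixed' or 'knee'")

    def replace(self, **kw) -> "FitSettings":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SpectralFit:
    """Full decomposition of one power spectrum."""

    aperiodic: AperiodicComponent
    peaks: list          # of PeakComponent, in extraction (height) order
    fit_range: tuple
    freqs: np.ndarray = field(repr=False)
    log_power: np.ndarray = field(repr=False)   # data, log10, on fit range
    r_squared: float = np.nan
    error: float = np.nan                       # mean absolute error, log10
    settings: FitSettings = None

    def model(self) -> np.ndarray:
        """Modeled log10 power on the fit grid: L + sum of Gaussians."""
        out = aperiodic_model(self.freqs, self.aperiodic)
        for pk in self.peaks:
            out = out + gaussian_model(self.freqs, pk.power, pk.center,
                                       pk.width)
        return out

    def to_dict(self) -> dict:
        return {
            "aperiodic": {"offset": self.aperiodic.offset,
                          "exponent": self.aperiodic.exponent,
                          "knee": self.aperiodic.knee},
            "peaks": [{"power": p.power, "center": p.center,
                       "width": p.width} for p in self.peaks],
            "fit_range": list(self.fit_range),
            "r_squared": self.r_squared,
            "error": self.error,
            "settings": self.settings.to_dict() if self.settings else None,
        }


def aperiodic_model(freqs: np.ndarray, comp: AperiodicComponent) -> np.ndarray:
    """Evaluate the Lorentzian in log10 space."""
    if comp.knee is None:
        return comp.offset - comp.exponent * np.log10(freqs)
    return comp.offset - np.log10(comp.knee + freqs ** comp.exponent)


def gaussian_model(freqs: np.ndarray, a: float, c: float,
                   omega: float) -> np.ndarray:
    return a * np.exp(-((freqs - c) ** 2) / (2.0 * omega ** 2))


def detrend_epoch(samples: np.ndarray) -> np.ndarray:
    """Remove the best-fit linear trend (and mean) from a time series."""
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples to detrend")
    return signal.detrend(samples, type="linear")


def multitaper_psd(samples: np.ndarray, fs: float, half_bandwidth: float = 0.6,
                   n_tapers: int | None = None, detrend: bool = True,
                   meta: dict | None = None) -> PowerSpectrum:
    """One-sided multitaper PSD with DPSS (Slepian) tapers.

    Parameters
    ----------
    samples : array
        The epoch, sampled at ``fs`` Hz.
    half_bandwidth : float
        Spectral half-bandwidth W in Hz.  The time-bandwidth product
        ``T * W`` (T the epoch duration in s) is recorded in ``meta`` and
        must be >= 1.
    n_tapers : int, optional
        Number of tapers; must satisfy ``n_tapers <= 2 T W - 1``.  Defaults
        to the floor of that bound.

    The estimate averages the eigenspectra of the DPSS tapers and satisfies
    Parseval: the integral of the PSD over frequency approximates the
    sample variance of the (detrended) input.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    t_dur = n / fs
    tw = t_dur * half_bandwidth
    if tw < 1:
        raise ValueError(f"time-bandwidth product {tw:.3f} < 1; increase "
                         "epoch length or bandwidth")
    max_tapers = int(np.floor(2 * tw - 1))
    if n_tapers is None:
        n_tapers = max_tapers
    if n_tapers > max_tapers:
        raise ValueError(f"{n_tapers} tapers requested but 2TW-1 = "
                         f"{max_tapers} for T*W = {tw:.2f}")
    if n_tapers < 1:
        raise ValueError("need at least one taper")

    if detrend:
        samples = detrend_epoch(samples)
    tapers = signal.windows.dpss(n, tw, Kmax=n_tapers)  # rows: sum w^2 = 1
    spectra = np.abs(np.fft.rfft(tapers * samples[None, :], axis=1)) ** 2
    psd = spectra.mean(axis=0) / fs
    # one-sided: double everything except DC (and Nyquist for even n)
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    m = dict(meta or {})
    m.update({"time_bandwidth": tw, "n_tapers": n_tapers,
              "half_bandwidth_hz": half_bandwidth, "fs": fs})
    return PowerSpectrum(freqs, psd, m)


# ---------------------------------------------------------------------------
# Parameterization
# ---------------------------------------------------------------------------

def _fit_aperiodic_once(freqs, log_power, mode, guess=None):
    """Single least-squares pass of the aperiodic model in log10 space."""
    if mode == "fixed":
        if guess is None:
            slope, icpt = np.polyfit(np.log10(freqs), log_power, 1)
            guess = (icpt, -slope)
        popt, _ = optimize.curve_fit(
            lambda f, b, x: b - x * np.log10(f), freqs, log_power,
            p0=guess, maxfev=5000)
        return AperiodicComponent(offset=popt[0], exponent=popt[1])
    if guess is None:
        guess = (log_power[0], 0.0, 2.0)
    popt, _ = optimize.curve_fit(
        lambda f, b, k, x: b - np.log10(np.maximum(k + f ** x, 1e-20)),
        freqs, log_power, p0=guess,
        bounds=([-np.inf, 0, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=10000)
    return AperiodicComponent(offset=popt[0], exponent=popt[2], knee=popt[1])


def fit_aperiodic(spectrum: PowerSpectrum,
                  settings: FitSettings | None = None) -> AperiodicComponent:
    """Robust two-pass fit of the aperiodic component.

    A first least-squares fit is subtracted from the spectrum; bins rising
    above it (peak regions) are masked by keeping only residuals at or
    below a low percentile of the clipped residual distribution, and the
    aperiodic model is refit on the remaining bins.  This keeps narrowband
    peaks from dragging the broadband fit upward.
    """
    settings = settings or FitSettings()
    spec = spectrum.crop(*settings.freq_range)
    if spec.freqs.size < 3:
        raise ValueError("fewer than 3 bins inside the fit range")
    if np.any(spec.power <= 0):
        raise ValueError("power must be positive on the fit range")
    log_power = np.log10(spec.power)

    fit = _fit_aperiodic_once(spec.freqs, log_power, settings.aperiodic_mode)
    for _ in range(2):  # two masked refits settle the peak-region exclusion
        resid = log_power - aperiodic_model(spec.freqs, fit)
        resid = np.where(resid < 0, 0.0, resid)
        # keep bins at/below the fit; 2.5 marks how far into the positive
        # residuals the mask reaches (percentile of the clipped residuals)
        thresh = np.percentile(resid, 2.5)
        mask = resid <= thresh
        if mask.sum() < 3:
            break
        fit = _fit_aperiodic_once(
            spec.freqs[mask], log_power[mask], settings.aperiodic_mode,
            guess=((fit.offset, fit.exponent) if settings.aperiodic_mode
                   == "fixed" else (fit.offset, fit.knee, fit.exponent)))
    return fit


def _guess_peaks(freqs, flat, settings):
    """Iteratively locate peak guesses on the flattened spectrum."""
    flat = flat.copy()
    wlo, whi = settings.peak_width_limits
    guesses = []
    for _ in range(settings.max_peaks):
        idx = int(np.argmax(flat))
        height = flat[idx]
        # 1e-6 log10-power floor guards against fitting numerical residue
        # of noiseless spectra as peaks
        if height <= max(settings.peak_threshold * np.std(flat),
                         settings.min_peak_height, 1e-6):
            break
        cf = freqs[idx]
        # half-height width estimate, clipped to the configured limits
        half = height / 2.0
        right = idx
        while right < flat.size - 1 and flat[right] > half:
            right += 1
        left = idx
        while left > 0 and flat[left] > half:
            left -= 1
        fwhm = freqs[right] - freqs[left]
        omega = np.clip(fwhm / 2.355 if fwhm > 0 else wlo, wlo / 2, whi / 2)
        guesses.append((height, cf, omega))
        flat -= gaussian_model(freqs, height, cf, omega)
    return _prune_overlap(guesses)


def _prune_overlap(guesses, overlap_sd: float = 0.75):
    """Drop the lower of any pair of overlapping peak guesses.

    Two guesses overlap when their center +/- ``overlap_sd`` * width bands
    intersect; noise can split one broad peak into two nearby guesses, and
    keeping only the taller one lets the joint refit recover the true peak.
    """
    keep = sorted(guesses, key=lambda g: g[1])
    dropped = True
    while dropped:
        dropped = False
        for j in range(len(keep) - 1):
            a1, c1, w1 = keep[j]
            a2, c2, w2 = keep[j + 1]
            if c1 + overlap_sd * w1 >= c2 - overlap_sd * w2:
                del keep[j if a1 < a2 else j + 1]
                dropped = True
                break
    return keep


def _joint_gaussian_fit(freqs, flat, guesses, settings):
    """Refit all Gaussians simultaneously on the flattened spectrum."""
    wlo, whi = settings.peak_width_limits
    lo_f, hi_f = freqs[0], freqs[-1]
    p0, lb, ub = [], [], []
    for a, c, w in guesses:
        p0 += [a, c, w]
        lb += [0.0, max(c - 1.5 * w, lo_f - 2 * w), wlo / 2]
        ub += [np.inf, min(c + 1.5 * w, hi_f + 2 * w), whi / 2]

    def model(f, *p):
        out = np.zeros_like(f)
        for j in range(0, len(p), 3):
            out += gaussian_model(f, p[j], p[j + 1], p[j + 2])
        return out

    try:
        popt, _ = optimize.curve_fit(model, freqs, flat, p0=p0,
                                     bounds=(lb, ub), maxfev=5000)
    except RuntimeError:
        popt = np.asarray(p0, dtype=float)  # non-convergent refit: keep guesses
    peaks = [PeakComponent(power=popt[j], center=popt[j + 1],
                           width=popt[j + 2])
             for j in range(0, len(popt), 3)]
    return peaks


def extract_peaks(freqs: np.ndarray, flattened: np.ndarray,
                  settings: FitSettings | None = None) -> list:
    """Detect and fit Gaussian peaks on an aperiodic-flattened log spectrum.

    Peaks are found iteratively at the residual maximum, accepted only if
    they clear both ``peak_threshold`` standard deviations of the flattened
    spectrum and the absolute ``min_peak_height``, then refit jointly.
    Peaks whose fitted centers leave the fit range are dropped.  Returned
    in decreasing order of fitted height.
    """
    settings = settings or FitSettings()
    freqs = np.asarray(freqs, dtype=float)
    flattened = np.asarray(flattened, dtype=float)
    guesses = _guess_peaks(freqs, flattened, settings)
    if not guesses:
        return []
    peaks = _joint_gaussian_fit(freqs, flattened, guesses, settings)
    peaks = [p for p in peaks
             if freqs[0] <= p.center <= freqs[-1] and p.power > 1e-6]
    peaks.sort(key=lambda p: p.power, reverse=True)
    return peaks


def fit_spectral_model(spectrum: PowerSpectrum,
                       settings: FitSettings | None = None) -> SpectralFit:
    """Full decomposition: aperiodic fit, peak extraction, joint refit.

    Steps: robust aperiodic fit -> flatten -> peak extraction with joint
    Gaussian refit -> subtract fitted peaks -> final (plain) aperiodic fit
    on the peak-free spectrum.  Goodness of fit (R^2 and mean absolute
    error) is computed in log10 space against the data on the fit range.
    """
    settings = settings or FitSettings()
    spec = spectrum.crop(*settings.freq_range)
    if spec.freqs.size < 3:
        raise ValueError("fewer than 3 bins inside the fit range")
    log_power = np.log10(spec.power)

    ap = fit_aperiodic(spectrum, settings)
    flat = log_power - aperiodic_model(spec.freqs, ap)
    peaks = extract_peaks(spec.freqs, flat, settings)

    peak_sum = np.zeros_like(spec.freqs)
    for p in peaks:
        peak_sum += gaussian_model(spec.freqs, p.power, p.center, p.width)
    ap_final = _fit_aperiodic_once(
        spec.freqs, log_power - peak_sum, settings.aperiodic_mode,
        guess=((ap.offset, ap.exponent) if settings.aperiodic_mode == "fixed"
               else (ap.offset, ap.knee, ap.exponent)))

    fit = SpectralFit(aperiodic=ap_final, peaks=peaks,
                      fit_range=tuple(settings.freq_range),
                      freqs=spec.freqs, log_power=log_power,
                      settings=settings)
    model = fit.model()
    resid = log_power - model
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((log_power - log_power.mean()) ** 2))
    fit.r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    fit.error = float(np.mean(np.abs(resid)))
    return fit


def select_alpha(fit: SpectralFit,
                 band: tuple = ALPHA_BAND) -> PeakComponent | None:
    """The highest-power peak with center inside the alpha band, or None."""
    lo, hi = band
    candidates = [p for p in fit.peaks if lo <= p.center <= hi]
    if not candidates:
        return None
    return max(candidates, key=lambda p: p.power)


def average_spectra(spectra: Iterable[PowerSpectrum]) -> PowerSpectrum:
    """Average per-channel PSDs onto their (shared) grid."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to average")
    f0 = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != f0.shape or not np.allclose(s.freqs, f0):
            raise ValueError("spectra are on different frequency grids")
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(f0, power, {"n_averaged": len(spectra)})
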