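"""Welch spectra and periodic/aperiodic parameterization.

The power spectrum is modeled in log10 space as an aperiodic 1/f component
(offset, exponent; no knee) plus Gaussian peaks (center frequency, height
above the aperiodic curve, bandwidth = 2 SD). Fitting follows the standard
spectral-parameterization recipe: a robust aperiodic fit on the lower
envelope of the spectrum, iterative Gaussian extraction from the flattened
residual, a joint multi-Gaussian refinement, and a final aperiodic re-fit on
the peak-subtracted spectrum. Aperiodic-adjusted alpha power and center
frequency are read off the fitted peak inside a configurable band
(default 8-12 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .core import EEGRecording, EpochSet

__all__ = [
    "PSD",
    "SpectralFit",
    "AlphaParams",
    "SpectralSettings",
    "welch_psd",
    "average_psd_channels",
    "fit_aperiodic",
    "fit_peaks",
    "parameterize",
    "extract_alpha",
    "subject_spectral_fit",
]


@dataclass
class PSD:
    """One-sided power spectral density: ``power`` in µV²/Hz over ``freqs`` Hz."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def restrict(self, f_lo: float, f_hi: float) -> "PSD":
        m = (self.freqs >= f_lo) & (self.freqs <= f_hi)
        return PSD(freqs=self.freqs[m], power=self.power[m])


@dataclass
class SpectralFit:
    """Fitted aperiodic + peak model of one spectrum.

    ``peaks`` rows are (center_frequency Hz, height in log10 units above the
    aperiodic curve, bandwidth Hz = 2 SD). ``r_squared`` is the squared
    correlation between model and log10 spectrum; ``residual_error`` the mean
    absolute log10 residual.
    """

    offset: float
    exponent: float
    peaks: np.ndarray  # (n_peaks, 3)
    r_squared: float
    residual_error: float
    freqs: np.ndarray | None = None

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        """Full model in log10 power units."""
        out = self.aperiodic(freqs)
        for cf, h, bw in np.atleast_2d(self.peaks) if len(self.peaks) else []:
            out = out + _gaussian(freqs, cf, h, bw / 2.0)
        return out


@dataclass
class AlphaParams:
    """Aperiodic-adjusted alpha parameters; NaN when no in-band peak exists."""

    alpha_power: float
    alpha_cf: float

    @property
    def present(self) -> bool:
        return np.isfinite(self.alpha_cf)


@dataclass
class SpectralSettings:
    """Parameterization settings (defaults are the analysis-standard values)."""

    fit_range: tuple[float, float] = (1.0, 40.0)
    peak_width_limits: tuple[float, float] = (1.0, 10.0)
    max_n_peaks: int = 10
    peak_threshold: float = 1.0  # in SDs of the flattened residual
    min_peak_height: float = 0.0
    alpha_band: tuple[float, float] = (8.0, 12.0)
    ap_percentile: float = 2.5  # lower-envelope percentile for the robust re-fit
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5


def welch_psd(rec: EEGRecording, window_s: float = 2.0, overlap: float = 0.5) -> list[PSD]:
    """Per-channel Welch PSD (Hamming window, 50% overlap by default)."""
    nperseg = int(round(window_s * rec.fs))
    if rec.n_samples < nperseg:
        raise ValueError("recording shorter than one Welch window")
    freqs, power = signal.welch(
        rec.data,
        fs=rec.fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        axis=0,
        detrend="constant",
    )
    return [PSD(freqs=freqs, power=power[:, c]) for c in range(rec.n_channels)]


def welch_psd_epochs(epochs: EpochSet, window_s: float = 2.0, overlap: float = 0.5) -> list[PSD]:
    """Per-channel Welch PSD averaged over epochs."""
    per_epoch = [welch_psd(e, window_s, overlap) for e in epochs]
    n_ch = epochs.n_channels
    out = []
    for c in range(n_ch):
        power = np.mean([pe[c].power for pe in per_epoch], axis=0)
        out.append(PSD(freqs=per_epoch[0][c].freqs, power=power))
    return out


def average_psd_channels(psds: list[PSD]) -> PSD:
    """Arithmetic mean of power across channels on a shared frequency grid."""
    if not psds:
        raise ValueError("no PSDs to average")
    f0 = psds[0].freqs
    for p in psds[1:]:
        if p.freqs.shape != f0.shape or not np.allclose(p.freqs, f0):
            raise ValueError("PSDs are on different frequency grids")
    return PSD(freqs=f0.copy(), power=np.mean([p.power for p in psds], axis=0))


def _gaussian(f: np.ndarray, cf: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-((f - cf) ** 2) / (2.0 * sd**2))


def _aperiodic_func(log_f: np.ndarray, offset: float, exponent: float) -> np.ndarray:
    return offset - exponent * log_f


def _simple_ap_fit(freqs: np.ndarray, log_power: np.ndarray) -> tuple[float, float]:
    log_f = np.log10(freqs)
    slope, intercept = np.polyfit(log_f, log_power, 1)
    return float(intercept), float(-slope)


def fit_aperiodic(
    psd: PSD, fit_range: tuple[float, float] = (1.0, 40.0), ap_percentile: float = 2.5
) -> tuple[float, float]:
    """Robust (offset, exponent) of the 1/f background, knee-free.

    A first least-squares line in log-log space is refined on the lower
    envelope: residuals above the ``ap_percentile`` percentile of the
    positive residuals are excluded, which keeps the fit off oscillatory
    bumps. Deterministic.
    """
    p = psd.restrict(*fit_range)
    if p.freqs.size < 3:
        raise ValueError("too few frequencies in fit range")
    if np.any(p.power <= 0):
        raise ValueError("power must be positive on the fit range")
    log_power = np.log10(p.power)
    offset, exponent = _simple_ap_fit(p.freqs, log_power)
    resid = log_power - (offset - exponent * np.log10(p.freqs))
    resid = np.where(resid < 0, 0.0, resid)
    thresh = np.percentile(resid, ap_percentile)
    mask = resid <= thresh
    if mask.sum() >= 3:
        log_f = np.log10(p.freqs[mask])
        (offset, neg_slope), _ = optimize.curve_fit(
            lambda lf, o, e: o - e * lf, log_f, log_power[mask], p0=(offset, exponent)
        )
        offset, exponent = float(offset), float(neg_slope)
    return offset, exponent


def _estimate_width(freqs: np.ndarray, flat: np.ndarray, i_max: int, height: float) -> float:
    """Half-height crossing estimate of a peak's Gaussian SD."""
    half = height / 2.0
    i_lo = i_max
    while i_lo > 0 and flat[i_lo] > half:
        i_lo -= 1
    i_hi = i_max
    while i_hi < len(flat) - 1 and flat[i_hi] > half:
        i_hi += 1
    fwhm = freqs[i_hi] - freqs[i_lo]
    if fwhm <= 0:
        fwhm = freqs[1] - freqs[0]
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _drop_overlapping(
    guesses: list[tuple[float, float, float]], overlap_sds: float = 1.0
) -> list[tuple[float, float, float]]:
    """Keep only the taller of two Gaussian guesses whose ±overlap_sds·SD
    intervals intersect; overlapping guesses split one bump and destabilize
    the joint fit."""
    order = sorted(guesses, key=lambda g: g[0])
    kept: list[tuple[float, float, float]] = []
    for g in order:
        if kept:
            prev = kept[-1]
            if g[0] - overlap_sds * g[2] <= prev[0] + overlap_sds * prev[2]:
                if g[1] > prev[1]:
                    kept[-1] = g
                continue
        kept.append(g)
    return kept


def fit_peaks(
    freqs: np.ndarray,
    flattened: np.ndarray,
    peak_width_limits: tuple[float, float] = (1.0, 10.0),
    max_n_peaks: int = 10,
    peak_threshold: float = 1.0,
    min_peak_height: float = 0.0,
) -> np.ndarray:
    """Iterative Gaussian extraction from a flattened log spectrum.

    Repeatedly takes the largest residual point, accepts it while it clears
    both ``min_peak_height`` and ``peak_threshold`` SDs of the residual, fits
    and subtracts a Gaussian with SD clipped to ``peak_width_limits``/2, then
    jointly refines all accepted Gaussians. Returns (cf, height, bandwidth)
    rows sorted by center frequency; bandwidth = 2 SD.
    """
    freqs = np.asarray(freqs, dtype=float)
    flat = np.asarray(flattened, dtype=float).copy()
    sd_lo, sd_hi = peak_width_limits[0] / 2.0, peak_width_limits[1] / 2.0
    guesses: list[tuple[float, float, float]] = []
    for _ in range(max_n_peaks):
        i = int(np.argmax(flat))
        height = flat[i]
        # 1e-8 floor: log10-power roundoff must never seed a "peak"
        if height <= max(min_peak_height, peak_threshold * np.std(flat), 1e-8):
            break
        sd = float(np.clip(_estimate_width(freqs, flat, i, height), sd_lo, sd_hi))
        guesses.append((float(freqs[i]), float(height), sd))
        flat -= _gaussian(freqs, freqs[i], height, sd)
    if not guesses:
        return np.empty((0, 3))
    guesses = _drop_overlapping(guesses)

    def multi_gauss(f, *params):
        out = np.zeros_like(f)
        for j in range(0, len(params), 3):
            out += _gaussian(f, params[j], params[j + 1], params[j + 2])
        return out

    p0 = np.array(guesses).ravel()
    lo, hi = [], []
    for cf, h, sd in guesses:
        # centers may move at most 2 SD in the joint refinement, so noise
        # bumps elsewhere cannot drag an accepted peak off its band
        lo += [max(freqs[0], cf - 2 * sd), 0.0, sd_lo]
        hi += [min(freqs[-1], cf + 2 * sd), np.inf, sd_hi]
    try:
        popt, _ = optimize.curve_fit(
            multi_gauss, freqs, np.asarray(flattened, dtype=float),
            p0=p0, bounds=(lo, hi), maxfev=5000,
        )
    except RuntimeError:  # keep the iterative guesses if refinement stalls
        popt = p0
    peaks = popt.reshape(-1, 3)
    peaks[:, 2] *= 2.0  # SD -> bandwidth
    return peaks[np.argsort(peaks[:, 0])]


def parameterize(psd: PSD, settings: SpectralSettings | None = None) -> SpectralFit:
    """Full periodic/aperiodic decomposition of one spectrum.

    Pipeline: robust aperiodic fit -> flatten -> iterative + joint peak fit
    -> subtract the peak model and re-fit the aperiodic component with a
    plain least-squares line -> assemble the model and quality metrics.
    Warns when the fit misses the usual quality gates (r² <= 0.95 or mean
    absolute residual >= 0.03).
    """
    s = settings or SpectralSettings()
    p = psd.restrict(*s.fit_range)
    if np.any(p.power <= 0):
        raise ValueError("power must be positive on the fit range")
    log_power = np.log10(p.power)

    offset, exponent = fit_aperiodic(p, s.fit_range, s.ap_percentile)
    flattened = log_power - (offset - exponent * np.log10(p.freqs))
    peaks = fit_peaks(
        p.freqs, flattened, s.peak_width_limits, s.max_n_peaks,
        s.peak_threshold, s.min_peak_height,
    )
    peak_model = np.zeros_like(p.freqs)
    for cf, h, bw in peaks:
        peak_model += _gaussian(p.freqs, cf, h, bw / 2.0)
    offset, exponent = _simple_ap_fit(p.freqs, log_power - peak_model)

    model = (offset - exponent * np.log10(p.freqs)) + peak_model
    resid = log_power - model
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((log_power - log_power.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    err = float(np.mean(np.abs(resid)))
    if r2 <= 0.95 or err >= 0.03:
        warnings.warn(
            f"spectral fit quality below gates: r2={r2:.3f}, residual={err:.4f}"
        )
    return SpectralFit(
        offset=float(offset), exponent=float(exponent), peaks=peaks,
        r_squared=float(np.clip(r2, 0.0, 1.0)), residual_error=err,
        freqs=p.freqs,
    )


def extract_alpha(fit: SpectralFit, band: tuple[float, float] = (8.0, 12.0)) -> AlphaParams:
    """Highest-power fitted peak inside the alpha band; NaN when absent."""
    peaks = np.atleast_2d(fit.peaks) if len(fit.peaks) else np.empty((0, 3))
    in_band = peaks[(peaks[:, 0] >= band[0]) & (peaks[:, 0] <= band[1])] if len(peaks) else peaks
    if len(in_band) == 0:
        return AlphaParams(alpha_power=float("nan"), alpha_cf=float("nan"))
    best = in_band[np.argmax(in_band[:, 1])]
    return AlphaParams(alpha_power=float(best[1]), alpha_cf=float(best[0]))


def subject_spectral_fit(
    epochs: EpochSet, settings: SpectralSettings | None = None
) -> tuple[SpectralFit, AlphaParams]:
    """Channel-averaged Welch PSD -> parameterize -> alpha extraction."""
    s = settings or SpectralSettings()
    psds = welch_psd_epochs(epochs, s.welch_window_s, s.welch_overlap)
    mean_psd = average_psd_channels(psds)
    fit = parameterize(mean_psd, s)
    return fit, extract_alpha(fit, s.alpha_band)
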