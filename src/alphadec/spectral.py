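"""Welch spectra, aperiodic 1/f fitting, detrending and alpha-peak detection.

The aperiodic (1/f) component is modelled in log-log space as

    log p(f) = -log a - b * log f

with stretch ``a > 0`` and slope ``b``, fitted by least squares between 0
and 40 Hz while excluding a ±4 Hz window around the individual alpha peak
so that the oscillatory bump does not bias the fit.  Subtracting the fitted
curve from the log spectrum yields the detrended residual on which the
individual alpha peak (argmax in 8-13 Hz) and the component-selection
criteria operate.  Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import signal

__all__ = [
    "Spectrum",
    "OneOverFFit",
    "DetrendedSpectrum",
    "welch_psd",
    "fit_one_over_f",
    "detrend_spectrum",
    "find_alpha_peak",
    "ssd_bands",
]


@dataclass
class Spectrum:
    """Welch power spectral density (µV²/Hz) on a regular frequency grid."""

    freqs: NDArray[np.float64]
    power: NDArray[np.float64]
    fs: float
    welch_segment_s: float = 5.0
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have matching shapes")
        if np.any(np.diff(self.freqs) <= 0) or self.freqs[0] < 0:
            raise ValueError("freqs must be nonnegative and increasing")


@dataclass(frozen=True)
class OneOverFFit:
    """Parameters of the aperiodic fit log p = -log a - b log f."""

    a: float
    b: float
    fit_range_hz: tuple[float, float]
    exclusion_center_hz: float | None
    exclusion_halfwidth_hz: float

    def log_curve(self, freqs: NDArray[np.float64]) -> NDArray[np.float64]:
        freqs = np.asarray(freqs, dtype=float)
        if np.any(freqs <= 0):
            raise ValueError("1/f curve undefined at f <= 0")
        return -np.log(self.a) - self.b * np.log(freqs)


@dataclass
class DetrendedSpectrum:
    """Log-power residuals after removing the fitted aperiodic curve."""

    freqs: NDArray[np.float64]
    residual: NDArray[np.float64]

    def in_range(self, lo: float, hi: float) -> NDArray[np.bool_]:
        return (self.freqs >= lo) & (self.freqs <= hi)


def welch_psd(
    x: NDArray[np.float64],
    fs: float,
    segment_s: float = 5.0,
    overlap: float = 0.5,
) -> Spectrum:
    """Welch PSD with Hann-windowed segments of ``segment_s`` seconds and
    fractional ``overlap`` (density scaling)."""
    x = np.asarray(x, dtype=float).ravel()
    nperseg = int(round(segment_s * fs))
    if x.size < nperseg:
        raise ValueError("signal shorter than one Welch segment")
    freqs, power = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend="constant",
        scaling="density",
    )
    return Spectrum(
        freqs=freqs, power=power, fs=fs, welch_segment_s=segment_s, overlap_fraction=overlap
    )


def fit_one_over_f(
    spec: Spectrum,
    exclusion_center_hz: float | None = None,
    exclusion_halfwidth_hz: float = 4.0,
    range_hz: tuple[float, float] = (0.0, 40.0),
) -> OneOverFFit:
    """Least-squares line in (log f, log p) over ``range_hz``, excluding the
    zero-frequency bin and, if given, ±``exclusion_halfwidth_hz`` around the
    (putative) alpha peak."""
    mask = (spec.freqs > max(range_hz[0], 0.0)) & (spec.freqs <= range_hz[1]) & (spec.freqs > 0)
    if exclusion_center_hz is not None:
        mask &= np.abs(spec.freqs - exclusion_center_hz) > exclusion_halfwidth_hz
    f = spec.freqs[mask]
    p = spec.power[mask]
    ok = p > 0
    if not np.any(ok):
        raise ValueError("all power bins in the fit range are zero")
    f, p = f[ok], p[ok]
    if f.size < 5:
        raise ValueError("fewer than 5 usable bins for the 1/f fit")
    slope, intercept = np.polyfit(np.log(f), np.log(p), 1)
    return OneOverFFit(
        a=float(np.exp(-intercept)),
        b=float(-slope),
        fit_range_hz=range_hz,
        exclusion_center_hz=exclusion_center_hz,
        exclusion_halfwidth_hz=exclusion_halfwidth_hz,
    )


def detrend_spectrum(spec: Spectrum, fit: OneOverFFit) -> DetrendedSpectrum:
    """Residual = log power - fitted log 1/f curve, on the f > 0 grid.

    Zero-power bins give -inf residuals; they are left in place so callers
    notice rather than silently interpolating.
    """
    mask = spec.freqs > 0
    f = spec.freqs[mask]
    with np.errstate(divide="ignore"):
        resid = np.log(spec.power[mask]) - fit.log_curve(f)
    return DetrendedSpectrum(freqs=f, residual=resid)


def find_alpha_peak(
    detrended: DetrendedSpectrum,
    search_range: tuple[float, float] = (8.0, 13.0),
) -> float:
    """Frequency of the maximal detrended residual within ``search_range``.

    There is no minimum-prominence requirement: if the residual is
    monotone in the range the boundary argmax is returned as the peak.
    """
    mask = detrended.in_range(*search_range)
    if not np.any(mask):
        raise ValueError("search range contains no frequency bins")
    f = detrended.freqs[mask]
    r = detrended.residual[mask]
    return float(f[np.argmax(r)])


def ssd_bands(alpha_peak_hz: float) -> dict[str, tuple[float, float]]:
    """Frequency bands around the individual alpha peak used by SSD:
    bandpass signal ±2 Hz, bandstop ±3 Hz, bandpass noise ±4 Hz."""
    if not 8.0 <= alpha_peak_hz <= 13.0:
        raise ValueError("alpha peak must lie in [8, 13] Hz")
    return {
        "signal": (alpha_peak_hz - 2.0, alpha_peak_hz + 2.0),
        "stop": (alpha_peak_hz - 3.0, alpha_peak_hz + 3.0),
        "noise": (alpha_peak_hz - 4.0, alpha_peak_hz + 4.0),
    }
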