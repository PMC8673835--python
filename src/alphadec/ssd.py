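"""Spatio-spectral decomposition (SSD) and alpha-component selection.

SSD extracts oscillatory sources by solving the generalized eigenvalue
problem that maximizes variance in a signal band (individual alpha peak
±2 Hz) relative to flanking noise bands (±4 Hz bandpass with the ±3 Hz
band stopped out).  Filters are obtained after rank-truncating whitening;
spatial patterns come from (pseudo-)inverting the filter matrix.

Component selection follows a two-criterion rule on each component's
1/f-detrended log spectrum: (A) the detrended peak inside the alpha window
must exceed an absolute threshold, and (B) after z-scoring, the peak must
exceed the larger of the two adjacent 2-Hz flank means by a margin.
Subjects providing fewer than four selected components are excluded from
decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import linalg, signal

from .spectral import DetrendedSpectrum, detrend_spectrum, fit_one_over_f, welch_psd
from .synth import Recording

__all__ = [
    "SSDResult",
    "bandpass_filter",
    "bandstop_filter",
    "ssd_decompose",
    "select_components",
    "require_min_components",
]


def _fir_taps(fs: float, transition_hz: float = 1.0) -> int:
    # Hamming window: transition width ~ 3.3 / numtaps (normalized)
    return int(3.3 * fs / transition_hz) | 1


def bandpass_filter(
    data: NDArray[np.float64], fs: float, lo: float, hi: float, transition_hz: float = 1.0
) -> NDArray[np.float64]:
    """Zero-phase Hamming-windowed sinc FIR bandpass along the last axis."""
    taps = signal.firwin(
        _fir_taps(fs, transition_hz), [lo, hi], pass_zero=False, window="hamming", fs=fs
    )
    return signal.fftconvolve(data, taps[None, :], mode="same", axes=-1)


def bandstop_filter(
    data: NDArray[np.float64], fs: float, lo: float, hi: float, transition_hz: float = 1.0
) -> NDArray[np.float64]:
    """Zero-phase Hamming-windowed sinc FIR bandstop along the last axis."""
    taps = signal.firwin(
        _fir_taps(fs, transition_hz), [lo, hi], pass_zero="bandstop", window="hamming", fs=fs
    )
    return signal.fftconvolve(data, taps[None, :], mode="same", axes=-1)


@dataclass
class SSDResult:
    """Filters, patterns, eigenvalues and per-component detrended spectra."""

    filters_W: NDArray[np.float64]      # channels x components (unmixing)
    patterns_A: NDArray[np.float64]     # channels x components (scalp projections)
    eigenvalues: NDArray[np.float64]    # descending band-power ratios
    components: NDArray[np.float64]     # components x samples, signal-band filtered
    component_spectra: list[DetrendedSpectrum] = field(default_factory=list)
    selected: NDArray[np.int_] = field(default_factory=lambda: np.array([], dtype=int))
    fs: float = 0.0

    @property
    def n_components(self) -> int:
        return self.filters_W.shape[1]


def ssd_decompose(
    rec: Recording | NDArray[np.float64],
    bands: dict[str, tuple[float, float]],
    fs: float | None = None,
    rank_tol: float = 1e-10,
) -> SSDResult:
    """Decompose a recording into SSD components for the given band set.

    ``bands`` must provide "signal", "stop" and "noise" (lo, hi) pairs as
    produced by :func:`alphadec.spectral.ssd_bands`.  The returned
    ``components`` are the signal-band-filtered projections; the
    ``component_spectra`` used for selection are computed from broadband
    projections so the 1/f background is visible.
    """
    if isinstance(rec, Recording):
        X, fs = rec.data, rec.fs
    else:
        X = np.atleast_2d(np.asarray(rec, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    n_ch, n_samp = X.shape
    if n_ch < 2:
        raise ValueError("SSD needs at least two channels")
    if n_samp < 10 * fs:
        raise ValueError("recording shorter than 10 s")

    Xs = bandpass_filter(X, fs, *bands["signal"])
    Xn = bandstop_filter(bandpass_filter(X, fs, *bands["noise"]), fs, *bands["stop"])

    Cs = np.cov(Xs)
    Cn = np.cov(Xn)

    # rank-truncating whitening on the signal covariance
    d, V = np.linalg.eigh(Cs)
    keep = d > rank_tol * d.max()
    if keep.sum() < 2:
        raise ValueError("rank < 2 after truncation: degenerate input")
    M = V[:, keep] / np.sqrt(d[keep])

    evals, evecs = linalg.eigh(M.T @ Cs @ M, M.T @ Cn @ M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    W = M @ evecs

    components = W.T @ Xs
    broadband = W.T @ X
    alpha_center = 0.5 * (bands["signal"][0] + bands["signal"][1])
    spectra: list[DetrendedSpectrum] = []
    for comp in broadband:
        spec = welch_psd(comp, fs)
        fit = fit_one_over_f(spec, exclusion_center_hz=alpha_center)
        spectra.append(detrend_spectrum(spec, fit))

    patterns = np.linalg.pinv(W).T
    return SSDResult(
        filters_W=W,
        patterns_A=patterns,
        eigenvalues=evals,
        components=components,
        component_spectra=spectra,
        fs=float(fs),
    )


def select_components(
    res: SSDResult,
    alpha_peak_hz: float,
    threshold: float = 0.35,
    flank_sd: float = 1.45,
    flank_width_hz: float = 2.0,
    alpha_halfwidth_hz: float = 2.0,
) -> NDArray[np.int_]:
    """Indices of components with a clearly defined alpha peak.

    A component is kept iff
      (A) its detrended log-power peak within alpha_peak ± 2 Hz exceeds
          ``threshold`` (natural-log residual scale; the constant is a
          config parameter because the printed units are ambiguous), and
      (B) after z-scoring the detrended spectrum over the fit range, the
          peak exceeds the larger of the two adjacent 2-Hz flank means by
          at least ``flank_sd``.
    """
    lo_w = alpha_peak_hz - alpha_halfwidth_hz
    hi_w = alpha_peak_hz + alpha_halfwidth_hz
    selected = []
    for idx, det in enumerate(res.component_spectra):
        if not np.any(det.freqs <= lo_w - flank_width_hz) or not np.any(
            det.freqs >= hi_w + flank_width_hz
        ):
            raise ValueError("component spectrum does not cover the flank range")
        window = det.in_range(lo_w, hi_w)
        peak = det.residual[window].max()
        if not peak > threshold:  # criterion A
            continue
        finite = np.isfinite(det.residual)
        mu, sd = det.residual[finite].mean(), det.residual[finite].std()
        if sd == 0:
            continue
        z = (det.residual - mu) / sd
        left = (det.freqs >= lo_w - flank_width_hz) & (det.freqs < lo_w)
        right = (det.freqs > hi_w) & (det.freqs <= hi_w + flank_width_hz)
        flank = max(z[left].mean(), z[right].mean())
        if z[window].max() - flank >= flank_sd:  # criterion B
            selected.append(idx)
    return np.asarray(selected, dtype=int)


def require_min_components(selected: NDArray[np.int_], minimum: int = 4) -> bool:
    """True iff the subject provides at least ``minimum`` selected
    components and is kept for the decoding models."""
    return len(selected) >= minimum
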