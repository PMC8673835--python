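"""Ground-truth-known synthetic EEG + continuous arousal ratings.

The generator emulates the data model of a naturalistic rollercoaster-style
experiment: a 270-s multichannel EEG recording (30 scalp channels, 250 Hz)
together with a 1-Hz continuous self-report of emotional arousal (dial from
0 to 100 in 50 discrete steps), structured as ride - break - ride.

The EEG is a linear mixture of

* narrowband alpha sources (individual peak in 8-13 Hz).  The first alpha
  source is the "arousal source": its amplitude envelope is negatively
  coupled to the (min-max normalised) arousal trace with strength
  ``coupling_kappa`` -- high arousal, low alpha power.  The remaining alpha
  sources are stationary distractors so that downstream component-selection
  rules (which require several clean alpha components) are exercised.
* broadband 1/f^b aperiodic background sources,
* additive white sensor noise.

Because the mixing matrix and the arousal source's envelope are returned as
:class:`GroundTruth`, every downstream spatial-filtering stage can be tested
as a parameter-recovery problem.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import signal
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "CHANNELS_30",
    "PhaseProfile",
    "SynthConfig",
    "RatingTrace",
    "Recording",
    "GroundTruth",
    "generate_arousal_trace",
    "generate_subject",
    "pattern_similarity",
]

#: 30-channel scalp montage (10-20 names) used by the synthetic recordings.
CHANNELS_30 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

#: Channels carried mostly by parieto-occipital cortex in the emphasis option.
_PARIETO_OCCIPITAL = frozenset(
    {"CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8", "O1", "Oz", "O2"}
)


@dataclass(frozen=True)
class PhaseProfile:
    """Per-phase mean arousal levels and the roughness of the rating dial.

    ``segments`` holds (duration_s, offset) pairs in chronological order.
    The default profile mimics the experience structure: a first ride at
    moderate arousal, a low-arousal break, and a second, more arousing ride.
    ``smooth_s`` is the Gaussian smoothing bandwidth (seconds) of the random
    fluctuation around the offsets; the autocorrelation of real rating
    traces is not known precisely, so this is an explicit knob.
    """

    segments: tuple[tuple[float, float], ...] = ((148.0, 45.0), (30.0, 15.0), (92.0, 65.0))
    noise_sd: float = 14.0
    smooth_s: float = 8.0

    @property
    def duration_s(self) -> int:
        return int(round(sum(d for d, _ in self.segments)))


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters of one synthetic subject."""

    n_channels: int = 30
    fs: float = 250.0
    duration_s: int = 270
    segment_lengths_s: tuple[float, float, float] = (148.0, 30.0, 92.0)
    alpha_peak_hz: float = 10.0
    coupling_kappa: float = 0.8
    n_alpha_sources: int = 4
    n_background_sources: int = 8
    aperiodic_slope: float = 1.0
    alpha_source_amp: float = 8.0    # source std in µV at sensor scale
    background_amp: float = 12.0
    sensor_noise_sd: float = 2.0     # µV
    parieto_occipital_bias: bool = True
    rating_smooth_s: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.segment_lengths_s) - self.duration_s) > 1e-9:
            raise ValueError("segment_lengths_s must sum to duration_s")
        if not 0.0 <= self.coupling_kappa <= 1.0:
            raise ValueError("coupling_kappa must lie in [0, 1]")
        if not 8.0 <= self.alpha_peak_hz <= 13.0:
            raise ValueError("alpha_peak_hz must lie in the alpha range [8, 13]")
        if self.fs <= 2.0 * (self.alpha_peak_hz + 4.0):
            raise ValueError("fs too low to represent the alpha noise band")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least two channels")


@dataclass
class RatingTrace:
    """Continuous arousal self-report at 1 Hz.

    ``values`` lies in [0, 100]; when ``quantized`` the values sit on the
    ``n_levels``-point dial grid.  ``z`` is the z-scored copy used as the
    continuous decoding target.
    """

    values: NDArray[np.float64]
    n_levels: int = 50
    quantized: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D series")

    @property
    def z(self) -> NDArray[np.float64]:
        """Normalised, mean-centred target (z-score; zeros if constant)."""
        sd = self.values.std()
        if sd == 0:
            return np.zeros_like(self.values)
        return (self.values - self.values.mean()) / sd

    @property
    def duration_s(self) -> int:
        return int(self.values.size)


@dataclass
class Recording:
    """Multichannel EEG voltage matrix (channels x samples, µV)."""

    data: NDArray[np.float64]
    fs: float
    channel_labels: tuple[str, ...]
    #: interior segment boundaries in samples (0-based, half-open): the
    #: recording is [0, marks[0]) = ride1, [marks[0], marks[1]) = break,
    #: [marks[1], n_samples) = ride2.  Empty for unsegmented data.
    segment_marks: tuple[int, ...] = ()
    cropped: bool = False

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        n = self.data.shape[1]
        marks = tuple(int(m) for m in self.segment_marks)
        if any(m <= 0 or m >= n for m in marks) or list(marks) != sorted(set(marks)):
            raise ValueError("segment_marks must be strictly increasing interior indices")
        self.segment_marks = marks

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def segments(self) -> list[tuple[int, int]]:
        """(start, stop) sample pairs of the ride/break/ride segments."""
        bounds = (0, *self.segment_marks, self.n_samples)
        return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]


@dataclass
class GroundTruth:
    """What the generator actually planted (for parameter-recovery tests)."""

    mixing_matrix: NDArray[np.float64]          # channels x sources
    arousal_source_index: int
    source_envelope: NDArray[np.float64]        # per-second amplitude factor
    coupling_kappa: float

    @property
    def alpha_pattern(self) -> NDArray[np.float64]:
        """Forward scalp projection of the arousal-coupled alpha source."""
        return self.mixing_matrix[:, self.arousal_source_index]

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["mixing_matrix"] = self.mixing_matrix.tolist()
        d["source_envelope"] = self.source_envelope.tolist()
        return json.dumps(d)


# ---------------------------------------------------------------------------
# rating trace


def _quantize(values: NDArray[np.float64], n_levels: int) -> NDArray[np.float64]:
    """Snap to the dial grid: ``n_levels`` steps spanning [0, 100]."""
    grid = np.linspace(0.0, 100.0, n_levels)
    idx = np.argmin(np.abs(values[:, None] - grid[None, :]), axis=1)
    return grid[idx]


def generate_arousal_trace(
    duration_s: int | None = None,
    n_levels: int = 50,
    phase_profile: PhaseProfile | None = None,
    seed: int | np.random.Generator = 0,
) -> RatingTrace:
    """Simulate a 1-Hz continuous arousal rating.

    A Gaussian-smoothed noise process (unit variance after smoothing, scaled
    by ``phase_profile.noise_sd``) rides on per-phase offsets; the result is
    clipped to [0, 100] and quantized to the dial grid.

    Parameters
    ----------
    duration_s
        Trace length in seconds; defaults to the phase profile's total.
        Must equal the profile total when both are given.
    """
    profile = phase_profile or PhaseProfile()
    if duration_s is None:
        duration_s = profile.duration_s
    duration_s = int(duration_s)
    if duration_s < 30:
        raise ValueError("duration_s must be at least 30 s")
    if n_levels < 2:
        raise ValueError("n_levels must be at least 2")
    if duration_s != profile.duration_s:
        raise ValueError(
            f"duration_s={duration_s} does not match phase profile total "
            f"{profile.duration_s}"
        )
    rng = np.random.default_rng(seed)

    noise = rng.standard_normal(duration_s)
    if profile.smooth_s > 0:
        noise = gaussian_filter1d(noise, sigma=profile.smooth_s, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise /= sd
    fluct = profile.noise_sd * noise

    offsets = np.concatenate(
        [np.full(int(round(d)), off) for d, off in profile.segments]
    )
    # soften the step edges a little so phase transitions are not instantaneous
    if profile.smooth_s > 0:
        offsets = gaussian_filter1d(offsets, sigma=min(profile.smooth_s, 3.0), mode="nearest")

    values = np.clip(offsets + fluct, 0.0, 100.0)
    return RatingTrace(values=_quantize(values, n_levels), n_levels=n_levels)


# ---------------------------------------------------------------------------
# sources and mixing


def _narrowband_noise(
    n: int, fs: float, peak_hz: float, rng: np.random.Generator, sigma_hz: float = 0.8
) -> NDArray[np.float64]:
    """Unit-variance narrowband noise with a Gaussian spectral bump.

    The amplitude spectrum is a Gaussian centred at ``peak_hz`` with width
    ``sigma_hz``, so essentially all power lies within peak ± 2 Hz and the
    spectral maximum sits at the nominal individual alpha peak.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec *= np.exp(-0.5 * ((f - peak_hz) / sigma_hz) ** 2)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _aperiodic_noise(n: int, slope: float, rng: np.random.Generator) -> NDArray[np.float64]:
    """Unit-variance 1/f^slope noise via FFT spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec *= f ** (-slope / 2.0)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _smooth_channel_weights(
    n_channels: int,
    rng: np.random.Generator,
    emphasis: NDArray[np.float64] | None = None,
) -> NDArray[np.float64]:
    """Random spatial pattern, smoothed across the channel ordering.

    Neighbouring channels in the montage list are spatially close, so
    smoothing across the index yields plausibly blurred scalp projections
    without a lead-field model.
    """
    w = gaussian_filter1d(rng.standard_normal(n_channels), sigma=2.0, mode="nearest")
    if emphasis is not None:
        w = w * emphasis
    norm = np.linalg.norm(w)
    if norm < 1e-12:  # pathologically unlucky draw
        w = np.ones(n_channels)
        norm = np.linalg.norm(w)
    return w / norm


def generate_subject(config: SynthConfig) -> tuple[Recording, RatingTrace, GroundTruth]:
    """Generate one synthetic subject: recording, ratings and ground truth.

    The arousal source is narrowband noise in ``alpha_peak_hz`` ± 2 Hz whose
    instantaneous amplitude scales as ``1 - coupling_kappa * z01(t)`` with
    ``z01`` the min-max-normalised arousal trace: maximal arousal suppresses
    the source to a fraction ``1 - coupling_kappa`` of its baseline
    amplitude.  Generation is bit-reproducible from ``config``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    r1, br, r2 = config.segment_lengths_s
    profile = PhaseProfile(
        segments=((r1, 45.0), (br, 15.0), (r2, 65.0)),
        smooth_s=config.rating_smooth_s,
    )
    trace = generate_arousal_trace(
        config.duration_s, phase_profile=profile, seed=rng
    )

    span = trace.values.max() - trace.values.min()
    z01 = (
        (trace.values - trace.values.min()) / span
        if span > 0
        else np.full(trace.values.size, 0.5)
    )
    envelope_1hz = 1.0 - config.coupling_kappa * z01

    sources = []
    for k in range(config.n_alpha_sources):
        s = _narrowband_noise(n, config.fs, config.alpha_peak_hz, rng)
        if k == 0:
            env = np.repeat(envelope_1hz, int(round(config.fs)))[:n]
            # smooth the per-second steps so the envelope is physiological
            env = gaussian_filter1d(env, sigma=config.fs / 8.0, mode="nearest")
            s = s * env
        sources.append(config.alpha_source_amp * s)
    for _ in range(config.n_background_sources):
        sources.append(
            config.background_amp
            * _aperiodic_noise(n, config.aperiodic_slope, rng)
        )
    S = np.vstack(sources)

    emphasis = None
    if config.parieto_occipital_bias:
        labels = CHANNELS_30[: config.n_channels] if config.n_channels <= 30 else tuple(
            f"ch{i}" for i in range(config.n_channels)
        )
        emphasis = np.array(
            [3.0 if ch in _PARIETO_OCCIPITAL else 1.0 for ch in labels]
        )
    cols = []
    for k in range(S.shape[0]):
        is_alpha = k < config.n_alpha_sources
        cols.append(
            _smooth_channel_weights(
                config.n_channels, rng, emphasis if is_alpha else None
            )
        )
    M = np.column_stack(cols)

    data = M @ S + config.sensor_noise_sd * rng.standard_normal((config.n_channels, n))

    labels = (
        CHANNELS_30[: config.n_channels]
        if config.n_channels <= 30
        else tuple(f"ch{i}" for i in range(config.n_channels))
    )
    fs_i = int(round(config.fs))
    marks = (int(round(r1)) * fs_i, int(round(r1 + br)) * fs_i)
    rec = Recording(
        data=data,
        fs=config.fs,
        channel_labels=labels,
        segment_marks=marks,
        cropped=True,
    )
    gt = GroundTruth(
        mixing_matrix=M,
        arousal_source_index=0,
        source_envelope=envelope_1hz,
        coupling_kappa=config.coupling_kappa,
    )
    return rec, trace, gt


def pattern_similarity(a: NDArray[np.float64], b: NDArray[np.float64]) -> float:
    """Cosine similarity between two spatial patterns (scale-invariant).

    Spatial filters/patterns are defined up to sign and scale, so |cosine|
    close to 1 means the same scalp topography was recovered.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("patterns must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm pattern has no direction")
    return float(np.dot(a, b) / (na * nb))
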