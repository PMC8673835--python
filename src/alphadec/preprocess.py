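"""Deterministic data conditioning.

Cropping of the experience, 1-Hz resampling of the dial ratings, the
100-µV epoch screen and the subject-exclusion rule, 1-s epoching aligned to
the rating seconds, and the rank-based tertile split into low / mid / high
arousal classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

from .synth import RatingTrace, Recording

logger = logging.getLogger(__name__)

__all__ = [
    "EpochedData",
    "LabelSet",
    "EOG_PROXY_CHANNELS",
    "crop_experience",
    "resample_ratings",
    "screen_epochs",
    "exclude_subject",
    "epoch",
    "tertile_labels",
]

#: Frontal channels dominated by eye activity, ignored by the voltage screen.
EOG_PROXY_CHANNELS = ("Fp1", "Fp2", "F7", "F8")

LOW, MID, HIGH = 0, 1, 2


@dataclass
class EpochedData:
    """Consecutive, non-overlapping 1-s epochs: epochs x samples x channels."""

    tensor: NDArray[np.float64]
    fs: float
    epoch_length_s: float = 1.0

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        if self.tensor.ndim != 3:
            raise ValueError("tensor must be epochs x samples x channels")
        expected = int(round(self.fs * self.epoch_length_s))
        if self.tensor.shape[1] != expected:
            raise ValueError(
                f"samples per epoch {self.tensor.shape[1]} != fs*epoch_length "
                f"({expected})"
            )

    @property
    def n_epochs(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[2]


@dataclass
class LabelSet:
    """Per-epoch tertile classes (0=low, 1=mid, 2=high) and the cut ranks."""

    classes: NDArray[np.int_]
    boundaries: tuple[int, int]

    @property
    def binary_mask(self) -> NDArray[np.bool_]:
        """Epochs retained for binary decoding (mid tertile discarded)."""
        return self.classes != MID

    @property
    def binary_labels(self) -> NDArray[np.int_]:
        """-1 (low) / +1 (high) over the retained epochs, chronological."""
        kept = self.classes[self.binary_mask]
        return np.where(kept == HIGH, 1, -1)


def crop_experience(
    rec: Recording,
    include_break: bool = True,
    ride_margin_s: float = 2.5,
    break_keep_s: float = 30.0,
) -> Recording:
    """Crop to the analysed experience.

    Raw recordings have three segments (ride / break / ride): the first and
    last ``ride_margin_s`` of each ride are removed (on/offset effects) and
    the inter-individually variable break is trimmed to its first
    ``break_keep_s`` seconds.  Already-cropped recordings pass through
    unchanged apart from optional break removal, so the operation is
    idempotent.  ``include_break=False`` drops the break entirely (the
    rides-only control analysis).
    """
    segs = rec.segments()
    if len(segs) != 3:
        raise ValueError("recording must carry ride/break/ride segment marks")

    fs = rec.fs
    margin = 0 if rec.cropped else int(round(ride_margin_s * fs))
    keep = int(round(break_keep_s * fs))

    (a0, a1), (b0, b1), (c0, c1) = segs
    if (a1 - a0) <= 2 * margin or (c1 - c0) <= 2 * margin:
        raise ValueError("ride segment too short to crop margins from")
    if not rec.cropped and (b1 - b0) < keep:
        raise ValueError("break shorter than the requested cropped length")

    ride1 = rec.data[:, a0 + margin : a1 - margin]
    brk = rec.data[:, b0:b1] if rec.cropped else rec.data[:, b0 : b0 + keep]
    ride2 = rec.data[:, c0 + margin : c1 - margin]

    if include_break:
        parts = [ride1, brk, ride2]
        marks = (ride1.shape[1], ride1.shape[1] + brk.shape[1])
    else:
        parts = [ride1, ride2]
        marks = (ride1.shape[1],)
    return Recording(
        data=np.concatenate(parts, axis=1),
        fs=fs,
        channel_labels=rec.channel_labels,
        segment_marks=marks,
        cropped=True,
    )


def resample_ratings(raw: NDArray[np.float64], fs_in: float = 50.0) -> RatingTrace:
    """Resample a 50-Hz dial trace to 1 Hz by averaging non-overlapping
    one-second windows; a trailing partial window is dropped (logged)."""
    raw = np.asarray(raw, dtype=float).ravel()
    if raw.size == 0:
        raise ValueError("empty rating series")
    win = int(round(fs_in))
    n_sec = raw.size // win
    if n_sec == 0:
        raise ValueError("rating series shorter than one second")
    if raw.size % win:
        logger.info("dropping trailing partial window of %d samples", raw.size % win)
    values = raw[: n_sec * win].reshape(n_sec, win).mean(axis=1)
    return RatingTrace(values=values, quantized=False)


def screen_epochs(
    rec: Recording,
    threshold_uv: float = 100.0,
    excluded_channels: tuple[str, ...] = EOG_PROXY_CHANNELS,
) -> NDArray[np.int_]:
    """Indices of 1-s epochs whose |voltage| strictly exceeds ``threshold_uv``
    in any channel not on the exclusion list (eye-movement-dominated
    frontal channels are ignored)."""
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    unknown = set(excluded_channels) - set(rec.channel_labels)
    if unknown:
        raise ValueError(f"unknown excluded channel label(s): {sorted(unknown)}")
    keep = [i for i, ch in enumerate(rec.channel_labels) if ch not in excluded_channels]
    spe = int(round(rec.fs))
    n_ep = rec.n_samples // spe
    x = np.abs(rec.data[keep, : n_ep * spe]).reshape(len(keep), n_ep, spe)
    bad = x.max(axis=(0, 2)) > threshold_uv
    return np.flatnonzero(bad)


def exclude_subject(n_bad_epochs: int, max_bad: int = 90) -> bool:
    """True iff the subject is discarded: strictly more than ``max_bad``
    (one third of 270) epochs flagged by the voltage screen."""
    if n_bad_epochs < 0:
        raise ValueError("n_bad_epochs must be non-negative")
    return n_bad_epochs > max_bad


def epoch(
    data: Recording | NDArray[np.float64],
    fs: float | None = None,
    epoch_length_s: float = 1.0,
) -> EpochedData:
    """Cut a recording (channels x samples) into consecutive non-overlapping
    epochs (epochs x samples x channels).  Epoch k covers second k of the
    recording and is therefore aligned with rating sample k.  A trailing
    remainder shorter than one epoch is dropped (logged)."""
    if isinstance(data, Recording):
        arr, fs = data.data, data.fs
    else:
        arr = np.atleast_2d(np.asarray(data, dtype=float))
        if fs is None:
            raise ValueError("fs required when passing a bare array")
    spe = int(round(fs * epoch_length_s))
    if spe <= 0:
        raise ValueError("epoch length must be positive")
    n = arr.shape[1]
    if spe > n:
        raise ValueError("epoch length exceeds recording duration")
    n_ep = n // spe
    if n % spe:
        logger.info("dropping trailing remainder of %d samples", n % spe)
    tensor = (
        arr[:, : n_ep * spe].reshape(arr.shape[0], n_ep, spe).transpose(1, 2, 0)
    )
    return EpochedData(tensor=tensor, fs=fs, epoch_length_s=epoch_length_s)


def tertile_labels(trace: RatingTrace | NDArray[np.float64]) -> LabelSet:
    """Rank-based tertile split of the per-second ratings.

    The n epochs are sorted by rating (stable sort, so ties resolve to the
    earlier epoch getting the lower rank) and split into three contiguous
    rank groups whose sizes differ by at most one; 270 epochs yield exactly
    90 per class.  The mid class is marked for discarding by the binary
    decoders.
    """
    values = trace.values if isinstance(trace, RatingTrace) else np.asarray(trace, float)
    n = values.size
    if n < 3:
        raise ValueError("need at least 3 epochs for a tertile split")
    if np.ptp(values) == 0:
        raise ValueError("constant rating trace: tertile split is degenerate")
    order = np.argsort(values, kind="stable")
    sizes = [len(part) for part in np.array_split(np.arange(n), 3)]
    classes = np.empty(n, dtype=int)
    classes[order[: sizes[0]]] = LOW
    classes[order[sizes[0] : sizes[0] + sizes[1]]] = MID
    classes[order[sizes[0] + sizes[1] :]] = HIGH
    return LabelSet(classes=classes, boundaries=(sizes[0], sizes[0] + sizes[1]))
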