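"""Zero-phase Butterworth denoising and 10-s snippet extraction.

Two fixed bands are used throughout: a 1-47 Hz broadband denoising filter
(retains most EEG content while rejecting drift and mains interference) and
a 3-8 Hz band isolating slow-wave activity, which often carries the
transition out of postictal suppression. Both are 5th-order Butterworth
prototypes applied forward-backward (zero phase), so the effective magnitude
response is the square of the single-pass response and events are not
delayed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np
import scipy.signal

from .errors import ArgumentError
from .signal_io import CANONICAL_CHANNELS, Recording

#: Snippet duration in seconds — the maximum acceptable detection latency.
SNIPPET_DURATION_S = 10.0
#: Working sampling rate in Hz.
TARGET_FS = 200.0

#: (low, high, order) of the broadband denoising filter.
DENOISE_BAND = (1.0, 47.0, 5)
#: (low, high, order) of the slow-wave band.
LOWFREQ_BAND = (3.0, 8.0, 5)


@dataclass(frozen=True)
class FilterSpec:
    """A Butterworth bandpass definition (applied forward-backward)."""

    band_low: float
    band_high: float
    order: int = 5
    family: str = "butterworth"

    def sos(self, fs: float) -> np.ndarray:
        """Second-order sections for sampling rate ``fs``."""
        if not (0.0 < self.band_low < self.band_high < fs / 2.0):
            raise ArgumentError(
                f"band ({self.band_low}, {self.band_high}) Hz invalid for fs={fs}"
            )
        return scipy.signal.butter(
            self.order, (self.band_low, self.band_high), btype="bandpass",
            fs=fs, output="sos",
        )


def design_bandpass(band_low: float, band_high: float, order: int = 5,
                    fs: float = TARGET_FS) -> FilterSpec:
    """Design a Butterworth bandpass; validates the edges against ``fs``."""
    if order < 1:
        raise ArgumentError("filter order must be >= 1")
    spec = FilterSpec(band_low=band_low, band_high=band_high, order=order)
    spec.sos(fs)  # validate edges now rather than at application time
    return spec


def filter_zero_phase(x: np.ndarray, spec: FilterSpec, fs: float = TARGET_FS) -> np.ndarray:
    """Forward-backward (zero-phase) filtering of one or more series.

    Accepts a 1-D series or a (channels x time) array; filtering is along the
    last axis with odd-extension edge padding.
    """
    x = np.asarray(x, dtype=float)
    sos = spec.sos(fs)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[-1] <= padlen:
        raise ArgumentError(
            f"series of length {x.shape[-1]} too short for edge padding ({padlen})"
        )
    return scipy.signal.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


@dataclass
class Snippet:
    """A fixed-duration, multi-channel EEG window — the unit of classification.

    ``label`` is True when the window contains the annotated end of PGES.
    """

    samples: np.ndarray
    fs: float
    label: Optional[bool] = None
    patient_id: str = ""
    start_s: float = 0.0
    channel_names: Tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.samples.ndim != 2:
            raise ArgumentError("snippet samples must be channels x time")
        if self.samples.shape[0] != len(self.channel_names):
            raise ArgumentError(
                f"{self.samples.shape[0]} rows for {len(self.channel_names)} channel names"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def is_canonical(self) -> bool:
        """True for the standard 10-channel, 10-s, 200 Hz snippet."""
        return (
            self.channel_names == CANONICAL_CHANNELS
            and self.fs == TARGET_FS
            and self.samples.shape[1] == int(SNIPPET_DURATION_S * TARGET_FS)
        )


def denoise_snippet(s: Snippet) -> Snippet:
    """Apply the 1-47 Hz zero-phase filter to every channel."""
    spec = FilterSpec(*DENOISE_BAND[:2], order=DENOISE_BAND[2])
    return replace(s, samples=filter_zero_phase(s.samples, spec, s.fs))


def lowfreq_snippet(s: Snippet) -> Snippet:
    """Apply the 3-8 Hz (slow-wave) zero-phase filter to every channel."""
    spec = FilterSpec(*LOWFREQ_BAND[:2], order=LOWFREQ_BAND[2])
    return replace(s, samples=filter_zero_phase(s.samples, spec, s.fs))


def snippet_is_positive(start_s: float, pges_end_s: Optional[float],
                        duration_s: float = SNIPPET_DURATION_S) -> bool:
    """A window is positive iff it strictly contains the annotation.

    The open interval breaks the boundary tie deterministically: a transition
    exactly at a window edge is not usably "contained" and counts negative.
    """
    if pges_end_s is None:
        return False
    return start_s < pges_end_s < start_s + duration_s


def extract_snippets(rec: Recording, n_per_class: int, rng_seed: int) -> List[Snippet]:
    """Cut up to ``n_per_class`` positive and negative 10-s windows from ``rec``.

    Window starts lie on the sample grid and are drawn uniformly without
    replacement within each class, so repeated calls with the same seed give
    identical snippets. Recordings without an annotation yield only
    negatives; recordings shorter than 10 s yield an empty list with a
    warning.
    """
    if rec.fs != TARGET_FS:
        raise ArgumentError(f"recording must be at {TARGET_FS:g} Hz, got {rec.fs:g}")
    win = int(round(SNIPPET_DURATION_S * rec.fs))
    n_starts = rec.n_samples - win + 1
    if n_starts <= 0:
        warnings.warn(
            f"recording {rec.patient_id!r} shorter than {SNIPPET_DURATION_S:g} s; "
            "no snippets extracted",
            stacklevel=2,
        )
        return []
    starts = np.arange(n_starts)
    start_times = starts / rec.fs
    positive = np.array([
        snippet_is_positive(t, rec.pges_end_s) for t in start_times
    ])
    rng = np.random.default_rng(rng_seed)
    chosen: List[int] = []
    labels: List[bool] = []
    for label, pool in ((True, starts[positive]), (False, starts[~positive])):
        k = min(n_per_class, pool.size)
        if k > 0:
            picked = rng.choice(pool, size=k, replace=False)
            chosen.extend(int(p) for p in np.sort(picked))
            labels.extend([label] * k)
    out = []
    for start, label in zip(chosen, labels):
        out.append(Snippet(
            samples=rec.samples[:, start:start + win].copy(),
            fs=rec.fs,
            label=label,
            patient_id=rec.patient_id,
            start_s=start / rec.fs,
            channel_names=rec.channel_names,
        ))
    return out
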