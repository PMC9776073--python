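"""Segmentation, frequency-band decomposition and label binarization.

Multichannel recordings (channels x samples) are cut into overlapping
analysis windows, each window is decomposed into the four classical EEG
rhythm bands (theta 4-8, alpha 8-12, beta 12-30, gamma 30-45 Hz), and
ordinal affect ratings on the 1-9 scale are mapped to discrete class
labels by thresholding at the scale midpoint 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

#: Band name -> (low, high) edge in Hz.  gamma includes its upper edge so the
#: four bands exactly tile the 4-45 Hz analysis range.
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 45.0),
}

BAND_NAMES: tuple[str, ...] = tuple(BANDS)

#: Four-quadrant arousal/valence class ids, low/high encoded by threshold 5.
VA_CLASSES: tuple[str, ...] = ("LALV", "HALV", "LAHV", "HAHV")


class PreprocessError(ValueError):
    """Raised for invalid segmentation or decomposition requests."""


@dataclass
class Recording:
    """One multichannel trial.

    Parameters
    ----------
    data : ndarray, shape (channels, samples)
        Signal in its native units.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
    ratings : dict
        Ordinal self-report scores, keys ``"arousal"`` and ``"valence"``,
        each in [1, 9].
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    ratings: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PreprocessError("data must be channels x samples")
        if self.fs <= 0:
            raise PreprocessError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise PreprocessError("data contains non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        for key, val in self.ratings.items():
            if not (1.0 <= val <= 9.0):
                raise PreprocessError(f"rating {key}={val} outside [1, 9]")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.data.shape[1] / self.fs


@dataclass
class BandSegment:
    """One analysis window decomposed into the four rhythm bands.

    ``band_data`` has shape (4, channels, window_samples), ordered as
    :data:`BAND_NAMES`.
    """

    band_data: np.ndarray
    band_ids: tuple[str, ...] = BAND_NAMES
    window_index: int = 0
    label: int | None = None
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.band_data = np.asarray(self.band_data, dtype=float)
        if self.band_data.ndim != 3 or self.band_data.shape[0] != len(self.band_ids):
            raise PreprocessError("band_data must be (n_bands, channels, samples)")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def segment(recording: Recording, tw: float = 3.0, to: float = 1.5) -> list[np.ndarray]:
    """Cut a trial into overlapping windows.

    A trial of duration ``D`` seconds yields ``floor((D - tw)/to) + 1``
    windows of ``tw`` seconds, consecutive windows advancing by ``to``
    seconds; the defaults (3 s window, 1.5 s advance, i.e. 50 % overlap)
    give 39 windows for a 60 s trial.

    Returns
    -------
    list of ndarray
        Each of shape (channels, round(tw * fs)).
    """
    dur = recording.duration
    if to <= 0:
        raise PreprocessError("overlap step To must be positive")
    if tw <= 0:
        raise PreprocessError("window length Tw must be positive")
    if to > tw:
        raise PreprocessError("overlap step To must not exceed window length Tw")
    if tw > dur + 1e-9:
        raise PreprocessError(f"window length {tw} s exceeds trial duration {dur} s")
    n_windows = int(np.floor((dur - tw) / to + 1e-9)) + 1
    win_len = _round_half_up(tw * recording.fs)
    out = []
    for i in range(n_windows):
        start = _round_half_up(i * to * recording.fs)
        out.append(recording.data[:, start : start + win_len])
    return out


def _stft_band_filter(window: np.ndarray, fs: float, bands: dict[str, tuple[float, float]]) -> np.ndarray:
    """Band-split via STFT bin masking with a 1 s Hann window, 50 % hop."""
    n = window.shape[-1]
    nperseg = min(int(round(fs)), n)
    hop = max(nperseg // 2, 1)
    sft = signal.ShortTimeFFT(
        signal.windows.hann(nperseg, sym=False), hop=hop, fs=fs, fft_mode="onesided"
    )
    spec = sft.stft(window)  # (..., freq, frames)
    freqs = sft.f
    names = list(bands)
    out = np.empty((len(names),) + window.shape, dtype=float)
    for bi, name in enumerate(names):
        low, high = bands[name]
        if name == "gamma" or high >= max(e[1] for e in bands.values()):
            mask = (freqs >= low) & (freqs <= high)
        else:
            mask = (freqs >= low) & (freqs < high)
        masked = spec * mask[:, None]
        out[bi] = sft.istft(masked, k1=n)[..., :n]
    return out


def _butter_band_filter(window: np.ndarray, fs: float, bands: dict[str, tuple[float, float]]) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-split (config alternative)."""
    names = list(bands)
    out = np.empty((len(names),) + window.shape, dtype=float)
    for bi, name in enumerate(names):
        low, high = bands[name]
        sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
        out[bi] = signal.sosfiltfilt(sos, window, axis=-1)
    return out


def band_decompose(
    window: np.ndarray,
    fs: float,
    method: str = "stft",
    bands: dict[str, tuple[float, float]] | None = None,
    window_index: int = 0,
    label: int | None = None,
    channel_names: list[str] | None = None,
) -> BandSegment:
    """Decompose one window into band-limited time-domain signals.

    The default method computes a short-time Fourier transform (1 s Hann
    window, 50 % hop), zeroes all bins outside each band, and inverts;
    ``method="butter"`` uses a zero-phase 4th-order Butterworth bandpass
    instead.  Each band signal has the same length as the input.

    Raises
    ------
    PreprocessError
        If ``fs`` is too low to resolve a requested band (the sampling
        rate must be at least twice the band's upper edge).
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    if not np.all(np.isfinite(window)):
        raise PreprocessError("window contains non-finite values")
    bands = dict(bands or BANDS)
    for name, (low, high) in bands.items():
        if fs < 2 * high:
            raise PreprocessError(
                f"fs={fs} Hz cannot resolve band '{name}' up to {high} Hz "
                f"(needs fs >= {2 * high} Hz)"
            )
        if not (0 < low < high):
            raise PreprocessError(f"invalid edges for band '{name}': ({low}, {high})")
    if method == "stft":
        band_data = _stft_band_filter(window, fs, bands)
    elif method == "butter":
        band_data = _butter_band_filter(window, fs, bands)
    else:
        raise PreprocessError(f"unknown decomposition method '{method}'")
    return BandSegment(
        band_data=band_data,
        band_ids=tuple(bands),
        window_index=window_index,
        label=label,
        channel_names=list(channel_names or []),
    )


def binarize_labels(
    arousal: float | None = None,
    valence: float | None = None,
    task: str = "arousal",
) -> int:
    """Map 1-9 ratings to class ids by thresholding at the midpoint 5.

    Ratings strictly above 5 are "high"; ratings at or below 5 are "low".
    Binary tasks return 0 (low) or 1 (high).  The four-quadrant
    arousal-valence task (``task="va"``) returns the index into
    :data:`VA_CLASSES`: LALV=0, HALV=1, LAHV=2, HAHV=3.
    """
    task = task.lower()

    def _check(name: str, r: float | None) -> float:
        if r is None:
            raise PreprocessError(f"task '{task}' requires a {name} rating")
        if not (1.0 <= r <= 9.0):
            raise PreprocessError(f"{name} rating {r} outside [1, 9]")
        return r

    if task == "arousal":
        return int(_check("arousal", arousal) > 5.0)
    if task == "valence":
        return int(_check("valence", valence) > 5.0)
    if task == "va":
        hi_a = _check("arousal", arousal) > 5.0
        hi_v = _check("valence", valence) > 5.0
        return int(hi_a) + 2 * int(hi_v)
    raise PreprocessError(f"unknown task '{task}'")


def bandpass_4_45(recording: Recording, low: float = 4.0, high: float = 45.0) -> Recording:
    """Optional pipeline stage: zero-phase 4-45 Hz analysis bandpass."""
    sos = signal.butter(4, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    data = signal.sosfiltfilt(sos, recording.data, axis=-1)
    return Recording(data, recording.fs, list(recording.channel_names), dict(recording.ratings))


def remove_baseline(recording: Recording, baseline_seconds: float = 3.0) -> Recording:
    """Optional pipeline stage: drop the leading pre-stimulus baseline."""
    n = _round_half_up(baseline_seconds * recording.fs)
    if n >= recording.data.shape[1]:
        raise PreprocessError("baseline longer than the trial")
    return Recording(
        recording.data[:, n:], recording.fs, list(recording.channel_names), dict(recording.ratings)
    )


def downsample(recording: Recording, fs_target: float = 128.0) -> Recording:
    """Optional pipeline stage: polyphase resampling to ``fs_target``."""
    from fractions import Fraction

    frac = Fraction(fs_target / recording.fs).limit_denominator(1000)
    data = signal.resample_poly(recording.data, frac.numerator, frac.denominator, axis=-1)
    return Recording(data, fs_target, list(recording.channel_names), dict(recording.ratings))
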