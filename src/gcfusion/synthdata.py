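"""Synthetic multichannel recordings with planted causal structure.

Each trial is a realization of a stable vector-autoregressive (VAR)
process whose off-diagonal coefficients encode the planted directed
couplings, summed with band-limited oscillations (filtered white noise
per rhythm band).  Class membership modulates the variance of one band's
oscillation on a chosen channel subset, so both the causal graph and the
discriminative band are known exactly downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .io import write_array_container
from .preprocess import BANDS, BAND_NAMES, Recording


class UnstableVARError(ValueError):
    """Raised when the requested coupling coefficients give a non-stationary VAR."""


@dataclass
class SynthSpec:
    """Parameters of the synthetic study.

    Defaults emulate the benchmark recording geometry: 32 channels
    sampled at 128 Hz, 60 s trials, affect ratings on the 1-9 scale.

    Parameters
    ----------
    coupling_edges : list of (source, target, lag, coefficient)
        Directed VAR couplings; lag in samples (>= 1).
    band_effects : dict class -> (band, channels, variance multiplier)
        Trials of the given class have that band's oscillation variance
        scaled by the multiplier on the listed channels.
    classes : "binary" or "quad"
        Two classes rated on arousal only, or the four arousal/valence
        quadrants.
    ar_coef : float
        Per-channel lag-1 self-coefficient giving realistic temporal
        autocorrelation.
    osc_sd : float
        Standard deviation of each band-limited oscillation before any
        class multiplier.
    noise_sd : float
        Innovation standard deviation of the VAR component.
    """

    n_channels: int = 32
    fs: float = 128.0
    trial_seconds: float = 60.0
    n_trials: int = 40
    classes: str = "binary"
    coupling_edges: list[tuple[int, int, int, float]] = field(default_factory=list)
    band_effects: dict[int, tuple[str, tuple[int, ...], float]] = field(default_factory=dict)
    ar_coef: float = 0.45
    osc_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes not in {"binary", "quad"}:
            raise ValueError("classes must be 'binary' or 'quad'")
        for src, tgt, lag, _ in self.coupling_edges:
            for idx in (src, tgt):
                if not (0 <= idx < self.n_channels):
                    raise ValueError(f"channel index {idx} out of range (N={self.n_channels})")
            if lag < 1:
                raise ValueError("coupling lag must be >= 1 sample")
        for cls, (band, chans, mult) in self.band_effects.items():
            if band not in BANDS:
                raise ValueError(f"unknown band '{band}' in band_effects")
            if mult <= 0:
                raise ValueError("variance multiplier must be positive")
            for c in chans:
                if not (0 <= c < self.n_channels):
                    raise ValueError(f"band_effects channel {c} out of range")
        radius = self._spectral_radius()
        if radius >= 1.0:
            raise UnstableVARError(
                f"coupling spec yields an unstable VAR: companion spectral radius "
                f"{radius:.4f} >= 1"
            )

    @property
    def max_lag(self) -> int:
        return max([1] + [lag for _, _, lag, _ in self.coupling_edges])

    def var_coefficients(self) -> np.ndarray:
        """Stacked VAR coefficient matrices, shape (max_lag, N, N)."""
        P, N = self.max_lag, self.n_channels
        A = np.zeros((P, N, N))
        A[0][np.diag_indices(N)] = self.ar_coef
        for src, tgt, lag, coef in self.coupling_edges:
            A[lag - 1, tgt, src] += coef
        return A

    def _spectral_radius(self) -> float:
        P, N = self.max_lag, self.n_channels
        A = self.var_coefficients()
        companion = np.zeros((N * P, N * P))
        companion[:N] = A.transpose(1, 0, 2).reshape(N, N * P)
        if P > 1:
            companion[N:, : N * (P - 1)] = np.eye(N * (P - 1))
        return float(np.max(np.abs(np.linalg.eigvals(companion))))

    @property
    def n_classes(self) -> int:
        return 2 if self.classes == "binary" else 4


@dataclass
class GroundTruth:
    """What the generator planted: the directed graph, the informative band
    and the per-trial class labels."""

    true_adjacency: dict[str, np.ndarray]
    informative_band: str | None
    class_labels: np.ndarray


#: Ratings emitted for low/high classes; 3 and 7 sit well clear of the
#: binarization threshold at 5.
_LOW, _HIGH = 3.0, 7.0
_QUAD_RATINGS = {0: (_LOW, _LOW), 1: (_HIGH, _LOW), 2: (_LOW, _HIGH), 3: (_HIGH, _HIGH)}


def _simulate_var(spec: SynthSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    """One stable VAR realization, shape (N, n), burn-in discarded."""
    P, N = spec.max_lag, spec.n_channels
    A = spec.var_coefficients()
    burn = 200
    x = np.zeros((n + burn, N))
    eps = rng.normal(0.0, spec.noise_sd, size=(n + burn, N))
    for t in range(P, n + burn):
        acc = eps[t]
        for lag in range(P):
            acc = acc + A[lag] @ x[t - lag - 1]
        x[t] = acc
    return x[burn:].T


def _band_noise(
    rng: np.random.Generator, n_channels: int, n: int, fs: float, band: str
) -> np.ndarray:
    """Unit-variance band-limited noise, shape (channels, n)."""
    low, high = BANDS[band]
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    white = rng.normal(size=(n_channels, n + 2 * int(fs)))
    filt = signal.sosfiltfilt(sos, white, axis=-1)[:, int(fs) : int(fs) + n]
    sd = filt.std(axis=-1, keepdims=True)
    return filt / np.where(sd > 0, sd, 1.0)


def _trial_labels(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Balanced class assignment, shuffled deterministically."""
    C = spec.n_classes
    labels = np.arange(spec.n_trials) % C
    rng.shuffle(labels)
    return labels


def simulate_recordings(spec: SynthSpec) -> tuple[list[Recording], GroundTruth]:
    """Generate seeded trials with known causal and band-effect ground truth.

    Returns the trials plus a :class:`GroundTruth` whose per-band
    adjacency has ``A[target, source] = 1`` for every planted coupling
    (diagonal set to 1), whose ``informative_band`` is the band carrying a
    class effect (if any), and whose ``class_labels`` match what
    threshold-5 binarization of the emitted ratings reproduces.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.trial_seconds * spec.fs))
    N = spec.n_channels
    labels = _trial_labels(spec, rng)

    adjacency = np.eye(N)
    for src, tgt, _, _ in spec.coupling_edges:
        adjacency[tgt, src] = 1.0
    true_adj = {b: adjacency.copy() for b in BAND_NAMES}
    informative = next((b for b, _, _ in spec.band_effects.values()), None)

    recordings = []
    for trial, cls in enumerate(labels):
        data = _simulate_var(spec, rng, n)
        for band in BAND_NAMES:
            osc = _band_noise(rng, N, n, spec.fs, band) * spec.osc_sd
            effect = spec.band_effects.get(int(cls))
            if effect is not None and effect[0] == band:
                _, chans, mult = effect
                osc[list(chans)] *= np.sqrt(mult)
            data = data + osc
        if spec.classes == "binary":
            arousal = _HIGH if cls == 1 else _LOW
            valence = _LOW
        else:
            arousal, valence = _QUAD_RATINGS[int(cls)]
        recordings.append(
            Recording(
                data,
                spec.fs,
                [f"ch{i}" for i in range(N)],
                {"arousal": arousal, "valence": valence},
            )
        )
    truth = GroundTruth(true_adj, informative, labels.copy())
    return recordings, truth


def write_fixture(recordings: list[Recording], path: str | Path) -> Path:
    """Write trials to the array container; round-trips bit-exactly at float32."""
    return write_array_container(recordings, path)


def small_test_spec(**overrides) -> SynthSpec:
    """Compact default used by unit fixtures: 8 channels, 20 trials, 10 s."""
    params = dict(n_channels=8, fs=128.0, trial_seconds=10.0, n_trials=20, seed=0)
    params.update(overrides)
    return SynthSpec(**params)


def beta_band_study_spec(seed: int = 0) -> SynthSpec:
    """The reference synthetic study: 8 channels, 80 ten-second trials
    (400 segments at the default 3 s / 1.5 s windowing), two planted
    directed couplings, and a binary class effect that doubles the
    beta-band oscillation variance on channels 0-3 for the high class."""
    return SynthSpec(
        n_channels=8,
        fs=128.0,
        trial_seconds=10.0,
        n_trials=80,
        coupling_edges=[(0, 1, 1, 0.6), (2, 3, 2, 0.6)],
        band_effects={1: ("beta", (0, 1, 2, 3), 2.0)},
        seed=seed,
    )
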