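"""Differential-entropy node features.

Band-limited EEG amplitudes over a short window are well approximated as
Gaussian, for which the differential entropy has the closed form
h = 1/2 * ln(2*pi*e*sigma^2) nats.  One such scalar per (band, channel)
forms the node-value vector of each graph sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import BandSegment


class FeatureError(ValueError):
    pass


def differential_entropy(x: np.ndarray, on_constant: str = "raise") -> float:
    """Differential entropy of a band-limited window under the Gaussian model.

    Returns ``0.5 * ln(2*pi*e * var(x))`` in nats, with the unbiased
    (n-1 denominator) sample variance.  Invariant under translation;
    scaling the window by c adds ln|c|.

    Parameters
    ----------
    on_constant : "raise" or "neginf"
        Behaviour for a constant window (zero variance).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 8:
        raise FeatureError("window too short: need >= 8 samples")
    if not np.all(np.isfinite(x)):
        raise FeatureError("window contains non-finite values")
    var = float(np.var(x, ddof=1))
    if var == 0.0:
        if on_constant == "neginf":
            return -np.inf
        raise FeatureError("constant window: differential entropy undefined (-inf)")
    return 0.5 * np.log(2.0 * np.pi * np.e * var)


def build_node_matrix(segment: BandSegment, on_constant: str = "raise") -> np.ndarray:
    """Per-band node-value vectors for one window.

    Returns an (n_bands, channels) array of differential entropies,
    channel order matching the segment's channel ordering.
    """
    bands, channels, _ = segment.band_data.shape
    out = np.empty((bands, channels))
    for b in range(bands):
        for c in range(channels):
            out[b, c] = differential_entropy(segment.band_data[b, c], on_constant)
    return out


@dataclass
class DEFeatures:
    """Differential-entropy features for a stream of windows.

    ``values`` has shape (segments, bands, channels); ``labels`` one class
    id per segment.
    """

    values: np.ndarray
    labels: np.ndarray
    band_ids: tuple[str, ...]
    channel_names: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a table with one (band, channel) column per feature."""
        S, B, C = self.values.shape
        cols = [f"{self.band_ids[b]}_{self.channel_names[c]}" for b in range(B) for c in range(C)]
        df = pd.DataFrame(self.values.reshape(S, B * C), columns=cols)
        df.insert(0, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def compute_de_features(segments: list[BandSegment], on_constant: str = "raise") -> DEFeatures:
    """Node matrices for every window, stacked."""
    if not segments:
        raise FeatureError("no segments given")
    values = np.stack([build_node_matrix(s, on_constant) for s in segments])
    labels = np.array([-1 if s.label is None else s.label for s in segments])
    names = segments[0].channel_names or [f"ch{i}" for i in range(values.shape[2])]
    return DEFeatures(values, labels, segments[0].band_ids, names)
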