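"""End-to-end assembly: recordings -> per-band graph samples.

Each trial is segmented, each window band-decomposed; differential
entropies give the node values, per-band Granger matrices binarized at
retention fraction k give the adjacencies, and ratings give the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as feat
from . import granger, preprocess


@dataclass
class PipelineConfig:
    """Windowing, decomposition and connectivity settings."""

    tw: float = 3.0
    to: float = 1.5
    k: float = 0.5
    task: str = "arousal"  # arousal | valence | va
    decompose_method: str = "stft"
    var: granger.VARConfig = field(default_factory=granger.VARConfig)
    per_trial_gc: bool = False
    bands: dict[str, tuple[float, float]] | None = None


@dataclass
class GraphDataset:
    """Per-band graph samples ready for the fusion classifier.

    node_values : (segments, bands, channels) differential entropies
    adjacency : (segments, bands, channels, channels) binary masks
    labels : (segments,) class ids
    """

    node_values: np.ndarray
    adjacency: np.ndarray
    labels: np.ndarray
    band_ids: tuple[str, ...] = preprocess.BAND_NAMES
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        S, B, N = self.node_values.shape
        if self.adjacency.shape != (S, B, N, N):
            raise ValueError("adjacency shape inconsistent with node_values")
        if len(self.labels) != S:
            raise ValueError("labels length inconsistent with node_values")

    def __len__(self) -> int:
        return self.node_values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.node_values.shape[1]

    @property
    def n_channels(self) -> int:
        return self.node_values.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def subset(self, idx: np.ndarray) -> "GraphDataset":
        return GraphDataset(
            self.node_values[idx],
            self.adjacency[idx],
            self.labels[idx],
            self.band_ids,
            list(self.channel_names),
        )


def build_graph_dataset(
    recordings: list[preprocess.Recording],
    config: PipelineConfig | None = None,
) -> GraphDataset:
    """Run segmentation, band split, DE features and GC adjacencies."""
    config = config or PipelineConfig()
    node_rows, adj_rows, labels = [], [], []
    bands = config.bands or preprocess.BANDS
    band_names = tuple(bands)
    for rec in recordings:
        label = preprocess.binarize_labels(
            rec.ratings.get("arousal"), rec.ratings.get("valence"), config.task
        )
        trial_adj = None
        if config.per_trial_gc:
            whole = preprocess.band_decompose(
                rec.data, rec.fs, config.decompose_method, bands
            )
            trial_adj = np.stack(
                [
                    granger.binarize(
                        granger.gc_matrix(whole.band_data[b], config.var, band=band_names[b]),
                        config.k,
                    ).mask
                    for b in range(len(band_names))
                ]
            )
        for wi, window in enumerate(preprocess.segment(rec, config.tw, config.to)):
            seg = preprocess.band_decompose(
                window,
                rec.fs,
                config.decompose_method,
                bands,
                window_index=wi,
                label=label,
                channel_names=rec.channel_names,
            )
            node_rows.append(feat.build_node_matrix(seg))
            if trial_adj is not None:
                adj_rows.append(trial_adj)
            else:
                adj_rows.append(
                    np.stack(
                        [
                            granger.binarize(
                                granger.gc_matrix(
                                    seg.band_data[b], config.var, band=band_names[b]
                                ),
                                config.k,
                            ).mask
                            for b in range(len(band_names))
                        ]
                    )
                )
            labels.append(label)
    return GraphDataset(
        np.stack(node_rows),
        np.stack(adj_rows).astype(float),
        np.asarray(labels),
        band_names,
        list(recordings[0].channel_names),
    )
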