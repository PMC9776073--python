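"""Readers and writers for the simple array container and EDF.

The array container stores one subject as ``<base>.bin`` — trials x
channels x samples, little-endian float32, C order — plus a JSON sidecar
``<base>.json`` with the sampling rate, channel names and per-trial
ratings.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import Recording


def _base(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix("") if path.suffix in {".bin", ".json"} else path


def write_array_container(recordings: list[Recording], path: str | Path) -> Path:
    """Write trials to ``<base>.bin`` + ``<base>.json``; returns the base path."""
    if not recordings:
        raise ValueError("cannot write an empty list of recordings")
    shapes = {r.data.shape for r in recordings}
    if len(shapes) > 1:
        raise ValueError(f"all trials must share one shape, got {sorted(shapes)}")
    fs = {r.fs for r in recordings}
    if len(fs) > 1:
        raise ValueError("all trials must share one sampling rate")
    base = _base(path)
    arr = np.stack([r.data for r in recordings]).astype("<f4")
    arr.tofile(base.with_suffix(".bin"))
    meta = {
        "fs": recordings[0].fs,
        "channel_names": recordings[0].channel_names,
        "shape": list(arr.shape),
        "dtype": "<f4",
        "ratings": [
            {k: float(v) for k, v in r.ratings.items()} for r in recordings
        ],
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return base


def read_array_container(path: str | Path) -> list[Recording]:
    """Read trials written by :func:`write_array_container`."""
    base = _base(path)
    meta = json.loads(base.with_suffix(".json").read_text())
    shape = tuple(meta["shape"])
    arr = np.fromfile(base.with_suffix(".bin"), dtype=meta.get("dtype", "<f4"))
    arr = arr.reshape(shape).astype(float)
    ratings = meta.get("ratings") or [{}] * shape[0]
    return [
        Recording(arr[i], meta["fs"], list(meta["channel_names"]), dict(ratings[i]))
        for i in range(shape[0])
    ]


def read_edf(path: str | Path, ratings: dict[str, float] | None = None) -> Recording:
    """Load an EDF file as a single Recording (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return Recording(raw.get_data(), raw.info["sfreq"], list(raw.ch_names), ratings or {})
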