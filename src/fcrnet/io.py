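"""HDF5 epoch container, standard-format ingestion, and pipeline config.

Container schema (version ``1.0``)::

    /                     attrs: schema_version, fs, n_channels
    /sessions/<name>/signals   [n_trials x n_channels x n_samples] float64
    /sessions/<name>/labels    [n_trials] int64
    /sessions/<name>           attrs: channel_names, class_names, trial_onset

All sessions in one file share the sampling rate and channel count.  Round
trips are lossless.  GDF/EDF/FIF ingestion delegates parsing to MNE and never
resamples: the sampling rate is read from the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml

from .simulate import EpochedRecording, SimulationConfig

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

__all__ = [
    "DatasetContainer", "PipelineConfig", "SchemaError",
    "write_container", "read_container", "import_recording",
    "load_pipeline_config",
]


class SchemaError(ValueError):
    """Container file does not match the documented schema."""


@dataclass
class DatasetContainer:
    """Named sessions sharing sampling rate and montage size."""

    sessions: dict                        # name -> EpochedRecording
    fs: float
    schema_version: str = SCHEMA_VERSION

    def validate(self) -> None:
        if not self.sessions:
            raise ValueError("container holds no sessions")
        n_ch = None
        for name, rec in self.sessions.items():
            rec.validate()
            if rec.fs != self.fs:
                raise ValueError(
                    f"session {name!r} fs {rec.fs} != container fs {self.fs}"
                )
            if n_ch is None:
                n_ch = rec.n_channels
            elif rec.n_channels != n_ch:
                raise ValueError("sessions differ in channel count")


def write_container(recordings, path) -> str:
    """Write one or more recordings; ``recordings`` is a dict name->recording
    or a single EpochedRecording (stored as ``session0``)."""
    if isinstance(recordings, EpochedRecording):
        recordings = {"session0": recordings}
    container = DatasetContainer(sessions=dict(recordings),
                                 fs=next(iter(recordings.values())).fs)
    container.validate()
    first = next(iter(container.sessions.values()))
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["fs"] = float(container.fs)
        f.attrs["n_channels"] = int(first.n_channels)
        grp = f.create_group("sessions")
        for name, rec in container.sessions.items():
            g = grp.create_group(name)
            g.create_dataset("signals", data=rec.signals)
            g.create_dataset("labels", data=rec.labels)
            g.attrs["channel_names"] = [str(c) for c in rec.channel_names]
            g.attrs["class_names"] = [str(c) for c in rec.class_names]
            g.attrs["trial_onset"] = float(rec.trial_onset)
    logger.info("wrote %d session(s) to %s", len(container.sessions), path)
    return str(path)


def _require(node, key, where):
    if key not in node:
        raise SchemaError(f"missing {key!r} in {where}")
    return node[key]


def _require_attr(node, key, where):
    if key not in node.attrs:
        raise SchemaError(f"missing attribute {key!r} in {where}")
    return node.attrs[key]


def read_container(path) -> DatasetContainer:
    """Read and re-validate a container; schema violations name the key."""
    with h5py.File(path, "r") as f:
        version = str(_require_attr(f, "schema_version", "file root"))
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"unknown schema version {version!r} (expected {SCHEMA_VERSION})"
            )
        fs = float(_require_attr(f, "fs", "file root"))
        sessions_grp = _require(f, "sessions", "file root")
        sessions = {}
        for name in sessions_grp:
            g = sessions_grp[name]
            where = f"session {name!r}"
            sessions[name] = EpochedRecording(
                signals=np.asarray(_require(g, "signals", where)),
                labels=np.asarray(_require(g, "labels", where)),
                fs=fs,
                channel_names=tuple(
                    str(c) for c in _require_attr(g, "channel_names", where)
                ),
                class_names=tuple(
                    str(c) for c in _require_attr(g, "class_names", where)
                ),
                trial_onset=float(_require_attr(g, "trial_onset", where)),
            )
    container = DatasetContainer(sessions=sessions, fs=fs,
                                 schema_version=version)
    container.validate()
    return container


def import_recording(path, format: str = "auto",
                     epoch_window: tuple = (0.0, 4.0),
                     channels=None) -> EpochedRecording:
    """Epoch a continuous GDF/EDF/FIF recording around its event markers.

    Epochs are cut at ``[onset + start, onset + end)`` seconds (half-open;
    sample count ``round((end-start)*fs)``); event codes are mapped to labels
    ``0..K-1`` in sorted-code order.  Parsing is delegated to MNE; the
    sampling rate comes from the file and is never changed silently.
    """
    import mne  # optional dependency, needed only for this entry point

    readers = {
        "gdf": mne.io.read_raw_gdf,
        "edf": mne.io.read_raw_edf,
        "fif": mne.io.read_raw_fif,
    }
    fmt = format
    if fmt == "auto":
        suffix = str(path).rsplit(".", 1)[-1].lower()
        fmt = suffix if suffix in readers else None
        if fmt is None:
            raise ValueError(f"cannot infer format of {path!r}")
    if fmt not in readers:
        raise ValueError(f"unsupported format {fmt!r}")
    raw = readers[fmt](path, preload=True, verbose="error")
    if channels is not None:
        raw.pick(list(channels))
    fs = float(raw.info["sfreq"])
    events, event_id = _events_from_raw(raw)
    if len(events) == 0:
        raise ValueError(f"no events/annotations found in {path!r}")
    start, end = epoch_window
    n_samples = int(round((end - start) * fs))
    data = raw.get_data()
    n_total = data.shape[1]
    codes = sorted(event_id.values())
    code_to_label = {c: i for i, c in enumerate(codes)}
    epochs, labels = [], []
    for onset_sample, _, code in events:
        i0 = onset_sample + int(round(start * fs))
        i1 = i0 + n_samples
        if i0 < 0 or i1 > n_total:
            raise IndexError(
                f"window ({start}, {end}) s around sample {onset_sample} "
                f"exceeds the record ({n_total} samples)"
            )
        epochs.append(data[:, i0:i1])
        labels.append(code_to_label[code])
    return EpochedRecording(
        signals=np.stack(epochs),
        labels=np.array(labels, dtype=np.int64),
        fs=fs,
        channel_names=tuple(raw.ch_names),
        class_names=tuple(str(c) for c in codes),
        trial_onset=float(start),
    )


def _events_from_raw(raw):
    import mne

    if raw.annotations is not None and len(raw.annotations):
        events, event_id = mne.events_from_annotations(raw, verbose="error")
        return events, event_id
    stim = [ch for ch, kind in zip(raw.ch_names, raw.get_channel_types())
            if kind == "stim"]
    if not stim:
        return np.empty((0, 3), dtype=int), {}
    events = mne.find_events(raw, stim_channel=stim[0], verbose="error")
    return events, {str(c): int(c) for c in np.unique(events[:, 2])}


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings loaded from YAML/JSON."""

    simulation: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    training: dict = field(default_factory=dict)
    tuning: dict = field(default_factory=dict)

    def validate(self) -> None:
        folds = self.training.get("folds", 10)
        if folds < 2:
            raise ValueError("folds must be >= 2")
        dropout = self.network.get("dropout", 0.5)
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for section in (self.simulation, self.preprocessing, self.network,
                        self.training):
            for key, value in section.items():
                if key.startswith("n_") and isinstance(value, int) and value <= 0:
                    raise ValueError(f"{key} must be positive")

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(**self.simulation)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    cfg = PipelineConfig(**{k: raw.get(k, {}) for k in
                            ("simulation", "preprocessing", "network",
                             "training", "tuning")})
    cfg.validate()
    return cfg
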