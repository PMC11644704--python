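"""Readers/writers: HDF5 containers with JSON sidecars, model checkpoints,
YAML run configuration, and optional EDF import.

Every artifact written here carries the SHA-256 hash of the producing
configuration as an HDF5 attribute (and in the JSON sidecar), so pipelines
are replayable from logs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from macnet.errors import ConfigurationError, MontageError
from macnet.model import ModelConfig, MACNet, build_model
from macnet.preprocess import LINEAGE_DTYPE, SampleSet
from macnet.simulate import RawRecording


def config_hash(obj) -> str:
    """SHA-256 of a canonical JSON rendering of a config-like object."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_sidecar(path: Path, meta: dict) -> None:
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def save_recording(rec: RawRecording, path, cfg_hash: str = "") -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("event_samples",
                         data=np.array([s for s, _ in rec.events], dtype=np.int64))
        f.create_dataset(
            "event_labels",
            data=np.array([l for _, l in rec.events], dtype=h5py.string_dtype()),
        )
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["channel_names"] = list(rec.channel_names)
        f.attrs["classes"] = list(rec.classes)
        f.attrs["config_hash"] = cfg_hash
    _write_sidecar(path, {
        "kind": "recording",
        "sfreq": rec.sfreq,
        "n_channels": rec.data.shape[0],
        "n_samples": rec.data.shape[1],
        "n_events": len(rec.events),
        "channel_names": list(rec.channel_names),
        "classes": list(rec.classes),
        "config_hash": cfg_hash,
    })


def load_recording(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        samples = f["event_samples"][()]
        labels = [l.decode() if isinstance(l, bytes) else str(l)
                  for l in f["event_labels"][()]]
        return RawRecording(
            data=data,
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            sfreq=float(f.attrs["sfreq"]),
            events=list(zip((int(s) for s in samples), labels)),
            classes=tuple(str(c) for c in f.attrs["classes"]),
        )


# ---------------------------------------------------------------------------
# samplesets
# ---------------------------------------------------------------------------

def save_sampleset(s: SampleSet, path, cfg_hash: str = "") -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=s.data)
        f.create_dataset("labels", data=s.labels)
        f.create_dataset("lineage", data=s.lineage)
        f.attrs["sfreq"] = s.sfreq
        f.attrs["channel_names"] = list(s.channel_names)
        f.attrs["classes"] = list(s.classes)
        f.attrs["config_hash"] = cfg_hash
    _write_sidecar(path, {
        "kind": "sampleset",
        "shape": list(s.data.shape),
        "sfreq": s.sfreq,
        "classes": list(s.classes),
        "config_hash": cfg_hash,
    })


def load_sampleset(path) -> SampleSet:
    with h5py.File(path, "r") as f:
        return SampleSet(
            data=f["data"][()],
            labels=f["labels"][()],
            lineage=f["lineage"][()].astype(LINEAGE_DTYPE),
            sfreq=float(f.attrs["sfreq"]),
            channel_names=tuple(str(c) for c in f.attrs["channel_names"]),
            classes=tuple(str(c) for c in f.attrs["classes"]),
        )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: MACNet, path, ema_shadow=None,
                    cfg_hash: str = "") -> None:
    path = Path(path)
    state = model.state_arrays()
    with h5py.File(path, "w") as f:
        grp = f.create_group("state")
        for key, arr in state.items():
            grp.create_dataset(key, data=arr)
        if ema_shadow is not None:
            eg = f.create_group("ema")
            for i, arr in enumerate(ema_shadow):
                eg.create_dataset(str(i), data=arr)
        f.attrs["model_config"] = json.dumps(model.cfg.to_dict())
        f.attrs["config_hash"] = cfg_hash


def load_checkpoint(path) -> MACNet:
    with h5py.File(path, "r") as f:
        cfg = ModelConfig(**json.loads(f.attrs["model_config"]))
        model = build_model(cfg)
        state = {k: f["state"][k][()] for k in f["state"]}
        model.load_state_arrays(state)
        if "ema" in f:
            shadow = [f["ema"][str(i)][()] for i in range(len(f["ema"]))]
            model._ema_shadow = shadow
        return model


# ---------------------------------------------------------------------------
# run configuration (YAML, strict)
# ---------------------------------------------------------------------------

_KNOWN_SECTIONS = {"sim", "preprocess", "model", "train", "experiment",
                   "output", "seed"}


def load_run_config(path) -> dict:
    """Strict YAML loader: unknown top-level sections are rejected; section
    contents are validated against the corresponding dataclass fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("run config must be a mapping")
    unknown = set(raw) - _KNOWN_SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown config sections: {sorted(unknown)}")

    from macnet.simulate import SimSpec
    from macnet.train import TrainConfig

    def check(section: str, cls) -> None:
        if section not in raw or raw[section] is None:
            return
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw[section]) - valid
        if bad:
            raise ConfigurationError(
                f"unknown keys in section {section!r}: {sorted(bad)}"
            )

    check("sim", SimSpec)
    check("model", ModelConfig)
    check("train", TrainConfig)
    return raw


# ---------------------------------------------------------------------------
# external import (EDF and friends)
# ---------------------------------------------------------------------------

def read_recording_external(path, layout: dict) -> RawRecording:
    """Import a continuous recording from EDF via MNE.

    ``layout`` declares what the file must contain:
    ``{"channels": [...], "sfreq": float, "classes": [...],
    "event_map": {annotation_desc: class_label}}``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError("EDF import requires MNE") from exc

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc

    names = list(raw.ch_names)
    for ch in layout.get("channels", []):
        if ch not in names:
            raise MontageError(f"declared channel {ch!r} missing from {path}")
    sfreq = float(raw.info["sfreq"])
    want = layout.get("sfreq")
    if want is not None and abs(sfreq - want) > 1e-6:
        raise ConfigurationError(
            f"{path}: sampling rate {sfreq} != declared {want}"
        )
    event_map = layout.get("event_map", {})
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in event_map:
            events.append((int(round(onset * sfreq)), event_map[desc]))
    data = raw.get_data() * 1e6  # MNE is in volts; we carry µV
    classes = tuple(layout.get("classes")
                    or dict.fromkeys(event_map.values()))
    return RawRecording(
        data=data,
        channel_names=tuple(names),
        sfreq=sfreq,
        events=events,
        classes=classes,
    )
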