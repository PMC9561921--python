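"""Portable on-disk containers and run configuration.

A recording or epoch set is stored as a directory holding flat binary
arrays (``.npy``) plus a ``meta.json`` sidecar with schema version,
units (µV), sampling rate, channel labels, the event/epoch table, and a
SHA-256 checksum of the signal bytes — binary payload, diff-able
metadata.  Sample indices are 0-based; epoch times are ms from stimulus
onset.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .montage import Montage
from .paradigm import CodeBook, build_codebook
from .preprocess import ContinuousRecording, EpochSet
from .simulate import SessionEvent, SimConfig, SyntheticSession, \
    random_text, simulate_session

SCHEMA_VERSION = 1


class FormatError(ValueError):
    pass


def _sha256(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _check_version(meta: dict, path: Path) -> None:
    v = meta.get("schema_version")
    if v != SCHEMA_VERSION:
        raise FormatError(
            f"{path}: container schema version {v!r}, expected "
            f"{SCHEMA_VERSION}"
        )


# ---------------------------------------------------------------------------
# continuous recordings


def write_recording(rec: ContinuousRecording | SyntheticSession,
                    path) -> Path:
    """Write signal + events to a portable container directory."""
    if isinstance(rec, SyntheticSession):
        rec = ContinuousRecording.from_session(rec)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    signal = np.asarray(rec.signal, dtype=np.float32)
    np.save(path / "signal.npy", signal)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "recording",
        "units": "uV",
        "fs": rec.fs,
        "labels": list(rec.labels),
        "sha256": _sha256(signal),
        "events": [dataclasses.asdict(ev) for ev in rec.events],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_recording(path, fmt: str = "portable") -> ContinuousRecording:
    """Read a portable container back into a recording."""
    if fmt != "portable":
        raise FormatError(
            f"format {fmt!r} is not supported; use the portable container"
        )
    path = Path(path)
    try:
        meta = json.loads((path / "meta.json").read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise FormatError(f"{path}: cannot parse container metadata: {exc}")
    _check_version(meta, path)
    signal = np.load(path / "signal.npy")
    if _sha256(signal) != meta["sha256"]:
        raise FormatError(f"{path}: signal checksum mismatch")
    events = [SessionEvent(**ev) for ev in meta["events"]]
    return ContinuousRecording(
        signal=signal.astype(np.float64),
        fs=meta["fs"],
        labels=tuple(meta["labels"]),
        events=events,
    )


# ---------------------------------------------------------------------------
# epoch sets


def write_epochs(epochs: EpochSet, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    data = np.asarray(epochs.data, dtype=np.float32)
    np.save(path / "data.npy", data)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": "epochs",
        "units": "uV",
        "fs": epochs.fs,
        "window_ms": [0.0, 500.0],
        "labels": list(epochs.montage.labels),
        "positions": epochs.montage.positions.tolist(),
        "sha256": _sha256(data),
        "info": epochs.info.where(pd.notna(epochs.info), None)
        .to_dict(orient="records"),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_epochs(path) -> EpochSet:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    _check_version(meta, path)
    data = np.load(path / "data.npy")
    if _sha256(data) != meta["sha256"]:
        raise FormatError(f"{path}: epoch data checksum mismatch")
    info = pd.DataFrame(
        meta["info"],
        columns=["stage", "is_target", "char_index", "index", "character",
                 "group", "shown"],
    )
    montage = Montage(
        labels=tuple(meta["labels"]),
        positions=np.asarray(meta["positions"]),
    )
    return EpochSet(data=data, info=info, montage=montage, fs=meta["fs"])


# ---------------------------------------------------------------------------
# run configuration


_KNOWN_SECTIONS = {
    "codebook", "simulation", "preprocessing", "model", "training",
    "evaluation", "seed", "output_dir",
}


@dataclasses.dataclass
class RunConfig:
    """Nested run configuration with unknown-key rejection."""

    codebook: dict = dataclasses.field(default_factory=dict)
    simulation: dict = dataclasses.field(default_factory=dict)
    preprocessing: dict = dataclasses.field(default_factory=dict)
    model: dict = dataclasses.field(default_factory=dict)
    training: dict = dataclasses.field(default_factory=dict)
    evaluation: dict = dataclasses.field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_SECTIONS
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        d = yaml.safe_load(text) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    def make_codebook(self) -> CodeBook:
        codes = self.codebook.get("codes")
        charset = self.codebook.get("charset")
        return build_codebook(charset=charset,
                              codes=tuple(codes) if codes else None)

    def make_sim_config(self) -> SimConfig:
        return SimConfig(seed=self.seed, **self.simulation)


# ---------------------------------------------------------------------------
# fixtures


def make_fixtures(seed: int = 0, n_chars: int = 20,
                  noise_amplitude: float = 1.0,
                  out: str | Path | None = None) -> SyntheticSession:
    """Deterministic small low-noise session for end-to-end checks.

    20 characters → 160 markers, ~85 s of 64-channel signal; at this
    noise level (1 µV RMS under ±5 µV components) a trained decoder
    should spell every character.
    """
    cb = build_codebook()
    text = random_text(n_chars, cb, seed=seed)
    cfg = SimConfig(noise_amplitude=noise_amplitude, seed=seed)
    session = simulate_session(text, cb, cfg)
    if out is not None:
        write_recording(session, out)
    return session
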