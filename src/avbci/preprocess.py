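"""Continuous-EEG conditioning into 62x100 single-trial matrices.

Chain (in this order): re-reference to the bilateral mastoid average →
zero-phase 1–30 Hz Butterworth band-pass → decimate to 200 Hz → epoch
−0.1–0.5 s around each marker with 0.1 s baseline correction, keeping
the 0–0.5 s segment: 62 channels x 100 samples per trial.  Filtering
precedes decimation on purpose — the 30 Hz cutoff anti-aliases the
200 Hz rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import DATA_LABELS_62, MASTOIDS, Montage, default_montage
from .simulate import SessionEvent, SyntheticSession

logger = logging.getLogger(__name__)

EPOCH_SAMPLES = 100
BASELINE_S = 0.1
POST_S = 0.5
TARGET_FS = 200.0


class PreprocessError(ValueError):
    pass


@dataclass
class ContinuousRecording:
    """Multichannel continuous signal (µV) with event markers."""

    signal: np.ndarray            # (n_channels, n_samples)
    fs: float
    labels: tuple[str, ...]
    events: list[SessionEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise PreprocessError("channel labels must be unique")
        if self.signal.shape[0] != len(self.labels):
            raise PreprocessError("label count must match signal rows")

    @classmethod
    def from_session(cls, session: SyntheticSession) -> "ContinuousRecording":
        if session.signal is None:
            raise PreprocessError("session was simulated schedule-only")
        return cls(
            signal=np.asarray(session.signal),
            fs=session.fs,
            labels=tuple(session.labels),
            events=list(session.events),
        )


@dataclass
class Epoch:
    """One baseline-corrected single-trial matrix (62 x 100, µV)."""

    data: np.ndarray
    label: str                    # "target" | "nontarget"
    stage: int
    provenance: dict

    def __post_init__(self) -> None:
        if self.data.shape != (len(DATA_LABELS_62), EPOCH_SAMPLES):
            raise PreprocessError(
                f"epoch must be (62, {EPOCH_SAMPLES}), got {self.data.shape}"
            )


@dataclass
class EpochSet:
    """A stack of epochs with aligned metadata.

    data: (n_epochs, 62, 100); info: one row per epoch with stage,
    is_target, character provenance; montage: the 62-channel layout.
    """

    data: np.ndarray
    info: pd.DataFrame
    montage: Montage = field(default_factory=default_montage)
    fs: float = TARGET_FS

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1:] != (
            self.montage.n_channels,
            EPOCH_SAMPLES,
        ):
            raise PreprocessError(
                f"epoch stack must be (n, 62, {EPOCH_SAMPLES})"
            )
        if len(self.info) != len(self.data):
            raise PreprocessError("info rows must match epochs")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        """0/1 array, 1 = target."""
        return self.info["is_target"].to_numpy().astype(int)

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            info=self.info.iloc[mask].reset_index(drop=True),
            montage=self.montage,
            fs=self.fs,
        )

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(EPOCH_SAMPLES) / self.fs * 1000.0


def rereference(
    rec: ContinuousRecording, refs: tuple[str, str] = MASTOIDS
) -> ContinuousRecording:
    """Subtract the mean of the two reference channels; drop them."""
    for r in refs:
        if r not in rec.labels:
            raise PreprocessError(f"reference channel {r!r} not found")
    idx = [rec.labels.index(r) for r in refs]
    ref = rec.signal[idx].mean(axis=0, keepdims=True)
    keep = [i for i, lab in enumerate(rec.labels) if lab not in refs]
    return replace(
        rec,
        signal=rec.signal[keep] - ref,
        labels=tuple(rec.labels[i] for i in keep),
        events=list(rec.events),
    )


def bandpass(
    rec: ContinuousRecording, low: float = 1.0, high: float = 30.0
) -> ContinuousRecording:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    if rec.fs <= 2 * high:
        raise PreprocessError(
            f"fs={rec.fs} too low for a {high} Hz band edge"
        )
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    # channel-chunked so the float64 filtering temporaries stay small
    out = np.empty_like(rec.signal, dtype=rec.signal.dtype)
    for c0 in range(0, rec.signal.shape[0], 8):
        chunk = np.asarray(rec.signal[c0 : c0 + 8], dtype=np.float64)
        out[c0 : c0 + 8] = sps.sosfiltfilt(sos, chunk, axis=1)
    return replace(rec, signal=out, events=list(rec.events))


def downsample(
    rec: ContinuousRecording, target_fs: float = TARGET_FS
) -> ContinuousRecording:
    """Decimate by an integer factor; event samples remapped by rounding.

    Assumes the signal is already band-limited (run :func:`bandpass`
    first); plain sample picking is then alias-free.
    """
    factor = rec.fs / target_fs
    if abs(factor - round(factor)) > 1e-9:
        raise PreprocessError(
            f"fs {rec.fs} not an integer multiple of {target_fs}"
        )
    factor = int(round(factor))
    events = [
        replace(ev, sample=int(round(ev.sample / factor))) for ev in rec.events
    ]
    return ContinuousRecording(
        signal=rec.signal[:, ::factor],
        fs=target_fs,
        labels=rec.labels,
        events=events,
    )


def extract_epochs(
    rec: ContinuousRecording,
    events: list[SessionEvent] | None = None,
) -> tuple[EpochSet, int]:
    """Cut −0.1–0.5 s epochs, baseline-correct, keep 0–0.5 s.

    The per-channel mean of the −0.1–0 s segment is subtracted before
    cropping.  Events too close to the recording edge are skipped with a
    warning; the skip count is returned alongside the set.
    """
    events = rec.events if events is None else events
    n_pre = int(round(BASELINE_S * rec.fs))
    n_post = int(round(POST_S * rec.fs))
    datas, rows = [], []
    n_skipped = 0
    for ev in events:
        lo, hi = ev.sample - n_pre, ev.sample + n_post
        if lo < 0 or hi > rec.signal.shape[1]:
            n_skipped += 1
            continue
        seg = rec.signal[:, lo:hi]
        baseline = seg[:, :n_pre].mean(axis=1, keepdims=True)
        datas.append((seg[:, n_pre:] - baseline).astype(np.float32))
        rows.append(
            {
                "stage": ev.stage,
                "is_target": ev.is_target,
                "char_index": ev.char_index,
                "index": ev.index,
                "character": ev.character,
                "group": ev.group,
                "shown": ev.shown,
            }
        )
    if n_skipped:
        logger.warning("skipped %d events too close to recording edge",
                       n_skipped)
    data = (
        np.stack(datas)
        if datas
        else np.empty((0, len(rec.labels), n_post), dtype=np.float32)
    )
    info = pd.DataFrame(
        rows,
        columns=["stage", "is_target", "char_index", "index", "character",
                 "group", "shown"],
    )
    montage = Montage(labels=rec.labels)
    return EpochSet(data=data, info=info, montage=montage, fs=rec.fs), n_skipped


def preprocess_pipeline(
    rec: ContinuousRecording | SyntheticSession,
) -> EpochSet:
    """Full chain: rereference → bandpass → downsample → extract_epochs."""
    if isinstance(rec, SyntheticSession):
        rec = ContinuousRecording.from_session(rec)
    rec = rereference(rec)
    rec = bandpass(rec)
    rec = downsample(rec)
    epochs, _ = extract_epochs(rec)
    return epochs
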