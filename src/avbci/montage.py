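"""Electrode montage: a 64-channel extended 10-20 cap with mastoids.

Recordings carry 64 channels; after re-referencing to the bilateral
mastoids (M1/M2) the 62 data channels remain — the channel dimension of
every epoch.  Positions are schematic 2-D head coordinates (nose up,
left negative x, unit head radius) sufficient for topography scatter
plots; no forward modelling uses them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RAW_LABELS_64: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "FZ", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCZ", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "M1", "TP7", "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6", "TP8",
    "M2", "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "CB1", "O1", "OZ", "O2", "CB2",
)

MASTOIDS: tuple[str, str] = ("M1", "M2")

DATA_LABELS_62: tuple[str, ...] = tuple(
    lab for lab in RAW_LABELS_64 if lab not in MASTOIDS
)

# Front-to-back row ordinate for each 10-20 row prefix.
_ROW_Y = {
    "FP": 0.95, "AF": 0.75, "F": 0.55, "FT": 0.40, "FC": 0.30,
    "T": 0.0, "C": 0.0, "M": -0.15, "TP": -0.40, "CP": -0.30,
    "P": -0.55, "PO": -0.75, "CB": -0.95, "O": -0.90,
}


def _position(label: str) -> tuple[float, float]:
    if label in MASTOIDS:
        return (-1.15 if label == "M1" else 1.15, -0.15)
    prefix = "".join(ch for ch in label if ch.isalpha() and ch != "Z")
    y = _ROW_Y[prefix]
    suffix = label[len(prefix):]
    if suffix in ("", "Z"):
        return 0.0, y
    n = int(suffix)
    # odd numbers = left hemisphere, even = right; larger = more lateral
    x = ((n + 1) // 2) * 0.22 * (-1 if n % 2 else 1)
    if prefix in ("T", "FT", "TP"):
        x = 1.0 * (-1 if n % 2 else 1)
    return x, y


@dataclass(frozen=True)
class Montage:
    """Channel labels with schematic 2-D positions for topographies."""

    labels: tuple[str, ...] = DATA_LABELS_62
    positions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if self.positions is None:
            pos = np.array([_position(lab) for lab in self.labels])
            object.__setattr__(self, "positions", pos)
        elif np.asarray(self.positions).shape != (len(self.labels), 2):
            raise ValueError("positions must be (n_labels, 2)")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError as exc:
            raise KeyError(f"channel {label!r} not in montage") from exc


def default_montage() -> Montage:
    """The 62 data channels (64-channel cap minus the two mastoids)."""
    return Montage()


def recording_montage() -> Montage:
    """All 64 recorded channels including M1/M2."""
    return Montage(labels=RAW_LABELS_64)
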