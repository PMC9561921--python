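"""Synthetic ERP session generator.

Produces continuous 64-channel recordings (62 data channels + two
mastoids) at 1000 Hz in which every scheduled stimulus is marked and the
attended stimuli carry parametric ERP templates — sums of Gaussian bumps
with per-channel topographies — embedded in 1/f background noise.  The
stage-1 target response is the motion-onset complex (P1/N2/P2 at ~90,
130, 195 ms); the stage-2 audio-assisted target response adds a P300 at
350 ms with earlier mVEP latencies (50/90/180 ms).  Non-attended stimuli
evoke no response (attention-gated), so nontarget templates default to
zero amplitude.

Every downstream stage (preprocessing, decoding, evaluation) is testable
against the recorded ground truth; all randomness flows from
:class:`SimConfig.seed`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import DATA_LABELS_62, RAW_LABELS_64, Montage, default_montage
from .paradigm import (
    CodeBook,
    TrialSchedule,
    TRIAL_SPAN_S,
    build_schedule,
    encode_character,
)

EPOCH_WINDOW_MS = 500.0


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class ErpComponent:
    """One Gaussian ERP component.

    latency/width in ms post-onset, amplitude in µV (signed), topography
    a per-channel weight in [0, 1] over the 62 data channels.
    """

    name: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: np.ndarray

    def __post_init__(self) -> None:
        topo = np.asarray(self.topography, dtype=float)
        object.__setattr__(self, "topography", topo)
        if self.latency_ms + 3 * self.width_ms > EPOCH_WINDOW_MS:
            raise SimulationError(
                f"{self.name}: latency + 3 sigma exceeds the "
                f"{EPOCH_WINDOW_MS:.0f} ms epoch window"
            )
        if not np.any(topo != 0):
            raise SimulationError(f"{self.name}: empty topography")


@dataclass(frozen=True)
class ErpTemplate:
    """Target or nontarget component set for one stage."""

    stage: int
    condition: str  # "target" | "nontarget"
    components: tuple[ErpComponent, ...]


@dataclass(frozen=True)
class SimConfig:
    """Simulator knobs.

    noise_amplitude is the per-channel RMS of the background noise in µV
    (default 10, a realistic spontaneous-EEG scale); component
    amplitudes are ±5 µV scaled by snr_scale, so snr_scale=1 gives a
    realistic single-trial SNR, larger values an easier regime.
    """

    fs: float = 1000.0
    noise_amplitude: float = 10.0
    spectral_exponent: float = 1.0
    snr_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise SimulationError("fs must be positive")
        if self.noise_amplitude < 0:
            raise SimulationError("noise_amplitude must be >= 0")


@dataclass(frozen=True)
class SessionEvent:
    """Marker for one scheduled stimulus in a continuous session."""

    sample: int
    stage: int
    char_index: int
    index: int            # sub-trial k (stage 1) or slot (stage 2)
    is_target: bool
    character: str        # character being spelled
    group: int            # attended group index
    shown: str | None = None       # stage 2: character shown in this slot
    flashed_bits: str | None = None  # stage 1: which groups flashed


@dataclass
class SyntheticSession:
    """Continuous synthetic recording with markers and ground truth."""

    signal: np.ndarray | None   # (64, n_samples) µV, None if schedule-only
    fs: float
    labels: tuple[str, ...]
    events: list[SessionEvent]
    text: str
    schedules: list[TrialSchedule]
    config: SimConfig

    @property
    def n_samples(self) -> int:
        if self.signal is not None:
            return self.signal.shape[1]
        return int(self.events[-1].sample + self.fs) if self.events else 0


def gaussian_topography(
    centroid: str = "P4", sigma: float = 0.45, montage: Montage | None = None
) -> np.ndarray:
    """Weights falling off with 2-D distance from a centroid electrode."""
    montage = montage or default_montage()
    center = montage.positions[montage.index(centroid)]
    d2 = np.sum((montage.positions - center) ** 2, axis=1)
    return np.exp(-d2 / (2 * sigma**2))


def default_templates(stage: int) -> tuple[ErpTemplate, ErpTemplate]:
    """Target and nontarget templates for a stage.

    Stage 1: motion-onset P1(+, 90 ms), N2(−, 130 ms), P2(+, 195 ms).
    Stage 2: P1(+, 50 ms), N2(−, 90 ms), P2(+, 180 ms) plus a broad
    P300(+, 350 ms).  Topographies weight temporo-occipital/parietal
    channels with right-hemisphere dominance (centroid P4; the P300 a
    touch more medial).  Nontargets carry no components.
    """
    topo = gaussian_topography("P4")
    if stage == 1:
        comps = (
            ErpComponent("P1", 90.0, 20.0, 5.0, topo),
            ErpComponent("N2", 130.0, 20.0, -5.0, topo),
            ErpComponent("P2", 195.0, 20.0, 5.0, topo),
        )
    elif stage == 2:
        p300_topo = 0.5 * topo + 0.5 * gaussian_topography("PZ")
        comps = (
            ErpComponent("P1", 50.0, 20.0, 5.0, topo),
            ErpComponent("N2", 90.0, 20.0, -5.0, topo),
            ErpComponent("P2", 180.0, 20.0, 5.0, topo),
            ErpComponent("P300", 350.0, 50.0, 5.0, p300_topo),
        )
    else:
        raise ValueError(f"stage must be 1 or 2, got {stage}")
    target = ErpTemplate(stage=stage, condition="target", components=comps)
    nontarget = ErpTemplate(stage=stage, condition="nontarget", components=())
    return target, nontarget


def render_template(
    template: ErpTemplate,
    fs: float,
    duration_s: float = EPOCH_WINDOW_MS / 1000.0,
    snr_scale: float = 1.0,
) -> np.ndarray:
    """Render a template as a (62, round(duration*fs)) waveform in µV.

    Superposition of Gaussians: each component contributes
    ``amplitude * topography[c] * exp(-(t - latency)^2 / (2 sigma^2))``.
    Deterministic.
    """
    n = int(round(duration_s * fs))
    for comp in template.components:
        if comp.latency_ms / 1000.0 > duration_s:
            raise SimulationError(
                f"{comp.name} at {comp.latency_ms} ms lies outside a "
                f"{duration_s * 1000:.0f} ms render window"
            )
    out = np.zeros((len(DATA_LABELS_62), n))
    t_ms = np.arange(n) / fs * 1000.0
    for comp in template.components:
        bump = np.exp(-((t_ms - comp.latency_ms) ** 2) / (2 * comp.width_ms**2))
        out += (snr_scale * comp.amplitude_uv) * np.outer(comp.topography, bump)
    return out


def simulate_noise(
    cfg: SimConfig,
    n_channels: int,
    n_samples: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Zero-mean 1/f^alpha noise, per-channel RMS = cfg.noise_amplitude.

    White Gaussian noise is shaped in the frequency domain by
    ``f^(-alpha/2)`` (DC removed), then rescaled to the requested RMS.
    Channels are independent.
    """
    if n_samples <= 1:
        raise SimulationError("need more than one sample")
    if cfg.noise_amplitude == 0:
        return np.zeros((n_channels, n_samples), dtype=np.float32)
    rng = rng or np.random.default_rng(cfg.seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / cfg.fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-cfg.spectral_exponent / 2.0)
    out = np.empty((n_channels, n_samples), dtype=np.float32)
    # chunked over channels to bound transient f64/complex memory
    block = 8
    for c0 in range(0, n_channels, block):
        c1 = min(c0 + block, n_channels)
        white = rng.standard_normal((c1 - c0, n_samples))
        spec = np.fft.rfft(white, axis=1)
        noise = np.fft.irfft(spec * shape, n=n_samples, axis=1)
        rms = np.sqrt(np.mean(noise**2, axis=1, keepdims=True))
        out[c0:c1] = noise * (cfg.noise_amplitude / rms)
    return out


def simulate_session(
    text: str,
    cb: CodeBook,
    cfg: SimConfig | None = None,
    schedule_only: bool = False,
    lead_in_s: float = 1.0,
) -> SyntheticSession:
    """Simulate a continuous copy-spelling session for ``text``.

    Per character: 3 stage-1 sub-trial markers and 5 stage-2 slot
    markers (8 markers, 4.0 s of stimulation).  The stage-appropriate
    target template is inserted at a marker iff the attended location
    flashed (stage 1: attended group's code bit is '1'; stage 2: the
    slot shows the spelled character); nontargets evoke nothing.  1/f
    noise is added on all 64 channels.  With ``schedule_only`` no signal
    is rendered (markers and truth only) — useful for large sessions.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs

    events: list[SessionEvent] = []
    schedules: list[TrialSchedule] = []
    n_samples = int(round((lead_in_s + TRIAL_SPAN_S * len(text) + 1.0) * fs))

    target1, _ = default_templates(1)
    target2, _ = default_templates(2)
    if not schedule_only:
        signal = simulate_noise(cfg, len(RAW_LABELS_64), n_samples, rng=rng)
        wave1 = render_template(target1, fs, snr_scale=cfg.snr_scale)
        wave2 = render_template(target2, fs, snr_scale=cfg.snr_scale)
        data_rows = np.array(
            [RAW_LABELS_64.index(lab) for lab in DATA_LABELS_62]
        )
    else:
        signal = None

    for ci, c in enumerate(text):
        gi, code, wi = encode_character(c, cb)
        sched = build_schedule(c, cb, seed=int(rng.integers(2**31)))
        schedules.append(sched)
        t0 = lead_in_s + ci * TRIAL_SPAN_S
        flashed = [
            "".join(cb.codes[g][k] for g in range(len(cb.groups)))
            for k in range(3)
        ]
        for k in range(3):
            sample = int(round((t0 + k * 0.5) * fs))
            is_target = code[k] == "1"
            events.append(
                SessionEvent(
                    sample=sample, stage=1, char_index=ci, index=k,
                    is_target=is_target, character=c, group=gi,
                    flashed_bits=flashed[k],
                )
            )
            if is_target and signal is not None:
                signal[data_rows, sample : sample + wave1.shape[1]] += wave1
        for slot, ev in enumerate(sched.stage2_events):
            sample = int(round((t0 + ev.onset) * fs))
            shown = cb.groups[gi][sched.stage2_order[slot]]
            is_target = shown == c
            events.append(
                SessionEvent(
                    sample=sample, stage=2, char_index=ci, index=slot,
                    is_target=is_target, character=c, group=gi, shown=shown,
                )
            )
            if is_target and signal is not None:
                signal[data_rows, sample : sample + wave2.shape[1]] += wave2

    if signal is not None:
        signal = signal.astype(np.float32, copy=False)
    return SyntheticSession(
        signal=signal,
        fs=fs,
        labels=RAW_LABELS_64,
        events=events,
        text=text,
        schedules=schedules,
        config=cfg,
    )


def random_text(n_chars: int, cb: CodeBook, seed: int) -> str:
    """A seeded random spelled text drawn uniformly from the charset."""
    rng = np.random.default_rng(seed)
    chars = cb.charset.characters
    return "".join(chars[i] for i in rng.integers(0, len(chars), n_chars))
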