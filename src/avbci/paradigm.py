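"""Stimulus coding for the two-stage audio-assisted visual speller.

Forty characters are split into eight groups of five.  In stage 1 every
group is driven by a 3-bit code over three 0.5-s sub-trials ("space
division multiple access"): a motion-onset stimulus (a bar sweeping for
0.3 s) is shown at the group's location in sub-trial ``k`` iff bit ``k``
of its code is '1', and all eight groups play their codes simultaneously.
Decoding the three attended/not-attended responses identifies the group.
In stage 2 the five characters of the chosen group are presented one at a
time in random order, each with its spoken name (an oddball sequence),
and the attended character elicits a P300.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

#: 40-character speller alphabet ('_' stands for space).
DEFAULT_CHARSET: str = "ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.,?"

#: Default assignment of the eight 3-bit codes to groups in reading order.
#: The A–E group carries "101"; the remaining order is a package convention
#: (the full 8-code set over 3 bits is forced by having 8 groups).
DEFAULT_CODES: tuple[str, ...] = (
    "101", "011", "110", "111", "001", "010", "100", "000",
)

DEFAULT_LAYOUT: tuple[str, ...] = (
    "top-left", "top-center-left", "top-center-right", "top-right",
    "bottom-left", "bottom-center-left", "bottom-center-right", "bottom-right",
)

N_GROUPS = 8
GROUP_SIZE = 5
STAGE1_SUBTRIALS = 3
STAGE2_SLOTS = GROUP_SIZE

#: Motion-onset stimulus duration and inter-stimulus interval, seconds.
STIM_DURATION_S = 0.3
ISI_S = 0.2
#: Stimulus-onset asynchrony: one stimulus slot.
SOA_S = STIM_DURATION_S + ISI_S
STAGE1_SPAN_S = STAGE1_SUBTRIALS * SOA_S
STAGE2_SPAN_S = STAGE2_SLOTS * SOA_S
TRIAL_SPAN_S = STAGE1_SPAN_S + STAGE2_SPAN_S


class CodebookError(ValueError):
    """Invalid charset, codes, or character lookup."""


@dataclass(frozen=True)
class Charset:
    """Ordered speller alphabet of exactly 40 unique symbols."""

    characters: tuple[str, ...] = tuple(DEFAULT_CHARSET)

    def __post_init__(self) -> None:
        if len(self.characters) != N_GROUPS * GROUP_SIZE:
            raise CodebookError(
                f"charset must have {N_GROUPS * GROUP_SIZE} characters, "
                f"got {len(self.characters)}"
            )
        if len(set(self.characters)) != len(self.characters):
            raise CodebookError("charset characters must be unique")

    def __contains__(self, c: str) -> bool:
        return c in self.characters


@dataclass(frozen=True)
class StimulusEvent:
    """One motion-onset (stage 1) or audiovisual (stage 2) stimulus.

    ``location`` is a group index in stage 1 and a within-group index in
    stage 2.  Onset is in seconds from trial start; the event occupies
    ``[onset, onset + STIM_DURATION_S)``.
    """

    stage: int
    onset: float
    location: int
    is_motion: bool = True
    has_audio: bool = False

    def __post_init__(self) -> None:
        if self.has_audio and self.stage != 2:
            raise ValueError("audio accompanies stage-2 stimuli only")


@dataclass(frozen=True)
class TrialSchedule:
    """Full two-stage stimulus schedule for spelling one character.

    ``stage1_events[k]`` holds the simultaneous motion events of sub-trial
    ``k`` (one per group whose code bit ``k`` is '1').  ``stage2_events``
    holds the five audiovisual presentations in seeded random order;
    ``stage2_order[slot]`` is the within-group index shown at that slot.
    """

    character: str
    stage1_events: tuple[tuple[StimulusEvent, ...], ...]
    stage2_events: tuple[StimulusEvent, ...]
    stage2_order: tuple[int, ...]
    rng_seed: int

    @property
    def stage1_span(self) -> float:
        return STAGE1_SPAN_S

    @property
    def stage2_span(self) -> float:
        return STAGE2_SPAN_S

    @property
    def total_span(self) -> float:
        return TRIAL_SPAN_S


@dataclass(frozen=True)
class CodeBook:
    """Partition of the charset into 8 coded groups of 5.

    groups: eight ordered character quintets, reading order.
    codes: group index -> 3-character binary string.
    layout: group index -> screen position label (metadata only; no
        rendering is implemented).
    """

    groups: tuple[tuple[str, ...], ...]
    codes: tuple[str, ...]
    layout: tuple[str, ...] = DEFAULT_LAYOUT
    charset: Charset = field(default_factory=Charset)

    def __post_init__(self) -> None:
        flat = [c for g in self.groups for c in g]
        if len(self.groups) != N_GROUPS or any(
            len(g) != GROUP_SIZE for g in self.groups
        ):
            raise CodebookError("codebook needs 8 groups of 5 characters")
        if len(set(flat)) != N_GROUPS * GROUP_SIZE:
            raise CodebookError("characters must appear in exactly one group")
        if len(self.codes) != N_GROUPS or len(set(self.codes)) != N_GROUPS:
            raise CodebookError("need 8 distinct group codes")
        for code in self.codes:
            if len(code) != STAGE1_SUBTRIALS or set(code) - {"0", "1"}:
                raise CodebookError(f"malformed 3-bit code {code!r}")

    def group_of(self, c: str) -> int:
        for gi, g in enumerate(self.groups):
            if c in g:
                return gi
        raise CodebookError(f"character {c!r} not in codebook")

    def to_json(self) -> str:
        return json.dumps(
            {
                "groups": [list(g) for g in self.groups],
                "codes": list(self.codes),
                "layout": list(self.layout),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CodeBook":
        d = json.loads(text)
        flat = tuple(c for g in d["groups"] for c in g)
        return cls(
            groups=tuple(tuple(g) for g in d["groups"]),
            codes=tuple(d["codes"]),
            layout=tuple(d["layout"]),
            charset=Charset(flat),
        )


def build_codebook(
    charset: Charset | str | None = None,
    codes: tuple[str, ...] | None = None,
    layout: tuple[str, ...] = DEFAULT_LAYOUT,
) -> CodeBook:
    """Partition ``charset`` into 8 reading-order groups of 5 with 3-bit codes.

    Deterministic: group ``g`` holds characters ``5g..5g+4`` and receives
    ``codes[g]`` (default :data:`DEFAULT_CODES`, placing "101" on the
    group that contains 'A').
    """
    if charset is None:
        charset = Charset()
    elif isinstance(charset, str):
        charset = Charset(tuple(charset))
    codes = DEFAULT_CODES if codes is None else tuple(codes)
    groups = tuple(
        tuple(charset.characters[g * GROUP_SIZE : (g + 1) * GROUP_SIZE])
        for g in range(N_GROUPS)
    )
    return CodeBook(groups=groups, codes=codes, layout=layout, charset=charset)


def encode_character(c: str, cb: CodeBook) -> tuple[int, str, int]:
    """Map a character to ``(group_index, group_code, within_group_index)``."""
    gi = cb.group_of(c)
    return gi, cb.codes[gi], cb.groups[gi].index(c)


def decode_character(gi: int, wi: int, cb: CodeBook) -> str:
    """Inverse of :func:`encode_character`."""
    return cb.groups[gi][wi]


def build_schedule(c: str, cb: CodeBook, seed: int) -> TrialSchedule:
    """Build the seeded two-stage stimulus schedule for one character.

    Stage 1 spans 1.5 s (3 sub-trials x 0.5 s); every group with code bit
    '1' in sub-trial ``k`` emits a motion event at onset ``0.5 k``.
    Stage 2 spans 2.5 s: the 5 group members in a seeded random order,
    each with audio.
    """
    gi, _code, _wi = encode_character(c, cb)
    stage1 = tuple(
        tuple(
            StimulusEvent(stage=1, onset=k * SOA_S, location=g)
            for g in range(N_GROUPS)
            if cb.codes[g][k] == "1"
        )
        for k in range(STAGE1_SUBTRIALS)
    )
    rng = np.random.default_rng(seed)
    order = tuple(int(i) for i in rng.permutation(GROUP_SIZE))
    stage2 = tuple(
        StimulusEvent(
            stage=2,
            onset=STAGE1_SPAN_S + slot * SOA_S,
            location=order[slot],
            has_audio=True,
        )
        for slot in range(STAGE2_SLOTS)
    )
    return TrialSchedule(
        character=c,
        stage1_events=stage1,
        stage2_events=stage2,
        stage2_order=order,
        rng_seed=seed,
    )


def presentations_per_character(cb: CodeBook, mode: str = "two_stage") -> int:
    """Stimulus presentations needed to spell one character.

    ``two_stage``: 3 stage-1 sub-trials + 5 stage-2 slots = 8.
    ``fully_parallel``: ceil(log2 groups) + ceil(log2 group size) = 6,
    the lower bound if both stages used parallel binary coding.
    """
    if mode == "two_stage":
        return STAGE1_SUBTRIALS + STAGE2_SLOTS
    if mode == "fully_parallel":
        return math.ceil(math.log2(len(cb.groups))) + math.ceil(
            math.log2(GROUP_SIZE)
        )
    raise ValueError(f"unknown mode {mode!r}")


def matrix_speller_presentations(n_rows: int = 5, n_cols: int = 8) -> int:
    """Row+column flash count of a classical matrix speller (reference)."""
    return n_rows + n_cols


def chance_level(cb: CodeBook) -> float:
    """Probability of spelling a character correctly by uniform guessing."""
    return 1.0 / (len(cb.groups) * GROUP_SIZE)
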