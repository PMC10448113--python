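"""Stimulus protocols for amino-acid odor panels.

A recording session presents odorants to the olfactory epithelium for a few
seconds each, separated by long inter-stimulus intervals to avoid receptor
desensitization. Every analysis window downstream (response peaks, baseline
intervals, SBR) is defined relative to the stimulus onsets stored here.

Single amino-acid stimuli carry uppercase one-letter codes (panel order
M, L, I, H, K, R, F, W); mixtures and controls carry lowercase codes
(``b`` basic-aromatic mix, ``l`` long-chain-neutral mix, ``s`` short-chain
neutral mix, ``o`` mixture of all odorants, ``x`` bile acids, ``a`` amines,
``c`` control ringer).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

#: Fixed panel order used for tuning labels, matrices and plots.
PANEL = ("M", "L", "I", "H", "K", "R", "F", "W")

#: Lowercase mixture / control codes.
MIXTURE_CODES = ("b", "l", "s", "x", "a", "o", "c")

_VALID_CODES = set(PANEL) | set(MIXTURE_CODES)


@dataclass(frozen=True)
class StimulusEvent:
    """One odorant application: ``code`` at ``onset`` seconds for ``duration`` seconds."""

    code: str
    onset: float
    duration: float = 5.0

    def __post_init__(self):
        if self.code not in _VALID_CODES:
            raise ValueError(f"unknown stimulus code {self.code!r}")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing of a full recording: frame rate, lead-in, and ordered stimulus events."""

    frame_rate: float
    events: tuple[StimulusEvent, ...]
    pre_record: float = 15.0
    inter_stimulus: float = 60.0
    n_frames: int = 0

    def __post_init__(self):
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("stimulus onsets must be strictly increasing")
        if any(b - a < self.inter_stimulus - 1e-9 for a, b in zip(onsets, onsets[1:])):
            raise ValueError("consecutive onsets closer than the inter-stimulus interval")
        if onsets and onsets[0] < self.pre_record - 1e-9:
            raise ValueError("first onset precedes the pre-stimulus recording window")
        if onsets and self.n_frames / self.frame_rate < onsets[-1] + 40.0:
            raise ValueError("n_frames does not cover the last event's analysis windows")

    # -- frame arithmetic ------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate

    def frames_in(self, t0: float, t1: float) -> np.ndarray:
        """Indices of frames with t0 <= t < t1, clipped to the recording."""
        t = self.times
        return np.nonzero((t >= t0 - 1e-9) & (t < t1 - 1e-9))[0]

    def events_for(self, code: str) -> list[StimulusEvent]:
        return [e for e in self.events if e.code == code]

    @property
    def codes(self) -> list[str]:
        """Distinct codes in order of first occurrence."""
        seen: dict[str, None] = {}
        for e in self.events:
            seen.setdefault(e.code, None)
        return list(seen)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["events"] = [asdict(e) for e in self.events]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        events = tuple(StimulusEvent(**e) for e in d["events"])
        return cls(frame_rate=d["frame_rate"], events=events, pre_record=d["pre_record"],
                   inter_stimulus=d["inter_stimulus"], n_frames=d["n_frames"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)


def make_protocol(panel=PANEL, repeats: int = 1, frame_rate: float = 1.0,
                  seed: int | None = None, mix_code: str = "o",
                  mix_at_end: bool = False, shuffle: bool = True,
                  pre_record: float = 15.0, inter_stimulus: float = 60.0,
                  stimulus_duration: float = 5.0) -> AcquisitionProtocol:
    """Build a stimulus sequence for ``panel``, repeated ``repeats`` times.

    Each repeat opens with the odorant mixture ``mix_code`` followed by the
    single stimuli (order shuffled per repeat when ``shuffle``); with
    ``mix_at_end`` the mixture also closes each repeat. Onsets are spaced by
    ``inter_stimulus`` seconds with a ``pre_record`` lead-in; the recording
    extends one full interval past the last onset so that every response and
    baseline window fits.
    """
    if not panel:
        raise ValueError("stimulus panel is empty")
    if not 0.25 <= frame_rate <= 2.0:
        raise ValueError(f"frame rate {frame_rate} Hz outside the supported 0.25-2 Hz range")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    sequence: list[str] = []
    for _ in range(repeats):
        order = list(panel)
        if shuffle:
            rng.shuffle(order)
        sequence.append(mix_code)
        sequence.extend(order)
        if mix_at_end:
            sequence.append(mix_code)
    events = tuple(
        StimulusEvent(code, onset=pre_record + i * inter_stimulus, duration=stimulus_duration)
        for i, code in enumerate(sequence)
    )
    n_frames = int(np.ceil((events[-1].onset + inter_stimulus) * frame_rate))
    return AcquisitionProtocol(frame_rate=frame_rate, events=events,
                               pre_record=pre_record, inter_stimulus=inter_stimulus,
                               n_frames=n_frames)
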