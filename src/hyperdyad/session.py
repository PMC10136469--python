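"""Domain types shared by every stage of the dyad-analysis pipeline.

The objects here describe one hyperscanning session: the optode montage,
the task timeline (alternating rest periods and competition blocks), the
two participants' optical or hemoglobin recordings, and the trial-level
behavioral record.  All times are seconds from recording start; channels
are numbered from 1 to match the montage convention used throughout
(e.g. "channel 3 of the male member").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ROI",
    "ProbeLayout",
    "Segment",
    "Trial",
    "TaskTimeline",
    "ParticipantRecording",
    "BehavioralTrials",
    "DyadSession",
    "default_layout",
]

#: Valid regions of interest for the default montage.
ROI = ("PFC", "lTPJ", "rTPJ")


class ValidationError(ValueError):
    """An object violates one of its structural invariants."""


@dataclass(frozen=True)
class ProbeLayout:
    """Channel montage: 1-based channel ids with region labels and ROIs.

    The default montage has 23 channels over the prefrontal cortex and
    the bilateral temporoparietal junction; channel 3 sits over the left
    middle temporal cortex and channel 6 over the right TPJ.
    """

    channel_ids: tuple[int, ...]
    region_labels: tuple[str, ...]
    rois: tuple[str, ...]

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def validate(self) -> None:
        n = len(self.channel_ids)
        if self.channel_ids != tuple(range(1, n + 1)):
            raise ValidationError("channel ids must be unique and contiguous from 1")
        if len(self.region_labels) != n or len(self.rois) != n:
            raise ValidationError("labels/rois must match channel count")
        bad = [r for r in self.rois if r not in ROI]
        if bad:
            raise ValidationError(f"unknown ROI(s): {sorted(set(bad))}")

    def roi_of(self, channel: int) -> str:
        return self.rois[channel - 1]


def default_layout() -> ProbeLayout:
    """The 23-channel montage: ch 1-4 left TPJ probe, 5-8 right TPJ probe,
    9-23 prefrontal probe.  Channel 3 is labelled left MTC and channel 6
    right TPJ, the pair at which the inter-brain effect is expected."""
    labels, rois = [], []
    for ch in range(1, 24):
        if ch <= 4:
            rois.append("lTPJ")
            labels.append("left MTC" if ch == 3 else "left TPJ")
        elif ch <= 8:
            rois.append("rTPJ")
            labels.append("right TPJ")
        else:
            rois.append("PFC")
            labels.append("PFC")
    layout = ProbeLayout(tuple(range(1, 24)), tuple(labels), tuple(rois))
    layout.validate()
    return layout


def small_layout(n_channels: int) -> ProbeLayout:
    """A reduced montage (first ``n_channels`` of the default scheme) for
    fast simulation studies."""
    base = default_layout()
    if not 1 <= n_channels <= base.n_channels:
        raise ValidationError("n_channels must be in 1..23")
    layout = ProbeLayout(
        base.channel_ids[:n_channels],
        base.region_labels[:n_channels],
        base.rois[:n_channels],
    )
    layout.validate()
    return layout


@dataclass(frozen=True)
class Segment:
    kind: str  # "rest" | "block"
    onset_s: float
    duration_s: float
    block_index: Optional[int] = None  # 1 or 2 for blocks

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class Trial:
    block_index: int
    trial_index: int  # 1-based within block
    cue_onset_s: float
    go_onset_s: float
    response_window_s: float
    feedback_onset_s: float
    blank_onset_s: float


@dataclass(frozen=True)
class TaskTimeline:
    """Ordered rest/block segments plus per-trial event times.

    Default design: rest (30 s), block 1 (20 trials), rest (30 s),
    block 2 (20 trials), rest (30 s); 40 trials total.
    """

    segments: tuple[Segment, ...]
    trials: tuple[Trial, ...]

    @property
    def duration_s(self) -> float:
        return self.segments[-1].end_s if self.segments else 0.0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def validate(self) -> None:
        t = 0.0
        for seg in self.segments:
            if seg.onset_s < t - 1e-9:
                raise ValidationError("segments overlap or are out of order")
            if seg.duration_s <= 0:
                raise ValidationError("segment duration must be positive")
            t = seg.end_s
        for seg in self.segments:
            if seg.kind == "block" and seg.block_index is None:
                raise ValidationError("block segment without block_index")

    def segments_of(self, kind: str, block_index: Optional[int] = None) -> tuple[Segment, ...]:
        out = [s for s in self.segments if s.kind == kind]
        if block_index is not None:
            out = [s for s in out if s.block_index == block_index]
        return tuple(out)

    def sample_mask(self, fs_hz: float, n_samples: int, kind: str,
                    block_index: Optional[int] = None) -> np.ndarray:
        """Boolean mask over a sample grid (t_i = i / fs) selecting the
        requested segment kind (optionally a single block)."""
        t = np.arange(n_samples) / fs_hz
        mask = np.zeros(n_samples, dtype=bool)
        for seg in self.segments_of(kind, block_index):
            mask |= (t >= seg.onset_s) & (t < seg.end_s)
        return mask


@dataclass(frozen=True)
class ParticipantRecording:
    """One participant's recording: either dual-wavelength raw intensity
    (channel x wavelength x time, arbitrary units) or hemoglobin series
    (channel x time, micromolar), at ``fs_hz``."""

    participant_id: str
    sex: str  # "M" | "F"
    fs_hz: float = 7.81
    intensity: Optional[np.ndarray] = None  # (n_ch, 2, n_t), a.u., > 0
    hbo: Optional[np.ndarray] = None        # (n_ch, n_t), uM
    hbr: Optional[np.ndarray] = None
    wavelengths_nm: tuple[float, float] = (760.0, 830.0)
    source_detector_distance_cm: float = 3.0

    @property
    def n_channels(self) -> int:
        arr = self.intensity if self.intensity is not None else self.hbo
        return 0 if arr is None else arr.shape[0]

    @property
    def n_samples(self) -> int:
        if self.intensity is not None:
            return self.intensity.shape[-1]
        return 0 if self.hbo is None else self.hbo.shape[-1]

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise ValidationError("fs_hz must be positive")
        if self.sex not in ("M", "F"):
            raise ValidationError("sex must be 'M' or 'F'")
        if self.intensity is None and self.hbo is None:
            raise ValidationError("recording needs intensity or hbo data")
        if self.intensity is not None:
            if self.intensity.ndim != 3 or self.intensity.shape[1] != 2:
                raise ValidationError("intensity must be (n_ch, 2, n_t)")
            if not np.all(self.intensity > 0):
                raise ValidationError("intensity must be strictly positive")
        if self.hbo is not None and self.hbo.ndim != 2:
            raise ValidationError("hbo must be (n_ch, n_t)")


@dataclass(frozen=True)
class BehavioralTrials:
    """Per-trial response times (ms) for both members plus outcome."""

    dyad_id: str
    block_index: np.ndarray   # (n_trials,) int, 1 or 2
    trial_index: np.ndarray   # (n_trials,) int, 1-based within block
    rt_ms_member1: np.ndarray  # male member
    rt_ms_member2: np.ndarray  # female member
    winner: np.ndarray        # (n_trials,) int: 1 or 2 (faster member)
    points_delta: np.ndarray  # points won by member 1 on the trial (+/-2, 0 tie)

    @property
    def n_trials(self) -> int:
        return len(self.block_index)

    def validate(self) -> None:
        n = self.n_trials
        for name in ("trial_index", "rt_ms_member1", "rt_ms_member2",
                     "winner", "points_delta"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"behavior field {name} has wrong length")
        if np.any(self.rt_ms_member1 <= 0) or np.any(self.rt_ms_member2 <= 0):
            raise ValidationError("response times must be positive")
        if not np.all(np.isin(self.block_index, (1, 2))):
            raise ValidationError("block_index must be 1 or 2")


@dataclass(frozen=True)
class DyadSession:
    """One dyad: paired recordings, timeline, behavior, and metadata."""

    dyad_id: str
    group: str  # "couple" | "control"
    member_m: ParticipantRecording
    member_f: ParticipantRecording
    timeline: TaskTimeline
    behavior: BehavioralTrials
    layout: ProbeLayout
    covariates: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.group not in ("couple", "control"):
            raise ValidationError("group must be 'couple' or 'control'")
        if {self.member_m.sex, self.member_f.sex} != {"M", "F"}:
            raise ValidationError("dyad must contain one M and one F member")
        self.member_m.validate()
        self.member_f.validate()
        if self.member_m.n_samples != self.member_f.n_samples:
            raise ValidationError("members' time axes differ in length")
        self.timeline.validate()
        self.behavior.validate()
        self.layout.validate()

    def with_members(self, member_m: ParticipantRecording,
                     member_f: ParticipantRecording) -> "DyadSession":
        return replace(self, member_m=member_m, member_f=member_f)
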