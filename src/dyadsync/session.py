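"""Session data model for dyadic wearable recordings.

A *session* is one experimental day with a human and a canine subject.  Its
timeline is an ordered sequence of subsessions (baseline, interaction and
neutral periods); every modality — raw sensor channels, per-second behavior
labels and interstitial surveys — lives on the same clock, anchored at the
timeline origin.  All analyses share a single non-overlapping 10 s epoch
grid built from that timeline.

Time is in seconds throughout; channel values are in physical units fixed
per channel kind (mV, m/s^2, uS, degC).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

SPECIES = ("human", "canine")
ROLES = ("owner", "friend", "stranger")
CHANNEL_KINDS = ("ECG", "ACC3", "EDA", "ST")
KIND_UNITS = {"ECG": "mV", "ACC3": "m/s^2", "EDA": "uS", "ST": "degC"}
KIND_NCOLS = {"ECG": 1, "ACC3": 3, "EDA": 1, "ST": 1}
PLACEMENTS = ("chest", "harness", "left_wrist", "right_wrist", "collar")
SUBSESSION_LABELS = ("BASE", "INT1", "NEU1", "INT2", "NEU2", "POST")
INTERACTION_LABELS = ("INT1", "INT2")
#: Pooled groups used for session-type comparisons (ALL-NEU vs ALL-INT).
NEUTRAL_TYPE = ("BASE", "NEU1", "NEU2", "POST")

EPOCH_LEN_S = 10.0


class ValidationError(ValueError):
    """A session component violates a structural invariant."""


@dataclass(frozen=True)
class Subject:
    id: str
    species: str
    role: str | None = None  # meaningful for humans only

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        if self.role is not None and self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class Subsession:
    label: str
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.label not in SUBSESSION_LABELS:
            raise ValidationError(f"unknown subsession label {self.label!r}")
        if not self.t_end > self.t_start:
            raise ValidationError(
                f"subsession {self.label}: t_end {self.t_end} <= t_start {self.t_start}"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def is_interaction(self) -> bool:
        return self.label in INTERACTION_LABELS

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


class SubsessionTimeline:
    """Ordered, non-overlapping subsessions defining the session clock."""

    def __init__(self, subsessions: Sequence[Subsession]):
        subs = list(subsessions)
        if not subs:
            raise ValidationError("timeline is empty")
        for a, b in zip(subs, subs[1:]):
            if b.t_start < a.t_end - 1e-9:
                raise ValidationError(
                    f"subsessions {a.label} and {b.label} overlap or are out of order"
                )
        self.subsessions = subs

    @classmethod
    def from_plan(cls, plan: Sequence[tuple[str, float]], origin: float = 0.0
                  ) -> "SubsessionTimeline":
        """Build a contiguous timeline from (label, duration_s) pairs."""
        t = float(origin)
        subs = []
        for label, dur in plan:
            subs.append(Subsession(label, t, t + float(dur)))
            t += float(dur)
        return cls(subs)

    @property
    def origin(self) -> float:
        return self.subsessions[0].t_start

    @property
    def t_end(self) -> float:
        return self.subsessions[-1].t_end

    @property
    def duration(self) -> float:
        return self.t_end - self.origin

    def interactions(self) -> list[Subsession]:
        return [s for s in self.subsessions if s.is_interaction]

    def __iter__(self) -> Iterator[Subsession]:
        return iter(self.subsessions)

    def __len__(self) -> int:
        return len(self.subsessions)

    def __getitem__(self, label: str) -> Subsession:
        for s in self.subsessions:
            if s.label == label:
                return s
        raise KeyError(label)

    def __eq__(self, other) -> bool:
        return isinstance(other, SubsessionTimeline) and \
            self.subsessions == other.subsessions


@dataclass
class Channel:
    """One sensor channel: a time-stamped 1- or 3-column series.

    Missing/masked samples are NaN.  A canine channel that is absent for a
    whole subsession (dog out of the room) is NaN over that span, keeping a
    single uniform time base per channel.
    """

    subject_id: str
    kind: str
    placement: str
    fs: float
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in CHANNEL_KINDS:
            raise ValidationError(f"unknown channel kind {self.kind!r}")
        if self.placement not in PLACEMENTS:
            raise ValidationError(f"unknown placement {self.placement!r}")
        ncols = KIND_NCOLS[self.kind]
        if ncols == 1 and self.values.ndim != 1:
            raise ValidationError(f"{self.kind} channel must be 1-column")
        if ncols == 3 and (self.values.ndim != 2 or self.values.shape[1] != 3):
            raise ValidationError(f"{self.kind} channel must have 3 columns")
        if len(self.t) != len(self.values):
            raise ValidationError("time and value lengths differ")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            bad = np.nonzero(dt <= 0)[0]
            if bad.size:
                raise ValidationError(
                    f"non-monotone time at row {bad[0] + 1} "
                    f"(t={self.t[bad[0] + 1]:.6f} after t={self.t[bad[0]]:.6f})"
                )
            span = self.t[-1] - self.t[0]
            expected = (len(self.t) - 1) / self.fs
            if span > 1.0 and abs(expected - span) > 0.01 * span:
                raise ValidationError(
                    f"{self.kind}@{self.placement}: sample count inconsistent with "
                    f"fs={self.fs} over span {span:.1f} s"
                )

    @property
    def units(self) -> str:
        return KIND_UNITS[self.kind]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) else 0.0

    def copy_with(self, values: np.ndarray | None = None,
                  t: np.ndarray | None = None) -> "Channel":
        return replace(
            self,
            t=self.t.copy() if t is None else t,
            values=self.values.copy() if values is None else values,
        )


@dataclass
class BehaviorStream:
    """Per-second behavior labels from one rater for one subject.

    codes[k] labels second [origin + k, origin + k + 1); values are
    -1 (negative), 0 (neutral), +1 (positive) or NaN (subject off screen).
    """

    rater: str
    subject_id: str
    codes: np.ndarray
    origin: float = 0.0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        ok = np.isnan(self.codes) | np.isin(self.codes, (-1.0, 0.0, 1.0))
        if not ok.all():
            bad = np.nonzero(~ok)[0][0]
            raise ValidationError(
                f"behavior code {self.codes[bad]!r} at second {bad} is not in "
                "{-1, 0, 1, offscreen}"
            )


@dataclass
class SessionBundle:
    """Everything recorded on one experimental day."""

    session_id: str
    subjects: list[Subject]
    timeline: SubsessionTimeline
    channels: list[Channel]
    behavior: list[BehaviorStream] = field(default_factory=list)
    surveys: pd.DataFrame | None = None  # columns: subject, timepoint, scale, value

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.id == subject_id:
                return s
        raise KeyError(subject_id)

    def subjects_of(self, species: str) -> list[Subject]:
        return [s for s in self.subjects if s.species == species]

    def channel(self, subject_id: str, kind: str,
                placement: str | None = None) -> Channel:
        hits = [c for c in self.channels
                if c.subject_id == subject_id and c.kind == kind
                and (placement is None or c.placement == placement)]
        if not hits:
            raise KeyError((subject_id, kind, placement))
        if len(hits) > 1 and placement is None:
            raise KeyError(
                f"multiple {kind} channels for {subject_id}; specify placement"
            )
        return hits[0]

    def behavior_streams(self, subject_id: str | None = None,
                         rater: str | None = None) -> list[BehaviorStream]:
        return [b for b in self.behavior
                if (subject_id is None or b.subject_id == subject_id)
                and (rater is None or b.rater == rater)]

    def validate(self) -> None:
        """Check cross-component invariants, raising ValidationError."""
        ids = {s.id for s in self.subjects}
        for ch in self.channels:
            if ch.subject_id not in ids:
                raise ValidationError(f"channel subject {ch.subject_id!r} unknown")
            if len(ch.t) and (ch.t[0] < self.timeline.origin - 1.0 / ch.fs - 1e-6
                              or ch.t[-1] > self.timeline.t_end + 1.0 / ch.fs + 1e-6):
                raise ValidationError(
                    f"channel {ch.kind}@{ch.placement} of {ch.subject_id} extends "
                    "outside the session timeline"
                )
        for b in self.behavior:
            if b.subject_id not in ids:
                raise ValidationError(f"behavior subject {b.subject_id!r} unknown")


@dataclass
class EpochGrid:
    """Half-open 10 s epochs [t0, t0+10) that never straddle subsessions.

    ``frame`` columns: subsession (label), epoch (global 0-based index),
    epoch_in_sub, t0, t1.  A trailing partial interval shorter than
    ``epoch_len`` is dropped so every epoch has identical support.
    """

    epoch_len: float
    frame: pd.DataFrame

    def epochs_of(self, label: str) -> pd.DataFrame:
        return self.frame[self.frame["subsession"] == label]

    def __len__(self) -> int:
        return len(self.frame)


def build_epoch_grid(timeline: SubsessionTimeline,
                     epoch_len: float = EPOCH_LEN_S) -> EpochGrid:
    """Partition each subsession into floor(duration/epoch_len) epochs."""
    rows = []
    k = 0
    for sub in timeline:
        n = int(np.floor(sub.duration / epoch_len + 1e-9))
        if n == 0:
            warnings.warn(
                f"subsession {sub.label} ({sub.duration:.1f} s) is shorter than "
                f"one {epoch_len:.0f} s epoch; it contributes no epochs",
                stacklevel=2,
            )
        for j in range(n):
            t0 = sub.t_start + j * epoch_len
            rows.append((sub.label, k, j, t0, t0 + epoch_len))
            k += 1
    frame = pd.DataFrame(rows, columns=["subsession", "epoch", "epoch_in_sub",
                                        "t0", "t1"])
    return EpochGrid(epoch_len=epoch_len, frame=frame)
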