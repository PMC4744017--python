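"""Shared data model: face layouts, fixations, trials, datasets.

All geometry lives in a single coordinate frame: degrees of visual angle,
origin at the top-left corner of the stimulus image, x increasing rightward
and y increasing downward.  Rectangles are half-open — a point belongs to a
rectangle iff ``x0 <= x < x1 and y0 <= y < y1`` — so a shared bisection edge
(e.g. between the two nose halves) assigns every point to exactly one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

RACES = ("caucasian", "african", "chinese")
START_POSITIONS = ("left", "right", "up", "down")
PHASES = ("study", "test")

#: the seven rectangular regions drawn on every face
AOI_NAMES = (
    "left_eye",
    "bridge",
    "right_eye",
    "nose_left",
    "nose_right",
    "mouth_left",
    "mouth_right",
)

#: the six groups used for counting (nose and mouth halves pooled)
AOI_GROUPS = ("left_eye", "bridge", "right_eye", "nose", "mouth", "other")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in degrees, half-open on its far edges."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        for name in ("x0", "y0", "x1", "y1"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValidationError(
                f"degenerate rectangle ({self.x0}, {self.y0}, {self.x1}, {self.y1})"
            )

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and other.x1 <= self.x1
            and other.y1 <= self.y1
        )

    def overlaps(self, other: "Rect") -> bool:
        return (
            self.x0 < other.x1
            and other.x0 < self.x1
            and self.y0 < other.y1
            and other.y0 < self.y1
        )

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0


@dataclass(frozen=True)
class FaceLayout:
    """Per-face geometry: the image frame and the seven feature AOIs."""

    face_id: str
    race: str
    frame: Rect
    aois: dict[str, Rect]

    def __post_init__(self) -> None:
        if self.race not in RACES:
            raise ValidationError(f"unknown race {self.race!r}")
        missing = set(AOI_NAMES) - set(self.aois)
        if missing:
            raise ValidationError(
                f"face {self.face_id!r} missing AOIs: {sorted(missing)}"
            )
        extra = set(self.aois) - set(AOI_NAMES)
        if extra:
            raise ValidationError(f"face {self.face_id!r} unknown AOIs: {sorted(extra)}")
        for name, rect in self.aois.items():
            if not self.frame.contains_rect(rect):
                raise ValidationError(
                    f"face {self.face_id!r}: AOI {name!r} not inside frame"
                )
        names = list(AOI_NAMES)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if self.aois[a].overlaps(self.aois[b]):
                    raise ValidationError(
                        f"face {self.face_id!r}: AOIs {a!r} and {b!r} overlap"
                    )
        for left, right in (("nose_left", "nose_right"), ("mouth_left", "mouth_right")):
            a, b = self.aois[left], self.aois[right]
            if not (
                abs(a.x1 - b.x0) < 1e-9
                and abs(a.y0 - b.y0) < 1e-9
                and abs(a.y1 - b.y1) < 1e-9
            ):
                raise ValidationError(
                    f"face {self.face_id!r}: {left}/{right} do not share a bisection edge"
                )

    def aoi_center(self, name: str) -> tuple[float, float]:
        return self.aois[name].center

    def group_rect(self, group: str) -> Rect:
        """Bounding rectangle of a pooled AOI group (nose, mouth) or single AOI."""
        if group == "nose":
            a, b = self.aois["nose_left"], self.aois["nose_right"]
        elif group == "mouth":
            a, b = self.aois["mouth_left"], self.aois["mouth_right"]
        else:
            return self.aois[group]
        return Rect(min(a.x0, b.x0), min(a.y0, b.y0), max(a.x1, b.x1), max(a.y1, b.y1))

    def mirrored(self) -> "FaceLayout":
        """Reflect the layout across the vertical midline of the image frame."""
        cx = self.frame.x0 + self.frame.x1

        def flip(r: Rect) -> Rect:
            return Rect(cx - r.x1, r.y0, cx - r.x0, r.y1)

        swap = {
            "left_eye": "right_eye",
            "right_eye": "left_eye",
            "bridge": "bridge",
            "nose_left": "nose_right",
            "nose_right": "nose_left",
            "mouth_left": "mouth_right",
            "mouth_right": "mouth_left",
        }
        return FaceLayout(
            face_id=self.face_id,
            race=self.race,
            frame=flip(self.frame),
            aois={swap[name]: flip(rect) for name, rect in self.aois.items()},
        )


@dataclass(frozen=True)
class FixationRecord:
    participant_id: str
    phase: str
    trial_index: int
    face_id: str
    race: str
    start_position: str
    ordinal: int
    x: float
    y: float
    duration: float  # ms

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValidationError(f"unknown phase {self.phase!r}")
        if self.race not in RACES:
            raise ValidationError(f"unknown race {self.race!r}")
        if self.start_position not in START_POSITIONS:
            raise ValidationError(f"unknown start position {self.start_position!r}")
        if self.trial_index < 1:
            raise ValidationError("trial_index must be >= 1")
        if self.ordinal < 1:
            raise ValidationError("ordinal must be >= 1")
        if not self.duration > 0:
            raise ValidationError("duration must be > 0 ms")


@dataclass(frozen=True)
class Response:
    judgment: str  # "old" | "new"
    rt: float  # ms from stimulus onset

    def __post_init__(self) -> None:
        if self.judgment not in ("old", "new"):
            raise ValidationError(f"unknown judgment {self.judgment!r}")
        if not self.rt > 0:
            raise ValidationError("rt must be > 0 ms")


@dataclass(frozen=True)
class Trial:
    participant_id: str
    phase: str
    trial_index: int
    face_id: str
    race: str
    start_position: str
    was_studied: bool
    fixations: tuple[FixationRecord, ...]
    response: Optional[Response] = None

    def __post_init__(self) -> None:
        if self.phase == "test" and self.response is None:
            raise ValidationError("test trial without a response")
        if self.phase == "study" and self.response is not None:
            raise ValidationError("study trial with a response")
        if self.phase == "study" and len(self.fixations) < 1:
            raise ValidationError("study trial with no fixations")
        for i, f in enumerate(self.fixations, start=1):
            if f.ordinal != i:
                raise ValidationError(
                    f"trial {self.participant_id}/{self.phase}/{self.trial_index}: "
                    f"ordinal gap (expected {i}, found {f.ordinal})"
                )
            for attr in ("participant_id", "phase", "trial_index", "face_id",
                         "race", "start_position"):
                if getattr(f, attr) != getattr(self, attr):
                    raise ValidationError(
                        f"fixation {attr} disagrees with its trial metadata"
                    )


@dataclass
class Dataset:
    """A full experiment: shared face layouts plus every trial of every participant."""

    layouts: list[FaceLayout]
    trials: list[Trial]

    def __post_init__(self) -> None:
        known = {lay.face_id for lay in self.layouts}
        if len(known) != len(self.layouts):
            raise ValidationError("duplicate face_id among layouts")
        for t in self.trials:
            if t.face_id not in known:
                raise ValidationError(f"trial references unknown face {t.face_id!r}")

    @property
    def layout_by_face(self) -> dict[str, FaceLayout]:
        return {lay.face_id: lay for lay in self.layouts}

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.participant_id, None)
        return list(seen)

    def select(
        self,
        phase: str | None = None,
        race: str | None = None,
        start_position: str | None = None,
        participant_id: str | None = None,
    ) -> list[Trial]:
        out = []
        for t in self.trials:
            if phase is not None and t.phase != phase:
                continue
            if race is not None and t.race != race:
                continue
            if start_position is not None and t.start_position != start_position:
                continue
            if participant_id is not None and t.participant_id != participant_id:
                continue
            out.append(t)
        return out

    def design_counts(self) -> dict[tuple[str, str, str, str], int]:
        """Trial counts per (participant, phase, race, start_position)."""
        counts: dict[tuple[str, str, str, str], int] = {}
        for t in self.trials:
            key = (t.participant_id, t.phase, t.race, t.start_position)
            counts[key] = counts.get(key, 0) + 1
        return counts


# --- analysis windows ------------------------------------------------------

#: ordinal window used for all study-phase spatial analyses: the first five
#: fixations, with the first excluded (its duration is reliably shorter and
#: carries little identity information).
STUDY_WINDOW = (2, 5)
STUDY_WINDOW_SIZE = STUDY_WINDOW[1] - STUDY_WINDOW[0] + 1  # 4 fixations / trial

TEST_DISPLAY_MS = 1000.0


def window_fixations(
    trial: Trial,
    phase_rule: str | None = None,
    *,
    include_first: bool = False,
) -> list[FixationRecord]:
    """Select the analyzed fixations of a trial.

    ``phase_rule`` defaults to the trial's own phase.  The study rule keeps
    ordinals 2..5 (1..5 with ``include_first``); the test rule keeps every
    fixation whose onset — the cumulative duration of the preceding fixations —
    falls within the 1 s display.
    """
    rule = phase_rule or trial.phase
    if rule == "study":
        lo = 1 if include_first else STUDY_WINDOW[0]
        return [f for f in trial.fixations if lo <= f.ordinal <= STUDY_WINDOW[1]]
    if rule == "test":
        out = []
        onset = 0.0
        for f in trial.fixations:
            if onset < TEST_DISPLAY_MS:
                out.append(f)
            onset += f.duration
        return out
    raise ValueError(f"unknown phase rule {rule!r}")
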