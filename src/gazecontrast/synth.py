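"""Synthetic fixation datasets with the study's design and effect structure.

The generative model is deliberately minimal: each analyzed fixation first
draws an AOI-group *label* from a race-specific mixture over
{left_eye, bridge, right_eye, nose, mouth, other}, then a location —
Gaussian scatter around the feature center, or uniform over the non-feature
part of the image for "other".  Early fixations are additionally tilted
toward the pre-stimulus start side.  Race acts only on the mixture weights
and start position only on the tilt, so the two influences are independent
by construction.  Old/new behavior is Bernoulli per trial with race-specific
hit and false-alarm probabilities.

Default parameters encode the emulated study: 30 participants, 3 face races
x 4 start positions, 16 study trials per race (48 study, 96 test trials),
forehead-scale face template of about 10 degrees, subtle own-race eye bias
and other-race nose/mouth bias (paired effect sizes around 0.2), a
recognition deficit for Chinese faces (paired d' effect near 0.9) and a
criterion ordering Caucasian > African > Chinese.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    AOI_GROUPS,
    AOI_NAMES,
    Dataset,
    FaceLayout,
    FixationRecord,
    RACES,
    Rect,
    Response,
    START_POSITIONS,
    Trial,
    ValidationError,
)


class ConfigurationError(ValueError):
    """Raised when generator parameters cannot realize a balanced design."""


class GeometryError(ValueError):
    """Raised when start-point geometry is degenerate (collinear centers)."""


# --- parameters ------------------------------------------------------------

def _default_feature_weights() -> dict[str, dict[str, float]]:
    # own-race (Caucasian observers): eye bias; other races: nose/mouth bias.
    return {
        "caucasian": {"left_eye": 0.225, "bridge": 0.145, "right_eye": 0.205,
                      "nose": 0.155, "mouth": 0.125, "other": 0.145},
        "african": {"left_eye": 0.219, "bridge": 0.145, "right_eye": 0.199,
                    "nose": 0.163, "mouth": 0.133, "other": 0.141},
        "chinese": {"left_eye": 0.212, "bridge": 0.145, "right_eye": 0.192,
                    "nose": 0.165, "mouth": 0.131, "other": 0.155},
    }


def _default_behavior() -> dict[str, dict[str, float]]:
    # hit/false-alarm probabilities per race of face; with 16 old + 16 new
    # faces per race these produce d' Caucasian ~ African > Chinese and
    # criterion Caucasian > African > Chinese.
    return {
        "caucasian": {"hit_rate": 0.72, "fa_rate": 0.18},
        "african": {"hit_rate": 0.75, "fa_rate": 0.22},
        "chinese": {"hit_rate": 0.70, "fa_rate": 0.30},
    }


@dataclass
class GeneratorParams:
    n_participants: int = 30
    trials_per_race_study: int = 16
    faces_per_race: int = 32
    feature_weights: dict[str, dict[str, float]] = field(
        default_factory=_default_feature_weights
    )
    scatter_sd: float = 0.4  # deg, within-feature Gaussian scatter
    start_pull: float = 0.35  # in [0,1]; bias of early fixations to start side
    layout_jitter_sd: float = 0.3  # deg, per-face AOI-block center jitter
    behavior: dict[str, dict[str, float]] = field(default_factory=_default_behavior)
    rt_meanlog: float = math.log(900.0)  # ms; median test-phase RT
    rt_sdlog: float = 0.25
    rt_outlier_rate: float = 0.02
    n_fix_study: tuple[int, int] = (5, 9)  # inclusive uniform range
    n_fix_test: tuple[int, int] = (3, 5)
    fix_duration_meanlog: float = math.log(250.0)  # ms
    fix_duration_sdlog: float = 0.35
    include_test: bool = True
    seed: int = 0

    def validate(self) -> None:
        for race in RACES:
            w = self.feature_weights[race]
            total = sum(w[g] for g in AOI_GROUPS)
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"feature_weights[{race!r}] sum {total!r} != 1"
                )
            if any(w[g] < 0 for g in AOI_GROUPS):
                raise ConfigurationError(f"negative weight for {race!r}")
            b = self.behavior[race]
            for k in ("hit_rate", "fa_rate"):
                if not 0.0 < b[k] < 1.0:
                    raise ConfigurationError(f"behavior[{race!r}][{k}] not in (0,1)")
        if not 0.0 <= self.start_pull <= 1.0:
            raise ConfigurationError("start_pull must be in [0,1]")
        if self.trials_per_race_study % 8 != 0:
            raise ConfigurationError(
                "trials_per_race_study must be divisible by 8 (4 start positions "
                "x even per-cell count for the same/opposite start rule at test)"
            )
        if self.faces_per_race < 2 * self.trials_per_race_study:
            raise ConfigurationError(
                "faces_per_race must be >= 2 * trials_per_race_study "
                "(studied + equally many new test faces)"
            )


@dataclass(frozen=True)
class StartPoint:
    position: str
    x: float
    y: float


# --- face template and layouts ---------------------------------------------

#: hand-drawn template layout; forehead (frame) width close to the 10-degree
#: presentation scale, eyes in the upper third, nose central, mouth lower.
def template_layout(face_id: str = "template", race: str = "caucasian") -> FaceLayout:
    return FaceLayout(
        face_id=face_id,
        race=race,
        frame=Rect(0.0, 0.0, 13.0, 15.0),
        aois={
            "left_eye": Rect(2.6, 4.8, 5.3, 6.4),
            "bridge": Rect(5.3, 4.8, 7.7, 6.4),
            "right_eye": Rect(7.7, 4.8, 10.4, 6.4),
            "nose_left": Rect(4.9, 6.65, 6.5, 9.2),
            "nose_right": Rect(6.5, 6.65, 8.1, 9.2),
            "mouth_left": Rect(4.3, 9.45, 6.5, 11.3),
            "mouth_right": Rect(6.5, 9.45, 8.7, 11.3),
        },
    )


#: feature rows jittered rigidly, so within-row adjacency (bridge between the
#: eyes, bisected nose and mouth halves) survives any jitter draw
_BLOCKS = (
    ("left_eye", "bridge", "right_eye"),
    ("nose_left", "nose_right"),
    ("mouth_left", "mouth_right"),
)

#: jitter split: a shared configural offset plus an independent per-row
#: offset; the variances sum to layout_jitter_sd^2 so every AOI center is
#: marginally N(template center, layout_jitter_sd^2) while relative row
#: displacements stay small enough that overlap redraws are rare
_COMMON_FRAC = 0.87

_MAX_JITTER_RETRIES = 100


def _jitter_layout(
    base: FaceLayout, face_id: str, race: str, sd: float, rng: np.random.Generator
) -> FaceLayout:
    """Shift each feature row by a Gaussian offset (shared + per-row part),
    preserving sizes and the nose/mouth bisection edges; redraw the face on
    overlap or frame violation."""
    common_sd = sd * math.sqrt(_COMMON_FRAC)
    block_sd = sd * math.sqrt(1.0 - _COMMON_FRAC)
    for _ in range(_MAX_JITTER_RETRIES):
        common = rng.normal(0.0, common_sd, size=2)
        offsets = common + rng.normal(0.0, block_sd, size=(len(_BLOCKS), 2))
        aois = {}
        for (names, (dx, dy)) in zip(_BLOCKS, offsets):
            for name in names:
                r = base.aois[name]
                aois[name] = Rect(r.x0 + dx, r.y0 + dy, r.x1 + dx, r.y1 + dy)
        try:
            return FaceLayout(face_id=face_id, race=race, frame=base.frame, aois=aois)
        except ValidationError:
            continue
    raise ConfigurationError(
        f"could not jitter layout for {face_id!r} without AOI overlap "
        f"after {_MAX_JITTER_RETRIES} retries (layout_jitter_sd too large?)"
    )


def generate_face_layouts(params: GeneratorParams) -> list[FaceLayout]:
    """One jittered layout per face; a random half of faces is mirrored to
    scrub stimulus-side laterality, all seed-controlled."""
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    layouts: list[FaceLayout] = []
    prefixes = {"caucasian": "cau", "african": "afr", "chinese": "chi"}
    for race in RACES:
        base = template_layout(race=race)
        for i in range(params.faces_per_race):
            face_id = f"{prefixes[race]}_{i:03d}"
            if params.layout_jitter_sd > 0:
                lay = _jitter_layout(base, face_id, race, params.layout_jitter_sd, rng)
            else:
                lay = FaceLayout(
                    face_id=face_id, race=race, frame=base.frame, aois=dict(base.aois)
                )
            layouts.append(lay)
    flip = rng.permutation(len(layouts)) < len(layouts) // 2
    return [lay.mirrored() if f else lay for lay, f in zip(layouts, flip)]


# --- start-point geometry ---------------------------------------------------

def circumcenter(
    a: tuple[float, float], b: tuple[float, float], c: tuple[float, float]
) -> tuple[float, float]:
    """The point equidistant from three non-collinear points."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-12:
        raise GeometryError("feature centers are collinear; no equidistant point")
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    return (ux, uy)


def compute_start_points(layout: FaceLayout) -> dict[str, StartPoint]:
    """Pre-stimulus gaze locations for the four start positions.

    Left/right points are equidistant from the nearest eye, half-nose and
    half-mouth centers (the circumcenter of that triangle).  The up point
    lies on the perpendicular bisector of the two eye centers, above them;
    the down point below the two mouth-half centers; both at a distance equal
    to the mean of the left/right equidistances.
    """
    le = layout.aoi_center("left_eye")
    re = layout.aoi_center("right_eye")
    nl = layout.aoi_center("nose_left")
    nr = layout.aoi_center("nose_right")
    ml = layout.aoi_center("mouth_left")
    mr = layout.aoi_center("mouth_right")

    left_pt = circumcenter(le, nl, ml)
    right_pt = circumcenter(re, nr, mr)
    r_left = math.hypot(left_pt[0] - le[0], left_pt[1] - le[1])
    r_right = math.hypot(right_pt[0] - re[0], right_pt[1] - re[1])
    d = (r_left + r_right) / 2.0

    def bisector_point(p: tuple, q: tuple, distance: float, below: bool) -> tuple:
        mx, my = (p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0
        half = math.hypot(q[0] - p[0], q[1] - p[1]) / 2.0
        if distance < half:
            raise GeometryError(
                "required equidistance is smaller than half the feature separation"
            )
        off = math.sqrt(distance**2 - half**2)
        # unit perpendicular to p->q; y grows downward, so "above" is -y
        dx, dy = q[0] - p[0], q[1] - p[1]
        norm = math.hypot(dx, dy)
        px, py = -dy / norm, dx / norm
        if (py > 0) != below:
            px, py = -px, -py
        return (mx + off * px, my + off * py)

    up_pt = bisector_point(le, re, d, below=False)
    down_pt = bisector_point(ml, mr, d, below=True)
    return {
        "left": StartPoint("left", *left_pt),
        "right": StartPoint("right", *right_pt),
        "up": StartPoint("up", *up_pt),
        "down": StartPoint("down", *down_pt),
    }


# --- fixation generation ----------------------------------------------------

_SIDE_GROUPS = {
    "left": ("left_eye",),
    "right": ("right_eye",),
    "up": ("left_eye", "bridge", "right_eye"),
    "down": ("mouth",),
}

_MAX_OTHER_RETRIES = 200


def _feature_center(layout: FaceLayout, group: str) -> tuple[float, float]:
    return layout.group_rect(group).center


def _face_center(layout: FaceLayout) -> tuple[float, float]:
    cs = [layout.aois[name].center for name in AOI_NAMES]
    return (sum(c[0] for c in cs) / len(cs), sum(c[1] for c in cs) / len(cs))


def _sample_other(layout: FaceLayout, rng: np.random.Generator) -> tuple[float, float]:
    """Uniform over the frame excluding the internal-feature AOIs."""
    fr = layout.frame
    for _ in range(_MAX_OTHER_RETRIES):
        x = rng.uniform(fr.x0, fr.x1)
        y = rng.uniform(fr.y0, fr.y1)
        if not any(layout.aois[name].contains(x, y) for name in AOI_NAMES):
            return (x, y)
    return (fr.x0 + 0.05 * fr.width, fr.y0 + 0.05 * fr.height)  # forehead corner


def _tilted_weights(
    weights: dict[str, float], start_position: str, tilt: float
) -> np.ndarray:
    w = np.array([weights[g] for g in AOI_GROUPS], dtype=float)
    if tilt > 0:
        boost = np.ones(len(AOI_GROUPS))
        for g in _SIDE_GROUPS[start_position]:
            boost[AOI_GROUPS.index(g)] += tilt
        w = w * boost
        w = w / w.sum()
    return w


def generate_trial_fixations(
    layout: FaceLayout,
    start: StartPoint,
    race: str,
    n_fix: int,
    params: GeneratorParams,
    rng: np.random.Generator,
    *,
    participant_id: str = "p000",
    phase: str = "study",
    trial_index: int = 1,
    was_studied: bool = False,
    response: Response | None = None,
) -> Trial:
    """One trial's fixation sequence.

    Fixation 1 lands near the face center, displaced toward the start side by
    ``start_pull``.  Every later fixation draws an AOI-group label from the
    race's mixture (early ordinals tilted toward start-side groups with a
    geometrically decaying strength) and scatters around the feature center.
    """
    if n_fix < 1:
        raise ConfigurationError("n_fix must be >= 1")
    fc = _face_center(layout)
    fixations = []
    for ordinal in range(1, n_fix + 1):
        if ordinal == 1:
            pull = params.start_pull * 0.5
            x = fc[0] + pull * (start.x - fc[0]) + rng.normal(0, params.scatter_sd)
            y = fc[1] + pull * (start.y - fc[1]) + rng.normal(0, params.scatter_sd)
        else:
            tilt = params.start_pull * 0.5 ** (ordinal - 2)
            w = _tilted_weights(params.feature_weights[race], start.position, tilt)
            group = AOI_GROUPS[rng.choice(len(AOI_GROUPS), p=w)]
            if group == "other":
                x, y = _sample_other(layout, rng)
            else:
                cx, cy = _feature_center(layout, group)
                x = cx + rng.normal(0, params.scatter_sd)
                y = cy + rng.normal(0, params.scatter_sd)
        duration = float(
            rng.lognormal(params.fix_duration_meanlog, params.fix_duration_sdlog)
        )
        fixations.append(
            FixationRecord(
                participant_id=participant_id,
                phase=phase,
                trial_index=trial_index,
                face_id=layout.face_id,
                race=race,
                start_position=start.position,
                ordinal=ordinal,
                x=float(x),
                y=float(y),
                duration=duration,
            )
        )
    return Trial(
        participant_id=participant_id,
        phase=phase,
        trial_index=trial_index,
        face_id=layout.face_id,
        race=race,
        start_position=start.position,
        was_studied=was_studied,
        fixations=tuple(fixations),
        response=response,
    )


def generate_responses(
    race: str, was_studied: bool, params: GeneratorParams, rng: np.random.Generator
) -> Response:
    """Old/new judgment and RT for one test trial."""
    b = params.behavior[race]
    p_old = b["hit_rate"] if was_studied else b["fa_rate"]
    judgment = "old" if rng.random() < p_old else "new"
    rt = float(rng.lognormal(params.rt_meanlog, params.rt_sdlog))
    if rng.random() < params.rt_outlier_rate:
        rt *= rng.uniform(3.0, 6.0)
    return Response(judgment=judgment, rt=rt)


# --- whole-dataset generation -----------------------------------------------

_OPPOSITE = {"left": "right", "right": "left", "up": "down", "down": "up"}


def generate_dataset(params: GeneratorParams | None = None) -> Dataset:
    """A full balanced dataset, deterministic given ``params.seed``.

    Per participant: ``3 * trials_per_race_study`` self-paced study trials
    (per race, equally many per start position), then — if ``include_test`` —
    twice as many 1 s test trials: every studied face plus an equal number of
    new faces, half of the studied faces keeping their study start position
    and half switching to the opposite side.
    """
    params = params or GeneratorParams()
    params.validate()
    layouts = generate_face_layouts(params)
    by_race: dict[str, list[FaceLayout]] = {race: [] for race in RACES}
    for lay in layouts:
        by_race[lay.race].append(lay)
    start_points = {lay.face_id: compute_start_points(lay) for lay in layouts}
    layout_of = {lay.face_id: lay for lay in layouts}

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
    per_cell = params.trials_per_race_study // 4
    trials: list[Trial] = []

    for p in range(params.n_participants):
        pid = f"p{p:03d}"
        # study assignment: faces and balanced start positions per race
        study_plan: list[tuple[str, str]] = []  # (face_id, start_position)
        test_old_plan: list[tuple[str, str]] = []
        test_new_plan: list[tuple[str, str]] = []
        for race in RACES:
            faces = [lay.face_id for lay in by_race[race]]
            chosen = list(rng.choice(faces, size=2 * params.trials_per_race_study,
                                     replace=False))
            studied = chosen[: params.trials_per_race_study]
            new = chosen[params.trials_per_race_study :]
            starts = [sp for sp in START_POSITIONS for _ in range(per_cell)]
            starts = list(rng.permutation(starts))
            for face_id, sp in zip(studied, starts):
                study_plan.append((face_id, sp))
            # same/opposite split: within each start cell, half keep, half flip
            by_start: dict[str, list[str]] = {sp: [] for sp in START_POSITIONS}
            for face_id, sp in zip(studied, starts):
                by_start[sp].append(face_id)
            for sp, cell_faces in by_start.items():
                order = rng.permutation(len(cell_faces))
                for j, idx in enumerate(order):
                    test_sp = sp if j < len(cell_faces) // 2 else _OPPOSITE[sp]
                    test_old_plan.append((cell_faces[idx], test_sp))
            new_starts = [sp for sp in START_POSITIONS for _ in range(per_cell)]
            new_starts = list(rng.permutation(new_starts))
            for face_id, sp in zip(new, new_starts):
                test_new_plan.append((face_id, sp))

        order = rng.permutation(len(study_plan))
        for trial_index, idx in enumerate(order, start=1):
            face_id, sp = study_plan[idx]
            lay = layout_of[face_id]
            n_fix = int(rng.integers(params.n_fix_study[0], params.n_fix_study[1] + 1))
            trials.append(
                generate_trial_fixations(
                    lay, start_points[face_id][sp], lay.race, n_fix, params, rng,
                    participant_id=pid, phase="study", trial_index=trial_index,
                )
            )

        if params.include_test:
            test_plan = [(fid, sp, True) for fid, sp in test_old_plan] + [
                (fid, sp, False) for fid, sp in test_new_plan
            ]
            order = rng.permutation(len(test_plan))
            for trial_index, idx in enumerate(order, start=1):
                face_id, sp, was_studied = test_plan[idx]
                lay = layout_of[face_id]
                response = generate_responses(lay.race, was_studied, params, rng)
                n_fix = int(
                    rng.integers(params.n_fix_test[0], params.n_fix_test[1] + 1)
                )
                trials.append(
                    generate_trial_fixations(
                        lay, start_points[face_id][sp], lay.race, n_fix, params, rng,
                        participant_id=pid, phase="test", trial_index=trial_index,
                        was_studied=was_studied, response=response,
                    )
                )

    return Dataset(layouts=layouts, trials=trials)
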