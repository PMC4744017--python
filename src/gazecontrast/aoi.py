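"""AOI assignment, relative fixation frequencies, and planned paired contrasts.

A fixation is pooled into one of six groups — left_eye, bridge, right_eye,
nose (both halves), mouth (both halves), other (anywhere else, including
outside the image frame).  Relative frequency is the number of actual
fixations in a group divided by the total number of *possible* fixations of
the condition: for the study phase that denominator is design-determined
(trials x 4 in-window ordinals, e.g. 16 trials x 4 = 64), for the 1 s test
phase it is the realized number of in-window fixations per trial, summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

from .behavior import hedges_g_paired
from .model import (
    AOI_GROUPS,
    AOI_NAMES,
    Dataset,
    FaceLayout,
    FixationRecord,
    RACES,
    STUDY_WINDOW_SIZE,
    window_fixations,
)

_GROUP_OF = {
    "left_eye": "left_eye",
    "bridge": "bridge",
    "right_eye": "right_eye",
    "nose_left": "nose",
    "nose_right": "nose",
    "mouth_left": "mouth",
    "mouth_right": "mouth",
}


def assign_fixation(f: FixationRecord, layout: FaceLayout) -> str:
    """Half-open rectangle membership; at most one AOI can match."""
    if layout.face_id != f.face_id:
        raise ValueError(
            f"layout {layout.face_id!r} does not match fixation face {f.face_id!r}"
        )
    for name in AOI_NAMES:
        if layout.aois[name].contains(f.x, f.y):
            return _GROUP_OF[name]
    return "other"


def relative_frequencies(
    ds: Dataset,
    phase: str,
    pool_start: bool = True,
    include_first: bool = False,
    fixed_test_window: int | None = None,
) -> pd.DataFrame:
    """Long-format relative-frequency table.

    One row per participant x race (x start position unless ``pool_start``)
    x AOI group, with the group's relative frequency and the condition's
    possible-fixation denominator.  ``fixed_test_window`` switches the test
    phase from realized to fixed per-trial possible counts.
    """
    layouts = ds.layout_by_face
    start_levels = [None] if pool_start else list(ds_start_positions(ds))
    rows = []
    for pid in ds.participants:
        for race in RACES:
            for sp in start_levels:
                trials = ds.select(
                    phase=phase, race=race, participant_id=pid, start_position=sp
                )
                if not trials:
                    continue
                if phase == "study":
                    per_trial = STUDY_WINDOW_SIZE + (1 if include_first else 0)
                    denominator = len(trials) * per_trial
                elif fixed_test_window is not None:
                    denominator = len(trials) * fixed_test_window
                else:
                    denominator = sum(
                        len(window_fixations(t, "test")) for t in trials
                    )
                counts = {g: 0 for g in AOI_GROUPS}
                analyzed = 0
                for t in trials:
                    for f in window_fixations(t, phase, include_first=include_first):
                        counts[assign_fixation(f, layouts[t.face_id])] += 1
                        analyzed += 1
                for g in AOI_GROUPS:
                    rows.append(
                        {
                            "participant_id": pid,
                            "phase": phase,
                            "race": race,
                            "start_position": sp or "pooled",
                            "aoi_group": g,
                            "count": counts[g],
                            "denominator": denominator,
                            "rel_freq": (
                                counts[g] / denominator if denominator else np.nan
                            ),
                            "n_analyzed": analyzed,
                        }
                    )
    return pd.DataFrame(rows)


def ds_start_positions(ds: Dataset) -> list[str]:
    seen: dict[str, None] = {}
    for t in ds.trials:
        seen.setdefault(t.start_position, None)
    return list(seen)


@dataclass(frozen=True)
class ContrastSpec:
    """A planned paired comparison on one AOI group between two conditions.

    ``tail='greater'`` tests race_a > race_b (one-tailed); 'less' and
    'two-sided' are also accepted.  ``aoi_group`` may be a single group or
    a tuple of groups whose frequencies are summed (e.g. both eyes).
    """

    label: str
    race_a: str
    race_b: str
    aoi_group: str | tuple[str, ...]
    tail: str = "greater"


@dataclass(frozen=True)
class ContrastResult:
    label: str
    aoi_group: str
    races: tuple[str, str]
    tail: str
    t: float
    df: int
    p: float
    hedges_g: float
    direction: str  # "a_greater" | "b_greater" | "tied"


#: the replication hypotheses: more eye fixations on own-race faces, more
#: nose and mouth fixations on other-race faces.
def default_contrasts(own: str = "caucasian") -> list[ContrastSpec]:
    others = [r for r in RACES if r != own]
    specs = []
    for other in others:
        for eye in ("left_eye", "right_eye"):
            specs.append(
                ContrastSpec(f"{eye}:{own}>{other}", own, other, eye, "greater")
            )
        for feat in ("nose", "mouth"):
            specs.append(
                ContrastSpec(f"{feat}:{other}>{own}", other, own, feat, "greater")
            )
    return specs


def _condition_vector(
    tbl: pd.DataFrame, race: str, group: str | tuple[str, ...]
) -> pd.Series:
    groups = (group,) if isinstance(group, str) else group
    sub = tbl[(tbl.race == race) & tbl.aoi_group.isin(groups)]
    return sub.groupby("participant_id").rel_freq.sum().sort_index()


def planned_contrasts(
    tbl: pd.DataFrame, specs: list[ContrastSpec]
) -> list[ContrastResult]:
    """Paired t-tests (with Hedges' g) for each declared contrast.

    ``tbl`` must be pooled across start positions — the paper-style workflow
    pools once the start-position and race influences prove independent.
    """
    if set(tbl.start_position.unique()) != {"pooled"}:
        raise ValueError("contrast table must be pooled across start positions")
    results = []
    for spec in specs:
        a = _condition_vector(tbl, spec.race_a, spec.aoi_group)
        b = _condition_vector(tbl, spec.race_b, spec.aoi_group)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 participants per condition")
        if not a.index.equals(b.index):
            raise ValueError("participants differ between conditions")
        diff = a.to_numpy() - b.to_numpy()
        if np.all(diff == diff[0]) and diff[0] == 0.0:
            # identical conditions: no evidence either way
            t_stat = 0.0
            p_val = 0.5 if spec.tail in ("greater", "less") else 1.0
        else:
            res = ttest_rel(a.to_numpy(), b.to_numpy(), alternative=spec.tail)
            t_stat = float(res.statistic)
            p_val = float(res.pvalue)
        g = hedges_g_paired(a.to_numpy(), b.to_numpy())
        mean_diff = float(np.mean(diff))
        direction = (
            "a_greater" if mean_diff > 0 else "b_greater" if mean_diff < 0 else "tied"
        )
        group_label = (
            spec.aoi_group
            if isinstance(spec.aoi_group, str)
            else "+".join(spec.aoi_group)
        )
        results.append(
            ContrastResult(
                label=spec.label,
                aoi_group=group_label,
                races=(spec.race_a, spec.race_b),
                tail=spec.tail,
                t=t_stat,
                df=len(a) - 1,
                p=p_val,
                hedges_g=g,
                direction=direction,
            )
        )
    return results


def contrasts_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
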