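"""Signal-detection behavior metrics for the old/new recognition test.

Discrimination is d' = z(hit rate) - z(false-alarm rate) and response bias is
the criterion c = -[z(hit rate) + z(false-alarm rate)]/2, with z the inverse
standard-normal quantile.  Reaction times more extreme than 2.5 standard
deviations from the median within each participant x condition cell are
excluded before taking the cell median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import Dataset, RACES, START_POSITIONS

RT_SD_CRITERION = 2.5


class RateError(ValueError):
    pass


def correct_rates(k_yes: int, n: int, rule: str = "clamp") -> float:
    """Turn a yes-count into a rate usable by the z transform.

    ``clamp`` maps 0 -> 1/(2n) and n -> 1 - 1/(2n), leaving interior counts
    untouched; ``loglinear`` returns (k + 0.5)/(n + 1) for every count.
    """
    if n < 1:
        raise RateError("n must be >= 1")
    if not 0 <= k_yes <= n:
        raise RateError("k_yes must be in [0, n]")
    if rule == "clamp":
        rate = k_yes / n
        if rate == 0.0:
            return 1.0 / (2 * n)
        if rate == 1.0:
            return 1.0 - 1.0 / (2 * n)
        return rate
    if rule == "loglinear":
        return (k_yes + 0.5) / (n + 1)
    raise ValueError(f"unknown correction rule {rule!r}")


def _check_rate(rate: float, name: str) -> None:
    if not 0.0 < rate < 1.0:
        raise RateError(
            f"{name} = {rate} is not strictly inside (0, 1); apply correct_rates "
            "to extreme counts first"
        )


def dprime(hit_rate: float, fa_rate: float) -> float:
    _check_rate(hit_rate, "hit_rate")
    _check_rate(fa_rate, "fa_rate")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def criterion(hit_rate: float, fa_rate: float) -> float:
    _check_rate(hit_rate, "hit_rate")
    _check_rate(fa_rate, "fa_rate")
    return float(-(norm.ppf(hit_rate) + norm.ppf(fa_rate)) / 2.0)


def filter_rts(rts: list[float]) -> dict[str, list[float]]:
    """Split RTs into kept/excluded by the 2.5-SD-from-the-median rule.

    The spread is the sample standard deviation of the *unfiltered* list;
    singleton or zero-variance lists are kept whole.
    """
    rts = list(rts)
    if len(rts) == 0:
        return {"kept": [], "excluded": []}
    if len(rts) == 1:
        return {"kept": rts, "excluded": []}
    arr = np.asarray(rts, dtype=float)
    med = float(np.median(arr))
    sd = float(np.std(arr, ddof=1))
    if sd == 0.0:
        return {"kept": rts, "excluded": []}
    keep = np.abs(arr - med) <= RT_SD_CRITERION * sd
    return {
        "kept": [r for r, k in zip(rts, keep) if k],
        "excluded": [r for r, k in zip(rts, keep) if not k],
    }


def hedges_g_paired(a, b) -> float:
    """Bias-corrected paired standardized mean difference (d_av convention).

    g = J(df) * mean(a - b) / s with s the average of sd(a) and sd(b), and
    J(df) = 1 - 3/(4 df - 1), df = n - 1.  A zero standardizer with a nonzero
    mean difference yields signed infinity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and paired")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    mean_diff = float(np.mean(a - b))
    s = (float(np.std(a, ddof=1)) + float(np.std(b, ddof=1))) / 2.0
    j = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    if s == 0.0:
        if mean_diff == 0.0:
            return 0.0
        return math.copysign(math.inf, mean_diff)
    return j * mean_diff / s


@dataclass(frozen=True)
class BehaviorSummary:
    participant_id: str
    race: str
    start_position: str  # one of the four positions, or "pooled"
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    median_rt: float
    n_rt_excluded: int


def summarize_behavior(
    ds: Dataset,
    by_start_position: bool = False,
    rate_rule: str = "clamp",
) -> pd.DataFrame:
    """Per-participant signal-detection summary of the test phase.

    One row per participant x race (x start position when requested, plus the
    pooled rows otherwise only).  RT medians are computed on correct trials
    after outlier filtering within each cell.
    """
    rows: list[BehaviorSummary] = []
    start_levels: list[str | None] = [None]
    if by_start_position:
        start_levels += list(START_POSITIONS)
    for pid in ds.participants:
        for race in RACES:
            for sp in start_levels:
                trials = ds.select(
                    phase="test", race=race, participant_id=pid, start_position=sp
                )
                if not trials:
                    continue
                hits = sum(
                    1 for t in trials if t.was_studied and t.response.judgment == "old"
                )
                misses = sum(
                    1 for t in trials if t.was_studied and t.response.judgment == "new"
                )
                fas = sum(
                    1
                    for t in trials
                    if not t.was_studied and t.response.judgment == "old"
                )
                crs = sum(
                    1
                    for t in trials
                    if not t.was_studied and t.response.judgment == "new"
                )
                hr = correct_rates(hits, hits + misses, rate_rule)
                fr = correct_rates(fas, fas + crs, rate_rule)
                correct_rts = [
                    t.response.rt
                    for t in trials
                    if (t.response.judgment == "old") == t.was_studied
                ]
                filt = filter_rts(correct_rts)
                med_rt = float(np.median(filt["kept"])) if filt["kept"] else math.nan
                rows.append(
                    BehaviorSummary(
                        participant_id=pid,
                        race=race,
                        start_position=sp or "pooled",
                        hits=hits,
                        misses=misses,
                        false_alarms=fas,
                        correct_rejections=crs,
                        hit_rate=hr,
                        fa_rate=fr,
                        dprime=dprime(hr, fr),
                        criterion=criterion(hr, fr),
                        median_rt=med_rt,
                        n_rt_excluded=len(filt["excluded"]),
                    )
                )
    return pd.DataFrame([vars(r) for r in rows])


def race_contrast_dprime(summary: pd.DataFrame, race_a: str, race_b: str) -> dict:
    """Paired comparison of pooled d' between two races of face."""
    pooled = summary[summary.start_position == "pooled"]
    a = pooled[pooled.race == race_a].sort_values("participant_id").dprime.to_numpy()
    b = pooled[pooled.race == race_b].sort_values("participant_id").dprime.to_numpy()
    from scipy.stats import ttest_rel

    res = ttest_rel(a, b)
    return {
        "races": (race_a, race_b),
        "mean_a": float(np.mean(a)),
        "mean_b": float(np.mean(b)),
        "t": float(res.statistic),
        "df": a.size - 1,
        "p_two_tailed": float(res.pvalue),
        "hedges_g": hedges_g_paired(a, b),
    }
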