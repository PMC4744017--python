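"""Monte Carlo permutation inference on fixation-density contrasts.

The null hypothesis is that the distribution of fixation locations of each
ordinal fixation (fixation 2, fixation 3, ...) is the same in the two
contrasted conditions.  Exchangeability therefore holds only within a
(participant x ordinal) cell: each resampling iteration reassigns the
(location, face-alignment) tokens of such a cell to the two condition slots
at random, preserving each condition's token count, rebuilds both
per-participant density maps, subtracts, and averages the differences across
participants.  Pixel-wise p-values count how often the resampled group
difference is at least as extreme as the observed one, on the side of the
observed sign; profile p-values apply the same count to the resampled maps
collapsed along one axis (the identical resamples are reused, not
regenerated).

Because each fixation token's pixel map never changes — only its condition
label does — the resampler precomputes one unit-mass map per token and forms
every resampled group difference as a weighted sum of token maps.  The
"matmul" backend batches this as one matrix product per chunk of iterations;
the "sum" backend reproduces, iteration by iteration, the exact floating-
point reduction order of naively re-rendering each condition, and is the
reference the fast path is checked against.

P-values use the (count + 1)/(n_iter + 1) convention so a Monte Carlo p is
never zero; the exact-enumeration oracle reports raw tail proportions.
Zero-difference pixels get p = 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from statsmodels.stats.multitest import multipletests

from .density import (
    DEFAULT_SIGMA,
    DensityMap,
    GridSpec,
    _accumulate,
    alignment_offsets,
    fixation_token_maps,
)
from .model import Dataset, FaceLayout, window_fixations


@dataclass
class PermutationConfig:
    n_iter: int = 104_000
    seed: int = 0
    backend: str = "matmul"  # "matmul" | "sum"
    chunk_size: int = 256

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.backend not in ("matmul", "sum"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class PValueMap:
    p: np.ndarray  # in [0,1]; 2-D for maps, 1-D for profiles
    tail_sign: np.ndarray  # {-1, 0, +1}, same shape
    n_iter: int
    grid: GridSpec | None = None
    axis: str | None = None  # set for profile maps


@dataclass
class SignificanceMap:
    mask: np.ndarray  # boolean, same shape as the p map
    method: str  # "uncorrected" | "fdr"
    threshold: dict
    grid: GridSpec | None = None
    analysis_mask: np.ndarray | None = None


# --- contrast tokens --------------------------------------------------------

@dataclass
class ContrastTokens:
    """Everything the resampler needs about one two-condition contrast."""

    grid: GridSpec
    sigma: float
    maps: np.ndarray  # (T, height, width) unit-mass token maps, aligned
    xs: np.ndarray  # aligned coordinates (kept for the naive-render oracle)
    ys: np.ndarray
    participant_index: np.ndarray  # (T,) int
    ordinals: np.ndarray  # (T,) int
    in_a: np.ndarray  # (T,) bool: original condition assignment
    participants: list[str]
    n_trials_a: np.ndarray  # (P,) trials per participant in condition a
    n_trials_b: np.ndarray
    cells: list[np.ndarray]  # token indices per (participant, ordinal) cell

    @property
    def n_tokens(self) -> int:
        return self.maps.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.grid.height * self.grid.width

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-token weights (alpha if assigned to a, beta if to b) in the
        across-participant mean of per-participant map differences."""
        p_count = len(self.participants)
        alpha = 1.0 / (p_count * self.n_trials_a[self.participant_index])
        beta = -1.0 / (p_count * self.n_trials_b[self.participant_index])
        return alpha, beta


def build_contrast_tokens(
    ds: Dataset,
    cond_a: dict,
    cond_b: dict,
    grid: GridSpec,
    sigma: float = DEFAULT_SIGMA,
    phase: str = "study",
) -> ContrastTokens:
    """Window, align and pre-render the fixations of a two-condition contrast.

    ``cond_a``/``cond_b`` are selector dicts (e.g. ``{"race": "caucasian"}``
    or ``{"start_position": "left"}``) applied to the study-phase trials.
    Every participant must contribute trials to both conditions.
    """
    offsets = alignment_offsets(ds.layouts)
    participants = ds.participants
    xs: list[float] = []
    ys: list[float] = []
    part_idx: list[int] = []
    ordinals: list[int] = []
    in_a: list[bool] = []
    n_trials_a = np.zeros(len(participants), dtype=int)
    n_trials_b = np.zeros(len(participants), dtype=int)
    for pi, pid in enumerate(participants):
        for is_a, cond in ((True, cond_a), (False, cond_b)):
            trials = ds.select(phase=phase, participant_id=pid, **cond)
            if not trials:
                label = "a" if is_a else "b"
                raise ValueError(
                    f"participant {pid!r} has no trials in condition {label} ({cond})"
                )
            if is_a:
                n_trials_a[pi] = len(trials)
            else:
                n_trials_b[pi] = len(trials)
            for t in trials:
                dx, dy = offsets[t.face_id]
                for f in window_fixations(t, phase):
                    xs.append(f.x + dx)
                    ys.append(f.y + dy)
                    part_idx.append(pi)
                    ordinals.append(f.ordinal)
                    in_a.append(is_a)
    xs_arr = np.array(xs)
    ys_arr = np.array(ys)
    part_arr = np.array(part_idx, dtype=int)
    ord_arr = np.array(ordinals, dtype=int)
    in_a_arr = np.array(in_a, dtype=bool)
    maps = fixation_token_maps(xs_arr, ys_arr, grid, sigma)
    cells = []
    for pi in range(len(participants)):
        for o in np.unique(ord_arr[part_arr == pi]):
            idx = np.flatnonzero((part_arr == pi) & (ord_arr == o))
            cells.append(idx)
    return ContrastTokens(
        grid=grid,
        sigma=sigma,
        maps=maps,
        xs=xs_arr,
        ys=ys_arr,
        participant_index=part_arr,
        ordinals=ord_arr,
        in_a=in_a_arr,
        participants=list(participants),
        n_trials_a=n_trials_a,
        n_trials_b=n_trials_b,
        cells=cells,
    )


def observed_difference_map(tokens: ContrastTokens) -> DensityMap:
    """Group difference map for the original condition assignment, computed
    with the reference ("sum") reduction order."""
    values = _group_difference_sum(tokens, tokens.in_a)
    return DensityMap(
        grid=tokens.grid,
        values=values,
        n_fixations=tokens.n_tokens,
        mass_in_grid=float(values.sum()),
    )


def _group_difference_sum(tokens: ContrastTokens, assign_a: np.ndarray) -> np.ndarray:
    """Per-participant (mean trial map of a) - (mean of b), then participant
    mean, using strictly sequential token accumulation (bit-identical to the
    naive render path)."""
    diffs = []
    for pi in range(len(tokens.participants)):
        mine = tokens.participant_index == pi
        map_a = _accumulate(tokens.maps[mine & assign_a]) / tokens.n_trials_a[pi]
        map_b = _accumulate(tokens.maps[mine & ~assign_a]) / tokens.n_trials_b[pi]
        diffs.append(map_a - map_b)
    return np.mean(diffs, axis=0)


# --- resampling -------------------------------------------------------------

def assignment_matrix(
    tokens: ContrastTokens, n_iter: int, seed: int
) -> np.ndarray:
    """Random condition reassignments, shape (n_iter, T) boolean (True = a).

    Each (participant x ordinal) cell is permuted independently with its own
    generator seeded from (seed, cell index), so results do not depend on
    chunking or on the order cells are processed.
    """
    T = tokens.n_tokens
    out = np.empty((n_iter, T), dtype=bool)
    for ci, idx in enumerate(tokens.cells):
        m = idx.size
        k_a = int(tokens.in_a[idx].sum())
        rng = np.random.default_rng(np.random.SeedSequence([seed, ci]))
        ranks = rng.random((n_iter, m)).argsort(axis=1)
        out[:, idx] = ranks < k_a
    return out


def resample_null_maps(
    tokens: ContrastTokens, cfg: PermutationConfig
) -> Iterator[np.ndarray]:
    """Stream of resampled group difference maps, in chunks of shape
    (k, height, width); deterministic given ``cfg.seed``."""
    assign = assignment_matrix(tokens, cfg.n_iter, cfg.seed)
    if cfg.backend == "sum":
        for i in range(cfg.n_iter):
            yield _group_difference_sum(tokens, assign[i])[None, :, :]
        return
    alpha, beta = tokens.coefficients()
    flat = tokens.maps.reshape(tokens.n_tokens, -1)
    delta = alpha - beta
    h, w = tokens.grid.height, tokens.grid.width
    for lo in range(0, cfg.n_iter, cfg.chunk_size):
        hi = min(lo + cfg.chunk_size, cfg.n_iter)
        coef = beta[None, :] + assign[lo:hi] * delta[None, :]
        yield (coef @ flat).reshape(hi - lo, h, w)


# --- p-values ---------------------------------------------------------------

def _tail_counts(
    observed: np.ndarray, chunks: Iterable[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, int]:
    """Count resamples >= / <= the observed value, element-wise."""
    ge = np.zeros(observed.shape, dtype=np.int64)
    le = np.zeros(observed.shape, dtype=np.int64)
    n = 0
    for chunk in chunks:
        ge += (chunk >= observed[None]).sum(axis=0)
        le += (chunk <= observed[None]).sum(axis=0)
        n += chunk.shape[0]
    return ge, le, n


def _pvalues_from_counts(
    observed: np.ndarray, ge: np.ndarray, le: np.ndarray, n: int, smoothed: bool
) -> tuple[np.ndarray, np.ndarray]:
    if smoothed:
        p_pos = (ge + 1) / (n + 1)
        p_neg = (le + 1) / (n + 1)
    else:
        p_pos = ge / n
        p_neg = le / n
    p = np.where(observed > 0, p_pos, np.where(observed < 0, p_neg, 1.0))
    return p, np.sign(observed).astype(np.int8)


def pixel_pvalues(
    observed: DensityMap, resamples: Iterable[np.ndarray], n_iter: int
) -> PValueMap:
    """Sign-dependent pixel-wise Monte Carlo p-values.

    A positively valued observed pixel is tested against the upper tail of
    the resampled distribution, a negative one against the lower tail; zero
    pixels get p = 1.
    """
    ge, le, n = _tail_counts(observed.values, resamples)
    if n != n_iter:
        raise ValueError(f"stream yielded {n} iterations, expected {n_iter}")
    p, sign = _pvalues_from_counts(observed.values, ge, le, n, smoothed=True)
    return PValueMap(p=p, tail_sign=sign, n_iter=n_iter, grid=observed.grid)


def collapse_stream(
    resamples: Iterable[np.ndarray], axis: str
) -> Iterator[np.ndarray]:
    """Collapse each chunk of resampled maps to profile curves."""
    np_axis = 1 if axis == "x_profile" else 2
    for chunk in resamples:
        yield chunk.sum(axis=np_axis)


def profile_pvalues(
    observed_profile: np.ndarray,
    resamples: Iterable[np.ndarray],
    axis: str,
    n_iter: int,
    grid: GridSpec | None = None,
    pre_collapsed: bool = False,
) -> PValueMap:
    """P-values along one profile axis, reusing the spatial resamples.

    ``resamples`` is the same stream the 2-D test consumed; each chunk is
    summed along the orthogonal dimension before counting (pass
    ``pre_collapsed=True`` when that collapse already happened upstream).
    """
    if axis not in ("x_profile", "y_profile"):
        raise ValueError(f"unknown profile axis {axis!r}")
    observed_profile = np.asarray(observed_profile, dtype=float)
    stream = resamples if pre_collapsed else collapse_stream(resamples, axis)
    ge, le, n = _tail_counts(observed_profile, stream)
    if n != n_iter:
        raise ValueError(f"stream yielded {n} iterations, expected {n_iter}")
    p, sign = _pvalues_from_counts(observed_profile, ge, le, n, smoothed=True)
    return PValueMap(p=p, tail_sign=sign, n_iter=n_iter, grid=grid, axis=axis)


def permutation_maps(
    tokens: ContrastTokens,
    cfg: PermutationConfig,
    profile_axes: tuple[str, ...] = ("x_profile", "y_profile"),
) -> dict[str, PValueMap]:
    """One-pass spatial + profile inference on a contrast.

    Returns ``{"map": ..., "x_profile": ..., "y_profile": ...}`` with every
    profile computed from the identical resampling iterations as the spatial
    map.
    """
    observed = observed_difference_map(tokens)
    if cfg.backend == "matmul":
        # count against the matmul-path observed values so an iteration that
        # happens to redraw the identity assignment ties with them exactly;
        # signs and exact zeros still come from the canonical observed map
        alpha, beta = tokens.coefficients()
        obs_values = (
            (beta + tokens.in_a * (alpha - beta))
            @ tokens.maps.reshape(tokens.n_tokens, -1)
        ).reshape(tokens.grid.height, tokens.grid.width)
    else:
        obs_values = observed.values
    canon_profiles = {
        "x_profile": observed.values.sum(axis=0),
        "y_profile": observed.values.sum(axis=1),
    }
    obs_profiles = {
        "x_profile": obs_values.sum(axis=0),
        "y_profile": obs_values.sum(axis=1),
    }
    ge = np.zeros_like(obs_values, dtype=np.int64)
    le = np.zeros_like(obs_values, dtype=np.int64)
    prof_ge = {a: np.zeros(obs_profiles[a].shape, dtype=np.int64) for a in profile_axes}
    prof_le = {a: np.zeros(obs_profiles[a].shape, dtype=np.int64) for a in profile_axes}
    n = 0
    for chunk in resample_null_maps(tokens, cfg):
        ge += (chunk >= obs_values[None]).sum(axis=0)
        le += (chunk <= obs_values[None]).sum(axis=0)
        for axis in profile_axes:
            np_axis = 1 if axis == "x_profile" else 2
            collapsed = chunk.sum(axis=np_axis)
            prof_ge[axis] += (collapsed >= obs_profiles[axis][None]).sum(axis=0)
            prof_le[axis] += (collapsed <= obs_profiles[axis][None]).sum(axis=0)
        n += chunk.shape[0]
    out: dict[str, PValueMap] = {}
    p, sign = _pvalues_from_counts(observed.values, ge, le, n, smoothed=True)
    out["map"] = PValueMap(p=p, tail_sign=sign, n_iter=n, grid=tokens.grid)
    for axis in profile_axes:
        p, sign = _pvalues_from_counts(
            canon_profiles[axis], prof_ge[axis], prof_le[axis], n, smoothed=True
        )
        out[axis] = PValueMap(p=p, tail_sign=sign, n_iter=n, grid=tokens.grid, axis=axis)
    out["observed"] = observed  # type: ignore[assignment]
    return out


# --- thresholding and FDR ---------------------------------------------------

def threshold_pmap(pm: PValueMap, per_tail_alpha: float) -> SignificanceMap:
    """Uncorrected thresholding at a per-tail significance level.

    The recorded metadata includes the two-tailed equivalent 2 * alpha (e.g.
    per-tail 0.01 corresponds to two-tailed 0.02; per-tail 0.025 to 0.05).
    """
    if not 0.0 < per_tail_alpha < 0.5:
        raise ValueError("per_tail_alpha must be in (0, 0.5)")
    return SignificanceMap(
        mask=pm.p < per_tail_alpha,
        method="uncorrected",
        threshold={
            "per_tail_alpha": per_tail_alpha,
            "two_tailed_equivalent": 2.0 * per_tail_alpha,
        },
        grid=pm.grid,
    )


def fdr_correct(
    pm: PValueMap, analysis_mask: np.ndarray | None = None, q: float = 0.05
) -> SignificanceMap:
    """Benjamini-Hochberg step-up over the pixels inside ``analysis_mask``.

    Pixels outside the mask are ignored by the correction and can never be
    significant — the analogue of masking out non-face pixels before FDR.
    A missing mask means all pixels participate (the profile-map rule).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if analysis_mask is None:
        analysis_mask = np.ones(pm.p.shape, dtype=bool)
    analysis_mask = np.asarray(analysis_mask, dtype=bool)
    if analysis_mask.shape != pm.p.shape:
        raise ValueError("analysis mask shape does not match p map")
    if not analysis_mask.any():
        raise ValueError("analysis mask is empty")
    reject_in, _, _, _ = multipletests(
        pm.p[analysis_mask].ravel(), alpha=q, method="fdr_bh"
    )
    mask = np.zeros(pm.p.shape, dtype=bool)
    mask[analysis_mask] = reject_in
    return SignificanceMap(
        mask=mask,
        method="fdr",
        threshold={"q": q},
        grid=pm.grid,
        analysis_mask=analysis_mask,
    )


def face_region_mask(grid: GridSpec, layouts: list[FaceLayout]) -> np.ndarray:
    """Default analysis mask: pixels whose centers fall inside the union of
    the aligned face frames."""
    offsets = alignment_offsets(layouts)
    xc = grid.x_centers[None, :]
    yc = grid.y_centers[:, None]
    mask = np.zeros((grid.height, grid.width), dtype=bool)
    for lay in layouts:
        dx, dy = offsets[lay.face_id]
        fr = lay.frame
        mask |= (
            (xc >= fr.x0 + dx)
            & (xc < fr.x1 + dx)
            & (yc >= fr.y0 + dy)
            & (yc < fr.y1 + dy)
        )
    return mask


# --- exact enumeration oracle -----------------------------------------------

MAX_ENUMERATION = 1_000_000


def count_reassignments(tokens: ContrastTokens) -> int:
    total = 1
    for idx in tokens.cells:
        m = idx.size
        k = int(tokens.in_a[idx].sum())
        total *= math.comb(m, k)
        if total > MAX_ENUMERATION:
            return total
    return total


def exact_enumeration(tokens: ContrastTokens) -> PValueMap:
    """Exhaustive within-cell reassignment test (the Monte Carlo oracle).

    Enumerates every admissible condition reassignment, computes the group
    difference map for each, and reports raw (unsmoothed) sign-dependent tail
    proportions.  The identity assignment is part of the enumeration, so no
    p-value can be below 1/N.
    """
    total = count_reassignments(tokens)
    if total > MAX_ENUMERATION:
        raise ValueError(
            f"instance admits about {total} reassignments "
            f"(> {MAX_ENUMERATION}); use the Monte Carlo test"
        )
    per_cell_choices: list[list[np.ndarray]] = []
    for idx in tokens.cells:
        k = int(tokens.in_a[idx].sum())
        choices = []
        for combo in itertools.combinations(range(idx.size), k):
            mask = np.zeros(tokens.n_tokens, dtype=bool)
            mask[idx[list(combo)]] = True
            choices.append(mask)
        per_cell_choices.append(choices)
    alpha, beta = tokens.coefficients()
    flat = tokens.maps.reshape(tokens.n_tokens, -1)
    # the observed map must go through the identical arithmetic path as the
    # enumerated maps, or float round-off breaks the >= / <= tie with itself
    obs = ((beta + tokens.in_a * (alpha - beta)) @ flat).reshape(
        tokens.grid.height, tokens.grid.width
    )
    ge = np.zeros(obs.shape, dtype=np.int64)
    le = np.zeros(obs.shape, dtype=np.int64)
    h, w = tokens.grid.height, tokens.grid.width
    batch: list[np.ndarray] = []

    def flush() -> None:
        nonlocal batch
        if not batch:
            return
        coef = np.stack(batch)
        diffs = (coef @ flat).reshape(len(batch), h, w)
        np.add(ge, (diffs >= obs[None]).sum(axis=0), out=ge)
        np.add(le, (diffs <= obs[None]).sum(axis=0), out=le)
        batch = []

    for combo in itertools.product(*per_cell_choices):
        assign = np.zeros(tokens.n_tokens, dtype=bool)
        for mask in combo:
            assign |= mask
        batch.append(beta + assign * (alpha - beta))
        if len(batch) >= 4096:
            flush()
    flush()
    p, sign = _pvalues_from_counts(obs, ge, le, total, smoothed=False)
    return PValueMap(p=p, tail_sign=sign, n_iter=total, grid=tokens.grid)
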