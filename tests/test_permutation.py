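"""Permutation inference: counting conventions, oracles, FDR, determinism."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gazecontrast.density import GridSpec, render_density
from gazecontrast.model import Dataset, FixationRecord, Trial
from gazecontrast.permutation import (
    PermutationConfig,
    PValueMap,
    assignment_matrix,
    build_contrast_tokens,
    count_reassignments,
    exact_enumeration,
    face_region_mask,
    fdr_correct,
    observed_difference_map,
    permutation_maps,
    pixel_pvalues,
    profile_pvalues,
    resample_null_maps,
    threshold_pmap,
)
from gazecontrast.synth import (
    GeneratorParams,
    compute_start_points,
    generate_trial_fixations,
    template_layout,
)

GRID = GridSpec(width=16, height=16, pixel_size=1.0, origin=(-1.5, -0.5))


def _study_trial(points, participant, trial_index, race, face_id="template"):
    fixations = tuple(
        FixationRecord(
            participant_id=participant, phase="study", trial_index=trial_index,
            face_id=face_id, race=race, start_position="left", ordinal=i + 1,
            x=x, y=y, duration=200.0,
        )
        for i, (x, y) in enumerate(points)
    )
    return Trial(
        participant_id=participant, phase="study", trial_index=trial_index,
        face_id=face_id, race=race, start_position="left", was_studied=False,
        fixations=fixations,
    )


def _two_condition_dataset(n_participants=2, n_trials=3, n_fix=4, seed=0):
    lay = template_layout()
    rng = np.random.default_rng(seed)
    trials = []
    for p in range(n_participants):
        for race in ("caucasian", "chinese"):
            for t in range(n_trials):
                pts = rng.uniform(2.0, 11.0, size=(n_fix, 2))
                trials.append(
                    _study_trial(
                        [tuple(q) for q in pts], f"p{p}", t + 1, race
                    )
                )
    return Dataset(layouts=[lay], trials=trials)


class TestCountingConvention:
    def _pm(self, observed, resamples):
        grid = GridSpec(width=observed.shape[1], height=observed.shape[0],
                        pixel_size=1.0)
        from gazecontrast.density import DensityMap

        dm = DensityMap(grid=grid, values=observed, n_fixations=1,
                        mass_in_grid=float(observed.sum()))
        return pixel_pvalues(dm, [resamples], resamples.shape[0])

    def test_observed_exceeding_all_resamples(self):
        observed = np.array([[1.0]])
        resamples = np.full((99, 1, 1), 0.5)
        pm = self._pm(observed, resamples)
        assert pm.p[0, 0] == pytest.approx(1 / 100)
        assert pm.tail_sign[0, 0] == 1

    def test_zero_difference_pixel_gets_p_one(self):
        pm = self._pm(np.array([[0.0]]), np.random.default_rng(0).normal(size=(50, 1, 1)))
        assert pm.p[0, 0] == 1.0
        assert pm.tail_sign[0, 0] == 0

    def test_negative_pixel_uses_lower_tail(self):
        observed = np.array([[-1.0]])
        resamples = np.concatenate(
            [np.full((9, 1, 1), 0.0), np.full((1, 1, 1), -2.0)]
        )
        pm = self._pm(observed, resamples)
        # one resample <= -1, so p = (1+1)/(10+1)
        assert pm.p[0, 0] == pytest.approx(2 / 11)
        assert pm.tail_sign[0, 0] == -1

    def test_tie_with_observed_counts_as_extreme(self):
        observed = np.array([[1.0]])
        resamples = np.full((9, 1, 1), 1.0)
        pm = self._pm(observed, resamples)
        assert pm.p[0, 0] == 1.0  # (9+1)/(9+1)


class TestThresholding:
    def _pm(self, p):
        p = np.asarray(p, dtype=float)
        return PValueMap(p=p, tail_sign=np.sign(0.5 - p).astype(np.int8),
                         n_iter=1000)

    def test_two_tailed_equivalents_reported(self):
        sm = threshold_pmap(self._pm([[0.5]]), 0.01)
        assert sm.threshold["two_tailed_equivalent"] == pytest.approx(0.02)
        sm = threshold_pmap(self._pm([[0.5]]), 0.025)
        assert sm.threshold["two_tailed_equivalent"] == pytest.approx(0.05)

    def test_all_p_one_gives_empty_mask(self):
        sm = threshold_pmap(self._pm(np.ones((4, 4))), 0.01)
        assert not sm.mask.any()

    def test_masks_nested_in_alpha(self):
        rng = np.random.default_rng(1)
        pm = self._pm(rng.uniform(size=(10, 10)))
        small = threshold_pmap(pm, 0.01).mask
        large = threshold_pmap(pm, 0.05).mask
        assert (small <= large).all()

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            threshold_pmap(self._pm([[0.5]]), 0.6)


def _bh_reference(pvals, q):
    """Independent step-up implementation for cross-checking."""
    m = len(pvals)
    order = np.argsort(pvals)
    sorted_p = np.asarray(pvals)[order]
    below = sorted_p <= q * (np.arange(1, m + 1) / m)
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = np.max(np.nonzero(below)[0])
        reject[order[: k + 1]] = True
    return reject


class TestFdr:
    def _pm(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return PValueMap(p=p, tail_sign=np.ones_like(p, dtype=np.int8), n_iter=1000)

    def test_worked_vector(self):
        pm = self._pm([0.01, 0.02, 0.03, 0.04, 0.2])
        sm = fdr_correct(pm, q=0.05)
        assert sm.mask.ravel().tolist() == [True, True, True, True, False]

    def test_all_ones_no_rejections(self):
        assert not fdr_correct(self._pm(np.ones(10)), q=0.05).mask.any()

    def test_single_pixel_mask(self):
        pm = self._pm([[0.01, 0.5]])
        mask = np.array([[True, False]])
        sm = fdr_correct(pm, analysis_mask=mask, q=0.05)
        assert sm.mask[0, 0] and not sm.mask[0, 1]

    def test_out_of_mask_pixels_never_significant(self):
        rng = np.random.default_rng(2)
        pm = self._pm(rng.uniform(0, 0.001, size=(6, 6)))
        mask = np.zeros((6, 6), dtype=bool)
        mask[:3] = True
        sm = fdr_correct(pm, analysis_mask=mask, q=0.05)
        assert sm.mask[:3].all() and not sm.mask[3:].any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            fdr_correct(self._pm([[0.5]]), analysis_mask=np.array([[False]]))

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_independent_step_up(self, pvals, q):
        sm = fdr_correct(self._pm(pvals), q=q)
        assert sm.mask.ravel().tolist() == _bh_reference(pvals, q).tolist()


class TestResampling:
    def test_deterministic_stream(self):
        ds = _two_condition_dataset()
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        cfg = PermutationConfig(n_iter=20, seed=5)
        a = np.concatenate(list(resample_null_maps(tok, cfg)))
        b = np.concatenate(list(resample_null_maps(tok, cfg)))
        assert np.array_equal(a, b)

    def test_chunk_size_does_not_change_results(self):
        ds = _two_condition_dataset()
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        a = np.concatenate(
            list(resample_null_maps(tok, PermutationConfig(n_iter=30, seed=5, chunk_size=7)))
        )
        b = np.concatenate(
            list(resample_null_maps(tok, PermutationConfig(n_iter=30, seed=5, chunk_size=30)))
        )
        assert np.array_equal(a, b)

    def test_assignment_preserves_cell_counts(self):
        ds = _two_condition_dataset(n_trials=2)
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        assign = assignment_matrix(tok, 50, seed=3)
        for idx in tok.cells:
            expected = tok.in_a[idx].sum()
            assert (assign[:, idx].sum(axis=1) == expected).all()

    def test_fast_sum_path_bit_identical_to_naive_rerender(self):
        """For every resampled assignment, summing precomputed token maps in
        token order equals rendering the reassigned fixations from scratch,
        bit for bit."""
        ds = _two_condition_dataset(n_participants=2, n_trials=3)
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        cfg = PermutationConfig(n_iter=5, seed=9, backend="sum")
        assign = assignment_matrix(tok, cfg.n_iter, cfg.seed)
        fast = np.concatenate(list(resample_null_maps(tok, cfg)))
        zero_off = {"template": (0.0, 0.0)}
        for i in range(cfg.n_iter):
            per_participant = []
            for pi, pid in enumerate(tok.participants):
                mine = tok.participant_index == pi
                maps = {}
                for cond, sel in (("a", assign[i] & mine), ("b", ~assign[i] & mine)):
                    fx = [
                        FixationRecord(
                            participant_id=pid, phase="study", trial_index=1,
                            face_id="template", race="caucasian",
                            start_position="left", ordinal=1,
                            x=tok.xs[j], y=tok.ys[j], duration=100.0,
                        )
                        for j in np.flatnonzero(sel)
                    ]
                    maps[cond] = render_density(fx, zero_off, GRID, tok.sigma)
                per_participant.append(
                    maps["a"].values / tok.n_trials_a[pi]
                    - maps["b"].values / tok.n_trials_b[pi]
                )
            naive = np.mean(per_participant, axis=0)
            assert np.array_equal(fast[i], naive)

    def test_matmul_matches_sum_backend(self):
        ds = _two_condition_dataset()
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        s = np.concatenate(
            list(resample_null_maps(tok, PermutationConfig(n_iter=10, seed=4, backend="sum")))
        )
        m = np.concatenate(
            list(resample_null_maps(tok, PermutationConfig(n_iter=10, seed=4, backend="matmul")))
        )
        assert np.allclose(s, m, atol=1e-12)

    def test_identical_token_multisets_give_null_everywhere(self):
        """If both conditions hold the very same fixation locations in every
        cell, every resampled difference map is exactly zero and p = 1."""
        lay = template_layout()
        pts = [(4.0, 5.5), (6.5, 7.0), (5.5, 10.0)]
        trials = []
        for race in ("caucasian", "chinese"):
            trials.append(_study_trial([(1.0, 1.0)] + pts, "p0", 1, race))
            trials.append(_study_trial([(1.0, 1.0)] + pts, "p1", 1, race))
        ds = Dataset(layouts=[lay], trials=trials)
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        maps = permutation_maps(tok, PermutationConfig(n_iter=50, seed=2))
        assert (maps["map"].p == 1.0).all()
        assert not observed_difference_map(tok).values.any()

    def test_missing_condition_names_participant(self):
        lay = template_layout()
        trials = [
            _study_trial([(5.0, 5.0)] * 3, "p0", 1, "caucasian"),
            _study_trial([(5.0, 5.0)] * 3, "p0", 1, "chinese"),
            _study_trial([(5.0, 5.0)] * 3, "p1", 1, "caucasian"),
        ]
        ds = Dataset(layouts=[lay], trials=trials)
        with pytest.raises(ValueError, match="p1"):
            build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)


class TestProfileInference:
    def test_collapse_then_count_equals_precollapsed_bitwise(self):
        ds = _two_condition_dataset(seed=4)
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        cfg = PermutationConfig(n_iter=40, seed=6)
        obs = observed_difference_map(tok).values.sum(axis=0)
        a = profile_pvalues(
            obs, resample_null_maps(tok, cfg), "x_profile", cfg.n_iter, GRID
        )
        pre = (c.sum(axis=1) for c in resample_null_maps(tok, cfg))
        b = profile_pvalues(obs, pre, "x_profile", cfg.n_iter, GRID,
                            pre_collapsed=True)
        assert np.array_equal(a.p, b.p)

    def test_zero_profile_difference_gives_all_ones(self):
        obs = np.zeros(16)
        chunks = [np.random.default_rng(0).normal(size=(30, 16, 16))]
        pm = profile_pvalues(obs, chunks, "y_profile", 30, GRID)
        assert (pm.p == 1.0).all()

    def test_reused_resamples_match_onepass_profiles(self):
        ds = _two_condition_dataset(seed=7)
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        cfg = PermutationConfig(n_iter=60, seed=8, backend="sum")
        combined = permutation_maps(tok, cfg)
        for axis, np_axis in (("x_profile", 0), ("y_profile", 1)):
            obs = combined["observed"].values.sum(axis=np_axis)
            separate = profile_pvalues(
                obs, resample_null_maps(tok, cfg), axis, cfg.n_iter, GRID
            )
            assert np.array_equal(separate.p, combined[axis].p)

    def test_profile_distribution_matches_independent_rerun(self):
        """Collapsed resamples from one seed and an independent run agree in
        distribution (two-sample KS test, alpha = 0.01) at a central pixel."""
        from scipy.stats import ks_2samp

        ds = _two_condition_dataset(n_participants=3, n_trials=4, seed=10)
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        n = 10_000
        run1 = np.concatenate(
            [c.sum(axis=1) for c in resample_null_maps(tok, PermutationConfig(n_iter=n, seed=1))]
        )
        run2 = np.concatenate(
            [c.sum(axis=1) for c in resample_null_maps(tok, PermutationConfig(n_iter=n, seed=2))]
        )
        res = ks_2samp(run1[:, 8], run2[:, 8])
        assert res.pvalue > 0.01


class TestExactEnumeration:
    def test_single_cell_pair_gives_half_or_one(self):
        """One participant, one exchangeable ordinal slot with tokens {a1, b1}:
        two reassignments, so every signed pixel has p = 0.5 and zero pixels
        p = 1."""
        lay = template_layout()
        trials = [
            _study_trial([(1.0, 1.0), (4.0, 5.5)], "p0", 1, "caucasian"),
            _study_trial([(1.0, 1.0), (8.9, 5.6)], "p0", 1, "chinese"),
        ]
        ds = Dataset(layouts=[lay], trials=trials)
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        assert count_reassignments(tok) == 2
        pm = exact_enumeration(tok)
        assert set(np.unique(pm.p)) <= {0.5, 1.0}
        assert (pm.p[pm.tail_sign != 0] == 0.5).all()

    def test_condition_swap_symmetry(self, tiny_two_condition_dataset):
        g = GridSpec(width=24, height=24, pixel_size=0.7, origin=(-1.9, -1.4))
        fwd = exact_enumeration(
            build_contrast_tokens(
                tiny_two_condition_dataset, {"race": "caucasian"}, {"race": "chinese"}, g
            )
        )
        rev = exact_enumeration(
            build_contrast_tokens(
                tiny_two_condition_dataset, {"race": "chinese"}, {"race": "caucasian"}, g
            )
        )
        assert np.array_equal(fwd.p, rev.p)
        assert np.array_equal(fwd.tail_sign, -rev.tail_sign)

    def test_oversized_instance_rejected_with_estimate(self):
        ds = _two_condition_dataset(n_participants=4, n_trials=6, n_fix=5)
        tok = build_contrast_tokens(ds, {"race": "caucasian"}, {"race": "chinese"}, GRID)
        with pytest.raises(ValueError, match="reassignments"):
            exact_enumeration(tok)


class TestFaceMask:
    def test_mask_covers_face_not_margins(self, small_dataset):
        grid = GridSpec(width=64, height=64, pixel_size=0.25, origin=(-1.5, -0.5))
        mask = face_region_mask(grid, small_dataset.layouts)
        # the template frame spans x 0..13, y 0..15 before alignment
        assert mask[32, 32]  # center of the face
        assert not mask[0, 0]  # margin corner
        assert 0 < mask.sum() < mask.size
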