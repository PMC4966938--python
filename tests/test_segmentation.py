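import logging

import numpy as np
import pytest

from methet import (
    LRRMatrix,
    ProbePanel,
    SegmentationParams,
    atomic_segments,
    call_aberrations,
    multipcf,
    pcf_breakpoints,
    pcf_single,
    segment_samples,
    winsorize,
)
from methet.segmentation import impute_missing
from conftest import (
    brute_force_objective,
    exact_search_objective,
    make_profile,
    segmentation_objective,
)

RAW = SegmentationParams(normalize=False)


class TestWinsorize:
    def test_constant_vector_unchanged(self):
        y = np.full(50, 0.7)
        np.testing.assert_array_equal(winsorize(y), y)

    def test_single_spike_reduced_others_unchanged(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 1, 101)
        y[50] = 10.0
        out = winsorize(y)
        assert abs(out[50]) < 10.0
        # values already inside their clamp bounds are untouched
        untouched = np.delete(out, 50) == np.delete(y, 50)
        assert untouched.mean() > 0.9

    def test_reapplication_after_clamping(self):
        # once the spike is clamped the data sit inside the running bounds
        rng = np.random.default_rng(1)
        y = rng.normal(0, 0.1, 200)
        y[100] = 5.0
        once = winsorize(y)
        np.testing.assert_allclose(winsorize(once), once, atol=1e-12)

    def test_window_larger_than_chromosome_truncates(self):
        # window truncates to the 5 available probes; zero MAD at the edge
        # clamps the outlier to the window median
        y = np.array([0.0, 0.0, 0.0, 0.0, 5.0])
        out = winsorize(y, SegmentationParams(winsor_window=25))
        assert len(out) == 5
        assert out[4] == 0.0


class TestPCFSingle:
    def test_two_level_toy(self):
        # SSE(one segment) = 2.5 > SSE(split) 0 + gamma 0.5
        y = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], float)
        bounds = pcf_breakpoints(y[None, :], gamma=0.5, k_min=5)
        assert bounds == [(0, 5), (5, 10)]
        prof = pcf_single(y, np.arange(1, 11) * 100,
                          SegmentationParams(gamma=0.5, k_min=5, normalize=False))
        assert [s.estimate for s in prof.segments] == [0.0, 1.0]

    def test_constant_input_single_segment(self):
        y = np.full(30, 0.42)
        prof = pcf_single(y, np.arange(30) + 1, RAW)
        assert len(prof.segments) == 1
        assert prof.segments[0].estimate == pytest.approx(0.42)

    def test_huge_gamma_returns_global_mean(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 1, 40)
        prof = pcf_single(y, np.arange(40) + 1,
                          SegmentationParams(gamma=1e9, k_min=5, normalize=False))
        assert len(prof.segments) == 1
        assert prof.segments[0].estimate == pytest.approx(y.mean())

    def test_fewer_probes_than_kmin_single_segment(self, caplog):
        with caplog.at_level(logging.WARNING, logger="methet"):
            prof = pcf_single(np.array([1.0, 2.0]), np.array([10, 20]), RAW)
        assert len(prof.segments) == 1
        assert any("single segment" in r.message for r in caplog.records)

    @pytest.mark.parametrize("gamma", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("k_min", [1, 2, 5])
    def test_matches_exhaustive_enumeration(self, gamma, k_min):
        rng = np.random.default_rng(hash((gamma, k_min)) % 2**31)
        for _ in range(10):
            n = int(rng.integers(max(k_min, 3), 13))
            y = rng.normal(0, 1, n) + np.repeat(
                rng.normal(0, 1, 2), [n // 2, n - n // 2]
            )
            bounds = pcf_breakpoints(y[None, :], gamma, k_min)
            got = segmentation_objective(bounds, y, gamma)
            want = brute_force_objective(y, gamma, k_min)
            assert got == pytest.approx(want, abs=1e-9)

    def test_breakpoint_count_non_increasing_in_gamma(self):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 60) + np.repeat(rng.normal(0, 2, 4), 15)
        counts = [
            len(pcf_breakpoints(y[None, :], g, 3)) for g in (0.1, 1, 10, 100)
        ]
        assert counts == sorted(counts, reverse=True) or all(
            a >= b for a, b in zip(counts, counts[1:])
        )


class TestMultiPCF:
    def test_single_sample_reduces_to_pcf(self):
        rng = np.random.default_rng(4)
        y = rng.normal(0, 0.5, 30) + np.repeat([0.0, 1.5], 15)
        pos = np.arange(30) * 10 + 1
        panel = ProbePanel.from_positions(["1"] * 30, pos)
        matrix = LRRMatrix(panel, ["s"], y[None, :])
        joint = multipcf(matrix, RAW, apply_winsor=False)[0]
        single = pcf_single(y, pos, RAW)
        assert joint.segments == single.segments

    def test_shared_step_gives_one_shared_breakpoint(self):
        y1 = np.repeat([0.0, 1.0], [6, 6])
        y2 = np.repeat([0.0, -1.0], [6, 6])
        bounds = pcf_breakpoints(np.vstack([y1, y2]), gamma=0.5, k_min=3)
        assert bounds == [(0, 6), (6, 12)]

    def test_steps_at_different_probes_both_kept(self):
        # exhaustive check over admissible shared segmentations at small n
        y1 = np.repeat([0.0, 2.0], [4, 8])
        y2 = np.repeat([0.0, 2.0], [8, 4])
        stacked = np.vstack([y1, y2])
        bounds = pcf_breakpoints(stacked, gamma=0.1, k_min=2)
        cuts = {b[0] for b in bounds}
        assert {4, 8} <= cuts
        # optimality against enumeration of the summed objective
        from conftest import compositions

        def joint_objective(comp):
            idx, sse = 0, 0.0
            for L in comp:
                block = stacked[:, idx : idx + L]
                sse += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum()
                idx += L
            return sse + 0.1 * (len(comp) - 1)

        best = min(joint_objective(c) for c in compositions(12, 2))
        got = sum(
            ((stacked[:, i:j] - stacked[:, i:j].mean(axis=1, keepdims=True)) ** 2).sum()
            for i, j in bounds
        ) + 0.1 * (len(bounds) - 1)
        assert got == pytest.approx(best, abs=1e-9)

    def test_duplicated_identical_samples_keep_breakpoints(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 0.3, 40) + np.repeat([0.0, 1.0], 20)
        single = pcf_breakpoints(y[None, :], 2.0, 5)
        dup = pcf_breakpoints(np.vstack([y, y]), 4.0, 5)  # doubled SSE, doubled gamma
        assert single == dup


class TestAtomicSegments:
    def test_split_parent_estimates_repeat(self):
        a = make_profile("A", [1000], [0.5])
        b = make_profile("B", [400, 600], [0.1, 0.9])
        atoms = atomic_segments([a, b])
        assert atoms.n_atoms == 2
        np.testing.assert_allclose(atoms.sample_values("A"), [0.5, 0.5])
        np.testing.assert_allclose(atoms.sample_values("B"), [0.1, 0.9])
        np.testing.assert_array_equal(atoms.lengths_bp, [400, 600])

    def test_identical_segmentations_are_identity(self):
        a = make_profile("A", [300, 700], [0.1, -0.2])
        b = make_profile("B", [300, 700], [0.4, 0.0])
        atoms = atomic_segments([a, b])
        assert atoms.n_atoms == 2
        np.testing.assert_array_equal(atoms.lengths_bp, [300, 700])

    def test_union_of_breakpoints(self):
        # breakpoint sets {p1}, {p2}, {p1,p2} -> 3 atoms
        a = make_profile("A", [300, 700], [0, 1])
        b = make_profile("B", [600, 400], [0, 1])
        c = make_profile("C", [300, 300, 400], [0, 1, 2])
        atoms = atomic_segments([a, b, c])
        assert atoms.n_atoms == 3
        np.testing.assert_array_equal(atoms.lengths_bp, [300, 300, 400])

    def test_territory_conservation_random(self):
        rng = np.random.default_rng(6)
        pos = np.sort(rng.choice(np.arange(1, 10_000), size=60, replace=False))
        panel = ProbePanel.from_positions(["1"] * 60, pos)
        for _ in range(20):
            values = rng.normal(0, 0.5, (3, 60)) + np.repeat(
                rng.normal(0, 1, (3, 3)), 20, axis=1
            )
            matrix = LRRMatrix(panel, ["a", "b", "c"], values)
            profiles = segment_samples(
                matrix, SegmentationParams(gamma=2, k_min=3, normalize=False),
                apply_winsor=False,
            )
            atoms = atomic_segments(profiles, {"1": pos})
            for p in profiles:
                assert atoms.total_bp == p.total_bp
            assert atoms.atoms["n_probes"].sum() == 60
            # every atom value equals its parent segment's estimate
            for si, p in enumerate(profiles):
                for k, atom in enumerate(atoms.atoms.itertuples()):
                    parent = [
                        s for s in p.segments
                        if s.start_bp <= atom.start_bp and atom.end_bp <= s.end_bp
                    ]
                    assert len(parent) == 1
                    assert atoms.estimates[si, k] == parent[0].estimate

    def test_inconsistent_territory_errors(self):
        a = make_profile("A", [1000], [0.0])
        b = make_profile("B", [500], [0.0])
        with pytest.raises(ValueError, match="territory"):
            atomic_segments([a, b])


class TestCallAberrations:
    def test_threshold_is_strict(self):
        np.testing.assert_array_equal(
            call_aberrations(np.array([0.10, 0.11, -0.10, -0.11, 0.0]), 0.1),
            [0, 1, 0, -1, 0],
        )

    def test_loss_call(self):
        assert call_aberrations(np.array([-0.3]), 0.1)[0] == -1

    def test_monotone_fewer_aberrant_bp_with_rising_cutoff(self):
        rng = np.random.default_rng(7)
        est = rng.normal(0, 0.12, 500)
        lengths = rng.integers(1, 100, 500)
        bp = [
            lengths[call_aberrations(est, c) != 0].sum() for c in (0.05, 0.1, 0.2)
        ]
        assert bp[0] >= bp[1] >= bp[2]


def test_impute_missing_nearest_neighbor():
    y = np.array([np.nan, 1.0, np.nan, np.nan, 4.0, np.nan])
    filled, n = impute_missing(y)
    np.testing.assert_array_equal(filled, [1.0, 1.0, 1.0, 4.0, 4.0, 4.0])
    assert n == 4
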