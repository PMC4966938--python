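import numpy as np
import pandas as pd
import pytest

from methet import (
    AlleleSpecificProfile,
    ccf_diversity,
    longitudinal_heterogeneity,
    pairwise_euclidean,
    patient_heterogeneity,
    ploidy_adjusted_heterogeneity,
    proportion_genome_different,
    variance_filter,
)
from conftest import make_atoms, make_cohort


class TestVarianceFilter:
    def test_zero_variance_atom_removed(self):
        atoms = make_atoms([100, 100], [[0.5, 0.0], [0.5, 0.4]])
        out = variance_filter(atoms, 0.03)
        assert out.n_atoms == 1
        np.testing.assert_allclose(out.estimates[:, 0], [0.0, 0.4])

    def test_sample_variance_hand_value(self):
        # two samples at 0 and 0.4: var(ddof=1) = 0.08 > 0.03 -> retained
        atoms = make_atoms([100], [[0.0], [0.4]])
        assert variance_filter(atoms, 0.03).n_atoms == 1
        # 0 and 0.2: var = 0.02 <= 0.03 -> removed, triggering the error
        with pytest.raises(ValueError, match="cutoff=None"):
            variance_filter(make_atoms([100], [[0.0], [0.2]]), 0.03)

    def test_strictness_at_cutoff(self):
        # var of (0, 0.5) with ddof=1 is exactly 0.125: not > 0.125
        with pytest.raises(ValueError):
            variance_filter(make_atoms([100], [[0.0], [0.5]]), 0.125)

    def test_none_is_identity(self):
        atoms = make_atoms([100, 100], [[0.5, 0.0], [0.5, 0.4]])
        assert variance_filter(atoms, None) is atoms


class TestPairwiseEuclidean:
    def test_identity(self):
        a = np.array([0.1, -0.5, 2.0])
        assert pairwise_euclidean(a, a) == 0.0

    def test_hand_value(self):
        # diffs (0.3, -0.4) -> sqrt(0.09 + 0.16) = 0.5
        assert pairwise_euclidean([0.3, 0.0], [0.0, 0.4]) == pytest.approx(0.5)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 40))
        perm = rng.permutation(40)
        assert pairwise_euclidean(a, b) == pytest.approx(
            pairwise_euclidean(a[perm], b[perm])
        )

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_euclidean([1.0], [1.0, 2.0])

    def test_dimension_scaling_sqrt_k(self):
        # a fixed per-atom difference replicated over k atoms scales as sqrt(k)
        for k in (1, 4, 9, 16):
            a = np.zeros(k)
            b = np.full(k, 0.3)
            assert pairwise_euclidean(a, b) == pytest.approx(0.3 * np.sqrt(k))


class TestPatientHeterogeneity:
    def test_identical_samples_zero(self):
        atoms = make_atoms([100], [[0.5], [0.5], [5.0]])  # third sample for variance
        res = patient_heterogeneity(atoms, ["s0", "s1"], "P", 0.03)
        assert res.score == 0.0
        assert res.n_pairs == 1

    def test_mean_of_pairwise_distances(self):
        # one atom, values 0,1,3 -> distances 1,3,2 -> mean 2
        atoms = make_atoms([100], [[0.0], [1.0], [3.0]])
        res = patient_heterogeneity(atoms, ["s0", "s1", "s2"], "P", 0.03)
        assert res.score == pytest.approx(2.0)
        assert res.n_pairs == 3

    def test_single_deposit_absent_with_reason(self):
        atoms = make_atoms([100], [[0.0], [1.0]])
        res = patient_heterogeneity(atoms, ["s0"], "P", 0.03)
        assert res.score is None
        assert "fewer than two" in res.reason

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(1)
        est = rng.normal(0, 1, (4, 20))
        atoms = make_atoms([10] * 20, est)
        ids = ["s0", "s1", "s2", "s3"]
        a = patient_heterogeneity(atoms, ids, "P", 0.03).score
        b = patient_heterogeneity(atoms, ids[::-1], "P", 0.03).score
        assert a == pytest.approx(b)

    def test_duplicated_cohort_unchanged_for_distinct_pairs(self):
        # adding copies of every sample to the matrix does not change a
        # patient's score when pairs stay restricted to the originals
        rng = np.random.default_rng(2)
        est = rng.normal(0, 1, (3, 10))
        atoms = make_atoms([10] * 10, est, samples=["a", "b", "c"])
        doubled = make_atoms(
            [10] * 10, np.vstack([est, est]),
            samples=["a", "b", "c", "a2", "b2", "c2"],
        )
        s1 = patient_heterogeneity(atoms, ["a", "b", "c"], "P", None).score
        s2 = patient_heterogeneity(doubled, ["a", "b", "c"], "P", None).score
        assert s1 == pytest.approx(s2)


class TestProportionGenomeDifferent:
    def test_identical_zero(self):
        atoms = make_atoms([100, 200], [[0.5, 0.0], [0.5, 0.0]])
        assert proportion_genome_different(atoms, ["s0", "s1"]).score == 0.0

    def test_bp_bookkeeping(self):
        # 30 Mbp atom differing by 0.5 out of 100 Mbp -> 30%
        atoms = make_atoms([30_000_000, 70_000_000], [[0.5, 0.0], [0.0, 0.0]])
        res = proportion_genome_different(atoms, ["s0", "s1"])
        assert res.score == pytest.approx(30.0)

    def test_difference_at_cutoff_not_counted(self):
        atoms = make_atoms([100], [[0.1], [0.2]])  # |diff| == 0.1 exactly
        assert proportion_genome_different(atoms, ["s0", "s1"], diff_cutoff=0.1).score == 0.0

    def test_invariant_to_atom_refinement(self):
        atoms = make_atoms([100, 200], [[0.5, 0.0], [0.0, 0.0]])
        refined = make_atoms([50, 50, 200], [[0.5, 0.5, 0.0], [0.0, 0.0, 0.0]])
        a = proportion_genome_different(atoms, ["s0", "s1"]).score
        b = proportion_genome_different(refined, ["s0", "s1"]).score
        assert a == pytest.approx(b)


class TestLongitudinal:
    def test_identical_pair_zero(self):
        atoms = make_atoms([100], [[0.5], [0.5], [9.0]])
        res = longitudinal_heterogeneity(atoms, ["s0"], ["s1"], "P", 0.03)
        assert res.score == 0.0
        assert res.n_pairs == 1

    def test_cross_pair_count(self):
        atoms = make_atoms([100], [[0.0], [1.0], [2.0]])
        res = longitudinal_heterogeneity(atoms, ["s0", "s1"], ["s2"], "P", None)
        # pairs (s0,s2), (s1,s2): distances 2 and 1 -> mean 1.5
        assert res.n_pairs == 2
        assert res.score == pytest.approx(1.5)

    def test_cross_vs_all_pairs_differ(self):
        atoms = make_atoms([100], [[0.0], [1.0], [2.0]])
        cross = longitudinal_heterogeneity(
            atoms, ["s0", "s1"], ["s2"], "P", None, cross_pairs_only=True
        ).score
        allp = longitudinal_heterogeneity(
            atoms, ["s0", "s1"], ["s2"], "P", None, cross_pairs_only=False
        ).score
        assert cross == pytest.approx(1.5)  # (2 + 1) / 2
        assert allp == pytest.approx((1 + 2 + 1) / 3)

    def test_empty_resection_absent(self):
        atoms = make_atoms([100], [[0.0], [1.0]])
        res = longitudinal_heterogeneity(atoms, ["s0"], [], "P", None)
        assert res.score is None


def _ascn(sample_id, copies, ploidy, lengths=(1000,)):
    seg = pd.DataFrame(
        {
            "chrom": "1",
            "start_bp": np.concatenate([[1], 1 + np.cumsum(lengths)[:-1]]),
            "end_bp": np.cumsum(lengths),
            "nA": [c[0] for c in copies],
            "nB": [c[1] for c in copies],
        }
    )
    return AlleleSpecificProfile(sample_id, purity=0.6, ploidy=ploidy, segments=seg)


class TestPloidyAdjusted:
    def test_identical_profiles_zero(self):
        a = _ascn("a", [(1, 1)], 2.0)
        b = _ascn("b", [(1, 1)], 2.0)
        assert ploidy_adjusted_heterogeneity([a, b], ["a", "b"]).score == 0.0

    def test_genome_doubling_cancels(self):
        a = _ascn("a", [(1, 1)], 2.0)
        b = _ascn("b", [(2, 2)], 4.0)
        assert ploidy_adjusted_heterogeneity([a, b], ["a", "b"]).score == pytest.approx(0.0)

    def test_single_atom_hand_value(self):
        a = _ascn("a", [(1, 1)], 2.0)
        b = _ascn("b", [(1, 2)], 2.0)
        res = ploidy_adjusted_heterogeneity([a, b], ["a", "b"])
        assert res.score == pytest.approx(0.5)

    def test_missing_profile_skipped(self):
        a = _ascn("a", [(1, 1)], 2.0)
        res = ploidy_adjusted_heterogeneity([a], ["a", "b"])
        assert res.score is None


class TestCcfDiversity:
    def test_equal_fractions_zero(self):
        cohort = make_cohort({"P": ["s1", "s2"]}, ccf={"s1": 0.6, "s2": 0.6})
        assert ccf_diversity(cohort, "P") == 0.0

    def test_enumerated_mean(self):
        cohort = make_cohort(
            {"P": ["s1", "s2", "s3"]}, ccf={"s1": 0.3, "s2": 0.5, "s3": 0.9}
        )
        assert ccf_diversity(cohort, "P") == pytest.approx(0.4)

    def test_missing_fraction_excluded(self):
        cohort = make_cohort({"P": ["s1", "s2", "s3"]}, ccf={"s1": 0.5, "s3": 0.7})
        assert ccf_diversity(cohort, "P") == pytest.approx(0.2)

    def test_fewer_than_two_usable_absent(self):
        cohort = make_cohort({"P": ["s1", "s2"]}, ccf={"s1": 0.5})
        assert ccf_diversity(cohort, "P") is None
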