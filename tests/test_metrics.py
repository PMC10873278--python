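import numpy as np
import pytest

from codhet import (
    AlignmentError,
    CauseProfile,
    DissimilarityMatrix,
    ProfileError,
    aggregate_contributions,
    cod_inequality,
    decompose,
    dissimilarity_matrix,
    profile_from_counts,
    simpson_diversity,
    uniform_dissimilarity,
)
from conftest import random_profile, random_tree
from oracles import per_cause_contributions, quadratic_index


def random_dmat(rng, k):
    """Random symmetric zero-diagonal matrix in [0, 1] (not tree-derived)."""
    raw = rng.random((k, k))
    values = (raw + raw.T) / 2
    np.fill_diagonal(values, 0.0)
    return DissimilarityMatrix(tuple(f"c{i}" for i in range(k)), values)


class TestProfileFromCounts:
    @pytest.mark.parametrize(
        "counts, expected",
        [((10, 10, 10), (1 / 3, 1 / 3, 1 / 3)), ((1, 0, 0), (1, 0, 0)), ((3, 1), (0.75, 0.25))],
    )
    def test_normalisation(self, counts, expected):
        prof = profile_from_counts([f"c{i}" for i in range(len(counts))], counts)
        np.testing.assert_allclose(prof.shares, expected)

    def test_all_zero_counts(self):
        with pytest.raises(ProfileError, match="zero"):
            profile_from_counts(["a", "b"], [0, 0])

    def test_negative_count(self):
        with pytest.raises(ProfileError, match="negative|non-negative"):
            profile_from_counts(["a", "b"], [3, -1])


class TestCauseProfile:
    def test_silent_renormalisation_within_tolerance(self):
        prof = CauseProfile(("a", "b"), np.array([0.5, 0.5 + 5e-7]))
        assert prof.shares.sum() == pytest.approx(1.0, abs=1e-15)

    def test_rejects_large_deviation(self):
        with pytest.raises(ProfileError, match="sum"):
            CauseProfile(("a", "b"), np.array([0.5, 0.6]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ProfileError, match="duplicate"):
            CauseProfile(("a", "a"), np.array([0.5, 0.5]))

    def test_rejects_bounds_not_bracketing(self):
        with pytest.raises(ProfileError, match="bounds"):
            CauseProfile(
                ("a", "b"), np.array([0.5, 0.5]),
                bounds=np.array([[0.6, 0.7], [0.4, 0.6]]),
            )


class TestCodInequality:
    def test_degenerate_profile_is_zero(self, rng):
        prof = CauseProfile(("a", "b", "c"), np.array([1.0, 0.0, 0.0]))
        dmat = DissimilarityMatrix(("a", "b", "c"), random_dmat(rng, 3).values)
        assert cod_inequality(prof, dmat).value == pytest.approx(0.0, abs=1e-15)

    def test_society_a(self, society_a):
        tree, profile = society_a
        res = cod_inequality(profile, dissimilarity_matrix(tree))
        assert res.value == pytest.approx(4 / 9, abs=1e-12)
        assert res.value == pytest.approx(
            quadratic_index(profile.shares, dissimilarity_matrix(tree).values), abs=1e-12
        )

    def test_society_b_and_ordering(self, society_a, society_b):
        tree_a, prof_a = society_a
        tree_b, prof_b = society_b
        val_a = cod_inequality(prof_a, dissimilarity_matrix(tree_a)).value
        val_b = cod_inequality(prof_b, dissimilarity_matrix(tree_b)).value
        assert val_b == pytest.approx(2 / 3, abs=1e-12)
        assert val_b > val_a

    def test_matches_double_loop_oracle_on_random_instances(self, rng):
        """Vectorised quadratic form vs explicit O(k^2) loop, 200 instances."""
        for _ in range(200):
            k = int(rng.integers(2, 20))
            dmat = random_dmat(rng, k)
            prof = random_profile(rng, dmat.causes)
            res = cod_inequality(prof, dmat)
            assert res.value == pytest.approx(
                quadratic_index(prof.shares, dmat.values), abs=1e-12
            )
            np.testing.assert_allclose(
                res.contributions,
                per_cause_contributions(prof.shares, dmat.values),
                atol=1e-12,
            )

    def test_alignment_by_id_not_order(self, rng):
        k = 5
        dmat = random_dmat(rng, k)
        prof = random_profile(rng, dmat.causes)
        perm = rng.permutation(k)
        shuffled = CauseProfile(
            tuple(prof.causes[i] for i in perm), prof.shares[perm]
        )
        a = cod_inequality(prof, dmat)
        b = cod_inequality(shuffled, dmat)
        assert a.value == pytest.approx(b.value, abs=1e-12)
        by_id_a = dict(zip(a.causes, a.contributions))
        by_id_b = dict(zip(b.causes, b.contributions))
        for c in a.causes:
            assert by_id_a[c] == pytest.approx(by_id_b[c], abs=1e-12)

    def test_cause_set_mismatch_lists_ids(self, rng):
        dmat = random_dmat(rng, 3)
        prof = CauseProfile(("c0", "c1", "zz"), np.full(3, 1 / 3))
        with pytest.raises(AlignmentError, match="zz"):
            cod_inequality(prof, dmat)

    def test_zero_cause_neutrality(self, rng):
        """Appending a share-0 cause changes nothing, whatever its distances."""
        tree = random_tree(rng, max_depth=3)
        causes = tree.analysis_causes
        if len(causes) < 2:
            tree = random_tree(np.random.default_rng(7), max_depth=3, max_branch=3)
            causes = tree.analysis_causes
        base_causes = causes[:-1]
        shares = rng.dirichlet(np.ones(len(base_causes)))
        prof_small = CauseProfile(base_causes, shares)
        prof_big = CauseProfile(causes, np.append(shares, 0.0))
        small = cod_inequality(prof_small, dissimilarity_matrix(tree, base_causes))
        big = cod_inequality(prof_big, dissimilarity_matrix(tree, causes))
        assert big.value == pytest.approx(small.value, abs=1e-12)
        assert big.contributions[-1] == 0.0
        np.testing.assert_allclose(big.contributions[:-1], small.contributions, atol=1e-12)

    def test_merge_invariance(self, rng):
        """Merging two zero-distance causes with identical distance rows into
        one cause with the summed share leaves I unchanged."""
        k = 6
        dmat = random_dmat(rng, k)
        values = dmat.values.copy()
        values[1, :] = values[0, :]
        values[:, 1] = values[:, 0]
        values[0, 1] = values[1, 0] = 0.0
        np.fill_diagonal(values, 0.0)
        dmat = DissimilarityMatrix(dmat.causes, values)
        prof = random_profile(rng, dmat.causes)
        full = cod_inequality(prof, dmat)
        merged_shares = np.concatenate([[prof.shares[0] + prof.shares[1]], prof.shares[2:]])
        keep = [0] + list(range(2, k))
        merged_dmat = DissimilarityMatrix(
            tuple(dmat.causes[i] for i in keep), values[np.ix_(keep, keep)]
        )
        merged_prof = CauseProfile(merged_dmat.causes, merged_shares)
        merged = cod_inequality(merged_prof, merged_dmat)
        assert merged.value == pytest.approx(full.value, abs=1e-12)


class TestSimpsonDiversity:
    @pytest.mark.parametrize(
        "shares, expected",
        [((1.0, 0.0), 0.0), ((1 / 3, 1 / 3, 1 / 3), 2 / 3), ((0.25,) * 4, 0.75)],
    )
    def test_examples(self, shares, expected):
        prof = CauseProfile(tuple(f"c{i}" for i in range(len(shares))), np.array(shares))
        assert simpson_diversity(prof).value == pytest.approx(expected, abs=1e-12)

    def test_uniform_profile_attains_max(self, rng):
        for k in (2, 5, 17):
            uniform = CauseProfile(tuple(f"c{i}" for i in range(k)), np.full(k, 1 / k))
            assert simpson_diversity(uniform).value == pytest.approx(1 - 1 / k, abs=1e-12)
            other = random_profile(rng, uniform.causes)
            assert simpson_diversity(other).value <= 1 - 1 / k + 1e-12

    def test_equals_inequality_with_unit_uniform_matrix(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 30))
            causes = tuple(f"c{i}" for i in range(k))
            prof = random_profile(rng, causes)
            s = simpson_diversity(prof)
            i = cod_inequality(prof, uniform_dissimilarity(k, 1.0))
            assert i.value == pytest.approx(s.value, abs=1e-12)
            np.testing.assert_allclose(
                i.contributions, prof.shares * (1 - prof.shares), atol=1e-12
            )

    def test_scaled_uniform_matrix(self, rng):
        """With constant d the inequality index is d times Simpson."""
        k = 4
        causes = tuple(f"c{i}" for i in range(k))
        prof = CauseProfile(causes, np.full(k, 0.25))
        i = cod_inequality(prof, uniform_dissimilarity(k, 0.5))
        assert i.value == pytest.approx(0.5 * simpson_diversity(prof).value, abs=1e-12)


class TestInvariants:
    def test_dominance_and_bounds_random_tree_profiles(self, rng):
        """0 <= I <= S <= 1, strict I < S when some positive-share pair has
        d < 1."""
        for _ in range(100):
            tree = random_tree(rng)
            prof = random_profile(rng, tree.analysis_causes)
            dmat = dissimilarity_matrix(tree)
            i_val = cod_inequality(prof, dmat).value
            s_val = simpson_diversity(prof).value
            assert 0.0 <= i_val <= s_val <= 1.0 + 1e-12
            pos = prof.shares > 1e-9
            off = dmat.values[np.ix_(pos, pos)]
            strict = np.any((off < 1.0) & ~np.eye(int(pos.sum()), dtype=bool))
            if strict and s_val > 0:
                assert i_val < s_val

    def test_conservation(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 25))
            dmat = random_dmat(rng, k)
            prof = random_profile(rng, dmat.causes)
            res = cod_inequality(prof, dmat)
            assert res.contributions.sum() == pytest.approx(res.value, abs=1e-9)
            s = simpson_diversity(prof)
            assert s.contributions.sum() == pytest.approx(s.value, abs=1e-9)
            np.testing.assert_allclose(
                res.contributions, prof.shares * res.per_cause_mean_distance, atol=1e-12
            )


class TestDecompose:
    def test_society_b_equal_thirds(self, society_b):
        tree, profile = society_b
        res = cod_inequality(profile, dissimilarity_matrix(tree))
        table = decompose(res, tree)
        np.testing.assert_allclose(table["contribution"], 2 / 9, atol=1e-12)
        np.testing.assert_allclose(table["contribution_pct"], 100 / 3, atol=1e-9)
        assert table["contribution_pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_simpson_half_half(self):
        prof = CauseProfile(("a", "b"), np.array([0.5, 0.5]))
        res = simpson_diversity(prof)
        table = decompose(res)
        assert res.value == pytest.approx(0.5, abs=1e-15)
        np.testing.assert_allclose(table["contribution"], 0.25, atol=1e-15)

    def test_zero_share_cause_contributes_zero(self, rng):
        dmat = random_dmat(rng, 4)
        prof = CauseProfile(dmat.causes, np.array([0.5, 0.5, 0.0, 0.0]))
        table = decompose(cod_inequality(prof, dmat))
        zeros = table.set_index("cause_id").loc[["c2", "c3"], "contribution"]
        np.testing.assert_array_equal(zeros.to_numpy(), 0.0)

    def test_zero_value_flagged_not_an_error(self):
        prof = CauseProfile(("a", "b"), np.array([1.0, 0.0]))
        table = decompose(simpson_diversity(prof))
        assert table.attrs["contribution_pct_defined"] is False
        np.testing.assert_array_equal(table["contribution_pct"].to_numpy(), 0.0)

    def test_ordering_descending_with_stable_tie_break(self, rng):
        dmat = uniform_dissimilarity(4, 1.0)
        prof = CauseProfile(dmat.causes, np.array([0.4, 0.3, 0.15, 0.15]))
        table = decompose(simpson_diversity(prof))
        contrib = table["contribution"].to_numpy()
        assert np.all(np.diff(contrib) <= 1e-15)
        tied = table[np.isclose(table["contribution"], 0.15 * 0.85)]
        assert list(tied["cause_id"]) == sorted(tied["cause_id"])


class TestAggregateContributions:
    def test_society_b_level1_thirds(self, society_b):
        tree, profile = society_b
        res = cod_inequality(profile, dissimilarity_matrix(tree))
        table = aggregate_contributions(decompose(res, tree), tree, 1)
        assert len(table) == 3
        np.testing.assert_allclose(table["contribution"], res.value / 3, atol=1e-12)

    def test_identity_at_leaf_level(self, society_b):
        tree, profile = society_b
        table = decompose(cod_inequality(profile, dissimilarity_matrix(tree)), tree)
        again = aggregate_contributions(table, tree, tree.depth)
        np.testing.assert_allclose(again["contribution"], table["contribution"])

    def test_single_level1_group_holds_everything(self, society_a):
        tree, profile = society_a
        res = cod_inequality(profile, dissimilarity_matrix(tree))
        table = aggregate_contributions(decompose(res, tree), tree, 1)
        assert len(table) == 1
        assert table.loc[0, "contribution"] == pytest.approx(res.value, abs=1e-12)
        assert table.loc[0, "contribution_pct"] == pytest.approx(100.0, abs=1e-9)

    def test_conservation_at_every_level(self, fixture_tree, fixture_dmat, rng):
        prof = random_profile(rng, fixture_tree.analysis_causes)
        res = cod_inequality(prof, fixture_dmat)
        table = decompose(res, fixture_tree)
        for level in (1, 2, 3):
            agg = aggregate_contributions(table, fixture_tree, level)
            assert agg["contribution"].sum() == pytest.approx(res.value, abs=1e-9)

    def test_bad_level(self, fixture_tree, society_b):
        tree, profile = society_b
        table = decompose(cod_inequality(profile, dissimilarity_matrix(tree)))
        with pytest.raises(AlignmentError):
            aggregate_contributions(table, tree, 0)
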