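import numpy as np
import pandas as pd
import pytest

from nichescape.famd import NicheSpace
from nichescape.niche_metrics import (
    MetricError,
    neighbour_robustness,
    rank_and_flag,
    specialisation_scores,
    subset_rerun,
    top_bottom,
    uniqueness_scores,
)


def make_space(points, labels=None):
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    n, d = points.shape
    labels = labels or [f"s{i:03d}" for i in range(n)]
    coords = pd.DataFrame(
        points, index=pd.Index(labels, name="species_id"),
        columns=[f"Dim{j+1}" for j in range(d)],
    )
    return NicheSpace(
        coordinates=coords,
        eigenvalues=np.ones(d),
        pct_variance=np.full(d, 100.0 / d),
        cumulative_pct=np.linspace(100.0 / d, 100.0, d),
        contributions=pd.DataFrame(),
    )


class TestUniqueness:
    def test_hand_example_k1(self):
        space = make_space([0.0, 1.0, 3.0])
        np.testing.assert_allclose(
            uniqueness_scores(space, k=1), [1.0, 1.0, 2.0]
        )

    def test_hand_example_k2(self):
        space = make_space([0.0, 1.0, 3.0])
        np.testing.assert_allclose(
            uniqueness_scores(space, k=2), [2.0, 1.5, 2.5]
        )

    def test_coincident_points_share_zero_distance(self):
        space = make_space([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        u = uniqueness_scores(space, k=1)
        assert u.iloc[0] == 0.0 and u.iloc[1] == 0.0

    def test_k_bounds(self):
        space = make_space([0.0, 1.0, 3.0])
        with pytest.raises(MetricError):
            uniqueness_scores(space, k=3)
        with pytest.raises(MetricError):
            uniqueness_scores(space, k=0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(15, 4))
            space = make_space(X)
            for k in (1, 3, 5):
                got = uniqueness_scores(space, k=k)
                for i in range(15):
                    d = np.sort(np.linalg.norm(X - X[i], axis=1))[1 : k + 1]
                    assert got.iloc[i] == pytest.approx(d.mean(), abs=0)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(1)
        space = make_space(rng.normal(size=(20, 3)))
        prev = uniqueness_scores(space, k=1)
        for k in range(2, 10):
            cur = uniqueness_scores(space, k=k)
            assert (cur.to_numpy() >= prev.to_numpy() - 1e-12).all()
            prev = cur

    def test_removing_nearest_neighbour_never_decreases(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        space = make_space(X)
        u = uniqueness_scores(space, k=3)
        focal = space.species[0]
        d = np.linalg.norm(X - X[0], axis=1)
        nearest = space.species[int(np.argsort(d)[1])]
        keep = [s for s in space.species if s != nearest]
        reduced = make_space(
            space.coordinates.loc[keep].to_numpy(), labels=keep
        )
        assert uniqueness_scores(reduced, k=3)[focal] >= u[focal] - 1e-12

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 4))
        u1 = uniqueness_scores(make_space(X), k=3)
        u2 = uniqueness_scores(make_space(X + 17.5), k=3)
        np.testing.assert_allclose(u1, u2, atol=1e-10)


class TestSpecialisation:
    def test_hand_example(self):
        space = make_space([0.0, 1.0, 3.0])
        np.testing.assert_allclose(
            specialisation_scores(space), [4 / 3, 1 / 3, 5 / 3]
        )

    def test_species_at_centroid_scores_zero(self):
        space = make_space([[1.0, 1.0], [-1.0, -1.0], [0.0, 0.0]])
        assert specialisation_scores(space).iloc[2] == pytest.approx(0.0)

    def test_mirror_pair_equal(self):
        space = make_space([[2.0, 0.0], [-2.0, 0.0]])
        s = specialisation_scores(space)
        assert s.iloc[0] == pytest.approx(s.iloc[1])

    def test_rotation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        s1 = specialisation_scores(make_space(X))
        s2 = specialisation_scores(make_space(X @ R.T))
        np.testing.assert_allclose(s1, s2, atol=1e-10)
        u1 = uniqueness_scores(make_space(X), k=3)
        u2 = uniqueness_scores(make_space(X @ R.T), k=3)
        np.testing.assert_allclose(u1, u2, atol=1e-10)


class TestRobustness:
    def test_reference_self_correlation_is_one(self):
        rng = np.random.default_rng(5)
        space = make_space(rng.normal(size=(20, 3)))
        r = neighbour_robustness(space, ks=(5,), reference_k=5)
        assert r[5] == 1.0

    def test_k_too_large_errors(self):
        space = make_space([0.0, 1.0, 3.0])
        with pytest.raises(MetricError):
            neighbour_robustness(space, ks=(1, 100), reference_k=1)

    def test_neighbouring_k_strongly_correlated(self):
        rng = np.random.default_rng(6)
        space = make_space(rng.normal(size=(60, 5)))
        r = neighbour_robustness(space, ks=(3, 5, 10), reference_k=5)
        assert r[3] > 0.9 and r[10] > 0.9


class TestRankAndFlag:
    def test_equal_scores_give_zero_outliers(self):
        # four corners of a square: all scores identical
        space = make_space(
            [[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0], [0.0, 0.0]]
        )
        scores = rank_and_flag(space, k=2)
        assert scores.scores["outlier_specialisation"].sum() == 0

    def test_ranks_are_permutation(self, small_study):
        from nichescape.famd import famd_fit, retain_kaiser
        from nichescape.trait_data import life_history_score

        table, _, _ = small_study
        reduced, _ = life_history_score(table)
        space = retain_kaiser(famd_fit(reduced))
        scores = rank_and_flag(space)
        n = len(scores.species)
        for col in ("rank_uniqueness", "rank_specialisation"):
            assert sorted(scores.scores[col]) == list(range(1, n + 1))

    def test_extreme_point_is_flagged_and_ranked_first(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(size=(30, 3)), [[50.0, 50.0, 50.0]]])
        space = make_space(X)
        scores = rank_and_flag(space, k=3)
        outlier = scores.scores.index[-1]
        assert scores.scores.loc[outlier, "rank_uniqueness"] == 1
        assert scores.scores.loc[outlier, "rank_specialisation"] == 1
        assert bool(scores.scores.loc[outlier, "outlier_uniqueness"])

    def test_rank_ties_broken_by_species_id(self):
        space = make_space([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]],
                           labels=["d", "c", "b", "a"])
        scores = rank_and_flag(space, k=1)
        s = scores.scores
        # "c" and "d" tie on specialisation; lexicographically smaller first
        assert s.loc["c", "rank_specialisation"] < s.loc["d", "rank_specialisation"]


class TestSubsetRerun:
    def test_full_subset_is_identity(self):
        rng = np.random.default_rng(8)
        space = make_space(rng.normal(size=(25, 4)))
        full = rank_and_flag(space, k=5)
        sub, report = subset_rerun(space, space.species, k=5)
        pd.testing.assert_frame_equal(full.scores, sub.scores)
        assert report["n_shared"] == 10

    def test_subset_too_small_errors(self):
        space = make_space([0.0, 1.0, 3.0])
        with pytest.raises(MetricError):
            subset_rerun(space, space.species[:2], k=5)

    def test_subset_uses_only_subset_neighbours(self):
        # three clustered points + one outlier: dropping the cluster's
        # members raises uniqueness of the rest
        space = make_space([0.0, 0.1, 0.2, 10.0])
        sub, _ = subset_rerun(space, [space.species[0], space.species[3]], k=1)
        assert sub.scores.loc[space.species[0], "uniqueness"] == pytest.approx(10.0)


def test_top_bottom_lists(small_study):
    from nichescape.famd import famd_fit, retain_kaiser
    from nichescape.trait_data import life_history_score

    table, _, _ = small_study
    reduced, _ = life_history_score(table)
    space = retain_kaiser(famd_fit(reduced))
    scores = rank_and_flag(space)
    tb = top_bottom(scores, "uniqueness", m=10)
    assert len(tb["top"]) == 10 and len(tb["bottom"]) == 10
    assert not set(tb["top"]) & set(tb["bottom"])


class TestScoreProperties:
    """Distribution-free invariants on arbitrary point configurations."""

    from hypothesis import given, settings, strategies as st
    from hypothesis.extra.numpy import arrays

    @given(
        arrays(
            float, (8, 3),
            elements=st.floats(-100, 100, allow_nan=False, width=32),
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_uniqueness_monotone_and_nonnegative(self, X):
        import numpy as np

        space = make_space(np.asarray(X, dtype=float))
        prev = uniqueness_scores(space, k=1)
        assert (prev.to_numpy() >= 0).all()
        for k in (2, 4, 7):
            cur = uniqueness_scores(space, k=k)
            assert (cur.to_numpy() >= prev.to_numpy() - 1e-9).all()
            prev = cur

    @given(
        arrays(
            float, (6, 2),
            elements=st.floats(-50, 50, allow_nan=False, width=32),
        ),
        st.floats(-1000, 1000, allow_nan=False, width=32),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_translation_leaves_both_scores_unchanged(self, X, shift):
        import numpy as np

        X = np.asarray(X, dtype=float)
        s1 = specialisation_scores(make_space(X))
        s2 = specialisation_scores(make_space(X + shift))
        np.testing.assert_allclose(s1, s2, atol=1e-6 * (1 + abs(shift)))
        u1 = uniqueness_scores(make_space(X), k=2)
        u2 = uniqueness_scores(make_space(X + shift), k=2)
        np.testing.assert_allclose(u1, u2, atol=1e-6 * (1 + abs(shift)))
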