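import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from ringms.stats import (
    bray_curtis,
    intensity_by_ubiquity,
    intersection_counts,
    pcoa,
    permanova,
    ubiquity_curve,
)
from ringms.tables import AlignedFeatureTable


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_f(d2: np.ndarray, labels) -> float:
    """PERMANOVA pseudo-F straight from the distance-based definition."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels))
    g = len(groups)
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for grp in groups:
        idx = [i for i, l in enumerate(labels) if l == grp]
        ss_within += sum(
            d2[i, j] for a, i in enumerate(idx) for j in idx[a + 1:]
        ) / len(idx)
    ss_among = ss_total - ss_within
    if ss_within == 0:
        return math.inf if ss_among > 0 else math.nan
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def oracle_exact_p(d2: np.ndarray, labels) -> float:
    """Brute force over ALL n! label orderings; p = #{F* >= F} / n!."""
    labels = list(labels)
    f_obs = oracle_f(d2, labels)
    count = total = 0
    for perm in itertools.permutations(labels):
        total += 1
        f = oracle_f(d2, list(perm))
        if (math.isnan(f_obs)) or (f >= f_obs):
            count += 1
    return float(Fraction(count, total))


def two_group_distance(n1: int, n2: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    points = np.vstack(
        [rng.normal(0, 1, size=(n1, 2)), rng.normal(1.5, 1, size=(n2, 2))]
    )
    return squareform(pdist(points))


class TestBrayCurtis:
    def test_identical_rows_have_zero_distance(self):
        m = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert bray_curtis(m).iloc[0, 1] == 0.0

    def test_disjoint_supports_have_distance_one(self):
        m = np.array([[1.0, 0.0], [0.0, 5.0]])
        assert bray_curtis(m).iloc[0, 1] == 1.0

    def test_hand_evaluated_example(self):
        m = np.array([[2.0, 1.0], [1.0, 1.0]])
        # (|2-1| + |1-1|) / (3 + 2) = 0.2
        assert bray_curtis(m).iloc[0, 1] == pytest.approx(0.2)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis(np.array([[1.0, -1.0], [1.0, 1.0]]))

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestPcoa:
    def test_collinear_points_recover_one_axis(self):
        x = np.array([[0.0], [3.0], [5.0]])
        d = squareform(pdist(x))
        result = pcoa(d)
        assert result.coordinates.shape[1] == 1
        recon = squareform(pdist(result.coordinates.to_numpy()))
        assert np.allclose(recon, d, atol=1e-8)
        assert result.proportion_explained[0] == pytest.approx(1.0)

    def test_zero_matrix_gives_zero_eigenvalues(self):
        result = pcoa(np.zeros((4, 4)))
        assert np.allclose(result.eigenvalues, 0.0)
        assert result.coordinates.shape[1] == 0

    def test_two_points_sit_at_plus_minus_half_distance(self):
        d = np.array([[0.0, 4.0], [4.0, 0.0]])
        coords = pcoa(d).coordinates.to_numpy().ravel()
        assert sorted(coords) == pytest.approx([-2.0, 2.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_euclidean_distance_recovery(self, seed):
        rng = np.random.default_rng(seed)
        points = rng.normal(size=(8, 3))
        d = squareform(pdist(points))
        result = pcoa(d)
        recon = squareform(pdist(result.coordinates.to_numpy()))
        assert np.allclose(recon, d, atol=1e-8)
        assert (result.eigenvalues >= -1e-8).all()

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        points = rng.uniform(0, 5, size=(6, 4))
        d = squareform(pdist(points))
        ours = pcoa(d)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        k = ours.coordinates.shape[1]
        assert np.allclose(
            np.sort(ours.eigenvalues[:k]), np.sort(theirs.eigvals.to_numpy()[:k]), atol=1e-8
        )
        assert np.allclose(
            np.abs(ours.coordinates.to_numpy()),
            np.abs(theirs.samples.to_numpy()[:, :k]),
            atol=1e-6,
        )

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(d)


class TestPermanova:
    def test_perfectly_separated_groups_hand_example(self):
        # 6 samples, two groups of 3; within-group distance 0, between 1.
        # SS_total = 9/6 = 1.5, SS_within = 0 -> R2 = 1, F = inf; under full
        # enumeration only the 2 of C(6,3)=20 assignments reproducing the
        # partition attain F* >= F, so exact p = 0.1.
        d = np.ones((6, 6))
        d[:3, :3] = 0.0
        d[3:, 3:] = 0.0
        np.fill_diagonal(d, 0.0)
        labels = ["x"] * 3 + ["y"] * 3
        res = permanova(d, labels, method="exact")
        assert res.r_squared == pytest.approx(1.0)
        assert math.isinf(res.pseudo_F)
        assert res.p_value == pytest.approx(2 / 20)
        assert res.n_permutations == 20

    def test_equal_distances_are_fully_exchangeable(self):
        d = np.ones((6, 6)) - np.eye(6)
        labels = ["x"] * 3 + ["y"] * 3
        assert permanova(d, labels, method="exact").p_value == 1.0
        assert permanova(d, labels, method="permutation", seed=0).p_value == 1.0

    @pytest.mark.parametrize(
        "sizes", [(1, 2), (2, 2), (1, 3), (2, 3), (3, 3), (2, 4)]
    )
    def test_exact_mode_matches_brute_force_oracle(self, sizes):
        n1, n2 = sizes
        d = two_group_distance(n1, n2, seed=n1 * 10 + n2)
        labels = ["a"] * n1 + ["b"] * n2
        res = permanova(d, labels, method="exact")
        assert res.p_value == oracle_exact_p(d**2, labels)

    def test_monte_carlo_agrees_with_exact_within_binomial_error(self):
        d = two_group_distance(3, 3, seed=5)
        labels = ["a"] * 3 + ["b"] * 3
        p_exact = permanova(d, labels, method="exact").p_value
        p_mc = permanova(d, labels, method="permutation", n_permutations=999, seed=1).p_value
        se = math.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(p_mc - p_exact) <= 3 * se + 1 / 999

    def test_f_statistic_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        d = two_group_distance(5, 6, seed=9)
        labels = ["a"] * 5 + ["b"] * 6
        ours = permanova(d, labels, method="permutation", n_permutations=99, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d), grouping=labels, permutations=99
        )
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-10)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_random_labels_give_chance_level_r_squared(self, seed):
        rng = np.random.default_rng(seed)
        d = two_group_distance(12, 12, seed=100 + seed)
        labels = rng.permutation(["a"] * 12 + ["b"] * 12)
        res = permanova(d, list(labels), method="permutation", n_permutations=199, seed=seed)
        # under the null, R2 concentrates near 1/(N-1)
        assert res.r_squared < 0.25

    def test_r_squared_invariant_to_consistent_relabeling(self):
        d = two_group_distance(4, 4, seed=3)
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(d, labels, method="exact")
        perm = np.random.default_rng(0).permutation(8)
        res_p = permanova(d[np.ix_(perm, perm)], [labels[i] for i in perm], method="exact")
        assert res_p.r_squared == pytest.approx(res.r_squared)
        assert res_p.p_value == res.p_value

    def test_single_group_rejected(self):
        d = two_group_distance(2, 2, seed=1)
        with pytest.raises(ValueError, match="two groups"):
            permanova(d, ["a"] * 4)

    def test_invalid_permutation_count_rejected(self):
        d = two_group_distance(2, 2, seed=1)
        with pytest.raises(ValueError, match="n_permutations"):
            permanova(d, ["a", "a", "b", "b"], n_permutations=0)


class TestIntersections:
    def test_two_lab_enumeration(self):
        summary = intersection_counts({"lab1": {"f1", "f2"}, "lab2": {"f2", "f3"}})
        assert summary.exclusive[frozenset({"lab1"})] == 1
        assert summary.exclusive[frozenset({"lab2"})] == 1
        assert summary.exclusive[frozenset({"lab1", "lab2"})] == 1
        assert summary.n_union == 3

    def test_identical_presence_only_full_subset(self):
        summary = intersection_counts({l: {"f1", "f2"} for l in ("a", "b", "c")})
        assert summary.exclusive == {frozenset({"a", "b", "c"}): 2}
        assert summary.shared_all_fraction == 1.0

    def test_single_lab_total(self):
        summary = intersection_counts({"solo": {"f1", "f2", "f3"}})
        assert summary.exclusive == {frozenset({"solo"}): 3}
        assert summary.totals["solo"] == 3

    def test_exclusive_counts_partition_the_union(self):
        rng = np.random.default_rng(4)
        presence = pd.DataFrame(
            rng.random((5, 40)) < 0.4, index=[f"lab{i}" for i in range(5)]
        )
        summary = intersection_counts(presence)
        assert sum(summary.exclusive.values()) == summary.n_union


def _aligned(values, labs_samples, mz=None):
    """Build an AlignedFeatureTable from a dense matrix and (lab, sample) pairs."""
    values = np.asarray(values, dtype=float)
    gids = [f"G{i:03d}" for i in range(values.shape[0])]
    cols = pd.MultiIndex.from_tuples(labs_samples, names=("lab", "sample"))
    intensities = pd.DataFrame(values, index=gids, columns=cols)
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 500, len(gids)),
            "rt": np.linspace(1, 8, len(gids)),
            "annotation": [None] * len(gids),
            "n_labs": np.nan,
        },
        index=gids,
    )
    types = [s.rsplit("_", 1)[0] for _, s in labs_samples]
    samples = pd.DataFrame(
        {"sample_type": types, "is_blank": [t == "blank" for t in types]}, index=cols
    )
    return AlignedFeatureTable(intensities, features, samples, {}, "mz_rt")


COLS = [("lab_a", "A_1"), ("lab_a", "M_1"), ("lab_b", "A_1"), ("lab_b", "M_1")]


class TestUbiquity:
    def test_everything_everywhere_gives_identity_curve(self):
        table = _aligned(np.full((4, 4), 5.0) + np.arange(4)[:, None], COLS)
        curve = ubiquity_curve(table)
        assert curve.cumulative.tolist() == [1, 2, 3, 4]

    def test_hand_counted_curve(self):
        # by descending mean intensity the presence-in-all-labs flags are
        # [yes, yes, no, yes] -> cumulative [1, 2, 2, 3]
        values = np.array(
            [
                [40.0, 40, 40, 40],
                [30.0, 30, 30, 30],
                [20.0, 20, 0, 0],  # lab_b never sees it
                [10.0, 10, 10, 10],
            ]
        )
        curve = ubiquity_curve(_aligned(values, COLS))
        assert curve.cumulative.tolist() == [1, 2, 2, 3]

    def test_nothing_shared_gives_constant_zero(self):
        values = np.array([[5.0, 5, 0, 0], [0.0, 0, 7, 7]])
        curve = ubiquity_curve(_aligned(values, COLS))
        assert curve.cumulative.tolist() == [0, 0]

    def test_curve_is_nondecreasing_with_unit_steps(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(0, 10, size=(30, 4)) * (rng.random((30, 4)) < 0.7)
        values[0] = 1.0  # ensure no all-zero row issues
        curve = ubiquity_curve(_aligned(values, COLS))
        steps = np.diff(np.concatenate([[0], curve.cumulative]))
        assert set(steps.tolist()) <= {0, 1}

    def test_requires_two_labs(self):
        table = _aligned(np.ones((2, 2)), [("lab_a", "A_1"), ("lab_a", "M_1")])
        with pytest.raises(ValueError, match="2 labs"):
            ubiquity_curve(table)


class TestIntensityByUbiquity:
    def test_single_level_forms_one_group(self):
        table = _aligned(np.full((3, 4), 2.0), COLS)
        summary = intensity_by_ubiquity(table)
        assert list(summary.index) == [2]
        assert summary.loc[2, "n_features"] == 3

    def test_shared_features_report_higher_medians(self):
        values = np.array(
            [
                [50.0, 50, 50, 50],  # in both labs, 10x intensity
                [60.0, 60, 60, 60],
                [5.0, 5, 0, 0],  # lab_a only
                [4.0, 6, 0, 0],
            ]
        )
        summary = intensity_by_ubiquity(_aligned(values, COLS))
        assert summary.loc[2, "median"] > summary.loc[1, "median"]

    def test_empty_alignment_gives_empty_summary(self):
        table = _aligned(np.empty((0, 4)), COLS)
        assert intensity_by_ubiquity(table).empty
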