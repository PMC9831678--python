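import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from oralmicro import (AbundanceTable, ValidationError, alpha_group_test,
                       bray_curtis, composition_summary, distance_matrix,
                       patient_clustering_test, pcoa, permanova,
                       shannon_index)
from oralmicro.diversity import read_distance_matrix, write_distance_matrix


class TestShannon:
    @pytest.mark.parametrize("p, expected", [
        ([0.1] * 10, np.log(10)),
        ([1.0], 0.0),
        ([0.5, 0.25, 0.25], -(0.5 * np.log(0.5) + 0.5 * np.log(0.25))),
    ])
    def test_closed_forms(self, p, expected):
        assert shannon_index(p) == pytest.approx(expected, abs=1e-9)

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=30))
    def test_bounds_and_zero_padding(self, weights):
        p = np.asarray(weights) / np.sum(weights)
        h = shannon_index(p)
        assert -1e-12 <= h <= np.log(len(p)) + 1e-12
        padded = np.concatenate([p, np.zeros(5)])
        assert shannon_index(padded) == pytest.approx(h, abs=1e-12)

    def test_uniform_is_strict_maximum(self):
        assert shannon_index([0.4, 0.3, 0.3]) < shannon_index([1 / 3] * 3)

    def test_invalid_vectors(self):
        with pytest.raises(ValidationError):
            shannon_index([-0.1, 1.1])
        with pytest.raises(ValidationError):
            shannon_index([0.0, 0.0])


class TestBrayCurtis:
    def test_closed_form(self):
        assert bray_curtis([2, 6, 2], [4, 2, 4]) == pytest.approx(0.4,
                                                                  abs=1e-12)

    def test_identity_and_disjoint(self):
        assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
        assert bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 5), min_size=2, max_size=10),
           st.lists(st.floats(0, 5), min_size=2, max_size=10))
    def test_symmetry_and_range(self, x, y):
        n = min(len(x), len(y))
        x, y = np.asarray(x[:n]) + 0.01, np.asarray(y[:n]) + 0.01
        d = bray_curtis(x, y)
        assert d == pytest.approx(bray_curtis(y, x), abs=1e-12)
        assert 0 <= d <= 1

    def test_both_zero_undefined(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])


class TestDistanceMatrix:
    def test_matches_double_loop_oracle(self, random_counts):
        dm = distance_matrix(random_counts)
        rel = random_counts.to_relative().data
        for i, j in itertools.combinations(range(rel.shape[1]), 2):
            expected = bray_curtis(rel.iloc[:, i], rel.iloc[:, j])
            assert dm.data[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_columns_have_zero_distance(self):
        t = AbundanceTable(pd.DataFrame(
            [[3, 3, 1], [1, 1, 5]], index=["a", "b"],
            columns=["s1", "s2", "s3"]))
        dm = distance_matrix(t)
        assert dm.data[0, 1] == 0.0
        assert dm.data[0, 2] == pytest.approx(dm.data[1, 2], abs=1e-12)

    def test_tsv_round_trip(self, tmp_path, random_counts):
        dm = distance_matrix(random_counts)
        p = tmp_path / "dm.tsv"
        write_distance_matrix(dm, p)
        again = read_distance_matrix(p)
        assert list(again.ids) == list(dm.ids)
        assert np.allclose(again.data, dm.data, atol=1e-12)


class TestPcoa:
    def test_two_sample_closed_form(self):
        d = 0.6
        dm = DistanceMatrix([[0, d], [d, 0]], ids=["a", "b"])
        res = pcoa(dm)
        assert res.eigenvalues == pytest.approx([d ** 2 / 2], abs=1e-12)
        assert sorted(res.coordinates[:, 0]) == pytest.approx(
            [-d / 2, d / 2], abs=1e-12)

    def test_unit_square_geometry(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = pcoa(DistanceMatrix(d, ids=list("abcd")))
        assert res.eigenvalues[:2] == pytest.approx([1.0, 1.0], abs=1e-10)
        recon = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None], axis=-1)
        assert np.allclose(recon, d, atol=1e-8)

    def test_euclidean_reconstruction_and_trace(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 4))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        res = pcoa(DistanceMatrix(d, ids=[str(i) for i in range(7)]))
        recon = np.linalg.norm(
            res.coordinates[:, None] - res.coordinates[None], axis=-1)
        assert np.allclose(recon, d, atol=1e-8)
        n = 7
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ (d ** 2) @ j
        assert res.eigenvalues.sum() == pytest.approx(np.trace(b), abs=1e-10)

    def test_bray_curtis_matrix_against_skbio(self, random_counts):
        dm = distance_matrix(random_counts)
        ours = pcoa(dm)
        ref = skbio_pcoa(dm)
        ref_evals = np.asarray(ref.eigvals)
        ref_pos = np.sort(ref_evals[ref_evals > 1e-9])[::-1]
        assert np.allclose(ours.eigenvalues[:len(ref_pos)], ref_pos,
                           atol=1e-8)
        # distortion from dropped negative eigenvalues bounds the error
        recon = np.linalg.norm(
            ours.coordinates[:, None] - ours.coordinates[None], axis=-1)
        err = np.abs(recon ** 2 - np.asarray(dm.data) ** 2).max()
        assert err <= 4 * ours.negative_eigenvalue_magnitude + 1e-8

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            pcoa(DistanceMatrix(np.zeros((3, 3)), ids=list("abc")))


class TestPermanova:
    def _random_dm(self, n, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 5))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])

    def test_statistic_matches_skbio(self):
        dm = self._random_dm(14, 1)
        labels = np.array(["a"] * 7 + ["b"] * 7)
        ours = permanova(dm, labels, 99, 0)
        ref = skbio_permanova(dm, labels.tolist(), permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"],
                                               abs=1e-9)

    def test_relabeling_invariance(self):
        dm = self._random_dm(12, 2)
        labels = np.array(["a", "b"] * 6)
        base = permanova(dm, labels, 99, 0).statistic
        perm = np.random.default_rng(5).permutation(12)
        d2 = np.asarray(dm.data)[np.ix_(perm, perm)]
        shuffled = permanova(
            DistanceMatrix(d2, ids=[f"s{i}" for i in range(12)]),
            labels[perm], 99, 0).statistic
        assert shuffled == pytest.approx(base, abs=1e-12)

    def test_separated_clusters_saturate_p(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.1, (6, 3)),
                         rng.normal(50, 0.1, (6, 3))])
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(12)])
        res = permanova(dm, ["a"] * 6 + ["b"] * 6, 199, 0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_preconditions(self):
        dm = self._random_dm(6, 3)
        with pytest.raises(ValidationError, match="2 groups"):
            permanova(dm, ["a"] * 6, 99, 0)
        with pytest.raises(ValidationError, match="fewer than 2"):
            permanova(dm, ["a"] * 5 + ["b"], 99, 0)
        with pytest.raises(ValidationError, match="99"):
            permanova(dm, ["a"] * 3 + ["b"] * 3, 50, 0)

    def test_seed_reproducibility(self):
        dm = self._random_dm(10, 4)
        labels = ["a"] * 5 + ["b"] * 5
        r1 = permanova(dm, labels, 199, 7)
        r2 = permanova(dm, labels, 199, 7)
        assert r1 == r2


class TestAlphaGroupTest:
    def test_exact_enumeration_minimal_p(self):
        # 20 arrangements of ranks for n=3,3; fully separated groups sit at
        # both extremes -> two-sided p = 2/20
        res = alpha_group_test([1, 2, 3], [10, 11, 12])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "mannwhitneyu-exact"

    def test_identical_groups_p_near_one(self):
        res = alpha_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value >= 0.99

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=10), rng.normal(1, 1, size=12)
        res1 = alpha_group_test(a, b)
        res2 = alpha_group_test(np.exp(a), np.exp(b))
        assert res1.p_value == pytest.approx(res2.p_value, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            alpha_group_test([1, 2], [3, 4, 5])


class TestPatientClustering:
    def test_extreme_case(self):
        # within-patient distances 0, between-patient 1, for 6 patients
        # with 2 specimens each: statistic 1, p saturates at 1/(P+1)
        n = 12
        ids = [f"s{i}" for i in range(n)]
        patient_of = {s: f"pat{i // 2}" for i, s in enumerate(ids)}
        d = np.ones((n, n)) - np.eye(n)
        for i in range(0, n, 2):
            d[i, i + 1] = d[i + 1, i] = 0.0
        dm = DistanceMatrix(d, ids=ids)
        res = patient_clustering_test(dm, patient_of, 199, 0)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_shuffled_labels_give_null_statistic(self):
        # destroying the patient structure before input: statistic near 0
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(16, 4))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
        ids = [f"s{i}" for i in range(16)]
        dm = DistanceMatrix(d, ids=ids)
        stats, ps = [], []
        for rep in range(30):
            labels = rng.permutation([f"p{i // 2}" for i in range(16)])
            res = patient_clustering_test(dm, dict(zip(ids, labels)),
                                          199, seed=rep)
            stats.append(res.statistic)
            ps.append(res.p_value)
        assert abs(np.mean(stats)) < 0.05
        assert 0.2 < np.mean(ps) < 0.8

    def test_requires_multi_specimen_patients(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(d, ids=["a", "b", "c"])
        with pytest.raises(ValidationError):
            patient_clustering_test(dm, {"a": "A", "b": "B", "c": "C"},
                                    199, 0)


class TestCompositionSummary:
    def test_single_sample_is_its_own_composition(self, random_counts):
        one = random_counts.subset_samples(["s0"])
        rel = one.to_relative()
        out = composition_summary(rel, {"s0": "g"})
        assert np.allclose(out["g"], rel.data["s0"])

    def test_two_disjoint_samples_average(self):
        t = AbundanceTable(pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"],
                                        columns=["s1", "s2"]))
        out = composition_summary(t, {"s1": "g", "s2": "g"})
        assert out["g"].tolist() == [0.5, 0.5]

    def test_matches_per_group_loop_oracle(self, random_counts):
        groups = {s: ("x" if i % 2 else "y")
                  for i, s in enumerate(random_counts.sample_ids)}
        out = composition_summary(random_counts, groups)
        rel = random_counts.to_relative().data
        for g in ("x", "y"):
            cols = [s for s in rel.columns if groups[s] == g]
            assert np.allclose(out[g], rel[cols].mean(axis=1), atol=1e-12)
        assert np.allclose(out.sum(axis=0), 1.0, atol=1e-9)

    def test_level_map_and_top_k(self, random_counts):
        level_map = {"g0": "PhylumA", "g1": "PhylumA", "g2": "PhylumB"}
        with pytest.warns(UserWarning, match="Unclassified"):
            out = composition_summary(
                random_counts, {s: "all" for s in random_counts.sample_ids},
                level_map=level_map)
        assert set(out.index) == {"PhylumA", "PhylumB", "Unclassified"}
        top = composition_summary(
            random_counts, {s: "all" for s in random_counts.sample_ids},
            top_k=2)
        assert list(top.index)[-1] == "Other"
        assert np.allclose(top.sum(axis=0), 1.0, atol=1e-9)
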