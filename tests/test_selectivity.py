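import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketeer.selectivity_analysis import (
    DistanceMatrix,
    classical_mds,
    distance_matrix,
    distinctness,
    roc_evaluate,
    selectivity_row,
    spearman_matrix_corr,
    SelectivityRow,
)
from pocketeer.structure_io import DONOR, HYDROPHOBE, TypedAtomSet
from pocketeer.shape_align import AlignConfig

from oracles import auc_pair_count_oracle, spearman_oracle

FAST = AlignConfig(n_random_starts=1, max_evals=80)


def _set(rng, n=4):
    feats = [HYDROPHOBE] * (n - 1) + [DONOR]
    return TypedAtomSet(rng.uniform(-3, 3, (n, 3)), feats,
                        np.full(n, 1.6))


class TestDistanceMatrix:
    def test_duplicate_entry_near_zero(self):
        rng = np.random.default_rng(0)
        a = _set(rng)
        b = _set(rng)
        dm = distance_matrix([a, a, b], config=FAST)
        assert dm.values[0, 1] < 1e-3
        assert dm.values.shape == (3, 3)

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(1)
        sets = [_set(rng) for _ in range(4)]
        dm = distance_matrix(sets, config=FAST)
        np.testing.assert_allclose(dm.values, dm.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(dm.values), 0.0)

    def test_too_few_exemplars(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="at least 2"):
            distance_matrix([_set(rng)])


class TestClassicalMds:
    def test_3_4_5_triangle_reproduced(self):
        labels = ["a", "b", "c"]
        d = np.array([[0.0, 3, 4], [3, 0, 5], [4, 5, 0]])
        dm = DistanceMatrix(labels, d)
        coords = classical_mds(dm, dim=2).to_numpy()
        got = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.testing.assert_allclose(got, d, atol=1e-9)

    def test_collinear_second_axis_zero(self):
        labels = list("abcd")
        x = np.array([0.0, 1, 2, 3])
        d = np.abs(x[:, None] - x[None, :])
        coords = classical_mds(DistanceMatrix(labels, d), dim=2).to_numpy()
        np.testing.assert_allclose(coords[:, 1], 0.0, atol=1e-9)

    def test_all_zero_matrix(self):
        dm = DistanceMatrix(list("ab"), np.zeros((2, 2)))
        coords = classical_mds(dm).to_numpy()
        np.testing.assert_allclose(coords, 0.0)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 5, (5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        dm = DistanceMatrix(list("abcde"), d)
        c1 = classical_mds(dm).to_numpy()
        c2 = classical_mds(dm).to_numpy()
        np.testing.assert_array_equal(c1, c2)
        assert c1[np.nonzero(np.abs(c1[:, 0]) > 1e-12)[0][0], 0] > 0

    @given(st.integers(0, 1000))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_euclidean_inputs_reproduced(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-4, 4, (6, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        coords = classical_mds(DistanceMatrix(list("abcdef"), d), dim=2).to_numpy()
        got = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        np.testing.assert_allclose(got, d, atol=1e-9)


class TestDistinctness:
    def test_matches_double_loop(self):
        rng = np.random.default_rng(4)
        n = 15
        vals = rng.uniform(0.1, 2.0, (n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix([f"c{i}" for i in range(n)], vals)
        membership = {"p1": [0, 1, 2, 3, 4], "p2": [5, 6, 7, 8, 9],
                      "p3": [10, 11, 12, 13, 14]}
        out = distinctness(membership, dm)
        for v in out:
            own = [i for i in membership[v.protein_id] if i != v.conformation_id]
            other = [i for p, ix in membership.items() if p != v.protein_id
                     for i in ix]
            assert v.d_self == pytest.approx(min(vals[v.conformation_id, i] for i in own))
            assert v.d_other == pytest.approx(min(vals[v.conformation_id, i] for i in other))
            assert v.distinctness == pytest.approx(v.d_other - v.d_self)

    def test_identical_ensembles_not_distinct(self):
        # two proteins sampling the same two pockets: d_other <= d_self + tol
        vals = np.array([
            [0.0, 1.0, 0.0, 1.0],
            [1.0, 0.0, 1.0, 0.0],
            [0.0, 1.0, 0.0, 1.0],
            [1.0, 0.0, 1.0, 0.0],
        ])
        dm = DistanceMatrix(list("abcd"), vals)
        out = distinctness({"p1": [0, 1], "p2": [2, 3]}, dm)
        assert all(v.distinctness <= 1e-9 for v in out)

    def test_single_conformation_protein_rejected(self):
        dm = DistanceMatrix(list("abc"), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="p2"):
            distinctness({"p1": [0, 1], "p2": [2]}, dm)


class TestSelectivityRow:
    def test_zscore_closed_form(self):
        row = SelectivityRow("r", ["a", "b", "c"], np.array([1.0, 2.0, 3.0]),
                             np.array([0.0, 0, 0]))
        # recompute through the public path with stub ensembles
        mins = np.array([1.0, 2.0, 3.0])
        z = (mins - mins.mean()) / mins.std()
        np.testing.assert_allclose(z, [-1.22474487, 0.0, 1.22474487])

    def test_row_via_exemplars(self):
        rng = np.random.default_rng(5)
        ref = _set(rng, 5)
        far = TypedAtomSet(ref.positions * 0.3 + 8.0,
                           [HYDROPHOBE] * len(ref), np.full(len(ref), 1.3))
        ensembles = {"pa": [ref], "pb": [far], "pc": [far]}
        row = selectivity_row(ref, ensembles, reference_id="self", config=FAST)
        assert row.protein_ids[int(np.argmin(row.z_scores))] == "pa"
        assert row.min_distances[0] == pytest.approx(0.0, abs=1e-3)
        assert row.z_scores.mean() == pytest.approx(0.0, abs=1e-9)
        assert row.z_scores.std() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_row_flagged(self):
        rng = np.random.default_rng(6)
        a = _set(rng)
        ensembles = {"pa": [a], "pb": [a]}
        row = selectivity_row(a, ensembles, config=FAST)
        assert row.degenerate
        np.testing.assert_allclose(row.z_scores, 0.0)


class TestRoc:
    def _rows(self, z_and_labels):
        rows = []
        for rid, cells in z_and_labels.items():
            pids = list(cells)
            z = np.array([cells[p][0] for p in pids], dtype=float)
            labels = {p: cells[p][1] for p in pids}
            rows.append(SelectivityRow(rid, pids, z.copy(), z, labels=labels))
        return rows

    def test_perfect_separation(self):
        rows = self._rows({"r1": {"a": (-1.0, "strong"), "b": (1.0, "none")},
                           "r2": {"a": (-2.0, "strong"), "b": (0.5, "none")}})
        auc, p, (fpr, tpr) = roc_evaluate(rows)
        assert auc == 1.0
        assert fpr[0] == 0.0 and tpr[-1] == 1.0

    def test_inverted_labels(self):
        rows = self._rows({"r1": {"a": (-1.0, "none"), "b": (1.0, "strong")},
                           "r2": {"a": (-2.0, "none"), "b": (0.5, "strong")}})
        auc, _, _ = roc_evaluate(rows)
        assert auc == 0.0

    def test_single_class_error(self):
        rows = self._rows({"r1": {"a": (-1.0, "strong"), "b": (1.0, "strong")}})
        with pytest.raises(ValueError, match="positive and.*negative"):
            roc_evaluate(rows)

    def test_unknown_cells_excluded(self):
        rows = self._rows({"r1": {"a": (-1.0, "strong"), "b": (0.0, "unknown"),
                                  "c": (1.0, "none")}})
        auc, _, _ = roc_evaluate(rows)
        assert auc == 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pos, n_neg = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        pos = np.round(rng.normal(0, 1, n_pos), 1)
        neg = np.round(rng.normal(0.5, 1, n_neg), 1)
        cells = {}
        for i, v in enumerate(pos):
            cells[f"p{i}"] = (v, "strong")
        for i, v in enumerate(neg):
            cells[f"n{i}"] = (v, "none")
        rows = self._rows({"r": cells})
        auc, _, _ = roc_evaluate(rows)
        assert auc == pytest.approx(auc_pair_count_oracle(list(pos), list(neg)))

    def test_antisymmetry_on_tie_free_scores(self):
        rng = np.random.default_rng(8)
        pos = rng.normal(0, 1, 5)
        neg = rng.normal(0.5, 1, 4)
        rows = self._rows({"r": {
            **{f"p{i}": (v, "strong") for i, v in enumerate(pos)},
            **{f"n{i}": (v, "none") for i, v in enumerate(neg)},
        }})
        auc, _, _ = roc_evaluate(rows)
        flipped = self._rows({"r": {
            **{f"p{i}": (-v, "strong") for i, v in enumerate(pos)},
            **{f"n{i}": (-v, "none") for i, v in enumerate(neg)},
        }})
        auc_f, _, _ = roc_evaluate(flipped)
        assert auc + auc_f == pytest.approx(1.0)


class TestSpearman:
    def test_identity(self):
        rng = np.random.default_rng(9)
        m = rng.uniform(0, 2, (5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        rho, _ = spearman_matrix_corr(m, m)
        assert rho == pytest.approx(1.0)

    def test_antitone_transform(self):
        rng = np.random.default_rng(10)
        m = rng.uniform(0, 2, (5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        rho, _ = spearman_matrix_corr(m, -m)
        assert rho == pytest.approx(-1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_rank_then_pearson(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 2, (6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = np.round(a + rng.normal(0, 0.3, a.shape), 1)
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        rho, _ = spearman_matrix_corr(a, b)
        iu = np.triu_indices(6, k=1)
        assert rho == pytest.approx(spearman_oracle(a[iu], b[iu]), abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            spearman_matrix_corr(np.zeros((3, 3)), np.zeros((4, 4)))
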