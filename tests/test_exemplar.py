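import numpy as np
import pytest
from scipy.spatial.distance import pdist

from pocketeer.exemplar import (
    ExemplarParams,
    NoPocketError,
    build_exemplar,
    cluster_exemplar,
    fill_hydrophobic,
    place_polar_probes,
    read_exemplar,
    write_exemplar,
)
from pocketeer.pocket_detection import (
    DEEP_POCKET,
    POCKET,
    SOLVENT,
    GridParams,
    PocketGrid,
)
from pocketeer.structure_io import (
    ACCEPTOR,
    DONOR,
    HYDROPHOBE,
    Atom,
    PolarGroup,
    Structure,
    TypedAtomSet,
)
from pocketeer.synthetic_fixtures import FixtureSpec, make_shell_protein

from oracles import single_linkage_oracle


def _grid_with_pocket_at(point, origin=np.zeros(3), spacing=1.0, dims=(9, 9, 9)):
    labels = np.full(dims, SOLVENT, dtype=np.int8)
    idx = np.round((np.asarray(point) - origin) / spacing).astype(int)
    labels[tuple(idx)] = POCKET
    return PocketGrid(origin, spacing, dims, labels, [("A", 1)])


def _donor_group(position=(0.0, 0.0, 0.0), direction=(1.0, 0.0, 0.0)):
    atom = Atom(1, "N", "N", "GLY", "A", 1, np.asarray(position, float))
    return PolarGroup(atom, DONOR, [np.asarray(direction, float)])


class TestPolarProbes:
    def test_collinear_probe_placement(self):
        grid = _grid_with_pocket_at((3.0, 0.0, 0.0), origin=np.array([-1.0, -4.0, -4.0]))
        st = Structure([Atom(1, "N", "N", "GLY", "A", 1, np.zeros(3))])
        placed = place_polar_probes(st, grid, [_donor_group()])
        assert len(placed) == 1
        np.testing.assert_allclose(placed.positions[0], [2.9, 0, 0])
        assert placed.features == [ACCEPTOR]   # complement of the donor

    def test_probe_outside_pocket_dropped(self):
        grid = _grid_with_pocket_at((8.0, 8.0, 8.0))
        st = Structure([Atom(1, "N", "N", "GLY", "A", 1, np.zeros(3))])
        placed = place_polar_probes(st, grid, [_donor_group()])
        assert len(placed) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_retention_matches_nearest_point_search(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.where(rng.random((9, 9, 9)) < 0.1, POCKET, SOLVENT).astype(np.int8)
        grid = PocketGrid(np.zeros(3), 1.0, (9, 9, 9), labels, [("A", 1)])
        groups = []
        for i in range(8):
            pos = rng.uniform(0, 8, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            atom = Atom(i + 1, "N", "N", "GLY", "A", i + 1, pos)
            groups.append(PolarGroup(atom, DONOR, [d]))
        placed = place_polar_probes(Structure([g.heavy_atom for g in groups]),
                                    grid, groups)
        pocket_pts = np.argwhere(labels == POCKET) * 1.0
        expected = 0
        for g in groups:
            probe = g.heavy_atom.position + 2.9 * g.directions[0]
            if len(pocket_pts) and np.min(
                    np.linalg.norm(pocket_pts - probe, axis=1)) <= 1.0:
                expected += 1
        assert len(placed) == expected


class TestHydrophobicFill:
    def _line_grid(self, n=35, pitch=0.1):
        labels = np.full((n, 1, 1), DEEP_POCKET, dtype=np.int8)
        return PocketGrid(np.zeros(3), pitch, (n, 1, 1), labels, [("A", 1)])

    def test_line_packing(self):
        grid = self._line_grid()  # 3.4 A of deep points at 0.1 A pitch
        empty = TypedAtomSet(np.empty((0, 3)), [], np.empty(0))
        out = fill_hydrophobic(grid, empty)
        assert len(out) == 3
        xs = sorted(out.positions[:, 0])
        assert xs[0] == pytest.approx(0.0)
        assert xs[1] >= 1.7 - 1e-9
        assert xs[2] >= 3.4 - 1e-9

    def test_no_deep_points_is_identity(self):
        labels = np.full((5, 5, 5), POCKET, dtype=np.int8)
        grid = PocketGrid(np.zeros(3), 1.0, (5, 5, 5), labels, [("A", 1)])
        placed = TypedAtomSet(np.array([[1.0, 1, 1]]), [DONOR], np.array([1.5]))
        out = fill_hydrophobic(grid, placed)
        assert len(out) == 1
        assert out.features == [DONOR]

    @pytest.mark.parametrize("seed", range(5))
    def test_greedy_result_feasible_and_maximal(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.where(rng.random((9, 9, 9)) < 0.2, DEEP_POCKET, SOLVENT).astype(np.int8)
        grid = PocketGrid(np.zeros(3), 0.7, (9, 9, 9), labels, [("A", 1)])
        empty = TypedAtomSet(np.empty((0, 3)), [], np.empty(0))
        out = fill_hydrophobic(grid, empty)
        if len(out) > 1:
            assert pdist(out.positions).min() >= 1.7 - 1e-9
        # maximality: every remaining deep point violates the spacing
        deep_pts = grid.point_coords(labels == DEEP_POCKET)
        for p in deep_pts:
            dmin = np.min(np.linalg.norm(out.positions - p, axis=1))
            assert dmin < 1.7 or dmin == pytest.approx(0.0)

    def test_shrinking_spacing_never_reduces_count(self):
        rng = np.random.default_rng(11)
        labels = np.where(rng.random((9, 9, 9)) < 0.3, DEEP_POCKET, SOLVENT).astype(np.int8)
        grid = PocketGrid(np.zeros(3), 0.7, (9, 9, 9), labels, [("A", 1)])
        empty = TypedAtomSet(np.empty((0, 3)), [], np.empty(0))
        counts = [
            len(fill_hydrophobic(grid, empty, ExemplarParams(min_spacing=s)))
            for s in (2.5, 2.0, 1.7, 1.2)
        ]
        assert counts == sorted(counts)


class TestClustering:
    def _grid(self):
        labels = np.full((5, 5, 5), SOLVENT, dtype=np.int8)
        return PocketGrid(np.zeros(3), 1.0, (5, 5, 5), labels, [("A", 1)])

    def _structure(self, target=(0.0, 0.0, 0.0)):
        return Structure([Atom(1, "C", "C", "ALA", "A", 1, np.asarray(target, float))])

    def test_below_threshold_single_component(self):
        atoms = TypedAtomSet(np.array([[0.0, 0, 0], [4.9, 0, 0]]),
                             [HYDROPHOBE, HYDROPHOBE], np.array([1.7, 1.7]))
        ex = cluster_exemplar(atoms, self._grid(), self._structure())
        assert len(ex) == 2

    def test_above_threshold_keeps_target_proximal(self):
        atoms = TypedAtomSet(np.array([[0.0, 0, 0], [5.1, 0, 0]]),
                             [HYDROPHOBE, DONOR], np.array([1.7, 1.5]))
        ex = cluster_exemplar(atoms, self._grid(), self._structure((0.0, 0, 0)))
        assert len(ex) == 1
        assert ex.atoms.features == [HYDROPHOBE]

    def test_empty_input_is_error(self):
        empty = TypedAtomSet(np.empty((0, 3)), [], np.empty(0))
        with pytest.raises(ValueError, match="empty"):
            cluster_exemplar(empty, self._grid(), self._structure())

    @pytest.mark.parametrize("seed", range(5))
    def test_components_match_union_find(self, seed):
        rng = np.random.default_rng(40 + seed)
        n = int(rng.integers(5, 15))
        pts = rng.uniform(0, 15, (n, 3))
        atoms = TypedAtomSet(pts, [HYDROPHOBE] * n, np.full(n, 1.7))
        params = ExemplarParams(keep_all_components=True)
        ex = cluster_exemplar(atoms, self._grid(), self._structure(), params)
        assert len(ex) == n  # keep_all retains everything
        # the retained component under default params is one oracle component
        ex1 = cluster_exemplar(atoms, self._grid(), self._structure())
        oracle = single_linkage_oracle(pts, 5.0)
        kept = frozenset(
            i for i in range(n)
            if any(np.allclose(pts[i], q) for q in ex1.atoms.positions))
        assert kept in oracle


class TestBuildExemplar:
    def test_convex_shell_has_no_pocket(self):
        shell = make_shell_protein(FixtureSpec(seed=2))
        with pytest.raises(NoPocketError):
            build_exemplar(shell, [("A", 5)], GridParams(14.0, 0.7))

    def test_cup_exemplar_has_probe_and_hydrophobes(self, cup_exemplar):
        feats = cup_exemplar.atoms.features
        assert feats.count(DONOR) >= 1        # from the buried carbonyl
        assert feats.count(HYDROPHOBE) >= 3
        assert cup_exemplar.deep_volume > 0

    def test_spacing_invariant(self, cup_exemplar):
        assert pdist(cup_exemplar.atoms.positions).min() >= 1.7 - 1e-9

    def test_hydrophobes_on_deep_points(self, cup, cup_targets, grid_params):
        from pocketeer.pocket_detection import detect_pockets

        grid, _, _ = detect_pockets(cup, cup_targets, grid_params)
        deep_pts = grid.point_coords(grid.labels == DEEP_POCKET)
        ex = build_exemplar(cup, cup_targets, grid_params)
        for pos, feat in zip(ex.atoms.positions, ex.atoms.features):
            if feat == HYDROPHOBE:
                assert np.min(np.linalg.norm(deep_pts - pos, axis=1)) < 1e-9

    def test_deterministic_output(self, cup, cup_targets, grid_params):
        a = write_exemplar(build_exemplar(cup, cup_targets, grid_params))
        b = write_exemplar(build_exemplar(cup, cup_targets, grid_params))
        assert a == b


class TestExemplarIO:
    def test_round_trip(self, cup_exemplar):
        text = write_exemplar(cup_exemplar)
        back = read_exemplar(text)
        np.testing.assert_allclose(back.atoms.positions,
                                   np.round(cup_exemplar.atoms.positions, 3),
                                   atol=1e-9)
        assert back.atoms.features == cup_exemplar.atoms.features
        np.testing.assert_allclose(back.atoms.radii, cup_exemplar.atoms.radii,
                                   atol=0.01)
        assert back.deep_volume == pytest.approx(cup_exemplar.deep_volume, abs=1e-3)

    def test_empty_refused(self):
        from pocketeer.exemplar import Exemplar

        empty = Exemplar(TypedAtomSet(np.empty((0, 3)), [], np.empty(0)))
        with pytest.raises(ValueError, match="empty"):
            write_exemplar(empty)

    def test_line_count(self):
        from pocketeer.exemplar import Exemplar

        rng = np.random.default_rng(0)
        n = 100
        atoms = TypedAtomSet(rng.uniform(0, 20, (n, 3)),
                             [HYDROPHOBE] * n, np.full(n, 1.7))
        text = write_exemplar(Exemplar(atoms, source="big"))
        assert len(text.splitlines()) == n + 2   # REMARK header + END

    def test_malformed_record(self):
        with pytest.raises(ValueError, match="malformed"):
            read_exemplar("HETATM    1  X   XYZ X   1       bad\n")
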