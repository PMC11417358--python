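"""Phosphate point extraction, triplet geometry, superposition, chains
and clash resolution."""

import itertools

import numpy as np
import pytest

from nucleograph.builder import (ChainCandidate, Fragment, Placement,
                                 assemble_chains, build_model, clash_score,
                                 extract_phosphate_points, find_triplets,
                                 interior_angle, prune_isolated,
                                 resolve_clashes, score_placement,
                                 superpose_fragment)
from nucleograph.maps import Atom, AtomicModel, DensityMap, OrthoGrid
from nucleograph.synthetic import make_fragment_library
from nucleograph.training import random_rotation


def _bump_grid(centres, shape=(40, 40, 40), spacing=0.7, sigma=1.2, amp=1.0):
    """Grid with Gaussian bumps at given Cartesian centres."""
    idx = np.indices(shape).astype(float) * spacing
    vals = np.zeros(shape)
    for c in np.atleast_2d(centres):
        d2 = sum((idx[i] - c[i]) ** 2 for i in range(3))
        vals += amp * np.exp(-d2 / (2 * sigma ** 2))
    return OrthoGrid(values=vals, spacing=spacing, origin=np.zeros(3))


class TestExtractPoints:
    def test_single_blob_single_point(self):
        centre = np.array([14.1, 13.8, 14.3])
        grid = _bump_grid(centre)
        pts = extract_phosphate_points(grid)
        assert len(pts) == 1
        assert np.linalg.norm(pts[0].position - centre) < 0.5

    def test_two_distant_blobs_two_points(self):
        c1 = np.array([9.0, 14.0, 14.0])
        c2 = np.array([19.0, 14.0, 14.0])
        pts = extract_phosphate_points(_bump_grid([c1, c2]))
        assert len(pts) == 2
        got = sorted(p.position[0] for p in pts)
        assert abs(got[0] - 9.0) < 0.5 and abs(got[1] - 19.0) < 0.5

    def test_nearby_maxima_merged_to_mean(self):
        # two maxima 1.0 Å apart collapse into their mean
        pts = np.array([[10.0, 10.0, 10.0], [11.0, 10.0, 10.0]])
        from nucleograph.builder import _merge_points
        merged = _merge_points(pts, 1.5)
        assert merged.shape == (1, 3)
        np.testing.assert_allclose(merged[0], [10.5, 10.0, 10.0])

    def test_all_zero_prediction_empty(self):
        grid = OrthoGrid(values=np.zeros((20, 20, 20)), spacing=0.7,
                         origin=np.zeros(3))
        assert extract_phosphate_points(grid) == []

    def test_refined_point_stays_in_positive_region(self):
        centre = np.array([14.0, 14.0, 14.0])
        pred = _bump_grid(centre)
        # density maximum displaced 1 Å from the predicted maximum
        density = _bump_grid(centre + np.array([1.0, 0.0, 0.0]))
        pts = extract_phosphate_points(pred, density)
        assert len(pts) == 1
        assert pred.sample(pts[0].position[None])[0] > 0.1
        assert pts[0].refined


def brute_force_triplets(pos, max_dist=8.0, lo=100.0, hi=180.0):
    """O(n^3) enumeration oracle with the same dedupe rule."""
    best = {}
    n = len(pos)
    for j in range(n):
        for i, k in itertools.combinations(
                [x for x in range(n) if x != j], 2):
            if np.linalg.norm(pos[i] - pos[j]) > max_dist:
                continue
            if np.linalg.norm(pos[j] - pos[k]) > max_dist:
                continue
            ang = interior_angle(pos[i], pos[j], pos[k])
            if not (lo <= ang <= hi):
                continue
            key = frozenset((i, j, k))
            tup = (i, j, k) if i < k else (k, j, i)
            if key not in best or tup < best[key]:
                best[key] = tup
    return sorted(best.values())


class TestTriplets:
    def test_collinear_points(self):
        pos = np.array([[0.0, 0, 0], [6.0, 0, 0], [12.0, 0, 0]])
        trips = find_triplets(pos)
        assert len(trips) == 1
        assert trips[0].indices == (0, 1, 2)
        assert trips[0].angle_deg == pytest.approx(180.0)

    def test_right_angle_rejected(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0], [5.0, 5.0, 0]])
        assert find_triplets(pos) == []

    def test_far_apart_rejected(self):
        pos = np.array([[0.0, 0, 0], [9.0, 0, 0], [18.0, 0, 0]])
        assert find_triplets(pos) == []

    def test_fewer_than_three_points(self):
        assert find_triplets(np.zeros((2, 3))) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_points(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.random((20, 3)) * 30.0
        got = [t.indices for t in find_triplets(pos)]
        assert got == brute_force_triplets(pos)


class TestSuperposition:
    @pytest.fixture(scope="class")
    def fragment(self):
        return make_fragment_library()[0]

    def test_self_superposition_identity(self, fragment):
        pls = superpose_fragment(fragment, fragment.p_positions)
        fw = [p for p in pls if p.direction == "5'->3'"][0]
        assert fw.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fw.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(fw.translation, 0.0, atol=1e-9)

    def test_rigid_motion_recovered(self, fragment):
        rot = random_rotation(np.random.default_rng(3))
        shift = np.array([5.0, -2.0, 7.0])
        target = fragment.p_positions @ rot.T + shift
        fw = [p for p in superpose_fragment(fragment, target)
              if p.direction == "5'->3'"][0]
        assert fw.rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fw.rotation, rot, atol=1e-8)

    def test_rmsd_invariant_under_rigid_motion(self, fragment, rng):
        noisy = fragment.p_positions + rng.normal(0, 0.3, (3, 3))
        base = min(p.rmsd for p in superpose_fragment(fragment, noisy))
        rot = random_rotation(np.random.default_rng(9))
        moved = noisy @ rot.T + np.array([3.0, 4.0, 5.0])
        after = min(p.rmsd for p in superpose_fragment(fragment, moved))
        assert after == pytest.approx(base, abs=1e-6)

    def test_noisy_target_rmsd_near_noise_scale(self, fragment, rng):
        noise = 0.3
        noisy = fragment.p_positions + rng.normal(0, noise, (3, 3))
        fw = [p for p in superpose_fragment(fragment, noisy)
              if p.direction == "5'->3'"][0]
        # coarse rotation grid search as an independent oracle
        best = np.inf
        src = fragment.p_positions - fragment.p_positions.mean(axis=0)
        dst = noisy - noisy.mean(axis=0)
        from scipy.spatial.transform import Rotation
        for a in np.linspace(0, 2 * np.pi, 13)[:-1]:
            for b in np.linspace(0, np.pi, 7):
                for c in np.linspace(0, 2 * np.pi, 13)[:-1]:
                    m = Rotation.from_euler("zyz", [a, b, c]).as_matrix()
                    r = np.sqrt(np.mean(np.sum((src @ m.T - dst) ** 2,
                                               axis=1)))
                    best = min(best, r)
        assert fw.rmsd <= best + 1e-9
        assert fw.rmsd < 3 * noise

    def test_coincident_points_rejected(self, fragment):
        bad = np.array([[0.0, 0, 0], [0.0, 0, 0], [5.0, 0, 0]])
        with pytest.raises(ValueError, match="coincident"):
            superpose_fragment(fragment, bad)

    def test_both_directions_returned(self, fragment):
        pls = superpose_fragment(fragment, fragment.p_positions + 1.0)
        assert {p.direction for p in pls} == {"5'->3'", "3'->5'"}


class TestScoring:
    def _const_map(self, c, shape=(30, 30, 30)):
        return OrthoGrid(values=np.full(shape, c), spacing=1.0,
                         origin=np.full(3, -15.0))

    def test_zero_density_zero_score(self):
        frag = make_fragment_library()[0]
        assert score_placement(frag, self._const_map(0.0)) == 0.0

    def test_constant_density_linear(self):
        frag = make_fragment_library()[0]
        k = sum(1 for a in frag.atoms
                if a.name in {"P", "OP1", "OP2", "O5'", "O3'", "C1'", "C2'",
                              "C3'", "C4'", "C5'", "O4'", "O2'"})
        assert score_placement(frag, self._const_map(2.0)) == \
            pytest.approx(2.0 * k)

    def test_centered_beats_displaced(self, duplex10, duplex10_map):
        frag = make_fragment_library()[0]
        anchors = np.array([a.pos for a in duplex10.atoms
                            if a.name == "P" and a.chain == "A"][:3])
        good = [p for p in superpose_fragment(frag, anchors)
                if p.direction == "5'->3'"][0]
        displaced = Fragment(
            atoms=[Atom(a.name, a.element, a.pos + np.array([5.0, 0, 0]),
                        a.res_seq, a.res_name, a.chain, a.kind)
                   for a in good.fragment.atoms])
        assert score_placement(good.fragment, duplex10_map) > \
            score_placement(displaced, duplex10_map)


class TestChains:
    def _placement(self, triplet, direction, score, offset=0.0):
        frag = make_fragment_library()[0]
        pl = Placement(fragment=frag, rotation=np.eye(3),
                       translation=np.zeros(3), rmsd=0.0,
                       direction=direction, triplet=triplet, score=score)
        return pl

    def test_disjoint_triplets_make_two_chains(self):
        density = OrthoGrid(values=np.ones((10, 10, 10)), spacing=1.0,
                            origin=np.zeros(3))
        pls = [self._placement((0, 1, 2), "5'->3'", 1.0),
               self._placement((0, 1, 2), "3'->5'", 0.5),
               self._placement((5, 6, 7), "5'->3'", 1.0),
               self._placement((5, 6, 7), "3'->5'", 0.5)]
        chains = assemble_chains(pls, density)
        assert len(chains) == 2

    def test_shared_anchor_pair_joins(self):
        density = OrthoGrid(values=np.ones((10, 10, 10)), spacing=1.0,
                            origin=np.zeros(3))
        pls = [self._placement((0, 1, 2), "5'->3'", 1.0),
               self._placement((1, 2, 3), "5'->3'", 1.0)]
        chains = assemble_chains(pls, density)
        assert len(chains) == 1
        assert chains[0].anchor_path == [0, 1, 2, 3]

    def test_direction_tie_prefers_5_to_3(self):
        density = OrthoGrid(values=np.ones((10, 10, 10)), spacing=1.0,
                            origin=np.zeros(3))
        pls = [self._placement((0, 1, 2), "5'->3'", 1.0),
               self._placement((0, 1, 2), "3'->5'", 1.0)]
        chains = assemble_chains(pls, density)
        assert chains[0].direction == "5'->3'"

    def test_end_to_end_duplex_recovery(self, duplex10, duplex10_map):
        from nucleograph.inference import OracleNetwork, predict
        from nucleograph.maps import interpolate_to_ortho
        from nucleograph.training import make_target_map
        ortho = interpolate_to_ortho(duplex10_map, 0.7)
        truth = make_target_map(duplex10, ortho, "phosphate")
        pred = predict(duplex10_map, OracleNetwork(truth.values))
        built, points, chains = build_model(pred, duplex10_map)
        planted = np.array([a.pos for a in duplex10.atoms if a.name == "P"])
        built_p = np.array([a.pos for a in built.atoms if a.name == "P"])
        assert len(built_p) > 0
        from scipy.spatial import cKDTree
        d, _ = cKDTree(built_p).query(planted)
        assert np.mean(d <= 1.5) >= 0.9
        # a single chain should span most of one strand
        assert max(len(c.anchor_path) for c in chains) >= 8


def _flat_diff_map(value, origin=(-10.0, -10.0, -10.0), shape=(20, 20, 20)):
    cell = tuple(np.array(shape) * 1.0) + (90.0, 90.0, 90.0)
    return DensityMap(values=np.full(shape, value), cell=cell,
                      origin=np.array(origin))


class TestClashScore:
    def _atoms(self, pos_list, kind="nucleic", chain="N", names=None):
        names = names or ["P"] * len(pos_list)
        return [Atom(n, n[0], np.asarray(p, dtype=float), i + 1, "DA",
                     chain, kind)
                for i, (n, p) in enumerate(zip(names, pos_list))]

    def test_zero_field_scores_zero(self):
        atoms = self._atoms([[0.0, 0.0, 0.0]])
        assert clash_score(atoms, _flat_diff_map(0.0)) == 0.0

    def test_constant_field_scores_minus_abs(self):
        atoms = self._atoms([[0.0, 0.0, 0.0]])
        assert clash_score(atoms, _flat_diff_map(-1.7)) == \
            pytest.approx(-1.7)

    def test_matches_brute_force_enumeration(self, rng):
        shape = (14, 14, 14)
        vals = rng.normal(size=shape)
        cell = tuple(np.array(shape) * 1.0) + (90.0, 90.0, 90.0)
        dmap = DensityMap(values=vals, cell=cell,
                          origin=np.array([-7.0, -7.0, -7.0]))
        atoms = self._atoms([[0.0, 0.0, 0.0], [2.0, 1.0, 0.0]])
        # brute force: every grid point within 5 Å of any atom
        total, n = 0.0, 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    p = dmap.origin + np.array([i, j, k]) * 1.0
                    if min(np.linalg.norm(p - a.pos) for a in atoms) <= 5.0:
                        total += abs(vals[i, j, k])
                        n += 1
        assert clash_score(atoms, dmap) == pytest.approx(-total / n)

    def test_always_nonpositive(self, rng):
        vals = rng.normal(size=(12, 12, 12))
        dmap = DensityMap(values=vals, cell=(12.0, 12.0, 12.0, 90, 90, 90),
                          origin=np.array([-6.0, -6.0, -6.0]))
        atoms = self._atoms([[0.0, 0.0, 0.0]])
        assert clash_score(atoms, dmap) <= 0.0

    def test_region_far_from_grid_rejected(self):
        atoms = self._atoms([[100.0, 100.0, 100.0]])
        with pytest.raises(ValueError, match="5"):
            clash_score(atoms, _flat_diff_map(1.0))


class TestResolveClashes:
    def _protein(self, x0=0.0):
        atoms = []
        for i in range(3):
            for name in ("N", "CA", "C"):
                off = {"N": -1.2, "CA": 0.0, "C": 1.2}[name]
                atoms.append(Atom(name, name[0],
                                  np.array([x0 + i * 3.8 + off, 0.0, 0.0]),
                                  i + 1, "ALA", "P", "protein"))
        return AtomicModel(atoms)

    def _nucleic(self, origin):
        atoms = []
        for i in range(2):
            base = np.asarray(origin, dtype=float) + np.array([i * 6.0, 0, 0])
            for name, off in (("P", [0.0, 0, 0]), ("O5'", [1.5, 0, 0]),
                              ("O3'", [4.5, 0.0, 0.0])):
                atoms.append(Atom(name, name[0], base + off, i + 1, "DA",
                                  "N", "nucleic"))
        return AtomicModel(atoms)

    def test_non_overlapping_concatenated(self):
        prot = self._protein()
        nuc = self._nucleic([0.0, 8.0, 0.0])
        merged = resolve_clashes(prot, nuc, _flat_diff_map(1.0))
        assert len(merged) == len(prot) + len(nuc)

    def test_weaker_density_side_removed(self):
        # nucleic sits atop the protein; density is strong only around the
        # nucleic side's neighbourhood, so the protein (weaker) is removed
        prot = self._protein()
        nuc = self._nucleic([0.0, 0.5, 0.0])
        shape = (20, 20, 20)
        vals = np.zeros(shape)
        origin = np.array([-5.0, -10.0, -10.0])
        idx = np.indices(shape).astype(float)
        # strong |rho| everywhere within the shared neighbourhood
        vals[:] = 2.0
        merged = resolve_clashes(prot, nuc, DensityMap(
            values=vals, cell=(20.0, 20.0, 20.0, 90, 90, 90), origin=origin))
        kinds = {a.kind for a in merged.atoms}
        # equal scores: protein removed on the >= tie rule
        assert "nucleic" in kinds and "protein" not in kinds

    def test_isolated_nucleotide_pruned(self):
        nuc = self._nucleic([0.0, 0.0, 0.0])
        lone = Atom("P", "P", np.array([50.0, 50.0, 50.0]), 99, "DA", "N",
                    "nucleic")
        model = AtomicModel(nuc.atoms + [lone])
        pruned = prune_isolated(model)
        assert all(a.res_seq != 99 for a in pruned.atoms)
        assert len(pruned) == len(nuc)
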