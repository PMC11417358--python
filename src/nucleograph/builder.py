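"""Phosphate-guided nucleic-acid backbone building.

From a predicted phosphate map plus a real-space density map:

1. grid points above a 0.1 threshold climb the trilinear interpolant of the
   predicted map to their local maxima; maxima within 1.5 Å of one another
   are averaged into single phosphorus estimates, each then refined to the
   local density maximum while staying inside the positive predicted region;
2. point triplets with inter-point distances up to 8 Å and an interior
   angle of 150 +/- 50 degrees at the middle point become superposition
   candidates;
3. trinucleotide template fragments are rigidly superposed onto each
   triplet in both the 3' and 5' directions (least-squares on the three P
   atoms, no further refinement) and scored by summed density at the
   phosphate and sugar atom positions;
4. placements sharing consecutive phosphate anchors are joined into chains,
   the two direction variants of each chain are compared by mean density
   and the better kept.

Clash resolution between a protein and a nucleic model uses the mean
absolute difference density within 5 Å of a clashing region (reported
negated, so 0 is best and more negative means stronger density): the side
with the higher (weaker-density) score is removed, then isolated residues
with no neighbouring atoms within 2.5 Å of their bonding atoms are pruned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .maps import Atom, AtomicModel, DensityMap, OrthoGrid, interpolate_to_ortho
from .training import PHOSPHATE_ATOMS, SUGAR_ATOMS

PRED_THRESHOLD = 0.1
MERGE_RADIUS = 1.5        # Å
TRIPLET_MAX_DIST = 8.0    # Å
TRIPLET_ANGLE_CENTER = 150.0
TRIPLET_ANGLE_TOL = 50.0
ASCENT_STEP = 0.2         # Å
ASCENT_TOL = 1e-4
ASCENT_MAX_ITER = 200
CLASH_DIST = 1.0          # Å
CLASH_SHELL = 5.0         # Å
PRUNE_DIST = 2.5          # Å
NUCLEIC_BOND_ATOMS = {"P", "O5'", "O3'"}
PROTEIN_BOND_ATOMS = {"N", "C"}


@dataclass
class PhosphatePoint:
    position: np.ndarray
    predicted_value: float
    refined: bool = False


@dataclass
class Triplet:
    indices: tuple[int, int, int]  # ordered, middle point second
    max_pair_distance: float
    angle_deg: float


@dataclass
class Fragment:
    """A trinucleotide template: atoms plus its three phosphorus anchors."""

    atoms: list[Atom]
    direction: str = "5'->3'"

    @property
    def p_positions(self) -> np.ndarray:
        ps = [a.pos for a in self.atoms if a.name == "P"]
        if len(ps) != 3:
            raise ValueError(
                f"fragment must contain exactly 3 P atoms, got {len(ps)}")
        return np.array(ps)

    def transformed(self, rot: np.ndarray, shift: np.ndarray,
                    direction: str) -> "Fragment":
        atoms = [Atom(a.name, a.element, rot @ a.pos + shift, a.res_seq,
                      a.res_name, a.chain, a.kind) for a in self.atoms]
        return Fragment(atoms=atoms, direction=direction)


@dataclass
class Placement:
    fragment: Fragment
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    direction: str
    triplet: tuple[int, int, int] | None = None
    score: float = 0.0


@dataclass
class ChainCandidate:
    fragments: list[Placement]
    direction: str
    fit_score: float
    anchor_path: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Phosphate point extraction

def _gradient_ascent(start: np.ndarray, grid, step: float = ASCENT_STEP,
                     tol: float = ASCENT_TOL,
                     max_iter: int = ASCENT_MAX_ITER,
                     constraint=None) -> np.ndarray:
    """Vectorised hill climb on a trilinear interpolant.

    ``constraint(pos) -> bool array`` may veto proposed steps (used to keep
    density refinement inside the positive predicted region).
    """
    pos = np.array(start, dtype=float)
    if pos.ndim == 1:
        pos = pos[None]
    val = grid.sample(pos)
    active = np.ones(len(pos), dtype=bool)
    h = 0.5 * step
    for _ in range(max_iter):
        if not active.any():
            break
        p = pos[active]
        grad = np.empty_like(p)
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = h
            grad[:, ax] = (grid.sample(p + dp) - grid.sample(p - dp)) / (2 * h)
        norm = np.linalg.norm(grad, axis=1)
        moving = norm > 1e-12
        prop = p.copy()
        prop[moving] += step * grad[moving] / norm[moving, None]
        new_val = grid.sample(prop)
        improve = new_val - val[active]
        ok = moving & (improve > tol)
        if constraint is not None:
            ok &= constraint(prop)
        upd = np.where(active)[0][ok]
        pos[upd] = prop[ok]
        val[upd] = new_val[ok]
        still = np.zeros_like(active)
        still[upd] = True
        active = still
    return pos


def _merge_points(points: np.ndarray, radius: float) -> np.ndarray:
    """Average mutually-nearby points (single-linkage components)."""
    if len(points) == 0:
        return points
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    parent = np.arange(len(points))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(len(points))])
    merged = [points[roots == r].mean(axis=0) for r in np.unique(roots)]
    return np.array(merged)


def extract_phosphate_points(pred, density=None,
                             threshold: float = PRED_THRESHOLD,
                             merge_radius: float = MERGE_RADIUS
                             ) -> list[PhosphatePoint]:
    """Estimate one phosphorus position per predicted phosphate blob.

    ``pred`` and ``density`` may be :class:`DensityMap` or
    :class:`OrthoGrid`.  With no density given, the merge result is
    returned unrefined.
    """
    mask = pred.values > threshold
    if not mask.any():
        return []
    idx = np.argwhere(mask).astype(float)
    if isinstance(pred, OrthoGrid):
        starts = pred.origin + idx * pred.spacing
    else:
        frac = idx / np.array(pred.shape)
        starts = frac @ pred.orth.T + pred.origin
    maxima = _gradient_ascent(starts, pred)
    merged = _merge_points(maxima, merge_radius)
    refined = False
    if density is not None:
        inside = lambda p: pred.sample(p) > threshold  # noqa: E731
        merged = _gradient_ascent(merged, density, constraint=inside)
        refined = True
    values = pred.sample(merged)
    return [PhosphatePoint(position=m, predicted_value=float(v),
                           refined=refined)
            for m, v in zip(merged, values)]


# ---------------------------------------------------------------------------
# Triplets

def interior_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b in degrees, range [0, 180]."""
    u = a - b
    v = c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def find_triplets(points: list[PhosphatePoint] | np.ndarray,
                  max_dist: float = TRIPLET_MAX_DIST,
                  angle_center: float = TRIPLET_ANGLE_CENTER,
                  angle_tol: float = TRIPLET_ANGLE_TOL) -> list[Triplet]:
    """All point triples usable as trinucleotide anchors.

    A triple qualifies when both legs from the middle point are within
    ``max_dist`` and the interior angle at the middle point lies in
    [center - tol, min(center + tol, 180)].  Each unordered triple is
    reported once, by its lexicographically smallest qualifying ordering.
    """
    if len(points) and isinstance(points[0], PhosphatePoint):
        pos = np.array([p.position for p in points])
    else:
        pos = np.asarray(points, dtype=float)
    if len(pos) < 3:
        return []
    lo = angle_center - angle_tol
    hi = min(angle_center + angle_tol, 180.0)
    tree = cKDTree(pos)
    neighbours = tree.query_ball_point(pos, max_dist)
    best: dict[frozenset, tuple] = {}
    for j, nb in enumerate(neighbours):
        nb = [i for i in nb if i != j]
        for ai in range(len(nb)):
            for bi in range(ai + 1, len(nb)):
                i, k = nb[ai], nb[bi]
                if i > k:
                    i, k = k, i
                ang = interior_angle(pos[i], pos[j], pos[k])
                if not (lo <= ang <= hi):
                    continue
                key = frozenset((i, j, k))
                d = max(np.linalg.norm(pos[i] - pos[j]),
                        np.linalg.norm(pos[j] - pos[k]))
                entry = ((i, j, k), d, ang)
                if key not in best or entry[0] < best[key][0]:
                    best[key] = entry
    triplets = [Triplet(indices=t, max_pair_distance=float(d),
                        angle_deg=float(a))
                for t, d, a in sorted(best.values())]
    return triplets


# ---------------------------------------------------------------------------
# Superposition and scoring

def _kabsch(src: np.ndarray, dst: np.ndarray
            ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping src onto dst."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(dst - cd, src - cs)
    mat = rot.as_matrix()
    shift = cd - mat @ cs
    moved = (src @ mat.T) + shift
    rmsd = float(np.sqrt(np.mean(np.sum((moved - dst) ** 2, axis=1))))
    return mat, shift, rmsd


def superpose_fragment(fragment: Fragment,
                       triplet_positions: np.ndarray) -> list[Placement]:
    """Superpose a fragment's P atoms onto a triplet, both directions.

    Returns the two direction assignments — (P1,P2,P3) -> (t1,t2,t3) as
    5'->3' and the reversed anchor order as 3'->5'.  No rotational or
    translational refinement is applied afterwards.
    """
    dst = np.asarray(triplet_positions, dtype=float)
    if dst.shape != (3, 3):
        raise ValueError("triplet_positions must be three 3-D points")
    if (np.linalg.norm(dst[0] - dst[1]) < 1e-9
            or np.linalg.norm(dst[1] - dst[2]) < 1e-9
            or np.linalg.norm(dst[0] - dst[2]) < 1e-9):
        raise ValueError("triplet contains coincident points")
    src = fragment.p_positions
    placements = []
    for direction, target in (("5'->3'", dst), ("3'->5'", dst[::-1])):
        mat, shift, rmsd = _kabsch(src, target)
        placed = fragment.transformed(mat, shift, direction)
        placements.append(Placement(fragment=placed, rotation=mat,
                                    translation=shift, rmsd=rmsd,
                                    direction=direction))
    return placements


def score_placement(placed: Fragment, density, sugar_map=None,
                    base_map=None) -> float:
    """Sum of density at phosphate- and sugar-atom positions.

    When sugar/base predicted maps are given the score is augmented by the
    mean predicted value at the corresponding atom positions, rewarding
    placements whose sugars and bases land in predicted moiety density.
    """
    backbone = [a for a in placed.atoms
                if a.name in PHOSPHATE_ATOMS | SUGAR_ATOMS]
    if not backbone:
        return 0.0
    pos = np.array([a.pos for a in backbone])
    outside = _warn_outside(pos, density)
    vals = density.sample(pos)
    vals[outside] = 0.0  # no data outside the extent
    score = float(np.sum(vals))
    if sugar_map is not None:
        sugars = np.array([a.pos for a in placed.atoms
                           if a.name in SUGAR_ATOMS])
        if len(sugars):
            score += float(np.mean(sugar_map.sample(sugars)))
    if base_map is not None:
        bases = np.array([a.pos for a in placed.atoms
                          if a.name not in PHOSPHATE_ATOMS | SUGAR_ATOMS])
        if len(bases):
            score += float(np.mean(base_map.sample(bases)))
    return score


def _warn_outside(pos: np.ndarray, grid) -> np.ndarray:
    if isinstance(grid, OrthoGrid):
        idx = (pos - grid.origin) / grid.spacing
    else:
        idx = grid.index_of(pos)
    outside = np.any((idx < 0) | (idx > np.array(grid.shape) - 1), axis=1)
    if outside.any():
        warnings.warn(f"{int(outside.sum())} scored atoms fall outside the "
                      "density extent and contribute 0", stacklevel=3)
    return outside


# ---------------------------------------------------------------------------
# Chain assembly

def assemble_chains(placements: list[Placement], density
                    ) -> list[ChainCandidate]:
    """Join scored placements that share consecutive phosphate anchors.

    Keeps the best-scoring placement per (triplet, direction), links
    triplets overlapping in two consecutive anchors, and for each linked
    region keeps the better-scoring direction variant (mean density over
    atom positions; ties prefer 5'->3').
    """
    if not placements:
        return []
    best: dict[tuple, Placement] = {}
    for pl in placements:
        if pl.triplet is None:
            raise ValueError("placement lacks its anchor triplet")
        key = (pl.triplet, pl.direction)
        if key not in best or pl.score > best[key].score:
            best[key] = pl
    triplets = sorted({t for t, _ in best})
    t_index = {t: n for n, t in enumerate(triplets)}
    # adjacency: (i,j,k) ~ (j,k,l) in either orientation
    parent = list(range(len(triplets)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def pairs_of(t):
        return {(t[0], t[1]), (t[1], t[2]),
                (t[1], t[0]), (t[2], t[1])}

    for a in range(len(triplets)):
        for b in range(a + 1, len(triplets)):
            if pairs_of(triplets[a]) & pairs_of(triplets[b]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    components: dict[int, list[tuple]] = {}
    for t in triplets:
        components.setdefault(find(t_index[t]), []).append(t)

    chains: list[ChainCandidate] = []
    for comp in components.values():
        comp = sorted(comp)
        scores = {}
        for direction in ("5'->3'", "3'->5'"):
            frags = [best[(t, direction)] for t in comp
                     if (t, direction) in best]
            if not frags:
                scores[direction] = (None, -np.inf)
                continue
            atoms = np.array([a.pos for pl in frags
                              for a in pl.fragment.atoms])
            scores[direction] = (frags, float(np.mean(density.sample(atoms))))
        d53, d35 = scores["5'->3'"], scores["3'->5'"]
        if d53[0] is not None and d53[1] >= d35[1]:
            direction, (frags, fit) = "5'->3'", d53
        else:
            direction, (frags, fit) = "3'->5'", d35
        anchor_path: list[int] = []
        for t in comp:
            for i in t:
                if i not in anchor_path:
                    anchor_path.append(i)
        chains.append(ChainCandidate(fragments=frags, direction=direction,
                                     fit_score=fit,
                                     anchor_path=anchor_path))
    chains.sort(key=lambda c: -c.fit_score)
    return chains


def chains_to_model(chains: list[ChainCandidate]) -> AtomicModel:
    """Emit placed fragments as residues, one chain per candidate.

    Fragments overlap on shared anchors; each anchor contributes the
    residue of the first fragment that covers it.
    """
    chain_ids = ("N", "M", "O", "Q", "R", "S", "T", "U", "V", "W")
    atoms: list[Atom] = []
    for ci, chain in enumerate(chains):
        cid = chain_ids[ci % len(chain_ids)]
        seen_anchors: set[int] = set()
        res_counter = 1
        for pl in chain.fragments:
            anchors = (pl.triplet if pl.direction == "5'->3'"
                       else pl.triplet[::-1])
            by_res = {}
            for a in pl.fragment.atoms:
                by_res.setdefault(a.res_seq, []).append(a)
            for anchor, (_, res_atoms) in zip(anchors,
                                              sorted(by_res.items())):
                if anchor in seen_anchors:
                    continue
                seen_anchors.add(anchor)
                for a in res_atoms:
                    atoms.append(Atom(a.name, a.element, a.pos.copy(),
                                      res_counter, a.res_name, cid,
                                      "nucleic"))
                res_counter += 1
    return AtomicModel(atoms)


def build_model(pred_phosphate, density, fragments=None, sugar_map=None,
                base_map=None, threshold: float = PRED_THRESHOLD,
                merge_radius: float = MERGE_RADIUS
                ) -> tuple[AtomicModel, list[PhosphatePoint],
                           list[ChainCandidate]]:
    """Full build: points -> triplets -> placements -> chains -> model."""
    if fragments is None:
        from .synthetic import make_fragment_library
        fragments = make_fragment_library()
    points = extract_phosphate_points(pred_phosphate, density,
                                      threshold=threshold,
                                      merge_radius=merge_radius)
    triplets = find_triplets(points)
    pos = np.array([p.position for p in points]) if points else np.zeros((0, 3))
    scored: list[Placement] = []
    for trip in triplets:
        anchor = pos[list(trip.indices)]
        for frag in fragments:
            for pl in superpose_fragment(frag, anchor):
                pl.triplet = trip.indices
                pl.score = score_placement(pl.fragment, density,
                                           sugar_map=sugar_map,
                                           base_map=base_map)
                scored.append(pl)
    chains = assemble_chains(scored, density)
    return chains_to_model(chains), points, chains


# ---------------------------------------------------------------------------
# Clash resolution between protein and nucleic models

def clash_score(region_atoms, diff_density) -> float:
    """Negated mean absolute difference density within 5 Å of a region.

    ``diff_density`` must be sampled on (or resampled to) a 1 Å grid.
    Always <= 0; equals 0 only where the difference density vanishes.
    """
    atoms = (region_atoms.atoms if isinstance(region_atoms, AtomicModel)
             else list(region_atoms))
    if not atoms:
        raise ValueError("empty region")
    apos = np.array([a.pos for a in atoms])
    grid_pos = diff_density.positions().reshape(-1, 3)
    tree = cKDTree(apos)
    dist, _ = tree.query(grid_pos, k=1)
    near = dist <= CLASH_SHELL
    if not near.any():
        raise ValueError("no grid points within 5 Å of the region")
    rho = diff_density.values.reshape(-1)[near]
    return float(-np.mean(np.abs(rho)))


def _contiguous_regions(model: AtomicModel,
                        selected: set[tuple[str, int]]) -> list[list[tuple]]:
    regions: list[list[tuple]] = []
    current: list[tuple] = []
    prev = None
    for key, _ in model.residues():
        if key in selected:
            if prev is not None and (key[0] != prev[0]
                                     or key[1] != prev[1] + 1):
                if current:
                    regions.append(current)
                current = []
            current.append(key)
            prev = key
        else:
            if current:
                regions.append(current)
                current = []
            prev = None
    if current:
        regions.append(current)
    return regions


def _residue_atoms(model: AtomicModel, keys: list[tuple]) -> list[Atom]:
    keyset = set(keys)
    return [a for a in model.atoms if (a.chain, a.res_seq) in keyset]


def prune_isolated(model: AtomicModel,
                   prune_dist: float = PRUNE_DIST) -> AtomicModel:
    """Remove residues with no neighbouring atoms near their bonding atoms.

    Bonding atoms are the backbone-linkage atoms: P/O5'/O3' for nucleic
    residues, N/C for protein.
    """
    residues = model.residues()
    if len(residues) <= 1:
        return model
    all_pos = model.positions()
    res_ids = {key: n for n, (key, _) in enumerate(residues)}
    owner = np.array([res_ids[(a.chain, a.res_seq)] for a in model.atoms])
    tree = cKDTree(all_pos)
    keep: set[tuple] = set()
    for key, atoms in residues:
        bond_names = (NUCLEIC_BOND_ATOMS if atoms[0].kind == "nucleic"
                      else PROTEIN_BOND_ATOMS)
        bonding = [a for a in atoms if a.name in bond_names] or atoms
        rid = res_ids[key]
        isolated = True
        for a in bonding:
            if any(owner[idx] != rid
                   for idx in tree.query_ball_point(a.pos, prune_dist)):
                isolated = False
                break
        if not isolated:
            keep.add(key)
    return AtomicModel([a for a in model.atoms
                        if (a.chain, a.res_seq) in keep])


def resolve_clashes(protein_model: AtomicModel, nucleic_model: AtomicModel,
                    diff_density: DensityMap,
                    clash_dist: float = CLASH_DIST) -> AtomicModel:
    """Merge a protein and a nucleic model, adjudicating clashing regions.

    A clash region is a run of contiguous nucleic residues all within
    ``clash_dist`` of a run of contiguous protein residues.  Both sides are
    scored by :func:`clash_score` on a 1 Å resampling of the difference
    density and the higher-scoring (weaker-density) side removed.
    """
    if len(protein_model) == 0 or len(nucleic_model) == 0:
        return AtomicModel(protein_model.atoms + nucleic_model.atoms)
    ppos = protein_model.positions()
    ptree = cKDTree(ppos)
    clashing_nucleic: set[tuple] = set()
    for key, atoms in nucleic_model.residues():
        pos = np.array([a.pos for a in atoms])
        if ptree.query_ball_point(pos, clash_dist, return_length=True).sum():
            clashing_nucleic.add(key)
    if not clashing_nucleic:
        merged = AtomicModel(protein_model.atoms + nucleic_model.atoms)
        return merged
    grid1 = interpolate_to_ortho(diff_density, spacing=1.0)
    drop_protein: set[tuple] = set()
    drop_nucleic: set[tuple] = set()
    patoms = protein_model.atoms
    for region in _contiguous_regions(nucleic_model, clashing_nucleic):
        n_atoms = _residue_atoms(nucleic_model, region)
        npos = np.array([a.pos for a in n_atoms])
        ntree = cKDTree(npos)
        near_prot = {(a.chain, a.res_seq) for a in patoms
                     if ntree.query_ball_point(a.pos, clash_dist,
                                               return_length=True)}
        prot_regions = _contiguous_regions(protein_model, near_prot)
        p_keys = [k for reg in prot_regions for k in reg]
        if not p_keys:
            continue
        p_atoms = _residue_atoms(protein_model, p_keys)
        s_nuc = clash_score(n_atoms, grid1)
        s_prot = clash_score(p_atoms, grid1)
        # the higher score (weaker density) loses
        if s_prot >= s_nuc:
            drop_protein.update(p_keys)
        else:
            drop_nucleic.update(region)
    kept = ([a for a in protein_model.atoms
             if (a.chain, a.res_seq) not in drop_protein]
            + [a for a in nucleic_model.atoms
               if (a.chain, a.res_seq) not in drop_nucleic])
    return prune_isolated(AtomicModel(kept))
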