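"""Density maps, orthogonal working grids and atomic models.

Everything downstream speaks two grid dialects:

* :class:`DensityMap` — a (possibly non-orthogonal) crystallographic grid
  read from or destined for a CCP4 map file.  The stored block of values is
  treated as the map's extent (for synthetic P1 maps it is the whole cell).
* :class:`OrthoGrid` — a regular orthogonal grid with a single isotropic
  spacing (0.7 Å by default), the working representation for the network.

Grid index (0, 0, 0) sits at ``origin`` (Cartesian Å); index ``(i, j, k)``
maps to ``origin + M @ (i/nx, j/ny, k/nz)`` where ``M`` is the
orthogonalization matrix of the box cell.  All interpolation is trilinear;
points outside a grid's extent evaluate to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy.ndimage import map_coordinates

DEFAULT_SPACING = 0.7  # Å, working-grid spacing

STANDARD_NUCLEOTIDES = {
    "A", "C", "G", "U", "I", "DA", "DC", "DG", "DT", "DU", "DI",
}
STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}


class MapFormatError(ValueError):
    """Raised when a CCP4 map file cannot be interpreted."""


class ModelFormatError(ValueError):
    """Raised when a PDB/mmCIF model file cannot be interpreted."""


def _orthogonalization_matrix(cell: tuple[float, ...]) -> np.ndarray:
    uc = gemmi.UnitCell(*cell)
    return np.array(uc.orth.mat.tolist())


@dataclass
class DensityMap:
    """A block of density values on a crystallographic grid.

    ``cell`` holds the box cell: lengths are the Cartesian span of the
    stored block along each crystal axis, so spacing = length / n points.
    """

    values: np.ndarray
    cell: tuple[float, float, float, float, float, float]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_order: tuple[int, int, int] = (0, 1, 2)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("density values must be a 3-D grid")
        if any(s <= 0 for s in self.spacing_per_axis):
            raise ValueError("grid spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spacing_per_axis(self) -> np.ndarray:
        return np.array(self.cell[:3]) / np.array(self.shape)

    @property
    def orth(self) -> np.ndarray:
        return _orthogonalization_matrix(self.cell)

    def positions(self) -> np.ndarray:
        """Cartesian positions of every grid point, shape (*grid, 3)."""
        nx, ny, nz = self.shape
        frac = np.stack(np.meshgrid(
            np.arange(nx) / nx, np.arange(ny) / ny, np.arange(nz) / nz,
            indexing="ij"), axis=-1)
        return frac @ self.orth.T + self.origin

    def index_of(self, positions: np.ndarray) -> np.ndarray:
        """Fractional grid indices of Cartesian positions."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        frac = np.linalg.solve(self.orth, (pos - self.origin).T).T
        return frac * np.array(self.shape)

    def sample(self, positions: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian positions.

        Sampling beyond the stored extent clamps to the edge value, so
        resampling round trips are exact up to the boundary.
        """
        pos = np.asarray(positions, dtype=float)
        flat = pos.reshape(-1, 3)
        idx = self.index_of(flat)
        out = map_coordinates(self.values, idx.T, order=1, mode="nearest")
        return out.reshape(pos.shape[:-1])

    def with_values(self, values: np.ndarray) -> "DensityMap":
        if values.shape != self.values.shape:
            raise ValueError("replacement values must match the grid shape")
        return DensityMap(values=np.asarray(values, dtype=float),
                          cell=self.cell, origin=self.origin.copy(),
                          axis_order=self.axis_order)


@dataclass
class OrthoGrid:
    """Regular orthogonal grid with isotropic spacing."""

    values: np.ndarray
    spacing: float = DEFAULT_SPACING
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a 3-D grid")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def positions(self) -> np.ndarray:
        nx, ny, nz = self.shape
        idx = np.stack(np.meshgrid(np.arange(nx), np.arange(ny),
                                   np.arange(nz), indexing="ij"), axis=-1)
        return self.origin + idx * self.spacing

    def position(self, index: tuple[int, int, int]) -> np.ndarray:
        return self.origin + np.asarray(index, dtype=float) * self.spacing

    def sample(self, positions: np.ndarray) -> np.ndarray:
        """Trilinear interpolation, edge-clamped beyond the extent."""
        pos = np.asarray(positions, dtype=float)
        flat = pos.reshape(-1, 3)
        idx = (flat - self.origin) / self.spacing
        out = map_coordinates(self.values, idx.T, order=1, mode="nearest")
        return out.reshape(pos.shape[:-1])

    def with_values(self, values: np.ndarray) -> "OrthoGrid":
        if values.shape != self.values.shape:
            raise ValueError("replacement values must match the grid shape")
        return OrthoGrid(values=np.asarray(values, dtype=float),
                         spacing=self.spacing, origin=self.origin.copy())


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray
    res_seq: int
    res_name: str
    chain: str
    kind: str  # protein | nucleic | other

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if not np.all(np.isfinite(self.pos)):
            raise ValueError(f"non-finite position for atom {self.name}")


@dataclass
class AtomicModel:
    """Flat list of atoms with residue/chain bookkeeping."""

    atoms: list[Atom] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    def positions(self) -> np.ndarray:
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.pos for a in self.atoms])

    def select(self, kind: str | None = None,
               atom_names: set[str] | None = None) -> "AtomicModel":
        picked = [a for a in self.atoms
                  if (kind is None or a.kind == kind)
                  and (atom_names is None or a.name in atom_names)]
        return AtomicModel(picked)

    def residues(self) -> list[tuple[tuple[str, int], list[Atom]]]:
        """Atoms grouped by (chain, residue id), in encounter order."""
        order: list[tuple[str, int]] = []
        groups: dict[tuple[str, int], list[Atom]] = {}
        for a in self.atoms:
            key = (a.chain, a.res_seq)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(a)
        return [(k, groups[k]) for k in order]


def polymer_kind(res_name: str) -> str:
    name = res_name.strip().upper()
    if name in STANDARD_NUCLEOTIDES:
        return "nucleic"
    if name in STANDARD_AMINO_ACIDS:
        return "protein"
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        if info.is_nucleic_acid():
            return "nucleic"
        if info.is_amino_acid():
            return "protein"
    return "other"


# ---------------------------------------------------------------------------
# CCP4 map I/O

_ORIGIN_WORDS = (50, 51, 52)  # MRC2014 ORIGIN x, y, z


def read_map(path: str | Path) -> DensityMap:
    """Read a CCP4/MRC map, resolving axis order so values are x, y, z."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size < 1024:
        raise MapFormatError(
            f"{path}: file shorter than the 1024-byte CCP4 header")
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise MapFormatError(f"{path}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in (0, 1, 2, 6):
        raise MapFormatError(f"{path}: unsupported MODE field {mode}")
    mapc, mapr, maps_ = (m.header_i32(i) for i in (17, 18, 19))
    if sorted((mapc, mapr, maps_)) != [1, 2, 3]:
        raise MapFormatError(
            f"{path}: MAPC/MAPR/MAPS fields {mapc},{mapr},{maps_} are not a "
            "permutation of 1,2,3")
    axis_order = (mapc - 1, mapr - 1, maps_ - 1)
    # starts are stored in file axis order; map them to crystal axes
    starts_file = [m.header_i32(i) for i in (5, 6, 7)]
    starts = [0, 0, 0]
    for file_axis, crystal_axis in enumerate(axis_order):
        starts[crystal_axis] = starts_file[file_axis]
    sampling = np.array([m.header_i32(i) for i in (8, 9, 10)], dtype=float)
    if np.any(sampling < 1):
        raise MapFormatError(f"{path}: non-positive MX/MY/MZ sampling")
    m.setup(0.0, gemmi.MapSetup.ReorderOnly)
    values = np.array(m.grid, copy=True, dtype=np.float64)
    uc = m.grid.unit_cell
    full_cell = (uc.a, uc.b, uc.c, uc.alpha, uc.beta, uc.gamma)
    shape = np.array(values.shape)
    box_cell = tuple(np.array(full_cell[:3]) * shape / sampling) + full_cell[3:]
    orth = _orthogonalization_matrix(full_cell)
    origin = np.array([m.header_float(i) for i in _ORIGIN_WORDS])
    origin = origin + orth @ (np.array(starts, dtype=float) / sampling)
    return DensityMap(values=values, cell=box_cell, origin=origin,
                      axis_order=axis_order)


def write_map(dmap: DensityMap, path: str | Path) -> None:
    """Write a map in CCP4 mode-2 (float32) format, x,y,z axis order."""
    grid = gemmi.FloatGrid(np.ascontiguousarray(dmap.values,
                                                dtype=np.float32))
    grid.unit_cell = gemmi.UnitCell(*dmap.cell)
    grid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    for word, val in zip(_ORIGIN_WORDS, dmap.origin):
        ccp4.set_header_float(word, float(val))
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# Resampling between crystallographic and working grids

def interpolate_to_ortho(dmap: DensityMap,
                         spacing: float = DEFAULT_SPACING,
                         padding: float = 0.0) -> OrthoGrid:
    """Resample a map onto a regular orthogonal grid.

    The output grid covers the Cartesian bounding box of the map's extent
    plus ``padding`` Å on all sides.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    nx, ny, nz = dmap.shape
    corners_idx = np.array([(i, j, k) for i in (0, nx - 1)
                            for j in (0, ny - 1) for k in (0, nz - 1)],
                           dtype=float)
    frac = corners_idx / np.array(dmap.shape)
    corners = frac @ dmap.orth.T + dmap.origin
    lo = corners.min(axis=0) - padding
    hi = corners.max(axis=0) + padding
    shape = np.maximum(np.floor((hi - lo) / spacing).astype(int) + 1, 1)
    grid = OrthoGrid(values=np.zeros(shape), spacing=spacing, origin=lo)
    grid.values[...] = dmap.sample(grid.positions())
    return grid


def interpolate_from_ortho(grid: OrthoGrid, template: DensityMap) -> DensityMap:
    """Resample an orthogonal grid back onto a template map's grid.

    Template points outside the orthogonal grid's extent are set to 0
    (with a warning) — there is no data there to interpolate.
    """
    pos = template.positions()
    idx = (pos.reshape(-1, 3) - grid.origin) / grid.spacing
    outside = np.any((idx < 0) | (idx > np.array(grid.shape) - 1), axis=1)
    values = grid.sample(pos)
    if np.any(outside):
        warnings.warn(
            f"{int(outside.sum())} template grid points fall outside the "
            "orthogonal grid extent; filled with 0", stacklevel=2)
        flat = values.reshape(-1)
        flat[outside] = 0.0
        values = flat.reshape(values.shape)
    return template.with_values(values)


# ---------------------------------------------------------------------------
# Atomic model I/O

def read_model(path: str | Path) -> AtomicModel:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ModelFormatError(f"{path}: {exc}") from exc
    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                kind = polymer_kind(res.name)
                for at in res:
                    if at.element.name == "H":
                        continue
                    atoms.append(Atom(
                        name=at.name, element=at.element.name,
                        pos=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        res_seq=res.seqid.num, res_name=res.name,
                        chain=chain.name, kind=kind))
        break  # first model only
    return AtomicModel(atoms)


def write_model(model: AtomicModel, path: str | Path,
                cell: tuple[float, ...] | None = None) -> None:
    path = Path(path)
    st = gemmi.Structure()
    if cell is not None:
        st.cell = gemmi.UnitCell(*cell)
    st.spacegroup_hm = "P 1"
    gmodel = gemmi.Model("1")
    # build complete residues before inserting (gemmi copies on add)
    chain_order: list[str] = []
    residues: dict[str, list[tuple[int, gemmi.Residue]]] = {}
    for a in model.atoms:
        if a.chain not in residues:
            residues[a.chain] = []
            chain_order.append(a.chain)
        rlist = residues[a.chain]
        if not rlist or rlist[-1][0] != a.res_seq:
            res = gemmi.Residue()
            res.name = a.res_name
            res.seqid = gemmi.SeqId(a.res_seq, " ")
            rlist.append((a.res_seq, res))
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.pos)
        atom.occ = 1.0
        atom.b_iso = 30.0
        rlist[-1][1].add_atom(atom)
    for cname in chain_order:
        chain = gemmi.Chain(cname)
        for _, res in residues[cname]:
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))
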