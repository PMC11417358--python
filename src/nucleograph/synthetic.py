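"""Desk-scale synthetic data: idealized duplexes, Gaussian-atom density,
ground-truth target maps and the trinucleotide fragment library.

The duplex generator stacks an idealized nucleotide template (cylindrical
coordinates; bond lengths fitted to standard values, phosphorus radius
9.4 Å) by the helical rise and twist of the chosen form, generating the
complementary strand by dyad symmetry.  Density maps are sums of
electron-count-weighted isotropic Gaussians whose width is parameterized as
an effective B-factor (sigma^2 = B / (8 pi^2)); map degradation emulating
post-molecular-replacement quality adds an extra Gaussian blur and white
noise at a fraction of the peak level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .builder import Fragment
from .maps import Atom, AtomicModel, DensityMap, write_map, write_model
from .training import GROUPS, make_target_map

# Idealized single-nucleotide backbone/sugar templates, cylindrical
# (radius Å, azimuth deg, z Å).  Bond lengths fitted to standard values
# under each form's helical symmetry (B: rise 3.4 Å, twist 36 deg;
# A: rise 2.6 Å, twist 32.7 deg); the O3'(i)-P(i+1) linkage is 1.60 Å.
B_FORM_TEMPLATE = {
    "P":   (9.387, 0.048, -0.004),
    "OP1": (10.553, 3.264, 0.714),
    "OP2": (9.694, -3.254, -1.339),
    "O5'": (8.312, 7.687, -0.122),
    "C5'": (8.447, 14.039, 0.968),
    "C4'": (7.529, 22.611, 0.863),
    "O4'": (6.709, 23.947, 2.043),
    "C3'": (8.436, 31.307, 1.040),
    "O3'": (8.264, 36.154, 2.251),
    "C2'": (7.237, 36.465, 0.415),
    "C1'": (6.027, 32.440, 1.238),
}
A_FORM_TEMPLATE = {
    "P":   (9.403, -0.001, 0.004),
    "OP1": (10.551, 3.360, 0.734),
    "OP2": (9.778, -3.753, -1.283),
    "O5'": (8.380, 7.725, -0.279),
    "C5'": (8.216, 13.066, 0.926),
    "C4'": (7.208, 21.293, 0.711),
    "O4'": (6.725, 25.015, 2.000),
    "C3'": (8.111, 30.256, 0.400),
    "O3'": (8.291, 35.848, 1.562),
    "C2'": (6.883, 36.909, 0.185),
    "C1'": (5.907, 33.211, 1.287),
    "O2'": (7.422, 47.263, 0.362),
}
HELIX_PARAMS = {"B": (3.4, 36.0), "A": (2.6, 32.7)}  # rise Å, twist deg

DNA_NAMES = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
RNA_NAMES = {"A": "A", "C": "C", "G": "G", "U": "U"}
DNA_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
PURINES = {"A", "G"}

ATOMIC_NUMBER = {"C": 6, "N": 7, "O": 8, "P": 15, "S": 16}
DEFAULT_B_FACTOR = 30.0  # Å^2
MR_BLUR = 1.5            # Å extra Gaussian blur for degraded maps
MR_NOISE = 0.10          # white-noise sigma as a fraction of the peak


@dataclass
class DuplexSpec:
    n_base_pairs: int = 10
    form: str = "B"
    sequence: str | None = None  # strand-1 bases; random if None
    origin: np.ndarray | None = None       # rigid placement offset
    orientation: np.ndarray | None = None  # 3x3 rotation

    def __post_init__(self) -> None:
        if self.n_base_pairs < 1:
            raise ValueError("n_base_pairs must be >= 1")
        if self.form not in HELIX_PARAMS:
            raise ValueError(f"unknown duplex form {self.form!r}")


@dataclass
class DensitySpec:
    b_factor: float = DEFAULT_B_FACTOR  # Gaussian width, Å^2
    spacing: float = 0.7                # grid spacing, Å
    noise_sigma: float = 0.0            # fraction of the peak value
    blur_extra: float = 0.0             # Å, degradation blur
    margin: float = 5.0                 # Å padding around the model

    def __post_init__(self) -> None:
        if self.b_factor <= 0 or self.spacing <= 0 or self.margin < 0:
            raise ValueError("b_factor, spacing must be > 0, margin >= 0")
        if self.noise_sigma < 0 or self.blur_extra < 0:
            raise ValueError("noise_sigma and blur_extra must be >= 0")


def _cyl(r: float, phi_deg: float, z: float) -> np.ndarray:
    p = np.deg2rad(phi_deg)
    return np.array([r * np.cos(p), r * np.sin(p), z])


def _element_of(name: str) -> str:
    return name.lstrip("0123456789")[0]


def _base_ring(c1: np.ndarray, base: str) -> list[tuple[str, np.ndarray]]:
    """Planar idealized base attached at C1', pointing toward the axis."""
    radial = c1.copy()
    radial[2] = 0.0
    u = -radial / np.linalg.norm(radial)       # inward
    v = np.array([-u[1], u[0], 0.0])           # azimuthal, in-plane

    def at(centre, radius, angle_deg):
        a = np.deg2rad(angle_deg)
        return centre + radius * (np.cos(a) * (-u) + np.sin(a) * v)

    atoms: list[tuple[str, np.ndarray]] = []
    if base in PURINES:
        # fused pentagon + hexagon; N9 sits between C1' and the 5-ring
        # centre, the 6-ring extends further inward from the C4-C5 edge
        n9 = c1 + 1.47 * u
        pent_c = n9 + 1.17 * u
        names5 = ["N9", "C8", "N7", "C5", "C4"]
        pent = {nm: at(pent_c, 1.17, 72.0 * k)
                for k, nm in enumerate(names5)}
        atoms += [(nm, pent[nm]) for nm in names5]
        mid = 0.5 * (pent["C4"] + pent["C5"])
        away = mid - pent_c
        away /= np.linalg.norm(away)
        edge_len = float(np.linalg.norm(pent["C5"] - pent["C4"]))
        h = np.sqrt(max(1.39 ** 2 - (edge_len / 2) ** 2, 0.1))
        hex_c = mid + h * away
        r6 = float(np.linalg.norm(pent["C4"] - hex_c))

        def hexangle(p):
            d = p - hex_c
            return np.degrees(np.arctan2(np.dot(d, v), np.dot(d, -u)))

        a4, a5 = hexangle(pent["C4"]), hexangle(pent["C5"])
        step = 60.0 if ((a5 - a4) % 360.0) > 180.0 else -60.0
        ring6 = {nm: at(hex_c, r6, a4 + step * (k + 1))
                 for k, nm in enumerate(["N3", "C2", "N1", "C6"])}
        atoms += [(nm, ring6[nm]) for nm in ring6]
        exo = "N6" if base == "A" else "O6"
        d = ring6["C6"] - hex_c
        atoms.append((exo, ring6["C6"] + 1.34 * d / np.linalg.norm(d)))
    else:
        n1 = c1 + 1.47 * u
        hex_c = n1 + 1.39 * u
        names6 = ["N1", "C2", "N3", "C4", "C5", "C6"]
        ring = {nm: at(hex_c, 1.39, 60.0 * k)
                for k, nm in enumerate(names6)}
        atoms += [(nm, ring[nm]) for nm in names6]

        def exo(on, name, dist):
            d = ring[on] - hex_c
            atoms.append((name, ring[on] + dist * d / np.linalg.norm(d)))

        exo("C2", "O2", 1.22)
        if base in ("T", "U"):
            exo("C4", "O4", 1.22)
            if base == "T":
                exo("C5", "C7", 1.50)
        else:  # C
            exo("C4", "N4", 1.34)
    return atoms


def make_duplex(spec: DuplexSpec, seed: int = 0) -> AtomicModel:
    """Build an idealized full-atom double helix."""
    rng = np.random.default_rng(seed)
    form = spec.form
    rise, twist = HELIX_PARAMS[form]
    template = B_FORM_TEMPLATE if form == "B" else A_FORM_TEMPLATE
    names = DNA_NAMES if form == "B" else RNA_NAMES
    complement = DNA_COMPLEMENT if form == "B" else RNA_COMPLEMENT
    alphabet = sorted(names)
    n = spec.n_base_pairs
    seq = spec.sequence or "".join(rng.choice(alphabet) for _ in range(n))
    seq = seq.upper()
    if len(seq) != n:
        raise ValueError("sequence length must equal n_base_pairs")
    for b in seq:
        if b not in names:
            raise ValueError(f"unknown base letter {b!r} for form {form}")

    def rot_z(deg):
        a = np.deg2rad(deg)
        return np.array([[np.cos(a), -np.sin(a), 0],
                         [np.sin(a), np.cos(a), 0], [0, 0, 1]])

    # strand 2 = dyad image (180 deg about x) advanced half a turn
    dyad = np.diag([1.0, -1.0, -1.0])
    half = rot_z(180.0)
    s2_base = half @ dyad

    atoms: list[Atom] = []
    for i, b in enumerate(seq):
        step_rot = rot_z(i * twist)
        shift = np.array([0.0, 0.0, i * rise])
        for strand, chain, base in ((0, "A", b), (1, "B", complement[b])):
            res_name = names[base]
            xform = step_rot if strand == 0 else step_rot @ s2_base
            placed: list[tuple[str, np.ndarray]] = []
            for atom_name, cylcoord in template.items():
                placed.append((atom_name, xform @ _cyl(*cylcoord) + shift))
            c1 = dict(placed)["C1'"]
            placed += _base_ring(c1, base)
            for atom_name, pos in placed:
                atoms.append(Atom(name=atom_name,
                                  element=_element_of(atom_name),
                                  pos=pos, res_seq=i + 1, res_name=res_name,
                                  chain=chain, kind="nucleic"))
    model = AtomicModel(atoms)
    centre = model.positions().mean(axis=0)
    rot = spec.orientation if spec.orientation is not None else np.eye(3)
    offset = (np.asarray(spec.origin, dtype=float)
              if spec.origin is not None else np.zeros(3))
    for a in model.atoms:
        a.pos = rot @ (a.pos - centre) + offset
    return model


def make_alpha_helix(n_residues: int = 12,
                     origin: np.ndarray | None = None,
                     chain: str = "P") -> AtomicModel:
    """Crude idealized poly-alanine helix, for protein-complex fixtures."""
    rise, twist = 1.5, 100.0
    template = {
        "N": (1.55, -28.0, -0.9), "CA": (2.30, 0.0, 0.0),
        "C": (1.70, 28.0, 0.8), "O": (2.60, 42.0, 0.9),
        "CB": (3.45, -8.0, -0.6),
    }
    atoms = []
    for i in range(n_residues):
        a = np.deg2rad(i * twist)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        for name, cylcoord in template.items():
            pos = rot @ _cyl(*cylcoord) + np.array([0, 0, i * rise])
            atoms.append(Atom(name=name, element=name[0], pos=pos,
                              res_seq=i + 1, res_name="ALA", chain=chain,
                              kind="protein"))
    model = AtomicModel(atoms)
    centre = model.positions().mean(axis=0)
    offset = (np.asarray(origin, dtype=float) if origin is not None
              else np.zeros(3))
    for a in model.atoms:
        a.pos = a.pos - centre + offset
    return model


def make_density(model: AtomicModel, spec: DensitySpec | None = None,
                 seed: int = 0, origin: np.ndarray | None = None,
                 shape: tuple[int, int, int] | None = None) -> DensityMap:
    """Gaussian-atom density for a model on an orthogonal P1 grid.

    By default the grid is sized to the model's bounding box plus the
    spec margin; an explicit ``origin``/``shape`` must still contain the
    model plus margin.
    """
    spec = spec or DensitySpec()
    if len(model) == 0:
        raise ValueError("model has no atoms")
    rng = np.random.default_rng(seed)
    pos = model.positions()
    lo = pos.min(axis=0) - spec.margin
    hi = pos.max(axis=0) + spec.margin
    if origin is None and shape is None:
        origin = lo
        shape = np.ceil((hi - lo) / spec.spacing).astype(int) + 1
    else:
        if origin is None or shape is None:
            raise ValueError("give both origin and shape, or neither")
        origin = np.asarray(origin, dtype=float)
        shape = np.asarray(shape, dtype=int)
        top = origin + (shape - 1) * spec.spacing
        if np.any(origin > lo) or np.any(top < hi):
            raise ValueError(
                "grid too small to contain the model plus margin")
    values = np.zeros(tuple(shape))
    sigma2 = spec.b_factor / (8.0 * np.pi ** 2)
    sigma = np.sqrt(sigma2)
    cutoff = 4.0 * sigma
    amp_norm = 1.0 / ((2 * np.pi * sigma2) ** 1.5)
    halo = int(np.ceil(cutoff / spec.spacing))
    for a in model.atoms:
        z = ATOMIC_NUMBER.get(a.element.upper())
        if z is None:
            continue
        centre_idx = (a.pos - origin) / spec.spacing
        lo_i = np.maximum(np.floor(centre_idx).astype(int) - halo, 0)
        hi_i = np.minimum(np.ceil(centre_idx).astype(int) + halo + 1, shape)
        if np.any(lo_i >= hi_i):
            continue
        sl = tuple(slice(l, h) for l, h in zip(lo_i, hi_i))
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo_i, hi_i)],
                            indexing="ij")
        d2 = sum((g * spec.spacing + o - p) ** 2
                 for g, o, p in zip(grids, origin, a.pos))
        values[sl] += z * amp_norm * np.exp(-d2 / (2.0 * sigma2))
    if spec.blur_extra > 0:
        values = gaussian_filter(values, spec.blur_extra / spec.spacing)
    peak = float(values.max())
    if spec.noise_sigma > 0 and peak > 0:
        values = values + rng.normal(0.0, spec.noise_sigma * peak,
                                     size=values.shape)
    cell = tuple(np.array(shape) * spec.spacing) + (90.0, 90.0, 90.0)
    return DensityMap(values=values, cell=cell, origin=np.asarray(origin))


def make_fragment_library() -> list[Fragment]:
    """Idealized A-form and B-form trinucleotide template fragments."""
    frags = []
    for form in ("B", "A"):
        seq = "GCG" if form == "B" else "GCG"
        duplex = make_duplex(DuplexSpec(n_base_pairs=3, form=form,
                                        sequence=seq), seed=0)
        strand = [a for a in duplex.atoms if a.chain == "A"]
        frags.append(Fragment(atoms=strand))
    return frags


def write_fragment_library(path: str | Path,
                           fragments: list[Fragment] | None = None) -> None:
    fragments = fragments or make_fragment_library()
    chain_names = "FGHIJK"
    atoms = []
    for i, frag in enumerate(fragments):
        for a in frag.atoms:
            atoms.append(Atom(a.name, a.element, a.pos, a.res_seq,
                              a.res_name, chain_names[i], a.kind))
    write_model(AtomicModel(atoms), path, cell=(60, 60, 60, 90, 90, 90))


def load_fragment_library(path: str | Path) -> list[Fragment]:
    """Each chain of the file is one trinucleotide fragment."""
    from .maps import read_model
    model = read_model(path)
    by_chain: dict[str, list[Atom]] = {}
    for a in model.atoms:
        by_chain.setdefault(a.chain, []).append(a)
    frags = [Fragment(atoms=atoms) for atoms in by_chain.values()]
    for f in frags:
        f.p_positions  # validate three P anchors
    return frags


# ---------------------------------------------------------------------------
# Fixture suite

def make_fixture_suite(out_dir: str | Path, seed: int = 7) -> dict:
    """Write a standard test kit and return its manifest.

    Duplex models at 5/10/20 bp, a clean and a degraded map per model,
    per-group target maps on each clean map's grid, the fragment library,
    and a training manifest covering the three source categories.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"models": [], "maps": [], "targets": [],
                      "fragments": None, "training": []}
    clean = DensitySpec()
    degraded = DensitySpec(blur_extra=MR_BLUR, noise_sigma=MR_NOISE)
    source_tags = ["na_only", "pna_deposited", "pna_mr_like"]
    for bp, src in zip((5, 10, 20), source_tags):
        sub_seed = int(rng.integers(2 ** 31))
        model = make_duplex(DuplexSpec(n_base_pairs=bp), seed=sub_seed)
        mpath = out / f"duplex_{bp}bp.pdb"
        write_model(model, mpath, cell=(80, 80, 100, 90, 90, 90))
        manifest["models"].append(str(mpath))
        cmap = make_density(model, clean, seed=sub_seed)
        dmap = make_density(model, degraded, seed=sub_seed)
        cpath = out / f"duplex_{bp}bp_clean.ccp4"
        dpath = out / f"duplex_{bp}bp_degraded.ccp4"
        write_map(cmap, cpath)
        write_map(dmap, dpath)
        manifest["maps"] += [str(cpath), str(dpath)]
        for group in GROUPS:
            target = make_target_map(model, cmap, group)
            tpath = out / f"duplex_{bp}bp_target_{group}.ccp4"
            write_map(DensityMap(values=target.values.values, cell=cmap.cell,
                                 origin=cmap.origin), tpath)
            manifest["targets"].append(str(tpath))
        use = cpath if src != "pna_mr_like" else dpath
        manifest["training"].append(
            {"map": str(use), "model": str(mpath), "source": src})
    fpath = out / "fragment_library.pdb"
    write_fragment_library(fpath)
    manifest["fragments"] = str(fpath)
    with open(out / "training_manifest.csv", "w") as fh:
        fh.write("map,model,source\n")
        for row in manifest["training"]:
            fh.write(f"{row['map']},{row['model']},{row['source']}\n")
    manifest["training_manifest"] = str(out / "training_manifest.csv")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
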