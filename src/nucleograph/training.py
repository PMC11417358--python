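"""Target-map generation, rotated cube sampling and network training.

A target map marks every working-grid point lying within 1.5 Å of an atom
of the chosen nucleotide moiety (phosphate group, sugar ring or base).
Training draws 32-cube samples from density/target map pairs at a uniformly
random rigid orientation; during the restricted (early-curriculum) phase
only cubes containing at least one positive target point are accepted.
Three map sources — nucleic-acid-only maps, full-complex maps and degraded
complex maps emulating post-molecular-replacement quality — are cycled
round-robin, one step each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maps import AtomicModel, OrthoGrid
from .nn import Adam, UNet3D, focal_loss

LABEL_RADIUS = 1.5  # Å

# Atom-name partition of a nucleotide into the three target moieties.
# O5'/O3' are bonded to the phosphorus and carry phosphate-like density.
PHOSPHATE_ATOMS = {"P", "OP1", "OP2", "O5'", "O3'"}
SUGAR_ATOMS = {"C1'", "C2'", "C3'", "C4'", "C5'", "O4'", "O2'"}
GROUPS = ("phosphate", "sugar", "base")


def group_atoms(model: AtomicModel, group: str) -> AtomicModel:
    """Atoms of one target moiety, drawn from nucleic residues only."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    nucleic = model.select(kind="nucleic")
    if group == "phosphate":
        return nucleic.select(atom_names=PHOSPHATE_ATOMS)
    if group == "sugar":
        return nucleic.select(atom_names=SUGAR_ATOMS)
    other = PHOSPHATE_ATOMS | SUGAR_ATOMS
    return AtomicModel([a for a in nucleic.atoms
                        if a.name not in other and a.element != "H"])


@dataclass
class TargetMap:
    values: OrthoGrid  # binary 0/1
    group: str
    label_radius: float = LABEL_RADIUS


def make_target_map(model: AtomicModel, grid, group: str,
                    radius: float = LABEL_RADIUS) -> TargetMap:
    """Label grid points within ``radius`` of any atom of the group.

    ``grid`` may be an :class:`OrthoGrid` or a :class:`DensityMap`; the
    labelling works directly on that grid's point positions.
    """
    atoms = group_atoms(model, group)
    values = np.zeros(grid.shape)
    if len(atoms) == 0:
        import warnings
        warnings.warn(f"model has no nucleic atoms for group {group!r}; "
                      "target map is all zero", stacklevel=2)
        return TargetMap(values=_as_grid(grid, values), group=group,
                         label_radius=radius)
    shape = np.array(grid.shape)
    for atom in atoms.atoms:
        idx = _index_of(grid, atom.pos)
        halo = _index_halo(grid, radius)
        lo = np.maximum(np.floor(idx - halo).astype(int), 0)
        hi = np.minimum(np.ceil(idx + halo).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        pos = _sub_positions(grid, lo, hi)
        d2 = np.sum((pos - atom.pos) ** 2, axis=-1)
        values[sub] = np.where(d2 <= radius * radius, 1.0, values[sub])
    return TargetMap(values=_as_grid(grid, values), group=group,
                     label_radius=radius)


def _as_grid(grid, values):
    return grid.with_values(values)


def _index_of(grid, pos: np.ndarray) -> np.ndarray:
    if isinstance(grid, OrthoGrid):
        return (pos - grid.origin) / grid.spacing
    return grid.index_of(pos)[0]


def _index_halo(grid, radius: float) -> np.ndarray:
    if isinstance(grid, OrthoGrid):
        return np.full(3, radius / grid.spacing)
    return radius / grid.spacing_per_axis


def _sub_positions(grid, lo, hi) -> np.ndarray:
    idx = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                               indexing="ij"), axis=-1).astype(float)
    if isinstance(grid, OrthoGrid):
        return grid.origin + idx * grid.spacing
    frac = idx / np.array(grid.shape)
    return frac @ grid.orth.T + grid.origin


# ---------------------------------------------------------------------------
# Random cube sampling

@dataclass
class TrainingSample:
    input_cube: np.ndarray   # (e, e, e)
    target_cube: np.ndarray  # (e, e, e) binary
    rotation: np.ndarray     # 3x3
    translation: np.ndarray  # Cartesian centre, Å
    source: str = "na_only"


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation matrix via unit-quaternion sampling."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def sample_cube(density: OrthoGrid, target: TargetMap,
                rng: np.random.Generator, require_target: bool = False,
                edge: int = 32, max_attempts: int = 100,
                source: str = "na_only") -> TrainingSample:
    """Draw a randomly rotated/translated cube from a map pair.

    The cube lattice keeps the working spacing; interpolated target values
    are re-binarised at 0.5 so labels stay exact.  With ``require_target``
    the draw repeats until the target cube contains a positive point.
    """
    if density.shape != target.values.shape:
        raise ValueError("density and target must share a grid")
    spacing = density.spacing
    offsets = (np.stack(np.meshgrid(*[np.arange(edge)] * 3, indexing="ij"),
                        axis=-1) - (edge - 1) / 2.0) * spacing
    extent = (np.array(density.shape) - 1) * spacing
    for _ in range(max_attempts):
        rot = random_rotation(rng)
        centre = density.origin + rng.random(3) * extent
        positions = centre + offsets @ rot.T
        target_cube = (target.values.sample(positions) >= 0.5).astype(float)
        if require_target and not target_cube.any():
            continue
        input_cube = density.sample(positions)
        return TrainingSample(input_cube=input_cube,
                              target_cube=target_cube, rotation=rot,
                              translation=centre, source=source)
    raise RuntimeError(
        f"no cube with a positive target point found in {max_attempts} "
        "attempts (require_target is set)")


# ---------------------------------------------------------------------------
# Training loop

@dataclass
class TrainingConfig:
    epochs: int = 10
    steps_per_epoch: int = 30
    batch_size: int = 8
    restricted_epochs: int = 2   # full scale: 200 of 1000
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    learning_rate: float = 1e-4
    seed: int = 0
    cube_edge: int = 32

    def __post_init__(self) -> None:
        if min(self.epochs, self.steps_per_epoch, self.batch_size) < 1:
            raise ValueError("epochs, steps and batch size must be positive")
        if self.restricted_epochs < 0:
            raise ValueError("restricted_epochs must be >= 0")


@dataclass
class SourceEntry:
    """One training map with its per-group targets."""
    density: OrthoGrid
    targets: dict[str, TargetMap]
    source: str


def load_training_manifest(path) -> list[list[SourceEntry]]:
    """Read a manifest of (density map path, model path, source tag) rows.

    Accepts the CSV written by the fixture suite (columns: map, model,
    source).  Returns one source list per tag, ordered na_only,
    pna_deposited, pna_mr_like (tags with no entries are dropped).
    """
    import csv

    from .maps import interpolate_to_ortho, read_map, read_model

    by_tag: dict[str, list[SourceEntry]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            dmap = read_map(row["map"])
            model = read_model(row["model"])
            ortho = interpolate_to_ortho(dmap)
            targets = {g: make_target_map(model, ortho, g) for g in GROUPS}
            by_tag.setdefault(row["source"], []).append(
                SourceEntry(density=ortho, targets=targets,
                            source=row["source"]))
    order = ("na_only", "pna_deposited", "pna_mr_like")
    return [by_tag[t] for t in order if t in by_tag] + \
        [v for k, v in by_tag.items() if k not in order]


def train(models: dict[str, UNet3D],
          sources: list[list[SourceEntry]],
          cfg: TrainingConfig,
          sample_log: list | None = None,
          history_csv=None,
          checkpoint_dir=None) -> dict[str, list[float]]:
    """Train one network per group, cycling map sources round-robin.

    Returns the per-epoch mean loss history for each group; optionally
    writes the history as CSV and a per-epoch checkpoint per group.
    Training aborts with the offending epoch/step on a divergent (NaN)
    loss.
    """
    if not sources or any(len(s) == 0 for s in sources):
        raise ValueError("every map source needs at least one entry")
    histories: dict[str, list[float]] = {}
    for group, net in models.items():
        rng = np.random.default_rng(cfg.seed)
        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        history: list[float] = []
        step_counter = 0
        for epoch in range(cfg.epochs):
            restricted = epoch < cfg.restricted_epochs
            losses = []
            for step in range(cfg.steps_per_epoch):
                entries = sources[step_counter % len(sources)]
                entry = entries[rng.integers(len(entries))]
                step_counter += 1
                xs, ys = [], []
                for _ in range(cfg.batch_size):
                    s = sample_cube(entry.density, entry.targets[group],
                                    rng, require_target=restricted,
                                    edge=cfg.cube_edge, source=entry.source)
                    if sample_log is not None:
                        sample_log.append((epoch, step, restricted))
                    xs.append(s.input_cube)
                    ys.append(s.target_cube)
                x = np.asarray(xs, dtype=np.float32)[:, None]
                y = np.asarray(ys, dtype=np.float32)
                opt.zero_grad()
                logits = net.forward_logits(x)
                loss, dlogits = focal_loss(logits, y, cfg.focal_alpha,
                                           cfg.focal_gamma)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"divergent loss at epoch {epoch}, step {step} "
                        f"for group {group!r}")
                net.backward(dlogits)
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if checkpoint_dir is not None:
                from pathlib import Path
                ckdir = Path(checkpoint_dir)
                ckdir.mkdir(parents=True, exist_ok=True)
                net.save(ckdir / f"{group}_epoch{epoch:04d}.npz")
        histories[group] = history
    if history_csv is not None:
        import pandas as pd
        rows = [{"group": g, "epoch": e, "loss": v}
                for g, hist in histories.items()
                for e, v in enumerate(hist)]
        pd.DataFrame(rows).to_csv(history_csv, index=False)
    return histories
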