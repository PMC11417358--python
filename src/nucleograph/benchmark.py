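"""Desk-scale end-to-end benchmarks on synthetic duplex maps.

These routines wire the whole pipeline together at sizes that run on a
single CPU in minutes: a reduced network (depth 3, 8 first-layer filters)
is trained on three synthetic map sources — a nucleic-acid-only duplex, a
protein-nucleic complex, and the same complex degraded to
post-molecular-replacement-like quality — then evaluated on a held-out
duplex it has never seen.  The reduced depth only changes capacity, not
any architectural rule; the full-size configuration is the default
elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import resolution_sweep
from .maps import AtomicModel, DensityMap, interpolate_to_ortho
from .nn import UNet3D, UNetConfig
from .synthetic import (DensitySpec, DuplexSpec, MR_BLUR, MR_NOISE,
                        make_alpha_helix, make_density, make_duplex)
from .training import SourceEntry, TrainingConfig, make_target_map, train

DESK_NET = UNetConfig(first_filters=8, depth=3)
DESK_TRAINING = TrainingConfig(epochs=10, steps_per_epoch=28, batch_size=4,
                               restricted_epochs=2, learning_rate=1e-3)
SWEEP_BLURS = (0.0, 1.5, 3.0)  # Å of extra Gaussian blur


def _source_entry(model: AtomicModel, spec: DensitySpec, seed: int,
                  tag: str, groups=("phosphate",)) -> SourceEntry:
    dmap = make_density(model, spec, seed=seed)
    ortho = interpolate_to_ortho(dmap, spacing=spec.spacing)
    targets = {g: make_target_map(model, ortho, g) for g in groups}
    return SourceEntry(density=ortho, targets=targets, source=tag)


def desk_scale_sources(seed: int = 0, groups=("phosphate",)
                       ) -> list[list[SourceEntry]]:
    """The three training map sources at desk scale.

    na_only: a clean 8 bp duplex map; pna_deposited: a 9 bp duplex plus an
    idealized protein helix; pna_mr_like: the same complex blurred and
    noised to emulate a post-molecular-replacement map.
    """
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(x) for x in rng.integers(2 ** 31, size=3))
    clean = DensitySpec()
    degraded = DensitySpec(blur_extra=MR_BLUR, noise_sigma=MR_NOISE)
    na = make_duplex(DuplexSpec(n_base_pairs=8), seed=s1)
    duplex = make_duplex(DuplexSpec(n_base_pairs=9), seed=s2)
    helix = make_alpha_helix(12, origin=np.array([16.0, 0.0, 0.0]))
    complex_model = AtomicModel(duplex.atoms + helix.atoms)
    return [
        [_source_entry(na, clean, s1, "na_only", groups)],
        [_source_entry(complex_model, clean, s2, "pna_deposited", groups)],
        [_source_entry(complex_model, degraded, s3, "pna_mr_like", groups)],
    ]


@dataclass
class BenchmarkResult:
    network: UNet3D
    loss_history: list[float]
    inclusion_by_blur: dict[float, float]
    held_out_model: AtomicModel = None
    builder_match_pct: float = float("nan")

    @property
    def clean_inclusion_pct(self) -> float:
        return self.inclusion_by_blur[min(self.inclusion_by_blur)]


def train_phosphate_benchmark(seed: int = 0,
                              training: TrainingConfig | None = None,
                              net_config: UNetConfig | None = None,
                              sweep_blurs=SWEEP_BLURS) -> BenchmarkResult:
    """Train a phosphate model from scratch and score it on held-out maps.

    The held-out structure is a 10 bp duplex not in the training set;
    inclusion is measured on maps at increasing extra blur, the first
    (0 Å) being the clean map.
    """
    rng = np.random.default_rng(seed)
    training = training or TrainingConfig(
        **{**DESK_TRAINING.__dict__, "seed": int(rng.integers(2 ** 31))})
    net_config = net_config or DESK_NET
    sources = desk_scale_sources(int(rng.integers(2 ** 31)))
    net = UNet3D(net_config, seed=int(rng.integers(2 ** 31)))
    history = train({"phosphate": net}, sources, training)["phosphate"]

    held_seed = int(rng.integers(2 ** 31))
    held_out = make_duplex(DuplexSpec(n_base_pairs=10), seed=held_seed)

    def factory(blur: float) -> DensityMap:
        spec = DensitySpec(blur_extra=blur,
                           noise_sigma=MR_NOISE if blur > 0 else 0.0)
        return make_density(held_out, spec, seed=held_seed)

    sweep = resolution_sweep(sweep_blurs, {"phosphate": net}, held_out,
                             factory)
    inclusion = {float(r.blur): float(r.atom_inclusion_pct)
                 for r in sweep.itertuples()}
    return BenchmarkResult(network=net, loss_history=history,
                           inclusion_by_blur=inclusion,
                           held_out_model=held_out)


def builder_benchmark(seed: int = 0, n_base_pairs: int = 10
                      ) -> dict[str, float]:
    """Build a backbone from a duplex density plus an oracle phosphate map.

    Returns the fraction of planted P atoms matched by a built phosphate
    within 1.5 Å, and the reverse (built-P precision).
    """
    from .builder import build_model
    from .inference import OracleNetwork, predict
    from .training import group_atoms

    model = make_duplex(DuplexSpec(n_base_pairs=n_base_pairs), seed=seed)
    dmap = make_density(model, DensitySpec(), seed=seed)
    ortho = interpolate_to_ortho(dmap, 0.7)
    truth = make_target_map(model, ortho, "phosphate")
    pred = predict(dmap, OracleNetwork(truth.values))
    built, points, chains = build_model(pred, dmap)
    planted = np.array([a.pos for a in model.atoms if a.name == "P"])
    built_p = np.array([a.pos for a in built.atoms if a.name == "P"])
    if len(built_p) == 0:
        return {"match_pct": 0.0, "precision_pct": 0.0,
                "n_built": 0, "n_planted": len(planted)}
    from scipy.spatial import cKDTree
    d_planted, _ = cKDTree(built_p).query(planted)
    d_built, _ = cKDTree(planted).query(built_p)
    return {"match_pct": float(np.mean(d_planted <= 1.5) * 100.0),
            "precision_pct": float(np.mean(d_built <= 1.5) * 100.0),
            "n_built": int(len(built_p)), "n_planted": int(len(planted))}
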