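"""Target-map labelling, cube sampling and the training loop."""

import numpy as np
import pytest

from nucleograph.maps import Atom, AtomicModel, OrthoGrid
from nucleograph.nn import UNet3D, UNetConfig
from nucleograph.training import (GROUPS, SourceEntry, TrainingConfig,
                                  group_atoms, make_target_map, sample_cube,
                                  train)


def _p_atom(pos, seq=1, chain="A"):
    return Atom("P", "P", np.asarray(pos, dtype=float), seq, "DA", chain,
                "nucleic")


def _grid(shape=(20, 20, 20), spacing=0.7):
    return OrthoGrid(values=np.zeros(shape), spacing=spacing,
                     origin=np.zeros(3))


def brute_force_labels(model, grid, group, radius=1.5):
    """Independent all-pairs distance oracle for target labelling."""
    atoms = group_atoms(model, group)
    pos = grid.positions().reshape(-1, 3)
    out = np.zeros(len(pos))
    for a in atoms.atoms:
        out = np.maximum(out,
                         (np.linalg.norm(pos - a.pos, axis=1) <= radius)
                         .astype(float))
    return out.reshape(grid.shape)


class TestTargetMap:
    def test_empty_model_all_zero_with_warning(self):
        with pytest.warns(UserWarning, match="no nucleic"):
            t = make_target_map(AtomicModel([]), _grid(), "phosphate")
        assert t.values.values.sum() == 0

    def test_single_atom_matches_brute_force(self):
        model = AtomicModel([_p_atom([7.0, 7.3, 6.9])])
        grid = _grid()
        t = make_target_map(model, grid, "phosphate")
        np.testing.assert_array_equal(
            t.values.values, brute_force_labels(model, grid, "phosphate"))
        assert t.values.values.sum() > 0

    def test_duplex_matches_brute_force_all_groups(self, duplex10):
        # restrict to a sub-model of < 50 atoms for the oracle
        sub = AtomicModel(duplex10.atoms[:45])
        grid = OrthoGrid(values=np.zeros((24, 24, 24)), spacing=0.7,
                         origin=sub.positions().min(axis=0) - 2.0)
        for group in GROUPS:
            t = make_target_map(sub, grid, group)
            np.testing.assert_array_equal(
                t.values.values, brute_force_labels(sub, grid, group),
                err_msg=group)

    def test_two_distant_atoms_union(self):
        a = AtomicModel([_p_atom([3.0, 3.0, 3.0])])
        b = AtomicModel([_p_atom([3.0, 3.0, 13.0])])
        both = AtomicModel(a.atoms + b.atoms)
        grid = _grid((26, 26, 26))
        ta = make_target_map(a, grid, "phosphate").values.values
        tb = make_target_map(b, grid, "phosphate").values.values
        tu = make_target_map(both, grid, "phosphate").values.values
        np.testing.assert_array_equal(tu, np.maximum(ta, tb))

    def test_labeled_volume_monotone_in_radius(self):
        model = AtomicModel([_p_atom([7.0, 7.0, 7.0])])
        grid = _grid()
        counts = [make_target_map(model, grid, "phosphate",
                                  radius=r).values.values.sum()
                  for r in (0.5, 1.0, 1.5, 2.5)]
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]

    def test_binary_valued(self, duplex10):
        grid = OrthoGrid(values=np.zeros((30, 30, 30)), spacing=0.7,
                         origin=duplex10.positions().min(axis=0))
        t = make_target_map(duplex10, grid, "sugar")
        assert set(np.unique(t.values.values)) <= {0.0, 1.0}


class TestSampleCube:
    def _pair(self, shape=(32, 32, 32)):
        rng = np.random.default_rng(5)
        density = OrthoGrid(values=rng.random(shape), spacing=0.7,
                            origin=np.zeros(3))
        model = AtomicModel([_p_atom(np.array(shape) * 0.7 / 2)])
        target = make_target_map(model, density, "phosphate")
        return density, target

    def test_require_target_postcondition(self):
        density, target = self._pair()
        rng = np.random.default_rng(0)
        for _ in range(5):
            s = sample_cube(density, target, rng, require_target=True)
            assert s.target_cube.sum() >= 1

    def test_fixed_seed_reproducible(self):
        density, target = self._pair()
        s1 = sample_cube(density, target, np.random.default_rng(42))
        s2 = sample_cube(density, target, np.random.default_rng(42))
        np.testing.assert_array_equal(s1.input_cube, s2.input_cube)
        np.testing.assert_array_equal(s1.target_cube, s2.target_cube)

    def test_attempt_cap_error_names_cap(self):
        density, _ = self._pair()
        empty = make_target_map(AtomicModel([]), density, "phosphate")
        with pytest.raises(RuntimeError, match="7 attempts"):
            sample_cube(density, empty, np.random.default_rng(0),
                        require_target=True, max_attempts=7)

    def test_target_cube_binary(self):
        density, target = self._pair()
        s = sample_cube(density, target, np.random.default_rng(3),
                        require_target=True)
        assert set(np.unique(s.target_cube)) <= {0.0, 1.0}

    def test_shares_positions_with_input(self):
        # a cube of the density's own values: identity check via constant map
        density, target = self._pair()
        const = density.with_values(np.full(density.shape, 4.0))
        s = sample_cube(const, target, np.random.default_rng(1))
        inside = s.input_cube != 0  # outside the extent samples to 0
        assert np.allclose(s.input_cube[inside], 4.0)


def _tiny_sources(groups=("phosphate",)):
    rng = np.random.default_rng(9)
    density = OrthoGrid(values=rng.random((32, 32, 32)), spacing=0.7,
                        origin=np.zeros(3))
    model = AtomicModel([_p_atom([11.0, 11.0, 11.0]),
                         _p_atom([11.0, 11.0, 16.0], seq=2)])
    targets = {g: make_target_map(model, density, g) for g in groups}
    entry = SourceEntry(density=density, targets=targets, source="na_only")
    return [[entry], [entry], [entry]]


class TestTrainLoop:
    CFG = dict(epochs=1, steps_per_epoch=2, batch_size=2,
               restricted_epochs=1, learning_rate=1e-3, seed=7)

    def _net(self):
        return UNet3D(UNetConfig(input_edge=32, first_filters=2, depth=1),
                      seed=2)

    def test_deterministic_final_weights(self):
        sources = _tiny_sources()
        cfg = TrainingConfig(**self.CFG)
        nets = []
        for _ in range(2):
            net = self._net()
            train({"phosphate": net}, sources, cfg)
            nets.append(net)
        for pa, pb in zip(nets[0].parameters(), nets[1].parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_restricted_phase_respected(self):
        sources = _tiny_sources()
        log = []
        cfg = TrainingConfig(**{**self.CFG, "restricted_epochs": 0})
        train({"phosphate": self._net()}, sources, cfg, sample_log=log)
        assert log and all(not restricted for _, _, restricted in log)
        log2 = []
        cfg2 = TrainingConfig(**{**self.CFG, "epochs": 2,
                                 "restricted_epochs": 1})
        train({"phosphate": self._net()}, sources, cfg2, sample_log=log2)
        flags = {epoch: restricted for epoch, _, restricted in log2}
        assert flags[0] is True and flags[1] is False

    def test_empty_source_rejected(self):
        sources = _tiny_sources()
        sources[1] = []
        with pytest.raises(ValueError, match="source"):
            train({"phosphate": self._net()}, sources,
                  TrainingConfig(**self.CFG))

    def test_loss_history_shape(self):
        cfg = TrainingConfig(**{**self.CFG, "epochs": 2})
        hist = train({"phosphate": self._net()}, _tiny_sources(), cfg)
        assert len(hist["phosphate"]) == 2
        assert all(np.isfinite(x) for x in hist["phosphate"])


class TestManifestAndArtifacts:
    def test_manifest_round_trip_and_training_artifacts(self, tmp_path):
        from nucleograph.synthetic import make_fixture_suite
        from nucleograph.training import load_training_manifest
        manifest = make_fixture_suite(tmp_path / "kit", seed=5)
        sources = load_training_manifest(manifest["training_manifest"])
        assert len(sources) == 3
        assert [s[0].source for s in sources] == [
            "na_only", "pna_deposited", "pna_mr_like"]
        cfg = TrainingConfig(epochs=2, steps_per_epoch=1, batch_size=1,
                             restricted_epochs=1, seed=0)
        net = UNet3D(UNetConfig(input_edge=32, first_filters=2, depth=1),
                     seed=0)
        csv = tmp_path / "history.csv"
        ckdir = tmp_path / "ckpt"
        hist = train({"phosphate": net}, sources, cfg, history_csv=csv,
                     checkpoint_dir=ckdir)
        assert csv.exists()
        assert len(list(ckdir.glob("phosphate_epoch*.npz"))) == 2
        assert len(hist["phosphate"]) == 2
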