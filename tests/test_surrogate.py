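"""Geometry dataset generation and surrogate network fidelity."""

import numpy as np
import pytest

from morphsim import Morphology
from morphsim.surrogate import (
    SAMPLES_BY_ARITY,
    excursion_consistency,
    generate_geometry_dataset,
    load_surrogates,
    save_surrogates,
    surrogate_eval,
    train_surrogate,
)

SMALL = {1: 1200, 2: 600, 3: 800}


@pytest.fixture(scope="module")
def dataset(desk_model):
    return generate_geometry_dataset(desk_model, n_models=80, seed=0,
                                     samples_by_arity=SMALL)


@pytest.fixture(scope="module")
def soleus_net(dataset):
    return train_surrogate(dataset, "soleus_r", epochs=800, batch_size=64, seed=0)


class TestDataset:
    def test_deterministic(self, desk_model, dataset):
        ds2 = generate_geometry_dataset(desk_model, n_models=80, seed=0,
                                        samples_by_arity=SMALL)
        for k in dataset.tables:
            np.testing.assert_array_equal(dataset.tables[k]["X"], ds2.tables[k]["X"])
            np.testing.assert_array_equal(dataset.tables[k]["Y"], ds2.tables[k]["Y"])

    def test_sample_count_rule(self, dataset, desk_model):
        for m in desk_model.muscles:
            arity = min(len(m.spanned_coordinates), 3)
            assert dataset.n_samples(m.name) == SMALL[arity]

    def test_default_counts_are_desk_scale(self):
        assert SAMPLES_BY_ARITY == {1: 2000, 2: 8200, 3: 20000}

    def test_scale_draws_in_box(self, dataset):
        for k, tab in dataset.tables.items():
            ps = tab["X"][:, len(tab["coords"]):]
            assert np.all(ps >= 0.8) and np.all(ps <= 1.2)

    def test_poses_within_rom(self, dataset, desk_model):
        rom = desk_model.rom_bounds()
        for k, tab in dataset.tables.items():
            for j, c in enumerate(tab["coords"]):
                lo, hi = rom[c]
                q = tab["X"][:, j]
                assert np.all(q >= lo) and np.all(q <= hi)

    def test_labels_match_analytic_geometry(self, dataset, desk_model, desk_geo):
        tab = dataset.tables["gastroc_r"]
        nc = len(tab["coords"])
        groups = desk_model.scaling_groups()
        rng = np.random.default_rng(1)
        for k in rng.integers(0, len(tab["X"]), 4):
            q = np.zeros(desk_model.n_coordinates)
            ci = [desk_model.coord_index(c) for c in tab["coords"]]
            q[ci] = tab["X"][k, :nc]
            ps = {g: np.ones(3) for g in groups}
            for i, g in enumerate(tab["groups"]):
                ps[g] = tab["X"][k, nc + 3 * i:nc + 3 * (i + 1)]
            morph = Morphology(p_s=ps, p_v=np.ones(18))
            lmt, R = desk_geo.eval_muscle("gastroc_r", q, morph)
            assert lmt == pytest.approx(tab["Y"][k, 0], abs=1e-10)
            np.testing.assert_allclose(R[ci], tab["Y"][k, 1:], atol=1e-10)


class TestTraining:
    def test_same_seed_identical_weights(self, dataset):
        s1 = train_surrogate(dataset, "soleus_r", epochs=30, batch_size=64, seed=5)
        s2 = train_surrogate(dataset, "soleus_r", epochs=30, batch_size=64, seed=5)
        for w1, w2 in zip(s1.net.weights, s2.net.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_zero_epochs_is_untrained(self, dataset):
        s = train_surrogate(dataset, "soleus_r", epochs=0, batch_size=64, seed=0)
        assert s.holdout_rmse[0] > 3e-3  # lengths well off untrained

    def test_heldout_rmse_below_tolerance(self, soleus_net):
        assert soleus_net.holdout_rmse[0] < 1e-3  # < 1 mm on l_mt

    def test_excursion_consistency_reported(self, soleus_net, dataset):
        stats = excursion_consistency(soleus_net, dataset.tables["soleus_r"]["X"])
        assert set(stats) == {"max", "mean", "rms"}
        assert stats["rms"] < 5e-3  # moment-arm vs length-gradient, m


class TestEvaluation:
    def test_zero_velocity_zero_rate(self, soleus_net):
        _, ldot, _ = surrogate_eval(soleus_net, [0.1], [0.0], np.ones(6))
        assert ldot == pytest.approx(0.0, abs=1e-12)

    def test_velocity_matches_finite_difference(self, soleus_net):
        qd = 1.7
        h = 1e-6
        l1, _, _ = surrogate_eval(soleus_net, [0.2 + h], [0.0], np.ones(6))
        l0, _, _ = surrogate_eval(soleus_net, [0.2 - h], [0.0], np.ones(6))
        _, ldot, _ = surrogate_eval(soleus_net, [0.2], [qd], np.ones(6))
        assert ldot == pytest.approx((l1 - l0) / (2 * h) * qd, abs=1e-6 * abs(qd))

    def test_matches_analytic_on_random_points(self, soleus_net, desk_model, desk_geo):
        rng = np.random.default_rng(2)
        rom = desk_model.rom_bounds()
        lo, hi = rom["ankle_r_q"]
        errs = []
        for _ in range(200):
            qv = rng.uniform(lo, hi)
            ps = rng.uniform(0.8, 1.2, (2, 3))
            q = np.zeros(9)
            q[desk_model.coord_index("ankle_r_q")] = qv
            morph = Morphology(
                p_s={g: (ps[soleus_net.groups.index(g)] if g in soleus_net.groups
                         else np.ones(3)) for g in desk_model.scaling_groups()},
                p_v=np.ones(18))
            l_true, _ = desk_geo.eval_muscle("soleus_r", q, morph)
            l_net, _, _ = surrogate_eval(soleus_net, [qv], [0.0], ps.ravel())
            errs.append(l_net - l_true)
        assert np.sqrt(np.mean(np.square(errs))) < 1e-3

    def test_extrapolation_warns(self, soleus_net):
        with pytest.warns(UserWarning, match="outside training domain"):
            surrogate_eval(soleus_net, [5.0], [0.0], np.ones(6))

    def test_round_trip_hdf5(self, soleus_net, tmp_path):
        path = tmp_path / "sur.h5"
        save_surrogates({"soleus_r": soleus_net}, path)
        loaded = load_surrogates(path)["soleus_r"]
        x = np.array([0.3, *np.ones(6)])
        np.testing.assert_allclose(loaded.predict(x[None, :]),
                                   soleus_net.predict(x[None, :]), atol=1e-12)
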