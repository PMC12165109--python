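"""Guided reverse diffusion: modulation, determinism, checkpoints, training."""

import numpy as np
import pytest

from diffmcgen.chem_io import QM9_ALPHABET, check_validity, encode_graph
from diffmcgen.nn import MLP, Tensor
from diffmcgen.sampling import (DiffMCGenModels, GuidanceConfig,
                                GuidanceRegressor, TrainConfig, _modulate,
                                generate, guided_step, train)


@pytest.fixture(scope="module")
def tiny_models(fixture20):
    """A quickly trained bundle for functional (non-quality) tests."""
    from diffmcgen.denoiser_discrete import DiscreteDenoiserConfig
    cfg = TrainConfig(T=20, n_max=10, steps_discrete=60, steps_uncond=40,
                      steps_continuous=30, steps_regressor=60, seed=0,
                      denoiser=DiscreteDenoiserConfig(layers=1, d_node=32,
                                                      d_edge=16))
    return train(fixture20.molecules[:8], cfg)


def random_state(models, B=3, n=6, seed=0):
    rng = np.random.default_rng(seed)
    n_max = models.config.n_max
    a = models.alphabet.n_atom_types
    b = models.alphabet.n_bond_types
    mask = np.zeros((B, n_max), dtype=bool)
    mask[:, :n] = True
    X = np.zeros((B, n_max, a))
    X[:, :n] = np.eye(a)[rng.integers(0, a, (B, n))]
    E = np.zeros((B, n_max, n_max, b))
    iu, ju = np.triu_indices(n_max, 1)
    for i in range(B):
        sel = mask[i, iu] & mask[i, ju]
        idx = rng.integers(0, b, sel.sum())
        E[i, iu[sel], ju[sel], idx] = 1
        E[i, ju[sel], iu[sel], idx] = 1
        d = np.arange(n)
        E[i, d, d, 0] = 1
    return X, E, mask


class TestGuidanceReduction:
    def test_lambda_zero_is_unguided(self, tiny_models):
        """lam=0 must leave the sampling distribution untouched: identical
        randomness gives identical states whatever the other guidance
        settings are."""
        X, E, mask = random_state(tiny_models)
        outs = []
        for rule in ("adaptive", "constant"):
            cfg = GuidanceConfig(lam=0.0, weight_rule=rule,
                                 targets=np.array([0.1, 0.9, 0.2, 0.7]))
            rng = np.random.default_rng(42)
            outs.append(guided_step(X, E, mask, None, 5, tiny_models, cfg, rng))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1], outs[1][1])

    def test_modulation_conserves_probability(self):
        rng = np.random.default_rng(1)
        post = rng.dirichlet(np.ones(4), size=(2, 5))
        phi = rng.random((4, 2, 1))
        sens = rng.standard_normal((4, 2, 5, 4)) * 0.1
        cur = np.eye(4)[rng.integers(0, 4, (2, 5))]
        cfg = GuidanceConfig(lam=2.0, targets=np.array([0.5, 1.0, 0.0, 0.0]))
        w = np.ones((4, 2))
        out = _modulate(post, phi, sens, cur, cfg, w)
        assert np.abs(out.sum(-1) - 1.0).max() < 1e-10
        assert out.min() >= 0.0

    def test_large_lambda_shifts_argmax_to_preferred_category(self):
        """A regressor that scores category 2 as high-property pulls the
        tilted posterior toward category 2."""
        post = np.full((1, 1, 3), 1.0 / 3.0)
        phi = np.array([[[0.5]], [[0.5]], [[0.5]], [[0.5]]])
        sens = np.zeros((4, 1, 1, 3))
        sens[1, 0, 0] = [0.0, 0.0, 0.4]        # property 2 rises with cat 2
        cur = np.array([[[1.0, 0.0, 0.0]]])
        cfg = GuidanceConfig(lam=5.0, targets=np.array([0.5, 1.0, 0.0, 0.0]),
                             weights=np.array([0.0, 1.0, 0.0, 0.0]),
                             weight_rule="constant")
        w = np.array([[0.0], [1.0], [0.0], [0.0]])
        out = _modulate(post, phi, sens, cur, cfg, w)
        assert out[0, 0].argmax() == 2
        # hand-computed: penalties |0.5 - 1|, |0.5 - 1|, |0.9 - 1| with
        # gain 10 -> tilts exp(-25), exp(-25), exp(-5)
        from diffmcgen.sampling import GUIDANCE_GAIN
        tilts = np.exp(-5.0 * GUIDANCE_GAIN / 10.0
                       * 10.0 * np.array([0.5, 0.5, 0.1]))
        expected = tilts / tilts.sum()
        assert np.allclose(out[0, 0], expected, atol=1e-12)


class TestGenerate:
    def test_same_seed_reproducible(self, tiny_models):
        a = generate(8, tiny_models, GuidanceConfig(seed=3))
        b = generate(8, tiny_models, GuidanceConfig(seed=3))
        for m1, m2 in zip(a, b):
            assert m1.atoms == m2.atoms and m1.bonds == m2.bonds

    def test_invalid_molecules_returned_not_dropped(self, tiny_models):
        mols = generate(12, tiny_models, GuidanceConfig(seed=4))
        assert len(mols) == 12              # nothing silently dropped

    def test_node_counts_from_histogram(self, tiny_models):
        mols = generate(30, tiny_models, GuidanceConfig(seed=5))
        observed = {m.n_atoms for m in mols}
        allowed = set(np.nonzero(tiny_models.n_hist)[0])
        assert observed <= allowed

    def test_coords_generated_and_bond_fill_flagged(self, tiny_models):
        mols, infos = generate(4, tiny_models, GuidanceConfig(seed=6),
                               with_coords=True, return_info=True)
        for m, info in zip(mols, infos):
            assert m.coords is not None
            assert m.coords.shape == (m.n_atoms, 3)
            assert np.abs(m.coords.mean(axis=0)).max() < 1e-6
            assert "geometry_filled_bonds" in info

    def test_guided_sampling_runs_with_adaptive_weights(self, tiny_models):
        mols = generate(4, tiny_models,
                        GuidanceConfig(seed=7, lam=1.0,
                                       weight_rule="adaptive"))
        assert len(mols) == 4


class TestCheckpoint:
    def test_save_load_identical_generation(self, tiny_models, tmp_path):
        tiny_models.save(tmp_path / "ckpt")
        back = DiffMCGenModels.load(tmp_path / "ckpt")
        a = generate(6, tiny_models, GuidanceConfig(seed=8))
        b = generate(6, back, GuidanceConfig(seed=8))
        for m1, m2 in zip(a, b):
            assert m1.atoms == m2.atoms and m1.bonds == m2.bonds
        assert np.array_equal(back.n_hist, tiny_models.n_hist)


class TestTraining:
    def test_loss_decreases(self, tiny_models):
        for key in ("cond", "uncond", "regressor"):
            hist = tiny_models.history[key]
            assert hist[-1] < hist[0]

    def test_continuous_loss_logged(self, tiny_models):
        assert len(tiny_models.history["continuous"]) > 0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TrainConfig())

    def test_guidance_config_validation(self):
        with pytest.raises(ValueError):
            GuidanceConfig(lam=-1.0)
        with pytest.raises(ValueError):
            GuidanceConfig(period=0)


class TestRegressor:
    def test_outputs_in_unit_interval(self, tiny_models):
        X, E, mask = random_state(tiny_models, B=4)
        phi = tiny_models.regressor.predict(X, E, mask, 3)
        assert phi.shape == (4, 4)
        assert phi.min() >= 0.0 and phi.max() <= 1.0

    def test_sensitivities_match_finite_differences(self, tiny_models):
        X, E, mask = random_state(tiny_models, B=1)
        reg = tiny_models.regressor
        phi, gx, ge = reg.sensitivities(X, E, mask, 3)
        eps = 1e-6
        i, c = 2, 1
        Xp = X.copy()
        Xp[0, i, c] += eps
        Xm = X.copy()
        Xm[0, i, c] -= eps
        num = (reg.predict(Xp, E, mask, 3) - reg.predict(Xm, E, mask, 3)) \
            / (2 * eps)
        assert np.abs(gx[:, 0, i, c] - num[0]).max() < 1e-5

    def test_predicts_qed_on_noised_low_t_states(self, guidance_models,
                                                 fixture160):
        """Regressor trained on noised states correlates with clean QED."""
        from diffmcgen import constraints as C
        from diffmcgen.diffusion_discrete import forward_sample_discrete
        rng = np.random.default_rng(0)
        mols = fixture160.molecules[:60]
        graphs = [encode_graph(m, QM9_ALPHABET, guidance_models.config.n_max)
                  for m in mols]
        noisy = [forward_sample_discrete(g, 3, guidance_models.sched_d, rng)
                 for g in graphs]
        X = np.stack([g.X for g in noisy])
        E = np.stack([g.E for g in noisy])
        mask = np.stack([g.mask for g in noisy])
        phi = guidance_models.regressor.predict(X, E, mask, 3)
        qed_true = np.array([C.qed(m) for m in mols])
        assert np.corrcoef(phi[:, 1], qed_true)[0, 1] > 0.5


def test_overfit_sampling_memorizes_single_molecule(single_mol_models):
    """A model overfit on one molecule regenerates it most of the time."""
    models, mol = single_mol_models
    mols = generate(40, models, GuidanceConfig(seed=9, period=1))
    target = mol.to_smiles()
    hits = sum(1 for m in mols
               if check_validity(m)[0] and m.to_smiles() == target)
    assert hits / len(mols) >= 0.8
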