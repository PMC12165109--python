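"""Graph-transformer denoiser: composition reduction, AdaIN, equivariance."""

import numpy as np
import pytest

from diffmcgen.chem_io import EncodedGraph, QM9_ALPHABET, encode_graph, \
    parse_smiles
from diffmcgen.denoiser_discrete import (ConditionEmbedding,
                                         DiscreteDenoiser,
                                         DiscreteDenoiserConfig, _AdaIN,
                                         _DCMHALayer)
from diffmcgen.nn import Tensor


def make_layer(seed=0, plain=False, d=32, de=16, H=4):
    cfg = DiscreteDenoiserConfig(layers=1, heads=H, d_node=d, d_edge=de,
                                 plain_attention=plain)
    return _DCMHALayer(cfg, d_cond=8, rng=np.random.default_rng(seed)), cfg


def reference_mha(layer, h, e, mask):
    """Independent numpy implementation of standard masked MHA."""
    W = layer
    q = h @ W.q.weight.data + W.q.bias.data
    k = h @ W.k.weight.data + W.k.bias.data
    v = h @ W.v.weight.data + W.v.bias.data
    B, n, d = h.shape
    H = W.cfg.heads
    dh = d // H
    out = np.zeros((B, n, d))
    for b in range(B):
        for head in range(H):
            sl = slice(head * dh, (head + 1) * dh)
            logits = q[b][:, sl] @ k[b][:, sl].T / np.sqrt(dh)
            logits = logits + (1.0 - mask[b].astype(float)) * -1e9
            z = np.exp(logits - logits.max(axis=1, keepdims=True))
            p = z / z.sum(axis=1, keepdims=True)
            p = p * mask[b].astype(float)
            out[b][:, sl] = p @ v[b][:, sl]
    return out @ W.out.weight.data + W.out.bias.data


class TestCompositionReduction:
    def test_plain_attention_matches_reference(self):
        layer, _ = make_layer(plain=True)
        rng = np.random.default_rng(1)
        h = rng.standard_normal((2, 6, 32))
        e = rng.standard_normal((2, 6, 6, 16))
        mask = np.ones((2, 6), dtype=bool)
        mask[1, 4:] = False
        got, _ = layer.attention(Tensor(h), Tensor(e), mask)
        ref = reference_mha(layer, h, e, mask)
        assert np.abs(got.data - ref).max() < 1e-5

    def test_identity_composition_equals_plain(self):
        """At init the static maps are identity, the dynamic maps and the
        edge bias are zero, so the composed path must equal plain MHA."""
        layer, cfg = make_layer(plain=False)
        rng = np.random.default_rng(2)
        h = Tensor(rng.standard_normal((2, 5, 32)))
        e = Tensor(rng.standard_normal((2, 5, 5, 16)))
        mask = np.ones((2, 5), dtype=bool)
        composed, _ = layer.attention(h, e, mask)
        cfg.plain_attention = True
        plain, _ = layer.attention(h, e, mask)
        cfg.plain_attention = False
        assert np.abs(composed.data - plain.data).max() < 1e-12

    def test_nontrivial_composition_changes_output(self):
        layer, _ = make_layer(plain=False)
        rng = np.random.default_rng(3)
        h = Tensor(rng.standard_normal((1, 5, 32)))
        e = Tensor(rng.standard_normal((1, 5, 5, 16)))
        mask = np.ones((1, 5), dtype=bool)
        before, _ = layer.attention(h, e, mask)
        layer.comp_pre.data += rng.standard_normal((4, 4)) * 0.3
        layer.dyn_u_post.weight.data += rng.standard_normal(
            layer.dyn_u_post.weight.data.shape) * 0.1
        layer.dyn_v_post.weight.data += rng.standard_normal(
            layer.dyn_v_post.weight.data.shape) * 0.1
        after, _ = layer.attention(h, e, mask)
        assert np.abs(before.data - after.data).max() > 1e-4

    def test_fully_masked_graph_contributes_nothing(self):
        layer, _ = make_layer(plain=False)
        rng = np.random.default_rng(4)
        h = Tensor(rng.standard_normal((1, 4, 32)))
        e = Tensor(rng.standard_normal((1, 4, 4, 16)))
        mask = np.zeros((1, 4), dtype=bool)
        out, _ = layer.attention(h, e, mask)
        # all attention probabilities masked to zero -> only the output bias
        assert np.abs(out.data - layer.out.bias.data).max() < 1e-12


class TestAdaIN:
    def test_zero_condition_is_instance_norm(self):
        adain = _AdaIN(6, 4, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        x = Tensor(rng.standard_normal((2, 5, 6)))
        c = Tensor(np.zeros((2, 4)))
        out = adain(x, c).data
        assert np.abs(out.mean(axis=-1)).max() < 1e-9
        assert np.abs(out.std(axis=-1) - 1.0).max() < 1e-2

    def test_constant_features_finite(self):
        adain = _AdaIN(6, 4, np.random.default_rng(0))
        x = Tensor(np.full((1, 3, 6), 2.5))
        out = adain(x, Tensor(np.zeros((1, 4)))).data
        assert np.all(np.isfinite(out))

    def test_condition_sensitivity(self):
        adain = _AdaIN(6, 4, np.random.default_rng(0))
        adain.affine.weight.data += np.random.default_rng(1).standard_normal(
            adain.affine.weight.data.shape) * 0.5
        x = Tensor(np.random.default_rng(2).standard_normal((1, 3, 6)))
        out1 = adain(x, Tensor(np.ones((1, 4)))).data
        out2 = adain(x, Tensor(-np.ones((1, 4)))).data
        assert np.abs(out1 - out2).max() > 1e-3


@pytest.fixture(scope="module")
def denoiser():
    return DiscreteDenoiser(QM9_ALPHABET, T=50, seed=0)


class TestDenoiserForward:

    def test_outputs_are_distributions(self, denoiser):
        g = encode_graph(parse_smiles("CC(=O)NC"), n_max=8)
        pX, pE = denoiser.predict_clean_graph(g, 10)
        assert np.abs(pX[g.mask].sum(-1) - 1.0).max() < 1e-12
        assert np.abs(pE.sum(-1) - 1.0).max() < 1e-12
        assert np.abs(pE - pE.transpose(1, 0, 2)).max() < 1e-12

    def test_permutation_equivariance(self, denoiser):
        g = encode_graph(parse_smiles("CC=CC(C)N"), n_max=8)
        rng = np.random.default_rng(5)
        for _ in range(5):
            perm = rng.permutation(8)
            gp = EncodedGraph(g.X[perm], g.E[perm][:, perm], g.mask[perm])
            pX, pE = denoiser.predict_clean_graph(g, 7, ConditionEmbedding(t=7))
            pXp, pEp = denoiser.predict_clean_graph(gp, 7,
                                                    ConditionEmbedding(t=7))
            assert np.abs(pX[perm] - pXp).max() < 1e-5
            assert np.abs(pE[perm][:, perm] - pEp).max() < 1e-5

    def test_condition_changes_output(self, denoiser):
        g = encode_graph(parse_smiles("CCO"), n_max=8)
        pX1, _ = denoiser.predict_clean_graph(
            g, 5, ConditionEmbedding(targets=np.full(4, 0.1), t=5))
        pX2, _ = denoiser.predict_clean_graph(
            g, 5, ConditionEmbedding(targets=np.full(4, 0.9), t=5))
        assert np.abs(pX1 - pX2).max() > 1e-8

    def test_unconditional_ignores_targets(self):
        den = DiscreteDenoiser(
            QM9_ALPHABET, DiscreteDenoiserConfig(conditional=False),
            T=50, seed=0)
        g = encode_graph(parse_smiles("CCO"), n_max=8)
        pX1, _ = den.predict_clean_graph(
            g, 5, ConditionEmbedding(targets=np.full(4, 0.1), t=5))
        pX2, _ = den.predict_clean_graph(
            g, 5, ConditionEmbedding(targets=np.full(4, 0.9), t=5))
        assert np.array_equal(pX1, pX2)


class TestConfigValidation:
    def test_rank_bounded_by_heads(self):
        with pytest.raises(ValueError):
            DiscreteDenoiserConfig(heads=2, rank=3)

    def test_condition_embedding_ranges(self):
        with pytest.raises(ValueError):
            ConditionEmbedding(targets=np.array([1.5, 0, 0, 0]))
        with pytest.raises(ValueError):
            ConditionEmbedding(weights=np.array([-1.0, 1, 1, 1]))


def test_overfit_single_molecule_memorizes(single_mol_models):
    """After overfitting one molecule the argmax prediction reproduces it
    from noisy states in the signal-bearing regime.

    At very high noise the per-entry argmax of an equivariant model mixes
    the molecule's alignments by necessity, so the check covers the regime
    where the noisy state still anchors the alignment (t <= T/10)."""
    models, mol = single_mol_models
    from diffmcgen.chem_io import decode_graph
    from diffmcgen.diffusion_discrete import forward_sample_discrete
    g0 = encode_graph(mol, QM9_ALPHABET, 10)
    rng = np.random.default_rng(0)
    hits = 0
    trials = 30
    for k in range(trials):
        t = int(rng.integers(1, models.config.T // 10 + 1))
        gt = forward_sample_discrete(g0, t, models.sched_d, rng)
        pX, pE = models.uncond.predict_clean_graph(
            gt, t, ConditionEmbedding(t=t))
        hard = EncodedGraph(
            np.eye(4)[pX.argmax(-1)] * gt.mask[:, None],
            np.eye(5)[pE.argmax(-1)], gt.mask)
        try:
            if decode_graph(hard).to_smiles() == mol.to_smiles():
                hits += 1
        except Exception:
            pass
    assert hits / trials >= 0.8
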