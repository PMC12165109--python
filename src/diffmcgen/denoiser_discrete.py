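"""Graph-transformer denoiser for the discrete chain.

Predicts clean node/edge category distributions from a noisy one-hot graph.
Two architectural ingredients beyond a standard graph transformer:

* dynamically composable multi-head attention: the vector of H per-head
  attention scores at each node pair is linearly recombined by a static H x H
  map plus a low-rank query/key-dependent map, both before and after the
  softmax, and the composed maps drive the edge-stream update;
* adaptive instance normalization (AdaIN): node and edge streams are
  instance-normalized and then scaled/shifted by affine maps of the condition
  embedding (property targets, dynamic weights, timestep, global features y).

Everything is permutation-equivariant; padding positions are masked out of
attention, pooling and the loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_io import AtomAlphabet, EncodedGraph, QM9_ALPHABET, \
    compute_global_features, global_feature_length
from .nn import Tensor, Linear, MLP, LayerNorm, Module, concat, no_grad, \
    sinusoidal_embedding

__all__ = ["DiscreteDenoiserConfig", "ConditionEmbedding", "DiscreteDenoiser"]

N_PROPERTIES = 4   # pharmacophore, QED, SA, toxicity


@dataclass
class DiscreteDenoiserConfig:
    layers: int = 2
    heads: int = 4
    d_node: int = 64
    d_edge: int = 32
    d_global: int = 32
    rank: int = 2
    t_embed: int = 16
    conditional: bool = True     # False: unconditional model (timestep only)
    plain_attention: bool = False  # identity composition + zero edge bias

    def __post_init__(self):
        if self.heads < 1:
            raise ValueError("heads must be >= 1")
        if self.rank > self.heads:
            raise ValueError("rank must be <= heads")
        if self.d_node % self.heads:
            raise ValueError("d_node must be divisible by heads")


@dataclass
class ConditionEmbedding:
    """Targets + dynamic weights for the four constrained properties, the
    timestep and the global graph features y."""

    targets: np.ndarray = field(default_factory=lambda: np.zeros(N_PROPERTIES))
    weights: np.ndarray = field(default_factory=lambda: np.ones(N_PROPERTIES))
    t: int = 0
    y: np.ndarray | None = None

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.targets.shape != (N_PROPERTIES,) or self.weights.shape != (N_PROPERTIES,):
            raise ValueError(f"targets/weights must have length {N_PROPERTIES}")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if np.any((self.targets < 0) | (self.targets > 1)):
            raise ValueError("targets must lie in [0, 1]")


_ORDER_VALUES = {"none": 0.0, "single": 1.0, "double": 2.0, "triple": 3.0,
                 "aromatic": 1.5}


def _bond_order_values(alphabet: AtomAlphabet) -> np.ndarray:
    return np.array([_ORDER_VALUES.get(c, 1.0)
                     for c in alphabet.bond_categories])


def condition_vector(cond: ConditionEmbedding, T: int, t_embed: int,
                     y_len: int, conditional: bool) -> np.ndarray:
    """Flatten a ConditionEmbedding; the unconditional model sees only t."""
    temb = sinusoidal_embedding(cond.t / max(T, 1) * 1000.0, t_embed)
    if not conditional:
        return np.concatenate([temb, np.zeros(2 * N_PROPERTIES + y_len)])
    y = cond.y if cond.y is not None else np.zeros(y_len)
    return np.concatenate([temb, cond.targets, cond.weights, y])


def _masked_softmax(logits: Tensor, mask_j: np.ndarray) -> Tensor:
    """Softmax over the last axis with masked positions suppressed.

    mask_j: (B, 1, 1, n) float {0,1}; masked columns get -1e9 and are zeroed
    afterwards so they contribute nothing even post-composition.
    """
    neg = Tensor((1.0 - mask_j) * -1e9)
    return (logits + neg).softmax(axis=-1)


class _AdaIN(Module):
    def __init__(self, dim: int, d_cond: int, rng: np.random.Generator):
        self.norm = LayerNorm(dim)
        self.affine = Linear(d_cond, 2 * dim, rng, zero_init=True)
        self.dim = dim

    def __call__(self, x: Tensor, c: Tensor) -> Tensor:
        """x: (B, ..., dim); c: (B, d_cond). Scale/shift broadcast over middle axes."""
        ab = self.affine(c)           # (B, 2*dim)
        extra = x.ndim - 2
        shape = (ab.shape[0],) + (1,) * extra + (2 * self.dim,)
        ab = ab.reshape(shape)
        scale = ab[..., : self.dim]
        shift = ab[..., self.dim:]
        xn = self.norm.normalize_only(x)
        return xn * (scale + 1.0) + shift


class _DCMHALayer(Module):
    """One transformer block: composed attention + edge update + FFN + AdaIN."""

    def __init__(self, cfg: DiscreteDenoiserConfig, d_cond: int,
                 rng: np.random.Generator):
        d, de, H, r = cfg.d_node, cfg.d_edge, cfg.heads, cfg.rank
        self.cfg = cfg
        self.dh = d // H
        self.q = Linear(d, d, rng)
        self.k = Linear(d, d, rng)
        self.v = Linear(d, d, rng)
        self.out = Linear(d, d, rng)
        self.edge_bias = Linear(de, H, rng, zero_init=True)
        # static composition maps, identity-initialized
        self.comp_pre = Tensor(np.eye(H), requires_grad=True)
        self.comp_post = Tensor(np.eye(H), requires_grad=True)
        # dynamic low-rank maps, zero-initialized (no-op at start)
        self.dyn_u_pre = Linear(d, H * r, rng, zero_init=True)
        self.dyn_v_pre = Linear(d, r * H, rng, zero_init=True)
        self.dyn_u_post = Linear(d, H * r, rng, zero_init=True)
        self.dyn_v_post = Linear(d, r * H, rng, zero_init=True)

        self.edge_update = Linear(de + H, de, rng)
        self.node_norm = LayerNorm(d)
        self.edge_norm = LayerNorm(de)
        self.ffn = MLP([d, 2 * d, d], rng)
        self.ffn_norm = LayerNorm(d)
        self.adain_node = _AdaIN(d, d_cond, rng)
        self.adain_edge = _AdaIN(de, d_cond, rng)
        self.glob_in = Linear(cfg.d_global + d + de, cfg.d_global, rng)
        self.glob_out = Linear(cfg.d_global, d, rng, zero_init=True)

    def _compose(self, scores: Tensor, qn: Tensor, kn: Tensor,
                 static: Tensor, dyn_u: Linear, dyn_v: Linear) -> Tensor:
        """Linearly recombine the H head scores at every pair (i, j).

        scores: (B, n, n, H); qn/kn: (B, n, d). Static map plus rank-r
        input-dependent map U(q_i) V(k_j).
        """
        H, r = self.cfg.heads, self.cfg.rank
        B, n = scores.shape[0], scores.shape[1]
        out = scores @ static
        U = dyn_u(qn).reshape(B, n, H, r)             # indexed by i
        V = dyn_v(kn).reshape(B, n, r, H)             # indexed by j
        tmp = scores @ U                              # (B,n,n,H)@(B,n,H,r)->(B,n,n,r)
        tmp = tmp.transpose(0, 2, 1, 3) @ V           # batch over j -> (B,n_j,n_i,H)
        return out + tmp.transpose(0, 2, 1, 3)

    def attention(self, h: Tensor, e: Tensor, mask: np.ndarray):
        """Composed multi-head attention.

        Returns (attn_out (B,n,d), composed pre-softmax scores (B,n,n,H)).
        With ``plain_attention`` the edge bias and both composition maps are
        skipped and this reduces to standard masked multi-head attention.
        """
        cfg = self.cfg
        B, n = mask.shape
        H, dh = cfg.heads, self.dh
        mask_j = mask.astype(float).reshape(B, 1, 1, n)

        qn, kn, vn = self.q(h), self.k(h), self.v(h)
        q4 = qn.reshape(B, n, H, dh).transpose(0, 2, 1, 3)
        k4 = kn.reshape(B, n, H, dh).transpose(0, 2, 1, 3)
        v4 = vn.reshape(B, n, H, dh).transpose(0, 2, 1, 3)
        logits = (q4 @ k4.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))  # (B,H,n,n)

        if not cfg.plain_attention:
            logits = logits + self.edge_bias(e).transpose(0, 3, 1, 2)
            scores = logits.transpose(0, 2, 3, 1)                       # (B,n,n,H)
            scores = self._compose(scores, qn, kn, self.comp_pre,
                                   self.dyn_u_pre, self.dyn_v_pre)
            logits = scores.transpose(0, 3, 1, 2)

        probs = _masked_softmax(logits, mask_j)
        if not cfg.plain_attention:
            p_scores = probs.transpose(0, 2, 3, 1)
            p_scores = self._compose(p_scores, qn, kn, self.comp_post,
                                     self.dyn_u_post, self.dyn_v_post)
            probs = p_scores.transpose(0, 3, 1, 2)
        probs = probs * Tensor(mask_j)                                  # kill padding

        attn = (probs @ v4).transpose(0, 2, 1, 3).reshape(B, n, H * dh)
        return self.out(attn), logits.transpose(0, 2, 3, 1)

    def __call__(self, h: Tensor, e: Tensor, g: Tensor, c: Tensor,
                 mask: np.ndarray):
        cfg = self.cfg
        B, n = mask.shape
        mask_f = mask.astype(float)
        pair_mask = Tensor((mask_f[:, :, None] * mask_f[:, None, :])[..., None])

        attn_out, attn_feat = self.attention(h, e, mask)
        h = self.node_norm(h + attn_out)

        # edge stream fed by the composed attention maps
        e = self.edge_norm(e + self.edge_update(concat([e, attn_feat], axis=-1)))
        e = (e + e.transpose(0, 2, 1, 3)) * 0.5                          # symmetry
        e = e * pair_mask

        # global stream: masked means in, broadcast out
        inv_n = Tensor((1.0 / np.maximum(mask_f.sum(1), 1.0)).reshape(B, 1))
        mean_h = (h * Tensor(mask_f[..., None])).sum(axis=1) * inv_n
        inv_p = Tensor((1.0 / np.maximum(mask_f.sum(1) ** 2, 1.0)).reshape(B, 1))
        mean_e = (e * pair_mask).sum(axis=1).sum(axis=1) * inv_p
        g = g + self.glob_in(concat([g, mean_h, mean_e], axis=-1)).tanh()
        gb = self.glob_out(g)
        h = h + gb.reshape(B, 1, gb.shape[-1])

        h = self.ffn_norm(h + self.ffn(h))
        h = self.adain_node(h, c)
        e = self.adain_edge(e, c)
        h = h * Tensor(mask_f[..., None])
        e = e * pair_mask
        return h, e, g


class DiscreteDenoiser(Module):
    def __init__(self, alphabet: AtomAlphabet = QM9_ALPHABET,
                 config: DiscreteDenoiserConfig | None = None,
                 T: int = 500, seed: int = 0):
        cfg = config or DiscreteDenoiserConfig()
        rng = np.random.default_rng(seed)
        self.alphabet = alphabet
        self.cfg = cfg
        self.T = T
        a, b = alphabet.n_atom_types, alphabet.n_bond_types
        self.y_len = global_feature_length(alphabet)
        self.d_cond = cfg.t_embed + 2 * N_PROPERTIES + self.y_len
        # +2: per-node degree and valence sum derived from the current edge
        # state, so valence violations are directly visible to the denoiser
        self.node_in = Linear(a + 2 + self.d_cond, cfg.d_node, rng)
        self.edge_in = Linear(b, cfg.d_edge, rng)
        self.glob_init = Linear(self.d_cond, cfg.d_global, rng)
        self.blocks = [_DCMHALayer(cfg, self.d_cond, rng)
                       for _ in range(cfg.layers)]
        self.node_head = Linear(cfg.d_node, a, rng)
        self.edge_head = Linear(cfg.d_edge, b, rng)

    # -- core forward (training path, Tensor in/out) -----------------------
    def forward(self, X: np.ndarray, E: np.ndarray, mask: np.ndarray,
                cond_vecs: np.ndarray):
        """X: (B,n,a), E: (B,n,n,b), mask: (B,n), cond_vecs: (B,d_cond).

        Returns (logits_X, probs_X, logits_E, probs_E) as Tensors; the edge
        logits are symmetrized by averaging the (i,j) and (j,i) entries.
        """
        B, n = mask.shape
        mask_f = mask.astype(float)
        c = Tensor(cond_vecs)
        cb = cond_vecs[:, None, :].repeat(n, axis=1)
        # structural node features from the current edge state
        order_val = _bond_order_values(self.alphabet)
        pair = (mask_f[:, :, None] * mask_f[:, None, :])[..., None]
        Em = E * pair
        degree = (1.0 - Em[..., 0]) * pair[..., 0]
        deg = degree.sum(axis=2, keepdims=True) / 4.0
        val = (Em * order_val).sum(axis=(2, 3), keepdims=False)[..., None] / 4.0
        h = self.node_in(concat([Tensor(X), Tensor(deg), Tensor(val),
                                 Tensor(cb)], axis=-1))
        e = self.edge_in(Tensor(E))
        g = self.glob_init(c).tanh()
        for blk in self.blocks:
            h, e, g = blk(h, e, g, c, mask)
        logits_X = self.node_head(h)
        logits_E = self.edge_head(e)
        logits_E = (logits_E + logits_E.transpose(0, 2, 1, 3)) * 0.5
        return logits_X, logits_X.softmax(-1), logits_E, logits_E.softmax(-1)

    # -- inference convenience ---------------------------------------------
    def predict_clean_graph(self, g_t: EncodedGraph, t: int,
                            cond: ConditionEmbedding | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Normalized clean-category distributions (X_hat, E_hat) as numpy."""
        cond = cond or ConditionEmbedding(t=t)
        cond.t = t
        if cond.y is None and self.cfg.conditional:
            cond.y = compute_global_features(g_t, self.alphabet)
        vec = condition_vector(cond, self.T, self.cfg.t_embed, self.y_len,
                               self.cfg.conditional)
        with no_grad():
            _, pX, _, pE = self.forward(g_t.X[None], g_t.E[None],
                                        g_t.mask[None], vec[None])
        return pX.data[0], pE.data[0]

    def condition_vectors(self, graphs: list[EncodedGraph], t: int,
                          conds: "list[ConditionEmbedding] | None" = None
                          ) -> np.ndarray:
        conds = conds or [ConditionEmbedding(t=t) for _ in graphs]
        vecs = []
        for g, cd in zip(graphs, conds):
            cd.t = t
            if cd.y is None and self.cfg.conditional:
                cd.y = compute_global_features(g, self.alphabet)
            vecs.append(condition_vector(cd, self.T, self.cfg.t_embed,
                                         self.y_len, self.cfg.conditional))
        return np.stack(vecs)
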