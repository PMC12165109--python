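"""SE(3)-equivariant coordinate-noise predictor.

The network never updates coordinates directly. Geometry enters only through
rigid-motion-invariant scalars (pairwise distances, neighbor angles) and
per-edge local frames built by Gram-Schmidt on relative positions. Learned
invariant coefficients are combined with the frame axes to assemble the
predicted noise, so rotating the input rotates the output and translating it
changes nothing. The pharmacophore matching coefficient is the only property
the continuous model is conditioned on.

Frames and invariant features are computed in plain numpy and enter the
autodiff graph as constants: parameter gradients flow only through the
invariant message/coefficient networks, which keeps training cheap and the
equivariance exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Linear, MLP, Module, concat, no_grad, sinusoidal_embedding

__all__ = ["ContinuousDenoiserConfig", "GeometricFeatures", "LocalFrames",
           "build_local_frames", "geometric_features", "ContinuousDenoiser"]

_DEGENERATE_EPS = 1e-8


@dataclass
class ContinuousDenoiserConfig:
    cutoff: float = 5.0        # radius-graph cutoff, Angstrom
    hops: int = 2              # message-passing rounds (k-hop frame aggregation)
    d_scalar: int = 64
    d_message: int = 96
    n_rbf: int = 16
    t_embed: int = 8
    # ablation switch: without the frame-transition block the noise field is
    # restricted to radial (edge-direction) components, as in plain
    # distance-based equivariant updates
    use_frame_block: bool = True


@dataclass
class GeometricFeatures:
    """Invariant pairwise features inside the cutoff."""

    dist: np.ndarray        # (n, n) distances, Angstrom
    adj: np.ndarray         # (n, n) bool, radius graph without self-loops
    cos_ref: np.ndarray     # (n, n) cos angle between edge and reference neighbor
    mean_angle: np.ndarray  # (n, n) mean angle (radians) over other neighbors at i
    radius: np.ndarray = None  # (n,) distance from the center of mass


@dataclass
class LocalFrames:
    axes: np.ndarray        # (n, n, 3, 3) orthonormal triads, rows = axes
    valid: np.ndarray       # (n, n) bool, False where geometry is degenerate


def _reference_neighbor(dist: np.ndarray, adj: np.ndarray) -> np.ndarray:
    """ref[i, j] = nearest neighbor of i other than j (-1 if none)."""
    n = dist.shape[0]
    ref = -np.ones((n, n), dtype=int)
    for i in range(n):
        nbrs = np.where(adj[i])[0]
        for j in nbrs:
            others = nbrs[nbrs != j]
            if others.size:
                ref[i, j] = others[np.argmin(dist[i, others])]
    return ref


def build_local_frames(coords: np.ndarray, adj: np.ndarray) -> LocalFrames:
    """Per-edge orthonormal frame from Gram-Schmidt on (edge vector,
    reference-neighbor vector, cross product).

    Rotating the molecule rotates every valid frame identically; translations
    leave frames unchanged. Collinear or neighbor-less edges are flagged
    invalid and receive a deterministic fallback triad (completed from the
    least-aligned Cartesian axis) whose non-primary axes are ignored
    downstream.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    ref = _reference_neighbor(dist, adj)
    axes = np.zeros((n, n, 3, 3))
    valid = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            if not adj[i, j]:
                continue
            e1 = diff[i, j]
            d = np.linalg.norm(e1)
            if d < _DEGENERATE_EPS:
                continue
            e1 = e1 / d
            ok = False
            if ref[i, j] >= 0:
                v = diff[i, ref[i, j]]
                u = v - (v @ e1) * e1
                if np.linalg.norm(u) > _DEGENERATE_EPS:
                    e2 = u / np.linalg.norm(u)
                    ok = True
            if not ok:
                # fallback: least-aligned Cartesian axis, orthogonalized
                k = int(np.argmin(np.abs(e1)))
                v = np.zeros(3)
                v[k] = 1.0
                u = v - (v @ e1) * e1
                e2 = u / np.linalg.norm(u)
            e3 = np.cross(e1, e2)
            axes[i, j] = np.stack([e1, e2, e3])
            valid[i, j] = ok
    return LocalFrames(axes=axes, valid=valid)


def geometric_features(coords: np.ndarray, cutoff: float) -> GeometricFeatures:
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    n = coords.shape[0]
    diff = coords[None, :, :] - coords[:, None, :]
    dist = np.linalg.norm(diff, axis=-1)
    adj = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    cos_ref = np.zeros((n, n))
    mean_angle = np.zeros((n, n))
    ref = _reference_neighbor(dist, adj)
    for i in range(n):
        nbrs = np.where(adj[i])[0]
        for j in nbrs:
            u = diff[i, j] / max(dist[i, j], _DEGENERATE_EPS)
            if ref[i, j] >= 0:
                v = diff[i, ref[i, j]] / max(dist[i, ref[i, j]], _DEGENERATE_EPS)
                cos_ref[i, j] = float(np.clip(u @ v, -1.0, 1.0))
            others = nbrs[nbrs != j]
            if others.size:
                vs = diff[i, others] / np.maximum(
                    dist[i, others][:, None], _DEGENERATE_EPS)
                angles = np.arccos(np.clip(vs @ u, -1.0, 1.0))
                mean_angle[i, j] = float(angles.mean())
    radius = np.linalg.norm(coords - coords.mean(axis=0), axis=-1)
    return GeometricFeatures(dist=dist, adj=adj, cos_ref=cos_ref,
                             mean_angle=mean_angle, radius=radius)


def _rbf(dist: np.ndarray, n_rbf: int, cutoff: float) -> np.ndarray:
    centers = np.linspace(0.0, cutoff, n_rbf)
    gamma = (n_rbf / cutoff) ** 2
    return np.exp(-gamma * (dist[..., None] - centers) ** 2)


class ContinuousDenoiser(Module):
    def __init__(self, n_atom_types: int,
                 config: ContinuousDenoiserConfig | None = None,
                 T: int = 500, seed: int = 0):
        cfg = config or ContinuousDenoiserConfig()
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.T = T
        ds, dm = cfg.d_scalar, cfg.d_message
        # +1: pharmacophore coefficient; +t_embed: timestep
        self.node_embed = Linear(n_atom_types, ds, rng)
        # pair features: rbf(d) | cos_ref | mean_angle | |x_i| | |x_j| |
        # t-embedding | pharm coefficient | sender/receiver scalars
        d_pair = cfg.n_rbf + 4 + 2 * ds + cfg.t_embed + 1
        self.msg_mlps = [MLP([d_pair, dm, dm], rng) for _ in range(cfg.hops)]
        self.score_mlps = [MLP([d_pair, dm, 1], rng) for _ in range(cfg.hops)]
        self.upd_mlps = [MLP([ds + dm, dm, ds], rng) for _ in range(cfg.hops)]
        self.coef_mlp = MLP([d_pair + dm, dm, 3], rng, zero_init_last=True)

    def _pair_features(self, feats: GeometricFeatures, s: Tensor,
                       t: int, pharm: float) -> Tensor:
        n = feats.dist.shape[0]
        cfg = self.cfg
        const = np.concatenate([
            _rbf(feats.dist, cfg.n_rbf, cfg.cutoff),
            feats.cos_ref[..., None],
            feats.mean_angle[..., None],
            np.broadcast_to(feats.radius[:, None, None], (n, n, 1)),
            np.broadcast_to(feats.radius[None, :, None], (n, n, 1)),
            np.broadcast_to(
                sinusoidal_embedding(t / max(self.T, 1) * 1000.0, cfg.t_embed),
                (n, n, cfg.t_embed)),
            np.full((n, n, 1), float(pharm)),
        ], axis=-1)
        zeros = Tensor(np.zeros((n, n, s.shape[-1])))
        si = s.reshape(n, 1, s.shape[-1]) + zeros
        sj = s.reshape(1, n, s.shape[-1]) + zeros
        return concat([Tensor(const), si, sj], axis=-1)

    def forward(self, coords: np.ndarray, node_types: np.ndarray, t: int,
                pharm: float = 0.0,
                bonds_adj: np.ndarray | None = None) -> Tensor:
        """Predict coordinate noise; coords (n,3) centered, node_types (n,a).

        bonds_adj: optional (n,n) bool of known bonds, always kept in the
        radius graph.
        """
        coords = np.asarray(coords, dtype=float)
        n = coords.shape[0]
        cfg = self.cfg
        feats = geometric_features(coords, cfg.cutoff)
        if bonds_adj is not None:
            feats.adj |= (np.asarray(bonds_adj, dtype=bool)
                          & ~np.eye(n, dtype=bool))
        frames = build_local_frames(coords, feats.adj)

        adj_f = feats.adj.astype(float)
        neg = Tensor(((1.0 - adj_f) * -1e9)[..., None])
        adj_t = Tensor(adj_f[..., None])
        s = self.node_embed(Tensor(node_types)).tanh()
        w = Tensor(np.zeros((n, n, 1)))
        for hop in range(cfg.hops):
            pair = self._pair_features(feats, s, t, pharm)
            msg = self.msg_mlps[hop](pair)                       # (n, n, dm)
            score = self.score_mlps[hop](pair)                   # (n, n, 1)
            # attention over the neighbors j of each receiver i (axis 1);
            # isolated nodes end up with all-zero weights
            w = (score + neg).softmax(axis=1) * adj_t
            agg = (msg * w).sum(axis=1)                          # (n, dm)
            s = s + self.upd_mlps[hop](concat([s, agg], axis=-1)).tanh()

        # frame-transition block: invariant coefficients per edge, combined
        # with the frame axes (c1 e1 + c2 e2 + c3 e3)
        pair = self._pair_features(feats, s, t, pharm)
        if cfg.use_frame_block:
            edge_state = self.msg_mlps[-1](pair)
        else:
            edge_state = Tensor(np.zeros((n, n, cfg.d_message)))
        coefs = self.coef_mlp(concat([pair, edge_state], axis=-1))
        # zero the two non-primary axes where the frame is degenerate; the
        # ablated model keeps only the radial axis everywhere
        axis_mask = np.ones((n, n, 3))
        axis_mask[..., 1] = frames.valid if cfg.use_frame_block else 0.0
        axis_mask[..., 2] = frames.valid if cfg.use_frame_block else 0.0
        axis_mask *= feats.adj[..., None]
        coefs = coefs * Tensor(axis_mask)
        contrib = (coefs.reshape(n, n, 3, 1) * Tensor(frames.axes)).sum(axis=2)
        eps = (contrib * w).sum(axis=1)                          # (n, 3)
        # project to the zero-center-of-mass subspace
        P = Tensor(np.eye(n) - np.full((n, n), 1.0 / n))
        return P @ eps

    def predict_coord_noise(self, coords: np.ndarray, node_types: np.ndarray,
                            t: int, pharm: float = 0.0,
                            bonds_adj: np.ndarray | None = None) -> np.ndarray:
        with no_grad():
            return self.forward(coords, node_types, t, pharm, bonds_adj).data
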