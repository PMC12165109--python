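"""Categorical (discrete) diffusion on molecular graphs.

Forward noising applies row-stochastic transition matrices
``Q_t = alpha_t * I + (1 - alpha_t) * 1 m^T`` independently to every node
category and every unordered edge category, so the stationary distribution is
the declared marginal ``m`` over atom / bond types ("marginal noise"). The
reverse chain uses the exact categorical posterior ``q(x_{t-1} | x_t, x_0)``
marginalized over a predicted soft ``x0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem_io import EncodedGraph

__all__ = [
    "DiscreteNoiseSchedule", "build_discrete_schedule", "cosine_alpha_bar",
    "forward_sample_discrete", "discrete_posterior", "discrete_loss",
]


def cosine_alpha_bar(T: int, s: float = 0.008) -> np.ndarray:
    """Cumulative retention schedule: alpha_bar[0] = 1, decreasing to ~0."""
    t = np.arange(T + 1) / T
    f = np.cos((t + s) / (1 + s) * np.pi / 2.0) ** 2
    ab = f / f[0]
    return np.clip(ab, 1e-8, 1.0)


def _linear_alpha_bar(T: int) -> np.ndarray:
    betas = np.linspace(1e-4, 0.02, T)
    return np.concatenate([[1.0], np.cumprod(1.0 - betas)])


@dataclass
class DiscreteNoiseSchedule:
    T: int
    alpha_bar: np.ndarray           # (T+1,), alpha_bar[0] = 1, nonincreasing
    m_X: np.ndarray                 # stationary marginal over atom categories
    m_E: np.ndarray                 # stationary marginal over bond categories
    Q_X: np.ndarray                 # (T+1, a, a); Q_X[0] = I (unused step 0)
    Q_E: np.ndarray
    Qbar_X: np.ndarray              # cumulative products, Qbar[0] = I
    Qbar_E: np.ndarray
    schedule: str = "cosine"

    @property
    def alphas(self) -> np.ndarray:
        return self.alpha_bar[1:] / self.alpha_bar[:-1]


def _transition_stack(alpha_bar: np.ndarray, m: np.ndarray):
    k = m.size
    eye = np.eye(k)
    ones_m = np.outer(np.ones(k), m)
    alphas = alpha_bar[1:] / alpha_bar[:-1]
    Q = np.empty((alpha_bar.size, k, k))
    Qbar = np.empty_like(Q)
    Q[0] = eye
    Qbar[0] = eye
    for t in range(1, alpha_bar.size):
        Q[t] = alphas[t - 1] * eye + (1.0 - alphas[t - 1]) * ones_m
        Qbar[t] = Qbar[t - 1] @ Q[t]
    return Q, Qbar


def build_discrete_schedule(T: int, m_X: np.ndarray, m_E: np.ndarray,
                            schedule: str = "cosine",
                            noise: str = "marginal") -> DiscreteNoiseSchedule:
    if T < 1:
        raise ValueError("T must be >= 1")
    m_X = np.asarray(m_X, dtype=float)
    m_E = np.asarray(m_E, dtype=float)
    for name, m in (("m_X", m_X), ("m_E", m_E)):
        if not np.isclose(m.sum(), 1.0, atol=1e-8) or np.any(m < 0):
            raise ValueError(f"{name} must be a probability vector")
    if noise == "uniform":
        m_X = np.full_like(m_X, 1.0 / m_X.size)
        m_E = np.full_like(m_E, 1.0 / m_E.size)
    elif noise != "marginal":
        raise ValueError(f"unknown noise family {noise!r}")
    if schedule == "cosine":
        ab = cosine_alpha_bar(T)
    elif schedule == "linear":
        ab = _linear_alpha_bar(T)
    else:
        raise ValueError(f"unknown schedule {schedule!r}")
    Q_X, Qbar_X = _transition_stack(ab, m_X)
    Q_E, Qbar_E = _transition_stack(ab, m_E)
    return DiscreteNoiseSchedule(T=T, alpha_bar=ab, m_X=m_X, m_E=m_E,
                                 Q_X=Q_X, Q_E=Q_E, Qbar_X=Qbar_X, Qbar_E=Qbar_E,
                                 schedule=schedule)


def _sample_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw; probs (..., k) -> indices (...)."""
    flat = probs.reshape(-1, probs.shape[-1])
    cum = np.cumsum(flat, axis=1)
    u = rng.random(flat.shape[0])[:, None] * cum[:, -1:]
    idx = (u > cum).sum(axis=1)
    return idx.reshape(probs.shape[:-1])


def forward_sample_discrete(g0: EncodedGraph, t: int, sched: DiscreteNoiseSchedule,
                            rng: np.random.Generator) -> EncodedGraph:
    """Draw g_t ~ q(g_t | g_0) = Cat(g_0 Qbar_t), keeping E symmetric."""
    if not (1 <= t <= sched.T):
        raise ValueError(f"t={t} outside [1, {sched.T}]")
    n_max, a = g0.X.shape
    b = g0.E.shape[-1]
    mask = g0.mask
    out = g0.copy()

    probs_X = g0.X @ sched.Qbar_X[t]
    idx_X = _sample_categorical(probs_X[mask], rng)
    X = np.zeros((n_max, a))
    X[np.where(mask)[0], idx_X] = 1.0
    out.X = X

    E = np.zeros((n_max, n_max, b))
    iu, ju = np.triu_indices(n_max, k=1)
    keep = mask[iu] & mask[ju]
    iu, ju = iu[keep], ju[keep]
    probs_E = g0.E[iu, ju] @ sched.Qbar_E[t]
    idx_E = _sample_categorical(probs_E, rng)
    E[iu, ju, idx_E] = 1.0
    E[ju, iu, idx_E] = 1.0
    diag = np.where(mask)[0]
    E[diag, diag, 0] = 1.0     # self-loops fixed to "none"
    out.E = E
    return out


def discrete_posterior(x_t: np.ndarray, x0_dist: np.ndarray, t: int,
                       Q: np.ndarray, Qbar: np.ndarray) -> np.ndarray:
    """Exact posterior q(x_{t-1} | x_t, x0), marginalized over soft x0.

    x_t: one-hot (..., k); x0_dist: distribution (..., k). Q/Qbar are the
    (T+1, k, k) stacks for the relevant category space. Returns (..., k).
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    left = x_t @ Q[t].T                  # (..., k) over x_{t-1} categories
    # per-candidate-x0 posterior: num[c, j] = left[j] * Qbar_{t-1}[c, j]
    num = left[..., None, :] * Qbar[t - 1]
    z = num.sum(axis=-1, keepdims=True)
    if np.any(z <= 0):
        raise FloatingPointError("zero-probability transition in posterior")
    per_x0 = num / z                     # (..., k_x0, k_prev)
    post = (x0_dist[..., :, None] * per_x0).sum(axis=-2)
    return post / post.sum(axis=-1, keepdims=True)


def discrete_loss(pred_X: np.ndarray, pred_E: np.ndarray, g0: EncodedGraph,
                  lambda_E: float = 1.0, eps: float = 1e-12) -> float:
    """Masked cross-entropy vs the clean graph; edges on the upper triangle."""
    mask = g0.mask
    node_ce = -(g0.X[mask] * np.log(pred_X[mask] + eps)).sum(axis=-1)
    iu, ju = np.triu_indices(g0.X.shape[0], k=1)
    keep = mask[iu] & mask[ju]
    edge_ce = -(g0.E[iu[keep], ju[keep]]
                * np.log(pred_E[iu[keep], ju[keep]] + eps)).sum(axis=-1)
    loss = node_ce.mean()
    if edge_ce.size:
        loss = loss + lambda_E * edge_ce.mean()
    return float(loss)
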