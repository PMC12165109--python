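"""Training and multi-objective reverse-diffusion sampling.

The generation strategy alternates between a conditional model (discrete +
continuous chains, conditioned on property targets, dynamic weights and global
graph features) and a separately trained unconditional model (discrete chain
only, timestep conditioning alone), and modulates every categorical posterior
with a regressor over noisy graph states: candidate categories are reweighted
by ``exp(-lambda * sum_p w_p |phi_p(g with candidate) - target_p|)`` using a
first-order (input-gradient) estimate of the regressor's per-category
sensitivity. Dynamic weights track the currently worst-satisfied constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import chem_io
from .chem_io import (AtomAlphabet, EncodedGraph, Molecule, QM9_ALPHABET,
                      decode_graph, encode_graph, infer_bonds_from_distances)
from .constraints import (PharmacophoreHypothesis, ToxicityModel,
                          property_vector)
from .denoiser_discrete import (ConditionEmbedding, DiscreteDenoiser,
                                DiscreteDenoiserConfig, N_PROPERTIES)
from .denoiser_continuous import ContinuousDenoiser, ContinuousDenoiserConfig
from .diffusion_continuous import (build_continuous_schedule,
                                   forward_sample_coords, remove_com,
                                   reverse_step_coords, zero_com_noise)
from .diffusion_discrete import (build_discrete_schedule, discrete_posterior,
                                 forward_sample_discrete)
from .nn import Adam, MLP, Module, Tensor, no_grad

__all__ = ["GuidanceConfig", "GuidanceRegressor", "TrainConfig",
           "DiffMCGenModels", "train", "guided_step", "generate"]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class GuidanceConfig:
    """Targets, dynamic weights and strength for multi-objective sampling."""

    targets: np.ndarray = field(default_factory=lambda: np.array([1.0, 1.0, 0.0, 0.0]))
    weights: np.ndarray = field(default_factory=lambda: np.ones(N_PROPERTIES))
    weight_rule: str = "adaptive"      # "adaptive" | "constant"
    lam: float = 0.0                   # guidance strength lambda
    period: int = 5                    # unconditional model every k-th step
    seed: int = 0

    def __post_init__(self):
        self.targets = np.asarray(self.targets, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.period < 1:
            raise ValueError("period must be >= 1")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")


@dataclass
class TrainConfig:
    T: int = 500
    n_max: int = 16
    lambda_E: float = 5.0              # edge weight in the discrete loss
    lambda_cont: float = 1.0
    lr: float = 2e-3
    batch_size: int = 32               # minibatch of graphs per step
    steps_discrete: int = 1500
    steps_uncond: int = 800
    steps_continuous: int = 600
    steps_regressor: int = 1200
    seed: int = 0
    denoiser: DiscreteDenoiserConfig = field(default_factory=DiscreteDenoiserConfig)
    continuous: ContinuousDenoiserConfig = field(default_factory=ContinuousDenoiserConfig)
    schedule: str = "cosine"


# ---------------------------------------------------------------------------
# guidance regressor
# ---------------------------------------------------------------------------

class GuidanceRegressor(Module):
    """Predicts the four clean-molecule properties from a noisy graph state.

    Features are differentiable pooled statistics of (X, E): category
    fractions, and the atom-type x bond-type x atom-type co-occurrence tensor
    X^T E_k X - so input gradients give per-node / per-edge category
    sensitivities for first-order guidance.
    """

    def __init__(self, alphabet: AtomAlphabet, T: int, n_max: int,
                 hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        a, b = alphabet.n_atom_types, alphabet.n_bond_types
        self.alphabet = alphabet
        self.T = T
        self.n_max = n_max
        d_in = a + b + b * a * a + 2
        self.mlp = MLP([d_in, hidden, hidden, N_PROPERTIES], rng)

    def forward(self, X: Tensor, E: Tensor, mask: np.ndarray, t: int) -> Tensor:
        B, n = mask.shape
        a = self.alphabet.n_atom_types
        b = self.alphabet.n_bond_types
        mask_f = mask.astype(float)
        inv_n = (1.0 / np.maximum(mask_f.sum(1), 1.0))
        Xm = X * Tensor(mask_f[..., None])
        frac_X = Xm.sum(axis=1) * Tensor(inv_n[:, None])
        pair_f = (mask_f[:, :, None] * mask_f[:, None, :])[..., None]
        Em = E * Tensor(pair_f)
        inv_p = 1.0 / np.maximum(mask_f.sum(1) ** 2, 1.0)
        frac_E = Em.sum(axis=1).sum(axis=1) * Tensor(inv_p[:, None])
        Xt = Xm.transpose(0, 2, 1)                       # (B, a, n)
        coocs = []
        for k in range(b):
            cooc = (Xt @ Em[..., k]) @ Xm                # (B, a, a)
            coocs.append((cooc * Tensor(inv_p[:, None, None])).reshape(B, a * a))
        from .nn import concat
        extra = Tensor(np.stack([mask_f.sum(1) / self.n_max,
                                 np.full(B, t / max(self.T, 1))], axis=1))
        feats = concat([frac_X, frac_E] + coocs + [extra], axis=-1)
        return self.mlp(feats).sigmoid()

    def predict(self, X: np.ndarray, E: np.ndarray, mask: np.ndarray,
                t: int) -> np.ndarray:
        with no_grad():
            return self.forward(Tensor(X), Tensor(E), mask, t).data

    def sensitivities(self, X: np.ndarray, E: np.ndarray, mask: np.ndarray,
                      t: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(phi, dphi/dX, dphi/dE) with gradient arrays shaped
        (P, B, n, a) and (P, B, n, n, b) for the P properties."""
        B, n = mask.shape
        phi = None
        gx = np.zeros((N_PROPERTIES,) + X.shape)
        ge = np.zeros((N_PROPERTIES,) + E.shape)
        for p in range(N_PROPERTIES):
            Xin = Tensor(X, requires_grad=True)
            Ein = Tensor(E, requires_grad=True)
            out = self.forward(Xin, Ein, mask, t)
            if phi is None:
                phi = out.data.copy()
            out[:, p].sum().backward()
            gx[p] = Xin.grad
            ge[p] = Ein.grad
        return phi, gx, ge


# ---------------------------------------------------------------------------
# trained-model bundle
# ---------------------------------------------------------------------------

@dataclass
class DiffMCGenModels:
    alphabet: AtomAlphabet
    config: TrainConfig
    sched_d: object
    sched_c: object
    cond: DiscreteDenoiser
    uncond: DiscreteDenoiser
    cont: ContinuousDenoiser
    regressor: GuidanceRegressor
    n_hist: np.ndarray                 # empirical node-count distribution
    m_X: np.ndarray
    m_E: np.ndarray
    history: dict = field(default_factory=dict)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name, mod in (("cond", self.cond), ("uncond", self.uncond),
                          ("cont", self.cont), ("reg", self.regressor)):
            for k, v in mod.state_dict().items():
                arrays[f"{name}/{k}"] = v
        arrays["n_hist"] = self.n_hist
        arrays["m_X"] = self.m_X
        arrays["m_E"] = self.m_E
        np.savez(directory / "weights.npz", **arrays)
        cfg = asdict(self.config)
        cfg["alphabet"] = {"symbols": list(self.alphabet.symbols),
                           "valences": self.alphabet.valences,
                           "bond_categories": list(self.alphabet.bond_categories)}
        with open(directory / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1)

    @staticmethod
    def load(directory) -> "DiffMCGenModels":
        directory = Path(directory)
        with open(directory / "config.json") as fh:
            cfg = json.load(fh)
        alpha_d = cfg.pop("alphabet")
        alphabet = AtomAlphabet(symbols=tuple(alpha_d["symbols"]),
                                valences=alpha_d["valences"],
                                bond_categories=tuple(alpha_d["bond_categories"]))
        cfg["denoiser"] = DiscreteDenoiserConfig(**cfg["denoiser"])
        cfg["continuous"] = ContinuousDenoiserConfig(**cfg["continuous"])
        config = TrainConfig(**cfg)
        data = np.load(directory / "weights.npz")
        models = _build_models(alphabet, config, data["m_X"], data["m_E"])
        models.n_hist = data["n_hist"]
        for name, mod in (("cond", models.cond), ("uncond", models.uncond),
                          ("cont", models.cont), ("reg", models.regressor)):
            state = {k.split("/", 1)[1]: data[k] for k in data.files
                     if k.startswith(name + "/")}
            mod.load_state_dict(state)
        return models


def _build_models(alphabet: AtomAlphabet, cfg: TrainConfig,
                  m_X: np.ndarray, m_E: np.ndarray) -> DiffMCGenModels:
    sched_d = build_discrete_schedule(cfg.T, m_X, m_E, schedule=cfg.schedule)
    sched_c = build_continuous_schedule(cfg.T, schedule=cfg.schedule)
    uncond_cfg = DiscreteDenoiserConfig(**{**asdict(cfg.denoiser),
                                           "conditional": False})
    cond = DiscreteDenoiser(alphabet, cfg.denoiser, T=cfg.T, seed=cfg.seed)
    uncond = DiscreteDenoiser(alphabet, uncond_cfg, T=cfg.T, seed=cfg.seed + 1)
    cont = ContinuousDenoiser(alphabet.n_atom_types, cfg.continuous,
                              T=cfg.T, seed=cfg.seed + 2)
    reg = GuidanceRegressor(alphabet, cfg.T, cfg.n_max, seed=cfg.seed + 3)
    return DiffMCGenModels(alphabet=alphabet, config=cfg, sched_d=sched_d,
                           sched_c=sched_c, cond=cond, uncond=uncond,
                           cont=cont, regressor=reg,
                           n_hist=np.ones(1), m_X=m_X, m_E=m_E)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _marginals(graphs: list[EncodedGraph], alphabet: AtomAlphabet):
    a, b = alphabet.n_atom_types, alphabet.n_bond_types
    cx = np.zeros(a)
    ce = np.zeros(b)
    for g in graphs:
        cx += g.X[g.mask].sum(axis=0)
        iu, ju = np.triu_indices(g.X.shape[0], k=1)
        keep = g.mask[iu] & g.mask[ju]
        ce += g.E[iu[keep], ju[keep]].sum(axis=0)
    cx = np.maximum(cx, 1e-8)
    ce = np.maximum(ce, 1e-8)
    return cx / cx.sum(), ce / ce.sum()


def _tensor_ce(probs, target, weight):
    """Masked cross-entropy: probs Tensor, target/weight numpy constants."""
    logp = (probs + 1e-12).log()
    w = Tensor(weight)
    total = max(float(weight.sum()), 1.0)
    return -(Tensor(target) * logp * w).sum() * (1.0 / total)


def _decay_lr(opt: Adam, base_lr: float, step: int, total: int):
    """Linear decay to 10% of the base rate over the run."""
    opt.lr = base_lr * (1.0 - 0.9 * step / max(total - 1, 1))


def _train_discrete(den: DiscreteDenoiser, graphs, labels, models, cfg,
                    steps, rng, log):
    """Shared loop for the conditional and unconditional discrete denoisers."""
    opt = Adam(den.parameters(), lr=cfg.lr)
    N = len(graphs)
    n_max = cfg.n_max
    X0 = np.stack([g.X for g in graphs])
    E0 = np.stack([g.E for g in graphs])
    mask = np.stack([g.mask for g in graphs])
    node_w = mask.astype(float)[..., None]
    iu, ju = np.triu_indices(n_max, k=1)
    pair_w = np.zeros((N, n_max, n_max, 1))
    for bidx in range(N):
        keep = mask[bidx, iu] & mask[bidx, ju]
        pair_w[bidx, iu[keep], ju[keep], 0] = 1.0
    bs = min(cfg.batch_size, N)
    for step in range(steps):
        _decay_lr(opt, cfg.lr, step, steps)
        t = int(rng.integers(1, cfg.T + 1))
        idx = rng.choice(N, size=bs, replace=False) if bs < N \
            else np.arange(N)
        noisy = [forward_sample_discrete(graphs[i], t, models.sched_d, rng)
                 for i in idx]
        conds = [ConditionEmbedding(targets=labels[i],
                                    weights=np.ones(N_PROPERTIES), t=t)
                 for i in idx]
        vecs = den.condition_vectors(noisy, t, conds)
        Xt = np.stack([g.X for g in noisy])
        Et = np.stack([g.E for g in noisy])
        _, pX, _, pE = den.forward(Xt, Et, mask[idx], vecs)
        loss = _tensor_ce(pX, X0[idx], node_w[idx]) \
            + cfg.lambda_E * _tensor_ce(pE, E0[idx], pair_w[idx])
        if not np.isfinite(loss.data):
            raise RuntimeError(f"discrete training diverged at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        log.append(float(loss.data))


def _train_continuous(cont: ContinuousDenoiser, mols, models, cfg, rng, log):
    with_coords = [m for m in mols if m.coords is not None]
    if not with_coords:
        return
    opt = Adam(cont.parameters(), lr=cfg.lr)
    onehots = []
    coords0 = []
    for m in with_coords:
        g = encode_graph(m, models.alphabet, cfg.n_max)
        onehots.append(g.X[g.mask])
        coords0.append(remove_com(m.coords))
    for step in range(cfg.steps_continuous):
        _decay_lr(opt, cfg.lr, step, cfg.steps_continuous)
        t = int(rng.integers(1, cfg.T + 1))
        k = int(rng.integers(len(with_coords)))
        x_t, eps = forward_sample_coords(coords0[k], t, models.sched_c, rng,
                                         return_noise=True)
        eps_hat = cont.forward(x_t, onehots[k], t, pharm=0.5)
        diff = eps_hat - Tensor(eps)
        loss = (diff * diff).mean()
        if not np.isfinite(loss.data):
            raise RuntimeError(f"continuous training diverged at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        log.append(float(loss.data))


def _train_regressor(reg: GuidanceRegressor, graphs, labels, models, cfg,
                     rng, log):
    opt = Adam(reg.parameters(), lr=cfg.lr)
    N = len(graphs)
    mask = np.stack([g.mask for g in graphs])
    labels = np.stack(labels)
    bs = min(cfg.batch_size, N)
    for step in range(cfg.steps_regressor):
        _decay_lr(opt, cfg.lr, step, cfg.steps_regressor)
        t = int(rng.integers(1, cfg.T + 1))
        idx = rng.choice(N, size=bs, replace=False) if bs < N \
            else np.arange(N)
        noisy = [forward_sample_discrete(graphs[i], t, models.sched_d, rng)
                 for i in idx]
        Xt = np.stack([g.X for g in noisy])
        Et = np.stack([g.E for g in noisy])
        phi = reg.forward(Tensor(Xt), Tensor(Et), mask[idx], t)
        diff = phi - Tensor(labels[idx])
        loss = (diff * diff).mean()
        if not np.isfinite(loss.data):
            raise RuntimeError(f"regressor training diverged at step {step}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        log.append(float(loss.data))


def train(molecules: list[Molecule], config: TrainConfig | None = None,
          hypothesis: PharmacophoreHypothesis | None = None,
          toxmodel: ToxicityModel | None = None,
          alphabet: AtomAlphabet = QM9_ALPHABET,
          train_continuous: bool = True) -> DiffMCGenModels:
    """Train conditional + unconditional denoisers and the guidance regressor.

    Property labels for conditioning are computed with the constraint scorers;
    unavailable scorers (no hypothesis / toxicity model) default to 0.5.
    """
    if not molecules:
        raise ValueError("empty training set")
    cfg = config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    graphs = [encode_graph(m, alphabet, cfg.n_max) for m in molecules]
    m_X, m_E = _marginals(graphs, alphabet)
    models = _build_models(alphabet, cfg, m_X, m_E)
    counts = np.array([g.n for g in graphs])
    hist = np.bincount(counts, minlength=cfg.n_max + 1).astype(float)
    models.n_hist = hist / hist.sum()

    labels = []
    for m in molecules:
        pv = property_vector(m, hypothesis, toxmodel)
        arr = pv.as_array()
        arr[np.isnan(arr)] = 0.5
        labels.append(arr)

    hist_c, hist_u, hist_r, hist_x = [], [], [], []
    _train_discrete(models.cond, graphs, labels, models, cfg,
                    cfg.steps_discrete, rng, hist_c)
    _train_discrete(models.uncond, graphs, labels, models, cfg,
                    cfg.steps_uncond, rng, hist_u)
    if train_continuous:
        _train_continuous(models.cont, molecules, models, cfg, rng, hist_x)
    _train_regressor(models.regressor, graphs, labels, models, cfg, rng, hist_r)
    models.history = {"cond": hist_c, "uncond": hist_u,
                      "continuous": hist_x, "regressor": hist_r}
    return models


# ---------------------------------------------------------------------------
# guided sampling
# ---------------------------------------------------------------------------

def _sample_onehot(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    flat = probs.reshape(-1, probs.shape[-1])
    cum = np.cumsum(flat, axis=1)
    u = rng.random(flat.shape[0])[:, None] * cum[:, -1:]
    idx = (u > cum).sum(axis=1)
    out = np.zeros_like(flat)
    out[np.arange(flat.shape[0]), idx] = 1.0
    return out.reshape(probs.shape)


# Internal gain of the exponential tilt. The first-order per-entry property
# sensitivities are diluted by the pooled featurization (one entry moves a
# graph-level property estimate by O(1/graph size)), so guidance strengths of
# order 1 are mapped onto the regime where single-entry tilts are
# exp(O(0.1))-sized: strong enough to steer, weak enough not to override the
# denoiser's posterior.
GUIDANCE_GAIN = 10.0


def _modulate(post: np.ndarray, phi: np.ndarray, sens: np.ndarray,
              current: np.ndarray, cfg: GuidanceConfig,
              weights: np.ndarray) -> np.ndarray:
    """Exponential tilting of a categorical posterior.

    post: (..., k) posterior; phi: (P, B) property predictions broadcast to
    post's batch; sens: (P, ..., k) per-category sensitivity; current:
    (..., k) current (soft) state. First-order estimate of the property if
    the entry were flipped to category c:
    phi_c = phi + sens[c] - sum_c' current[c'] sens[c'].
    """
    base = (sens * current[None]).sum(axis=-1, keepdims=True)   # (P, ..., 1)
    cand = phi[..., None] + sens - base                         # (P, ..., k)
    penalty = np.abs(cand - cfg.targets.reshape((-1,) + (1,) * (cand.ndim - 1)))
    wshape = (N_PROPERTIES,) + weights.shape[1:] + (1,) * (cand.ndim - weights.ndim)
    tilt = np.exp(-cfg.lam * GUIDANCE_GAIN
                  * (weights.reshape(wshape) * penalty).sum(axis=0))
    out = post * tilt
    z = out.sum(axis=-1, keepdims=True)
    if np.any(~np.isfinite(z)) or np.any(z <= 0):
        raise FloatingPointError("guidance modulation produced invalid weights")
    return out / z


def guided_step(X: np.ndarray, E: np.ndarray, mask: np.ndarray,
                coords: np.ndarray | None, t: int, models: DiffMCGenModels,
                cfg: GuidanceConfig, rng: np.random.Generator,
                weights: np.ndarray | None = None):
    """One reverse step for a batch of graphs. Returns (X, E, coords, weights).

    Uses the unconditional model on every cfg.period-th step, the conditional
    model otherwise; with cfg.lam > 0 the categorical posteriors are tilted by
    the guidance regressor's first-order sensitivities.
    """
    B, n_max, a = X.shape
    b = E.shape[-1]
    # unconditional model every period-th step (period=1: fully unconditional)
    use_uncond = (t % cfg.period == 0)
    den = models.uncond if use_uncond else models.cond

    graphs = [EncodedGraph(X[i], E[i], mask[i]) for i in range(B)]
    conds = [ConditionEmbedding(targets=cfg.targets,
                                weights=(weights[i] if weights is not None
                                         else cfg.weights), t=t)
             for i in range(B)]
    vecs = den.condition_vectors(graphs, t, conds)
    with no_grad():
        _, pX0, _, pE0 = den.forward(X, E, mask, vecs)

    # masked rows are all-zero one-hots; give them a dummy category so the
    # posterior normalizer stays positive (they are re-masked after sampling)
    X_safe = X.copy()
    X_safe[~mask] = np.eye(a)[0]
    E_safe = E.copy()
    pair_ok = mask[:, :, None] & mask[:, None, :]
    E_safe[~pair_ok] = np.eye(b)[0]
    post_X = discrete_posterior(X_safe, pX0.data, t, models.sched_d.Q_X,
                                models.sched_d.Qbar_X)
    iu, ju = np.triu_indices(n_max, k=1)
    post_E = discrete_posterior(E_safe[:, iu, ju], pE0.data[:, iu, ju], t,
                                models.sched_d.Q_E, models.sched_d.Qbar_E)

    new_weights = weights
    if cfg.lam > 0:
        # evaluate the regressor at the denoiser's predicted clean graph,
        # where it is calibrated, rather than at the off-manifold noisy state
        phi, gx, _ = models.regressor.sensitivities(pX0.data, pE0.data,
                                                    mask, t)
        # modulate node categories only: edge tilts disrupt the valence
        # patterns the denoiser has learned, costing validity; the denoiser
        # re-adapts the bonds to the steered atom composition on its own
        post_X = _modulate(post_X, phi.T[:, :, None], gx, pX0.data, cfg,
                           _w(weights, cfg, B))
        if cfg.weight_rule == "adaptive":
            gap = np.abs(phi - cfg.targets[None, :]) + 1e-8
            new_weights = gap / gap.sum(axis=1, keepdims=True) * N_PROPERTIES

    Xn = _sample_onehot(post_X, rng) * mask[..., None]
    Eu = _sample_onehot(post_E, rng)
    En = np.zeros_like(E)
    En[:, iu, ju] = Eu
    En[:, ju, iu] = Eu
    pair = mask[:, :, None] & mask[:, None, :]
    En *= pair[..., None]
    for i in range(B):
        d = np.where(mask[i])[0]
        En[i, d, d] = 0.0
        En[i, d, d, 0] = 1.0

    new_coords = coords
    if coords is not None:
        new_coords = coords.copy()
        for i in range(B):
            sel = mask[i]
            eps_hat = models.cont.predict_coord_noise(
                coords[i, sel], Xn[i, sel], t, pharm=float(cfg.targets[0]))
            new_coords[i, sel] = reverse_step_coords(
                coords[i, sel], eps_hat, t, models.sched_c, rng=rng)
    return Xn, En, new_coords, new_weights


def _w(weights, cfg: GuidanceConfig, B: int) -> np.ndarray:
    if weights is None:
        return np.broadcast_to(cfg.weights[:, None], (N_PROPERTIES, B)).copy()
    return weights.T.copy()


def generate(n_samples: int, models: DiffMCGenModels,
             cfg: GuidanceConfig | None = None, with_coords: bool = False,
             return_info: bool = False,
             geometry_bond_fill: bool = True):
    """Generate molecules by guided reverse diffusion.

    Node counts are drawn from the training histogram; g_T from the
    stationary marginals (and an isotropic zero-CoM Gaussian for
    coordinates). Invalid molecules are returned, never dropped.

    Bond precedence at decode: the discrete edge state wins; when coordinates
    are present, pairs the discrete chain left unbonded but whose distance is
    well inside the covalent cutoff are filled with single bonds and flagged
    in the info record.
    """
    cfg = cfg or GuidanceConfig()
    rng = np.random.default_rng(cfg.seed)
    alphabet = models.alphabet
    n_max = models.config.n_max
    a, b = alphabet.n_atom_types, alphabet.n_bond_types
    T = models.config.T

    counts = rng.choice(len(models.n_hist), size=n_samples, p=models.n_hist)
    counts = np.maximum(counts, 1)
    mask = np.zeros((n_samples, n_max), dtype=bool)
    for i, c in enumerate(counts):
        mask[i, :c] = True

    X = _sample_onehot(np.broadcast_to(models.m_X, (n_samples, n_max, a)).copy(),
                       rng) * mask[..., None]
    iu, ju = np.triu_indices(n_max, k=1)
    Eu = _sample_onehot(
        np.broadcast_to(models.m_E, (n_samples, iu.size, b)).copy(), rng)
    E = np.zeros((n_samples, n_max, n_max, b))
    E[:, iu, ju] = Eu
    E[:, ju, iu] = Eu
    pair = mask[:, :, None] & mask[:, None, :]
    E *= pair[..., None]
    for i in range(n_samples):
        d = np.where(mask[i])[0]
        E[i, d, d] = 0.0
        E[i, d, d, 0] = 1.0

    coords = None
    if with_coords:
        coords = np.zeros((n_samples, n_max, 3))
        for i in range(n_samples):
            coords[i, mask[i]] = zero_com_noise((int(counts[i]), 3), rng)

    weights = None
    for t in range(T, 0, -1):
        X, E, coords, weights = guided_step(X, E, mask, coords, t, models,
                                            cfg, rng, weights)

    mols: list[Molecule] = []
    infos: list[dict] = []
    for i in range(n_samples):
        g = EncodedGraph(X[i], E[i], mask[i],
                         coords[i] if coords is not None else None)
        m = decode_graph(g, alphabet, mol_id=f"sample_{i}")
        info = {"id": m.id, "geometry_filled_bonds": []}
        if with_coords and geometry_bond_fill and m.n_atoms >= 2:
            geo = infer_bonds_from_distances(m.coords, m.atoms, tau=0.25)
            existing = {(x, y) for x, y, _ in m.bonds}
            for x, y, order in geo:
                if (x, y) not in existing:
                    m.bonds.add((x, y, "single"))
                    info["geometry_filled_bonds"].append((x, y))
        mols.append(m)
        infos.append(info)
    return (mols, infos) if return_info else mols
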