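"""Shared fixtures: synthetic molecule sets and trained model bundles.

The two training runs (the 20-molecule overfit study and the 160-molecule
guidance study) are session-scoped because several tests interrogate the same
trained models; they take a few minutes each on one CPU.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from diffmcgen.chem_io import QM9_ALPHABET, encode_graph
from diffmcgen.denoiser_continuous import ContinuousDenoiser
from diffmcgen.diffusion_continuous import (build_continuous_schedule,
                                            forward_sample_coords, remove_com)
from diffmcgen.fixtures import FixtureSpec, generate_fixture_dataset
from diffmcgen.nn import Adam, Tensor
from diffmcgen.sampling import TrainConfig, train

FIXTURE_SEED = 11
T_STUDY = 100
N_MAX_STUDY = 10


@pytest.fixture(scope="session")
def fixture20():
    """The 20-molecule conformer-bearing set used for the overfit study."""
    return generate_fixture_dataset(
        FixtureSpec(n_molecules=20, max_heavy_atoms=7, seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def fixture160():
    """The larger 2D set used for the guidance study."""
    return generate_fixture_dataset(
        FixtureSpec(n_molecules=160, max_heavy_atoms=7, seed=FIXTURE_SEED,
                    with_conformers=False))


@pytest.fixture(scope="session")
def overfit_models(fixture20):
    """Conditional + unconditional denoisers and regressor overfit on the
    20-molecule fixture."""
    cfg = TrainConfig(T=T_STUDY, n_max=N_MAX_STUDY, steps_discrete=3000,
                      steps_uncond=2500, steps_continuous=0,
                      steps_regressor=1500, seed=0, lr=2e-3)
    return train(fixture20.molecules, cfg)


@pytest.fixture(scope="session")
def guidance_models(fixture160):
    """Models for the guidance-monotonicity study (minibatch training)."""
    cfg = TrainConfig(T=T_STUDY, n_max=N_MAX_STUDY, steps_discrete=3000,
                      steps_uncond=1500, steps_continuous=0,
                      steps_regressor=3000, seed=0, lr=2e-3, batch_size=32)
    return train(fixture160.molecules, cfg)


@pytest.fixture(scope="session")
def overfit_conformer(fixture20):
    """(molecule, node one-hots, centered coords) of the largest fixture
    molecule, the overfit target for coordinate recovery."""
    m = max(fixture20.molecules, key=lambda x: x.n_atoms)
    g = encode_graph(m, QM9_ALPHABET, N_MAX_STUDY)
    return m, g.X[g.mask], remove_com(m.coords)


@pytest.fixture(scope="session")
def cont_overfit(overfit_conformer):
    """Continuous denoiser overfit on a single conformer (10k steps)."""
    _, onehot, x0 = overfit_conformer
    sched = build_continuous_schedule(T_STUDY)
    den = ContinuousDenoiser(QM9_ALPHABET.n_atom_types, T=T_STUDY, seed=0)
    opt = Adam(den.parameters(), lr=2e-3)
    rng = np.random.default_rng(10)
    steps = 10_000
    for step in range(steps):
        opt.lr = 2e-3 * (1.0 - 0.9 * step / steps)
        t = int(rng.integers(1, T_STUDY + 1))
        x_t, eps = forward_sample_coords(x0, t, sched, rng, return_noise=True)
        diff = den.forward(x_t, onehot, t, pharm=0.5) - Tensor(eps)
        loss = (diff * diff).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
    return den, sched


@pytest.fixture(scope="session")
def single_mol_models(fixture20):
    """Unconditional denoiser overfit on one molecule (memorization oracle).

    The target is the smallest acyclic multi-element fixture molecule: its
    node identities anchor the alignment, which keeps the memorization
    check about model capacity rather than graph symmetry."""
    acyclic = [m for m in fixture20.molecules
               if len(m.bonds) == m.n_atoms - 1 and len(set(m.atoms)) > 1]
    m = min(acyclic, key=lambda x: (x.n_atoms, x.to_smiles()))
    cfg = TrainConfig(T=T_STUDY, n_max=N_MAX_STUDY, steps_discrete=100,
                      steps_uncond=5000, steps_continuous=0,
                      steps_regressor=100, seed=0, lr=2e-3)
    return train([m], cfg), m


def marginal_histograms(mols, alphabet=QM9_ALPHABET):
    """Empirical atom-type and bond-type (incl. explicit none) distributions."""
    ca, cb = Counter(), Counter()
    for m in mols:
        for a in m.atoms:
            ca[a] += 1
        cb["none"] += m.n_atoms * (m.n_atoms - 1) // 2 - len(m.bonds)
        for _, _, order in m.bonds:
            cb[order] += 1
    at = np.array([ca[s] for s in alphabet.symbols], float)
    bt = np.array([cb[s] for s in alphabet.bond_categories], float)
    return at / max(at.sum(), 1), bt / max(bt.sum(), 1)


def total_variation(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def kabsch_rmsd(x, y):
    """Best-fit (rotation-aligned) RMSD between two centered point sets."""
    H = x.T @ y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    xa = x @ R.T
    return float(np.sqrt(np.mean(np.sum((xa - y) ** 2, axis=1))))
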