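"""Deterministic synthetic molecule sets for offline training and testing.

The generator emulates the statistics of small-organic generative benchmarks:
molecules over {C, N, O, F} with a bounded heavy-atom count, valid valences,
nondegenerate atom/bond-type marginals, force-field-relaxed 3D conformers, and
per-molecule property labels. An "actives" subset shares an anilide scaffold
so pharmacophore-hypothesis construction has recurrent donor/acceptor/aromatic
features to find. The LD50 table carries a planted linear signal in three
fingerprint bits plus Gaussian noise, giving the toxicity model something
learnable with a known ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from . import constraints
from .chem_io import Molecule, check_validity, from_rdkit, parse_smiles

__all__ = ["FixtureSpec", "FixtureDataset", "generate_fixture_dataset",
           "perturb_conformer", "embed_conformer"]


@dataclass
class FixtureSpec:
    n_molecules: int = 500
    max_heavy_atoms: int = 7
    min_heavy_atoms: int = 4   # benchmark sets are dominated by larger sizes
    alphabet_symbols: tuple[str, ...] = ("C", "N", "O", "F")
    seed: int = 0
    with_conformers: bool = True
    n_actives: int = 8
    # planted LD50 rule: intercept + coeffs on the 3 most variable Morgan bits
    ld50_intercept: float = 2.5
    ld50_coeffs: tuple[float, float, float] = (0.9, -0.7, 0.5)
    ld50_noise_sd: float = 0.1


@dataclass
class FixtureDataset:
    molecules: list[Molecule]
    labels: pd.DataFrame          # columns: id, smiles, qed, sa
    ld50_table: pd.DataFrame      # columns: structure, ld50_mg_kg
    actives: list[Molecule]
    spec: FixtureSpec = field(repr=False, default=None)


_ELEMENT_WEIGHTS = {"C": 0.70, "N": 0.12, "O": 0.14, "F": 0.04}
_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1}

# substituents decorating the shared anilide scaffold of the actives subset
_ACTIVE_SCAFFOLD = "CC(=O)Nc1ccc{sub}cc1"
_ACTIVE_SUBS = ["", "(C)", "(O)", "(N)", "(F)", "(CC)", "(OC)", "(C(C)C)"]


def embed_conformer(m: Molecule, seed: int = 0,
                    optimize: bool = True) -> Molecule:
    """ETKDG embedding + UFF relaxation; heavy-atom coordinates retained."""
    rd = Chem.AddHs(m.to_rdkit(sanitize=True))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2 ** 31 - 1)
    if AllChem.EmbedMolecule(rd, params) != 0:
        raise RuntimeError(f"conformer embedding failed for {m.id!r}")
    if optimize:
        AllChem.UFFOptimizeMolecule(rd, maxIters=500)
    rd = Chem.RemoveHs(rd)
    out = from_rdkit(rd, mol_id=m.id)
    out.coords -= out.coords.mean(axis=0)
    return out


def perturb_conformer(coords: np.ndarray, magnitude: float,
                      seed: int = 0) -> np.ndarray:
    """Gaussian displacement with the given RMS magnitude (Angstrom), re-centered."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    coords = np.asarray(coords, dtype=float)
    if magnitude == 0:
        return coords.copy()
    rng = np.random.default_rng(seed)
    disp = rng.standard_normal(coords.shape)
    disp *= magnitude / np.sqrt(np.mean(disp ** 2))
    out = coords + disp
    return out - out.mean(axis=0)


def _random_molecule(rng: np.random.Generator, spec: FixtureSpec) -> Molecule | None:
    """Grow a random valence-respecting tree, optionally close one ring and
    upgrade some bonds to double."""
    n = int(rng.integers(spec.min_heavy_atoms, spec.max_heavy_atoms + 1))
    symbols = list(spec.alphabet_symbols)
    probs = np.array([_ELEMENT_WEIGHTS.get(s, 0.1) for s in symbols])
    probs /= probs.sum()
    atoms = [str(rng.choice(symbols, p=probs)) for _ in range(n)]
    free = [_VALENCE[a] for a in atoms]
    bonds: set[tuple[int, int, str]] = set()
    order_val = {"single": 1, "double": 2, "triple": 3}

    for i in range(1, n):
        parents = [j for j in range(i) if free[j] > 0]
        if not parents:
            return None
        j = int(rng.choice(parents))
        bonds.add((j, i, "single"))
        free[i] -= 1
        free[j] -= 1

    # one optional ring closure
    if n >= 3 and rng.random() < 0.35:
        cands = [(i, j) for i in range(n) for j in range(i + 2, n)
                 if free[i] > 0 and free[j] > 0
                 and not any({a, b} == {i, j} for a, b, _ in bonds)]
        if cands:
            i, j = cands[int(rng.integers(len(cands)))]
            bonds.add((i, j, "single"))
            free[i] -= 1
            free[j] -= 1

    # upgrade a few bonds to double where valence allows (keeps bond-type
    # marginals nondegenerate); sort first: set order is not reproducible
    # across processes
    up = sorted(b for b in bonds if free[b[0]] > 0 and free[b[1]] > 0)
    rng.shuffle(up)
    for i, j, order in up[: int(rng.integers(0, 3))]:
        if free[i] > 0 and free[j] > 0:
            bonds.discard((i, j, order))
            bonds.add((i, j, "double"))
            free[i] -= 1
            free[j] -= 1
    _ = order_val
    return Molecule(atoms=atoms, bonds=bonds)


def generate_fixture_dataset(spec: FixtureSpec) -> FixtureDataset:
    rng = np.random.default_rng(spec.seed)
    mols: list[Molecule] = []
    attempt = 0
    while len(mols) < spec.n_molecules and attempt < 100 * spec.n_molecules:
        attempt += 1
        m = _random_molecule(rng, spec)
        if m is None:
            continue
        ok, _ = check_validity(m)
        if not ok:
            continue
        m = parse_smiles(m.to_smiles(), mol_id=f"fix_{len(mols)}")
        if m.n_atoms > spec.max_heavy_atoms:
            continue
        if spec.with_conformers:
            try:
                m = embed_conformer(m, seed=spec.seed * 7919 + len(mols))
            except RuntimeError:
                continue
        mols.append(m)
    if len(mols) < spec.n_molecules:
        raise RuntimeError("fixture generation failed to reach requested size")

    rows = []
    for m in mols:
        rows.append({"id": m.id, "smiles": m.to_smiles(),
                     "qed": constraints.qed(m), "sa": constraints.sa_normalized(m)})
    labels = pd.DataFrame(rows)

    # actives: shared anilide scaffold with varied para substituents
    actives = []
    for k in range(spec.n_actives):
        smi = _ACTIVE_SCAFFOLD.format(sub=_ACTIVE_SUBS[k % len(_ACTIVE_SUBS)])
        a = parse_smiles(smi, mol_id=f"active_{k}")
        actives.append(embed_conformer(a, seed=spec.seed * 104729 + k))

    # LD50 table with planted linear signal in the 3 most variable bits
    smiles = [m.to_smiles() for m in mols]
    n_tab = max(len(smiles), 50)
    tab_smiles = (smiles * (n_tab // len(smiles) + 1))[:n_tab]
    fps = constraints._fp_matrix(tab_smiles, 2, 1024)
    variability = fps.var(axis=0)
    bits = np.argsort(-variability)[:3]
    c = spec.ld50_coeffs
    log_ld50 = (spec.ld50_intercept
                + c[0] * fps[:, bits[0]] + c[1] * fps[:, bits[1]]
                + c[2] * fps[:, bits[2]]
                + rng.normal(0.0, spec.ld50_noise_sd, n_tab))
    ld50_table = pd.DataFrame({"structure": tab_smiles,
                               "ld50_mg_kg": 10.0 ** log_ld50})

    return FixtureDataset(molecules=mols, labels=labels,
                          ld50_table=ld50_table, actives=actives, spec=spec)
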