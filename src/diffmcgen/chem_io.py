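"""Molecule data model, format I/O, graph encoding and validity checks.

Molecules are heavy-atom graphs (implicit hydrogens) over a small declared
element alphabet, matching the convention of small-organic generative
benchmarks (nine heavy atoms or fewer, C/N/O/F). An explicit-hydrogen mode
is available for 3D work by putting "H" in the alphabet.

All canonical-SMILES comparisons package-wide go through
:func:`canonical_smiles` so uniqueness/novelty use one dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

BOND_ORDERS = ("single", "double", "triple", "aromatic")
_RD_BOND = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}
_FROM_RD_BOND = {v: k for k, v in _RD_BOND.items()}

# Pauling electronegativities, used by the bond-order assignment heuristic.
ELECTRONEGATIVITY = {
    "H": 2.20, "B": 2.04, "C": 2.55, "N": 3.04, "O": 3.44, "F": 3.98,
    "Si": 1.90, "P": 2.19, "S": 2.58, "Cl": 3.16, "Br": 2.96, "I": 2.66,
}


class ChemIOError(ValueError):
    pass


class AlphabetError(ChemIOError):
    pass


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomAlphabet:
    """Category index conventions shared by the discrete diffusion chain.

    ``bond_categories[0]`` is always "none" (the explicit no-bond category).
    """

    symbols: tuple[str, ...]
    valences: dict[str, int]
    bond_categories: tuple[str, ...] = ("none",) + BOND_ORDERS

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise AlphabetError("duplicate element symbols")
        if self.bond_categories[0] != "none":
            raise AlphabetError('"none" must be bond category 0')
        for s in self.symbols:
            if s not in self.valences:
                raise AlphabetError(f"no valence for element {s}")

    @property
    def n_atom_types(self) -> int:
        return len(self.symbols)

    @property
    def n_bond_types(self) -> int:
        return len(self.bond_categories)

    def atom_index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise AlphabetError(f"element {symbol!r} not in alphabet {self.symbols}")

    def bond_index(self, order: str) -> int:
        return self.bond_categories.index(order)


QM9_ALPHABET = AtomAlphabet(
    symbols=("C", "N", "O", "F"),
    valences={"C": 4, "N": 3, "O": 2, "F": 1},
)


@dataclass
class Molecule:
    """A heavy-atom molecular graph with optional 3D coordinates (Angstrom)."""

    atoms: list[str]
    bonds: set[tuple[int, int, str]] = field(default_factory=set)
    charges: list[int] | None = None
    coords: np.ndarray | None = None
    id: str = ""
    # total hydrogens per atom as perceived at parse time; None lets the
    # toolkit infer implicit hydrogens from valence (the case for graphs
    # decoded from diffusion states, which carry no H information)
    h_counts: list[int] | None = None

    def __post_init__(self):
        n = len(self.atoms)
        if self.charges is None:
            self.charges = [0] * n
        if len(self.charges) != n:
            raise ChemIOError("charges length != atom count")
        norm = set()
        seen_pairs = set()
        for i, j, order in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ChemIOError(f"bad bond endpoints ({i},{j}) for {n} atoms")
            if order not in BOND_ORDERS:
                raise ChemIOError(f"unknown bond order {order!r}")
            a, b = (i, j) if i < j else (j, i)
            if (a, b) in seen_pairs:
                raise ChemIOError(f"duplicate bond on pair ({a},{b})")
            seen_pairs.add((a, b))
            norm.add((a, b, order))
        self.bonds = norm
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (n, 3):
                raise ChemIOError("coords shape must be (n_atoms, 3)")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def to_rdkit(self, sanitize: bool = True) -> Chem.Mol:
        rw = Chem.RWMol()
        for i, (sym, q) in enumerate(zip(self.atoms, self.charges)):
            a = Chem.Atom(sym)
            a.SetFormalCharge(int(q))
            if self.h_counts is not None:
                a.SetNumExplicitHs(int(self.h_counts[i]))
                a.SetNoImplicit(True)
            rw.AddAtom(a)
        aromatic_atoms = set()
        for i, j, order in sorted(self.bonds):
            rw.AddBond(int(i), int(j), _RD_BOND[order])
            if order == "aromatic":
                aromatic_atoms.update((i, j))
        for idx in aromatic_atoms:
            rw.GetAtomWithIdx(int(idx)).SetIsAromatic(True)
        for i, j, order in self.bonds:
            if order == "aromatic":
                rw.GetBondBetweenAtoms(int(i), int(j)).SetIsAromatic(True)
        mol = rw.GetMol()
        if sanitize:
            Chem.SanitizeMol(mol)
        if self.coords is not None:
            conf = Chem.Conformer(self.n_atoms)
            for k, xyz in enumerate(self.coords):
                conf.SetAtomPosition(k, tuple(float(v) for v in xyz))
            mol.AddConformer(conf, assignId=True)
        return mol

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


def from_rdkit(mol: Chem.Mol, mol_id: str = "", keep_coords: bool = True) -> Molecule:
    atoms = [a.GetSymbol() for a in mol.GetAtoms()]
    charges = [a.GetFormalCharge() for a in mol.GetAtoms()]
    bonds = set()
    for b in mol.GetBonds():
        order = "aromatic" if b.GetIsAromatic() else _FROM_RD_BOND.get(b.GetBondType())
        if order is None:
            raise ChemIOError(f"unsupported bond type {b.GetBondType()}")
        bonds.add((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    coords = None
    if keep_coords and mol.GetNumConformers() > 0:
        coords = np.array(mol.GetConformer().GetPositions(), dtype=float)
    h_counts = [a.GetTotalNumHs() for a in mol.GetAtoms()]
    return Molecule(atoms=atoms, bonds=bonds, charges=charges, coords=coords,
                    id=mol_id, h_counts=h_counts)


def parse_smiles(s: str, mol_id: str = "") -> Molecule:
    """Parse a SMILES string into a sanitized, canonically ordered Molecule."""
    if not s or not s.strip():
        raise ChemIOError("empty SMILES string")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ChemIOError(f"unparsable SMILES: {s!r}")
    order = tuple(Chem.CanonicalRankAtoms(mol, breakTies=True))
    inv = [0] * len(order)
    for src, dst in enumerate(order):
        inv[dst] = src
    mol = Chem.RenumberAtoms(mol, inv)
    return from_rdkit(mol, mol_id=mol_id or s)


def canonical_smiles(x: "Molecule | str") -> str:
    """The one canonical SMILES dialect used repo-wide for identity."""
    if isinstance(x, Molecule):
        return x.to_smiles()
    mol = Chem.MolFromSmiles(x)
    if mol is None:
        raise ChemIOError(f"unparsable SMILES: {x!r}")
    return Chem.MolToSmiles(mol)


def check_validity(m: Molecule) -> tuple[bool, str]:
    """True iff the molecule sanitizes under standard valence rules."""
    try:
        m.to_rdkit(sanitize=True)
        return True, ""
    except Exception as e:  # rdkit raises several exception types
        return False, f"{type(e).__name__}: {e}"


# ---------------------------------------------------------------------------
# one-hot graph encoding
# ---------------------------------------------------------------------------

@dataclass
class EncodedGraph:
    """One-hot diffusion state: node tensor X, edge tensor E, padding mask."""

    X: np.ndarray            # (n_max, a)
    E: np.ndarray            # (n_max, n_max, b); channel 0 = "none"
    mask: np.ndarray         # (n_max,) bool
    coords: np.ndarray | None = None   # (n_max, 3)

    @property
    def n(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "EncodedGraph":
        return EncodedGraph(self.X.copy(), self.E.copy(), self.mask.copy(),
                            None if self.coords is None else self.coords.copy())


def encode_graph(m: Molecule, alphabet: AtomAlphabet = QM9_ALPHABET,
                 n_max: int = 16) -> EncodedGraph:
    n = m.n_atoms
    if n > n_max:
        raise ChemIOError(f"molecule has {n} atoms > n_max={n_max}")
    a, b = alphabet.n_atom_types, alphabet.n_bond_types
    X = np.zeros((n_max, a))
    E = np.zeros((n_max, n_max, b))
    mask = np.zeros(n_max, dtype=bool)
    mask[:n] = True
    for i, sym in enumerate(m.atoms):
        X[i, alphabet.atom_index(sym)] = 1.0
    E[:n, :n, 0] = 1.0
    for i, j, order in m.bonds:
        k = alphabet.bond_index(order)
        E[i, j] = 0.0
        E[j, i] = 0.0
        E[i, j, k] = 1.0
        E[j, i, k] = 1.0
    coords = None
    if m.coords is not None:
        coords = np.zeros((n_max, 3))
        coords[:n] = m.coords - m.coords.mean(axis=0)
    return EncodedGraph(X=X, E=E, mask=mask, coords=coords)


def decode_graph(g: EncodedGraph, alphabet: AtomAlphabet = QM9_ALPHABET,
                 mol_id: str = "") -> Molecule:
    """Argmax decode. Invalid chemistry is *not* fixed here; see check_validity."""
    idx = np.where(g.mask)[0]
    atoms = [alphabet.symbols[int(np.argmax(g.X[i]))] for i in idx]
    pos = {int(orig): new for new, orig in enumerate(idx)}
    bonds = set()
    for ii in idx:
        for jj in idx:
            if ii >= jj:
                continue
            k = int(np.argmax(g.E[ii, jj]))
            if k != 0:
                bonds.add((pos[int(ii)], pos[int(jj)], alphabet.bond_categories[k]))
    coords = None
    if g.coords is not None:
        coords = np.asarray(g.coords)[idx]
    return Molecule(atoms=atoms, bonds=bonds, coords=coords, id=mol_id)


# ---------------------------------------------------------------------------
# distance -> bond inference
# ---------------------------------------------------------------------------

def _covalent_radii() -> dict[str, float]:
    table = {}
    text = resources.files("diffmcgen.data").joinpath("covalent_radii.csv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        el, r = line.split(",")
        table[el] = float(r)
    return table


COVALENT_RADII = _covalent_radii()


def infer_bonds_from_distances(coords: np.ndarray, atoms: Sequence[str],
                               tau: float = 0.4,
                               valences: dict[str, int] | None = None
                               ) -> set[tuple[int, int, str]]:
    """Bond a pair iff its distance <= r_cov(i) + r_cov(j) + tau.

    Bond orders are then assigned by greedy valence completion: every inferred
    bond starts single; pairs are upgraded (single -> double -> triple) while
    both endpoints have free valence AND the distance is short enough to
    support the higher order (double: < r_sum - 0.10 A; triple:
    < r_sum - 0.22 A, reflecting typical bond-length contractions). Pairs are
    visited by decreasing summed Pauling electronegativity, ties broken by
    atom index.
    """
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ChemIOError("non-finite coordinates")
    n = len(atoms)
    if coords.shape != (n, 3):
        raise ChemIOError("coords shape must be (n_atoms, 3)")
    if valences is None:
        defaults = {"H": 1, "C": 4, "N": 3, "O": 2, "F": 1, "P": 5, "S": 6,
                    "Cl": 1, "Br": 1, "I": 1}
        valences = {s: defaults.get(s, 4) for s in set(atoms)}

    pairs = []
    dists = {}
    r_sums = {}
    for i in range(n):
        for j in range(i + 1, n):
            r_sum = COVALENT_RADII[atoms[i]] + COVALENT_RADII[atoms[j]]
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= r_sum + tau:
                pairs.append((i, j))
                dists[(i, j)] = d
                r_sums[(i, j)] = r_sum

    order = {p: 1 for p in pairs}
    free = {i: valences.get(atoms[i], 4) for i in range(n)}
    for i, j in pairs:
        free[i] -= 1
        free[j] -= 1
    ranked = sorted(
        pairs,
        key=lambda p: (-(ELECTRONEGATIVITY.get(atoms[p[0]], 2.5)
                         + ELECTRONEGATIVITY.get(atoms[p[1]], 2.5)), p[0], p[1]),
    )
    contraction = {2: 0.10, 3: 0.22}   # min shortening vs single-bond length
    for target in (2, 3):
        for i, j in ranked:
            if (order[(i, j)] == target - 1 and free[i] > 0 and free[j] > 0
                    and dists[(i, j)] < r_sums[(i, j)] - contraction[target]):
                order[(i, j)] = target
                free[i] -= 1
                free[j] -= 1

    names = {1: "single", 2: "double", 3: "triple"}
    return {(i, j, names[order[(i, j)]]) for i, j in pairs}


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_sdf(path) -> list[Molecule]:
    """Read a V2000 SDF. Malformed records are skipped with an indexed warning."""
    mols: list[Molecule] = []
    with open(path) as fh:
        if not fh.read().strip():
            return mols
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for idx, mol in enumerate(supplier):
        if mol is None:
            warnings.warn(f"SDF record {idx} in {path} is malformed; skipped")
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol_{idx}"
        mols.append(from_rdkit(mol, mol_id=name))
    return mols


def write_sdf(mols: Iterable[Molecule], path) -> None:
    writer = Chem.SDWriter(str(path))
    try:
        for m in mols:
            rd = m.to_rdkit(sanitize=True)
            rd.SetProp("_Name", m.id or "")
            if m.coords is None:
                conf = Chem.Conformer(rd.GetNumAtoms())
                rd.AddConformer(conf, assignId=True)
            writer.write(rd)
    finally:
        writer.close()


def read_xyz(path) -> list[Molecule]:
    """Multi-record XYZ: atoms + coordinates only (no bonds)."""
    mols = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    rec = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
            comment = lines[pos + 1] if pos + 1 < len(lines) else ""
            atoms, coords = [], []
            for ln in lines[pos + 2: pos + 2 + n]:
                parts = ln.split()
                atoms.append(parts[0])
                coords.append([float(v) for v in parts[1:4]])
            if len(atoms) != n:
                raise ChemIOError("truncated record")
            mols.append(Molecule(atoms=atoms, coords=np.array(coords),
                                 id=comment.strip() or f"xyz_{rec}"))
        except (ValueError, IndexError, ChemIOError):
            warnings.warn(f"XYZ record {rec} in {path} is malformed; skipped")
            n = 0
        pos += 2 + n if n else 1
        rec += 1
    return mols


def write_xyz(mols: Iterable[Molecule], path) -> None:
    with open(path, "w") as fh:
        for m in mols:
            if m.coords is None:
                raise ChemIOError(f"molecule {m.id!r} has no coordinates")
            fh.write(f"{m.n_atoms}\n{m.id}\n")
            for sym, (x, y, z) in zip(m.atoms, m.coords):
                fh.write(f"{sym} {x:.4f} {y:.4f} {z:.4f}\n")


def read_smiles_file(path) -> list[Molecule]:
    """One SMILES per line, optional tab-separated id."""
    mols = []
    with open(path) as fh:
        for idx, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            smi = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"smi_{idx}"
            try:
                mols.append(parse_smiles(smi, mol_id=mol_id))
            except ChemIOError:
                warnings.warn(f"SMILES line {idx} in {path} is malformed; skipped")
    return mols


def write_smiles_file(mols: Iterable[Molecule], path) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.to_smiles()}\t{m.id}\n")


# ---------------------------------------------------------------------------
# global graph features y
# ---------------------------------------------------------------------------

GLOBAL_FEATURE_K_EIGS = 5
_ATOMIC_WEIGHTS = {"H": 1.008, "B": 10.81, "C": 12.011, "N": 14.007,
                   "O": 15.999, "F": 18.998, "P": 30.974, "S": 32.06,
                   "Cl": 35.45, "Br": 79.904, "I": 126.904}
_CHARGE_BINS = (-1, 0, 1)
_VALENCE_BINS = tuple(range(7))   # 0..6
_BOND_VALENCE = {"single": 1.0, "double": 2.0, "triple": 3.0, "aromatic": 1.5}


def global_feature_length(alphabet: AtomAlphabet = QM9_ALPHABET) -> int:
    return 4 + GLOBAL_FEATURE_K_EIGS + 1 + len(_CHARGE_BINS) + len(_VALENCE_BINS) + 1


def compute_global_features(g: EncodedGraph,
                            alphabet: AtomAlphabet = QM9_ALPHABET) -> np.ndarray:
    """Fixed-length structural + molecular feature vector y.

    Layout: [cycle counts len 3..6 | k smallest nonzero Laplacian eigenvalues
    (zero-padded) | #connected components | formal-charge histogram (-1,0,+1)
    | valence histogram 0..6 | molecular weight / 100].
    Permutation-invariant by construction.
    """
    m = decode_graph(g, alphabet)
    G = nx.Graph()
    G.add_nodes_from(range(m.n_atoms))
    G.add_edges_from((i, j) for i, j, _ in m.bonds)

    cycles = [0.0] * 4  # lengths 3,4,5,6
    for cyc in nx.simple_cycles(G, length_bound=6):
        if 3 <= len(cyc) <= 6:
            cycles[len(cyc) - 3] += 1.0

    n_comp = float(nx.number_connected_components(G)) if m.n_atoms else 0.0
    eigs = np.zeros(GLOBAL_FEATURE_K_EIGS)
    if m.n_atoms >= 2:
        lap = nx.laplacian_matrix(G).toarray().astype(float)
        vals = np.sort(np.linalg.eigvalsh(lap))
        nonzero = vals[vals > 1e-9]
        k = min(GLOBAL_FEATURE_K_EIGS, nonzero.size)
        eigs[:k] = nonzero[:k]

    charge_hist = np.zeros(len(_CHARGE_BINS))
    for q in m.charges:
        qi = int(np.clip(q, _CHARGE_BINS[0], _CHARGE_BINS[-1])) - _CHARGE_BINS[0]
        charge_hist[qi] += 1.0

    valence = np.zeros(m.n_atoms)
    for i, j, order in m.bonds:
        valence[i] += _BOND_VALENCE[order]
        valence[j] += _BOND_VALENCE[order]
    val_hist = np.zeros(len(_VALENCE_BINS))
    for v in valence:
        val_hist[int(np.clip(round(v), 0, _VALENCE_BINS[-1]))] += 1.0

    # heavy-atom weight sum: cheap, defined for invalid intermediate graphs too
    mw = sum(_ATOMIC_WEIGHTS.get(s, 12.0) for s in m.atoms)

    return np.concatenate([cycles, eigs, [n_comp], charge_hist, val_hist, [mw / 100.0]])
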