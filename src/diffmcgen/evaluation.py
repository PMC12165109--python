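"""Generative-model evaluation metrics.

Validity, uniqueness, novelty, internal diversity, a descriptor-based Fréchet
distributional distance (with a pluggable embedding hook for learned
embeddings), the QED/SA success rate, and the force-field energy ratio.

Denominator conventions follow the common benchmark practice: uniqueness is
computed over valid molecules, novelty over valid unique molecules. Identity
is canonical SMILES via :func:`diffmcgen.chem_io.canonical_smiles`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, rdMolDescriptors
from rdkit.DataStructs import TanimotoSimilarity
from scipy import linalg

from . import constraints
from .chem_io import Molecule, canonical_smiles, check_validity

__all__ = ["EvalReport", "validity", "uniqueness", "novelty", "intdiv",
           "fcd_proxy", "success_rate", "energy_ratio", "evaluate"]

FP_RADIUS = 2
FP_BITS = 2048
SUCCESS_QED_MIN = 0.6    # success: QED >= 0.6 and normalized SA <= 0.4
SUCCESS_SA_MAX = 0.4
ENERGY_N_CONF = 50
ENERGY_FACTOR = 7.0


class MetricError(ValueError):
    pass


@dataclass
class EvalReport:
    validity: float
    uniqueness: float
    novelty: float
    intdiv: float
    fcd: float
    success_rate: float
    energy_ratio: float
    n_generated: int
    n_valid: int

    def to_dict(self) -> dict:
        return asdict(self)

    def table(self) -> str:
        head = ["Validity", "IntDiv", "FCD", "Novelty", "Uniqueness",
                "Success Rate", "Energy Ratio"]
        vals = [f"{self.validity:.2f}%", f"{self.intdiv:.2f}",
                f"{self.fcd:.3f}", f"{self.novelty:.2f}%",
                f"{self.uniqueness:.2f}%", f"{self.success_rate:.2f}%",
                f"{self.energy_ratio:.2f}%"]
        w = [max(len(h), len(v)) for h, v in zip(head, vals)]
        line1 = "  ".join(h.ljust(k) for h, k in zip(head, w))
        line2 = "  ".join(v.ljust(k) for v, k in zip(vals, w))
        return line1 + "\n" + line2


def _valid_mols(mols: list[Molecule]) -> list[Molecule]:
    return [m for m in mols if check_validity(m)[0]]


def _canon(m: Molecule) -> str:
    return m.to_smiles()


def validity(mols: list[Molecule]) -> float:
    """Percentage of molecules that sanitize under standard valence rules."""
    if not mols:
        return 0.0
    return 100.0 * len(_valid_mols(mols)) / len(mols)


def uniqueness(mols: list[Molecule]) -> float:
    """Percentage of distinct canonical SMILES among the valid molecules."""
    valid = _valid_mols(mols)
    if not valid:
        return 0.0
    return 100.0 * len({_canon(m) for m in valid}) / len(valid)


def novelty(mols: list[Molecule], training_smiles: set[str] | list[str]) -> float:
    """Percentage of valid unique molecules absent from the training set."""
    train = {canonical_smiles(s) for s in training_smiles}
    uniq = {_canon(m) for m in _valid_mols(mols)}
    if not uniq:
        return 0.0
    return 100.0 * len(uniq - train) / len(uniq)


def _fingerprint(m: Molecule):
    return AllChem.GetMorganFingerprintAsBitVect(
        m.to_rdkit(sanitize=True), FP_RADIUS, nBits=FP_BITS)


def intdiv(mols: list[Molecule]) -> float:
    """1 - mean pairwise Tanimoto similarity over the valid molecules."""
    valid = _valid_mols(mols)
    if len(valid) < 2:
        raise MetricError("internal diversity needs >= 2 valid molecules")
    fps = [_fingerprint(m) for m in valid]
    sims = [TanimotoSimilarity(fps[i], fps[j])
            for i in range(len(fps)) for j in range(i + 1, len(fps))]
    return 1.0 - float(np.mean(sims))


# ---------------------------------------------------------------------------
# Fréchet distributional distance (descriptor proxy, pluggable embedding)
# ---------------------------------------------------------------------------

def _descriptor_embedding(mols: list[Molecule]) -> np.ndarray:
    rows = []
    for m in mols:
        rd = m.to_rdkit(sanitize=True)
        rows.append([
            Descriptors.MolWt(rd),
            Crippen.MolLogP(rd),
            rdMolDescriptors.CalcTPSA(rd),
            rdMolDescriptors.CalcNumHBD(rd),
            rdMolDescriptors.CalcNumHBA(rd),
            rdMolDescriptors.CalcNumRotatableBonds(rd),
            rdMolDescriptors.CalcNumRings(rd),
            rdMolDescriptors.CalcFractionCSP3(rd),
            rd.GetNumAtoms(),
        ])
    return np.asarray(rows, dtype=float)


def frechet_distance(mu1, cov1, mu2, cov2, ridge: float = 1e-9) -> float:
    """d^2 = |mu1-mu2|^2 + Tr(C1 + C2 - 2 (C1 C2)^(1/2))."""
    mu1, mu2 = np.atleast_1d(mu1), np.atleast_1d(mu2)
    cov1, cov2 = np.atleast_2d(cov1), np.atleast_2d(cov2)
    diff = mu1 - mu2
    # Tr((C1 C2)^1/2) via the symmetric form sqrt(C1) C2 sqrt(C1): eigen
    # decompositions are far better behaved than sqrtm on the singular
    # covariances that small or degenerate sets produce. Evaluating both
    # orders and averaging keeps the metric exactly symmetric even when the
    # covariances are rank-deficient.
    def _chop(w):
        # sqrt has infinite slope at 0: numerically-zero eigenvalues of a
        # rank-deficient covariance must be chopped, not propagated
        tol = max(np.abs(w).max(), 1.0) * 1e-10
        w = np.clip(w, 0.0, None)
        w[w < tol] = 0.0
        return w

    def _tr_sqrt(ca, cb):
        w1, v1 = np.linalg.eigh(ca)
        if np.any(w1 < -1e-8):
            warnings.warn("covariance not PSD; ridge added")
            w1 = w1 + ridge
        s1 = (v1 * np.sqrt(_chop(w1))) @ v1.T
        m = s1 @ cb @ s1
        wm = np.linalg.eigvalsh((m + m.T) / 2.0)
        return float(np.sqrt(_chop(wm)).sum())

    tr_covmean = 0.5 * (_tr_sqrt(cov1, cov2) + _tr_sqrt(cov2, cov1))
    d2 = float(diff @ diff + np.trace(cov1) + np.trace(cov2) - 2.0 * tr_covmean)
    return max(d2, 0.0)


def fcd_proxy(gen: list[Molecule], ref: list[Molecule],
              embedding=None) -> float:
    """Fréchet distance between Gaussian fits of molecule embeddings.

    The default embedding is a standardized physicochemical descriptor
    vector; pass ``embedding`` (callable: molecules -> (n, d) array) to plug
    in a learned embedding such as ChemNet activations for true FCD.
    """
    gen_v, ref_v = _valid_mols(gen), _valid_mols(ref)
    if not gen_v or not ref_v:
        raise MetricError("both sets need at least one valid molecule")
    embed = embedding or _descriptor_embedding
    x, y = np.asarray(embed(gen_v), float), np.asarray(embed(ref_v), float)
    # standardize by the pooled statistics so the metric stays symmetric
    if embedding is None:
        pooled = np.concatenate([x, y], axis=0)
        mu, sd = pooled.mean(axis=0), pooled.std(axis=0)
        sd[sd < 1e-9] = 1.0
        x, y = (x - mu) / sd, (y - mu) / sd
    cov_x = np.cov(x, rowvar=False) if x.shape[0] > 1 else np.zeros((x.shape[1],) * 2)
    cov_y = np.cov(y, rowvar=False) if y.shape[0] > 1 else np.zeros((y.shape[1],) * 2)
    return frechet_distance(x.mean(axis=0), cov_x, y.mean(axis=0), cov_y)


def success_rate(mols: list[Molecule]) -> float:
    """Percent of valid molecules with QED >= 0.6 and normalized SA <= 0.4."""
    valid = _valid_mols(mols)
    if not valid:
        return 0.0
    n_ok = sum(1 for m in valid
               if constraints.qed(m) >= SUCCESS_QED_MIN
               and constraints.sa_normalized(m) <= SUCCESS_SA_MAX)
    return 100.0 * n_ok / len(valid)


# ---------------------------------------------------------------------------
# energy ratio
# ---------------------------------------------------------------------------

def _uff_energy(rd: Chem.Mol, conf_id: int) -> float:
    ff = AllChem.UFFGetMoleculeForceField(rd, confId=conf_id)
    return float(ff.CalcEnergy())


def _uff_minimize(rd: Chem.Mol, conf_id: int) -> float:
    ff = AllChem.UFFGetMoleculeForceField(rd, confId=conf_id)
    ff.Minimize(maxIts=500)
    return float(ff.CalcEnergy())


def energy_ratio(mols: list[Molecule], n_conf: int = ENERGY_N_CONF,
                 factor: float = ENERGY_FACTOR, seed: int = 0,
                 return_failures: bool = False):
    """Fraction of molecules whose generated-conformation energy is plausible.

    A molecule passes iff its strain energy does not exceed ``factor`` times
    the mean strain energy of ``n_conf`` freshly embedded (unconstrained)
    conformations. Strain is referenced against the molecule's own relaxed
    minimum, because raw force-field energies are signed and a raw-energy
    multiple would be ill-posed. Molecules whose embedding or force-field
    setup fails are excluded from the percentage and counted separately.
    """
    n_pass = n_eval = n_fail = 0
    for m in mols:
        if m.coords is None:
            n_fail += 1
            continue
        try:
            ok, _ = check_validity(m)
            if not ok:
                n_fail += 1
                continue
            rd = m.to_rdkit(sanitize=True)
            rd = Chem.AddHs(rd, addCoords=True)
            gen_conf = 0
            params = AllChem.ETKDGv3()
            params.randomSeed = seed % (2 ** 31 - 1)
            params.clearConfs = False
            conf_ids = list(AllChem.EmbedMultipleConfs(rd, numConfs=n_conf,
                                                       params=params))
            if not conf_ids:
                n_fail += 1
                continue
            energies = [_uff_energy(rd, c) for c in conf_ids]
            e_gen = _uff_energy(rd, gen_conf)
            # reference minimum: relax the lowest-energy embedded conformer
            best = conf_ids[int(np.argmin(energies))]
            e_min = _uff_minimize(rd, best)
            mean_strain = max(float(np.mean(energies)) - e_min, 1e-6)
            strain_gen = e_gen - e_min
            n_eval += 1
            if strain_gen <= factor * mean_strain:
                n_pass += 1
        except Exception:
            n_fail += 1
    pct = 100.0 * n_pass / n_eval if n_eval else 0.0
    return (pct, n_fail) if return_failures else pct


def evaluate(gen: list[Molecule], training_smiles: list[str] | set[str],
             with_energy: bool = False, n_conf: int = ENERGY_N_CONF,
             factor: float = ENERGY_FACTOR,
             ref: list[Molecule] | None = None) -> EvalReport:
    """Full metric report; shuffling the input changes nothing."""
    n_valid = len(_valid_mols(gen))
    try:
        idv = intdiv(gen)
    except MetricError:
        idv = float("nan")
    fcd = float("nan")
    if ref:
        try:
            fcd = fcd_proxy(gen, ref)
        except MetricError:
            pass
    er = energy_ratio(gen, n_conf=n_conf, factor=factor) if with_energy \
        else float("nan")
    return EvalReport(
        validity=validity(gen),
        uniqueness=uniqueness(gen),
        novelty=novelty(gen, training_smiles),
        intdiv=idv,
        fcd=fcd,
        success_rate=success_rate(gen),
        energy_ratio=er,
        n_generated=len(gen),
        n_valid=n_valid,
    )
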