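"""The four constrained-property scorers, each mapped to [0, 1].

Orientation is explicit and shared package-wide (:data:`FAVORABLE_HIGH`):
pharmacophore match and QED are better high; normalized SA and acute-oral
toxicity are better low.
"""

from __future__ import annotations

import itertools
import json
import math
import os
import pickle
import sys
from dataclasses import dataclass, field

import numpy as np
import yaml
from importlib import resources
from rdkit import Chem, RDConfig
from rdkit.Chem import AllChem, QED as _rdkit_qed
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold, cross_val_score

from .chem_io import Molecule, canonical_smiles, parse_smiles

__all__ = [
    "FAVORABLE_HIGH", "PropertyVector", "PharmacophoreHypothesis",
    "perceive_features", "build_pharmacophore_hypothesis", "pharmacophore_match",
    "qed", "qed_properties", "sa_raw", "sa_normalized",
    "ToxicityModel", "train_toxicity_model", "property_vector",
]

# property -> True if larger is better (used by guidance and success metrics)
FAVORABLE_HIGH = {"pharm": True, "qed": True, "sa": False, "tox": False}
PROPERTY_ORDER = ("pharm", "qed", "sa", "tox")

FEATURE_TYPES = ("donor", "acceptor", "aromatic", "hydrophobic",
                 "positive", "negative")
MEAN_BOND_LENGTH = 1.5   # Angstrom; topological-distance fallback for 2D mode


class ConstraintError(ValueError):
    pass


@dataclass
class PropertyVector:
    pharm: float
    qed: float
    sa: float
    tox: float

    def __post_init__(self):
        for name in PROPERTY_ORDER:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 or math.isnan(v)):
                raise ConstraintError(f"{name}={v} outside [0,1]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PROPERTY_ORDER])


# ---------------------------------------------------------------------------
# pharmacophore hypothesis & matching
# ---------------------------------------------------------------------------

def _smarts_families() -> dict[str, list]:
    text = resources.files("diffmcgen.data").joinpath(
        "pharmacophore_smarts.yaml").read_text()
    raw = yaml.safe_load(text)
    return {ftype: [Chem.MolFromSmarts(s) for s in pats]
            for ftype, pats in raw.items()}


_FAMILIES = None


def _families():
    global _FAMILIES
    if _FAMILIES is None:
        _FAMILIES = _smarts_families()
    return _FAMILIES


def perceive_features(m: Molecule) -> list[tuple[str, np.ndarray, tuple[int, ...]]]:
    """(type, 3D position, atom indices) per perceived feature.

    Position is the centroid of the matched atoms; molecules without
    coordinates get a zero position and matching falls back to topological
    distances between the matched atom sets.
    """
    rd = m.to_rdkit(sanitize=True)
    has3d = m.coords is not None
    feats = []
    seen: set[tuple[str, tuple[int, ...]]] = set()
    for ftype, patterns in _families().items():
        for pat in patterns:
            if pat is None:
                continue
            for match in rd.GetSubstructMatches(pat):
                key = (ftype, tuple(sorted(match)))
                if key in seen:
                    continue
                seen.add(key)
                pos = (m.coords[list(match)].mean(axis=0) if has3d
                       else np.zeros(3))
                feats.append((ftype, pos, tuple(sorted(match))))
    return feats


@dataclass
class PharmacophoreHypothesis:
    """Typed feature nodes with pairwise distances forming a complete graph."""

    types: list[str]
    positions: np.ndarray                      # (F, 3)
    distances: np.ndarray = field(default=None)  # (F, F)
    source: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.distances is None:
            d = self.positions[:, None, :] - self.positions[None, :, :]
            self.distances = np.linalg.norm(d, axis=-1)
        self.distances = np.asarray(self.distances, dtype=float)
        F = len(self.types)
        if F < 2:
            raise ConstraintError("a hypothesis needs at least 2 features")
        if self.positions.shape != (F, 3) or self.distances.shape != (F, F):
            raise ConstraintError("inconsistent hypothesis shapes")
        if not np.allclose(self.distances, self.distances.T, atol=1e-6):
            raise ConstraintError("distance matrix not symmetric")

    @property
    def n_features(self) -> int:
        return len(self.types)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"types": self.types,
                       "positions": self.positions.tolist(),
                       "distances": self.distances.tolist(),
                       "source": self.source}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PharmacophoreHypothesis":
        with open(path) as fh:
            d = json.load(fh)
        return cls(types=d["types"], positions=np.array(d["positions"]),
                   distances=np.array(d["distances"]), source=d.get("source", ""))


def _feature_distances(m: Molecule,
                       feats: list[tuple[str, np.ndarray, tuple[int, ...]]]
                       ) -> np.ndarray:
    """Pairwise feature distances; topological fallback without coordinates."""
    F = len(feats)
    D = np.zeros((F, F))
    if m.coords is not None:
        for a in range(F):
            for b in range(a + 1, F):
                D[a, b] = D[b, a] = np.linalg.norm(feats[a][1] - feats[b][1])
        return D
    import networkx as nx
    G = nx.Graph()
    G.add_nodes_from(range(m.n_atoms))
    G.add_edges_from((i, j) for i, j, _ in m.bonds)
    sp = dict(nx.all_pairs_shortest_path_length(G))
    for a in range(F):
        for b in range(a + 1, F):
            hops = min((sp[i].get(j, m.n_atoms)
                        for i in feats[a][2] for j in feats[b][2]), default=0)
            D[a, b] = D[b, a] = hops * MEAN_BOND_LENGTH
    return D


def build_pharmacophore_hypothesis(actives: list[Molecule],
                                   n_scaffold_classes: int = 1,
                                   min_fraction: float = 0.5,
                                   delta: float = 1.0) -> PharmacophoreHypothesis:
    """Hypothesis from a set of actives sharing scaffolds.

    Actives are grouped by Murcko scaffold; within the largest class the
    features of a reference active (the one with most features) that recur -
    i.e. can be matched by type with distance deviation < delta - in at least
    ``min_fraction`` of the class become hypothesis nodes, with matched
    distances averaged over the class.
    """
    if not actives:
        raise ConstraintError("no actives provided")
    with_coords = [m for m in actives if m.coords is not None]
    if not with_coords:
        raise ConstraintError("actives need 3D coordinates")

    groups: dict[str, list[Molecule]] = {}
    for m in with_coords:
        scaf = MurckoScaffold.MurckoScaffoldSmiles(
            mol=m.to_rdkit(sanitize=True), includeChirality=False)
        groups.setdefault(scaf, []).append(m)
    classes = sorted(groups.values(), key=len, reverse=True)[:max(n_scaffold_classes, 1)]
    cls = classes[0]

    feat_sets = [perceive_features(m) for m in cls]
    ref_idx = int(np.argmax([len(f) for f in feat_sets]))
    ref_feats = feat_sets[ref_idx]
    if not ref_feats:
        raise ConstraintError("no pharmacophore features found in actives")
    ref_D = _feature_distances(cls[ref_idx], ref_feats)

    F = len(ref_feats)
    counts = np.ones(F)                       # reference matches itself
    dist_sums = ref_D.copy()
    pos_sums = np.stack([f[1] for f in ref_feats])
    for k, feats in enumerate(feat_sets):
        if k == ref_idx:
            continue
        D = _feature_distances(cls[k], feats)
        assign = _best_assignment(ref_feats, ref_D, feats, D, delta)
        for a, b in assign.items():
            counts[a] += 1
            pos_sums[a] += feats[b][1]
        for a, b in assign.items():
            for a2, b2 in assign.items():
                dist_sums[a, a2] += D[b, b2]

    keep = [a for a in range(F) if counts[a] / len(cls) >= min_fraction]
    if len(keep) < 2:
        keep = list(range(min(F, 2)))         # degenerate class: keep reference
    if not keep:
        raise ConstraintError("no recurrent features")
    types = [ref_feats[a][0] for a in keep]
    positions = np.stack([pos_sums[a] / counts[a] for a in keep])
    pair_counts = np.minimum.outer(counts[keep], counts[keep])
    distances = dist_sums[np.ix_(keep, keep)] / pair_counts
    np.fill_diagonal(distances, 0.0)
    return PharmacophoreHypothesis(
        types=types, positions=positions, distances=distances,
        source=f"{len(cls)} actives, scaffold class 1/{len(classes)}")


def _best_assignment(ref_feats, ref_D, feats, D, delta):
    """Greedy same-type assignment of reference features onto `feats`,
    preferring distance-consistent placements."""
    assign: dict[int, int] = {}
    used: set[int] = set()
    for a in sorted(range(len(ref_feats))):
        cands = [b for b in range(len(feats))
                 if feats[b][0] == ref_feats[a][0] and b not in used]
        best, best_pen = None, None
        for b in cands:
            pen = sum(abs(D[b, assign[a2]] - ref_D[a, a2]) > delta
                      for a2 in assign)
            if best is None or pen < best_pen:
                best, best_pen = b, pen
        if best is not None:
            assign[a] = best
            used.add(best)
    return assign


def pharmacophore_match(m: Molecule, h: PharmacophoreHypothesis,
                        delta: float = 1.0, exact_limit: int = 6) -> float:
    """Best graph-matching score of a molecule against the hypothesis.

    Over injective (possibly partial) mappings of hypothesis features onto
    same-typed molecule features:
    score = (mapped fraction) x (fraction of mapped pairs whose distance
    deviates from the hypothesis by < delta); a single mapped feature has
    consistency 1. Exact enumeration up to ``exact_limit`` hypothesis
    features; beyond that a greedy assignment is used.
    """
    if h.n_features == 0:
        raise ConstraintError("empty hypothesis")
    feats = perceive_features(m)
    D = _feature_distances(m, feats)
    F = h.n_features

    cand = [[b for b in range(len(feats)) if feats[b][0] == h.types[a]]
            for a in range(F)]
    if all(not c for c in cand):
        return 0.0

    def score_of(assign: dict[int, int]) -> float:
        k = len(assign)
        if k == 0:
            return 0.0
        pairs = [(a1, a2) for a1, a2 in itertools.combinations(assign, 2)]
        if pairs:
            ok = sum(abs(D[assign[a1], assign[a2]] - h.distances[a1, a2]) < delta
                     for a1, a2 in pairs)
            consistency = ok / len(pairs)
        else:
            consistency = 1.0
        return (k / F) * consistency

    if F <= exact_limit:
        best = 0.0

        def rec(a: int, assign: dict[int, int], used: set[int]):
            nonlocal best
            if a == F:
                best = max(best, score_of(assign))
                return
            rec(a + 1, assign, used)          # skip feature a
            for b in cand[a]:
                if b not in used:
                    assign[a] = b
                    used.add(b)
                    rec(a + 1, assign, used)
                    del assign[a]
                    used.remove(b)

        rec(0, {}, set())
        return best

    # heuristic for large hypotheses: greedy consistent placement
    ref_feats = [(t, p, ()) for t, p in zip(h.types, h.positions)]
    assign = _best_assignment(ref_feats, h.distances, feats, D, delta)
    return score_of(assign)


# ---------------------------------------------------------------------------
# QED — own desirability math over rdkit-perceived properties
# ---------------------------------------------------------------------------

# Published asymmetric-double-sigmoid parameters (a, b, c, d, e, f, dmax)
# and weights of the eight QED properties.
_ADS_PARAMS = {
    "MW":     (2.817065973, 392.5754953, 290.7489764, 2.419764353,
               49.22325677, 65.37051707, 104.9805561),
    "ALOGP":  (3.172690585, 137.8624751, 2.534937431, 4.581497897,
               0.822739154, 0.576295591, 131.3186604),
    "HBA":    (2.948620388, 160.4605972, 3.615294657, 4.435986202,
               0.290141953, 1.300669958, 148.7763046),
    "HBD":    (1.618662227, 1010.051101, 0.985094388, 0.000000001,
               0.713820843, 0.920922555, 258.1632616),
    "PSA":    (1.876861559, 125.2232657, 62.90773554, 87.83366614,
               12.01999824, 28.51324732, 104.5686167),
    "ROTB":   (0.010000000, 272.4121427, 2.558379970, 1.565547684,
               1.271567166, 2.758063707, 105.4420403),
    "AROM":   (3.217788970, 957.7374108, 2.274627939, 0.000000001,
               1.317690384, 0.375760881, 312.3372610),
    "ALERTS": (0.010000000, 1199.094025, -0.09002883, 0.000000001,
               0.185904477, 0.875193782, 417.7253140),
}
_QED_WEIGHTS = {"MW": 0.66, "ALOGP": 0.46, "HBA": 0.05, "HBD": 0.61,
                "PSA": 0.06, "ROTB": 0.65, "AROM": 0.48, "ALERTS": 0.95}


def _ads(x: float, p: tuple) -> float:
    a, b, c, d, e, f, dmax = p
    v = a + b / (1 + math.exp(-(x - c + d / 2) / e)) \
        * (1 - 1 / (1 + math.exp(-(x - c - d / 2) / f)))
    return v / dmax


def qed_properties(m: Molecule) -> dict[str, float]:
    """The eight QED descriptors, perceived with the chemistry toolkit."""
    try:
        rd = m.to_rdkit(sanitize=True)
    except Exception as e:
        raise ConstraintError(f"cannot sanitize molecule for QED: {e}")
    props = _rdkit_qed.properties(rd)
    return {k: float(getattr(props, k)) for k in _ADS_PARAMS}


def qed(m: Molecule) -> float:
    """Weighted geometric mean of the eight desirability functions, in [0,1]."""
    props = qed_properties(m)
    wsum = sum(_QED_WEIGHTS.values())
    log_sum = sum(w * math.log(max(_ads(props[k], _ADS_PARAMS[k]), 1e-12))
                  for k, w in _QED_WEIGHTS.items())
    return float(math.exp(log_sum / wsum))


# ---------------------------------------------------------------------------
# synthetic accessibility
# ---------------------------------------------------------------------------

_sascorer = None


def _get_sascorer():
    global _sascorer
    if _sascorer is None:
        sys.path.append(os.path.join(RDConfig.RDContribDir, "SA_Score"))
        import sascorer  # fragment contributions + complexity penalty
        _sascorer = sascorer
    return _sascorer


def sa_raw(m: Molecule) -> float:
    """Ertl-Schuffenhauer synthetic-accessibility score on the 1-10 scale."""
    try:
        rd = m.to_rdkit(sanitize=True)
    except Exception as e:
        raise ConstraintError(f"cannot sanitize molecule for SA: {e}")
    return float(_get_sascorer().calculateScore(rd))


def normalize_sa(raw: float) -> float:
    return float(np.clip((raw - 1.0) / 9.0, 0.0, 1.0))


def sa_normalized(m: Molecule) -> float:
    """SA mapped to [0,1]; 0 favorable (easy to make), 1 unfavorable."""
    return normalize_sa(sa_raw(m))


# ---------------------------------------------------------------------------
# acute oral toxicity
# ---------------------------------------------------------------------------

@dataclass
class ToxicityModel:
    """Fingerprint regressor on log10(LD50); scores mapped to [0,1], 1 = toxic."""

    fp_radius: int
    fp_bits: int
    regressor: Ridge
    lo: float          # 5th pct of training predictions (most toxic end)
    hi: float          # 95th pct
    cv_r2: float

    def _fingerprint(self, m: Molecule) -> np.ndarray:
        rd = m.to_rdkit(sanitize=True)
        fp = AllChem.GetMorganFingerprintAsBitVect(rd, self.fp_radius,
                                                   nBits=self.fp_bits)
        return np.array(fp, dtype=float)

    def predict_log_ld50(self, m: Molecule) -> float:
        return float(self.regressor.predict(self._fingerprint(m)[None])[0])

    def score(self, m: Molecule) -> float:
        """Toxicity in [0,1]: low predicted LD50 (potent poison) -> 1."""
        pred = self.predict_log_ld50(m)
        if self.hi <= self.lo:
            return 0.5
        return float(np.clip((self.hi - pred) / (self.hi - self.lo), 0.0, 1.0))

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "ToxicityModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def _fp_matrix(smiles: list[str], radius: int, bits: int) -> np.ndarray:
    rows = []
    for s in smiles:
        rd = Chem.MolFromSmiles(s)
        if rd is None:
            raise ConstraintError(f"bad structure in LD50 table: {s!r}")
        rows.append(np.array(AllChem.GetMorganFingerprintAsBitVect(
            rd, radius, nBits=bits), dtype=float))
    return np.stack(rows)


def train_toxicity_model(table, fp_radius: int = 2, fp_bits: int = 1024,
                         alpha: float = 1.0, cv: int = 5,
                         seed: int = 0) -> ToxicityModel:
    """Fit a ridge regressor on Morgan fingerprints vs log10(LD50 mg/kg).

    `table` is a DataFrame-like with columns ``structure`` (SMILES) and
    ``ld50_mg_kg``. Reports 5-fold cross-validated R^2.
    """
    smiles = list(table["structure"])
    ld50 = np.asarray(table["ld50_mg_kg"], dtype=float)
    if len(smiles) < 50:
        raise ConstraintError("need >= 50 rows to train the toxicity model")
    if np.any(ld50 <= 0):
        raise ConstraintError("LD50 values must be positive")
    y = np.log10(ld50)
    if np.allclose(y, y[0]):
        raise ConstraintError("degenerate labels: all LD50 equal")
    X = _fp_matrix(smiles, fp_radius, fp_bits)
    reg = Ridge(alpha=alpha)
    kf = KFold(n_splits=cv, shuffle=True, random_state=seed)
    cv_r2 = float(np.mean(cross_val_score(reg, X, y, cv=kf, scoring="r2")))
    reg.fit(X, y)
    pred = reg.predict(X)
    lo, hi = float(np.percentile(pred, 5)), float(np.percentile(pred, 95))
    return ToxicityModel(fp_radius=fp_radius, fp_bits=fp_bits, regressor=reg,
                         lo=lo, hi=hi, cv_r2=cv_r2)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def property_vector(m: Molecule,
                    hypothesis: PharmacophoreHypothesis | None = None,
                    toxmodel: ToxicityModel | None = None) -> PropertyVector:
    """All four constrained properties; unavailable scorers yield NaN."""
    def safe(fn):
        try:
            return float(fn())
        except Exception:
            return float("nan")

    return PropertyVector(
        pharm=safe(lambda: pharmacophore_match(m, hypothesis)) if hypothesis else float("nan"),
        qed=safe(lambda: qed(m)),
        sa=safe(lambda: sa_normalized(m)),
        tox=safe(lambda: toxmodel.score(m)) if toxmodel else float("nan"),
    )
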