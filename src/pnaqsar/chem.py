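"""SMILES handling, fingerprints, PCA reduction, molecular graphs and Tanimoto similarity.

Everything downstream — curation, the multitask network, the applicability
domain — consumes the feature objects built here.  Chemistry is delegated to
RDKit; this module fixes the featurization conventions:

* canonical desalted SMILES (largest covalent fragment),
* a configurable registry of 16 boolean fingerprint families concatenated
  into one block, reduced by PCA fitted on training data only,
* molecular graphs with 30-dimensional atom rows and 75-dimensional rows per
  directed bond, and
* 2048-bit ECFP4 keys with Tanimoto similarity for the applicability domain.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Avalon import pyAvalonTools
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
from rdkit.Chem.EState.Fingerprinter import FingerprintMol as _estate_fp
from sklearn.decomposition import PCA

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

__all__ = [
    "CanonicalMolecule",
    "FeatureBlock",
    "MolGraph",
    "FeatureReducer",
    "DEFAULT_FAMILIES",
    "canonicalize_desalt",
    "fingerprint_block",
    "fit_feature_reducer",
    "smiles_to_graph",
    "ecfp4",
    "tanimoto",
    "bulk_tanimoto",
]

NODE_DIM = 30
EDGE_DIM = 75
ECFP4_NBITS = 2048


# ---------------------------------------------------------------------------
# canonicalization / desalting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalMolecule:
    """A desalted, canonicalized molecule. ``parse_ok`` is False for bad SMILES."""

    smiles: str
    parse_ok: bool

    def mol(self) -> Chem.Mol:
        if not self.parse_ok:
            raise ValueError(f"cannot build Mol from unparsable SMILES {self.smiles!r}")
        return Chem.MolFromSmiles(self.smiles)


def _fragment_key(frag: Chem.Mol) -> tuple:
    # largest fragment by heavy atoms; ties by molecular weight then SMILES
    from rdkit.Chem import Descriptors

    return (frag.GetNumHeavyAtoms(), Descriptors.MolWt(frag), Chem.MolToSmiles(frag))


def canonicalize_desalt(smiles: str) -> CanonicalMolecule:
    """Parse, keep the largest covalent fragment and return canonical SMILES.

    Unparsable input never raises: it returns ``parse_ok=False`` so bulk
    pipelines can count and log failures.
    """
    if not smiles or not smiles.strip():
        return CanonicalMolecule(smiles=smiles, parse_ok=False)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return CanonicalMolecule(smiles=smiles, parse_ok=False)
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=_fragment_key)
    return CanonicalMolecule(smiles=Chem.MolToSmiles(mol), parse_ok=True)


# ---------------------------------------------------------------------------
# fingerprint families
# ---------------------------------------------------------------------------

def _morgan(radius: int, nbits: int, features: bool = False):
    kwargs = dict(radius=radius, fpSize=nbits)
    if features:
        kwargs["atomInvariantsGenerator"] = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
    gen = rdFingerprintGenerator.GetMorganGenerator(**kwargs)

    def compute(mol):
        return np.frombuffer(
            gen.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
        ) == ord("1")

    return compute, nbits


def _rdkit_path(max_path: int, nbits: int):
    gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=max_path, fpSize=nbits)

    def compute(mol):
        return np.frombuffer(
            gen.GetFingerprint(mol).ToBitString().encode(), dtype=np.uint8
        ) == ord("1")

    return compute, nbits


def _bv_to_bool(bv) -> np.ndarray:
    return np.frombuffer(bv.ToBitString().encode(), dtype=np.uint8) == ord("1")


def _maccs(mol):
    return _bv_to_bool(MACCSkeys.GenMACCSKeys(mol))


def _estate(mol):
    counts, _ = _estate_fp(mol)
    return np.asarray(counts) > 0


def _avalon(mol):
    return _bv_to_bool(pyAvalonTools.GetAvalonFP(mol, nBits=512))


def _atom_pair(mol, _gen=rdFingerprintGenerator.GetAtomPairGenerator(fpSize=1024)):
    return _bv_to_bool(_gen.GetFingerprint(mol))


def _torsion(mol, _gen=rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=1024)):
    return _bv_to_bool(_gen.GetFingerprint(mol))


def _layered(mol):
    return _bv_to_bool(Chem.LayeredFingerprint(mol, fpSize=1024))


def _pattern(mol):
    return _bv_to_bool(Chem.PatternFingerprint(mol, fpSize=1024))


def _registry() -> dict:
    reg: dict[str, tuple] = {
        "maccs": (_maccs, 167),
        "estate": (_estate, 79),
        "avalon": (_avalon, 512),
        "atom_pair": (_atom_pair, 1024),
        "torsion": (_torsion, 1024),
        "layered": (_layered, 1024),
        "pattern": (_pattern, 1024),
    }
    for r in (1, 2, 3):
        reg[f"ecfp{2 * r}"] = _morgan(r, 1024)
        reg[f"fcfp{2 * r}"] = _morgan(r, 1024, features=True)
    for p in (5, 6, 7):
        reg[f"rdkit_path{p}"] = _rdkit_path(p, 1024)
    return reg


_FAMILY_REGISTRY = _registry()

#: the default 16-family roster spanning key-based, circular, path-based,
#: pair/torsion and substructure-pattern fingerprints
DEFAULT_FAMILIES: tuple[str, ...] = (
    "maccs",
    "estate",
    "avalon",
    "ecfp2",
    "ecfp4",
    "ecfp6",
    "fcfp2",
    "fcfp4",
    "fcfp6",
    "rdkit_path5",
    "rdkit_path6",
    "rdkit_path7",
    "atom_pair",
    "torsion",
    "layered",
    "pattern",
)


@dataclass
class FeatureBlock:
    """Concatenated boolean fingerprint vector with per-family offsets."""

    bits: np.ndarray
    family_offsets: Mapping[str, tuple[int, int]]
    reduced: np.ndarray | None = None
    explained_variance: float | None = None

    def __post_init__(self):
        total = sum(length for _, length in self.family_offsets.values())
        if total != self.bits.shape[0]:
            raise ValueError(
                f"block length {self.bits.shape[0]} != sum of family lengths {total}"
            )


def family_lengths(families: Sequence[str]) -> dict[str, int]:
    out = {}
    for name in families:
        if name not in _FAMILY_REGISTRY:
            raise KeyError(
                f"unknown fingerprint family {name!r}; known: {sorted(_FAMILY_REGISTRY)}"
            )
        out[name] = _FAMILY_REGISTRY[name][1]
    return out


def fingerprint_block(
    mol: CanonicalMolecule, families: Sequence[str] = DEFAULT_FAMILIES
) -> FeatureBlock:
    """Compute the concatenated boolean fingerprint block for one molecule."""
    if not mol.parse_ok:
        raise ValueError("fingerprint_block requires a parsable molecule")
    if not families:
        raise ValueError("families must be non-empty")
    lengths = family_lengths(families)
    rdmol = mol.mol()
    offsets: dict[str, tuple[int, int]] = {}
    parts = []
    pos = 0
    for name in families:
        fn, length = _FAMILY_REGISTRY[name]
        vec = np.asarray(fn(rdmol), dtype=bool)
        if vec.shape[0] != length:  # pragma: no cover - registry self-consistency
            raise RuntimeError(f"family {name} produced {vec.shape[0]} bits, expected {length}")
        offsets[name] = (pos, length)
        parts.append(vec)
        pos += length
    return FeatureBlock(bits=np.concatenate(parts), family_offsets=offsets)


def block_matrix(blocks: Sequence[FeatureBlock]) -> np.ndarray:
    return np.stack([b.bits for b in blocks]).astype(np.float64)


# ---------------------------------------------------------------------------
# PCA reducer
# ---------------------------------------------------------------------------

class FeatureReducer:
    """PCA projection of fingerprint blocks keeping >= ``variance_target`` variance.

    Fitted only on training blocks; applying it to the training mean returns
    the zero vector (the projection is centered).
    """

    def __init__(self, variance_target: float = 0.95):
        if not 0 < variance_target <= 1:
            raise ValueError("variance_target must be in (0, 1]")
        self.variance_target = variance_target
        self._pca: PCA | None = None

    def fit(self, blocks: Sequence[FeatureBlock]) -> "FeatureReducer":
        if len(blocks) < 2:
            raise ValueError("need at least 2 training blocks to fit the reducer")
        X = block_matrix(blocks)
        if np.allclose(X.var(axis=0), 0):
            raise ValueError("all fingerprint features are constant; nothing to reduce")
        # svd_solver='full' is required for fractional n_components (minimal
        # component count whose cumulative explained variance >= target)
        n_comp = self.variance_target if self.variance_target < 1 else min(X.shape)
        self._pca = PCA(n_components=n_comp, svd_solver="full")
        self._pca.fit(X)
        if self.variance_target >= 1:
            # full retention: keep exactly the numerical rank
            ev = self._pca.explained_variance_ratio_
            rank = int(np.sum(self._pca.explained_variance_ > 1e-10))
            self._pca.components_ = self._pca.components_[:rank]
            self._pca.explained_variance_ratio_ = ev[:rank]
            self._pca.explained_variance_ = self._pca.explained_variance_[:rank]
            self._pca.n_components_ = rank
        return self

    @property
    def n_components_(self) -> int:
        self._check_fitted()
        return int(self._pca.n_components_)

    @property
    def explained_variance_(self) -> float:
        self._check_fitted()
        return float(self._pca.explained_variance_ratio_.sum())

    def _check_fitted(self):
        if self._pca is None:
            raise RuntimeError("FeatureReducer is not fitted")

    def transform(self, blocks: Sequence[FeatureBlock]) -> np.ndarray:
        self._check_fitted()
        X = block_matrix(blocks)
        Z = self._pca.transform(X)
        for b, row in zip(blocks, Z):
            b.reduced = row
            b.explained_variance = self.explained_variance_
        return Z

    def fit_transform(self, blocks: Sequence[FeatureBlock]) -> np.ndarray:
        return self.fit(blocks).transform(blocks)


def fit_feature_reducer(
    train_blocks: Sequence[FeatureBlock], variance_target: float = 0.95
) -> FeatureReducer:
    return FeatureReducer(variance_target=variance_target).fit(train_blocks)


# ---------------------------------------------------------------------------
# molecular graphs
# ---------------------------------------------------------------------------

_ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")  # + other
_HYBRID = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)  # + other
_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)
_BOND_STEREO = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOCIS,
    Chem.BondStereo.STEREOTRANS,
    Chem.BondStereo.STEREOANY,
)


def _one_hot(value, choices, with_other: bool = True) -> list[float]:
    vec = [1.0 if value == c else 0.0 for c in choices]
    if with_other:
        vec.append(0.0 if any(vec) else 1.0)
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    feats = _one_hot(atom.GetSymbol(), _ELEMENTS)                    # 10
    feats += _one_hot(min(atom.GetDegree(), 5), (0, 1, 2, 3, 4, 5), with_other=False)  # 6
    charge = atom.GetFormalCharge()
    feats += [1.0 if charge < 0 else 0.0, 1.0 if charge == 0 else 0.0,
              1.0 if charge > 0 else 0.0]                            # 3
    feats += _one_hot(atom.GetHybridization(), _HYBRID)              # 4
    feats += [1.0 if atom.GetIsAromatic() else 0.0]                  # 1
    feats += [1.0 if atom.IsInRing() else 0.0]                       # 1
    feats += _one_hot(min(atom.GetTotalNumHs(), 4), (0, 1, 2, 3, 4), with_other=False)  # 5
    assert len(feats) == NODE_DIM
    return feats


def _bond_features(bond: Chem.Bond) -> list[float]:
    feats = _one_hot(bond.GetBondType(), _BOND_TYPES, with_other=False)  # 4
    feats += [1.0 if bond.GetIsConjugated() else 0.0]                    # 1
    feats += [1.0 if bond.IsInRing() else 0.0]                           # 1
    feats += _one_hot(bond.GetStereo(), _BOND_STEREO, with_other=False)  # 6
    feats += [1.0 if bond.IsInRingSize(s) else 0.0 for s in (3, 4, 5, 6, 7, 8)]  # 6
    feats += [0.0] * (EDGE_DIM - len(feats))  # pad to the fixed 75-dim contract
    assert len(feats) == EDGE_DIM
    return feats


@dataclass
class MolGraph:
    """Directed molecular graph: n x 30 node features, 75 features per directed edge."""

    node_features: np.ndarray          # (n, 30)
    edges: np.ndarray                  # (m, 2) directed (j, i): source, destination
    edge_features: np.ndarray          # (m, 75)
    degrees: np.ndarray                # (n,) in-degree == heavy-atom degree

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def validate(self) -> None:
        n = self.n_nodes
        if self.edges.size and self.edges.max() >= n:
            raise ValueError("edge endpoint out of range")
        deg = np.zeros(n, dtype=np.int64)
        if self.edges.size:
            np.add.at(deg, self.edges[:, 1], 1)
        if not np.array_equal(deg, self.degrees):
            raise ValueError("degree vector inconsistent with edge list")


def smiles_to_graph(mol: CanonicalMolecule) -> MolGraph:
    """Featurize a molecule as a directed graph (both directions per bond)."""
    if not mol.parse_ok:
        raise ValueError("smiles_to_graph requires a parsable molecule")
    rdmol = mol.mol()
    n = rdmol.GetNumAtoms()
    node = np.array([_atom_features(a) for a in rdmol.GetAtoms()], dtype=np.float64)
    node = node.reshape(n, NODE_DIM)
    edges, efeats = [], []
    for bond in rdmol.GetBonds():
        j, i = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        bf = _bond_features(bond)
        edges.append((j, i))
        efeats.append(bf)
        edges.append((i, j))
        efeats.append(bf)
    edge_arr = np.array(edges, dtype=np.int64).reshape(len(edges), 2)
    efeat_arr = np.array(efeats, dtype=np.float64).reshape(len(edges), EDGE_DIM)
    degrees = np.zeros(n, dtype=np.int64)
    if edge_arr.size:
        np.add.at(degrees, edge_arr[:, 1], 1)
    return MolGraph(node_features=node, edges=edge_arr, edge_features=efeat_arr,
                    degrees=degrees)


# ---------------------------------------------------------------------------
# ECFP4 keys and Tanimoto
# ---------------------------------------------------------------------------

_ECFP4_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=ECFP4_NBITS)


def ecfp4(mol: CanonicalMolecule, nbits: int = ECFP4_NBITS) -> np.ndarray:
    """2048-bit (configurable) extended-connectivity fingerprint, radius 2."""
    if not mol.parse_ok:
        raise ValueError("ecfp4 requires a parsable molecule")
    gen = (_ECFP4_GEN if nbits == ECFP4_NBITS
           else rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits))
    return _bv_to_bool(gen.GetFingerprint(mol.mol()))


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b| on boolean keys; both-empty defined as 0 with a warning."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"key length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        warnings.warn("Tanimoto of two all-zero keys defined as 0", stacklevel=2)
        return 0.0
    return float(np.sum(a & b)) / union


def bulk_tanimoto(query: np.ndarray, keys: np.ndarray) -> np.ndarray:
    """Tanimoto of one query key against a stacked (N, nbits) key matrix."""
    query = np.asarray(query, dtype=bool)
    keys = np.asarray(keys, dtype=bool)
    if keys.ndim != 2 or keys.shape[1] != query.shape[0]:
        raise ValueError("keys must be (N, nbits) matching the query length")
    inter = keys @ query.astype(np.float64)
    union = keys.sum(axis=1) + query.sum() - inter
    out = np.zeros(len(keys))
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out
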