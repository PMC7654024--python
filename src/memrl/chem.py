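"""Molecule normalization, fingerprints, scaffolds and similarity kernels.

Every other module builds on the primitives here: SMILES are validated and
canonicalized into :class:`MoleculeRecord` objects with stereochemistry
stripped, fingerprints are computed deterministically from the canonical form,
and chemotype keys (whole-compound fingerprint, Bemis-Murcko scaffold, carbon
skeleton, fuzzy skeleton) give the four similarity criteria used by the
memory unit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Mapping, Optional, Union

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FingerprintKind",
    "SimilarityCriterion",
    "MoleculeRecord",
    "Fingerprint",
    "ScaffoldKey",
    "EMPTY_SCAFFOLD_KEY",
    "canonicalize",
    "mol_from_record",
    "fingerprint",
    "tanimoto",
    "minmax_similarity",
    "bm_scaffold",
    "carbon_skeleton",
    "scaffold_key",
    "crippen_logp",
    "ecfp6_count_matrix",
    "read_smiles_file",
    "write_smiles_file",
]

ECFP6_FOLD = 2048

#: Reserved key under which acyclic molecules (empty scaffold) are bucketed.
EMPTY_SCAFFOLD_KEY = ""


class FingerprintKind(str, Enum):
    ECFP4_BINARY = "ecfp4_binary"
    ECFP6_COUNT_2048 = "ecfp6_count_2048"
    ATOM_PAIR = "atom_pair"


class SimilarityCriterion(str, Enum):
    """The four chemotype-equivalence criteria of the memory unit."""

    COMPOUND = "compound"
    BM_SCAFFOLD = "bm_scaffold"
    CARBON_SKELETON = "carbon_skeleton"
    FUZZY_SKELETON = "fuzzy_skeleton"


@dataclass(frozen=True)
class MoleculeRecord:
    """A validated molecule; invalid input yields an empty, zero-atom record."""

    input_smiles: str
    canonical_smiles: str
    is_valid: bool
    heavy_atom_count: int


@dataclass(frozen=True)
class Fingerprint:
    """A typed sparse count vector; binary kinds carry counts of 1."""

    kind: FingerprintKind
    counts: Mapping[int, int]
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind is FingerprintKind.ECFP6_COUNT_2048 and self.length != ECFP6_FOLD:
            object.__setattr__(self, "length", ECFP6_FOLD)

    def dense(self) -> np.ndarray:
        if self.length is None:
            raise ValueError("unfolded fingerprints have no dense form")
        vec = np.zeros(self.length, dtype=np.int64)
        for k, v in self.counts.items():
            vec[k] = v
        return vec


@dataclass(frozen=True)
class ScaffoldKey:
    """Bucket-index key: a canonical SMILES string or a fingerprint.

    Scaffold criteria compare keys by string equality; compound and fuzzy
    skeleton keys are fingerprints compared by Tanimoto similarity. Acyclic
    molecules map to :data:`EMPTY_SCAFFOLD_KEY` under all scaffold criteria
    (including fuzzy) so that they share one bucket instead of evading the
    memory.
    """

    criterion: SimilarityCriterion
    key: Union[str, Fingerprint]

    @property
    def is_string(self) -> bool:
        return isinstance(self.key, str)


@lru_cache(maxsize=200_000)
def _mol(canonical_smiles: str):
    return Chem.MolFromSmiles(canonical_smiles)


def canonicalize(smiles: str) -> MoleculeRecord:
    """Parse, strip stereochemistry, and canonicalize a SMILES string.

    Never raises: unparseable input yields ``is_valid=False`` with an empty
    canonical form and zero heavy atoms.
    """
    if not isinstance(smiles, str):
        return MoleculeRecord(str(smiles), "", False, 0)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or mol.GetNumHeavyAtoms() == 0:
        return MoleculeRecord(smiles, "", False, 0)
    Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(smiles, canonical, True, mol.GetNumHeavyAtoms())


def mol_from_record(mol: MoleculeRecord):
    """RDKit Mol for a valid record (cached on the canonical SMILES)."""
    if not mol.is_valid:
        raise ValueError(f"invalid molecule: {mol.input_smiles!r}")
    return _mol(mol.canonical_smiles)


_MORGAN_R2 = rdFingerprintGenerator.GetMorganGenerator(radius=2)
_MORGAN_R3 = rdFingerprintGenerator.GetMorganGenerator(radius=3)
_ATOM_PAIR = rdFingerprintGenerator.GetAtomPairGenerator()


def _fp_from_mol(rdmol, kind: FingerprintKind) -> Fingerprint:
    if kind is FingerprintKind.ECFP4_BINARY:
        sparse = _MORGAN_R2.GetSparseCountFingerprint(rdmol).GetNonzeroElements()
        return Fingerprint(kind, {k: 1 for k in sparse})
    if kind is FingerprintKind.ECFP6_COUNT_2048:
        sparse = _MORGAN_R3.GetSparseCountFingerprint(rdmol).GetNonzeroElements()
        folded: dict[int, int] = {}
        for feature_id, count in sparse.items():
            bin_ = feature_id % ECFP6_FOLD  # colliding bins sum their counts
            folded[bin_] = folded.get(bin_, 0) + count
        return Fingerprint(kind, folded, ECFP6_FOLD)
    if kind is FingerprintKind.ATOM_PAIR:
        sparse = _ATOM_PAIR.GetSparseCountFingerprint(rdmol).GetNonzeroElements()
        return Fingerprint(kind, dict(sparse))
    raise ValueError(f"unknown fingerprint kind: {kind}")


def fingerprint(mol: MoleculeRecord, kind: FingerprintKind) -> Fingerprint:
    """Fingerprint of a valid molecule; deterministic per (canonical, kind)."""
    kind = FingerprintKind(kind)
    return _fp_from_mol(mol_from_record(mol), kind)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto (Jaccard) similarity; min-sum/max-sum on count vectors.

    Two empty fingerprints are defined to have similarity 0.0 so that empty
    molecules never match a memory index.
    """
    if a.kind != b.kind:
        raise ValueError(f"fingerprint kind mismatch: {a.kind} vs {b.kind}")
    num = 0
    den = 0
    keys = set(a.counts) | set(b.counts)
    for k in keys:
        va = a.counts.get(k, 0)
        vb = b.counts.get(k, 0)
        num += min(va, vb)
        den += max(va, vb)
    return num / den if den else 0.0


def minmax_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """MinMax kernel value for two folded ECFP6 count vectors."""
    if a.kind is not FingerprintKind.ECFP6_COUNT_2048 or a.kind != b.kind:
        raise ValueError("minmax_similarity requires two ecfp6_count_2048 fingerprints")
    return tanimoto(a, b)


def bm_scaffold(mol: MoleculeRecord) -> str:
    """Canonical Bemis-Murcko scaffold SMILES; '' for acyclic molecules."""
    rdmol = mol_from_record(mol)
    try:
        scaffold = MurckoScaffold.GetScaffoldForMol(rdmol)
    except Exception:
        return EMPTY_SCAFFOLD_KEY
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD_KEY
    return Chem.MolToSmiles(scaffold)


def carbon_skeleton(mol: MoleculeRecord) -> str:
    """Canonical carbon skeleton: BM scaffold with heteroatoms -> C, bonds -> single.

    Order of operations: extract scaffold, set bonds single, mutate atoms to
    neutral carbon, sanitize, canonicalize. Scaffolds whose skeleton cannot be
    sanitized (e.g. hypervalent centers becoming >4-coordinate carbon) map to
    the empty key.
    """
    scaffold = bm_scaffold(mol)
    if scaffold == EMPTY_SCAFFOLD_KEY:
        return EMPTY_SCAFFOLD_KEY
    rdmol = Chem.MolFromSmiles(scaffold)
    if rdmol is None:
        return EMPTY_SCAFFOLD_KEY
    rw = Chem.RWMol(rdmol)
    for bond in rw.GetBonds():
        bond.SetBondType(Chem.BondType.SINGLE)
        bond.SetIsAromatic(False)
    for atom in rw.GetAtoms():
        atom.SetAtomicNum(6)
        atom.SetFormalCharge(0)
        atom.SetNumRadicalElectrons(0)
        atom.SetNoImplicit(False)
        atom.SetNumExplicitHs(0)
        atom.SetIsAromatic(False)
    try:
        skeleton = rw.GetMol()
        Chem.SanitizeMol(skeleton)
    except Exception:
        return EMPTY_SCAFFOLD_KEY
    return Chem.MolToSmiles(skeleton)


def scaffold_key(mol: MoleculeRecord, criterion: SimilarityCriterion) -> ScaffoldKey:
    """Bucket-index key of a molecule under one of the four criteria."""
    criterion = SimilarityCriterion(criterion)
    if criterion is SimilarityCriterion.COMPOUND:
        return ScaffoldKey(criterion, fingerprint(mol, FingerprintKind.ECFP4_BINARY))
    if criterion is SimilarityCriterion.BM_SCAFFOLD:
        return ScaffoldKey(criterion, bm_scaffold(mol))
    if criterion is SimilarityCriterion.CARBON_SKELETON:
        return ScaffoldKey(criterion, carbon_skeleton(mol))
    # fuzzy skeleton: atom-pair fingerprint of the carbon skeleton
    skeleton = carbon_skeleton(mol)
    if skeleton == EMPTY_SCAFFOLD_KEY:
        return ScaffoldKey(criterion, EMPTY_SCAFFOLD_KEY)
    record = canonicalize(skeleton)
    return ScaffoldKey(criterion, fingerprint(record, FingerprintKind.ATOM_PAIR))


def crippen_logp(mol: MoleculeRecord) -> float:
    """Crippen atom-based AlogP of a valid molecule."""
    return float(Crippen.MolLogP(mol_from_record(mol)))


def ecfp6_count_matrix(mols: list[MoleculeRecord]) -> np.ndarray:
    """Dense (n, 2048) matrix of folded ECFP6 counts for valid molecules."""
    mat = np.zeros((len(mols), ECFP6_FOLD), dtype=np.float64)
    for i, m in enumerate(mols):
        for k, v in fingerprint(m, FingerprintKind.ECFP6_COUNT_2048).counts.items():
            mat[i, k] = v
    return mat


def read_smiles_file(path) -> list[str]:
    """Read one-SMILES-per-line (optional tab-separated ID); skips blanks/#."""
    out: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0].split()[0])
    return out


def write_smiles_file(path, smiles: list[str]) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
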