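"""Post-hoc diversity and analog analysis of generated compound sets.

Covers the evaluation machinery used on RL output: unique compound /
Bemis-Murcko scaffold / carbon skeleton counting, nearest-neighbor ECFP6
analog detection, size-restricted single-cut matched-molecular-pair (MMP)
fragmentation with shared-core analysis, Butina sphere-exclusion clustering,
and the cluster-wise 60/20/20 train/validation/test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from rdkit import Chem

from .chem import (
    MoleculeRecord,
    bm_scaffold,
    canonicalize,
    carbon_skeleton,
    ecfp6_count_matrix,
    mol_from_record,
)
from .scoring import minmax_kernel

__all__ = [
    "DiversityReport",
    "diversity_report",
    "ecfp6_analogs",
    "MMPFragmentation",
    "mmp_fragment",
    "shared_mmp_cores",
    "mmp_analogs",
    "butina_cluster",
    "ClusterSplit",
    "cluster_split",
]


@dataclass(frozen=True)
class DiversityReport:
    n_compounds: int
    n_unique_bm_scaffolds: int
    n_unique_carbon_skeletons: int
    n_skipped: int = 0


def diversity_report(
    compounds: Sequence[str],
    keep: Optional[Callable[[MoleculeRecord], bool]] = None,
) -> DiversityReport:
    """Unique compound / BM scaffold / carbon skeleton counts.

    Invalid SMILES are skipped (counted separately); compounds are
    deduplicated on the canonical SMILES before applying the optional filter
    predicate. Skeleton count <= scaffold count <= compound count always holds
    because both maps are functions of the canonical compound.
    """
    seen: dict[str, MoleculeRecord] = {}
    skipped = 0
    for smiles in compounds:
        rec = canonicalize(smiles)
        if not rec.is_valid:
            skipped += 1
            continue
        seen.setdefault(rec.canonical_smiles, rec)
    records = [r for r in seen.values() if keep is None or keep(r)]
    scaffolds = {bm_scaffold(r) for r in records}
    skeletons = {carbon_skeleton(r) for r in records}
    return DiversityReport(
        n_compounds=len(records),
        n_unique_bm_scaffolds=len(scaffolds),
        n_unique_carbon_skeletons=len(skeletons),
        n_skipped=skipped,
    )


def ecfp6_analogs(
    generated: Sequence[str],
    reference: Sequence[str],
    cutoff: float = 0.4,
) -> dict[str, float]:
    """Generated compounds whose nearest reference neighbor is >= cutoff.

    Similarity is the count-form (min-sum / max-sum) Tanimoto on folded ECFP6
    count fingerprints. Returns canonical SMILES -> nearest-neighbor
    similarity for the analogs.
    """
    ref_records = [r for r in (canonicalize(s) for s in reference) if r.is_valid]
    if not ref_records:
        raise ValueError("reference set has no valid molecules")
    gen_seen: dict[str, MoleculeRecord] = {}
    for s in generated:
        rec = canonicalize(s)
        if rec.is_valid:
            gen_seen.setdefault(rec.canonical_smiles, rec)
    if not gen_seen:
        return {}
    gen_records = list(gen_seen.values())
    sims = minmax_kernel(ecfp6_count_matrix(gen_records), ecfp6_count_matrix(ref_records))
    nearest = sims.max(axis=1)
    return {
        rec.canonical_smiles: float(nn)
        for rec, nn in zip(gen_records, nearest)
        if nn >= cutoff
    }


# -- matched molecular pairs ------------------------------------------------

ATTACHMENT = "*"  # uniform wildcard marking the cut position


@dataclass(frozen=True)
class MMPFragmentation:
    molecule: str
    pairs: tuple[tuple[str, str], ...]  # (core, side), core at least twice the side

    @property
    def cores(self) -> set[str]:
        return {core for core, _ in self.pairs}


def _fragment_heavy_atoms(frag) -> int:
    """Heavy atoms of a fragment excluding the attachment wildcard."""
    return sum(1 for a in frag.GetAtoms() if a.GetAtomicNum() > 1 and a.GetAtomicNum() != 0)


def mmp_fragment(mol: MoleculeRecord) -> MMPFragmentation:
    """Single-cut MMP fragmentation with the 2:1 core:side size restriction.

    Every acyclic single bond between two heavy atoms is cut once; the two
    fragments are canonicalized with a wildcard attachment atom. A pair is
    kept when the larger fragment (the MMP core) has at least twice as many
    heavy atoms as the smaller one (attachment points excluded). Molecules
    with no cuttable bond (e.g. pure rings) yield no pairs.
    """
    rdmol = mol_from_record(mol)
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for bond in rdmol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        fragmented = Chem.FragmentOnBonds(
            rdmol, [bond.GetIdx()], addDummies=True, dummyLabels=[(0, 0)]
        )
        try:
            frags = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
        except Exception:
            continue
        if len(frags) != 2:
            continue
        sizes = [_fragment_heavy_atoms(f) for f in frags]
        order = np.argsort(sizes)[::-1]
        core, side = frags[order[0]], frags[order[1]]
        core_n, side_n = sizes[order[0]], sizes[order[1]]
        if core_n < 2 * side_n:
            continue
        pair = (Chem.MolToSmiles(core), Chem.MolToSmiles(side))
        if pair not in seen:
            seen.add(pair)
            pairs.append(pair)
    return MMPFragmentation(molecule=mol.canonical_smiles, pairs=tuple(pairs))


def _core_sets(smiles: Sequence[str]) -> dict[str, set[str]]:
    """canonical SMILES -> set of MMP cores, for valid unique molecules."""
    out: dict[str, set[str]] = {}
    for s in smiles:
        rec = canonicalize(s)
        if not rec.is_valid or rec.canonical_smiles in out:
            continue
        out[rec.canonical_smiles] = mmp_fragment(rec).cores
    return out


def shared_mmp_cores(set_a: Sequence[str], set_b: Sequence[str]) -> tuple[int, list[str]]:
    """Cores occurring in the fragmentations of both sets."""
    cores_a = set().union(*_core_sets(set_a).values()) if set_a else set()
    cores_b = set().union(*_core_sets(set_b).values()) if set_b else set()
    shared = sorted(cores_a & cores_b)
    return len(shared), shared


def mmp_analogs(
    generated: Sequence[str], reference: Sequence[str]
) -> dict[str, list[str]]:
    """Generated compounds sharing at least one MMP core with a reference.

    Returns canonical generated SMILES -> list of reference partners; each
    generated compound counts once however many partners it has.
    """
    gen_cores = _core_sets(generated)
    ref_cores = _core_sets(reference)
    analogs: dict[str, list[str]] = {}
    for gen, cores in gen_cores.items():
        partners = [ref for ref, rcores in ref_cores.items() if cores & rcores]
        if partners:
            analogs[gen] = partners
    return analogs


# -- Butina clustering and cluster-wise splitting ---------------------------


def butina_cluster(smiles: Sequence[str], cutoff: float = 0.4) -> list[list[int]]:
    """Butina sphere-exclusion clustering on count-ECFP6 Tanimoto similarity.

    Molecules whose similarity is >= cutoff are neighbors. Candidate
    centroids are ranked by neighbor count (ties: earlier input index wins);
    each centroid claims its unassigned neighbors; singletons remain their
    own cluster. Returns clusters as lists of input indices; invalid SMILES
    are excluded entirely.
    """
    records = [canonicalize(s) for s in smiles]
    idx = [i for i, r in enumerate(records) if r.is_valid]
    if not idx:
        raise ValueError("no valid molecules to cluster")
    mat = ecfp6_count_matrix([records[i] for i in idx])
    sims = minmax_kernel(mat, mat)
    n = len(idx)
    neighbor_lists = [np.flatnonzero(sims[i] >= cutoff) for i in range(n)]
    # stable sort: descending neighbor count, ascending input index
    order = sorted(range(n), key=lambda i: (-len(neighbor_lists[i]), i))
    assigned = np.zeros(n, dtype=bool)
    clusters: list[list[int]] = []
    for centroid in order:
        if assigned[centroid]:
            continue
        members = [centroid] + [
            int(j) for j in neighbor_lists[centroid] if j != centroid and not assigned[j]
        ]
        for j in members:
            assigned[j] = True
        clusters.append([idx[j] for j in members])
    return clusters


@dataclass
class ClusterSplit:
    train: list[str]
    validation: list[str]
    test: list[str]
    cluster_assignment: dict[int, str] = field(default_factory=dict)


def cluster_split(
    clusters: Sequence[Sequence[str]],
    ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
    inactives: Sequence[str] = (),
    seed: int = 0,
) -> ClusterSplit:
    """Greedy cluster-wise 60/20/20 split; clusters are never divided.

    Clusters of actives are sorted by descending size and each is assigned to
    the partition (train/validation/test) currently furthest below its target
    share of actives. Inactives are split at the same ratios uniformly at
    random with the given seed.
    """
    if not clusters:
        raise ValueError("no clusters to split")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    names = ("train", "validation", "test")
    parts: dict[str, list[str]] = {n: [] for n in names}
    assignment: dict[int, str] = {}
    order = sorted(range(len(clusters)), key=lambda i: (-len(clusters[i]), i))
    counts = {n: 0 for n in names}
    total = sum(len(c) for c in clusters)
    for ci in order:
        # deficit = target fraction minus current fraction of assigned actives
        deficits = {
            n: ratios[k] - (counts[n] / total) for k, n in enumerate(names)
        }
        target = max(names, key=lambda n: deficits[n])
        parts[target].extend(clusters[ci])
        counts[target] += len(clusters[ci])
        assignment[ci] = target
    rng = np.random.default_rng(seed)
    for s in inactives:
        u = rng.random()
        if u < ratios[0]:
            parts["train"].append(s)
        elif u < ratios[0] + ratios[1]:
            parts["validation"].append(s)
        else:
            parts["test"].append(s)
    return ClusterSplit(
        train=parts["train"],
        validation=parts["validation"],
        test=parts["test"],
        cluster_assignment=assignment,
    )
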