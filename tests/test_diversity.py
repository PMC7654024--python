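"""Diversity reports, analog detection, MMP machinery, clustering, splits."""

import numpy as np
import pytest

from memrl.chem import canonicalize
from memrl.diversity import (
    butina_cluster,
    cluster_split,
    diversity_report,
    ecfp6_analogs,
    mmp_analogs,
    mmp_fragment,
    shared_mmp_cores,
)


class TestDiversityReport:
    def test_shared_scaffold_counted_once(self):
        report = diversity_report(["c1ccccc1", "Cc1ccccc1"])
        assert report.n_compounds == 2
        assert report.n_unique_bm_scaffolds == 1
        assert report.n_unique_carbon_skeletons == 1

    def test_empty_input(self):
        report = diversity_report([])
        assert (report.n_compounds, report.n_unique_bm_scaffolds) == (0, 0)

    def test_duplicates_deduplicated(self):
        report = diversity_report(["CCOc1ccccc1"] * 5)
        assert report.n_compounds == 1

    def test_invalids_skipped_and_counted(self):
        report = diversity_report(["c1ccccc1", "C1CC", "xyz"])
        assert report.n_compounds == 1 and report.n_skipped == 2

    def test_count_ordering_invariant(self, tiny_corpus):
        report = diversity_report(tiny_corpus)
        assert (
            report.n_unique_carbon_skeletons
            <= report.n_unique_bm_scaffolds
            <= report.n_compounds
        )

    def test_filter_predicate(self, tiny_corpus):
        full = diversity_report(tiny_corpus)
        small = diversity_report(tiny_corpus, keep=lambda r: r.heavy_atom_count <= 18)
        assert small.n_compounds <= full.n_compounds


class TestEcfp6Analogs:
    def test_identity_is_analog_with_similarity_one(self):
        hits = ecfp6_analogs(["CCOc1ccccc1"], ["CCOc1ccccc1", "CCCCCCCC"])
        assert hits == {canonicalize("CCOc1ccccc1").canonical_smiles: pytest.approx(1.0)}

    def test_dissimilar_not_analog(self):
        hits = ecfp6_analogs(["C"], ["c1ccc2nc3ccccc3nc2c1", "O=C(O)c1ccccc1O"])
        assert hits == {}

    def test_cutoff_zero_accepts_everything(self, tiny_corpus):
        hits = ecfp6_analogs(tiny_corpus[:10], tiny_corpus[-5:], cutoff=0.0)
        assert len(hits) == len({canonicalize(s).canonical_smiles for s in tiny_corpus[:10]})

    def test_monotone_in_cutoff(self, tiny_corpus):
        low = set(ecfp6_analogs(tiny_corpus[:20], tiny_corpus[20:30], cutoff=0.3))
        high = set(ecfp6_analogs(tiny_corpus[:20], tiny_corpus[20:30], cutoff=0.5))
        assert high <= low

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ecfp6_analogs(["CCO"], [])


class TestMMPFragment:
    def test_benzene_has_no_cuts(self):
        assert mmp_fragment(canonicalize("c1ccccc1")).pairs == ()

    def test_toluene_single_cut(self):
        frag = mmp_fragment(canonicalize("Cc1ccccc1"))
        # one acyclic bond; core benzene (6 heavy) vs methyl (1): 6 >= 2*1
        assert len(frag.pairs) == 1
        core, side = frag.pairs[0]
        assert "*" in core and "*" in side

    def test_ethylbenzene_size_restriction(self):
        frag = mmp_fragment(canonicalize("CCc1ccccc1"))
        # ring-CH2 cut: 6 vs 2 keeps; terminal CH3 cut: 7 vs 1 keeps
        assert len(frag.pairs) == 2

    def test_conservation_of_heavy_atoms(self, tiny_corpus):
        from rdkit import Chem

        def heavy(smiles):
            mol = Chem.MolFromSmiles(smiles)
            return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)

        for smiles in tiny_corpus[:25]:
            rec = canonicalize(smiles)
            for core, side in mmp_fragment(rec).pairs:
                assert heavy(core) + heavy(side) == rec.heavy_atom_count

    def test_core_at_least_twice_side(self, tiny_corpus):
        from rdkit import Chem

        def heavy(smiles):
            mol = Chem.MolFromSmiles(smiles)
            return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)

        for smiles in tiny_corpus[:25]:
            for core, side in mmp_fragment(canonicalize(smiles)).pairs:
                assert heavy(core) >= 2 * heavy(side)


class TestSharedCoresAndAnalogs:
    def test_identical_sets_share_all_cores(self):
        mols = ["CCc1ccccc1", "CCCc1ccccc1"]
        n, shared = shared_mmp_cores(mols, list(mols))
        all_cores = set()
        for s in mols:
            all_cores |= mmp_fragment(canonicalize(s)).cores
        assert n == len(all_cores) and set(shared) == all_cores

    def test_disjoint_chemistries_share_nothing(self):
        n, _ = shared_mmp_cores(["CCCCCCCC", "CCCCCCC"], ["Oc1ccc2ccccc2c1", "Nc1ccc2ccccc2c1"])
        assert n == 0

    def test_methyl_ethyl_swap_is_mmp_analog(self):
        # same core (benzene+attachment), different side chain
        analogs = mmp_analogs(["CCc1ccccc1"], ["Cc1ccccc1"])
        assert canonicalize("CCc1ccccc1").canonical_smiles in analogs

    def test_scaffold_hop_is_not_mmp_analog(self):
        analogs = mmp_analogs(["CCc1ccncc1"], ["CCc1ccccc1"])
        assert analogs == {}

    def test_ring_only_molecules_never_analogs(self):
        assert mmp_analogs(["c1ccccc1"], ["c1ccccc1"]) == {}


def _homolog_families(n_families=10, size=10):
    """Tight synthetic clusters: small substituent variants on a short linker
    to structurally distinct ring systems (intra-sim > 0.4 > inter-sim)."""
    scaffolds = [
        "c1ccccc1", "C1CCCCC1", "c1ccoc1", "c1cnc2ccccc2n1",
        "c1cc2ccc3cccc4ccc(c1)c2c34", "C1CN2CCC1CC2", "c1csc(-c2nccs2)c1",
        "C1CCOC1", "c1ccc2c(c1)CCCC2", "c1cncnc1",
    ][:n_families]
    substituents = ["", "O", "N", "F", "Cl", "Br", "C", "CC", "OC", "CN"][:size]
    return [[x + "CC" + s for x in substituents] for s in scaffolds]


class TestButina:
    def test_identical_molecules_single_cluster(self):
        clusters = butina_cluster(["CCOc1ccccc1"] * 4)
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_two_tight_clusters_recovered(self):
        fam = _homolog_families(2, 6)
        smiles = fam[0] + fam[1]
        clusters = butina_cluster(smiles, cutoff=0.4)
        memberships = [set(c) for c in clusters]
        assert set(range(6)) in memberships or any(
            set(range(6)) <= m for m in memberships
        )
        # no cluster mixes the two families
        for members in memberships:
            assert members <= set(range(6)) or members <= set(range(6, 12))

    def test_cutoff_one_groups_only_duplicates(self):
        smiles = ["CCO", "CCO", "CCN"]
        clusters = butina_cluster(smiles, cutoff=1.0)
        assert sorted(sorted(c) for c in clusters) == [[0, 1], [2]]

    def test_partition_property(self, tiny_corpus):
        clusters = butina_cluster(tiny_corpus, cutoff=0.4)
        flat = sorted(i for c in clusters for i in c)
        assert flat == list(range(len(tiny_corpus)))

    def test_matches_rdkit_reference_on_separated_data(self):
        # independent oracle: RDKit's Butina on the same similarity matrix
        from rdkit.ML.Cluster import Butina as RDKitButina
        from memrl.chem import ecfp6_count_matrix
        from memrl.scoring import minmax_kernel

        fam = _homolog_families(3, 5)
        smiles = [s for f in fam for s in f]
        records = [canonicalize(s) for s in smiles]
        mat = ecfp6_count_matrix(records)
        sims = minmax_kernel(mat, mat)
        dists = [1 - sims[i, j] for i in range(1, len(smiles)) for j in range(i)]
        reference = RDKitButina.ClusterData(dists, len(smiles), 0.6, isDistData=True)
        ours = butina_cluster(smiles, cutoff=0.4)
        assert sorted(sorted(c) for c in reference) == sorted(sorted(c) for c in ours)


class TestClusterSplit:
    def test_ten_equal_clusters_exact_fractions(self):
        clusters = [[f"mol{i}_{j}" for j in range(10)] for i in range(10)]
        split = cluster_split(clusters)
        assert len(split.train) == 60
        assert len(split.validation) == 20
        assert len(split.test) == 20

    def test_clusters_never_divided(self):
        clusters = [[f"m{i}_{j}" for j in range(np.random.default_rng(i).integers(2, 9))] for i in range(7)]
        split = cluster_split(clusters)
        parts = {
            name: set(getattr(split, name)) for name in ("train", "validation", "test")
        }
        for ci, cluster in enumerate(clusters):
            target = split.cluster_assignment[ci]
            assert set(cluster) <= parts[target]

    def test_single_cluster_goes_to_train(self):
        split = cluster_split([["a", "b", "c"]])
        assert split.train == ["a", "b", "c"] and not split.validation and not split.test

    def test_partitions_disjoint_with_inactives(self):
        clusters = [[f"act{i}_{j}" for j in range(5)] for i in range(5)]
        inactives = [f"inact{i}" for i in range(50)]
        split = cluster_split(clusters, inactives=inactives, seed=0)
        a, b, c = set(split.train), set(split.validation), set(split.test)
        assert not (a & b) and not (a & c) and not (b & c)
        assert len(a | b | c) == 25 + 50

    def test_empty_clusters_rejected(self):
        with pytest.raises(ValueError):
            cluster_split([])
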