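"""Memory-unit protocol: bucket matching, capacity, output modes, state."""

import math

import numpy as np
import pytest

from memrl.chem import SimilarityCriterion, canonicalize, bm_scaffold, tanimoto, fingerprint, FingerprintKind
from memrl.memory import (
    MemoryConfig,
    MemoryUnit,
    OutputMode,
    new_memory,
    output_mode_value,
)

# distinct alkylbenzene homologs: one shared benzene scaffold / cyclohexane skeleton
ALKYLBENZENES = ["C" * n + "c1ccccc1" for n in range(1, 31)]


class TestConfig:
    def test_default_empty_state(self):
        unit = new_memory()
        assert len(unit.buckets) == 0
        assert unit.total_stored == 0
        assert unit.config.bucket_size == 25

    def test_invalid_bucket_size(self):
        with pytest.raises(ValueError):
            MemoryConfig(bucket_size=0)

    def test_mode_recorded(self):
        unit = new_memory(MemoryConfig(output_mode="linear"))
        assert unit.config.output_mode is OutputMode.LINEAR


class TestOutputModes:
    def test_linear_closed_form(self):
        for fill in range(26):
            expected = 0.0 if fill >= 25 else 1.0 - fill / 25
            assert output_mode_value(OutputMode.LINEAR, fill, 25) == pytest.approx(expected)

    def test_sigmoid_closed_form_and_midpoint(self):
        size = 24
        for fill in range(size + 1):
            if fill >= size:
                expected = 0.0
            else:
                expected = 1 - 1 / (1 + math.exp(-((2 * fill / size - 1) / 0.15)))
            assert output_mode_value(OutputMode.SIGMOID, fill, size) == pytest.approx(expected)
        assert output_mode_value(OutputMode.SIGMOID, size // 2, size) == pytest.approx(0.5)

    def test_binary_step(self):
        values = [output_mode_value(OutputMode.BINARY, f, 25) for f in range(26)]
        assert values == [1.0] * 25 + [0.0]

    def test_modes_non_increasing_in_fill(self):
        for mode in OutputMode:
            vals = [output_mode_value(mode, f, 25) for f in range(26)]
            assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestMatchBucket:
    def test_empty_state_no_match(self):
        unit = new_memory()
        from memrl.chem import scaffold_key

        key = scaffold_key(canonicalize("c1ccccc1"), SimilarityCriterion.BM_SCAFFOLD)
        assert unit.match_bucket(key) is None

    def test_bm_equality_matches(self):
        unit = new_memory()
        unit.score_and_update(canonicalize("c1ccccc1"), 0.9)
        from memrl.chem import scaffold_key

        key = scaffold_key(canonicalize("Cc1ccccc1"), SimilarityCriterion.BM_SCAFFOLD)
        assert unit.match_bucket(key) is unit.buckets[0]

    def test_similarity_below_cutoff_no_match(self):
        unit = new_memory(MemoryConfig(criterion="compound", similarity_cutoff=0.6))
        unit.score_and_update(canonicalize("c1ccccc1"), 0.9)
        query = canonicalize("Cc1ccccc1")
        sim = tanimoto(
            fingerprint(query, FingerprintKind.ECFP4_BINARY),
            fingerprint(canonicalize("c1ccccc1"), FingerprintKind.ECFP4_BINARY),
        )
        assert sim < 0.6  # precondition of the example
        from memrl.chem import scaffold_key

        assert unit.match_bucket(scaffold_key(query, SimilarityCriterion.COMPOUND)) is None

    def test_criterion_mismatch_rejected(self):
        unit = new_memory()
        from memrl.chem import scaffold_key

        key = scaffold_key(canonicalize("c1ccccc1"), SimilarityCriterion.COMPOUND)
        with pytest.raises(ValueError):
            unit.match_bucket(key)


class TestScoreAndUpdate:
    def test_new_bucket_created(self):
        unit = new_memory()
        result = unit.score_and_update(canonicalize("c1ccccc1"), 0.9)
        assert result.value == 1.0 and result.was_added
        assert len(unit.buckets) == 1

    def test_low_score_bypass(self):
        unit = new_memory()
        result = unit.score_and_update(canonicalize("c1ccccc1"), 0.1)
        assert result.value == 1.0 and not result.was_added
        assert len(unit.buckets) == 0 and unit.total_stored == 0

    def test_saturation_rejection(self):
        unit = new_memory()
        for s in ALKYLBENZENES[:25]:
            assert unit.score_and_update(canonicalize(s), 0.9).value == 1.0
        result = unit.score_and_update(canonicalize(ALKYLBENZENES[25]), 0.9)
        assert result.value == 0.0 and not result.was_added
        assert unit.total_stored == 25

    def test_linear_fill_value(self):
        unit = new_memory(MemoryConfig(output_mode="linear"))
        for s in ALKYLBENZENES[:5]:
            unit.score_and_update(canonicalize(s), 0.9)
        # sixth compound sees fill 5 before insertion: 1 - 5/25 = 0.8
        assert unit.score_and_update(canonicalize(ALKYLBENZENES[5]), 0.9).value == pytest.approx(0.8)

    def test_duplicates_consume_slots(self):
        # repeated generation of one compound saturates its bucket
        unit = new_memory(MemoryConfig(bucket_size=3))
        for _ in range(3):
            assert unit.score_and_update(canonicalize("Cc1ccccc1"), 0.9).value == 1.0
        assert unit.score_and_update(canonicalize("Cc1ccccc1"), 0.9).value == 0.0
        assert unit.total_stored == 3

    def test_invalid_molecule_never_mutates(self):
        unit = new_memory()
        with pytest.raises(ValueError):
            unit.score_and_update(canonicalize("C1CC"), 0.9)
        assert len(unit.buckets) == 0


@pytest.mark.parametrize(
    "criterion",
    ["compound", "bm_scaffold", "carbon_skeleton", "fuzzy_skeleton"],
)
def test_full_decision_table_each_criterion(criterion):
    """New bucket / sub-capacity insert / saturation / low-score bypass."""
    unit = new_memory(MemoryConfig(criterion=criterion, bucket_size=4))
    stream = ALKYLBENZENES  # mutually same scaffold/skeleton; compound uses dups
    # compound criterion: homologs are not 0.6-similar, use duplicates instead
    inserts = (
        [stream[0]] * 4 if criterion == "compound" else stream[:4]
    )
    first = unit.score_and_update(canonicalize(inserts[0]), 0.9)
    assert first.value == 1.0 and first.was_added and len(unit.buckets) == 1
    for s in inserts[1:]:
        r = unit.score_and_update(canonicalize(s), 0.9)
        assert r.value == 1.0 and len(unit.buckets) == 1
    # saturated: high scorer matching the bucket is vetoed
    probe = inserts[0]
    r = unit.score_and_update(canonicalize(probe), 0.9)
    assert r.value == 0.0 and not r.was_added
    assert unit.total_stored == 4
    # low scorer bypasses untouched
    before = unit.to_json()
    r = unit.score_and_update(canonicalize(probe), 0.3)
    assert r.value == 1.0 and unit.to_json() == before


class TestInvariants:
    def test_saturation_monotonicity(self):
        # once full, every matching high-score query gets 0, in every mode
        for mode in OutputMode:
            unit = new_memory(MemoryConfig(bucket_size=5, output_mode=mode))
            rng = np.random.default_rng(0)
            for _ in range(40):
                s = ALKYLBENZENES[int(rng.integers(len(ALKYLBENZENES)))]
                unit.score_and_update(canonicalize(s), 0.9)
            assert unit.total_stored == 5
            for s in ALKYLBENZENES[:10]:
                assert unit.score_and_update(canonicalize(s), 0.9).value == 0.0

    def test_stored_never_exceeds_capacity(self, tiny_corpus):
        unit = new_memory(MemoryConfig(bucket_size=3))
        rng = np.random.default_rng(1)
        for _ in range(200):
            s = tiny_corpus[int(rng.integers(len(tiny_corpus)))]
            unit.score_and_update(canonicalize(s), float(rng.random()))
        assert unit.total_stored <= len(unit.buckets) * 3

    def test_criterion_nesting(self, tiny_corpus):
        # skeleton equivalence is coarser than scaffold, coarser than compound
        counts = {}
        for criterion in ("carbon_skeleton", "bm_scaffold"):
            unit = new_memory(MemoryConfig(criterion=criterion, bucket_size=1000))
            for s in tiny_corpus:
                unit.score_and_update(canonicalize(s), 0.9)
            counts[criterion] = len(unit.buckets)
        unique = len({canonicalize(s).canonical_smiles for s in tiny_corpus})
        assert counts["carbon_skeleton"] <= counts["bm_scaffold"] <= unique

    def test_replay_reproduces_snapshot(self, tiny_corpus):
        def run():
            unit = new_memory(MemoryConfig(bucket_size=4))
            rng = np.random.default_rng(5)
            for _ in range(120):
                s = tiny_corpus[int(rng.integers(len(tiny_corpus)))]
                unit.score_and_update(canonicalize(s), float(rng.random()))
            return unit

        assert run().to_json() == run().to_json()

    def test_json_roundtrip(self, tiny_corpus):
        unit = new_memory(MemoryConfig(criterion="compound", bucket_size=4))
        for s in tiny_corpus[:30]:
            unit.score_and_update(canonicalize(s), 0.9)
        restored = MemoryUnit.from_json(unit.to_json())
        assert restored.to_json() == unit.to_json()
        # restored state keeps matching behavior
        probe = canonicalize(tiny_corpus[0])
        assert restored.peek(probe, 0.9) == unit.peek(probe, 0.9)


class TestSnapshot:
    def test_empty(self):
        snap = new_memory().snapshot()
        assert snap["buckets"] == 0 and snap["stored"] == 0

    def test_counts_after_inserts(self):
        unit = new_memory()
        unit.score_and_update(canonicalize("c1ccccc1"), 0.9)
        snap = unit.snapshot()
        assert snap["buckets"] == 1 and snap["stored"] == 1

    def test_capacity_respected_in_snapshot(self):
        unit = new_memory()
        for s in ALKYLBENZENES[:26]:
            unit.score_and_update(canonicalize(s), 0.9)
        assert unit.snapshot()["stored"] == 25
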