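"""The memory unit: a hash table of index-bucket pairs penalizing re-visits.

During reinforcement learning every highly scored compound is compared to the
index (seed) structures of all buckets under a configurable chemotype
criterion. Matching compounds fill the bucket; once a bucket holds
``bucket_size`` compounds, further matches receive a memory score M(c)=0 and
the reward for that region of chemical space is extinguished, forcing the
generative model to move on. Compounds below the score threshold bypass the
memory entirely with M(c)=1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

from .chem import (
    Fingerprint,
    FingerprintKind,
    MoleculeRecord,
    ScaffoldKey,
    SimilarityCriterion,
    scaffold_key,
    tanimoto,
)

__all__ = [
    "OutputMode",
    "MemoryConfig",
    "Bucket",
    "MemoryScore",
    "MemoryUnit",
    "new_memory",
    "output_mode_value",
]


class OutputMode(str, Enum):
    BINARY = "binary"
    LINEAR = "linear"
    SIGMOID = "sigmoid"


# Width of the sigmoid fall-off in units of the normalized fill fraction.
SIGMOID_SCALE = 0.15


def output_mode_value(mode: OutputMode, fill: int, bucket_size: int) -> float:
    """Memory score for a matched bucket at a given fill (before insertion).

    binary: step function, 1 while the bucket has room.
    linear: 1 - fill/bucket_size.
    sigmoid: 1 - logistic((2*fill/bucket_size - 1)/0.15), midpoint 0.5 at
    half fill. A full bucket scores exactly 0 in every mode.
    """
    if fill >= bucket_size:
        return 0.0
    mode = OutputMode(mode)
    if mode is OutputMode.BINARY:
        return 1.0
    frac = fill / bucket_size
    if mode is OutputMode.LINEAR:
        return 1.0 - frac
    return 1.0 - 1.0 / (1.0 + math.exp(-((2.0 * frac - 1.0) / SIGMOID_SCALE)))


@dataclass
class MemoryConfig:
    criterion: SimilarityCriterion = SimilarityCriterion.BM_SCAFFOLD
    bucket_size: int = 25
    similarity_cutoff: float = 0.6
    score_threshold: float = 0.6
    output_mode: OutputMode = OutputMode.BINARY

    def __post_init__(self) -> None:
        self.criterion = SimilarityCriterion(self.criterion)
        self.output_mode = OutputMode(self.output_mode)
        if self.bucket_size < 1:
            raise ValueError("bucket_size must be >= 1")
        if not (0.0 < self.similarity_cutoff <= 1.0):
            raise ValueError("similarity_cutoff must be in (0, 1]")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must be in [0, 1]")


@dataclass
class Bucket:
    index_key: ScaffoldKey
    members: list[str] = field(default_factory=list)
    created_at: int = 0


@dataclass(frozen=True)
class MemoryScore:
    value: float
    matched_bucket: Optional[Bucket]
    was_added: bool


class MemoryUnit:
    """Mutable memory state: ordered index-bucket pairs plus configuration."""

    def __init__(self, config: Optional[MemoryConfig] = None) -> None:
        self.config = config if config is not None else MemoryConfig()
        self.buckets: list[Bucket] = []
        self._string_index: dict[str, Bucket] = {}
        self._counter = 0  # monotone creation counter

    @property
    def total_stored(self) -> int:
        return sum(len(b.members) for b in self.buckets)

    def match_bucket(self, key: ScaffoldKey) -> Optional[Bucket]:
        """Bucket matching a query key, or None.

        String keys (scaffold criteria) match by exact equality — one bucket
        per key. Fingerprint keys match the bucket with the highest Tanimoto
        similarity at or above the cutoff; ties go to the earliest-created
        bucket.
        """
        if key.criterion != self.config.criterion:
            raise ValueError(
                f"criterion mismatch: query {key.criterion} vs memory {self.config.criterion}"
            )
        if key.is_string:
            return self._string_index.get(key.key)
        best: Optional[Bucket] = None
        best_sim = -1.0
        for bucket in self.buckets:
            if bucket.index_key.is_string:
                continue  # reserved empty-scaffold bucket under fuzzy criterion
            sim = tanimoto(key.key, bucket.index_key.key)
            if sim >= self.config.similarity_cutoff and sim > best_sim:
                best, best_sim = bucket, sim
        return best

    def score_and_update(self, mol: MoleculeRecord, s_score: float) -> MemoryScore:
        """Score a compound and record it if it is a high scorer.

        Low scorers (S(c) below the score threshold) are never compared or
        stored and always get M(c)=1. High scorers are matched against the
        index structures: no match creates a new index-bucket pair seeded by
        this compound, a match with room inserts and scores by the fill before
        insertion, and a saturated match scores 0 and is rejected. A duplicate
        canonical SMILES already in its bucket is scored by the current fill
        but does not consume a second slot.
        """
        if not mol.is_valid:
            raise ValueError(f"invalid molecule: {mol.input_smiles!r}")
        if s_score < self.config.score_threshold:
            return MemoryScore(1.0, None, False)
        key = scaffold_key(mol, self.config.criterion)
        bucket = self.match_bucket(key)
        size = self.config.bucket_size
        if bucket is None:
            bucket = Bucket(index_key=key, created_at=self._counter)
            self._counter += 1
            self.buckets.append(bucket)
            if key.is_string:
                self._string_index[key.key] = bucket
            value = output_mode_value(self.config.output_mode, 0, size)
            bucket.members.append(mol.canonical_smiles)
            return MemoryScore(value, bucket, True)
        fill = len(bucket.members)
        if fill >= size:
            return MemoryScore(0.0, bucket, False)
        value = output_mode_value(self.config.output_mode, fill, size)
        bucket.members.append(mol.canonical_smiles)
        return MemoryScore(value, bucket, True)

    def peek(self, mol: MoleculeRecord, s_score: float) -> float:
        """Memory score a compound would receive now, without mutating state."""
        if not mol.is_valid:
            raise ValueError(f"invalid molecule: {mol.input_smiles!r}")
        if s_score < self.config.score_threshold:
            return 1.0
        bucket = self.match_bucket(scaffold_key(mol, self.config.criterion))
        fill = len(bucket.members) if bucket is not None else 0
        return output_mode_value(self.config.output_mode, fill, self.config.bucket_size)

    # -- introspection / serialization -------------------------------------

    def snapshot(self) -> dict:
        """Read-only JSON-serializable summary of the memory state."""
        fills: dict[int, int] = {}
        for b in self.buckets:
            fills[len(b.members)] = fills.get(len(b.members), 0) + 1
        return {
            "criterion": self.config.criterion.value,
            "output_mode": self.config.output_mode.value,
            "bucket_size": self.config.bucket_size,
            "buckets": len(self.buckets),
            "stored": self.total_stored,
            "fill_histogram": {str(k): v for k, v in sorted(fills.items())},
            "members": [list(b.members) for b in self.buckets],
        }

    def to_json(self) -> str:
        def encode_key(key: ScaffoldKey):
            if key.is_string:
                return {"type": "smiles", "value": key.key}
            fp: Fingerprint = key.key
            return {
                "type": "fingerprint",
                "kind": fp.kind.value,
                "counts": {str(k): v for k, v in fp.counts.items()},
                "length": fp.length,
            }

        payload = {
            "config": {
                "criterion": self.config.criterion.value,
                "bucket_size": self.config.bucket_size,
                "similarity_cutoff": self.config.similarity_cutoff,
                "score_threshold": self.config.score_threshold,
                "output_mode": self.config.output_mode.value,
            },
            "buckets": [
                {
                    "index_key": encode_key(b.index_key),
                    "members": list(b.members),
                    "created_at": b.created_at,
                }
                for b in self.buckets
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "MemoryUnit":
        payload = json.loads(text)
        cfg = payload["config"]
        unit = cls(
            MemoryConfig(
                criterion=cfg["criterion"],
                bucket_size=cfg["bucket_size"],
                similarity_cutoff=cfg["similarity_cutoff"],
                score_threshold=cfg["score_threshold"],
                output_mode=cfg["output_mode"],
            )
        )
        criterion = unit.config.criterion
        for b in payload["buckets"]:
            raw = b["index_key"]
            if raw["type"] == "smiles":
                key = ScaffoldKey(criterion, raw["value"])
            else:
                key = ScaffoldKey(
                    criterion,
                    Fingerprint(
                        FingerprintKind(raw["kind"]),
                        {int(k): v for k, v in raw["counts"].items()},
                        raw["length"],
                    ),
                )
            bucket = Bucket(index_key=key, members=list(b["members"]), created_at=b["created_at"])
            unit.buckets.append(bucket)
            if key.is_string:
                unit._string_index[key.key] = bucket
            unit._counter = max(unit._counter, bucket.created_at + 1)
        return unit


def new_memory(config: Optional[MemoryConfig] = None) -> MemoryUnit:
    """Create an empty memory unit (convenience constructor)."""
    return MemoryUnit(config)
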