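"""REINVENT-style reinforcement learning loop with memory modulation.

The agent network starts as a copy of the prior and is pulled toward an
augmented likelihood

    logP_aug(c) = logP_prior(c) + sigma * S(c) * M(c)

where S(c) is the scoring function and M(c) the memory-unit score. Each
iteration samples a batch, scores it, updates the memory, and takes one Adam
step on the mean squared difference between augmented and agent likelihood.
Optional experience replay re-presents k previously generated compounds per
iteration, drawn with probability proportional to their saved scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import MoleculeRecord, canonicalize
from .generator import (
    Adam,
    GeneratorModel,
    _gather_loglik,
    pad_sequences,
    sample_batch,
    save_model,
)
from .memory import MemoryUnit
from .scoring import ScoreResult

__all__ = [
    "RLConfig",
    "ReplayBuffer",
    "IterationLog",
    "augmented_likelihood",
    "rl_loss",
    "replay_draw",
    "rl_step",
    "run_rl",
]


@dataclass
class RLConfig:
    sigma: float = 60.0
    batch_size: int = 100
    iterations: int = 150
    learning_rate: float = 0.001
    temperature: float = 1.0
    max_len: int = 140
    replay: bool = False
    replay_k: int = 8
    # score replayed compounds through the current memory (read-only) instead
    # of fixing M=1; keeps replay from reinforcing already-saturated regions
    replay_through_memory: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma, self.batch_size, self.learning_rate) <= 0 or self.iterations < 0:
            raise ValueError("sigma, batch_size, learning_rate must be positive; iterations >= 0")
        if self.temperature <= 0 or self.replay_k < 1:
            raise ValueError("temperature must be positive and replay_k >= 1")


class ReplayBuffer:
    """Generated compounds with their scores, for score-proportional replay."""

    def __init__(self) -> None:
        self.entries: list[tuple[str, float]] = []

    def add(self, smiles: str, score: float) -> None:
        if score < 0:
            raise ValueError("replay scores must be non-negative")
        self.entries.append((smiles, score))

    def __len__(self) -> int:
        return len(self.entries)


def replay_draw(
    buffer: ReplayBuffer, k: int, rng: np.random.Generator
) -> list[tuple[str, float]]:
    """k draws with replacement, probability proportional to the saved score.

    An empty buffer (or all-zero scores) yields an empty draw so that replay
    is silently skipped on the first iteration.
    """
    if not buffer.entries:
        return []
    scores = np.array([s for _, s in buffer.entries])
    total = scores.sum()
    if total <= 0:
        return []
    idx = rng.choice(len(scores), size=k, replace=True, p=scores / total)
    return [buffer.entries[i] for i in idx]


def augmented_likelihood(prior_loglik: float, s: float, m: float, sigma: float):
    """logP_aug = logP_prior + sigma * S(c) * M(c) (elementwise on arrays)."""
    return prior_loglik + sigma * np.asarray(s) * np.asarray(m)


def rl_loss(aug_loglik: float, agent_loglik: float):
    """Squared disagreement between augmented and agent likelihood."""
    diff = np.asarray(aug_loglik) - np.asarray(agent_loglik)
    return diff * diff


@dataclass
class IterationLog:
    iteration: int
    mean_s: float
    mean_m: float
    mean_aug: float
    n_valid: int
    n_high_score: int
    n_memory_rejected: int
    n_buckets: int
    loss: float


@dataclass
class RLRun:
    trajectory: list[IterationLog]
    records: pd.DataFrame  # iteration, smiles, canonical, s, m, agent_nll, prior_nll


def _score_batch(
    scorer: Callable[[MoleculeRecord], ScoreResult],
    records: Sequence[MoleculeRecord],
) -> np.ndarray:
    scores = np.zeros(len(records))
    for i, rec in enumerate(records):
        if not rec.is_valid:
            continue
        try:
            scores[i] = float(scorer(rec).value)
        except Exception as exc:  # scorer failure: score 0, keep going
            warnings.warn(f"scorer failed on {rec.canonical_smiles!r}: {exc}")
    return scores


def rl_step(
    agent: GeneratorModel,
    prior: GeneratorModel,
    scorer: Callable[[MoleculeRecord], ScoreResult],
    memory: Optional[MemoryUnit],
    buffer: Optional[ReplayBuffer],
    config: RLConfig,
    optimizer: Adam,
    sample_rng: np.random.Generator,
    replay_rng: np.random.Generator,
    iteration: int = 0,
) -> tuple[IterationLog, list[dict]]:
    """One RL iteration; mutates agent, memory and buffer. Returns log + rows."""
    batch = sample_batch(
        agent,
        config.batch_size,
        temperature=config.temperature,
        max_len=config.max_len,
        seed=sample_rng,
    )
    records = [canonicalize(s) for s in batch.smiles]
    scores = _score_batch(scorer, records)
    m_values = np.ones(config.batch_size)
    n_rejected = 0
    threshold = memory.config.score_threshold if memory is not None else None
    for i, rec in enumerate(records):
        if not rec.is_valid:
            scores[i] = 0.0  # invalid: S=0, M=1, never stored
            continue
        if memory is not None:
            m_values[i] = memory.score_and_update(rec, scores[i]).value
            if m_values[i] == 0.0 and scores[i] >= threshold:
                n_rejected += 1

    # replayed compounds bypass the memory (M taken as 1)
    replayed = replay_draw(buffer, config.replay_k, replay_rng) if (
        config.replay and buffer is not None
    ) else []
    sequences = list(batch.token_ids)
    all_s = list(scores)
    all_m = list(m_values)
    for smiles, score in replayed:
        try:
            seq = agent.vocabulary.encode(smiles)
        except ValueError:
            continue  # out-of-vocabulary replay entry
        sequences.append(seq)
        all_s.append(score)
        if config.replay_through_memory and memory is not None:
            rec = canonicalize(smiles)
            all_m.append(memory.peek(rec, score) if rec.is_valid else 1.0)
        else:
            all_m.append(1.0)

    pad = agent.vocabulary.pad
    padded = pad_sequences(sequences, pad)
    inputs, targets = padded[:, :-1], padded[:, 1:]
    prior_loglik = prior.loglik(padded)
    logits, cache = agent.forward(inputs)
    agent_loglik = _gather_loglik(logits, targets, pad)
    aug = augmented_likelihood(prior_loglik, np.array(all_s), np.array(all_m), config.sigma)
    losses = rl_loss(aug, agent_loglik)
    n_total = len(sequences)
    # d(mean squared difference)/d agent_loglik
    coeff = 2.0 * (agent_loglik - aug) / n_total
    grads = agent.backward_loglik(cache, targets, coeff)
    optimizer.step(grads)

    if buffer is not None:
        # store the sampled string (always tokenizable under the vocabulary)
        for i, rec in enumerate(records):
            if rec.is_valid:
                buffer.add(batch.smiles[i], float(scores[i]))

    n_batch = config.batch_size
    rows = [
        {
            "iteration": iteration,
            "smiles": batch.smiles[i],
            "canonical": records[i].canonical_smiles,
            "s": float(scores[i]),
            "m": float(m_values[i]),
            "agent_nll": float(batch.agent_nll[i]),
            "prior_nll": float(-prior_loglik[i]),
        }
        for i in range(n_batch)
    ]
    high = memory.config.score_threshold if memory is not None else 0.6
    log = IterationLog(
        iteration=iteration,
        mean_s=float(scores.mean()),
        mean_m=float(m_values.mean()),
        mean_aug=float(aug[:n_batch].mean()),
        n_valid=int(sum(r.is_valid for r in records)),
        n_high_score=int((scores >= high).sum()),
        n_memory_rejected=n_rejected,
        n_buckets=len(memory.buckets) if memory is not None else 0,
        loss=float(losses[:n_batch].mean()),
    )
    return log, rows


def run_rl(
    prior: GeneratorModel,
    scorer: Callable[[MoleculeRecord], ScoreResult],
    memory: Optional[MemoryUnit],
    config: RLConfig,
    agent: Optional[GeneratorModel] = None,
    out_dir=None,
) -> RLRun:
    """Full RL run: agent initialized from the prior, one step per iteration.

    Returns the per-iteration trajectory and a table of every generated
    compound with its scores. When ``out_dir`` is given, writes
    ``generated.tsv``, ``trajectory.tsv``, ``memory.json`` and an agent
    checkpoint there.
    """
    if agent is None:
        agent = prior.clone()
    optimizer = Adam(agent.params, lr=config.learning_rate)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    sample_rng = np.random.default_rng(seeds[0])
    replay_rng = np.random.default_rng(seeds[1])
    buffer = ReplayBuffer() if config.replay else None
    trajectory: list[IterationLog] = []
    all_rows: list[dict] = []
    for it in range(config.iterations):
        log, rows = rl_step(
            agent, prior, scorer, memory, buffer, config, optimizer,
            sample_rng, replay_rng, iteration=it,
        )
        trajectory.append(log)
        all_rows.extend(rows)
    columns = ["iteration", "smiles", "canonical", "s", "m", "agent_nll", "prior_nll"]
    records = pd.DataFrame(all_rows, columns=columns)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "generated.tsv", sep="\t", index=False)
        pd.DataFrame([vars(t) for t in trajectory]).to_csv(
            out / "trajectory.tsv", sep="\t", index=False
        )
        if memory is not None:
            (out / "memory.json").write_text(memory.to_json())
        save_model(agent, out / "agent")
    return RLRun(trajectory=trajectory, records=records)
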