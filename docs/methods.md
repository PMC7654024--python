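# Methods

## Model and procedure

### Generative model

The generator is an autoregressive SMILES language model: a token embedding
(default dimension 128), a stack of GRU layers (default 3 × 256 units) and a
linear head over the vocabulary. Tokenization treats bracket atoms (`[nH]`,
`[O-]`, …), two-letter halogens (`Cl`, `Br`) and two-digit ring closures
(`%nn`) as single tokens; the vocabulary is the lexicographically sorted token
set of the training corpus plus pad/start/end specials. Training minimizes the
negative log-likelihood of the corpus with Adam; the loss is masked so padding
contributes nothing. Sampling draws tokens from `softmax(logits / T)` until
the end token or a maximum length (default 140 tokens, generous for drug-like
corpora); the pad and start tokens are masked out of the sampling
distribution. The per-sequence NLL recorded at sampling time is always the
*untempered* (T = 1) model likelihood, so the RL arithmetic below is
independent of the sampling temperature.

The model, backpropagation through time and the Adam optimizer are
implemented directly in NumPy. The backward pass computes gradients of any
objective of the form Σᵢ wᵢ · log-likelihoodᵢ, which covers both maximum-
likelihood training (wᵢ = −1/N) and the RL loss (wᵢ = 2(log Pᵢ_agent −
log Pᵢ_aug)/N); it is verified against central finite differences in the test
suite (absolute agreement ≈ 1e−9 on float64).

### Reinforcement-learning loop

The agent starts as a parameter copy of the prior. Per iteration it samples a
batch (default 100 SMILES), which is canonicalized, scored by S(c), and passed
through the memory unit for M(c); the agent then takes one Adam step (gradient
clipped at global norm 3) on the mean of

    L(c) = ( log P(c)_prior + σ·S(c)·M(c) − log P(c)_agent )².

Invalid SMILES receive S = 0 and M = 1 and are never stored. σ defaults to 60.
A stated alternative formulation that *maximizes* the squared disagreement is
internally inconsistent (it would drive the agent away from its own target);
this implementation minimizes the disagreement, the established practice for
prior-anchored policy updates.

With experience replay enabled, every valid scored compound is appended to a
buffer and k = 8 entries are redrawn per iteration with probability
proportional to their saved score; their loss terms are added to the batch.
Replayed compounds are scored through the current memory *read-only*
(`RLConfig.replay_through_memory = True`): fixing M = 1 for replays instead
re-reinforces regions whose buckets are already saturated and, in the
desk-scale experiments, made memory+replay perform *worse* than memory alone
on most seeds — the opposite of replay's purpose of providing multiple
high-scoring restart points. The M = 1 behavior remains available as a flag.

### Memory unit

State is an ordered list of index–bucket pairs. String keys (BM scaffold,
carbon skeleton) match by exact equality with one bucket per key; fingerprint
keys (compound = ECFP4, fuzzy skeleton = atom pair on the carbon skeleton)
match the bucket with the highest Tanimoto similarity at or above the cutoff
(default 0.6), ties to the earliest-created bucket. Compounds scoring below
the score threshold (default 0.6) bypass the memory entirely. A matched
insertion is scored by the output mode at the fill *before* insertion; a new
bucket's seed compound is scored at fill 0 (1.0 for binary/linear, ≈0.9987
for sigmoid). A full bucket returns exactly 0 in every output mode. The
sigmoid mode is `1 − logistic((2·fill/size − 1)/0.15)`, midpoint exactly 0.5
at half fill.

Two deliberate semantics:

* **Duplicates consume slots.** Policy collapse typically manifests as
  repeated generation of the *same* compound; if duplicates did not fill the
  bucket, the strongest form of collapse would never be penalized (observed
  directly at desk scale: a fine-grained compound-similarity memory whose
  buckets never filled had no effect whatsoever on the run).
* **Acyclic molecules** (empty scaffold) map to a reserved empty-string key
  under all scaffold criteria, including fuzzy — an empty atom-pair
  fingerprint can never reach a similarity cutoff (the Tanimoto of two empty
  fingerprints is defined as 0), so without the reserved key acyclic
  compounds would evade the memory entirely.

Memory state serializes to JSON for checkpoint/resume; bucket count is
unbounded and nothing is evicted.

### Scoring functions

* **LogP range score**: 1.0 for Crippen AlogP ∈ [2, 3] (endpoints inclusive;
  the fall-off gives 1.0 there in either reading since tanh(0) = 0), else
  `1 − tanh(min(|2 − AlogP|, |3 − AlogP|))`. Continuous, equal to 1 on the
  interval, strictly decreasing in the distance to it, → 0 at extremes.
  AlogP is RDKit's Crippen atom-based implementation.
* **Bioactivity SVM**: molecules are encoded as count ECFP6 (radius 3) folded
  to 2048 dimensions by `feature_id mod 2048` with counts summed in colliding
  bins; the kernel is MinMax, Σ min / Σ max (equal to Tanimoto on 0/1
  vectors), computed via the identity Σ min = (|a|₁ + |b|₁ − ‖a − b‖₁)/2.
  The grid search covers C ∈ {10⁻⁵ … 10⁵} (exponent step 1) × {uniform,
  balanced} class weights, selected by validation MCC with ties resolved
  toward uniform weights and smaller C; the winner is refit with Platt
  scaling on an internal 5-fold split (scikit-learn's
  `CalibratedClassifierCV(..., method="sigmoid", cv=5, ensemble=False)`).

### Diversity analysis

Reports deduplicate on canonical SMILES and count unique Bemis–Murcko
scaffolds and carbon skeletons (skeleton ≤ scaffold ≤ compound counts hold by
construction). ECFP6 analogs use the count-form Tanimoto at cutoff 0.4
against the nearest reference neighbor. MMP fragmentation cuts every acyclic
single bond between heavy atoms exactly once, canonicalizes both fragments
with a `*` attachment atom, and keeps pairs where the core has at least twice
the side's heavy atoms (attachment excluded); analog counting is
per-generated-compound, not per (compound, core) pair. Butina clustering
ranks candidate centroids by neighbor count at the similarity cutoff (ties:
earlier input index) and greedily claims unassigned neighbors — implemented
in-package because the tie-break is pinned; RDKit's implementation (which
breaks ties toward the later index) serves as an independent cross-check on
separated data in the tests. The cluster-wise split sorts active clusters by
descending size and assigns each to the partition furthest below its target
active fraction (0.6/0.2/0.2); inactives are split at the same ratios
uniformly at random.

## Carbon-skeleton construction

Scaffold → all bond orders to single → all atoms to neutral carbon (charges
and radicals cleared, aromatic flags dropped, implicit hydrogens recomputed)
→ sanitize → canonicalize. This order avoids aromatic-valence failures; the
rare scaffold whose skeleton cannot be sanitized (e.g. a hypervalent center
that would become a >4-coordinate carbon) maps to the empty key.

## Synthetic fixtures and the desk-scale study

The fixture generator decorates 12 scaffold families — deliberately spanning
12 distinct ring systems (21 distinct carbon skeletons across the default
corpus) and AlogP ≈ 1–4 — with substituents drawn from a 26-fragment pool at
two attachment points, yielding a deduplicated, canonical, seed-deterministic
corpus (default 480 molecules). Generation asserts that the median
intra-family count-ECFP6 similarity exceeds the inter-family median. The
activity fixture labels the first *k* families active, with optional
independent label flips to emulate assay noise.

The desk-scale LogP study (used by the seeded experiment tests) mirrors the
transfer-learning design of the underlying optimization task: a toy prior
(embedding 32, 2 × GRU-64 — the full architecture stays the package default;
this configuration samples ≈83 % valid SMILES after 30 epochs at learning
rate 0.01) is fine-tuned for 20 epochs on the corpus' high-AlogP slice
(AlogP ≥ 3.5, its top decile) and then driven by RL — σ = 60, learning rate
0.005, 50 iterations × 50 SMILES, temperature 1.0 — back into the 2–3 band.
Under these conditions the no-memory baseline reproducibly exhibits policy
collapse (≈98 % of late high scorers fall on two scaffolds), the phenomenon
the memory unit is designed to break. Problem sizes are the package's chosen
desk-scale study conditions; the trends, not the absolute counts, are the
claims under test.

One fixture-driven calibration: the fuzzy-skeleton criterion keeps its 0.6
default in the memory unit, but the desk-scale experiment uses 0.8, because
in the deliberately narrow fixture space 28 % of skeleton pairs exceed
atom-pair Tanimoto 0.6 (median 0.50) and the default would lump most families
into a handful of buckets; 0.8 restores the discriminative percentile that
0.6 has in a full-scale drug-like corpus.

**What the fixtures do not emulate:** real corpora are vastly larger and more
heterogeneous (the fixture has 12 chemotype islands, not a continuum), real
bioactivity labels carry structure–activity cliffs rather than clean family
membership, and the toy prior underestimates both the validity and the
diversity of a full-scale prior. Passing the desk-scale experiments therefore
demonstrates the *mechanism* — reward vetoes redirect the policy and multiply
chemotype diversity — not the absolute magnitudes achievable on full-scale
data.

## Numerical choices and degenerate inputs

* Tanimoto of two empty fingerprints: 0.0 (empty molecules never match).
* MinMax kernel of two all-zero vectors: 0.0.
* Canonicalization never raises; unparseable or atom-free SMILES give an
  invalid record (empty canonical form, zero heavy atoms), which scores 0,
  is excluded from the memory, and is skipped (but counted) by the
  diversity reports.
* Replay from an empty (or all-zero-score) buffer is silently skipped.
* NaN training loss aborts with a diagnostic rather than continuing.
* All randomness flows from named substreams of a single seed
  (`numpy.random.SeedSequence`); sampling and replay use independent
  generators, and every experiment is reproducible byte-for-byte given its
  seed.

## Known limitations

* Single-cut MMPs only; no double/triple cuts, no maximum-common-substructure
  analog definition.
* The memory compares queries against bucket *index* (seed) structures only,
  not all members — cheap, but a drifting chemotype can seed several adjacent
  buckets under the similarity criteria.
* No eviction policy: very long runs grow the bucket table linearly.
* The NumPy generator targets desk-scale corpora; it is CPU-bound and not
  intended for million-compound training.
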