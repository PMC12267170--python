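# Methods

This note documents the models, parameter choices and numerical
conventions behind `slsim`, and the limits of what its synthetic
benchmark shows.

## What is being simulated

A three-hospital swarm-learning consortium for six-class knee-radiograph
classification (Schatzker-derived fracture classes A, B, C, D, the
intercondylar class K, and fracture-free controls).  The simulator keeps
the *protocol* faithful — round structure, leader rotation, masked
aggregation, screening, quorum commit, audit chain — and replaces the two
parts that cannot run at desk scale: clinical radiographs become seeded
synthetic images, and the detection-grade deep network becomes a tiny
deterministic reference classifier behind the same parameter-vector
contract.

## Synthetic radiographs

Each image is a 64 × 64 (configurable, minimum 32) grayscale field:
a tilted intensity gradient plus Gaussian noise (σ = 0.15) around a base
level of 0.55, clipped to [0, 1].  A fracture class adds one dark line
segment (intensity −0.45, width 1.5–2.5 px, half-length 0.55–0.8 of the
half-image) through a jittered centre (±10 % of the image).  The five
fracture classes own disjoint orientation bands — centres 0°, 36°, 72°,
108°, 144° with ±8° jitter — and controls carry no primitive at all.

These choices were fixed once, with one aim: the classes must be cleanly
learnable by a small linear model (the package's separability tests ask
for ≥ 0.9 held-out accuracy on a 600-image fixture) while noise keeps
accuracy off the ceiling so that data volume still matters.  No claim of
radiological realism is made; what transfers to real data is the protocol
behaviour (exact cancellation, tamper evidence, screening, the IID/non-IID
ordering), not the absolute accuracy values.

Determinism: `(label, seed, size)` fixes every pixel; cohort generation
seeds one stream per `(master seed, class, index)`, so enlarging one
class never reshuffles another.

## Cohorts, splits and shards

The packaged tables reproduce the study's printed cohort compositions
(3,027 / 377 / 377 / 800 patients; study total 4,581) and the three-node
training distribution in both regimes.  Splitting is stratified per class
with largest-remainder (Hamilton) rounding, ties to the lower part index;
`apportion(3026, [5, 3, 2])` reproduces the printed node headers
1,513 / 908 / 605 exactly.  The unbalanced regime assigns C and D to
node 1, B and K to node 2, A to node 3, and splits controls 907 : 325 : 410
— each fracture class exists at exactly one node.

Two printed inconsistencies are kept as printed and surfaced by
`tables.consistency_report()` rather than reconciled: the node table's
class-K total (94) versus the cohort table's 95 (so the node pool sums to
3,026 against a 3,027 cohort), and the external cohort's fracture types
summing to 392 although the cohort is described as 400 fractures plus 400
controls.  `external_composition()` rescales the printed fracture mix to
400 by largest remainder when the described 400/400 fixture is wanted.

Because the printed balanced node cells are a random sample rather than an
exact proportional split, no deterministic rounding reproduces them from
the ratios alone; `make_node_shards(..., class_node_counts=TABLE2_BALANCED)`
reproduces them cell by cell instead.

## Reference classifier

Multinomial logistic regression on 4 × 4 block-pooled pixels, normalized
with the fixed constants (x − 0.485) / 0.229 — 1,542 parameters at the
64 × 64 default.  Training is minibatch SGD (batch 16) with momentum 0.937
and weight decay 5 · 10⁻⁴; the default learning rate is 0.02, chosen so
the model converges within a 30-round desk budget (0.01, the value natural
for a deep network under a cosine schedule over 100 epochs, demonstrably
under-converges here; no schedule is used because round-based training
resets the epoch counter anyway).

Two deliberate conventions make the protocol exactly composable:

* the shuffle of global epoch *t* is seeded by `(seed, node, t)` and is
  independent of manifest file order (records are sorted by id first);
* momentum buffers reset at each epoch boundary, so training E epochs in
  one call is bit-identical to E chained single-epoch calls.

Together these give the protocol-collapse guarantee: a one-node swarm
with masking off equals plain local training equals the centralized
baseline, bit for bit, under shared seeds.

## Secure aggregation

Pairwise antisymmetric masking, the standard secure-aggregation
construction, realises the study's (otherwise unspecified) "single
encoding aggregation" consistently with its Diffie-Hellman pair keys.
Each ordered pair derives a shared secret by modular exponentiation
(demo group: the 64-bit safe prime 18446744073709550147 with generator 2;
tests also use the hand-checkable p = 23, g = 5), hashes it to a 64-bit
seed, and expands `(seed, round)` to a mask vector.  Node *i* adds masks
for higher-indexed peers and subtracts them for lower-indexed ones, so the
masks cancel in the sum.

Fixed-point mode (default) quantizes values at 2²⁰ into int64 and draws
integer masks bounded by 2⁴⁰ — sums of six nodes stay far inside int64,
making cancellation *exact*.  Float mode uses Gaussian masks (σ = 32) and
cancels to ≈ 10⁻⁶.  The fixed-point quantization is applied whether or not
masking is on, so masked and unmasked fixed-point trajectories are
bit-identical.  This is a protocol simulator: the group sizes and seed
handling make no cryptographic-strength claim.

Screening needs plain update geometry, which masking deliberately hides;
following the design in which screening and quorum run over digests all
nodes can recompute, the simulator screens the plain updates first and the
kept nodes then mask among themselves (so cancellation holds over the kept
set).  A missing declared participant leaves a non-cancelling residual and
aborts aggregation with the node named.

## Ledger and consensus

One block per committed round: SHA-256 over the previous hash plus a
canonical (key-sorted, whitespace-free) JSON payload holding round, leader,
participants, kept/rejected sets, the aggregate digest, a metrics snapshot
and the votes.  Consensus is a one-shot quorum — commit iff affirmative
votes ≥ ⌊2n/3⌋ + 1 — standing in for PBFT without view changes or
networking.  Only digests go on-chain, never parameters.  Verification
recomputes every hash and link and reports the first violating index; a
mutation to block *k* surfaces at *k*, and re-hashing *k* after tampering
moves the break to *k* + 1.

## Protocol round and baselines

Defaults follow the study's stated experimental protocol: one local epoch
per round (the alternative batch-frequency/local-update-step settings are
exposed in `SwarmConfig` but unused, since the two descriptions conflict
and the experiment section's "one epoch per round" is the operative one),
minimum participation 3, screening factor 5, 100 rounds nominal — desk
experiments use 30.  Aggregation weights are local sample counts (the
Fed-Avg standard; the study does not state weights).  Leader election is a
PRNG seeded by the chain head, the round index and the sorted node ids;
the leader holds no special trust.  Commit failure retries once, then the
round aborts.  Best checkpoint: highest global-validation accuracy,
earliest round on ties.

The centralized baseline trains one site on the pooled training set for
the same number of epochs as the swarm has rounds, with per-epoch
best-checkpoint selection; local-only baselines are the same routine on a
single shard.  All three consume the identical validation set, so the
comparison isolates the data-distribution effect.

## Evaluation

One-vs-rest per class: sensitivity, specificity, precision, F1, AUROC
(trapezoid over the tie-grouped ROC; equal to the Mann-Whitney rank
statistic with ties at one half), and step-interpolated average precision;
macro averages over classes, with the macro-AP named `map_macro` because
no detection-style box overlap is involved.  A class absent from the truth
reports NaN (missing), never zero, and macro averages skip missing
entries.  Youden's operating point maximizes sensitivity + specificity − 1
with ties resolved to the lowest threshold.  Cohen's kappa returns NaN for
degenerate marginals.  Repeat tables report mean (SD) over 5 re-seeded
runs by default, mirroring the study's five-iteration scheme (re-seeded
runs, not CV folds, since the study is ambiguous between the two).

## Desk-scale experiment conditions

The comparative experiment draws a 750-image pool with the training
cohort's class mix (≈ 54 % controls), splits 8:1:1 (599–600 training
images), and runs 30 rounds.  Under these fixed conditions the simulator
reproduces the study's qualitative findings: the swarm model beats every
local-only model on class-exclusive shards, stays within a few points of
the centralized baseline, balanced shards perform at least as well as
unbalanced, and a ×1000 poisoning node is screened out every round with
negligible effect on the final model.

## Known limitations

* Synthetic lesions are linearly separable by construction; absolute
  accuracies say nothing about radiographs.
* The reference learner is convex; Fed-Avg's behaviour on deep networks
  (client drift, permutation symmetry) is not exercised.
* Consensus is simulated in-process: no asynchrony, network faults, view
  changes, or Byzantine voting strategies beyond update scaling.
* Masking is not dropout-resilient (no secret sharing): a node that
  vanishes mid-round aborts the aggregate rather than being recovered.
* The patient/image distinction is not modelled; one image is one subject.
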