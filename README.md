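# slsim — swarm learning for fracture-image classification, at desk scale

`slsim` is a faithful, fully offline simulator of a blockchain-coordinated
**swarm-learning (SL)** system of the kind used for multi-hospital
tibial-plateau-fracture (TPF) diagnosis from knee radiographs.  Three
"hospital" nodes hold disjoint image shards and never share data; each
round they train locally, exchange **masked** parameter updates, and a
dynamically elected leader aggregates them by sample-weighted federated
averaging (Fed-Avg), with every round committed to a hash-chained audit
ledger by quorum vote.

It is written for researchers who want to study the *protocol* — non-IID
robustness, secure aggregation, poisoning defenses, auditability — without
clinical data or GPUs: a seeded synthetic radiograph generator reproduces
the study-design conditions (six Schatzker-derived classes A/B/C/D/K plus
fracture-free controls, an 8:1:1 train/validation/test split, and a 5:3:2
three-node apportionment in balanced/IID and unbalanced/non-IID regimes),
and everything downstream runs in seconds on one CPU.

## The protocol

Per round *r*, with global parameters **w**ᵣ and node shards *D₁…Dₙ*:

1. **Leader election** — leader = PRNG(hash(ledger head ‖ r ‖ node ids)),
   uniform over nodes and recomputable by every participant.
2. **Local training** — each node runs one epoch of minibatch SGD
   (momentum 0.937, weight decay 5·10⁻⁴) on its shard:
   **w**ᵢ = SGD(**w**ᵣ, *Dᵢ*).
3. **Screening** — update *uᵢ* is rejected iff
   ‖*uᵢ* − med‖₂ > 5 · medianⱼ‖*uⱼ* − med‖₂ (med = coordinate-wise median);
   rounds abort if fewer than 3 nodes remain.
4. **Secure aggregation** — Diffie-Hellman pair secrets seed antisymmetric
   masks: node *i* submits *nᵢ***w**ᵢ + Σⱼ₍ⱼ≠ᵢ₎ ±m(sᵢⱼ).  The masks cancel
   in the sum, so the leader sees only Σᵢ *nᵢ***w**ᵢ, never an individual
   update.  In fixed-point mode (2²⁰ scaling) cancellation is bit-exact.
5. **Fed-Avg** — **w**ᵣ₊₁ = Σᵢ *nᵢ***w**ᵢ / Σᵢ *nᵢ*.
6. **Commit** — the round record (leader, participants, aggregate digest,
   metrics, votes) appends to the SHA-256 hash chain iff affirmative votes
   reach the PBFT-style quorum ⌊2n/3⌋ + 1.

The best checkpoint is chosen by global-validation accuracy.  Baselines
(`run_centralized`) train one site on everything, or each node on its own
shard only, under the identical schedule — the comparison the study design
is built around.

## Worked example

```python
from slsim import (generate_cohort, PartitionSpec, split_train_val_test,
                   make_node_shards, SwarmModel, SwarmConfig, TrainConfig,
                   run_centralized)
from slsim.tables import scaled_composition

pool = generate_cohort(scaled_composition(750), seed=0)      # 750 images, study class mix
spec = PartitionSpec(seed=0, mode="unbalanced")              # non-IID: class-exclusive shards
train, val, test = split_train_val_test(pool, spec)          # 8:1:1, stratified
shards = make_node_shards(train, spec)                       # 3 nodes, 5:3:2

result = SwarmModel(shards, val, train_config=TrainConfig(seed=0),
                    config=SwarmConfig(n_rounds=30, seed=0)).fit()
print(result.summary())
print("global test accuracy:", round(result.accuracy(test), 4))

central = run_centralized(train, val, train_config=TrainConfig(seed=0), epochs=30)
print("centralized test accuracy:", round(central.accuracy(test), 4))
```

prints

```
Swarm learning run
==================
nodes:            3
rounds:           30
masking:          on (fixed-point)
best round:       15  (val accuracy 0.9870)
final val acc:    0.9870
rounds w/ reject: 0
ledger verified:  True
global test accuracy: 0.9459
centralized test accuracy: 0.9865
```

Even though node 3 only ever saw class A and controls (`shards[2]` holds
nothing else), the collaborative model classifies all six classes at
accuracy close to the centralized baseline — while each node's data never
left it, every exchanged update was masked, and the full round history
survives in a tamper-evident ledger (`result.ledger.save("ledger.jsonl")`,
`slsim ledger-verify ledger.jsonl`).

The same comparison over repeated seeds, with metric tables in the
published schema (accuracy / recall / specificity / precision / F1 / AUROC
as mean (SD)):

```bash
slsim report --seed 0 --out run/ --repeats 5 --rounds 30
```

## Layout

| module | contents |
| --- | --- |
| `slsim.synth` | seeded six-class radiograph generator, cohort manifests |
| `slsim.tables` | the study's printed cohort/node tables + consistency checks |
| `slsim.partition` | largest-remainder apportionment, 8:1:1 split, node shards |
| `slsim.preprocess` | long-side resize, letterbox, ROI crop, seeded augmentation |
| `slsim.classifier` | parameter-vector contract + tiny softmax reference learner |
| `slsim.secure` | Diffie-Hellman key agreement, pairwise antisymmetric masking |
| `slsim.ledger` | hash-chained blocks, PBFT-style quorum commit, verification |
| `slsim.swarm` | `SwarmModel` / `SwarmResults`, leader election, Fed-Avg, screening |
| `slsim.metrics` | confusion stats, ROC/Youden, PR/AP, Cohen's kappa, tables |
| `slsim.experiments` | one-config comparative experiment bundles |
| `slsim.cli` | the `slsim` command (`synth`, `split`, `train-*`, `report`, …) |

See `docs/methods.md` for the model assumptions, parameter choices, and
what the synthetic benchmark does and does not demonstrate.
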