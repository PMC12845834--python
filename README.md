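# ntfold

Attention-based RNA secondary structure prediction: from a nucleotide sequence
to a valid base-pair contact map, pseudoknots included.

## The problem

The secondary structure of an RNA — the set of base pairs it forms — controls
its folding, stability and function.  Classical predictors minimise a
thermodynamic free energy with dynamic programming, which restricts them to
nested (pseudoknot-free) structures.  `ntfold` instead treats prediction as a
contact-map problem: for a sequence of length *L*, predict the symmetric
binary matrix *M* ∈ {0,1}^(L×L) with *M[i,j]* = 1 iff nucleotides *i* and *j*
pair.  Because the decoder works on the matrix directly, crossing pairs
(pseudoknots) cost nothing extra.

The pipeline has three stages:

1. **Nucleotide attention.**  Each residue is embedded as a learned vector
   *e_i* plus a fixed sinusoidal positional encoding *p_i*, giving
   *z_i = e_i + p_i*.  Multi-head scaled dot-product attention
   *A_h = softmax(Q_h K_hᵀ / √d_h)* over *Z* yields per-head L×L maps, and the
   head average *C = (1/H) Σ_h A_h* is a row-stochastic correlation map whose
   entry (i, j) estimates the pairing propensity of the two positions.
2. **Structural refinement.**  A small U-Net over *C* (2× max-pool per level
   down, nearest-neighbour up, concatenation skips) suppresses noise and
   reinforces the anti-diagonal stem lines; a final logistic plus
   symmetrisation yields a contact-probability map *C_refined* ∈ [0,1]^(L×L).
3. **Constrained decoding.**  A soft threshold
   *C̃ = soft_sign(C_refined − s) ⊙ C_refined* suppresses weak entries; a
   Lagrangian loop with one multiplier per nucleotide pushes the relaxed map
   toward the evidence while penalising row sums above one; a greedy matcher
   then emits a binary map guaranteed to satisfy symmetry, pairing exclusivity
   (each nucleotide in at most one pair), the minimum-loop/legality mask and a
   zero diagonal.

Stages 1–2 are trained jointly with weighted binary cross-entropy against true
contact maps; the decoder is untrained post-processing.  Predictions are
scored by exact base-pair precision, recall and F1 = 2·P·R/(P+R).

The package ships a synthetic generator (hairpins, tRNA-like cloverleafs,
H-type pseudoknots, with wobble pairs and sequence mutation noise) so every
stage is testable without external data, plus readers/writers for FASTA, CT,
BPSEQ and pseudoknot-layered dot-bracket.

## Worked example

Train the default tiny model (d=64, H=4 heads, depth-2 U-Net) on 500 noisy
synthetic hairpins and predict held-out ones:

```python
import ntfold as nf
from ntfold.train_eval import TrainConfig, predict

spec = nf.FamilySpec("hairpin", mutation_rate=0.02)
train_set = nf.make_dataset(500, {"hairpin": 1}, {"hairpin": spec}, seed=11)
test_set = nf.make_dataset(5, {"hairpin": 1}, {"hairpin": spec}, seed=12)
ckpt = nf.train(train_set, cfg=TrainConfig(epochs=30, seed=7))
print(f"final training loss: {ckpt.loss_history[-1]:.4f}")
for seq, truth in test_set:
    ss, _ = predict(seq, ckpt)
    r = nf.evaluate(ss, truth)
    print(f"{seq.id}  L={seq.L:2d}  {nf.write_dotbracket(ss)}  F1={r.f1:.2f}")
```

Output (about a minute on one CPU):

```
final training loss: 0.0285
hairpin_0000  L=28  ((((((((((........))))))))))  F1=1.00
hairpin_0001  L=27  ((.(((.((((.....).))))).)))  F1=0.42
hairpin_0002  L=20  ((((((((....))))))))  F1=0.86
hairpin_0003  L=19  (((((((.....)))))))  F1=0.93
hairpin_0004  L=18  ((((((......))))))  F1=0.92
```

The model has learned to place the stem (paired brackets closing around an
unpaired loop); per-sequence F1 counts exactly matching base pairs, so a stem
shifted by one position scores 0 for those pairs — record 0001 shows a
partially mis-registered stem.  Mean held-out F1 over 100 such hairpins is
≈ 0.93–0.95 depending on the seed.

The same pipeline is available from the shell:

```sh
ntfold simulate --family mix --n 100 --seed 3 --out-dir data
ntfold train --data data --out model.ckpt
ntfold predict --ckpt model.ckpt --input data/hairpin_0001.fasta --out-dir preds
ntfold evaluate --pred preds --truth data --out metrics.tsv
ntfold decode --scores scores.tsv --seq seq.fasta --out pred.ct   # standalone decoder
```

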