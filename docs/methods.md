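# Methods

This note documents the model, the numerical choices, the synthetic data the
package is validated on, and the limits of what those validations show.

## Model

### Encoder: nucleotide attention

A sequence over the alphabet {A, U, G, C, N} is embedded per residue as
*z_i = E[x_i] + p_i*, where *E* is a learned |V|×d table (N gets its own
learned row) and *p* is the standard fixed sinusoidal positional encoding
*p[i, 2t] = sin(i / 10000^(2t/d))*, *p[i, 2t+1] = cos(i / 10000^(2t/d))*.
The sinusoidal form is deterministic, depends only on the position index, and
extrapolates to lengths unseen in training.

Each of *H* attention heads projects *Z* with learned d×d_h matrices to
queries, keys and values, and computes *A_h = softmax(Q_h K_hᵀ / √d_h)*.
The correlation map is the head average *C = (1/H) Σ_h A_h*.  *C* is
row-stochastic and in general asymmetric; symmetry is a structural constraint
and is imposed downstream (refiner output, decoder iterates), not here.

Defaults: d = 64, H = 4, d_h = 16 (d = H·d_h).  These are deliberately small:
with them the full benchmark (three model variants, 500 training sequences,
30 epochs) trains in a few minutes on one CPU.  A single attention layer is
used; the value path exists in the API (`attention_head` returns the context
vectors) but only *C* feeds the refiner.

### Refiner: U-Net over the map

The refiner treats the L×L map as an image.  Level *k* of the encoder path is
`ConvBlock_k(Down(F_{k-1}))` with `F_0` the input; the decoder path is
`ConvBlock'_k(Up(G_{k-1}) ‖ F_{n-k})` with concatenation skips.  Blocks are
two 3×3 convolutions with ReLU; Down is 2×2 max-pooling; Up is
nearest-neighbour.  A final 1×1 convolution, logistic squashing and
symmetrisation (X + Xᵀ)/2 produce the refined map in [0,1].

Inputs are zero-padded on the right/bottom to the next multiple of 2^n and
cropped back after decoding, so any L ≥ 1 is accepted.  By default the
single-channel map is stacked with two coordinate channels (normalised row and
column index over the padded grid); stems are anti-diagonal line segments
whose position relative to the diagonal encodes pairing distance, and the
coordinate channels let a small network express that position dependence.
This can be switched off (`use_coords=False`).

Defaults: depth n = 2, base 16 channels (16 then 32 on the encoder path).
Deeper or wider settings are configurable but unnecessary at the lengths the
generator produces.

### Decoder: constrained binarisation

Three steps convert the refined map into a valid structure:

1. `threshold_map`: C̃ = soft_sign(C_refined − s) ⊙ C_refined with
   soft_sign(x) = 1/(1 + e^(−κx)).  Entries well below the sparsity threshold
   *s* shrink toward zero; entries well above pass nearly unchanged.  C̃ is
   elementwise non-increasing in *s*.
2. `lagrangian_decode`: starting from A = sym(C̃ ⊙ mask), λ = 0, iterate
   T times

       G = A ⊙ [λ_i · soft_sign(Σ_j A_ij − 1) − ½ C̃]
       A ← clip(A − η G, 0, 1), re-mask, re-symmetrise
       λ ← λ + η_λ · ReLU(Σ_j A_ij − 1)

   The evidence term (−½C̃) grows entries supported by the scores; the
   multiplier term shrinks rows claiming more than one partner.  λ is one
   multiplier per nucleotide (the constraint is per-row), broadcast across the
   row.  Clipping, masking and symmetrising every iterate keeps A
   interpretable as pair probabilities and guarantees the binariser's
   preconditions regardless of step sizes.
3. `binarize`: upper-triangle cells with A above the binarisation cut and an
   open mask are accepted greedily in descending score order (ties broken by
   smaller i, then j), skipping cells whose endpoints are taken.

The hard guarantees — symmetry, pairing exclusivity, mask compliance, zero
diagonal — are enforced by the greedy matcher, never assumed from convergence
of the relaxation.  The legality mask requires |i − j| ≥ min_sep (default 4,
i.e. at least 3 unpaired residues between partners) and can optionally
restrict to canonical + wobble pairs ({AU, UA, GC, CG, GU, UG}; N never pairs
in that mode).  `canonical_only` defaults to off so non-canonical interactions
found by the model are kept.

Defaults: s = 0.5, κ = 10, η = η_λ = 0.01, T = 100, bin_threshold = 0.5.
With a strong planted signal (0.95) over weak background (≤ 0.05), these
defaults recover the exact pair set: the background is gated to ≤ 6·10⁻⁴,
planted entries grow along the evidence term and saturate at 1, and the
matcher reads them off.

`brute_force_decode` enumerates all matchings over the candidate cells
(branch-and-bound, L ≤ 12) and is used in tests as the exact maximum-weight
reference.  Greedy matching does not always equal maximum-weight matching:
whenever the top candidate conflicts with two disjoint lower candidates whose
weights sum past it, greedy takes the single top pair.  On uniform random
8×8 maps this affects a few percent of instances; the tests assert the exact
statements — oracle weight dominates greedy weight always, and the pair sets
coincide whenever greedy never skips a conflicting candidate.

A related regime effect: the number of decoded pairs is **not** globally
monotone in the sparsity threshold *s*.  On dense random maps, low *s* admits
many competing candidates, row sums exceed one and the growing multiplier
suppresses all of them; high *s* leaves a lone candidate that no multiplier
opposes.  On contact-like maps (strong sparse signal, weak background) the
count is monotone, and that is the regime the test asserts.

### Training

Encoder and refiner are trained jointly by Adam (lr 10⁻³) on a weighted
binary cross-entropy over upper-triangle cells with j − i ≥ min_sep,
comparing C_refined against the true contact map.  Paired cells are
up-weighted (default pos_weight = 10) because a structure has ~L/2 positive
cells out of ~L²/2.  Sequences are bucketed by length and batched within a
bucket (default 16), which avoids padding and masking inside attention.
The decoder never receives gradients: the refined map is the model's
structural estimate and decoding is post-processing.

All networks are NumPy with hand-written analytic backprop; the gradients are
verified against central finite differences in the test suite (relative
agreement better than 10⁻³, typically 10⁻⁶).  Training with a fixed seed is
bitwise reproducible on a given platform.

Two ablation switches exercise the pipeline without one component:

- `no_attention`: the correlation map is replaced by the logistic
  outer-product map σ(z_i·z_j / √d) computed from the embeddings alone.  The
  √d scaling keeps the logistic away from saturation at initialisation; only
  the embedding table is trained in this mode.
- `no_refiner`: refinement becomes logistic squashing + symmetrisation of C.
  Because rows of C sum to one, the squashed map lives in [0.5, 0.73] and
  carries little contrast — the variant trains end to end but performs poorly,
  which is the point of the comparison.

## Synthetic data

The generator emulates the structural phenomena a contact-map predictor must
handle, not the thermodynamics of any real family:

- **hairpin** — one stem of k pairs around a loop of m ≥ 3 unpaired residues;
- **cloverleaf** — a closing stem around three stem-loops joined by linkers
  (≥ 1 nt), fully nested, tRNA-like topology;
- **pseudoknot** — H-type: stem 1 pairs region A with C, stem 2 pairs B with
  D, A < B < C < D, so all k₁·k₂ pair combinations cross.

Stems are complementary under Watson–Crick pairing with probability
`gu_fraction` (default 0.1) of a G–U wobble per position.  Loops and linkers
are uniform over {A, C, G, U} so base composition alone carries no structural
signal.  `mutation_rate` applies per-residue random substitutions to the
sequence *after* construction while the structure label keeps the
pre-mutation truth, emulating an imperfect pairing signal.  Default ranges
(stems 4–10, loops 3–8) give hairpins of L ≈ 11–28; `compact_specs()`
provides per-family ranges that cap all three families at L ≤ 60.  Every
generated pair satisfies j − i ≥ 4, so generated truths are always reachable
under the default decoder mask.

What passing tests on these data do **not** show: performance on real RNA
families with non-canonical pairs, modified nucleotides, long-range tertiary
contacts, or lengths in the hundreds; robustness to the family imbalance and
annotation noise of curated corpora.  The benchmark here demonstrates that
the pipeline can learn and recover planted structure, not that it rivals
field predictors on community benchmarks.

## Benchmark conditions

The learning benchmark trains on 500 hairpins with mutation_rate 0.02
(L ≤ 40), evaluates on 100 held-out hairpins from a different seed, 30
epochs, and compares the full model with both ablations and with the
untrained network.  Metrics are exact-match base-pair precision/recall/F1
(no ±1 slippage tolerance), macro-averaged over sequences.  Typical results:
trained mean F1 ≈ 0.93–0.95, untrained 0.0, no-attention ≈ 0.6–0.85,
no-refiner ≈ 0.03.  The no-attention spread across seeds is large because the
outer-product map is a much weaker evidence source and its training is less
stable; the ordering full ≥ ablated has held in every run.

## Numerical and format choices

- Internal coordinates are 0-based; CT, BPSEQ and dot-bracket are 1-based on
  disk.  Conversion happens only at the I/O boundary.
- T → U and lowercase → uppercase at ingest; any residue outside
  {A, C, G, U, T, N} is an error with position.
- Dot-bracket uses layers ( ), [ ], { }, < >; the writer assigns each pair
  greedily to the lowest layer where it crosses nothing already placed
  (pairs processed in ascending i), canonicalising layer assignment; more
  than 4 layers is an error.  Round-trips preserve the pair set.
- CT titles are written as "L id"; on parse everything after the first token
  of the header line is the title.
- Logistics are computed in the numerically stable two-branch form; the BCE
  clips probabilities to [10⁻⁷, 1 − 10⁻⁷].
- Checkpoints are a single `.npz` container with a JSON header (shapes,
  config, loss history, config hash).

## Known limitations

- Single attention layer and no padding/masking inside attention: batches
  must be length-homogeneous (the trainer buckets by length automatically).
- The Lagrangian reading of the update direction follows the package's
  documented interpretation (evidence ascent + row-sum penalty); alternative
  gradient forms can be swapped in one function (`lagrangian_decode`).
- Greedy binarisation is O(L² log L) and constraint-safe but not
  maximum-weight; the exhaustive reference is exponential and test-only.
- CPU-only by design; lengths beyond ~500 make the L×L refiner the
  bottleneck.
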