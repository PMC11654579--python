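# Methods

## Problem and model

`captox` classifies short peptides (≤ 50 standard residues) as toxic or
non-toxic from sequence alone. Toxicity corpora are imbalanced (roughly
1:2.5 toxic:non-toxic after curation), and the discriminative signal is a
mixture of short local patterns and longer-range context, so the encoder
combines two complementary residual blocks over learned token + position
embeddings `X ∈ R^{L×d}`:

**Convolutional modulation.** A depthwise (per-channel) 1-D convolution of
one linear projection gates a second projection elementwise:

    A = DConv_k(X W1),   V = X W2,   Z = A ⊙ V.

Each output position aggregates the residues in the window of width `k`
centred on it, giving the encoder locality and single-residue sensitivity
that plain dot-product attention lacks. The kernel length `k` is forced
odd so the window is genuinely centred; the convolution is zero-padded to
'same' length, and masked (padding) rows are zeroed before and after the
convolution so padding can never leak into real positions.

**Multi-head self-attention.** Standard scaled dot-product attention,
`S = softmax(QKᵀ/√d_k)`, `out = SV`, with padded key columns excluded from
each softmax (forced to −∞ pre-softmax). The `1/√d_k` scale is applied for
numerical stability even in configurations where it matters little at
`d_k = 16`.

Both block kinds use post-layer-norm residual wiring and a GELU
feed-forward sublayer with expansion factor 4. Convolutional block(s)
precede attention block(s) by default; the order is configurable
(`encoder_order`) so the composition itself can be ablated. Max pooling
over unmasked rows summarises the `L×d` feature matrix (min / mean /
attention / CLS pooling are selectable; the CLS token, index 21, is
prepended only when CLS pooling is chosen, since it is dead weight
otherwise). A two-logit softmax head yields `P(toxic)`; hard labels use
threshold 0.5.

The vocabulary is fixed and published so checkpoints are portable:
`A..Y → 1..20` alphabetically, `PAD = 0`, `CLS = 21`.

## Training objective

The loss is binary cross-entropy plus a batch supervised contrastive term
on the pooled representations. For a pair with cosine distance
`D = 1 − cos(Z1, Z2)` and pair label `y = 1` when the two peptides come
from **different** classes:

    L_pair = ½ (1−y) D² + ½ y max(D_max − D, 0)³,    D_max = 1.5.

Same-class pairs are pulled together quadratically; cross-class pairs are
pushed toward the margin with a cubic penalty that weights hard pairs
heavily — this is what protects minority-class (toxic) recall under
imbalance. Two implementation choices deserve note:

* **Clamping.** Cosine distance ranges over [0, 2] while the margin is
  1.5, so the raw cubic term can go negative for well-separated pairs; the
  shortfall is clamped at zero, which leaves the loss unchanged on
  `D ≤ D_max` and guarantees non-negativity.
* **Pair reduction.** All unordered pairs within a batch contribute, mean
  reduced. A single-class batch degrades gracefully to same-class pairs
  with a logged warning.

Total loss = `BCE + λ · mean pair loss` with `λ = 1` by default. Training
is Adam (lr 1e-3, batch 64, 16 epochs) with a cosine learning-rate decay
to lr/10 across the run — the decay calms the late-epoch threshold jitter
that a constant rate leaves in MCC — plus optional early stopping on
validation MCC; everything is seeded and single-threaded, so runs are
bit-for-bit reproducible. These optimisation defaults, like the
architecture defaults (`d = 64`, 4 heads, 1 conv + 1 attention block,
dropout 0.1), are the package's own choices and are serialised into every
checkpoint and run manifest so they are always auditable.

The network runs on an in-repo reverse-mode autodiff engine over numpy
arrays (`captox._autodiff`): a deliberately small tape machine whose every
operator gradient is finite-difference checked in the test suite. This
keeps the package dependency-light and CPU-native; the cost is speed, so
default problem sizes are desk scale (minutes, not hours).

## Dataset curation

The curation pipeline mirrors how a toxicity corpus is assembled from
multiple labelled sources: concatenate sources verbatim (duplicates
retained so conflicts can be detected), remove **every** copy of any
sequence that appears with both labels, deduplicate exact copies (first
occurrence wins), reduce redundancy at 0.9 identity, and split 85/15 per
class. The test set receives exactly `floor(0.15·N)` records per class —
on class totals 2138/5375 this yields 320/806 test and 1818/4569 train,
which is the arithmetic the acceptance checks exercise.

The redundancy reducer is a greedy longest-first clusterer (ties broken
lexicographically): a sequence joins the first representative it matches
at ≥ threshold identity, where identity is matches over the shorter length
in an ungapped, zero-offset comparison. This is an acknowledged
approximation of CD-HIT-style clustering — no gapped alignment, no word
filtering — chosen for exact reproducibility without a compiled
dependency; a hook shells out to a `cd-hit` binary when one is on PATH,
but the internal method is the tested default.

## Metrics

SN, SP (percent), BACC = (SN+SP)/2, and MCC computed in closed form from
the confusion cells; AUC is rank-based (Mann–Whitney with mid-ranks, via
scikit-learn). Printed values are rounded half-up (2 dp for percentages,
3 dp for MCC) to match table conventions; raw values are always carried
alongside. When an MCC marginal is zero the value is reported as 0 with a
degeneracy flag. `reconstruct_confusion` inverts printed SN/SP percentages
back to the unique integer confusion cells on a known test composition and
errors if the inversion is not unique — this is what lets published
metric tables be re-derived arithmetically rather than trusted.

Cross-validation reports per-fold metrics, their arithmetic mean, and the
pooled metrics (all held-out predictions scored together), since the two
aggregations genuinely differ and published tables rarely say which was
used.

## Interpretation suite

* **ISM.** Every residue is substituted by the 19 alternatives and the
  absolute change in `P(toxic)` recorded (batched forward passes; the
  batched sweep is tested equal to one-at-a-time recomputation). The
  self-substitution cell is 0. Per-position scores are the mean over the
  19 substitutions — the mean rather than the sum so the score is
  invariant to the substitution count.
* **Amino-acid contributions** credit each position's score to the
  reference residue sitting there (crediting the substituting residue is
  available as `attribution="target"`), then average per class, with the
  class amino-acid composition as the natural reference vector.
* **Position-ratio profiles.** Positions map into 10 length-normalised
  bins via `bin = min(⌊(p−1)·10/L⌋+1, 10)`; sequences shorter than 10
  residues occupy alternating bins (L=5 → bins 1,3,5,7,9), and empty bins
  are reported absent, not zero. Per-bin means and variances of pooled
  position scores show which regions drive predictions.
* **The 20×10 residue-by-region map** is the mean position score per
  (reference residue, bin) cell, min-max normalised over occupied cells;
  the normalisation is a presentation choice, stated here because the
  underlying statistic could equally be reported raw.
* **Clipping scans** truncate `round(r·L)` residues (round-half-up) from
  the front, back, or `round(r·L/2)` from each end, never below one
  residue (the central residue survives extreme both-end clipping), and
  re-measure BACC/MCC per ratio. Ratio 0 reproduces the untruncated
  evaluation exactly.

## Synthetic corpus generator

The generator emulates the statistical shape of a curated toxicity corpus
without imitating toxin biology: lengths uniform on 5–50, uniform
background composition (a natural-composition preset exists), a 1:2.5
class imbalance (570 toxic / 1425 non-toxic by default), and short planted
motifs that make the toxic class learnable and localisable — `WKKR` in
position-ratio bin 1 (head) and `CCHF` in bins 5–6 (center), each present
with probability 0.6 and corrupted at mutation rate 0.03 per residue.
Placement minimises spill: the whole motif sits inside the region's bins
whenever the sequence is long enough, and otherwise takes the tightest
achievable position (short sequences have bins narrower than a motif).
Every toxic peptide is guaranteed at least one motif; insertion
probabilities are deliberately below 1 because if nearly every positive
carried both motifs, either one alone would be redundant for a max-pooling
classifier and mutagenesis would under-attribute it. Region placement
reuses the same binning function as the interpretation suite, so recovery
tests are self-consistent by construction.

What passing the recovery study shows — and does not show. The study
(`captox.workflows.motif_recovery_study`) trains on 85% of such a corpus
for a fixed 16-epoch budget and verifies that held-out MCC is high, that
the ISM position-ratio profile ranks the planted head/central bins at the
top, and that forward clipping degrades BACC faster than backward
clipping. This demonstrates the machinery end to end: the optimiser
trains the encoder, and the interpretation stack localises signal where
it was planted. It does not demonstrate performance on real peptides,
whose discriminative signal is weaker, compositional, and confounded with
length and composition; real corpora are expected to need more epochs,
regularisation tuning, and give lower ceilings.

The companion ablation (`contrastive_ablation_study`) targets the
early-training window on a 1:9 corpus where cross-entropy learns the
minority class slowly (its gradient is diluted 1:9) while the pairwise
term amplifies it: three seeded replicates train for three epochs with
and without the contrastive term, and sensitivity is measured on a large
freshly drawn corpus (400 peptides per replicate) so SN has fine
resolution; the reported quantity is the per-arm mean over replicates.

## Numerical and degenerate-input conventions

* Masked softmax subtracts a detached row max before exponentiation;
  fully-masked rows produce uniform weights and are zeroed afterwards.
* Max pooling splits gradient evenly across ties.
* Cosine distance raises on zero vectors in the reference API; the
  training path adds 1e-12 to squared norms for stability.
* Representation norms, layer-norm variance (ε = 1e-5) and Adam (ε = 1e-8)
  follow common conventions.
* Empty FASTA yields an empty list with a warning; malformed FASTA errors
  with a line number; records failing validation are reported by id.

## Known limitations

* The internal redundancy reducer is not CD-HIT; identity is ungapped and
  end-anchored, so it under-merges sequences related by indels.
* The autodiff engine is single-threaded float64; training beyond ~10⁴
  sequences or `d` ≫ 64 is slow by design.
* No pretrained weights ship with the package; all reported numbers are
  recomputed from seeds.
* Attention-pooling uses a single learned scoring vector; richer pooled
  summaries (multi-query, gated) are out of scope.
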