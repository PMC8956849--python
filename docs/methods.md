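# Methods

## Problem and data model

The task is binary classification of amino-acid sequences: NifH
(dinitrogenase reductase, label 1) versus non-NifH (label 0). Input records
come from FASTA or two-column tables; the accepted alphabet is the 20
standard residues plus the ambiguity/rare codes X, B, Z, U, O (uppercased).
Records with other characters are dropped at ingest with a logged count
rather than raising, since public database exports routinely contain a few
malformed rows.

Preprocessing mirrors the canonical cleaning of the NifH training corpus:

* **Length filter**: keep sequences with 50 ≤ length ≤ 1173 aa, both bounds
  inclusive. The inclusive reading is the one consistent with a corpus whose
  reported minimum is exactly 50 and maximum exactly 1173.
* **Redundancy reduction** at 90 % identity. The default `internal_greedy`
  method sorts by length descending and greedily nominates representatives,
  scoring identity as exact-match columns of an ungapped head-to-head
  alignment divided by the shorter length. This is deliberately simpler than
  CD-HIT's short-word heuristic — it needs no external binary and is exact on
  the synthetic data used in tests — and an `external_cdhit` mode shells out
  to a real CD-HIT binary when present for faithful replication on database
  data.

## Feature extraction

**k-mer presence bits.** For each configured k (defaults 5 and 7) a general
list (GL) is built from the *positive* training sequences only: every
overlapping k-mer occurrence is counted (within-sequence repeats included),
and the top-N (default 100) by count form the ordered GL. Ties at equal
count break lexicographically so the list — and therefore the feature layout
— is deterministic and permutation-invariant to input order. A sequence's
block is then the binary vector of GL-ordered substring presence. A
document-frequency counting mode (`count_mode="presence"`) is available
behind a flag because the ranking convention is not fixed by the problem;
occurrence counting is the default.

**Embedding-vector (EV) features.** Sequences are tokenised with a fixed
alphabetical map (A=1, B=2, …; 0 reserved for padding — the specific
assignment is immaterial, so a deterministic one is used) and right-padded
with zeros to M = 1173, the longest positive sequence. The extractor stack
is

    embedding(vocab 26 → L=32, padding row frozen at zero)
    → conv1d(128 filters, width 31, valid) → ReLU
    → temporal max-pool(3) → global max-pool

yielding exactly one value per filter (128 features). The temporal-then-
global pooling is the only pooling arrangement that produces a fixed-length
128-vector from variable-content 1-D feature maps, and is what this package
implements. The embedding dimension L is a free parameter; 32 is the
default on the grounds that a 25-letter alphabet needs no more, and the
output dimensionality is set by the filter count, not by L.

The extractor is trained *standalone*: a small dense softmax head is
attached, the whole stack is optimised end-to-end on the training labels
(Adam, learning rate 1e-3, batch 64, 5 epochs by default — the extractor
converges much faster than the downstream classifier because its gradients
are not throttled by a tiny learning rate), then the head is discarded and
the truncated stack frozen for feature emission. Training it jointly with
the final 328-input classifier is the main design alternative; the
separate-then-freeze protocol was chosen because it makes the EV block a
fixed featurisation that can be serialised, reused and audited
independently of any downstream classifier.

## Classifier

The hybrid vector (100 + 100 + 128 = 328 values, fixed block order
kmer5 ‖ kmer7 ‖ ev) feeds a dense network with the layer stack

    dense(128) → dropout → dense(64) → batch-norm → ReLU → dropout
    → dense(32) → batch-norm → ReLU → dropout → dense(2) → softmax

Per-layer total parameter counts are 42112, 0, 8256, 256, 0, 0, 2080, 128,
0, 0, 66, 0 — dense layers contribute in·out+out and batch-norm 4·features
(gamma, beta, and the two non-trainable moving statistics), the convention
under which the counts are audited in the tests. Hidden activations are
ReLU and the output is a 2-unit softmax, the standard reading for a 2-class
cross-entropy objective; dropout rates default to 0.3 (unspecified
upstream, configurable). Training uses Adam at learning rate 6e-5 with
batch size 40 for 40 epochs. No class weighting is applied: the intended
corpus is nearly balanced (4911 vs 4782). Training aborts with a
learning-rate hint if the loss goes non-finite.

All layers are implemented in `nifhnet.nn` (NumPy): the convolution is
im2col + GEMM in float32, dropout is inverted, batch normalisation tracks
moving statistics with momentum 0.99, and every layer's backward pass is
verified against central finite differences in float64 in the test suite.
Determinism: all randomness (initialisation, shuffling, dropout) flows
through one seeded `numpy.random.Generator`, so a fixed seed reproduces
training bit-for-bit on a given platform.

## Evaluation protocol

`run_methodology` performs stratified k-fold cross-validation (k=4 by
default; stratification keeps the class ratio in every fold and reduces
variance at small k). Within each fold the GLs and the embedding extractor
are rebuilt **on the training folds only**, so no information from the
held-out fold leaks into feature construction; `global_artifacts=True`
switches to building them once on the full dataset, the simpler protocol
replication may call for. Metrics per fold: accuracy, sensitivity (=
recall), specificity, precision, F1 and test cross-entropy; division by
zero yields NaN, never an exception. The "best" classifier is the fold
with the highest held-out accuracy, ties broken by lower loss.
`compare_methodologies` reports fold-mean metrics per feature combination
on a percent scale (loss shown as cross-entropy × 100 alongside the raw
value), sorted by accuracy with ties keeping input order.

## Synthetic data

`nifhnet.synthetic` generates the two-class benchmark used throughout the
tests: negatives are i.i.d. background sequences (uniform over the 20
standard residues by default; an arbitrary composition can be supplied),
positives additionally carry each configured motif written in once at a
uniform random position, optionally corrupted by per-position
substitutions. Lengths are uniform on [50, 1173] by default, matching the
span of the real training corpus; the default planted signal is a single
clean 7-mer, the smallest signature the default feature set can capture
both via the 7-mer GL block and the width-31 convolution. With mutation
rate 0 the classes are separable by construction; with rate 1 the motif is
destroyed and accuracy must collapse to chance, which the permutation-null
checks exploit.

What this emulates — and what it does not: the generator reproduces the
*separability structure* of the problem (a class-discriminative subsequence
on a shared background, realistic lengths) but none of the phylogenetic
correlation, compositional bias or motif degeneracy of real UniProt
sequences. Passing the synthetic benchmark therefore demonstrates that the
pipeline's plumbing, features and optimisation work end-to-end, not that
real-data accuracy in the mid-90s will be reproduced; that requires the
deposited training corpus, which is not redistributable here.

## Problem sizes and numerical choices

The cross-validated benchmark uses 400 sequences (200 per class), the size
at which the 4-fold pipeline — including training the convolutional
extractor once per fold at M = 1173 — completes in minutes on one CPU while
leaving the classifier enough gradient updates to converge at its small
learning rate. Unit tests use an 80-record, short-sequence (M = 150)
variant and compensate for the reduced update count by training the DNN for
proportionally more epochs. Other conventions: softmax probabilities are
clipped at 1e-7 inside the cross-entropy; max-pool drops remainder
positions shorter than the window; the all-padding (empty) sequence is a
valid input producing a constant feature vector; duplicate record
identifiers are allowed.

## Known limitations

* The internal greedy clusterer is not CD-HIT: ungapped head-aligned
  identity under-counts similarity between frame-shifted homologs, so
  database-scale redundancy reduction should use the `external_cdhit` mode.
* Binary presence bits carry no dosage information; highly repetitive
  sequences are indistinguishable from single-occurrence ones in the k-mer
  blocks.
* Sequences longer than M cannot receive EV features and are flagged at
  prediction time rather than truncated.
* The NumPy training loop is single-threaded BLAS-bound; it is sized for
  thousands, not millions, of sequences.
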