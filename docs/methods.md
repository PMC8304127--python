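# Methods

## Model

The classifier maps one social-media post to a distribution over risk
classes. Tokens are lowercased words, punctuation marks and emoji (the
latter two must survive tokenization because the symbolic features count
them). Token vectors come from a trainable embedding table (rows for a
padding index 0 and an unknown index 1 are reserved; the padding row starts
at zero), optionally initialized from pretrained vectors in the common
text format; out-of-file rows are drawn from a seeded uniform(−0.25, 0.25).

A single-layer BiLSTM (zero initial states, default 200 units per
direction) produces per-position hidden states; forward and backward
states are concatenated, which is the standard reading of "combine the two
directional states" and gives a 2H-dimensional position vector. Additive
self-attention with a trainable context vector scores each position
(`e_k = uᵀ tanh(W h_k + b)`); scores are max-shifted before exponentiation,
padding positions receive −∞ score and hence exactly zero weight, and the
sentence vector is the attention-weighted sum of states — a convex
combination of the unmasked positions, which the tests assert. The additive
form is isolated in one function so a dot-product variant is a local swap.

The sentence vector is concatenated with the external feature vector,
passed through one tanh hidden layer (size = fused dimension / 2 by
default; the MLP depth/width is not pinned down by the model family, so it
is configurable), then a softmax. Dropout (default 0.5) is applied to the
fused vector during training as inverted dropout.

### Loss

Per-sample cross-entropy is scaled by a per-class distribution weight γ
initialized from inverse class frequency normalized to mean 1 — so classes
with more training data get strictly smaller weights — and trained further
as log-weights, which keeps γ positive under arbitrary gradient steps. The
L2 term λ‖θ‖² (λ = 1e-5) covers weight matrices only: LSTM input/recurrent
weights, the attention projection and context vector, and the MLP weights;
embeddings, biases and γ are excluded (regularizing γ towards zero would
fight its role, and embedding regularization is conventionally separate).
Probabilities are clamped at 1e-12 before the log.

All gradients come from a small in-package reverse-mode autodiff over numpy
arrays. Every primitive, and the full model loss, is checked against
central finite differences (1e-4 relative tolerance) in the test suite.

## Feature extraction

* **n-grams**: one combined bigram+trigram vocabulary (min document
  frequency 2 to bound the matrix) with TF-IDF weights, tf = raw count and
  idf = log((1+N)/(1+df)) with *no* +1 after the log — an n-gram present in
  every document scores exactly 0. The convention is recorded in the model
  metadata. The posts × n-grams matrix is factorized with seeded
  multiplicative-update NMF to K = 50 non-negative factors. New posts are
  projected by non-negative least squares of their TF-IDF row onto the
  fitted basis, solved through the K×K Gram system so the cost is
  independent of vocabulary size; a post with no known n-grams projects to
  the zero vector.
* **lexicon counts**: exact token matches (no stemming, for auditability)
  against a word→emotion-category table; a word in several categories
  increments each. The configured category list is (positive, negative,
  sadness, anger, despair, fear) plus post length. "Despair" is not a
  category of the standard NRC association lexicon, so the file format
  accepts arbitrary category names and the packaged toy lexicon (synthetic,
  46 words) covers all six; mapping despair onto NRC's sadness∧fear is a
  user-side configuration choice.
* **symbolic counts**: first-person *singular* pronouns {i, me, my, mine,
  myself} (plural forms carry no self-orientation signal), "?" tokens, and
  emoji identified by Unicode pictograph code-point ranges.

Counts stay exact integers in the feature vector; the trainer standardizes
features with training-set mean/sd (floored at 1e-8), stored in the
checkpoint.

## Label framings

Risk is 4-class, `a < b < c < d`. Existence collapses to `a` vs rest.
Urgency maps {c, d} → urgent: the narrative description and the worked
example table of the source model family disagree on this point, and we
follow the table, which is the reading consistent with urgency ordered by
risk; the mapping is a function argument so the alternative is selectable.

## Training and evaluation

Adam; stratified 10% development split (seeded); batches padded to the
longest member (length-sorted batching, batch order reshuffled per epoch);
early stopping on development macro-F1 with patience 5, plus an immediate
stop once the development set is classified perfectly; the checkpoint keeps
the best-development parameters. The published learning rate 0.2 is kept as
the config default for fidelity, but it is far too large for Adam in
practice; 1e-3 is recommended and used for the synthetic experiments.
Epoch count (30) and batch size (32) defaults are package choices, not
published values. Runs are bit-deterministic given the seed.

Evaluation computes the confusion matrix, per-class P = TP/(TP+FP),
R = TP/(TP+FN), F1 = 2PR/(P+R) with 0/0 := 0, and macro-F1 as the
unweighted mean; classes absent from both truth and prediction are flagged
in the report and contribute F1 = 0. The implementation is cross-checked
against an independent library implementation on random vectors.

Ablation retrains the model on the same split and seed with any subset of
the three feature blocks (the empty subset is the encoder-only model).

## Synthetic corpus

The generator emulates the statistical shape of the restricted study data:
four classes near 1:1:1:1, post lengths clipped to [14, 486] tokens (the
study corpus extremes) from a log-normal with median ≈ 55, a closed filler
vocabulary of 500 tokens with Zipf(1) frequencies (so TF-IDF/NMF see
realistic sparsity at desk scale), and class-conditional per-token rates
for: shared high-risk cue words (rising from 0.01 for class a to 0.14 for
class d), first-person pronouns (0.02→0.08), question marks, emoji, and
emotion-lexicon words whose category mix shifts from positive (class a)
towards sadness/despair/fear (class d). These rates are fixed package
defaults chosen to be plausible for first-person crisis-forum text; the
per-class monotone ordering is what the model family assumes.

The separable regime plants disjoint four-word cue sets per class; every
post gets at least three cue emissions, each from its own class's set with
probability (1+3m)/4 for margin m. At m = 1 a cue-count rule classifies
perfectly, which makes end-to-end recovery testable; as m → 0 the
class-conditional cue distributions coincide (verified by a contingency
chi-square test).

What the generator does *not* emulate: fluent English, topical coherence,
user-level post histories, annotator noise, or realistic class overlap in
vocabulary beyond the rate structure above. Passing recovery tests
therefore demonstrates that the implementation can learn planted
distributional structure end to end — not that it attains any particular
accuracy on real clinical text.

## Problem sizes and numerical choices

The shipped experiments use 2,000 training / 500 test posts for the
structure-recovery runs (learning rate 1e-3, ≤ 10 epochs, full-size 300/200
model) and 80–250 posts with reduced dimensions for unit-level runs; NMF
runs at most 400 multiplicative updates (tolerance 1e-9). Softmaxes
subtract the row maximum; masked positions get −∞ scores; the NNLS Gram
matrix is ridge-stabilized by 1e-10·tr(G); ties in argmax predictions
resolve to the lowest class index; vocabulary and n-gram column orders are
lexicographic so fits are order-independent.

## Known limitations

Single-layer encoder only (no stacking, no multi-head attention); no
negation handling, stemming, or multiword lexicon entries; contextual
embeddings are supported only as precomputed per-token vectors; risk is
treated as flat 4-class (no ordinal structure), matching macro-F1
evaluation; the CPU-only numpy implementation is intended for desk-scale
corpora, not the full shared-task scale.
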