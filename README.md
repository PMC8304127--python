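# riskattn

Post-level suicide-risk classification for social-media text, built around a
**multifeature fusion recurrent attention network**: a bidirectional LSTM +
additive self-attention encoder whose sentence vector is fused with three
handcrafted linguistic feature blocks and trained under a
distribution-weighted, L2-regularized cross-entropy.

It is aimed at mental-health informatics / clinical NLP researchers who need
a transparent, fully seeded implementation of this model family — including
per-token attention exports for auditing individual predictions — plus a
synthetic corpus generator, since the real shared-task corpora in this area
are access-restricted.

## Model

Each post is tokenized and embedded (`D = 300` by default). A single-layer
BiLSTM with `H = 200` units per direction runs the standard gate recurrence

```
f_k = σ(W_f x_k + V_f h_{k−1} + b_f)        i_k = σ(W_i x_k + V_i h_{k−1} + b_i)
o_k = σ(W_o x_k + V_o h_{k−1} + b_o)        c̃_k = tanh(W_c x_k + V_c h_{k−1} + b_c)
c_k = f_k ⊙ c_{k−1} + i_k ⊙ c̃_k            h_k = o_k ⊙ tanh(c_k)
```

in both directions; per-position states are concatenated (`h_k ∈ R^{2H}`).
Additive self-attention scores every position, `e_k = uᵀ tanh(W h_k + b)`,
normalizes with a masked softmax `α = softmax(e)`, and forms the sentence
vector `s = Σ_k α_k h_k`.

`s` is concatenated with a 60-dimensional external feature vector per post:

* **n-gram block (50)** — bigram+trigram TF-IDF (idf = log((1+N)/(1+df)))
  compressed by non-negative matrix factorization;
* **lexicon block (7)** — counts of words in six emotion categories
  (positive, negative, sadness, anger, despair, fear) plus post length;
* **symbolic block (3)** — counts of first-person singular pronouns,
  question marks, and emoji.

A one-hidden-layer MLP + softmax produces class probabilities. Training
minimizes

```
L = (1/N) Σ_i −γ_{c(i)} log p_i(c(i)) + λ‖θ‖²,     λ = 1e−5
```

where γ is a trainable per-class distribution weight initialized from
inverse class frequency (more data ⇒ smaller weight), kept positive through
a log-parameterization. Posts carry a 4-class risk label `a < b < c < d`;
two binary framings are derived from it (**existence**: `a` vs rest;
**urgency**: `{c,d}` vs rest) and every framing is scored with
macro-averaged F1. The whole network, including its reverse-mode autodiff,
is implemented in numpy and validated by finite-difference gradient checks.

## Worked example

```
$ python examples/03_train_evaluate.py
epoch 1: train loss 1.1931, dev macro-F1 0.575
epoch 2: train loss 0.6836, dev macro-F1 0.747
...
epoch 7: train loss 0.1714, dev macro-F1 0.896
...
test macro-F1: 0.8926
per-class F1 : {'a': 0.783, 'b': 0.818, 'c': 0.97, 'd': 1.0}
confusion    :
[[ 9  1  1  0]
 [ 3  9  0  0]
 [ 0  0 16  0]
 [ 0  0  0 11]]
```

This trains a compact configuration on 200 synthetic posts whose classes
are separable by planted cue tokens, then scores 50 held-out posts: the
macro-F1 of 0.89 and near-diagonal confusion matrix show the model
recovering the planted structure. `examples/04_attention_export.py` then
shows *why*: averaged over posts, the planted cue tokens receive ~2.5× the
uniform attention weight at this scale (an order of magnitude more with the
full-size model), e.g.

```
post label: d | cue tokens: ['painless', 'painless', 'suicide']
cue weights: [0.3475, 0.3281, 0.1247] | uniform: 0.0357
```

The other examples cover corpus generation (`01`), featurization (`02`) and
feature-block ablation (`05`). The same operations are scriptable through
the `riskattn` CLI (`riskattn synth|featurize|train|evaluate|attend|ablate`).

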