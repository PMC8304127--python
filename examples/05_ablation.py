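"""Compare feature-block subsets on the same split and seed.

Retrains the model with no external features, each single block, and all
blocks, reporting test macro-F1 side by side — the ablation design used to
judge what each handcrafted block adds on top of the neural encoder.
"""

from riskattn import FeatureExtractor, TrainConfig, ablate
from riskattn.synth import GeneratorSpec, generate_separable, toy_lexicon

posts = generate_separable(GeneratorSpec(seed=13), 250, margin=1.0)
tr, te = posts[:200], posts[200:]
extractor, tr_vecs = FeatureExtractor.fit(tr, toy_lexicon(), k=10, min_df=2)
te_vecs = extractor.transform_many(te)

cfg = TrainConfig(
    embedding_dim=32, hidden_units=16, attention_dim=8,
    learning_rate=1e-2, epochs=4, batch_size=16, seed=13, framing="risk",
)
subsets = [(), ("ngram",), ("lexicon",), ("symbolic",), ("ngram", "lexicon", "symbolic")]
results = ablate(tr, tr_vecs, te, te_vecs, cfg, subsets)
for subset, report in results.items():
    name = "+".join(subset) if subset else "encoder only"
    print(f"{name:25s} test macro-F1 {report.macro_f1:.4f}")
# With this deliberately under-trained encoder (4 epochs), each handcrafted
# block outperforms the encoder-only run: the external features deliver class
# signal long before the BiLSTM has learned it. Rankings between subsets are
# noisy at this tiny scale.
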