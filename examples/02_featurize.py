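"""Fit the three-block feature pipeline and featurize a post.

Blocks: 50 non-negative n-gram factors (bigram+trigram TF-IDF compressed by
NMF), 7 lexicon counts (six emotion categories + post length), and 3
symbolic counts (first-person singular pronouns, question marks, emoji).
"""

from riskattn import FeatureExtractor, Post
from riskattn.synth import GeneratorSpec, generate

posts, lexicon = generate(GeneratorSpec(seed=13), 200)
extractor, vectors = FeatureExtractor.fit(posts, lexicon, k=50, min_df=2, seed=13)

fv = vectors[0]
print("feature vector length:", len(fv), "(50 n-gram + 7 lexicon + 3 symbolic)")
print("n-gram block (first 5):", [round(float(v), 3) for v in fv.ngram[:5]])
print("lexicon block:", fv.lexicon.tolist(), "  # six emotion counts + post length")
print("symbolic block:", fv.symbolic.tolist(), "  # (1st-person, '?', emoji)")

new = Post(post_id="demo", raw_text="I feel hopeless and scared, why me? 😢", risk_label="c")
demo = extractor.transform(new)
print("demo lexicon counts:", demo.lexicon.tolist())
print("demo symbolic counts:", demo.symbolic.tolist())
# The demo post counts 'hopeless' (despair), 'scared' (fear); symbolic counts
# are (2, 1, 1): 'i' and 'me', one question mark, one emoji.
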