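import numpy as np
import pytest

from riskattn.corpus import Post
from riskattn.synth import GeneratorSpec, generate


TABLE_POSTS = [
    ("p1", "A nihilist teetering on edge. Things were good before I came into being", "a"),
    ("p2", "Has anyone attempted suicide and failed and then felt guilty for being incompetent?", "b"),
    (
        "p3",
        "Just sitting on a bench, waiting and thinking. I don’t want to, but it feels like the best option.",
        "c",
    ),
    ("p4", "Tell me how to commit suicide painlessly.", "d"),
]


@pytest.fixture(scope="session")
def table_posts() -> list[Post]:
    """The four published example posts, one per risk class."""
    return [Post(post_id=i, raw_text=t, risk_label=l) for i, t, l in TABLE_POSTS]


@pytest.fixture(scope="session")
def small_corpus():
    """80 synthetic posts + toy lexicon, enough to fit the feature pipeline."""
    posts, lexicon = generate(GeneratorSpec(seed=41), 80)
    return posts, lexicon


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)
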