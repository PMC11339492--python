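import pytest

from clinspan import Document, Entity, MarkupConfig, generate, mtsamples_config
from clinspan.markup import identity_config

# The canonical worked example: one discharge-summary sentence with a
# medical problem and a test entity, as rendered in the span-markup protocol.
WORKED_TEXT = (
    "He had been diagnosed with osteoarthritis of the knees and had "
    "undergone arthroscopy years prior to admission."
)
WORKED_MARKED = (
    "He had been diagnosed with <span class=“problem”>osteoarthritis "
    "of the knees</span> and had undergone <span class=“test”>"
    "arthroscopy</span> years prior to admission."
)


@pytest.fixture(scope="session")
def worked_doc() -> Document:
    s1 = WORKED_TEXT.index("osteoarthritis")
    s2 = WORKED_TEXT.index("arthroscopy")
    return Document(
        "worked",
        WORKED_TEXT,
        [
            Entity(s1, s1 + len("osteoarthritis of the knees"), "problem"),
            Entity(s2, s2 + len("arthroscopy"), "test"),
        ],
    )


@pytest.fixture(scope="session")
def i2b2_cfg() -> MarkupConfig:
    return MarkupConfig(
        {"problem": "problem", "treatment": "treatment", "test": "test"}
    )


@pytest.fixture(scope="session")
def synth_corpus():
    """A 200-document corpus for round-trip property tests."""
    return generate(mtsamples_config(n_docs=200, seed=42))


@pytest.fixture(scope="session")
def synth_cfg(synth_corpus):
    return identity_config(synth_corpus.labels)
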