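import numpy as np
import pytest

from vaxtopics import CorpusSpec, TweetVectorizer, generate_corpus


@pytest.fixture(scope="session")
def separable_corpus():
    """A small corpus with strongly separated stance vocabularies."""
    spec = CorpusSpec(
        n_per_class=(150, 150, 150), separation=6.0, dispersion=0.05, seed=3
    )
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def separable_features(separable_corpus):
    texts = [t.text for t in separable_corpus]
    labels = np.asarray([t.true_stance for t in separable_corpus])
    vec = TweetVectorizer().fit(texts)
    return vec.transform(texts), labels, vec.vocabulary_
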