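"""Annotator backends: oracle, noise channel statistics, chat adapter."""

import math

import pytest

from clinspan import (
    BackendConfig,
    Corpus,
    NoiseProfile,
    PromptConfig,
    build_prompt,
    categorize_corpus_errors,
    chat_annotate,
    generate,
    mtsamples_components,
    mtsamples_config,
    noisy_annotate,
    oracle_annotate,
    render_markup,
    score,
)
from clinspan.backends import BackendError, ConfigurationError
from clinspan.markup import identity_config
from clinspan.synth import generic_config


@pytest.fixture(scope="module")
def dense_corpus():
    """A corpus carrying well over 1000 gold entities."""
    corpus = generate(
        mtsamples_config(n_docs=250, sentences_per_doc=(3, 4), entity_density=1.8, seed=5)
    )
    assert sum(len(d.entities) for d in corpus) >= 1000
    return corpus


def _predict_all(corpus, cfg, noise):
    return {
        d.doc_id: noisy_annotate(d, cfg, noise).parsed.entities for d in corpus
    }


class TestOracle:
    def test_recovers_gold_exactly(self, synth_corpus, synth_cfg):
        for doc in synth_corpus.documents[:50]:
            res = oracle_annotate(doc, synth_cfg)
            assert res.parsed.entities == doc.entities

    def test_worked_example_renders_printed_markup(self, worked_doc, i2b2_cfg):
        res = oracle_annotate(worked_doc, i2b2_cfg)
        assert res.raw_output == render_markup(worked_doc, i2b2_cfg)
        assert '<span class="problem">osteoarthritis of the knees</span>' in res.raw_output

    def test_end_to_end_perfect_scores(self, synth_corpus, synth_cfg):
        sub = Corpus(synth_corpus.documents[:100], synth_corpus.labels)
        preds = {d.doc_id: oracle_annotate(d, synth_cfg).parsed.entities for d in sub}
        for mode in ("exact", "relaxed"):
            r = score(sub, preds, mode)
            assert (r.overall.precision, r.overall.recall, r.overall.f1) == (1, 1, 1)


class TestNoisy:
    def test_zero_noise_equals_oracle(self, synth_corpus, synth_cfg):
        for doc in synth_corpus.documents[:30]:
            noisy = noisy_annotate(doc, synth_cfg, NoiseProfile(seed=1))
            assert noisy.raw_output == oracle_annotate(doc, synth_cfg).raw_output

    def test_bit_reproducible(self, synth_corpus, synth_cfg):
        noise = NoiseProfile(p_miss=0.3, p_boundary=0.4, p_type=0.2,
                             spurious_rate=0.5, p_corrupt=0.3, seed=77)
        for doc in synth_corpus.documents[:20]:
            a = noisy_annotate(doc, synth_cfg, noise)
            b = noisy_annotate(doc, synth_cfg, noise)
            assert a.raw_output == b.raw_output

    def test_miss_rate_recovers_binomial_recall(self, dense_corpus):
        """p_miss=0.2 over >=1000 entities: exact recall within 3 binomial
        SE of 0.8, precision exactly 1.0."""
        cfg = identity_config(dense_corpus.labels)
        noise = NoiseProfile(p_miss=0.2, seed=13)
        preds = _predict_all(dense_corpus, cfg, noise)
        r = score(dense_corpus, preds, "exact")
        n = r.overall.n_gold
        se = math.sqrt(0.8 * 0.2 / n)
        assert abs(r.overall.recall - 0.8) <= 3 * se
        assert r.overall.precision == 1.0

    def test_full_type_swap_zero_f1_all_type_errors(self):
        """p_type=1 with two labels is a deterministic label swap: F1=0 in
        both modes, yet every error is type_only."""
        corpus = generate(generic_config(["A", "B"], n_docs=40, seed=3))
        cfg = identity_config(corpus.labels)
        noise = NoiseProfile(p_type=1.0, seed=9)
        preds = _predict_all(corpus, cfg, noise)
        assert sum(len(v) for v in preds.values()) > 0
        for mode in ("exact", "relaxed"):
            assert score(corpus, preds, mode).overall.f1 == 0.0
        bd = categorize_corpus_errors(corpus, preds)
        assert bd.type_only == bd.total > 0

    def test_boundary_jitter_keeps_relaxed_match(self, synth_corpus, synth_cfg):
        noise = NoiseProfile(p_boundary=1.0, boundary_max_tokens=1, seed=21)
        sub = Corpus(synth_corpus.documents[:60], synth_corpus.labels)
        preds = _predict_all(sub, synth_cfg, noise)
        r_exact = score(sub, preds, "exact")
        r_relax = score(sub, preds, "relaxed")
        assert r_relax.overall.f1 > r_exact.overall.f1
        assert r_relax.overall.recall > 0.9  # jitter never drops an entity

    def test_spurious_spans_lower_precision_only(self, synth_corpus, synth_cfg):
        noise = NoiseProfile(spurious_rate=1.0, seed=31)
        sub = Corpus(synth_corpus.documents[:60], synth_corpus.labels)
        preds = _predict_all(sub, synth_cfg, noise)
        r = score(sub, preds, "exact")
        assert r.overall.recall == 1.0
        assert r.overall.precision < 1.0

    def test_corruption_still_parses(self, synth_corpus, synth_cfg):
        noise = NoiseProfile(p_corrupt=1.0, seed=41)
        for doc in synth_corpus.documents[:30]:
            res = noisy_annotate(doc, synth_cfg, noise)
            assert res.parsed.entities == doc.entities  # mutation is outside spans

    def test_gold_never_mutated(self, synth_corpus, synth_cfg):
        doc = synth_corpus.documents[0]
        before = (doc.text, list(doc.entities))
        noisy_annotate(doc, synth_cfg,
                       NoiseProfile(p_miss=0.5, p_boundary=0.5, p_type=0.5,
                                    spurious_rate=1.0, p_corrupt=1.0, seed=2))
        assert (doc.text, doc.entities) == before

    def test_invalid_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            NoiseProfile(p_miss=1.5)
        with pytest.raises(ConfigurationError, match="sum"):
            NoiseProfile(confusion={"A": {"B": 0.6, "A": 0.6}})


class TestChat:
    def _bundle(self, doc):
        return build_prompt(mtsamples_components(), PromptConfig(), [], doc.text)

    def test_echo_gold_equals_oracle(self, synth_corpus, synth_cfg):
        doc = synth_corpus.documents[0]
        adapter = lambda prompt, cfg: render_markup(doc, synth_cfg)
        res = chat_annotate(doc, self._bundle(doc), BackendConfig(), synth_cfg, adapter)
        assert res.parsed.entities == doc.entities

    def test_identity_output_yields_zero_recall(self, synth_corpus, synth_cfg):
        doc = synth_corpus.documents[1]
        adapter = lambda prompt, cfg: doc.text
        res = chat_annotate(doc, self._bundle(doc), BackendConfig(), synth_cfg, adapter)
        assert res.parsed.entities == []

    def test_noisy_transcript_fixture_diagnostics(self, synth_cfg):
        """Hand-built transcript: one good span, one unknown class, one
        nested pair, one unclosed tag."""
        from clinspan import Document

        source = "alpha beta gamma delta epsilon"
        doc = Document("fx", source)
        transcript = (
            '<span class="Medical problem">alpha</span> '
            '<span class="bogus">beta</span> '
            '<span class="Test">gamma <span class="Test">delta</span></span> '
            '<span class="Treatment">epsilon'
        )
        adapter = lambda prompt, cfg: transcript
        res = chat_annotate(doc, self._bundle(doc), BackendConfig(), synth_cfg, adapter)
        d = res.parsed.diagnostics
        assert d["unknown_class"] == 1
        assert d["nested_span_flattened"] == 1
        assert d["malformed_tag"] == 1
        assert [e.label for e in res.parsed.entities] == [
            "Medical problem", "Test", "Treatment"]

    def test_retries_then_succeeds(self, synth_corpus, synth_cfg):
        doc = synth_corpus.documents[2]
        calls = []

        def flaky(prompt, cfg):
            calls.append(1)
            if len(calls) < 3:
                raise OSError("transient")
            return doc.text

        res = chat_annotate(doc, self._bundle(doc), BackendConfig(retries=3),
                            synth_cfg, flaky, sleep=lambda s: None)
        assert len(calls) == 3 and res.doc_id == doc.doc_id

    def test_transport_failure_carries_doc_id(self, synth_corpus, synth_cfg):
        doc = synth_corpus.documents[3]

        def dead(prompt, cfg):
            raise OSError("down")

        with pytest.raises(BackendError) as exc:
            chat_annotate(doc, self._bundle(doc), BackendConfig(retries=1),
                          synth_cfg, dead, sleep=lambda s: None)
        assert exc.value.doc_id == doc.doc_id

    def test_missing_adapter_is_configuration_error(self, synth_corpus, synth_cfg):
        doc = synth_corpus.documents[4]
        with pytest.raises(ConfigurationError, match="no chat adapter"):
            chat_annotate(doc, self._bundle(doc),
                          BackendConfig(model_id="unregistered"), synth_cfg)
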