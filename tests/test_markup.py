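"""Span-markup protocol: rendering, tag stripping, alignment, parsing."""

import random

import numpy as np
import pytest

from clinspan import (
    Document,
    Entity,
    MarkupConfig,
    align_texts,
    parse_markup,
    render_markup,
    strip_tags,
)
from clinspan.markup import MarkupError, UnknownClassError, similarity
from conftest import WORKED_MARKED, WORKED_TEXT


# --- independent quadratic DP oracle -------------------------------------

def dp_edit_distance(a: str, b: str) -> int:
    """Full Needleman-Wunsch unit-cost edit distance (oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def map_cost(source: str, plain: str, omap) -> int:
    """Edit cost implied by an OffsetMap: insertions (unaligned outputs)
    + mismatched aligned pairs + skipped source characters."""
    cost = 0
    used = set()
    prev_src = -1
    for i, ch in enumerate(plain):
        if omap.aligned[i]:
            s = omap.src_index[i]
            assert s > prev_src, "alignment must be strictly monotone"
            cost += s - prev_src - 1  # source chars skipped (deletions)
            cost += ch != source[s]
            used.add(s)
            prev_src = s
        else:
            cost += 1
    cost += len(source) - prev_src - 1
    return cost


# --- rendering -------------------------------------------------------------

class TestRender:
    def test_worked_example_matches_printed_markup(self, worked_doc, i2b2_cfg):
        rendered = render_markup(worked_doc, i2b2_cfg)
        assert rendered == WORKED_MARKED.replace("“", '"').replace("”", '"')

    def test_zero_entities_identity(self, i2b2_cfg):
        doc = Document("d", "nothing to mark here.")
        assert render_markup(doc, i2b2_cfg) == doc.text

    def test_unmapped_label_errors(self):
        doc = Document("d", "abc", [Entity(0, 3, "X")])
        with pytest.raises(MarkupError, match="no class mapping"):
            render_markup(doc, MarkupConfig({"Y": "y"}))

    def test_render_strip_round_trip(self, synth_corpus, synth_cfg):
        for doc in synth_corpus:
            plain, spans, diag = strip_tags(render_markup(doc, synth_cfg))
            assert plain == doc.text
            assert len(spans) == len(doc.entities)
            assert all(v == 0 for v in diag.values())


class TestStripTags:
    def test_worked_example(self, i2b2_cfg):
        plain, spans, diag = strip_tags(WORKED_MARKED)
        assert plain == WORKED_TEXT
        assert [c for _, _, c in spans] == ["problem", "test"]
        s, e, _ = spans[0]
        assert plain[s:e] == "osteoarthritis of the knees"

    def test_no_tags(self):
        plain, spans, diag = strip_tags("no markup at all")
        assert plain == "no markup at all" and spans == []

    def test_nested_flattened(self):
        plain, spans, diag = strip_tags(
            '<span class="test">a <span class="test">b</span> c</span>'
        )
        assert plain == "a b c"
        assert spans == [(0, 5, "test")]
        assert diag["nested_span_flattened"] == 1

    def test_unclosed_span_closed_at_line_end(self):
        plain, spans, diag = strip_tags('x <span class="problem">pain\nnew line')
        assert plain == "x pain\nnew line"
        assert spans == [(2, 6, "problem")]
        assert diag["malformed_tag"] == 1

    def test_stray_close_flagged(self):
        plain, spans, diag = strip_tags("text </span> more")
        assert plain == "text  more"
        assert spans == []
        assert diag["malformed_tag"] == 1


class TestAlign:
    def test_identity(self):
        m = align_texts("same text", "same text")
        assert m.distance == 0
        assert m.src_index == list(range(9)) and all(m.aligned)

    def test_inserted_word_example(self):
        source = "blood sugar was low"
        output = "blood sugar level was low"
        m = align_texts(source, output)
        # "was low" in the output maps back to its source offsets
        assert m.map_span(output.index("was"), len(output)) == (
            source.index("was"), len(source))
        # exactly the six inserted " level" characters are unaligned
        unaligned = {i for i, a in enumerate(m.aligned) if not a}
        assert len(unaligned) == 6 and unaligned <= set(range(11, 18))

    def test_missing_sentence_keeps_global_offsets(self):
        source = "First sentence here. Second sentence follows."
        output = "Second sentence follows."
        m = align_texts(source, output)
        assert m.map_span(0, len(output)) == (21, len(source))
        assert m.distance == dp_edit_distance(output, source)

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_dp_oracle_on_mutated_outputs(self, seed, synth_corpus):
        """Alignment distance equals the quadratic DP oracle and the offset
        map realizes an alignment of exactly that cost (200 random pairs)."""
        rng = random.Random(seed)
        docs = synth_corpus.documents
        for _ in range(50):
            source = rng.choice(docs).text[:500]
            out = list(source)
            for _ in range(rng.randint(0, 12)):
                op = rng.choice("ids")
                pos = rng.randrange(max(1, len(out)))
                if op == "i":
                    out.insert(pos, rng.choice("abcdefgh "))
                elif op == "d" and out:
                    out.pop(pos)
                elif out:
                    out[pos] = rng.choice("abcdefgh ")
            output = "".join(out)
            m = align_texts(source, output)
            oracle = dp_edit_distance(output, source)
            assert m.distance == oracle
            assert map_cost(source, output, m) == oracle


class TestParse:
    def test_worked_example(self, worked_doc, i2b2_cfg):
        result = parse_markup(WORKED_TEXT, WORKED_MARKED, i2b2_cfg)
        assert result.entities == worked_doc.entities
        assert result.entities[0].text == "osteoarthritis of the knees"
        assert result.entities[1].text == "arthroscopy"

    def test_untagged_output_yields_nothing(self, i2b2_cfg):
        result = parse_markup(WORKED_TEXT, WORKED_TEXT, i2b2_cfg)
        assert result.entities == []
        assert all(v == 0 for v in result.diagnostics.values())

    def test_hallucinated_span_dropped_not_misanchored(self, i2b2_cfg):
        source = "The patient was discharged home in stable condition."
        marked = (
            "The patient was discharged home "
            '<span class="problem">pneumonia</span> in stable condition.'
        )
        result = parse_markup(source, marked, i2b2_cfg)
        assert result.entities == []
        assert result.diagnostics["unaligned_span_dropped"] == 1

    def test_unknown_class_policies(self, i2b2_cfg):
        marked = 'a <span class="mystery">b</span> c'
        res = parse_markup("a b c", marked, i2b2_cfg)
        assert res.entities == [] and res.diagnostics["unknown_class"] == 1
        strict = MarkupConfig(i2b2_cfg.label_to_class, unknown_class_policy="error")
        with pytest.raises(UnknownClassError, match="mystery"):
            parse_markup("a b c", marked, strict)

    def test_round_trip_identity_on_200_docs(self, synth_corpus, synth_cfg):
        for doc in synth_corpus:
            res = parse_markup(doc.text, render_markup(doc, synth_cfg), synth_cfg)
            assert res.entities == doc.entities

    def test_fuzzed_output_never_violates_document_invariants(self, synth_cfg, synth_corpus):
        """Arbitrary garbage output parses to a valid (possibly empty)
        entity set, and diagnostics conserve the span count."""
        rng = random.Random(99)
        pieces = ['<span class="', '">', "</span>", "Medical problem", "zzz",
                  " text ", "<span", "\n", '<span class="Test">']
        for i in range(150):
            source = rng.choice(synth_corpus.documents).text
            marked = "".join(rng.choice(pieces) for _ in range(rng.randint(0, 25)))
            res = parse_markup(source, marked, synth_cfg)
            Document("fuzz", source, res.entities)  # raises if invalid
            _, spans, _ = strip_tags(marked)
            d = res.diagnostics
            assert len(spans) == (
                len(res.entities) + d["unaligned_span_dropped"]
                + d["unknown_class"] + d["overlap_dropped"]
            )

    def test_diagnostics_conserved_for_nested_output(self, synth_cfg):
        marked = ('x <span class="Test">a <span class="Test">b</span> c</span> y')
        res = parse_markup("x a b c y", marked, synth_cfg)
        assert res.diagnostics["nested_span_flattened"] == 1
        assert len(res.entities) == 1


def test_similarity_normalized():
    assert similarity("abc", "abc") == 1.0
    assert similarity("", "") == 1.0
    assert similarity("abc", "") == 0.0
    assert similarity("abcd", "abcx") == 0.75
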