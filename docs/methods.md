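# Methods

This note documents the models, conventions, and design choices behind
clinspan, and what its tests do and do not establish.

## Offsets, tokenization, and "identical boundaries"

All spans are 0-based, half-open, character-level. Exact-match evaluation
is usually phrased as "identical token boundaries"; here it is realized as
character-offset equality under a single shared tokenizer (alphanumeric
runs are one token; every other non-space character is its own token;
underscore counts as punctuation). This is consistent because both gold
entities and parsed predictions are snapped to token boundaries of the same
source text before comparison. The tokenizer deliberately does no clinical
abbreviation handling: determinism and reproducibility matter more here
than linguistic finesse, and any richer tokenizer would change what
"exact" means between runs and machines.

Entities not aligned to token boundaries are expanded **outward** to the
covering tokens (never truncated), with a logged warning. Expansion
preserves recallable content; truncation could silently delete the head of
a phrase. Overlapping or nested gold entities are rejected at construction:
the supported tasks are flat NER.

Sentence segmentation (used for few-shot sampling and CRF sequences) splits
on newlines, then after sentence-final punctuation followed by whitespace,
and keeps global offsets.

## The markup protocol and its failure modes

Only `<span class="...">...</span>` is part of the protocol; any other
HTML-looking content is literal text. The class attribute may be quoted
with straight or curly quotes (marked-up text that has passed through word
processors often carries curly quotes) and the tag name is
case-insensitive. The parser's repair policy:

- nested spans are flattened to the outermost (diagnostic
  `nested_span_flattened`);
- an open tag with no matching close is closed at the next newline or end
  of input (`malformed_tag`), as is a stray close tag;
- spans whose text cannot be anchored to the source are dropped
  (`unaligned_span_dropped`), never guessed at;
- duplicate/overlapping parsed spans are resolved keeping the
  leftmost-longest (`overlap_dropped`), matching the flat-NER assumption
  and giving a deterministic result.

Diagnostics are conserved: every span found in the output is either
returned as an entity or accounted for by exactly one drop/flatten counter,
a property the fuzz tests assert.

## Output-to-source alignment

Generative annotators do not reliably echo their input, so parsed spans
live in *output* coordinates and must be carried back to *source*
coordinates. The alignment is global minimum-edit-distance (unit costs,
matches free), computed with edlib's exact banded-doubling algorithm;
a quadratic Needleman–Wunsch oracle implemented independently in the test
suite verifies both the distance and that the produced offset map realizes
an alignment of exactly that cost. Output characters inserted by the
annotator map to the nearest preceding source position and are marked
unaligned; a span with no aligned characters is hallucinated by definition
and is dropped.

After mapping and token-snapping, the span's output text is compared to its
mapped source text by normalized Levenshtein similarity
(1 − d/max(|a|,|b|)); below `similarity_threshold` (default 0.8) the span
is dropped. The threshold is configurable and logged in parse diagnostics;
0.8 tolerates small copy noise (a character or two per short phrase) while
rejecting substituted words. How a real annotator's mutated output *should*
be scored is genuinely underdetermined; this procedure is this package's
contract, chosen to be conservative (never mis-anchor) and fully
diagnosable.

## Scoring conventions

Exact and relaxed matching are as defined in the README. Two conventions
deserve comment:

- **Micro vs macro.** Overall scores pool TP/FP/FN counts over labels
  (micro), the standard convention for concept-extraction shared tasks;
  macro averages are exposed as properties for comparison.
- **Many-to-many relaxed overlaps.** Counting is match-existence based: a
  prediction overlapping two golds counts once toward precision, and both
  golds count as recalled. Whether a relaxed scorer should deduplicate
  many-to-one overlaps is ambiguous in common usage; this choice is
  isolated in `score` so a one-to-one variant can be swapped in, and the
  greedy one-to-one pairing used by the error categorizer provides the
  alternative accounting.
- Empty denominators report 0 with an explicit `undefined` flag rather
  than NaN, so downstream tables never propagate missing values silently.

The error categorizer pairs exact matches first, then greedily
(left-to-right) pairs each remaining prediction with the first unpaired
overlapping gold: same label → `boundary_only`; same span, different label
→ `type_only`; both differ → `boundary_and_type`; leftovers are `missing`
(gold) or `spurious` (prediction).

## The noise channel

`NoiseProfile` applies independent error modes per gold entity: drop with
`p_miss`; boundary jitter with `p_boundary` (extend/shrink up to
`boundary_max_tokens`, default 2, never crossing a neighboring entity, with
extension biased leftward when an article/determiner precedes the span —
the characteristic "the study drug" boundary mistake); label swap with
`p_type` (uniform over other labels, or per a supplied confusion matrix
whose rows sum to 1); spurious spans on non-entity token runs of 1–4 tokens
with Poisson(`spurious_rate`) count; and with `p_corrupt`, insertion of a
filler word outside any entity, exercising the alignment path. Randomness
derives from the profile seed plus a CRC32 offset of the doc_id, so corpus
runs are bit-reproducible yet per-document streams are independent.

These modes make evaluator behaviour analytically checkable (e.g. miss-only
noise must yield precision exactly 1 and recall binomial around
1 − p_miss). `guideline_adjusted` scales `p_boundary` ×0.5 when the
guideline component is enabled and `p_type` ×0.3 when the error-analysis
component is enabled, emulating an annotator that follows added
instructions; it exists so incremental-prompt experiments have a mock whose
improvement direction is known.

## Prompt assembly

Section order is fixed (Task → Entity Markup Guide → Entity Definitions →
Annotation Guidelines → Error-analysis Guidelines → Examples → Input);
component 1 is mandatory and component 3 requires component 2, mirroring
the incremental design the framework supports. Few-shot examples are
sentence-level, sampled uniformly without replacement from training
sentences containing at least one entity (zero-entity exemplars are
excluded by default, configurable), rendered with the same markup config
used for parsing. Shots are sampled once per run and reused across inputs;
per-input resampling would confound incremental comparisons with sampling
variance. The shipped component texts are short defaults; users supply
full guideline bodies via config — the toolkit treats them as opaque text.

## CRF baseline

Features per token: lowercased surface, initial-capital/all-caps/any-digit
flags, prefixes and suffixes of lengths 1–3, neighbor surfaces at ±1 with
BOS/EOS sentinels. The affix lengths and window are the conventional
minimal set and are exposed in `CRFConfig`. Training maximizes L2-penalized
conditional log-likelihood (c2 = 0.1, up to 200 L-BFGS iterations,
ftol 1e−6) — the objective is convex and weights start at zero, so training
is deterministic without any seed. Decoding is unconstrained Viterbi
followed by BIO repair (illegal I → B, logged). These hyperparameters are
package defaults chosen for small corpora, not tuned per dataset.

## Synthetic corpus generator

Template-based: each sentence draws a slot count k = min(Poisson(density),
4), picks a template with k typed slots, and fills slots from per-label
lexicons (multi-word phrase with probability `multiword_fraction`, default
0.5, so boundary-jitter tests exercise both span shapes). Defaults: 50
documents of 2–4 sentences, density 1.5 entities/sentence, 60/20/20
train/valid/test split. Templates go up to 4 slots so the Poisson
truncation bias is negligible (E[min(X,4)] ≈ 1.476 at density 1.5).

What the generator emulates: exact gold offsets, realistic label
inventories and phrase shapes (including leading articles that trigger
boundary errors), configurable densities, punctuation attached to words.
What it does not: real clinical discourse, misspellings, abbreviation
ambiguity, nested or discontinuous mentions, annotator disagreement.
Passing tests therefore establish the *mechanical* correctness of
rendering, parsing, alignment, scoring, and training — not performance
claims on real clinical text. Because its lexicons are label-separable,
the CRF's near-perfect synthetic F1 is a sanity floor, not a benchmark.

## Problem sizes and numerical choices

Round-trip and parsing properties are tested on 200 seeded documents;
scorer equivalence on 500 fuzzed instances; noise statistics on corpora
with ≥ 1000 gold entities (3 binomial SEs of tolerance); alignment against
the DP oracle on 200 mutated pairs of ≤ 500 characters; the CRF on a
50-document corpus. These sizes give tight statistical checks while
keeping the default suite fast on a single core. Ties in alignment
(co-optimal paths) are resolved by edlib; tests assert cost-optimality of
the realized alignment rather than one arbitrary co-optimal path.

## Known limitations

- No discontinuous or nested entities; no 1-based or end-inclusive offset
  dialects; no i2b2 XML record format.
- The chat backend is an adapter contract only; no vendor SDK is shipped.
- No statistical significance testing between runs; no informative-shot
  selection strategies; no chain-of-thought prompting.
- Unicode beyond the basic multilingual plane is passed through but the
  alignment operates on code points, not grapheme clusters.
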