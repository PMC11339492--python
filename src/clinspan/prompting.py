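"""Four-component prompt assembly and few-shot example sampling.

A prompt is built from up to four components, added incrementally:

1. task description + output-format specification and an entity markup
   guide (always present);
2. entity definitions + annotation guidelines distilled from the task's
   annotation manual;
3. extra instructions derived from error analysis of model output on
   training data (requires component 2 — the instructions amend the
   guidelines);
4. annotated examples (few-shot learning), rendered in the span-markup
   protocol as ``Example Input{k}: ... / Example Output{k}: ...`` pairs.

Prompt text is a pure function of its arguments; identical inputs produce
byte-identical prompts.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import Corpus, Document
from .markup import MarkupConfig, render_markup

HEADER_TASK = "### Task"
HEADER_MARKUP = "### Entity Markup Guide"
HEADER_DEFS = "### Entity Definitions"
HEADER_GUIDELINES = "### Annotation Guidelines:"
HEADER_ERROR = "### Error-analysis-based Guidelines:"
HEADER_EXAMPLES = "### Examples"
HEADER_INPUT = "### Input"


class PromptError(ValueError):
    pass


@dataclass(frozen=True)
class PromptComponents:
    """Text blocks for the four prompt components plus enablement flags."""

    task_and_format: str
    markup_guide: str
    entity_definitions: str = ""
    annotation_guidelines: str = ""
    error_analysis_guidelines: str = ""
    enabled: frozenset[int] = frozenset({1})

    def __post_init__(self) -> None:
        if not self.enabled <= {1, 2, 3, 4}:
            raise PromptError(f"unknown component ids in {set(self.enabled)}")
        if 1 not in self.enabled:
            raise PromptError("component 1 (task/format) is always required")
        if 3 in self.enabled and 2 not in self.enabled:
            raise PromptError(
                "component 3 (error-analysis instructions) requires "
                "component 2 (annotation guidelines)"
            )

    def with_enabled(self, ids: set[int]) -> "PromptComponents":
        return PromptComponents(
            self.task_and_format,
            self.markup_guide,
            self.entity_definitions,
            self.annotation_guidelines,
            self.error_analysis_guidelines,
            frozenset(ids),
        )


@dataclass(frozen=True)
class PromptConfig:
    n_shots: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shots < 0:
            raise PromptError("n_shots must be non-negative")


@dataclass
class PromptBundle:
    sections: list[tuple[str, str]]
    shots: list[tuple[str, str]]  # (input sentence, marked output)
    text: str


def _markup_guide_text(cfg: MarkupConfig) -> str:
    lines = [
        f'Use <span class="{cls}"> to denote a {label.lower()}.'
        for label, cls in cfg.label_to_class.items()
    ]
    return "\n".join(lines)


def mtsamples_components(markup_cfg: MarkupConfig | None = None) -> PromptComponents:
    """Shipped component texts for the discharge-summary task
    (medical problems / treatments / tests)."""
    guide = (
        _markup_guide_text(markup_cfg)
        if markup_cfg
        else (
            'Use <span class="problem"> to denote a medical problem.\n'
            'Use <span class="treatment"> to denote a treatment.\n'
            'Use <span class="test"> to denote a test.'
        )
    )
    return PromptComponents(
        task_and_format=(
            "Your task is to generate an HTML version of an input text, "
            "marking up specific entities related to healthcare. The entities "
            'to be identified are: "medical problems", "treatments", and '
            '"tests". Use HTML <span> tags to highlight these entities. Each '
            "<span> should have a class attribute indicating the type of the "
            "entity. Leave the rest of the text unchanged."
        ),
        markup_guide=guide,
        entity_definitions=(
            "Medical problems are phrases that contain observations made by "
            "patients or clinicians about the patient's body or mind that are "
            "thought to be abnormal or caused by a disease. Treatments are "
            "procedures, interventions, and substances given to a patient to "
            "resolve a medical problem. Tests are procedures, panels, and "
            "measures performed on a patient to discover or rule out a "
            "medical problem."
        ),
        annotation_guidelines=(
            "Only complete noun phrases (NPs) and adjective phrases (APs) "
            "should be marked. Terms that fit concept semantic rules but are "
            "only used as modifiers in a noun phrase should not be marked. "
            "Include articles and determiners that begin the phrase."
        ),
        error_analysis_guidelines=(
            "Consultation procedures should not be annotated as tests. Do not "
            "mark laboratory values alone as medical problems."
        ),
        enabled=frozenset({1, 2, 3, 4}),
    )


def vaers_components(markup_cfg: MarkupConfig | None = None) -> PromptComponents:
    """Shipped component texts for the vaccine-safety-report task."""
    guide = (
        _markup_guide_text(markup_cfg)
        if markup_cfg
        else (
            'Use <span class="investigation"> to denote an investigation.\n'
            'Use <span class="nervous_ae"> to denote a nervous system '
            "adverse event.\n"
            'Use <span class="other_ae"> to denote any other adverse event.\n'
            'Use <span class="procedure"> to denote a procedure.'
        )
    )
    return PromptComponents(
        task_and_format=(
            "Your task is to generate an HTML version of an input text, "
            "marking up specific entities from vaccine safety reports. The "
            'entities to be identified are: "investigations", "nervous '
            'system adverse events", "other adverse events", and '
            '"procedures". Use HTML <span> tags to highlight these entities. '
            "Each <span> should have a class attribute indicating the type "
            "of the entity. Leave the rest of the text unchanged."
        ),
        markup_guide=guide,
        entity_definitions=(
            "Investigations are examinations and diagnostic workups performed "
            "to assess a reported event. Nervous system adverse events are "
            "post-vaccination symptoms and disorders of the nervous system. "
            "Other adverse events are post-vaccination symptoms not involving "
            "the nervous system. Procedures are therapeutic or administrative "
            "interventions performed on the patient."
        ),
        annotation_guidelines=(
            "Mark complete noun phrases only. Do not mark negated or "
            "hypothetical events. Do not include temporal expressions in the "
            "entity span."
        ),
        error_analysis_guidelines=(
            "Routine administration of the vaccine itself should be annotated "
            "as a procedure, not an investigation. Symptoms mentioned only as "
            "part of medical history should not be annotated."
        ),
        enabled=frozenset({1, 2, 3, 4}),
    )


def sample_shots(
    corpus: Corpus,
    n: int,
    seed: int,
    markup_cfg: MarkupConfig,
    require_entity: bool = True,
) -> list[tuple[Document, str]]:
    """Sample *n* distinct training sentences (with >= 1 entity by default),
    uniformly without replacement, paired with their rendered markup.

    Deterministic for a fixed seed. Sampling is sentence-level: training
    documents are segmented and each sentence is an eligible unit.
    """
    if n == 0:
        return []
    pool: list[Document] = []
    train = corpus.docs_in_split("train") or list(corpus.documents)
    for doc in train:
        for sent in doc.sentences():
            if sent.entities or not require_entity:
                pool.append(sent)
    if len(pool) < n:
        raise PromptError(
            f"requested {n} shots but only {len(pool)} eligible training "
            "sentences are available"
        )
    rng = random.Random(seed)
    chosen = rng.sample(pool, n)
    return [(d, render_markup(d, markup_cfg)) for d in chosen]


def build_prompt(
    components: PromptComponents,
    cfg: PromptConfig,
    shots: list[tuple[Document, str]],
    input_text: str,
) -> PromptBundle:
    """Assemble the final prompt string in the fixed section order:
    Task -> Entity Markup Guide -> Entity Definitions -> Annotation
    Guidelines -> Error-analysis Guidelines -> Examples -> Input."""
    if len(shots) != cfg.n_shots:
        raise PromptError(
            f"got {len(shots)} shots but config requests {cfg.n_shots}"
        )
    sections: list[tuple[str, str]] = [
        (HEADER_TASK, components.task_and_format),
        (HEADER_MARKUP, components.markup_guide),
    ]
    if 2 in components.enabled:
        sections.append((HEADER_DEFS, components.entity_definitions))
        sections.append((HEADER_GUIDELINES, components.annotation_guidelines))
    if 3 in components.enabled:
        sections.append((HEADER_ERROR, components.error_analysis_guidelines))
    shot_pairs = [(d.text, marked) for d, marked in shots]
    if 4 in components.enabled and shots:
        body = "\n".join(
            f"Example Input{k}: {inp}\nExample Output{k}: {out}"
            for k, (inp, out) in enumerate(shot_pairs, start=1)
        )
        sections.append((HEADER_EXAMPLES, body))
    sections.append((HEADER_INPUT, input_text))
    text = "\n\n".join(f"{h}\n{b}" for h, b in sections)
    return PromptBundle(sections, shot_pairs, text)
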