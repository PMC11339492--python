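"""Seeded generator of clinical-style annotated corpora.

Template-based, not neural: the generator's job is structural fidelity —
exact gold offsets, configurable label inventories, entity densities and
train/valid/test splits — so that every other module is testable without any
external dataset. It makes no attempt to imitate real clinical text
distributions.

Two shipped styles mirror common clinical NER label inventories: a
discharge-summary trio (Medical problem / Treatment / Test, as in the 2010
i2b2 concept extraction task) and a vaccine-safety-report quartet
(Investigation / Nervous adverse event / Other adverse event / Procedure).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, Document, Entity

MTSAMPLES_LABELS = ["Medical problem", "Treatment", "Test"]
VAERS_LABELS = [
    "Investigation",
    "Nervous adverse event",
    "Other adverse event",
    "Procedure",
]

_SLOT_RE = re.compile(r"\[\[([^\]]+)\]\]")

TemplatePart = tuple[str, str]  # ("lit", text) or ("slot", label)


class SynthError(ValueError):
    pass


def parse_template(pattern: str) -> list[TemplatePart]:
    """Split a ``... [[Label]] ...`` pattern into literal and slot parts."""
    parts: list[TemplatePart] = []
    pos = 0
    for m in _SLOT_RE.finditer(pattern):
        if m.start() > pos:
            parts.append(("lit", pattern[pos : m.start()]))
        parts.append(("slot", m.group(1)))
        pos = m.end()
    if pos < len(pattern):
        parts.append(("lit", pattern[pos:]))
    return parts


def _slot_count(parts: list[TemplatePart]) -> int:
    return sum(1 for kind, _ in parts if kind == "slot")


def default_lexicons(style: str = "mtsamples") -> dict[str, list[str]]:
    """Per-label surface-phrase lists, mixing single- and multi-word forms."""
    if style == "mtsamples":
        return {
            "Medical problem": [
                "hypertension", "pneumonia", "anemia", "asthma", "sepsis",
                "lung cancer", "diabetes mellitus", "chest pain",
                "atrial fibrillation", "osteoarthritis of the knees",
                "a large stroke", "congestive heart failure",
            ],
            "Treatment": [
                "chemotherapy", "aspirin", "metformin", "lisinopril",
                "insulin", "radiation therapy", "physical therapy",
                "intravenous antibiotics", "the study drug",
                "coronary artery bypass grafting",
            ],
            "Test": [
                "arthroscopy", "colonoscopy", "echocardiogram", "biopsy",
                "urinalysis", "CT scan", "chest x ray",
                "complete blood count", "a blood sugar level",
                "MRI of the brain",
            ],
        }
    if style == "vaers":
        return {
            "Investigation": [
                "neurological exam", "MRI", "EEG", "lumbar puncture",
                "blood test", "nerve conduction study", "CT scan of the head",
            ],
            "Nervous adverse event": [
                "tremors", "seizure", "numbness", "headache", "dizziness",
                "facial paralysis", "tingling in the hands",
                "loss of balance", "slurred speech",
            ],
            "Other adverse event": [
                "fever", "rash", "fatigue", "nausea", "vomiting",
                "pain at the injection site", "shortness of breath",
            ],
            "Procedure": [
                "vaccination", "intubation", "hospitalization", "surgery",
                "influenza vaccine administration", "physical therapy",
            ],
        }
    raise SynthError(f"unknown lexicon style {style!r}")


def _mt_templates() -> list[str]:
    P, T, X = "[[Medical problem]]", "[[Treatment]]", "[[Test]]"
    return [
        "The patient denies fever or chills.",
        "Vital signs were stable on admission.",
        "Review of systems was otherwise negative.",
        f"The patient was diagnosed with {P} last year.",
        f"She was started on {T} after admission.",
        f"A {X} was ordered on hospital day two.",
        f"He had been diagnosed with {P} and had undergone {X} years prior.",
        f"She was treated with {T} for {P} without complication.",
        f"Results of {X} were consistent with {P}.",
        f"Given {P}, the team recommended {T} and a follow up {X}.",
        f"A {X} confirmed {P}, and {T} was initiated that evening.",
        f"History includes {P} managed with {T}, {P} status post {T}.",
        f"Workup with {X} and {X} revealed {P}, prompting {T}.",
    ]


def _vaers_templates() -> list[str]:
    I, N, O, R = (
        "[[Investigation]]",
        "[[Nervous adverse event]]",
        "[[Other adverse event]]",
        "[[Procedure]]",
    )
    return [
        "The report was submitted by the patient's physician.",
        "No additional details were provided at this time.",
        f"The patient developed {N} two days after {R}.",
        f"A {I} was performed with unremarkable findings.",
        f"Following {R}, she reported {N} and {O}.",
        f"He experienced {O} shortly after {R} on the same day.",
        f"{I} showed no abnormality despite ongoing {N}.",
        f"Symptoms of {N}, {O}, and {O} began within hours of {R}.",
        f"After {R}, a {I} was ordered to evaluate persistent {N}.",
    ]


def generic_templates(labels: list[str]) -> list[str]:
    """Filler templates (0-4 slots) for an arbitrary label inventory."""
    slots = [f"[[{labels[i % len(labels)]}]]" for i in range(4)]
    return [
        "The record contains no findings of note.",
        f"The note mentions {slots[0]} in passing.",
        f"Both {slots[0]} and {slots[1]} were documented on review.",
        f"Entries list {slots[0]}, then {slots[1]}, then {slots[2]}.",
        f"Observed {slots[0]} with {slots[1]} after {slots[2]} and {slots[3]}.",
    ]


@dataclass
class GeneratorConfig:
    labels: list[str] = field(default_factory=lambda: list(MTSAMPLES_LABELS))
    lexicons: dict[str, list[str]] = field(default_factory=lambda: default_lexicons())
    templates: list[str] = field(default_factory=_mt_templates)
    n_docs: int = 50
    sentences_per_doc: tuple[int, int] = (2, 4)
    entity_density: float = 1.5
    multiword_fraction: float = 0.5
    split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise SynthError("split fractions must sum to 1")
        parsed = [parse_template(p) for p in self.templates]
        for parts in parsed:
            for kind, val in parts:
                if kind == "slot" and val not in self.labels:
                    raise SynthError(
                        f"template slot label {val!r} not in inventory {self.labels}"
                    )


def mtsamples_config(**kw) -> GeneratorConfig:
    return GeneratorConfig(**kw)


def vaers_config(**kw) -> GeneratorConfig:
    return GeneratorConfig(
        labels=list(VAERS_LABELS),
        lexicons=default_lexicons("vaers"),
        templates=_vaers_templates(),
        **kw,
    )


def generic_config(labels: list[str], phrases_per_label: int = 6, **kw) -> GeneratorConfig:
    """A config for an arbitrary inventory, with synthetic lexicons."""
    lex = {
        lab: [f"{lab.lower().replace(' ', '')}{j}" for j in range(phrases_per_label // 2)]
        + [f"{lab.lower().replace(' ', '')} finding {j}" for j in range(phrases_per_label - phrases_per_label // 2)]
        for lab in labels
    }
    return GeneratorConfig(
        labels=list(labels), lexicons=lex, templates=generic_templates(labels), **kw
    )


def _pick_phrase(rng: np.random.Generator, phrases: list[str], multi_frac: float) -> str:
    multi = [p for p in phrases if " " in p]
    single = [p for p in phrases if " " not in p]
    pool = multi if (multi and rng.random() < multi_frac) else (single or multi)
    return pool[int(rng.integers(len(pool)))]


def generate(cfg: GeneratorConfig) -> Corpus:
    """Generate a corpus with exact-by-construction gold offsets.

    Per sentence, the slot count is drawn as ``min(Poisson(density), 4)`` and
    a template with that many slots (or the closest smaller count) is chosen
    uniformly; slots are filled from the per-label lexicons. Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    parsed = [parse_template(p) for p in cfg.templates]
    by_count: dict[int, list[list[TemplatePart]]] = {}
    for parts in parsed:
        by_count.setdefault(_slot_count(parts), []).append(parts)
    max_slots = max(by_count)

    used_labels = {
        val for parts in parsed for kind, val in parts if kind == "slot"
    }
    for lab in used_labels:
        if not cfg.lexicons.get(lab):
            raise SynthError(f"empty lexicon for used label {lab!r}")

    lo, hi = cfg.sentences_per_doc
    docs: list[Document] = []
    for di in range(cfg.n_docs):
        n_sent = int(rng.integers(lo, hi + 1))
        sent_texts: list[str] = []
        entities: list[Entity] = []
        offset = 0
        for _ in range(n_sent):
            k = min(int(rng.poisson(cfg.entity_density)), max_slots)
            while k not in by_count:
                k -= 1
            parts = by_count[k][int(rng.integers(len(by_count[k])))]
            chunks: list[str] = []
            pos = offset
            for kind, val in parts:
                if kind == "lit":
                    chunks.append(val)
                    pos += len(val)
                else:
                    phrase = _pick_phrase(rng, cfg.lexicons[val], cfg.multiword_fraction)
                    entities.append(Entity(pos, pos + len(phrase), val, phrase))
                    chunks.append(phrase)
                    pos += len(phrase)
            sent = "".join(chunks)
            sent_texts.append(sent)
            offset = pos + 1  # joining space
        docs.append(Document(f"synth_{di:04d}", " ".join(sent_texts), entities))

    order = list(rng.permutation(cfg.n_docs))
    n_train = int(round(cfg.split_fractions[0] * cfg.n_docs))
    n_valid = int(round(cfg.split_fractions[1] * cfg.n_docs))
    split = {}
    for rank, di in enumerate(order):
        tag = "train" if rank < n_train else "valid" if rank < n_train + n_valid else "test"
        split[docs[di].doc_id] = tag
    return Corpus(docs, list(cfg.labels), split)
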