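"""Token feature extraction and a linear-chain CRF over BIO tags.

The feature set is the conventional minimal one for word-level sequence
labeling: bag-of-word identity (lowercased), capitalization/digit flags,
prefixes and suffixes of lengths 1-3, and neighboring-token surfaces in a
+-1 window with begin/end sentinels. Sizes are exposed as configuration.

The CRF is trained by maximizing the conditional log-likelihood with an L2
penalty, using L-BFGS; gradients come from forward-backward marginals.
Training is deterministic: weights start at zero and the objective is
convex, so no random initialization is involved. Decoding is Viterbi;
illegal I-transitions in decoded sequences are rewritten to B (and logged),
guaranteeing valid BIO output.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .corpus import (
    Corpus,
    Document,
    Entity,
    TokenizedDocument,
    bio_to_entities,
    entities_to_bio,
    segment_sentences,
    tokenize,
)

logger = logging.getLogger(__name__)


class CRFError(ValueError):
    pass


@dataclass(frozen=True)
class CRFConfig:
    affix_max_len: int = 3
    window: int = 1
    c2: float = 0.1  # L2 penalty weight
    max_iter: int = 200
    tol: float = 1e-6


def extract_features(
    tdoc: TokenizedDocument, cfg: CRFConfig = CRFConfig()
) -> list[list[str]]:
    """One feature-string list per token; a pure function of the surfaces."""
    surfaces = [surf for surf, _, _ in tdoc.tokens]
    feats: list[list[str]] = []
    for i, w in enumerate(surfaces):
        f = [
            f"w={w.lower()}",
            f"isupper_first={w[:1].isupper()}",
            f"isupper_all={w.isupper() and w.isalpha()}",
            f"hasdigit={any(c.isdigit() for c in w)}",
        ]
        for n in range(1, cfg.affix_max_len + 1):
            f.append(f"prefix{n}={w[:n].lower()}")
            f.append(f"suffix{n}={w[-n:].lower()}")
        for d in range(1, cfg.window + 1):
            f.append(f"w[-{d}]={surfaces[i - d].lower()}" if i - d >= 0 else f"w[-{d}]=<BOS>")
            f.append(
                f"w[+{d}]={surfaces[i + d].lower()}"
                if i + d < len(surfaces)
                else f"w[+{d}]=<EOS>"
            )
        feats.append(f)
    return feats


@dataclass
class ChainCRF:
    """A trained linear-chain CRF: feature/tag vocabularies and weights."""

    feature_index: dict[str, int]
    tags: list[str]
    emission: np.ndarray  # (n_features, n_tags)
    transition: np.ndarray  # (n_tags, n_tags)
    start: np.ndarray  # (n_tags,)
    end: np.ndarray  # (n_tags,)
    config: CRFConfig = field(default_factory=CRFConfig)
    labels: list[str] = field(default_factory=list)


def _doc_sequences(doc: Document, cfg: CRFConfig) -> list[tuple[list[list[str]], list[str]]]:
    """Per-sentence (features, BIO tags) pairs for one document."""
    out = []
    for sent in doc.sentences():
        toks = tokenize(sent.text)
        if not toks:
            continue
        tdoc = entities_to_bio(sent, toks)
        out.append((extract_features(tdoc, cfg), tdoc.bio_tags))
    return out


def _sentence_potentials(feat_ids, emission):
    # emission score matrix (T, n_tags) by summing active feature rows
    return np.stack([emission[ids].sum(axis=0) for ids in feat_ids])


def train_crf(corpus: Corpus, cfg: CRFConfig = CRFConfig()) -> ChainCRF:
    """Fit the CRF on the corpus training split (all documents if untagged)."""
    train_docs = corpus.docs_in_split("train") or list(corpus.documents)
    if not train_docs:
        raise CRFError("training split is empty")

    sequences: list[tuple[list[list[str]], list[str]]] = []
    for doc in train_docs:
        sequences.extend(_doc_sequences(doc, cfg))
    if not sequences:
        raise CRFError("no non-empty training sentences")

    tags = sorted({t for _, ts in sequences for t in ts} | {"O"})
    tag_idx = {t: i for i, t in enumerate(tags)}
    feature_index: dict[str, int] = {}
    indexed: list[tuple[list[np.ndarray], np.ndarray]] = []
    for feats, ts in sequences:
        fid_rows = []
        for fs in feats:
            ids = []
            for f in fs:
                if f not in feature_index:
                    feature_index[f] = len(feature_index)
                ids.append(feature_index[f])
            fid_rows.append(np.array(ids, dtype=np.intp))
        indexed.append((fid_rows, np.array([tag_idx[t] for t in ts], dtype=np.intp)))

    F, K = len(feature_index), len(tags)
    n_em = F * K

    def unpack(theta):
        em = theta[:n_em].reshape(F, K)
        tr = theta[n_em : n_em + K * K].reshape(K, K)
        st = theta[n_em + K * K : n_em + K * K + K]
        en = theta[n_em + K * K + K :]
        return em, tr, st, en

    def objective(theta):
        em, tr, st, en = unpack(theta)
        g_em = np.zeros_like(em)
        g_tr = np.zeros_like(tr)
        g_st = np.zeros_like(st)
        g_en = np.zeros_like(en)
        nll = 0.0
        for fid_rows, y in indexed:
            T = len(y)
            pot = _sentence_potentials(fid_rows, em)  # (T, K)
            # forward
            alpha = np.empty((T, K))
            alpha[0] = st + pot[0]
            for t in range(1, T):
                alpha[t] = pot[t] + logsumexp(alpha[t - 1][:, None] + tr, axis=0)
            logZ = logsumexp(alpha[-1] + en)
            # backward
            beta = np.empty((T, K))
            beta[-1] = en
            for t in range(T - 2, -1, -1):
                beta[t] = logsumexp(tr + (pot[t + 1] + beta[t + 1])[None, :], axis=1)
            # gold path score
            path = st[y[0]] + pot[np.arange(T), y].sum() + en[y[-1]]
            path += tr[y[:-1], y[1:]].sum() if T > 1 else 0.0
            nll += logZ - path
            # marginals
            node_m = np.exp(alpha + beta - logZ)  # (T, K)
            for t in range(T):
                g_em[fid_rows[t]] += node_m[t]
                g_em[fid_rows[t], y[t]] -= 1.0
            g_st += node_m[0]
            g_st[y[0]] -= 1.0
            g_en += node_m[-1]
            g_en[y[-1]] -= 1.0
            for t in range(T - 1):
                edge = alpha[t][:, None] + tr + (pot[t + 1] + beta[t + 1])[None, :]
                g_tr += np.exp(edge - logZ)
            if T > 1:
                np.add.at(g_tr, (y[:-1], y[1:]), -1.0)
        nll += cfg.c2 * float(theta @ theta)
        grad = np.concatenate(
            [g_em.ravel(), g_tr.ravel(), g_st, g_en]
        ) + 2 * cfg.c2 * theta
        return nll, grad

    theta0 = np.zeros(n_em + K * K + 2 * K)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol},
    )
    em, tr, st, en = unpack(res.x)
    labels = sorted({t[2:] for t in tags if t != "O"})
    return ChainCRF(feature_index, tags, em, tr, st, en, cfg, labels)


def save_crf(model: ChainCRF, path) -> None:
    """Serialize the model to a single JSON file with a version header."""
    import json

    payload = {
        "format": "clinspan-crf",
        "format_version": 1,
        "config": asdict(model.config),
        "tags": model.tags,
        "labels": model.labels,
        "feature_index": model.feature_index,
        "emission": model.emission.tolist(),
        "transition": model.transition.tolist(),
        "start": model.start.tolist(),
        "end": model.end.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_crf(path) -> ChainCRF:
    import json

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format") != "clinspan-crf":
        raise CRFError(f"{path}: not a clinspan CRF model file")
    return ChainCRF(
        feature_index=payload["feature_index"],
        tags=payload["tags"],
        emission=np.array(payload["emission"]),
        transition=np.array(payload["transition"]),
        start=np.array(payload["start"]),
        end=np.array(payload["end"]),
        config=CRFConfig(**payload["config"]),
        labels=payload["labels"],
    )


def _viterbi(pot: np.ndarray, tr: np.ndarray, st: np.ndarray, en: np.ndarray) -> list[int]:
    T, K = pot.shape
    delta = st + pot[0]
    back = np.zeros((T, K), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + tr
        back[t] = scores.argmax(axis=0)
        delta = pot[t] + scores.max(axis=0)
    delta = delta + en
    path = [int(delta.argmax())]
    for t in range(T - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


def _repair_bio(tags: list[str]) -> list[str]:
    """Rewrite illegal I-transitions to B; returns a valid BIO sequence."""
    out = []
    prev = "O"
    repaired = 0
    for t in tags:
        if t.startswith("I-") and (prev == "O" or prev[2:] != t[2:]):
            t = "B-" + t[2:]
            repaired += 1
        out.append(t)
        prev = t
    if repaired:
        logger.info("repaired %d illegal I-transitions during decoding", repaired)
    return out


def predict_crf(model: ChainCRF, documents: list[Document]) -> dict[str, list[Entity]]:
    """Viterbi-decode each document; returns entities per doc_id.

    Labels present in the documents' gold but absent from the training tag
    set are flagged with a warning (the model cannot emit them).
    """
    unseen = {
        e.label for d in documents for e in d.entities
    } - set(model.labels)
    if unseen:
        logger.warning("labels absent from training set: %s", sorted(unseen))

    K = len(model.tags)
    predictions: dict[str, list[Entity]] = {}
    for doc in documents:
        ents: list[Entity] = []
        for ss, se in segment_sentences(doc.text):
            sent_text = doc.text[ss:se]
            toks = tokenize(sent_text)
            if not toks:
                continue
            feats = extract_features(TokenizedDocument(toks, ["O"] * len(toks)), model.config)
            pot = np.zeros((len(toks), K))
            for t, fs in enumerate(feats):
                ids = [model.feature_index[f] for f in fs if f in model.feature_index]
                if ids:
                    pot[t] = model.emission[ids].sum(axis=0)
            path = _viterbi(pot, model.transition, model.start, model.end)
            tags = _repair_bio([model.tags[i] for i in path])
            for e in bio_to_entities(TokenizedDocument(toks, tags), sent_text):
                ents.append(Entity(e.start + ss, e.end + ss, e.label, e.text))
        predictions[doc.doc_id] = ents
    return predictions
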