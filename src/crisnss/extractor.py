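"""Candidate mention detection and hybrid rule/model classification.

The extraction pipeline mirrors how clinicians document negative symptoms in
correspondence: a cue phrase ("poor eye contact", "apathy", ...) appears
inside a sentence whose wording determines whether the symptom is affirmed
for the patient, negated ("denies apathy"), or attributed to someone else
("his mother reports ..."). Rules handle negation and experiencer
attribution deterministically; everything the rules leave undecided goes to
a per-symptom linear max-margin classifier over sentence bag-of-words
features. Rule verdicts always override the model.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Mapping, Sequence

from .corpus import SYMPTOMS, Document
from .lexicon import Lexicon, RuleSet
from .svm import LinearModel
from .text import segment_sentences, tokenize

POSITIVE = "positive"
NOT_POSITIVE = "not_positive"
FORCED_NOT_POSITIVE = "forced_not_positive"
UNDECIDED = "undecided"


@dataclass(frozen=True)
class Mention:
    """One cue occurrence with its sentence context.

    ``cue_token_index`` / ``cue_token_len`` locate the cue within
    ``context_tokens`` so negation scope can look backwards from the cue.
    """

    doc_id: str
    symptom: str
    cue_start: int
    cue_end: int
    sent_start: int
    sent_end: int
    context_tokens: tuple[str, ...]
    cue_token_index: int
    cue_token_len: int

    def __post_init__(self) -> None:
        if not (self.sent_start <= self.cue_start < self.cue_end <= self.sent_end):
            raise ValueError("cue span must lie within its sentence span")
        if not self.context_tokens:
            raise ValueError("context tokens must be non-empty")


def find_candidates(document: Document, lexicon: Lexicon) -> list[Mention]:
    """All cue matches in *document*, one mention per (cue occurrence, symptom).

    Matching is case-insensitive and token-aligned; overlapping cues for
    different symptoms each yield their own mention. Within one symptom,
    matches sharing the same first cue token keep only the longest cue
    (so "electively mute" does not additionally fire "mute" at the same spot).
    """
    mentions: list[Mention] = []
    for sent_start, sent_end in segment_sentences(document.text):
        tokens = tokenize(document.text[sent_start:sent_end], offset=sent_start)
        if not tokens:
            continue
        token_texts = tuple(t.text for t in tokens)
        for symptom in SYMPTOMS:
            hits: dict[int, tuple[int, int]] = {}  # first-token pos -> (len, cue chars)
            for cue in lexicon.cues[symptom]:
                L = len(cue)
                for i in range(len(tokens) - L + 1):
                    if token_texts[i:i + L] == cue:
                        if i not in hits or L > hits[i][0]:
                            hits[i] = (L, tokens[i + L - 1].end)
            for i, (L, cue_char_end) in sorted(hits.items()):
                mentions.append(
                    Mention(
                        doc_id=document.doc_id,
                        symptom=symptom,
                        cue_start=tokens[i].start,
                        cue_end=cue_char_end,
                        sent_start=sent_start,
                        sent_end=sent_end,
                        context_tokens=token_texts,
                        cue_token_index=i,
                        cue_token_len=L,
                    )
                )
    return mentions


def apply_rules(mention: Mention, rules: RuleSet) -> str:
    """``forced_not_positive`` or ``undecided``.

    Negation: a negation cue within ``rules.scope_window`` tokens immediately
    preceding the cue, same sentence. Experiencer: an experiencer cue
    anywhere in the sentence.
    """
    lo = max(0, mention.cue_token_index - rules.scope_window)
    preceding = mention.context_tokens[lo:mention.cue_token_index]
    if any(tok in rules.negation_cues for tok in preceding):
        return FORCED_NOT_POSITIVE
    if any(tok in rules.experiencer_cues for tok in mention.context_tokens):
        return FORCED_NOT_POSITIVE
    return UNDECIDED


def featurize(
    mention: Mention,
    ngram_orders: Sequence[int] = (1, 2),
    include_symptom: bool = False,
) -> frozenset[str]:
    """Binary bag-of-words features of the containing sentence.

    Unigrams and bigrams by default; stop-words and negation tokens are kept
    deliberately. With ``include_symptom`` the symptom label is appended as a
    categorical feature (for a single shared model across symptoms).
    """
    toks = mention.context_tokens
    feats: set[str] = set()
    if 1 in ngram_orders:
        feats.update(f"u:{t}" for t in toks)
    if 2 in ngram_orders:
        feats.update(f"b:{a}_{b}" for a, b in zip(toks, toks[1:]))
    for order in ngram_orders:
        if order not in (1, 2):
            raise ValueError(f"unsupported n-gram order {order}")
    if include_symptom:
        feats.add(f"sym:{mention.symptom}")
    return frozenset(feats)


def classify_mention(
    mention: Mention, model: LinearModel, rules: RuleSet
) -> str:
    """Hybrid verdict: rules first, then the sign of the model decision value.

    A decision value of exactly 0 maps to ``not_positive`` — the
    precision-favouring tie-break.
    """
    if apply_rules(mention, rules) == FORCED_NOT_POSITIVE:
        return NOT_POSITIVE
    include_symptom = any(k.startswith("sym:") for k in model.vocabulary)
    feats = featurize(
        mention,
        ngram_orders=tuple(model.hyperparams.get("ngram_orders", (1, 2))),
        include_symptom=include_symptom,
    )
    return POSITIVE if model.decision_value(feats) > 0 else NOT_POSITIVE


def extract_patient_flags(
    documents: Sequence[Document],
    models: Mapping[str, LinearModel] | LinearModel,
    rules: RuleSet,
    lexicon: Lexicon,
    cutoff_date: dt.date | None = None,
) -> dict[str, bool]:
    """Per-symptom binary flags for one patient's documents.

    A flag is true iff at least one mention of that symptom is classified
    positive in a document dated strictly before *cutoff_date* (any date when
    the cutoff is None). *models* is either one shared model or a mapping
    symptom -> model.
    """
    patient_ids = {d.patient_id for d in documents}
    if len(patient_ids) > 1:
        raise ValueError(f"documents span multiple patients: {sorted(patient_ids)}")
    flags = {s: False for s in SYMPTOMS}
    for doc in documents:
        if cutoff_date is not None and doc.date >= cutoff_date:
            continue
        for mention in find_candidates(doc, lexicon):
            if flags[mention.symptom]:
                continue
            model = (
                models[mention.symptom] if isinstance(models, Mapping) else models
            )
            if classify_mention(mention, model, rules) == POSITIVE:
                flags[mention.symptom] = True
    return flags
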