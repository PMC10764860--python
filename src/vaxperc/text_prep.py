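"""Cleaning and tokenization of open-ended survey answers.

The preparation pipeline mirrors standard survey-NLP practice: sentence
segmentation (word association is scoped to a sentence), punctuation and URL
removal, lower-casing, tokenization, lemmatization (or stemming), fusion of
multiword driver terms into single protected tokens ("side effects" ->
"SideEffects"), and stopword removal. Protected compounds keep their
canonical capitalization; everything else is lowercase.

The lemmatizer is a deterministic rule-and-lexicon normalizer: irregular
forms are looked up, then candidate suffix transformations are accepted only
when they land on a known base form. Participial and predicative terms that
the word graphs display as-is ("worried", "vaccinated", "confident") are
base forms themselves, so they survive unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

from . import resources

__all__ = [
    "split_sentences",
    "clean_and_tokenize",
    "lemmatize",
    "stem",
    "normalize_compounds",
    "remove_stopwords",
    "prepare_document",
    "TokenizedCorpus",
]

_URL_RE = re.compile(r"(?:https?://|www\.)\S+|\b\w+\.\w{2,3}(?:/\S*)?(?=\s|$)")
_SENT_SPLIT_RE = re.compile(r"(?<=[.!?])\s+")
_TOKEN_RE = re.compile(r"[A-Za-z]+")


def split_sentences(raw_text: str) -> List[str]:
    """Split free text into sentences on terminal punctuation.

    Text without a terminal mark is a single sentence; empty or blank input
    gives an empty list.
    """
    if not raw_text or not raw_text.strip():
        return []
    parts = _SENT_SPLIT_RE.split(raw_text.strip())
    return [p for p in (q.strip() for q in parts) if p]


def _protected_lower() -> FrozenSet[str]:
    return frozenset(canon.lower() for _, canon in resources.compound_lexicon())


def lemmatize(word: str) -> str:
    """Normalize an inflected word to its lemma.

    Irregulars first, then the base-form lexicon, then suffix rules whose
    candidates are validated against the lexicon, then a conservative
    plural strip as fallback. Fused compound tokens are left untouched.
    """
    if word.lower() in _protected_lower():
        return word
    exceptions = resources.lemma_exceptions()
    if word in exceptions:
        return exceptions[word]
    base = resources.baseforms()
    if word in base:
        return word

    def ok(cand: str) -> Optional[str]:
        return cand if cand in base else None

    if word.endswith("ies") and len(word) > 4:
        hit = ok(word[:-3] + "y")
        if hit:
            return hit
    if word.endswith("ied") and len(word) > 4:
        hit = ok(word[:-3] + "y")
        if hit:
            return hit
    if word.endswith("es") and len(word) > 3:
        hit = ok(word[:-2]) or ok(word[:-1])
        if hit:
            return hit
    if word.endswith("ed") and len(word) > 3:
        # advised -> advise, wanted -> want, stopped -> stop
        hit = ok(word[:-1]) or ok(word[:-2])
        if hit:
            return hit
        if len(word) > 4 and word[-3] == word[-4]:
            hit = ok(word[:-3])
            if hit:
                return hit
    if word.endswith("ing") and len(word) > 4:
        hit = ok(word[:-3]) or ok(word[:-3] + "e")
        if hit:
            return hit
        if len(word) > 5 and word[-4] == word[-5]:
            hit = ok(word[:-4])
            if hit:
                return hit
    if word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        hit = ok(word[:-1])
        if hit:
            return hit
        return word[:-1]
    return word


_STEM_SUFFIXES = ("ational", "fulness", "ousness", "iveness", "ization",
                  "ation", "ness", "ment", "tion", "ing", "ies", "ied",
                  "est", "ful", "ous", "ive", "ize", "ed", "es", "ly", "s")


def stem(word: str) -> str:
    """Light suffix-stripping stemmer (alternative normalizer to the lemmatizer)."""
    if word.lower() in _protected_lower():
        return word
    for suf in _STEM_SUFFIXES:
        if word.endswith(suf) and len(word) - len(suf) >= 3:
            stemmed = word[: -len(suf)]
            if suf in ("ies", "ied"):
                stemmed += "i"
            return stemmed
    return word


def clean_and_tokenize(sentence: str, lemmatize_tokens: bool = True) -> List[str]:
    """Clean one sentence into normalized lowercase tokens.

    URLs are dropped, punctuation is stripped, the remainder is lower-cased,
    tokenized on non-letter boundaries and lemmatized (default) or stemmed.
    """
    text = _URL_RE.sub(" ", sentence)
    tokens = [t.lower() for t in _TOKEN_RE.findall(text)]
    norm = lemmatize if lemmatize_tokens else stem
    return [norm(t) for t in tokens]


def normalize_compounds(
    tokens: Sequence[str],
    compound_lexicon: Optional[Iterable[Tuple[Tuple[str, ...], str]]] = None,
) -> List[str]:
    """Fuse multiword driver terms into their canonical single tokens.

    Maximal left-to-right matches of a lexicon sequence are replaced by the
    canonical token; the canonical token itself (already-fused input) is
    also mapped to canonical form, so the operation is idempotent.
    """
    lex = list(compound_lexicon if compound_lexicon is not None
               else resources.compound_lexicon())
    if not lex:
        return list(tokens)
    canon_lower = {canon.lower(): canon for _, canon in lex}
    out: List[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for seq, canon in lex:
            L = len(seq)
            if tuple(tokens[i:i + L]) == seq:
                out.append(canon)
                i += L
                matched = True
                break
        if not matched:
            tok = tokens[i]
            out.append(canon_lower.get(tok.lower(), tok))
            i += 1
    return out


def remove_stopwords(tokens: Sequence[str], stoplist: Optional[FrozenSet[str]] = None) -> List[str]:
    """Drop stoplist members, preserving order. "no" is kept by default."""
    stop = resources.stopwords() if stoplist is None else stoplist
    return [t for t in tokens if t.lower() not in stop]


def prepare_document(
    raw_text: str,
    lemmatize_tokens: bool = True,
    stoplist: Optional[FrozenSet[str]] = None,
    compound_lexicon: Optional[Iterable[Tuple[Tuple[str, ...], str]]] = None,
) -> List[List[str]]:
    """Full pipeline for one open answer: list of cleaned token sentences.

    Empty sentences (after cleaning) are dropped.
    """
    sentences = []
    for sent in split_sentences(raw_text):
        toks = clean_and_tokenize(sent, lemmatize_tokens=lemmatize_tokens)
        toks = normalize_compounds(toks, compound_lexicon)
        toks = remove_stopwords(toks, stoplist)
        if toks:
            sentences.append(toks)
    return sentences


@dataclass
class TokenizedCorpus:
    """Sentence-segmented token streams for one open-ended question.

    ``documents`` maps respondent id -> list of token sentences. Iterating
    the corpus yields sentences in respondent order.
    """

    question: str
    documents: Dict[str, List[List[str]]] = field(default_factory=dict)

    def sentences(self) -> List[List[str]]:
        out = []
        for rid in self.documents:
            out.extend(self.documents[rid])
        return out

    def tokens(self) -> List[str]:
        return [t for s in self.sentences() for t in s]

    @classmethod
    def from_answers(
        cls,
        question: str,
        answers: Mapping[str, str],
        lemmatize_tokens: bool = True,
        stoplist: Optional[FrozenSet[str]] = None,
        compound_lexicon: Optional[Iterable[Tuple[Tuple[str, ...], str]]] = None,
    ) -> "TokenizedCorpus":
        docs = {
            rid: prepare_document(
                text, lemmatize_tokens=lemmatize_tokens,
                stoplist=stoplist, compound_lexicon=compound_lexicon)
            for rid, text in answers.items()
        }
        return cls(question=question, documents=docs)
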