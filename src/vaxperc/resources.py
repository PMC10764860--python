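"""Loaders for the plain-text resources shipped with the package.

Every resource is a line-oriented UTF-8 text file under ``vaxperc/_resources``
so that tests are bit-stable and users can swap in their own lists (stoplist,
sentiment lexica, compound lexicon, transition rules) without code changes.
Lines starting with ``#`` are comments.
"""

from __future__ import annotations

import functools
from importlib import resources as _ilr
from typing import Dict, List, Tuple

import yaml

_PKG = "vaxperc._resources"


def _read_text(name: str) -> str:
    return _ilr.files(_PKG).joinpath(name).read_text(encoding="utf-8")


def _lines(name: str) -> List[str]:
    out = []
    for line in _read_text(name).splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


@functools.lru_cache(maxsize=None)
def stopwords() -> frozenset:
    """Default English stoplist (the negator "no" is deliberately retained)."""
    return frozenset(_lines("stopwords.txt"))


@functools.lru_cache(maxsize=None)
def compound_lexicon() -> Tuple[Tuple[Tuple[str, ...], str], ...]:
    """Multiword sequences and their fused canonical tokens.

    Returns ``((("side", "effect"), "SideEffects"), ...)`` sorted longest
    sequence first so maximal matches win.
    """
    entries = []
    for line in _lines("compounds.txt"):
        spaced, _, canon = line.partition("->")
        seq = tuple(spaced.split())
        entries.append((seq, canon.strip()))
    entries.sort(key=lambda e: -len(e[0]))
    return tuple(entries)


@functools.lru_cache(maxsize=None)
def baseforms() -> frozenset:
    return frozenset(_lines("baseforms.txt"))


@functools.lru_cache(maxsize=None)
def lemma_exceptions() -> Dict[str, str]:
    out = {}
    for line in _lines("lemma_exceptions.txt"):
        form, lemma = line.split()
        out[form] = lemma
    return out


@functools.lru_cache(maxsize=None)
def pos_lexicon() -> Dict[str, str]:
    out = {}
    for line in _lines("pos_lexicon.txt"):
        word, cls = line.split()
        out[word] = cls
    return out


@functools.lru_cache(maxsize=None)
def positive_words() -> frozenset:
    return frozenset(_lines("positive_words.txt"))


@functools.lru_cache(maxsize=None)
def negative_words() -> frozenset:
    return frozenset(_lines("negative_words.txt"))


@functools.lru_cache(maxsize=None)
def peer_words() -> frozenset:
    return frozenset(_lines("peer_words.txt"))


def transition_rule_templates() -> List[dict]:
    """Raw declarative transition-rule templates (the default structure)."""
    return yaml.safe_load(_read_text("transition_rules.yaml"))["rules"]


def default_survey_config() -> dict:
    """Default synthetic-survey configuration as a plain dict."""
    return yaml.safe_load(_read_text("default_survey.yaml"))
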