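"""Driving-factor extraction: term frequencies, bag-of-words, POS-restricted
word-association graphs and polarity annotation.

For each open-ended question the cleaned corpus yields a normalized term
frequency table; the top-k words (default k=6) form the bag-of-words whose
members become graph hubs. A hub b and a word xi are associated when xi is a
noun (for the noun graph G_n) or a verb (for the verb graph G_v) and xi and
b occur in the same sentence; edges carry the number of co-occurring
sentences. Node polarity (positive / negative / neutral / peer) comes from
sentiment word lists with manual overrides for neutral terms.

Part-of-speech classes come from a deterministic lexicon-plus-suffix tagger
collapsed to {noun, verb, other}; fused compound tokens ("SideEffects") are
always nouns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import pandas as pd

from . import resources
from .text_prep import TokenizedCorpus

__all__ = [
    "BagOfWords",
    "term_frequencies",
    "select_top_k",
    "tag_pos",
    "build_association_graph",
    "annotate_polarity",
    "graph_to_edge_frame",
]

_NOUN_SUFFIXES = ("tion", "sion", "ment", "ness", "ity", "ance", "ence",
                  "ship", "ism", "er", "or")
_VERB_SUFFIXES = ("ize", "ise", "ify", "ing", "ed")


@dataclass
class BagOfWords:
    """Top-k words of one question's corpus by normalized frequency."""

    question: str
    ranking: List[Tuple[str, float]]
    k: int

    @property
    def words(self) -> List[str]:
        return [w for w, _ in self.ranking]

    def __contains__(self, word: str) -> bool:
        return word in set(self.words)


def term_frequencies(corpus: TokenizedCorpus) -> pd.Series:
    """Normalized term frequencies over one question's cleaned corpus.

    Returns a Series indexed by word, summing to 1, sorted by descending
    frequency then word. Empty corpus gives an empty Series.
    """
    tokens = corpus.tokens()
    if not tokens:
        return pd.Series(dtype=float, name=corpus.question)
    counts = pd.Series(tokens).value_counts()
    freq = counts / counts.sum()
    freq = freq.sort_index().sort_values(ascending=False, kind="stable")
    freq.name = corpus.question
    return freq


def select_top_k(freq_table: pd.Series, k: int = 6,
                 question: Optional[str] = None) -> BagOfWords:
    """The k most frequent words; ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(freq_table.items(), key=lambda wf: (-wf[1], wf[0]))
    top = order[:k]
    return BagOfWords(question=question or str(freq_table.name or ""),
                      ranking=[(w, float(f)) for w, f in top], k=k)


def tag_pos(sentence_tokens: Sequence[str],
            lexicon: Optional[Mapping[str, str]] = None) -> List[Tuple[str, str]]:
    """Tag each token with a coarse class in {noun, verb, other}.

    Fused compounds (tokens with an internal capital) are nouns; known words
    come from the lexicon; unknown words fall back to suffix heuristics and
    default to noun, the standard tagger fallback.
    """
    lex = resources.pos_lexicon() if lexicon is None else lexicon
    out = []
    for tok in sentence_tokens:
        if tok[:1].isupper() or any(c.isupper() for c in tok[1:]):
            out.append((tok, "noun"))
            continue
        cls = lex.get(tok)
        if cls is None:
            if tok.endswith(_VERB_SUFFIXES):
                cls = "verb"
            elif tok.endswith(_NOUN_SUFFIXES):
                cls = "noun"
            else:
                cls = "noun"
        out.append((tok, cls))
    return out


def build_association_graph(corpus: TokenizedCorpus, bag: BagOfWords,
                            pos_class: str,
                            lexicon: Optional[Mapping[str, str]] = None
                            ) -> nx.Graph:
    """Sentence-co-occurrence graph between bag hubs and nouns or verbs.

    For every hub b in the bag and word xi of the requested class appearing
    with b in at least one sentence, the graph holds an undirected edge
    (b, xi) weighted by the number of such sentences. Hubs without
    associates remain as isolated flagged nodes; a co-occurrence of two
    hubs is a single edge flagged ``hub_hub``.
    """
    if pos_class not in ("noun", "verb"):
        raise ValueError("pos_class must be 'noun' or 'verb'")
    if not bag.words:
        raise ValueError("empty bag-of-words")
    hubs = set(bag.words)
    G = nx.Graph(question=corpus.question, pos_class=pos_class)
    for h in bag.words:
        G.add_node(h, is_hub=True, polarity="neutral")
    for sent in corpus.sentences():
        tagged = dict(tag_pos(sent, lexicon))
        present_hubs = [h for h in bag.words if h in tagged]
        if not present_hubs:
            continue
        seen_pairs = set()
        for h in present_hubs:
            for tok, cls in tagged.items():
                if tok == h:
                    continue
                is_hub_pair = tok in hubs
                if not is_hub_pair and cls != pos_class:
                    continue
                pair = frozenset((h, tok))
                if pair in seen_pairs:
                    continue
                seen_pairs.add(pair)
                if G.has_edge(h, tok):
                    G[h][tok]["count"] += 1
                else:
                    if tok not in G:
                        G.add_node(tok, is_hub=False, polarity="neutral")
                    G.add_edge(h, tok, count=1, hub_hub=is_hub_pair)
    return G


def annotate_polarity(graph: nx.Graph,
                      positive_list: Optional[Iterable[str]] = None,
                      negative_list: Optional[Iterable[str]] = None,
                      peer_list: Optional[Iterable[str]] = None,
                      manual_overrides: Optional[Mapping[str, str]] = None
                      ) -> nx.Graph:
    """Mark node polarity: override > peer > positive/negative > neutral.

    A word present in both sentiment lists without an override is an error
    (the lists must be disjoint after overrides are applied).
    """
    pos = set(resources.positive_words() if positive_list is None
              else positive_list)
    neg = set(resources.negative_words() if negative_list is None
              else negative_list)
    peer = set(resources.peer_words() if peer_list is None else peer_list)
    overrides = dict(manual_overrides or {})
    for node in graph.nodes:
        if node in overrides:
            graph.nodes[node]["polarity"] = overrides[node]
            continue
        if node in pos and node in neg:
            raise ValueError(
                f"{node!r} appears in both sentiment lists; add an override")
        if node in peer:
            graph.nodes[node]["polarity"] = "peer"
        elif node in pos:
            graph.nodes[node]["polarity"] = "positive"
        elif node in neg:
            graph.nodes[node]["polarity"] = "negative"
        else:
            graph.nodes[node]["polarity"] = "neutral"
    return graph


def graph_to_edge_frame(graph: nx.Graph) -> pd.DataFrame:
    """Edge-list export: hub, word, pos_class, count, polarity of the word."""
    rows = []
    for a, b, data in graph.edges(data=True):
        hub, word = (a, b) if graph.nodes[a].get("is_hub") else (b, a)
        rows.append({
            "hub": hub,
            "word": word,
            "pos_class": graph.graph.get("pos_class", ""),
            "count": data["count"],
            "polarity": graph.nodes[word].get("polarity", "neutral"),
        })
    return pd.DataFrame(rows, columns=["hub", "word", "pos_class", "count",
                                       "polarity"])


def question_graphs(corpus: TokenizedCorpus, k: int = 6,
                    lexicon: Optional[Mapping[str, str]] = None,
                    annotate: bool = True) -> Dict[str, nx.Graph]:
    """Noun and verb association graphs for one question's corpus."""
    freq = term_frequencies(corpus)
    if freq.empty:
        return {}
    bag = select_top_k(freq, k=k, question=corpus.question)
    out = {}
    for cls in ("noun", "verb"):
        G = build_association_graph(corpus, bag, cls, lexicon)
        if annotate:
            annotate_polarity(G)
        out[cls] = G
    return out
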