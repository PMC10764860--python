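"""Term frequencies, bags-of-words and association graphs vs brute force."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from vaxperc import resources
from vaxperc.synthetic_survey import generate_survey_dataset, profiles_from_config
from vaxperc.text_prep import TokenizedCorpus
from vaxperc.word_graph import (
    annotate_polarity,
    build_association_graph,
    graph_to_edge_frame,
    select_top_k,
    tag_pos,
    term_frequencies,
)


def _corpus(sentences, question="O1"):
    return TokenizedCorpus(question=question, documents={"R0": sentences})


def test_term_frequencies_normalized():
    freq = term_frequencies(_corpus([["a", "a", "b"]]))
    assert freq["a"] == pytest.approx(2 / 3)
    assert freq["b"] == pytest.approx(1 / 3)
    assert freq.sum() == pytest.approx(1.0)
    assert term_frequencies(_corpus([["only"]]))["only"] == 1.0
    assert term_frequencies(_corpus([])).empty


def test_select_top_k_and_ties():
    t = pd.Series({"a": 0.5, "b": 0.3, "c": 0.2})
    assert select_top_k(t, 2).words == ["a", "b"]
    tie = pd.Series({"c": 0.25, "a": 0.5, "b": 0.25})
    assert select_top_k(tie, 2).words == ["a", "b"]      # lexicographic tie
    assert select_top_k(t, 99).words == ["a", "b", "c"]
    with pytest.raises(ValueError):
        select_top_k(t, 0)


def test_tag_pos_examples():
    assert tag_pos(["doctor", "advise"]) == [("doctor", "noun"),
                                             ("advise", "verb")]
    assert tag_pos(["FamilyMembers"]) == [("FamilyMembers", "noun")]
    assert tag_pos([]) == []
    # unknown words fall back to suffix heuristics / noun default
    assert tag_pos(["flibbertigibbet"])[0][1] == "noun"
    assert tag_pos(["crystallize"])[0][1] == "verb"


def test_build_graph_single_sentence():
    corpus = _corpus([["FamilyMembers", "take", "vaccine"]])
    bag = select_top_k(pd.Series({"take": 1.0}), 1, question="O1")
    G = build_association_graph(corpus, bag, "noun")
    assert set(map(frozenset, G.edges())) == {
        frozenset({"take", "FamilyMembers"}), frozenset({"take", "vaccine"})}
    assert G["take"]["FamilyMembers"]["count"] == 1


def test_absent_hub_is_isolated():
    corpus = _corpus([["vaccine", "works"]])
    bag = select_top_k(pd.Series({"zebra": 1.0}), 1)
    G = build_association_graph(corpus, bag, "noun")
    assert G.number_of_edges() == 0
    assert G.nodes["zebra"]["is_hub"]


def _brute_edges(sentences, hubs, pos_class):
    """All-pairs sentence scan oracle."""
    counts = {}
    for sent in sentences:
        done = set()
        for h in hubs:
            if h not in sent:
                continue
            for tok in sent:
                if tok == h:
                    continue
                cls = dict(tag_pos([tok]))[tok]
                if tok not in hubs and cls != pos_class:
                    continue
                key = frozenset((h, tok))
                if key in done:
                    continue
                done.add(key)
                counts[key] = counts.get(key, 0) + 1
    return counts


def test_graph_matches_brute_force(rng):
    vocab = ["doctor", "advice", "take", "vaccine", "peer", "seem",
             "health", "feel", "slot"]
    sentences = [list(rng.choice(vocab, size=rng.integers(2, 6)))
                 for _ in range(40)]
    corpus = _corpus(sentences)
    bag = select_top_k(term_frequencies(corpus), 3)
    for cls in ("noun", "verb"):
        G = build_association_graph(corpus, bag, cls)
        got = {frozenset((a, b)): d["count"]
               for a, b, d in G.edges(data=True)}
        assert got == _brute_edges(sentences, set(bag.words), cls)


def test_graph_order_independent(rng):
    vocab = ["doctor", "advice", "take", "vaccine", "health"]
    sentences = [list(rng.choice(vocab, size=3)) for _ in range(25)]
    bag = select_top_k(term_frequencies(_corpus(sentences)), 2)
    G1 = build_association_graph(_corpus(sentences), bag, "noun")
    shuffled = list(sentences)
    rng.shuffle(shuffled)
    G2 = build_association_graph(_corpus(shuffled), bag, "noun")
    e1 = {frozenset((a, b)): d["count"] for a, b, d in G1.edges(data=True)}
    e2 = {frozenset((a, b)): d["count"] for a, b, d in G2.edges(data=True)}
    assert e1 == e2


def test_zero_noise_graph_equals_planted_pairs():
    """With no noise, edges are exactly the planted template co-locations."""
    cfg = resources.default_survey_config()
    cfg["noise"] = {"rate": 0.0, "vocab": []}
    ds = generate_survey_dataset(cfg, seed=23)
    profiles = {p.label: p for p in profiles_from_config(cfg)}
    for label in ("U", "H", "W"):
        prof = profiles[label]
        q = prof.open_question
        corpus = TokenizedCorpus.from_answers(q, ds.open_answers(q))
        hubs = sorted({t.hub for t in prof.keyword_templates})
        bag = select_top_k(
            pd.Series({h: 1.0 / len(hubs) for h in hubs}), len(hubs),
            question=q)
        for cls in ("noun", "verb"):
            G = build_association_graph(corpus, bag, cls)
            planted = {frozenset((t.hub, t.associate))
                       for t in prof.keyword_templates if t.pos == cls}
            got = {frozenset((a, b)) for a, b in G.edges()}
            assert got == planted, (label, cls)


def test_hub_recovery_from_planted_hesitant_corpus():
    """The hesitant corpus recovers its seeded transition co-locations."""
    cfg = resources.default_survey_config()
    cfg["noise"] = {"rate": 0.0, "vocab": []}
    ds = generate_survey_dataset(cfg, n=400, seed=5)
    corpus = TokenizedCorpus.from_answers("O2", ds.open_answers("O2"))
    freq = term_frequencies(corpus)
    assert freq.index[0] == "SideEffects"       # dominant driver term
    bag = select_top_k(freq, 6, question="O2")
    Gv = build_association_graph(corpus, bag, "verb")
    pairs = {frozenset((a, b)) for a, b in Gv.edges()}
    assert frozenset({"SideEffects", "confident"}) in pairs
    Gn = build_association_graph(corpus, bag, "noun")
    all_pairs = pairs | {frozenset((a, b)) for a, b in Gn.edges()}
    assert frozenset({"effective", "people"}) in all_pairs


def test_noun_and_verb_graphs_intersect_only_on_hubs():
    cfg = resources.default_survey_config()
    ds = generate_survey_dataset(cfg, seed=7)
    corpus = TokenizedCorpus.from_answers("O1", ds.open_answers("O1"))
    bag = select_top_k(term_frequencies(corpus), 6, question="O1")
    Gn = build_association_graph(corpus, bag, "noun")
    Gv = build_association_graph(corpus, bag, "verb")
    shared = set(Gn.nodes) & set(Gv.nodes)
    assert shared <= set(bag.words)


def test_polarity_annotation():
    G = nx.Graph(pos_class="verb")
    for w in ("confident", "health", "worried", "peer", "SideEffects"):
        G.add_node(w, is_hub=False, polarity="neutral")
    annotate_polarity(G)
    assert G.nodes["confident"]["polarity"] == "positive"
    assert G.nodes["worried"]["polarity"] == "negative"
    assert G.nodes["health"]["polarity"] == "neutral"
    assert G.nodes["peer"]["polarity"] == "peer"

    annotate_polarity(G, manual_overrides={"health": "negative"})
    assert G.nodes["health"]["polarity"] == "negative"

    with pytest.raises(ValueError):
        annotate_polarity(G, positive_list=["health"],
                          negative_list=["health"], peer_list=[])

    annotate_polarity(G, positive_list=[], negative_list=[], peer_list=[],
                      manual_overrides={})
    assert all(G.nodes[n]["polarity"] == "neutral" for n in G)


def test_edge_frame_export():
    corpus = _corpus([["take", "FamilyMembers"]])
    bag = select_top_k(pd.Series({"take": 1.0}), 1)
    G = build_association_graph(corpus, bag, "noun")
    annotate_polarity(G)
    frame = graph_to_edge_frame(G)
    assert list(frame.columns) == ["hub", "word", "pos_class", "count",
                                   "polarity"]
    assert frame.loc[0, "hub"] == "take"
    assert frame.loc[0, "polarity"] == "peer"     # FamilyMembers is peer-marked
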