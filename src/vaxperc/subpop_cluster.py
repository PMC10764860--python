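"""Compartment identification by agglomerative average-linkage clustering.

Respondents' closed-ended answers are vectorized (categorical options
one-hot, 1-10 scales mapped to [0,1]) and clustered bottom-up: starting from
singletons, the pair of clusters with the smallest average linkage

    d_al(Ci, Cj) = (1 / |Ci||Cj|) * sum of pairwise l2 distances

is merged until one cluster remains. The merge tree is cut either at a
height threshold or to a target number of clusters; on vaccine-perception
surveys the four-cluster cut separates the unwilling (U), hesitant (H),
willing (W) and vaccinated (V) subpopulations, with the first split dividing
the vaccine-reluctant {U, H} from the enthusiasts {W, V}.

The agglomeration is implemented directly (Lance-Williams average update
with a deterministic lowest-id tie-break) so merge order is reproducible
across platforms; scipy's hierarchical clustering is used in the test suite
as an independent cross-check, never as the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .synthetic_survey import SCALE_VALUES, SurveyDataset, ValidationError

__all__ = [
    "RespondentVector",
    "Dendrogram",
    "ClusterAssignment",
    "vectorize_closed",
    "linkage_distance",
    "agglomerate",
    "cut_tree",
    "suggest_cut_height",
    "assign_semantic_labels",
]


@dataclass(frozen=True)
class RespondentVector:
    respondent_id: str
    x: np.ndarray


@dataclass
class Dendrogram:
    """Merge list: (cluster_a, cluster_b, height, new_cluster_id) per step.

    Original observations are clusters ``0..n-1``; merge ``i`` creates
    cluster ``n+i`` (the scipy linkage-id convention). Average linkage with
    a metric distance is monotone, so heights never decrease.
    """

    merges: List[Tuple[int, int, float, int]]
    n_leaves: int

    def heights(self) -> np.ndarray:
        return np.array([m[2] for m in self.merges])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["a", "b", "height", "new_id"])


@dataclass
class ClusterAssignment:
    """Respondent -> contiguous cluster index, with optional semantic labels."""

    respondent_ids: List[str]
    clusters: np.ndarray
    cut: object
    labels: Optional[Dict[int, str]] = None

    def n_clusters(self) -> int:
        return len(np.unique(self.clusters))

    def members(self, cluster: int) -> List[str]:
        return [r for r, c in zip(self.respondent_ids, self.clusters)
                if c == cluster]

    def label_of(self, respondent_id: str) -> Optional[str]:
        if self.labels is None:
            return None
        i = self.respondent_ids.index(respondent_id)
        return self.labels.get(int(self.clusters[i]))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"respondent_id": self.respondent_ids,
                           "cluster": self.clusters})
        if self.labels is not None:
            df["label"] = [self.labels.get(int(c), "") for c in self.clusters]
        return df


def vectorize_closed(dataset: SurveyDataset,
                     encoding_spec: Optional[Dict[str, object]] = None
                     ) -> List[RespondentVector]:
    """Concatenate each respondent's closed answers into a numeric vector.

    Categorical options are one-hot in schema option order; scale answers
    map to [0,1] via (value - 1) / 9 so a single 1-10 question cannot
    dominate the one-hot coordinates. Questions appear in schema order.
    """
    schema = dataset.question_schema
    questions = dataset.closed_questions()
    blocks = []
    for q in questions:
        spec = schema[q]
        col = dataset.table[q]
        if spec.kind == "categorical":
            codes = col.astype(str)
            for rid, val in zip(dataset.respondent_ids, codes):
                if val not in spec.options:
                    raise ValidationError(
                        f"respondent {rid}: unknown code {val!r} for {q}")
            block = np.stack([
                (codes == opt).to_numpy(float) for opt in spec.options], axis=1)
        else:
            vals = pd.to_numeric(col).to_numpy(float)
            if ((vals < min(SCALE_VALUES)) | (vals > max(SCALE_VALUES))).any():
                bad = dataset.respondent_ids[int(np.argmax(
                    (vals < 1) | (vals > 10)))]
                raise ValidationError(
                    f"respondent {bad}: scale answer out of range for {q}")
            block = ((vals - 1.0) / 9.0)[:, None]
        blocks.append(block)
    X = np.hstack(blocks)
    return [RespondentVector(rid, X[i])
            for i, rid in enumerate(dataset.respondent_ids)]


def linkage_distance(Ci: Sequence[np.ndarray], Cj: Sequence[np.ndarray]) -> float:
    """Average linkage: mean pairwise l2 distance between two clusters."""
    if len(Ci) == 0 or len(Cj) == 0:
        raise ValidationError("linkage distance of an empty cluster")
    A = np.asarray(Ci, float)
    B = np.asarray(Cj, float)
    diff = A[:, None, :] - B[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).mean())


def agglomerate(vectors: Sequence[RespondentVector]) -> Dendrogram:
    """Bottom-up average-linkage agglomeration of respondent vectors.

    Exact Lance-Williams update: after merging clusters a and b,
    d(ab, k) = (|a| d(a,k) + |b| d(b,k)) / (|a| + |b|), which reproduces the
    brute-force mean of pairwise distances at every step. Ties are broken
    toward the pair with the lowest cluster ids.
    """
    n = len(vectors)
    if n < 2:
        raise ValidationError("need at least 2 vectors to agglomerate")
    X = np.stack([v.x for v in vectors])
    # condensed-style full matrix with inf diagonal
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))

    active_ids = list(range(n))          # cluster ids, ascending
    sizes = {i: 1 for i in range(n)}
    merges: List[Tuple[int, int, float, int]] = []
    big = np.inf
    np.fill_diagonal(D, big)

    for step in range(n - 1):
        m = len(active_ids)
        # active_ids stays ascending (new ids are appended last), so the
        # first flat argmin over the row-major matrix realizes the
        # lowest-(min id, then max id) tie-break
        flat = int(np.argmin(D))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        h = float(D[i, j])
        a, b = active_ids[i], active_ids[j]
        new_id = n + step
        na, nb = sizes[a], sizes[b]
        # Lance-Williams average-linkage row for the merged cluster
        drow = (na * D[i, :] + nb * D[j, :]) / (na + nb)
        drow = np.delete(drow, [i, j])
        D = np.delete(np.delete(D, [i, j], axis=0), [i, j], axis=1)
        D = np.pad(D, ((0, 1), (0, 1)), constant_values=big)
        D[-1, :-1] = drow
        D[:-1, -1] = drow
        del active_ids[j], active_ids[i]
        active_ids.append(new_id)
        sizes[new_id] = na + nb
        merges.append((a, b, h, new_id))
    return Dendrogram(merges=merges, n_leaves=n)


def _components(dendrogram: Dendrogram, n_merges: int) -> np.ndarray:
    """Leaf partition after applying the first ``n_merges`` merges."""
    n = dendrogram.n_leaves
    members: Dict[int, List[int]] = {i: [i] for i in range(n)}
    for a, b, _, new_id in dendrogram.merges[:n_merges]:
        members[new_id] = members.pop(a) + members.pop(b)
    out = np.empty(n, int)
    # contiguous cluster indices ordered by smallest leaf
    for idx, key in enumerate(sorted(members, key=lambda k: min(members[k]))):
        out[members[key]] = idx
    return out


def cut_tree(dendrogram: Dendrogram, cut) -> ClusterAssignment:
    """Cut the merge tree at a height (float) or to ``k`` clusters (int).

    A height cut applies every merge with height strictly below the
    threshold; a count cut stops after ``n - k`` merges.
    """
    n = dendrogram.n_leaves
    if isinstance(cut, (int, np.integer)) and not isinstance(cut, bool):
        k = int(cut)
        if not 1 <= k <= n:
            raise ValidationError(f"k={k} outside 1..{n}")
        n_merges = n - k
    else:
        t = float(cut)
        if t < 0:
            raise ValidationError("cut height must be >= 0")
        n_merges = int(np.sum(dendrogram.heights() < t))
    clusters = _components(dendrogram, n_merges)
    return ClusterAssignment(respondent_ids=[], clusters=clusters, cut=cut)


def suggest_cut_height(dendrogram: Dendrogram, window: int = 8) -> float:
    """Threshold at the largest gap between consecutive late merge heights.

    Operationalizes "cut where the linkage distance becomes considerably
    large": among the last ``window`` merges, place the threshold midway
    across the widest jump in merge height.
    """
    h = dendrogram.heights()
    tail = h[-min(window, len(h)):]
    if len(tail) < 2:
        return float(tail[-1])
    gaps = np.diff(tail)
    i = int(np.argmax(gaps))
    return float((tail[i] + tail[i + 1]) / 2.0)


def assign_semantic_labels(assignment: ClusterAssignment,
                           dataset: SurveyDataset,
                           willingness_question: str = "Q3",
                           vaccinated_question: str = "Q2",
                           vaccinated_code: str = "Yes") -> ClusterAssignment:
    """Post-hoc {U,H,W,V} labels from cluster-mean answers.

    The cluster with the highest share of already-vaccinated answers is V;
    the rest rank U < H < W by mean willingness. Only defined for
    assignments with exactly four clusters.
    """
    ks = sorted(int(c) for c in np.unique(assignment.clusters))
    if len(ks) != 4:
        raise ValidationError("semantic labels require exactly 4 clusters")
    will = pd.to_numeric(dataset.table[willingness_question]).to_numpy(float)
    vacc = (dataset.table[vaccinated_question].astype(str)
            == vaccinated_code).to_numpy(float)
    vshare = {k: vacc[assignment.clusters == k].mean() for k in ks}
    v_cluster = max(ks, key=lambda k: (vshare[k], will[assignment.clusters == k].mean()))
    rest = sorted((k for k in ks if k != v_cluster),
                  key=lambda k: will[assignment.clusters == k].mean())
    labels = {v_cluster: "V"}
    for k, lab in zip(rest, ("U", "H", "W")):
        labels[k] = lab
    return ClusterAssignment(
        respondent_ids=assignment.respondent_ids,
        clusters=assignment.clusters,
        cut=assignment.cut,
        labels=labels,
    )


def cluster_dataset(dataset: SurveyDataset, cut=4,
                    semantic: bool = True,
                    willingness_question: str = "Q3",
                    vaccinated_question: str = "Q2") -> ClusterAssignment:
    """Vectorize, agglomerate and cut in one call."""
    vectors = vectorize_closed(dataset)
    dend = agglomerate(vectors)
    if cut == "auto":
        cut_val = suggest_cut_height(dend)
    else:
        cut_val = cut
    assignment = cut_tree(dend, cut_val)
    assignment.respondent_ids = dataset.respondent_ids
    if semantic and assignment.n_clusters() == 4:
        assignment = assign_semantic_labels(
            assignment, dataset,
            willingness_question=willingness_question,
            vaccinated_question=vaccinated_question)
    return assignment
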