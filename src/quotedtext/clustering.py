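"""K-means clustering of word vectors with silhouette-guided k selection.

One-word quotation lemmas are mapped into an embedding space and grouped
with k-means (best of ``restarts`` k-means++ initialisations by inertia).
Because the inertia curve rarely shows a usable elbow, candidate cluster
counts are ranked by mean silhouette coefficient over a scan (2..20 by
default; k=1 contributes an inertia value only, silhouette being undefined
there).  The final choice is delegated to a labeler — in the original
workflow a human reading the 20 most frequent words of each cluster — which
accepts the first candidate, in descending silhouette order, that contains
at least one homogeneously labelable cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

__all__ = [
    "ClusterSolution",
    "ClusterReport",
    "KScan",
    "SelectionOutcome",
    "kmeans_cluster",
    "mean_silhouette",
    "scan_k",
    "cluster_report",
    "select_solution",
    "cluster_purity",
    "make_purity_labeler",
]


@dataclass
class ClusterSolution:
    k: int
    words: tuple[str, ...]
    assignments: dict[str, int]
    centroids: np.ndarray
    inertia: float
    mean_silhouette: float | None
    oov_words: tuple[str, ...]
    seed: int
    labels: np.ndarray = field(repr=False, default=None)

    def members(self, cluster_id: int) -> list[str]:
        return [w for w in self.words if self.assignments[w] == cluster_id]


@dataclass
class ClusterReport:
    """Per-cluster top-word listing with optional human labels."""

    k: int
    clusters: list[dict]  # cluster_id, size, top_words, label, homogeneous

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster_id": c["cluster_id"],
                    "size": c["size"],
                    "top_words": "|".join(c["top_words"]),
                    "label": c.get("label"),
                    "homogeneous": c.get("homogeneous"),
                }
                for c in self.clusters
            ]
        )


@dataclass
class KScan:
    table: pd.DataFrame  # columns k, inertia, mean_silhouette
    solutions: dict[int, ClusterSolution]


@dataclass
class SelectionOutcome:
    chosen: ClusterSolution | None
    report: ClusterReport | None
    audit_trail: list[dict]  # k, mean_silhouette, accepted

    @property
    def no_homogeneous_solution(self) -> bool:
        return self.chosen is None


def kmeans_cluster(
    matrix: np.ndarray,
    k: int,
    restarts: int = 10,
    seed: int = 0,
    words: Sequence[str] | None = None,
    oov_words: Sequence[str] = (),
) -> ClusterSolution:
    """Cluster rows of ``matrix`` with k-means, best of ``restarts`` runs.

    Lloyd iterations from k-means++ starts, at most 300 iterations each,
    keeping the run with the lowest inertia.  ``words`` labels the rows
    (defaults to row indices as strings).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if k < 1:
        raise ValueError("k must be ≥ 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of points ({n})")
    if words is None:
        words = [str(i) for i in range(n)]
    if len(words) != n:
        raise ValueError("words must align with matrix rows")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=300,
        algorithm="lloyd",
        random_state=seed,
    ).fit(matrix)
    labels = km.labels_.astype(int)
    sil = mean_silhouette(matrix, labels) if k > 1 else None
    return ClusterSolution(
        k=k,
        words=tuple(words),
        assignments={w: int(c) for w, c in zip(words, labels)},
        centroids=km.cluster_centers_,
        inertia=float(km.inertia_),
        mean_silhouette=sil,
        oov_words=tuple(oov_words),
        seed=seed,
        labels=labels,
    )


def mean_silhouette(matrix: np.ndarray, assignments: Sequence[int]) -> float:
    """Unweighted mean silhouette coefficient with Euclidean distance.

    s(i) = (b_i − a_i) / max(a_i, b_i), where a_i is the mean distance to
    the other members of i's cluster and b_i the smallest mean distance to
    another cluster.  Points in singleton clusters contribute 0, as do
    points where a_i = b_i = 0.  Undefined for a single cluster.
    """
    labels = np.asarray(assignments)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("mean silhouette requires at least 2 clusters")
    matrix = np.asarray(matrix, dtype=np.float64)
    if uniq.size == matrix.shape[0]:
        return 0.0  # every cluster a singleton
    return float(np.mean(silhouette_samples(matrix, labels, metric="euclidean")))


def scan_k(
    matrix: np.ndarray,
    k_min: int = 2,
    k_max: int = 20,
    restarts: int = 10,
    seed: int = 0,
    words: Sequence[str] | None = None,
    oov_words: Sequence[str] = (),
) -> KScan:
    """Fit one k-means solution per k in [k_min, k_max]; tabulate inertia
    and mean silhouette (NaN at k=1, where silhouette is undefined)."""
    if k_min < 1:
        raise ValueError("k_min must be ≥ 1")
    n = np.asarray(matrix).shape[0]
    if k_max > n:
        raise ValueError(f"k_max={k_max} exceeds number of points ({n})")
    if k_min > k_max:
        raise ValueError("k_min must not exceed k_max")
    solutions: dict[int, ClusterSolution] = {}
    rows = []
    for k in range(k_min, k_max + 1):
        sol = kmeans_cluster(matrix, k, restarts=restarts, seed=seed, words=words, oov_words=oov_words)
        solutions[k] = sol
        rows.append(
            {
                "k": k,
                "inertia": sol.inertia,
                "mean_silhouette": math.nan if sol.mean_silhouette is None else sol.mean_silhouette,
            }
        )
    return KScan(table=pd.DataFrame(rows), solutions=solutions)


def cluster_report(
    solution: ClusterSolution,
    frequencies: Mapping[str, int],
    top_n: int = 20,
) -> ClusterReport:
    """List each cluster's ``top_n`` most frequent member words.

    Words are ordered by descending corpus frequency with alphabetical
    tie-break; a cluster smaller than ``top_n`` lists all its members.
    """
    missing = [w for w in solution.words if w not in frequencies]
    if missing:
        raise ValueError(f"no frequency for words: {missing[:5]}")
    clusters = []
    for cid in range(solution.k):
        members = solution.members(cid)
        members.sort(key=lambda w: (-frequencies[w], w))
        clusters.append(
            {
                "cluster_id": cid,
                "size": len(members),
                "top_words": members[:top_n],
                "label": None,
                "homogeneous": None,
            }
        )
    return ClusterReport(k=solution.k, clusters=clusters)


Labeler = Callable[[ClusterReport], Mapping[int, tuple[str, bool]]]


def select_solution(
    scan: KScan,
    frequencies: Mapping[str, int],
    labeler: Labeler,
    top_n: int = 20,
) -> SelectionOutcome:
    """Iterate k candidates in descending mean-silhouette order and stop at
    the first whose report the labeler awards ≥1 homogeneous cluster.

    Ties on silhouette prefer the smaller k (parsimony).  If the labeler
    rejects every candidate the outcome records that explicitly rather than
    raising.  The audit trail keeps every k examined, in order.
    """
    tbl = scan.table.dropna(subset=["mean_silhouette"])
    if tbl.empty:
        raise ValueError("scan contains no k with a defined silhouette")
    order = tbl.sort_values(
        ["mean_silhouette", "k"], ascending=[False, True], kind="mergesort"
    )["k"].tolist()
    audit: list[dict] = []
    for k in order:
        sol = scan.solutions[int(k)]
        report = cluster_report(sol, frequencies, top_n=top_n)
        verdicts = labeler(report)
        any_homogeneous = False
        for c in report.clusters:
            label, homogeneous = verdicts.get(c["cluster_id"], (None, False))
            c["label"] = label
            c["homogeneous"] = bool(homogeneous)
            any_homogeneous = any_homogeneous or bool(homogeneous)
        audit.append(
            {"k": int(k), "mean_silhouette": sol.mean_silhouette, "accepted": any_homogeneous}
        )
        if any_homogeneous:
            return SelectionOutcome(chosen=sol, report=report, audit_trail=audit)
    return SelectionOutcome(chosen=None, report=None, audit_trail=audit)


def cluster_purity(
    assignments: Mapping[str, int], truth: Mapping[str, object]
) -> float:
    """Fraction of words whose cluster's majority true class matches theirs."""
    from collections import Counter, defaultdict

    by_cluster: dict[int, Counter] = defaultdict(Counter)
    for w, cid in assignments.items():
        by_cluster[cid][truth[w]] += 1
    correct = sum(c.most_common(1)[0][1] for c in by_cluster.values())
    return correct / len(assignments)


def make_purity_labeler(
    topic_map: Mapping[str, object], threshold: float = 0.8
) -> Labeler:
    """Automatic labeler: a cluster is homogeneous when ≥ ``threshold`` of
    its listed top words share one planted topic; the label is that topic."""

    def labeler(report: ClusterReport) -> dict[int, tuple[str, bool]]:
        from collections import Counter

        verdicts: dict[int, tuple[str, bool]] = {}
        for c in report.clusters:
            topics = Counter(topic_map[w] for w in c["top_words"] if w in topic_map)
            if not topics:
                verdicts[c["cluster_id"]] = ("unknown", False)
                continue
            top, n = topics.most_common(1)[0]
            share = n / len(c["top_words"])
            verdicts[c["cluster_id"]] = (str(top), share >= threshold)
        return verdicts

    return labeler
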