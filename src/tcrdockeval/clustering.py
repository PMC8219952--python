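"""Fraction-of-common-contacts (FCC) similarity and greedy model clustering.

Docked models are compared by the overlap of their receptor-ligand
residue-contact sets — a fast structure-free similarity.  Clusters are
extracted Taylor-Butina style: the unassigned model with the most
unassigned neighbours becomes a cluster centroid, it and its neighbours are
removed, and the process repeats.  Clusters are ranked by the mean score of
their best-scoring members (best four by default, matching how cluster-based
rankings are presented to docking users).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .metrics import ContactSet


@dataclass
class ModelRecord:
    """One docked model: platform rank, score (lower is better) and contacts."""

    model_id: str
    rank: int
    contact_set: ContactSet
    score: float | None = None


@dataclass(frozen=True)
class ClusterParams:
    """FCC clustering parameters (defaults match common docking practice:
    FCC cutoff 0.6, minimum cluster size 4, cluster score = mean of best 4).

    ``symmetry`` chooses how the directional FCC is symmetrized into a
    similarity: ``"min"`` (conservative; both directions must agree) or
    ``"either"`` (a pair is similar if either direction reaches the cutoff).
    """

    fcc_cutoff: float = 0.6
    min_size: int = 4
    top_k_for_score: int = 4
    symmetry: str = "min"
    higher_score_better: bool = False

    def __post_init__(self):
        if not 0.0 < self.fcc_cutoff <= 1.0:
            raise ValueError("fcc_cutoff must be in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.symmetry not in ("min", "either"):
            raise ValueError("symmetry must be 'min' or 'either'")


@dataclass
class Clustering:
    """Ordered clusters (members ordered by rank) plus unclustered model ids."""

    clusters: list[list[ModelRecord]] = field(default_factory=list)
    unclustered: list[str] = field(default_factory=list)


def fcc(a: ContactSet, b: ContactSet) -> float:
    """Fraction of ``a``'s contacts also present in ``b``; 0 for empty ``a``.

    Note the measure is directional: ``fcc(a, b) != fcc(b, a)`` in general.
    """
    if len(a) == 0:
        return 0.0
    return len(a.pairs & b.pairs) / len(a.pairs)


def _similarity(a: ContactSet, b: ContactSet, symmetry: str) -> float:
    ab, ba = fcc(a, b), fcc(b, a)
    return min(ab, ba) if symmetry == "min" else max(ab, ba)


def cluster(models: Sequence[ModelRecord], params: ClusterParams = ClusterParams()) -> Clustering:
    """Greedy FCC clustering of a ranked model set.

    Repeatedly selects the unassigned model with the most unassigned
    neighbours (similarity >= ``fcc_cutoff``; ties broken by better
    platform rank) as a centroid and assigns it together with those
    neighbours as one cluster.  Clusters smaller than ``min_size`` are
    dissolved into the unclustered pool at the end.  The result partitions
    the input and is deterministic.
    """
    if not models:
        raise ValueError("need at least one model")
    ranks = [m.rank for m in models]
    if len(set(ranks)) != len(ranks):
        raise ValueError("model ranks must be unique")
    n = len(models)
    cutoffs = {m.contact_set.cutoff for m in models}
    if len(cutoffs) > 1:
        raise ValueError(f"contact sets computed at differing cutoffs: {sorted(cutoffs)}")

    neighbours: list[set[int]] = [set() for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _similarity(models[i].contact_set, models[j].contact_set,
                           params.symmetry) >= params.fcc_cutoff:
                neighbours[i].add(j)
                neighbours[j].add(i)

    unassigned = set(range(n))
    raw_clusters: list[list[int]] = []
    while unassigned:
        centroid = max(
            unassigned,
            key=lambda i: (len(neighbours[i] & unassigned), -models[i].rank),
        )
        member_idx = {centroid} | (neighbours[centroid] & unassigned)
        raw_clusters.append(sorted(member_idx, key=lambda i: models[i].rank))
        unassigned -= member_idx

    result = Clustering()
    for members in raw_clusters:
        if len(members) >= params.min_size:
            result.clusters.append([models[i] for i in members])
        else:
            result.unclustered.extend(models[i].model_id for i in members)
    return result


def rank_clusters(
    clustering: Clustering, params: ClusterParams = ClusterParams()
) -> list[list[ModelRecord]]:
    """Order clusters by the mean score of their ``top_k_for_score`` best members.

    All members are used when a cluster has fewer.  Ties are broken by the
    best single member score, then by the lowest member rank, so the order
    is total and stable.  Raises ``ValueError`` if any clustered model
    lacks a score.
    """
    sign = -1.0 if params.higher_score_better else 1.0

    def sort_key(members: list[ModelRecord]):
        scores = [m.score for m in members]
        if any(s is None for s in scores):
            missing = [m.model_id for m in members if m.score is None]
            raise ValueError(f"models without scores cannot be ranked: {missing}")
        ordered = sorted(sign * s for s in scores)
        top = ordered[: params.top_k_for_score]
        return (sum(top) / len(top), ordered[0], min(m.rank for m in members))

    return sorted(clustering.clusters, key=sort_key)
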