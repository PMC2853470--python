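"""Ranks, tied-rank structure clustering, and evaluation statistics.

Large libraries return many near-identical structures (often plain
stereoisomers) that receive identical scores.  Two conservative
conventions are used throughout:

* the *worst-case rank* of a candidate counts every candidate scoring
  strictly higher plus the entire tied block the candidate sits in;
* within each tied block, candidates whose fingerprint Tanimoto
  similarity reaches a threshold (default 0.95) collapse into one
  cluster, and the *cluster rank* applies the same worst-case convention
  to clusters.

Clusters never span different scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chem_core import Fingerprint, tanimoto

logger = logging.getLogger(__name__)

__all__ = [
    "RankedCandidate",
    "worst_case_rank",
    "cluster_tied",
    "cluster_rank",
    "ppv",
    "rank_summary",
    "RankSummary",
    "rank_candidates",
]

#: scores closer than this are treated as tied (guards float noise in sums)
SCORE_TIE_TOL = 1e-9


@dataclass
class RankedCandidate:
    candidate_id: str
    score: float
    worst_case_rank: int
    cluster_id: int
    cluster_rank: int


def _tie_groups(scores: Sequence[float]) -> list[list[int]]:
    """Indices grouped by (near-)identical score, descending."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    groups: list[list[int]] = []
    for i in order:
        if groups and abs(scores[groups[-1][0]] - scores[i]) <= SCORE_TIE_TOL:
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def worst_case_rank(scores: Sequence[float], target_index: int) -> int:
    """Most pessimistic tied rank of one candidate.

    Counts every candidate scoring strictly higher, plus all candidates
    (the target included) in the target's tied block: a top score shared
    by ten candidates yields rank 10 for each of them.
    """
    if not 0 <= target_index < len(scores):
        raise IndexError(f"target index {target_index} out of range")
    s = scores[target_index]
    higher = sum(1 for x in scores if x > s + SCORE_TIE_TOL)
    tied = sum(1 for x in scores if abs(x - s) <= SCORE_TIE_TOL)
    return higher + tied


def cluster_tied(
    scores: Sequence[float],
    fingerprints: Sequence[Fingerprint],
    threshold: float = 0.95,
    linkage: str = "single",
) -> list[int]:
    """Cluster ids per candidate; clustering acts only within tied blocks.

    Within one block, single linkage connects candidates with pairwise
    similarity >= threshold (transitive closure); ``complete`` linkage
    instead requires every pair in a cluster to reach the threshold.
    Cluster ids are assigned in descending score order, so ids weakly
    increase as the score drops, and blocks never share a cluster.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(scores) != len(fingerprints):
        raise ValueError("scores and fingerprints differ in length")
    assignment = [0] * len(scores)
    next_id = 0
    for group in _tie_groups(scores):
        if linkage == "single":
            subclusters = _single_linkage(group, fingerprints, threshold)
        elif linkage == "complete":
            subclusters = _complete_linkage(group, fingerprints, threshold)
        else:
            raise ValueError(f"unknown linkage {linkage!r}")
        for cluster in subclusters:
            for i in cluster:
                assignment[i] = next_id
            next_id += 1
    return assignment


def _single_linkage(group, fingerprints, threshold):
    parent = {i: i for i in group}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a_pos, a in enumerate(group):
        for b in group[a_pos + 1:]:
            if tanimoto(fingerprints[a], fingerprints[b]) >= threshold:
                parent[find(a)] = find(b)
    roots: dict[int, list[int]] = {}
    for i in group:
        roots.setdefault(find(i), []).append(i)
    # deterministic order: by smallest member index
    return sorted(roots.values(), key=min)


def _complete_linkage(group, fingerprints, threshold):
    clusters: list[list[int]] = []
    for i in sorted(group):
        for cluster in clusters:
            if all(tanimoto(fingerprints[i], fingerprints[j]) >= threshold for j in cluster):
                cluster.append(i)
                break
        else:
            clusters.append([i])
    return clusters


def cluster_rank(
    scores: Sequence[float],
    cluster_ids: Sequence[int],
    target_index: int,
) -> int:
    """Worst-case rank computed over compound clusters.

    Clusters strictly above the target's score count once each; every
    cluster in the target's tied block counts as well (the pessimistic
    convention again).  With no ties anywhere this equals the plain
    worst-case rank.
    """
    s = scores[target_index]
    above = {cluster_ids[i] for i, x in enumerate(scores) if x > s + SCORE_TIE_TOL}
    tied = {cluster_ids[i] for i, x in enumerate(scores) if abs(x - s) <= SCORE_TIE_TOL}
    return len(above) + len(tied)


def ppv(matched_fragments: int, total_fragments: int) -> float:
    """Positive predictive value of the in-silico fragment set.

    The fraction of generated fragments that explain a measured peak;
    more (smaller) fragments inflate the denominator and dilute it.
    """
    if matched_fragments < 0 or total_fragments < matched_fragments:
        raise ValueError("need 0 <= matched <= total")
    if total_fragments == 0:
        return 0.0
    return matched_fragments / total_fragments


@dataclass(frozen=True)
class RankSummary:
    mean: float
    median: float
    q75: float
    std: float


def rank_summary(ranks: Sequence[float]) -> RankSummary:
    """Mean, median, 75% quantile (linear interpolation), sample std.

    The standard deviation uses the n-1 denominator (a single rank gives
    std 0 by convention).
    """
    if not len(ranks):
        raise ValueError("rank_summary needs at least one rank")
    arr = np.asarray(ranks, dtype=float)
    std = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return RankSummary(
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        q75=float(np.quantile(arr, 0.75)),  # numpy 'linear' interpolation
        std=std,
    )


def rank_candidates(
    scored: Sequence,
    fingerprints: Optional[Sequence[Fingerprint]] = None,
    threshold: float = 0.95,
    linkage: str = "single",
) -> list[RankedCandidate]:
    """Attach worst-case ranks and cluster ranks to scored candidates.

    ``scored`` is a sequence of objects with ``candidate_id`` and
    ``score`` (e.g. :class:`~fragrank.matching_scoring.CandidateScore`).
    Without fingerprints every candidate is its own cluster.
    """
    scores = [c.score for c in scored]
    if fingerprints is None:
        cluster_ids = list(range(len(scored)))
    else:
        cluster_ids = cluster_tied(scores, fingerprints, threshold, linkage)
    out = []
    for i, c in enumerate(scored):
        out.append(
            RankedCandidate(
                candidate_id=c.candidate_id,
                score=scores[i],
                worst_case_rank=worst_case_rank(scores, i),
                cluster_id=cluster_ids[i],
                cluster_rank=cluster_rank(scores, cluster_ids, i),
            )
        )
    return out
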