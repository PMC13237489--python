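"""Sequence-identity computation and leakage-aware cross-validation splits.

Homology leakage between training and validation folds inflates apparent
generalization.  This module provides the audit statistic (nearest-train
global-alignment identity, with a 3-mer TF-IDF cosine prefilter), identity-
capped fold construction via single-linkage clustering of the >=cap
similarity graph, and grouped species/genus-holdout folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from Bio import Align
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics.pairwise import cosine_similarity

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentScoring",
    "IdentityEstimate",
    "global_identity",
    "nearest_train_identity",
    "identity_capped_folds",
    "grouped_holdout_folds",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Needleman-Wunsch scores for the global aligner (configurable; the
    identity fraction is far less sensitive to these than the raw score)."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -0.5


@dataclass(frozen=True)
class IdentityEstimate:
    query_id: str
    neighbor_id: str
    identity: float


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def global_identity(a: str, b: str,
                    scoring: AlignmentScoring = AlignmentScoring()) -> float:
    """Matched residues / aligned length (gaps in the denominator) under an
    optimal global alignment; the first traceback is used when several are
    optimal."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aln = next(iter(_aligner(scoring).align(a, b)))
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(sa, sb))
    return matches / len(sa)


def nearest_train_identity(validation, training, prefilter_k: int = 25,
                           scoring: AlignmentScoring = AlignmentScoring()
                           ) -> list[IdentityEstimate]:
    """Maximum global identity of each validation sequence to the training set.

    Candidate neighbors are preranked by overlapping 3-mer TF-IDF cosine
    similarity (corpus = training set, smoothed idf) and only the top
    ``prefilter_k`` are aligned exactly.
    """
    validation, training = list(validation), list(training)
    if prefilter_k < 1:
        raise ValueError("prefilter_k must be >= 1")
    if not validation or not training:
        raise ValueError("both sets must be non-empty")
    vec = TfidfVectorizer(analyzer="char", ngram_range=(3, 3), lowercase=False)
    t_mat = vec.fit_transform([r.sequence for r in training])
    v_mat = vec.transform([r.sequence for r in validation])
    sims = cosine_similarity(v_mat, t_mat)
    k = min(prefilter_k, len(training))
    out = []
    for i, rec in enumerate(validation):
        cand = np.argsort(sims[i])[::-1][:k]
        best_id, best_nb = -1.0, ""
        for j in cand:
            ident = global_identity(rec.sequence, training[j].sequence, scoring)
            if ident > best_id:
                best_id, best_nb = ident, training[j].record_id
        out.append(IdentityEstimate(rec.record_id, best_nb, best_id))
    return out


def _single_linkage_clusters(records, cap, scoring) -> list[list[int]]:
    """Connected components of the graph joining pairs with identity >= cap."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if global_identity(records[i].sequence, records[j].sequence,
                               scoring) >= cap:
                parent[find(i)] = find(j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return list(clusters.values())


def identity_capped_folds(records, cap: float, k: int = 5, seed: int = 0,
                          scoring: AlignmentScoring = AlignmentScoring()
                          ) -> np.ndarray:
    """k folds with no cross-fold pair at or above the identity cap.

    Single-linkage clusters of the >=cap graph are assigned whole to folds
    by seeded greedy size balancing (largest cluster first, ties shuffled).
    """
    records = list(records)
    if not 0.0 < cap <= 1.0:
        raise ValueError("cap must lie in (0, 1]")
    clusters = _single_linkage_clusters(records, cap, scoring)
    biggest = max(len(c) for c in clusters)
    if biggest > (1.0 - 1.0 / k) * len(records):
        raise ValueError(
            f"one identity cluster holds {biggest}/{len(records)} records; "
            f"a cap of {cap} is too strict for {k} folds - loosen the cap")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    clusters = sorted((clusters[i] for i in order), key=len, reverse=True)
    fold_sizes = np.zeros(k, dtype=int)
    folds = np.empty(len(records), dtype=int)
    for cluster in clusters:
        f = int(np.argmin(fold_sizes))
        folds[cluster] = f
        fold_sizes[f] += len(cluster)
    return folds


def grouped_holdout_folds(records, group_key: str = "species", k: int = 5,
                          seed: int = 42, labels=None) -> np.ndarray:
    """Species- or genus-holdout folds: each group lies wholly in one fold.

    A seeded constrained assignment approximately balances fold size (and
    class composition when ``labels`` are given): groups are placed largest
    first onto the currently lightest fold, with the per-class load added to
    the cost when labels are available.
    """
    records = list(records)
    if group_key not in ("species", "genus"):
        raise ValueError("group_key must be 'species' or 'genus'")
    keys = [getattr(r, group_key) for r in records]
    if any(not key for key in keys):
        raise ValueError(f"every record must carry a {group_key}")
    groups: dict[str, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    if len(groups) < k:
        raise ValueError(f"only {len(groups)} {group_key} groups for k={k} folds")
    y = None if labels is None else np.asarray([int(v) for v in labels])
    rng = np.random.default_rng(seed)
    names = list(groups)
    rng.shuffle(names)
    names.sort(key=lambda g: len(groups[g]), reverse=True)
    fold_sizes = np.zeros(k)
    n_classes = 0 if y is None else int(y.max()) + 1
    fold_class = np.zeros((k, n_classes))
    folds = np.empty(len(records), dtype=int)
    for name in names:
        idx = groups[name]
        cost = fold_sizes.copy()
        if y is not None:
            gc = np.bincount(y[idx], minlength=n_classes)
            # penalize folds already heavy in this group's classes
            cost = cost + (fold_class * gc).sum(axis=1) / max(len(records), 1)
        f = int(np.argmin(cost))
        folds[idx] = f
        fold_sizes[f] += len(idx)
        if y is not None:
            fold_class[f] += np.bincount(y[idx], minlength=n_classes)
    return folds
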