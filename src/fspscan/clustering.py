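"""Partition sequences into specificity groups when no annotation exists.

Candidate partitions come from average-linkage hierarchical clustering on
the distance ``1 - pairwise_identity``.  Each candidate group count k is
scored by a within/between conservation contrast:

* ``W(k)`` — mean, over groups g and non-masked columns j, of the frequency
  of the most common residue of g at j (within-group conservation);
* ``B(k)`` — mean, over non-masked columns j, of the fraction of unordered
  group pairs whose group-consensus residues at j agree (between-group
  similarity);
* ``Q(k) = W(k) - B(k)``, maximized over the scanned k range, ties broken
  toward smaller k.

This contrast is this package's concrete instantiation of the idea of
maximizing conservation within groups while maximizing variability between
them; the objective name and value are recorded in output metadata.  Groups
smaller than ``min_group_size`` are merged into their nearest group (by mean
inter-group distance) before scoring, since singleton groups cannot exhibit
conservation.  Everything is deterministic given the input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import (
    AlignmentError,
    FamilyAnnotation,
    MultipleAlignment,
    identity_matrix,
)
from .stats import column_profile, consensus_residue

OBJECTIVE_NAME = "within-minus-between consensus conservation (Q = W - B)"


@dataclass
class ClusteringResult:
    """Chosen partition plus the full objective trace over the k scan."""

    annotation: FamilyAnnotation
    k: int
    objective_value: float
    objective_trace: list[tuple[int, float, float, float]]  # (k, W, B, Q)


def _merge_small_groups(
    labels: np.ndarray, dist: np.ndarray, min_group_size: int
) -> np.ndarray:
    """Absorb undersized groups into their nearest group (mean distance)."""
    labels = labels.copy()
    while True:
        groups, sizes = np.unique(labels, return_counts=True)
        if len(groups) <= 1:
            return labels
        small = [g for g, s in zip(groups, sizes) if s < min_group_size]
        if not small:
            return labels
        g = small[0]
        members = labels == g
        best, best_d = None, np.inf
        for h in groups:
            if h == g:
                continue
            d = dist[np.ix_(members, labels == h)].mean()
            if d < best_d:
                best, best_d = h, d
        labels[members] = best


def _score_partition(
    alignment: MultipleAlignment,
    labels: np.ndarray,
    gap_mask_threshold: float,
) -> tuple[float, float]:
    """Within-group conservation W and between-group consensus agreement B."""
    codes = alignment.codes()
    n_seq, n_cols = codes.shape
    groups = np.unique(labels)
    w_terms: list[float] = []
    b_terms: list[float] = []
    for j in range(n_cols):
        col = codes[:, j]
        effective = col >= 0
        if (n_seq - effective.sum()) / n_seq > gap_mask_threshold:
            continue  # masked column
        consensi: list[int] = []
        for g in groups:
            vals = col[(labels == g) & effective]
            if vals.size == 0:
                continue
            counts = np.bincount(vals, minlength=20)
            top = counts.max()
            w_terms.append(top / vals.size)
            consensi.append(int(np.flatnonzero(counts == top)[0]))
        if len(consensi) >= 2:
            agree = sum(
                consensi[a] == consensi[b]
                for a in range(len(consensi))
                for b in range(a + 1, len(consensi))
            )
            n_pairs = len(consensi) * (len(consensi) - 1) // 2
            b_terms.append(agree / n_pairs)
        else:
            b_terms.append(0.0)
    w = float(np.mean(w_terms)) if w_terms else 0.0
    b = float(np.mean(b_terms)) if b_terms else 0.0
    return w, b


def _labels_to_annotation(
    alignment: MultipleAlignment, labels: np.ndarray
) -> FamilyAnnotation:
    """Name groups by order of first appearance along the alignment rows."""
    name_of: dict[int, str] = {}
    mapping: dict[str, str] = {}
    for sid, g in zip(alignment.ids, labels):
        if int(g) not in name_of:
            name_of[int(g)] = f"group_{len(name_of) + 1}"
        mapping[sid] = name_of[int(g)]
    return FamilyAnnotation(mapping)


def cluster_specificity_groups(
    alignment: MultipleAlignment,
    k_range: range | list[int],
    min_group_size: int = 2,
    gap_mask_threshold: float = 0.50,
) -> ClusteringResult:
    """Choose the partition of sequences maximizing Q = W - B over k.

    Supplying a known :class:`FamilyAnnotation` to downstream stages bypasses
    this module entirely; it exists for unannotated sequence sets.
    """
    ks = sorted(set(int(k) for k in k_range))
    n = alignment.n_sequences
    if n < 2:
        raise AlignmentError("clustering requires >= 2 sequences")
    if not ks or ks[0] < 1 or ks[-1] > n:
        raise AlignmentError(f"k range {ks} outside [1, {n}]")

    ident = identity_matrix(alignment)
    dist = 1.0 - ident
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    if np.all(dist < 1e-12) and 1 not in ks:
        raise AlignmentError(
            "no separable structure: all sequences identical"
        )
    Z = linkage(squareform(dist, checks=False), method="average")

    trace: list[tuple[int, float, float, float]] = []
    best: tuple[float, int, np.ndarray] | None = None
    for k in ks:
        if k == 1:
            labels = np.ones(n, dtype=int)
        else:
            labels = fcluster(Z, t=k, criterion="maxclust")
        labels = _merge_small_groups(labels, dist, min_group_size)
        w, b = _score_partition(alignment, labels, gap_mask_threshold)
        q = w - b
        trace.append((k, w, b, q))
        if best is None or q > best[0] + 1e-12:
            best = (q, k, labels)
    assert best is not None
    q_best, k_best, labels_best = best
    return ClusteringResult(
        annotation=_labels_to_annotation(alignment, labels_best),
        k=k_best,
        objective_value=q_best,
        objective_trace=trace,
    )
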