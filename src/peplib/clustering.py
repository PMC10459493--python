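"""Binding-mode clustering of interaction fingerprints.

Ligands are grouped by Tanimoto similarity of their interaction fingerprints
with complete-linkage agglomerative clustering cut at a distance threshold.
Complete linkage guarantees that every pairwise distance within a cluster is
at or below the threshold, and groups smaller than ``min_size`` are flagged
outliers — mirroring screens where a minority of ligands adopt alternative
binding poses and cannot be assigned to any binding mode.

Merging is deterministic and input-order independent: at equal linkage
distance, the pair of clusters whose (sorted) lexicographically smallest
member ids come first is merged.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

from .fingerprints import InteractionFingerprint, residue_interaction_frequency

OUTLIER = -1


def tanimoto_distance(fp1, fp2) -> float:
    """Tanimoto (Jaccard) distance between two bit vectors, in [0, 1].

    ``1 - |intersection| / |union|`` over set bits; two all-zero vectors are
    identical by convention (distance 0).
    """
    a = np.asarray(fp1, dtype=bool)
    b = np.asarray(fp2, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    inter = np.logical_and(a, b).sum()
    return 1.0 - inter / union


def _pairwise_tanimoto(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=bool)
    inter = (X[:, None, :] & X[None, :, :]).sum(-1).astype(float)
    union = (X[:, None, :] | X[None, :, :]).sum(-1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = 1.0 - np.where(union > 0, inter / union, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def _complete_linkage(dist: np.ndarray, ids: Sequence[str], threshold: float
                      ) -> list[list[int]]:
    """Agglomerative complete linkage with a deterministic id-based tie rule.

    Returns clusters as lists of item indices.  At each step the pair of
    clusters with the smallest complete-linkage (maximum pairwise) distance is
    merged; ties are broken by the sorted member-id tuples of the candidate
    pair.  Merging stops when the smallest linkage exceeds ``threshold``.
    """
    clusters: list[list[int]] = [[i] for i in range(len(ids))]
    while len(clusters) > 1:
        best = None
        best_key = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                link = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                tie = tuple(sorted(ids[k] for k in clusters[i] + clusters[j]))
                key = (link, tie)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j)
        link = best_key[0]
        if link > threshold:
            break
        i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return clusters


@dataclass
class ClusterAssignment:
    """Ligand id -> cluster label (or outlier) with the clustering manifest."""

    labels: dict[str, int]  # OUTLIER (-1) marks outliers
    threshold: float
    min_size: int
    linkage: str = "complete"
    metric: str = "tanimoto"

    @property
    def n_clusters(self) -> int:
        return len({v for v in self.labels.values() if v != OUTLIER})

    @property
    def outliers(self) -> list[str]:
        return sorted(k for k, v in self.labels.items() if v == OUTLIER)

    def members(self, label: int) -> list[str]:
        return sorted(k for k, v in self.labels.items() if v == label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": k, "cluster": v if v != OUTLIER else pd.NA,
             "is_outlier": v == OUTLIER}
            for k, v in sorted(self.labels.items())
        ]
        return pd.DataFrame(rows)


class FingerprintClusterer(ClusterMixin, BaseEstimator):
    """Sklearn-style complete-linkage Tanimoto clusterer with outlier flagging.

    ``fit`` computes ``labels_`` over the input bit matrix; clusters smaller
    than ``min_size`` get the outlier label ``-1`` (DBSCAN convention).
    Cluster labels are assigned 0, 1, ... in order of decreasing size, ties
    broken by smallest member id, so labelling is deterministic and
    independent of input order.

    Parameters
    ----------
    threshold:
        Complete-linkage distance cut in [0, 1] (default 0.6).
    min_size:
        Minimum cluster size; smaller groups become outliers (default 2, so
        singleton binding modes are outliers).
    """

    def __init__(self, threshold: float = 0.6, min_size: int = 2):
        self.threshold = threshold
        self.min_size = min_size

    def fit(self, X, y=None, ids: Sequence[str] | None = None) -> "FingerprintClusterer":
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")
        if self.min_size < 1:
            raise ValueError(f"min_size must be >= 1, got {self.min_size}")
        X = np.asarray(X)
        if X.ndim != 2 or len(X) == 0:
            raise ValueError("X must be a non-empty 2D bit matrix")
        if ids is None:
            ids = [f"{i:06d}" for i in range(len(X))]
        if len(set(ids)) != len(ids):
            raise ValueError("ids must be unique")
        self.ids_ = list(ids)
        dist = _pairwise_tanimoto(X)
        groups = _complete_linkage(dist, self.ids_, self.threshold)
        kept = [g for g in groups if len(g) >= self.min_size]
        kept.sort(key=lambda g: (-len(g), min(self.ids_[i] for i in g)))
        labels = np.full(len(X), OUTLIER, dtype=int)
        for label, group in enumerate(kept):
            labels[group] = label
        self.labels_ = labels
        self.distance_matrix_ = dist
        return self

    def fit_predict(self, X, y=None, **kwargs) -> np.ndarray:
        return self.fit(X, **kwargs).labels_


def cluster_fingerprints(
    fingerprints: Sequence[InteractionFingerprint] | np.ndarray,
    threshold: float = 0.6,
    min_size: int = 2,
    ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Cluster fingerprints (or a bit matrix) into binding modes plus outliers."""
    if len(fingerprints) == 0:
        raise ValueError("need at least one fingerprint")
    if isinstance(fingerprints[0], InteractionFingerprint):
        X = np.stack([fp.bit_vector() for fp in fingerprints])
        if ids is None:
            ids = [fp.ligand_id or f"{i:06d}"
                   for i, fp in enumerate(fingerprints)]
    else:
        X = np.asarray(fingerprints)
    model = FingerprintClusterer(threshold=threshold, min_size=min_size)
    model.fit(X, ids=ids)
    return ClusterAssignment(
        labels=dict(zip(model.ids_, (int(v) for v in model.labels_))),
        threshold=threshold,
        min_size=min_size,
    )


def cluster_report(
    assignment: ClusterAssignment,
    fingerprints: Sequence[InteractionFingerprint],
    sequences: Sequence[str] | None = None,
) -> dict:
    """Per-cluster summary: size, representative, interaction and residue profiles.

    The representative is the member with minimal mean intra-cluster Tanimoto
    distance (lexicographically first id on ties).  Positional residue
    frequencies are computed over member sequences (the ids, for peptide
    ligands named by sequence).
    """
    by_id = {fp.ligand_id: fp for fp in fingerprints}
    if sequences is None:
        sequences = list(by_id)
    seq_of = {s: s for s in sequences}
    report: dict = {"threshold": assignment.threshold,
                    "min_size": assignment.min_size,
                    "n_clusters": assignment.n_clusters,
                    "outliers": assignment.outliers,
                    "clusters": {}}
    for label in sorted(set(assignment.labels.values()) - {OUTLIER}):
        members = assignment.members(label)
        fps = [by_id[m] for m in members]
        bits = np.stack([fp.bit_vector() for fp in fps])
        rep = members[0]
        if len(members) > 1:
            mean_d = []
            for i in range(len(members)):
                d = [tanimoto_distance(bits[i], bits[j])
                     for j in range(len(members)) if j != i]
                mean_d.append(float(np.mean(d)))
            order = sorted(range(len(members)), key=lambda i: (mean_d[i], members[i]))
            rep = members[order[0]]
        freq = residue_interaction_frequency(fps)
        member_seqs = [seq_of.get(m, m) for m in members]
        positional = {}
        if member_seqs and len({len(s) for s in member_seqs}) == 1:
            length = len(member_seqs[0])
            for p in range(1, length + 1):
                col: dict[str, float] = {}
                for s in member_seqs:
                    col[s[p - 1]] = col.get(s[p - 1], 0.0) + 1.0 / len(member_seqs)
                positional[p] = dict(sorted(col.items()))
        report["clusters"][int(label)] = {
            "size": len(members),
            "members": members,
            "representative": rep,
            "interaction_frequency": {
                res: {t: float(freq.loc[res, t]) for t in freq.columns
                      if freq.loc[res, t] > 0}
                for res in freq.index if freq.loc[res].sum() > 0
            },
            "positional_residue_frequency": positional,
        }
    return report
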