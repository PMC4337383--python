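"""Similarity structure of binary network activity vectors.

Trials in one time bin are compared through the Pearson correlation of
their 60-element binary vectors (the constant ground bit guarantees no
all-zero vector), clustered agglomeratively on the correlation distance
1 - r with average linkage and a distance-threshold cut, and displayed in
a deterministic order: clusters by decreasing size (ties toward the lowest
trial id), trials within a cluster re-sorted by stimulus identity then
trial id.  Each cluster's stimulus selectivity is summarized by the
Shannon entropy of its stimulus-label distribution and the equivalent
number of stimuli 2^H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import DataError
from .entropy import equivalent_stimuli, shannon_bits


def correlation_matrix(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trial-by-trial Pearson correlation of binary vectors.

    Returns ``(matrix, flagged)`` where ``flagged`` marks trials whose
    vector has zero variance across elements (all-ones once the ground bit
    is included); correlations with such a vector are defined as 1 for an
    identical vector and 0 otherwise.
    """
    P = np.asarray(patterns, dtype=float)
    if P.ndim != 2 or P.shape[0] < 2:
        raise DataError("need at least 2 trials of binary vectors")
    sd = P.std(axis=1)
    flagged = sd == 0
    n = P.shape[0]
    R = np.zeros((n, n))
    ok = ~flagged
    if ok.sum() >= 2:
        R[np.ix_(ok, ok)] = np.corrcoef(P[ok])
    elif ok.sum() == 1:
        R[np.ix_(ok, ok)] = 1.0
    if flagged.any():
        for i in np.flatnonzero(flagged):
            same = (P == P[i]).all(axis=1)
            R[i, :] = np.where(same, 1.0, 0.0)
            R[:, i] = R[i, :]
    np.fill_diagonal(R, 1.0)
    R = (R + R.T) / 2.0  # symmetry exactly
    return R, flagged


@dataclass
class Cluster:
    trial_indices: list[int]
    stimulus_tally: dict
    label_entropy_bits: float
    equivalent_stimuli: float

    @property
    def size(self) -> int:
        return len(self.trial_indices)

    def to_dict(self) -> dict:
        return {
            "trial_indices": list(self.trial_indices),
            "stimulus_tally": {str(k): int(v) for k, v in self.stimulus_tally.items()},
            "label_entropy_bits": self.label_entropy_bits,
            "equivalent_stimuli": self.equivalent_stimuli,
        }


@dataclass
class SimilarityReport:
    matrix: np.ndarray
    order: np.ndarray  # permutation of trial positions, cluster blocks
    clusters: list[Cluster] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "order": self.order.tolist(),
            "clusters": [c.to_dict() for c in self.clusters],
        }


def cluster_label_entropy(labels) -> tuple[float, float]:
    """Shannon entropy (bits) of a cluster's stimulus-label distribution
    and the equivalent number of stimuli 2^H."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DataError("empty cluster")
    _, tallies = np.unique(labels, return_counts=True)
    H = shannon_bits(tallies)
    return H, equivalent_stimuli(H)


def cluster_trials(
    matrix: np.ndarray,
    threshold: float = 0.5,
    stimulus_labels: np.ndarray | None = None,
    trial_ids: np.ndarray | None = None,
) -> SimilarityReport:
    """Agglomerative clustering of one bin's trials.

    ``matrix`` is the trial correlation matrix; clusters are cut from an
    average-linkage dendrogram on 1 - r at distance ``threshold``.
    ``stimulus_labels`` (per trial) enable within-cluster stimulus sorting
    and label entropies; ``trial_ids`` default to positions.
    """
    R = np.asarray(matrix, dtype=float)
    n = R.shape[0]
    if R.ndim != 2 or R.shape[1] != n or n == 0:
        raise DataError("matrix must be square and non-empty")
    ids = np.arange(n) if trial_ids is None else np.asarray(trial_ids)
    labels = np.zeros(n, dtype=int) if stimulus_labels is None else np.asarray(stimulus_labels)

    if n == 1:
        membership = np.array([1])
    else:
        D = 1.0 - R
        np.fill_diagonal(D, 0.0)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
        Z = linkage(squareform(D, checks=False), method="average")
        membership = fcluster(Z, t=threshold, criterion="distance")

    clusters: list[Cluster] = []
    for c in np.unique(membership):
        members = np.flatnonzero(membership == c)
        # within-cluster re-sort by stimulus identity, then trial id
        members = members[np.lexsort((ids[members], labels[members]))]
        tally_labels, tallies = np.unique(labels[members], return_counts=True)
        H = shannon_bits(tallies)
        clusters.append(
            Cluster(
                trial_indices=[int(i) for i in members],
                stimulus_tally={lab.item() if hasattr(lab, "item") else lab: int(t)
                                for lab, t in zip(tally_labels, tallies)},
                label_entropy_bits=H,
                equivalent_stimuli=equivalent_stimuli(H),
            )
        )
    # clusters ordered by size descending, ties toward the lowest trial id
    clusters.sort(key=lambda cl: (-cl.size, min(ids[i] for i in cl.trial_indices)))
    order = np.array([i for cl in clusters for i in cl.trial_indices], dtype=int)
    return SimilarityReport(matrix=R, order=order, clusters=clusters)
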