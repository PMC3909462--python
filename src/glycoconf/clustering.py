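"""Predominant 3D conformers by hierarchical clustering over pairwise RMSD.

Frames (typically subsampled with a stride of 50) are compared by
best-fit RMSD after optimal rigid-body superposition, the resulting
distance matrix is clustered agglomeratively (average linkage by
default) and each cluster is summarised by its medoid — the member
frame with the lowest mean RMSD to the rest of its cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from MDAnalysis.analysis import rms
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["ClusterReport", "pairwise_rmsd", "hierarchical_cluster"]

DEFAULT_STRIDE = 50


def pairwise_rmsd(frames, atom_subset=None) -> np.ndarray:
    """Symmetric matrix of best-fit RMSDs between all frame pairs, Å.

    Each pair is optimally superposed (translation + rotation via the
    Kabsch/SVD construction) before the RMSD is taken.

    Parameters
    ----------
    frames : (n_frames, n_atoms, 3) array
    atom_subset : index array, optional
        Restrict the comparison (e.g. heavy atoms only).
    """
    x = np.asarray(frames, dtype=float)
    if x.ndim != 3 or x.shape[-1] != 3:
        raise ValueError(f"expected (n_frames, n_atoms, 3), got {x.shape}")
    if atom_subset is not None:
        x = x[:, np.asarray(atom_subset), :]
    n, m = x.shape[:2]
    if n < 2:
        raise ValueError("need at least 2 frames")
    if m < 3:
        raise ValueError("need at least 3 atoms")
    spans = x - x.mean(axis=1, keepdims=True)
    if np.any(np.linalg.matrix_rank(spans[0]) < 2):
        raise ValueError("degenerate (collinear) atom set")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = rms.rmsd(
                x[i], x[j], center=True, superposition=True
            )
    return out


@dataclass
class ClusterReport:
    """Flat clustering of sampled frames with per-cluster medoids."""

    labels: np.ndarray            # cluster id per sampled frame (0-based)
    populations: dict[int, int]   # cluster id -> member count
    medoids: dict[int, int]       # cluster id -> sampled-frame index
    linkage_criterion: str
    stride: int

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def hierarchical_cluster(
    rmsd_matrix: np.ndarray,
    linkage_criterion: str = "average",
    cutoff: float | None = None,
    k: int | None = None,
    stride: int = DEFAULT_STRIDE,
) -> ClusterReport:
    """Agglomerative clustering of a pairwise RMSD matrix.

    Exactly one of ``cutoff`` (Å, distance criterion) or ``k`` (cluster
    count) selects the flat clustering.  Deterministic for a given
    input order; cluster ids are relabelled by first appearance.
    """
    d = np.asarray(rmsd_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("rmsd_matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8) or np.any(np.diag(d) > 1e-8):
        raise ValueError("rmsd_matrix must be symmetric with zero diagonal")
    if (cutoff is None) == (k is None):
        raise ValueError("give exactly one of cutoff or k")
    z = linkage(squareform(d, checks=False), method=linkage_criterion)
    if cutoff is not None:
        raw = fcluster(z, t=cutoff, criterion="distance")
    else:
        raw = fcluster(z, t=k, criterion="maxclust")
    # relabel clusters 0..K-1 in order of first appearance
    order: dict[int, int] = {}
    labels = np.empty(raw.size, dtype=int)
    for i, r in enumerate(raw):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    populations = {c: int(np.sum(labels == c)) for c in range(len(order))}
    medoids = {}
    for c in range(len(order)):
        members = np.nonzero(labels == c)[0]
        sub = d[np.ix_(members, members)]
        medoids[c] = int(members[np.argmin(sub.mean(axis=1))])
    return ClusterReport(
        labels=labels, populations=populations, medoids=medoids,
        linkage_criterion=linkage_criterion, stride=stride,
    )
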