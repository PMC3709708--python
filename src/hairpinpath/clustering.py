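"""RMSD-cutoff conformational clustering (Daura neighbor-count algorithm).

The algorithm of Daura et al. — the GROMOS/GROMACS default — iteratively
takes the conformation with the largest number of neighbors within the
cutoff (strictly ``<``) as a cluster center, removes the center and its
neighbors, and repeats until every frame is assigned.  Cluster ids are
relabelled so that id 1 is the most populated cluster ("the most clustered
structure" is its center).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_io import TrajectoryFrameSet, HairpinPathError


class ClusteringError(HairpinPathError):
    pass


DEFAULT_CUTOFF = 0.1  # nm


@dataclass
class ClusterResult:
    assignments: np.ndarray  # per-frame cluster id, 1-based, 1 = largest
    centers: np.ndarray  # frame index per cluster (position k = cluster k+1)
    populations: np.ndarray  # fraction of frames per cluster
    cutoff: float

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments)
        self.centers = np.asarray(self.centers)
        self.populations = np.asarray(self.populations, dtype=float)
        if not np.isclose(self.populations.sum(), 1.0):
            raise ClusteringError("cluster populations must sum to 1")
        if self.populations.size > 1 and np.any(
            self.populations[0] < self.populations[1:]
        ):
            raise ClusteringError("cluster 1 must be the most populated")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def to_frame(self, times: np.ndarray | None = None) -> pd.DataFrame:
        """Cluster table (id, population, center frame, center time)."""
        data = {
            "cluster": np.arange(1, self.n_clusters + 1),
            "population": self.populations,
            "center_frame": self.centers,
        }
        if times is not None:
            data["center_time_ns"] = np.asarray(times)[self.centers]
        return pd.DataFrame(data)


def cluster_daura(
    matrix: np.ndarray, cutoff: float = DEFAULT_CUTOFF
) -> ClusterResult:
    """Cluster frames from a symmetric pairwise RMSD matrix.

    Ties on neighbor count are broken by the lowest frame index.  Two
    conformations are neighbors when their mutual RMSD is strictly below
    ``cutoff`` (nm).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ClusteringError("matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ClusteringError("matrix must be symmetric")
    n = matrix.shape[0]
    if n == 0:
        raise ClusteringError("empty matrix")
    adj = matrix < cutoff
    np.fill_diagonal(adj, False)

    assignments = np.zeros(n, dtype=int)
    centers: list[int] = []
    remaining = np.ones(n, dtype=bool)
    counts = adj.sum(axis=1)
    cluster_id = 0
    while remaining.any():
        cluster_id += 1
        masked = np.where(remaining, counts, -1)
        center = int(np.argmax(masked))  # argmax takes the lowest index on ties
        members = (adj[center] & remaining) | (
            np.arange(n) == center
        )
        assignments[members] = cluster_id
        centers.append(center)
        remaining &= ~members
        counts = counts - (adj[:, members].sum(axis=1))

    centers_arr = np.asarray(centers)
    sizes = np.bincount(assignments)[1:]
    # Relabel so cluster 1 is the largest; stable on ties (extraction order).
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(len(order) + 1, dtype=int)
    relabel[order + 1] = np.arange(1, len(order) + 1)
    relabel[0] = 0
    return ClusterResult(
        assignments=relabel[assignments],
        centers=centers_arr[order],
        populations=sizes[order] / n,
        cutoff=cutoff,
    )


def representative_structure(
    frames: TrajectoryFrameSet, result: ClusterResult, cluster_id: int = 1
) -> np.ndarray:
    """Coordinates of the center frame of a cluster (the most clustered
    structure for ``cluster_id=1``)."""
    if not (1 <= cluster_id <= result.n_clusters):
        raise ClusteringError(
            f"no cluster {cluster_id}; result has {result.n_clusters}"
        )
    return frames.frame(int(result.centers[cluster_id - 1]))
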