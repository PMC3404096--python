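"""Presence/absence matrix construction and hierarchical clustering.

Profile hits (one profile per tribe, searched against every proteome)
are filtered on significance and coverage, each gene is assigned to at
most one profile (best E-value), and the assignments are tabulated into
a binary tribes x genomes matrix.  Both axes can then be clustered with
Manhattan distance and complete linkage, exactly as a practitioner would
do in R before viewing the matrix in Java TreeView.

The agglomeration is implemented here rather than delegated so that tie
breaking is fully pinned down (ties at the minimum inter-cluster
distance are resolved toward the smallest pair of cluster indices, and
the smaller-index child is always placed on the left), which makes the
exported CDT/GTR/ATR files bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PresenceMatrix",
    "Dendrogram",
    "filter_profile_hits",
    "assign_best_profile",
    "build_presence_matrix",
    "cluster_matrix",
    "complete_linkage_manhattan",
]


@dataclass
class PresenceMatrix:
    """Binary tribes x genomes matrix with fixed row/column orderings."""

    tribe_ids: list
    genome_ids: list
    values: np.ndarray

    def __post_init__(self):
        self.tribe_ids = list(self.tribe_ids)
        self.genome_ids = list(self.genome_ids)
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.tribe_ids), len(self.genome_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.tribe_ids)} tribes x {len(self.genome_ids)} genomes"
            )
        if len(set(self.tribe_ids)) != len(self.tribe_ids):
            raise ValueError("duplicate tribe ids")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            raise ValueError("duplicate genome ids")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.tribe_ids, columns=self.genome_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PresenceMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())

    def write_tsv(self, path) -> None:
        self.to_frame().rename_axis("tribe_id").to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def read_tsv(cls, path) -> "PresenceMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class Dendrogram:
    """Agglomeration result: n-1 ordered merges over n labelled leaves.

    ``merges`` follows the scipy linkage convention: row k merges
    clusters ``left`` and ``right`` (leaves are 0..n-1 in ``labels``
    order, internal clusters are n+k) at ``height`` (Manhattan units)
    into cluster n+k with ``size`` leaves.
    """

    labels: list
    merges: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))

    def __post_init__(self):
        self.labels = list(self.labels)
        self.merges = np.asarray(self.merges, dtype=float)
        n = len(self.labels)
        if self.merges.shape != (max(n - 1, 0), 4):
            raise ValueError(f"expected {n - 1} merges for {n} leaves")
        heights = self.merges[:, 2]
        if heights.size and np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")

    def leaf_order(self) -> list:
        """Leaf labels left-to-right (smaller-index child on the left)."""
        n = len(self.labels)
        if n == 1:
            return list(self.labels)
        children = {
            n + k: (int(left), int(right))
            for k, (left, right, _h, _s) in enumerate(self.merges)
        }
        order, stack = [], [n + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(self.labels[node])
            else:
                left, right = children[node]
                stack.append(right)
                stack.append(left)
        return order


def filter_profile_hits(
    hits: pd.DataFrame, e_max: float = 1e-4, cov_min: float = 0.80
) -> pd.DataFrame:
    """Keep hits with E-value strictly below ``e_max`` and both coverages
    strictly above ``cov_min``.

    The boundaries are strict on purpose: a hit *at* the E-value cutoff
    or *at* 80% coverage is discarded.
    """
    keep = (
        (hits["evalue"] < e_max)
        & (hits["cov_gene"] > cov_min)
        & (hits["cov_profile"] > cov_min)
    )
    return hits.loc[keep]


def assign_best_profile(filtered: pd.DataFrame) -> dict:
    """Map each gene to the single profile with the best (lowest) E-value.

    E-value ties are broken by higher profile coverage, then higher gene
    coverage, then lexicographic profile id, so the result does not
    depend on input row order.
    """
    if filtered.empty:
        return {}
    ordered = filtered.sort_values(
        ["gene_id", "evalue", "cov_profile", "cov_gene", "profile_id"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    best = ordered.groupby("gene_id", sort=False).head(1)
    return dict(zip(best["gene_id"], best["profile_id"]))


def build_presence_matrix(
    assignments: dict, tribe_ids: list, genome_ids: list, gene_to_genome: dict
) -> PresenceMatrix:
    """Tabulate gene->profile assignments into a binary matrix.

    ``entry(tribe, genome) = 1`` iff at least one gene of the genome is
    assigned to the tribe's profile.  Tribes or genomes with no
    assignments keep their all-zero rows/columns so the matrix dimensions
    are reproducible.
    """
    tribe_ids = list(tribe_ids)
    genome_ids = list(genome_ids)
    row = {t: i for i, t in enumerate(tribe_ids)}
    col = {g: j for j, g in enumerate(genome_ids)}
    values = np.zeros((len(tribe_ids), len(genome_ids)), dtype=np.int8)
    for gene, profile in assignments.items():
        if profile not in row:
            raise ValueError(f"assignment to unknown tribe id {profile!r}")
        genome = gene_to_genome.get(gene)
        if genome is None:
            raise ValueError(f"gene {gene!r} has no known genome")
        if genome not in col:
            raise ValueError(f"gene {gene!r} maps to unknown genome {genome!r}")
        values[row[profile], col[genome]] = 1
    return PresenceMatrix(tribe_ids, genome_ids, values)


def complete_linkage_manhattan(X: np.ndarray) -> np.ndarray:
    """Agglomerative complete-linkage clustering under Manhattan distance.

    Returns a scipy-style linkage array.  Deterministic: at every step
    the minimum-distance pair is chosen, ties resolved by the smallest
    (index_i, index_j) pair of cluster indices.
    """
    from scipy.spatial.distance import pdist, squareform

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    dist = squareform(pdist(X, metric="cityblock"))
    np.fill_diagonal(dist, np.inf)

    # Each position holds one live cluster; a merged-away position is
    # retired by setting its row/column to +inf.
    pos_id = np.arange(n)  # cluster id living at each position
    sizes = {i: 1 for i in range(n)}
    merges = np.empty((n - 1, 4))
    for k in range(n - 1):
        height = float(dist.min())
        cand_pi, cand_pj = np.nonzero(dist == height)
        # Resolve ties toward the smallest (id_i, id_j) cluster-id pair.
        ids = np.sort(
            np.stack([pos_id[cand_pi], pos_id[cand_pj]], axis=1), axis=1
        )
        best = int(np.lexsort((ids[:, 1], ids[:, 0]))[0])
        pi, pj = int(cand_pi[best]), int(cand_pj[best])
        if pos_id[pi] > pos_id[pj]:
            pi, pj = pj, pi
        ci, cj = int(pos_id[pi]), int(pos_id[pj])
        new_id = n + k
        merges[k] = (ci, cj, height, sizes[ci] + sizes[cj])
        sizes[new_id] = sizes[ci] + sizes[cj]

        # Complete linkage: distance to the union is the max of the parts.
        merged_row = np.maximum(dist[pi], dist[pj])
        dist[pi, :] = merged_row
        dist[:, pi] = merged_row
        dist[pi, pi] = np.inf
        dist[pj, :] = np.inf
        dist[:, pj] = np.inf
        pos_id[pi] = new_id
    return merges


def cluster_matrix(matrix: PresenceMatrix, axis: str = "rows") -> Dendrogram:
    """Cluster matrix rows or columns (Manhattan distance, complete linkage)."""
    if axis == "rows":
        labels, X = matrix.tribe_ids, matrix.values.astype(float)
    elif axis == "columns":
        labels, X = matrix.genome_ids, matrix.values.T.astype(float)
    else:
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    if len(labels) < 2:
        raise ValueError(f"cannot cluster a single-item axis ({axis})")
    return Dendrogram(labels=labels, merges=complete_linkage_manhattan(X))
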