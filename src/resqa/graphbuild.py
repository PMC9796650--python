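"""Residue-graph construction and the spatial-neighbour index.

The graph predictor sees a model as a directed graph: every residue pair
with Calpha distance <= 8 A is connected in both directions.  Each edge
carries three features: distance / 8, the cosine of the angle between the
two Calpha position vectors after centering the model on its centroid, and
the normalised sequence separation |i - j| / L.  Global features are the
six model-level agreement scores.

The residual-CNN predictor instead consumes, for each residue, the
concatenated features of its five spatially closest residues that are more
than six positions away in sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .features import FeatureBundle
from .structio import ModelStructure

__all__ = ["ProteinGraph", "NeighborIndex", "build_graph",
           "nearest_spatial_neighbors", "concat_neighbor_features", "PAD"]

PAD = -1  # sentinel for missing neighbour slots


@dataclass
class ProteinGraph:
    """Node / edge / global feature triple for one model.

    ``edges`` is an (|E|, 2) array of (sender, receiver) node indices; the
    edge set is symmetric and self-edge-free.
    """

    node_features: np.ndarray      # (L, D_v)
    edges: np.ndarray              # (E, 2) int
    edge_features: np.ndarray     # (E, 3)
    global_features: np.ndarray   # (D_u,)

    def __post_init__(self) -> None:
        self.node_features = np.asarray(self.node_features, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        self.edge_features = np.asarray(self.edge_features, dtype=float)
        self.global_features = np.asarray(self.global_features, dtype=float)
        if len(self.edges) == 0:
            raise ValueError("graph has no edges")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edge in graph")
        fwd = set(map(tuple, self.edges))
        if any((r, s) not in fwd for s, r in self.edges):
            raise ValueError("edge set is not symmetric")

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def save_npz(self, path) -> None:
        np.savez(path, node_features=self.node_features, edges=self.edges,
                 edge_features=self.edge_features,
                 global_features=self.global_features)

    @classmethod
    def load_npz(cls, path) -> "ProteinGraph":
        with np.load(path, allow_pickle=False) as z:
            return cls(z["node_features"], z["edges"], z["edge_features"],
                       z["global_features"])


@dataclass
class NeighborIndex:
    """For each residue, its k spatially closest sequence-distant residues.

    ``neighbors[i]`` lists residue indices sorted by ascending 3-D distance
    (ties broken by lower index), padded with ``PAD`` when fewer than k
    residues satisfy the sequence-separation constraint.
    """

    neighbors: np.ndarray  # (L, k) int, PAD-padded

    def __post_init__(self) -> None:
        self.neighbors = np.asarray(self.neighbors, dtype=int)


def build_graph(model: ModelStructure, node_features: np.ndarray,
                global_features: np.ndarray,
                cutoff: float = 8.0) -> ProteinGraph:
    """Connect every residue pair within ``cutoff`` A, both directions.

    Edge features, in order: Euclidean distance divided by the cutoff (in
    (0, 1]); cosine of the angle between the centroid-centred position
    vectors of the two residues; |i - j| / L.
    """
    L = len(model)
    if L < 2:
        raise ValueError("need >= 2 residues to build a graph")
    coords = model.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        raise ValueError("no residue pair within cutoff; graph degenerate")
    senders = np.concatenate([pairs[:, 0], pairs[:, 1]])
    receivers = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.lexsort((receivers, senders))
    senders, receivers = senders[order], receivers[order]

    centred = coords - coords.mean(axis=0)
    d = np.linalg.norm(coords[senders] - coords[receivers], axis=1)
    norms = np.linalg.norm(centred, axis=1)
    denom = norms[senders] * norms[receivers]
    cosine = np.where(
        denom > 1e-12,
        np.einsum("ij,ij->i", centred[senders], centred[receivers]) /
        np.maximum(denom, 1e-12),
        0.0)
    seqsep = np.abs(senders - receivers) / L
    return ProteinGraph(
        node_features=np.asarray(node_features, dtype=float),
        edges=np.column_stack([senders, receivers]),
        edge_features=np.column_stack([d / cutoff, cosine, seqsep]),
        global_features=np.asarray(global_features, dtype=float),
    )


def nearest_spatial_neighbors(model: ModelStructure, k: int = 5,
                              min_seq_sep: int = 7) -> NeighborIndex:
    """The k nearest residues j of each i with |i - j| >= min_seq_sep.

    Sorted by ascending Calpha distance with ties broken by lower residue
    index; slots beyond the number of eligible residues hold ``PAD``.
    """
    L = len(model)
    coords = model.coords
    out = np.full((L, k), PAD, dtype=int)
    dmat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    idx = np.arange(L)
    for i in range(L):
        eligible = idx[np.abs(idx - i) >= min_seq_sep]
        if len(eligible) == 0:
            continue
        # stable sort on distance; eligible already ascending, so ties keep
        # the lower index first
        order = eligible[np.argsort(dmat[i, eligible], kind="stable")]
        take = order[:k]
        out[i, :len(take)] = take
    return NeighborIndex(neighbors=out)


def concat_neighbor_features(bundle: FeatureBundle,
                             index: NeighborIndex) -> np.ndarray:
    """Row i = the k neighbours' feature rows concatenated in index order.

    Padding slots contribute zero rows, so the result is (L, k * D).
    """
    mat = bundle.matrix
    L, D = mat.shape
    nb = index.neighbors
    k = nb.shape[1]
    padded = np.vstack([mat, np.zeros((1, D))])
    safe = np.where(nb == PAD, L, nb)
    return padded[safe].reshape(L, k * D)
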