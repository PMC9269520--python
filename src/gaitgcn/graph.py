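"""Skeleton graph topology and adjacency construction.

The skeleton is an undirected tree over the V body joints.  The spatial
graph convolution consumes a set of partitioned, degree-normalized
adjacency matrices built here:

* ``adjacency_from_edges`` — binary adjacency A from the edge list,
* ``normalize_adjacency``  — A_norm = D̃^{-1/2} (A + I) D̃^{-1/2},
* ``partition_adjacency``  — splits the support of Ã = A + I into K
  groups (uni-label / distance / spatial-configuration) that receive
  separate convolution weights.

The built-in default topology is the 25-joint Kinect V2 skeleton, a tree
rooted at SpineMid.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SkeletonGraph",
    "AdjacencySet",
    "KINECT_V2_JOINT_NAMES",
    "KINECT_V2_EDGES",
    "kinect_v2_graph",
    "adjacency_from_edges",
    "normalize_adjacency",
    "partition_adjacency",
    "load_graph",
]

PARTITION_STRATEGIES = ("uni-label", "distance", "spatial-configuration")

# Kinect V2 SDK joint ordering.
KINECT_V2_JOINT_NAMES = [
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
]

KINECT_V2_EDGES = [
    (0, 1), (1, 20), (20, 2), (2, 3),
    (20, 4), (4, 5), (5, 6), (6, 7), (7, 21), (6, 22),
    (20, 8), (8, 9), (9, 10), (10, 11), (11, 23), (10, 24),
    (0, 12), (12, 13), (13, 14), (14, 15),
    (0, 16), (16, 17), (17, 18), (18, 19),
]

KINECT_V2_CENTER = 1  # SpineMid


class TopologyError(ValueError):
    """Raised when a graph definition is internally inconsistent."""


@dataclass(frozen=True)
class SkeletonGraph:
    """An undirected skeleton tree with a designated center joint.

    Parameters
    ----------
    num_joints : int
        Number of joints V.
    edges : list of (int, int)
        Unordered joint-index pairs; for a tree, exactly V - 1 of them.
    center_joint : int
        The root joint used for relative coordinates, spatial
        partitioning and the bone-tree orientation.
    joint_names : list of str, optional
        V labels; defaults to ``j0 … j{V-1}``.
    """

    num_joints: int
    edges: tuple[tuple[int, int], ...]
    center_joint: int
    joint_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        V = self.num_joints
        if V <= 0:
            raise TopologyError("num_joints must be positive")
        seen = set()
        for i, j in self.edges:
            if not (0 <= i < V and 0 <= j < V):
                raise TopologyError(f"edge ({i},{j}) out of range for V={V}")
            if i == j:
                raise TopologyError(f"self-loop at joint {i}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise TopologyError(f"duplicate edge {key}")
            seen.add(key)
        if not (0 <= self.center_joint < V):
            raise TopologyError(f"center_joint {self.center_joint} out of range")
        if not self.joint_names:
            object.__setattr__(
                self, "joint_names", tuple(f"j{i}" for i in range(V))
            )
        if len(self.joint_names) != V:
            raise TopologyError("joint_names length must equal num_joints")
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))

    @property
    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.num_joints)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def hop_distances(self, source: int | None = None) -> np.ndarray:
        """BFS hop distance from ``source`` (default: center) to every joint.

        Unreachable joints get -1.
        """
        if source is None:
            source = self.center_joint
        dist = np.full(self.num_joints, -1, dtype=int)
        dist[source] = 0
        adj = self.neighbors
        q = deque([source])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    q.append(v)
        return dist

    @property
    def parent_of(self) -> dict[int, int]:
        """Child → parent map of the tree oriented away from the center."""
        parents: dict[int, int] = {}
        dist = self.hop_distances()
        adj = self.neighbors
        order = sorted(range(self.num_joints), key=lambda v: dist[v])
        for v in order:
            if v == self.center_joint or dist[v] < 0:
                continue
            for u in adj[v]:
                if dist[u] == dist[v] - 1:
                    parents[v] = u
                    break
        return parents

    def is_tree(self) -> bool:
        return (
            len(self.edges) == self.num_joints - 1
            and bool(np.all(self.hop_distances() >= 0))
        )


@dataclass(frozen=True)
class AdjacencySet:
    """Normalized, partitioned adjacency matrices for one graph.

    ``partitions`` holds K matrices of shape V×V, each the self-loop
    augmented adjacency Ã masked to one partition group and normalized
    with that group's own degree matrix.  ``normalized_full`` is the
    unpartitioned A_norm = D̃^{-1/2} Ã D̃^{-1/2}.
    """

    strategy: str
    partitions: tuple[np.ndarray, ...]
    normalized_full: np.ndarray

    @property
    def num_partitions(self) -> int:
        return len(self.partitions)

    @property
    def num_joints(self) -> int:
        return self.normalized_full.shape[0]

    def stacked(self) -> np.ndarray:
        """K×V×V array of the partition matrices."""
        return np.stack(self.partitions, axis=0)


def kinect_v2_graph() -> SkeletonGraph:
    """The default 25-joint Kinect V2 skeleton tree rooted at SpineMid."""
    return SkeletonGraph(
        num_joints=25,
        edges=tuple(KINECT_V2_EDGES),
        center_joint=KINECT_V2_CENTER,
        joint_names=tuple(KINECT_V2_JOINT_NAMES),
    )


def adjacency_from_edges(graph: SkeletonGraph) -> np.ndarray:
    """Binary V×V adjacency: A[i, j] = 1 iff {i, j} is an edge."""
    V = graph.num_joints
    A = np.zeros((V, V), dtype=np.float64)
    for i, j in graph.edges:
        A[i, j] = 1.0
        A[j, i] = 1.0
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetrically normalized self-loop adjacency D̃^{-1/2} Ã D̃^{-1/2}.

    Ã = A + I always has positive degrees, so the inverse square root
    is well defined even for edgeless graphs.
    """
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    A_tilde = A + np.eye(A.shape[0])
    d = A_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def _masked_normalize(A_tilde: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Column-degree-normalize Ã restricted to ``mask``.

    Entries whose partition column-degree is zero stay zero, so empty
    partitions are harmless.
    """
    part = A_tilde * mask
    deg = part.sum(axis=0)
    with np.errstate(divide="ignore"):
        inv = np.where(deg > 0, 1.0 / deg, 0.0)
    return part * inv[None, :]


def partition_adjacency(
    graph: SkeletonGraph, strategy: str = "spatial-configuration"
) -> AdjacencySet:
    """Split Ã = A + I into K partition matrices for the graph convolution.

    Strategies
    ----------
    ``uni-label``
        K = 1; the whole Ã in one group (the symmetric A_norm).
    ``distance``
        K = 2; the self-loops (hop 0) vs the neighbor connections (hop 1).
    ``spatial-configuration``
        K = 3; for each connection (j → i): *self* when i == j,
        *centripetal* when j is not farther from the center joint than i,
        *centrifugal* when j is strictly farther.  Equal distances break
        toward centripetal.

    Every nonzero of Ã lands in exactly one partition; each partition is
    normalized with its own column degrees.
    """
    if strategy not in PARTITION_STRATEGIES:
        raise ValueError(
            f"unknown partition strategy {strategy!r}; "
            f"expected one of {PARTITION_STRATEGIES}"
        )
    A = adjacency_from_edges(graph)
    V = graph.num_joints
    A_tilde = A + np.eye(V)
    A_norm = normalize_adjacency(A)

    if strategy == "uni-label":
        partitions = (A_norm.copy(),)
    elif strategy == "distance":
        self_mask = np.eye(V)
        nbr_mask = (A_tilde > 0).astype(float) - self_mask
        partitions = (
            _masked_normalize(A_tilde, self_mask),
            _masked_normalize(A_tilde, nbr_mask),
        )
    else:  # spatial-configuration
        hop = graph.hop_distances()
        support = A_tilde > 0
        self_mask = np.eye(V)
        # entry (i, j): contribution of source joint j to target joint i
        centripetal = np.zeros((V, V))
        centrifugal = np.zeros((V, V))
        for i in range(V):
            for j in range(V):
                if i == j or not support[i, j]:
                    continue
                if hop[j] <= hop[i]:
                    centripetal[i, j] = 1.0
                else:
                    centrifugal[i, j] = 1.0
        partitions = (
            _masked_normalize(A_tilde, self_mask),
            _masked_normalize(A_tilde, centripetal),
            _masked_normalize(A_tilde, centrifugal),
        )

    return AdjacencySet(
        strategy=strategy, partitions=partitions, normalized_full=A_norm
    )


def load_graph(path: str | Path) -> SkeletonGraph:
    """Load a graph from a plain-text edge list.

    The first line is a header ``V=<n> center=<c>``; every following
    non-empty line holds one 0-based ``i j`` pair.
    """
    path = Path(path)
    lines = [
        ln.strip() for ln in path.read_text().splitlines() if ln.strip()
    ]
    if not lines:
        raise TopologyError(f"{path}: empty graph file")
    header = dict(
        tok.split("=", 1) for tok in lines[0].split() if "=" in tok
    )
    try:
        V = int(header["V"])
        center = int(header["center"])
    except (KeyError, ValueError) as exc:
        raise TopologyError(
            f"{path}: header must be 'V=<n> center=<c>', got {lines[0]!r}"
        ) from exc
    edges = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 2:
            raise TopologyError(f"{path}: bad edge line {ln!r}")
        edges.append((int(parts[0]), int(parts[1])))
    return SkeletonGraph(num_joints=V, edges=tuple(edges), center_joint=center)
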