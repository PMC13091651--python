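"""Bipartite interaction graph and the globally enhanced GCN.

Each layer performs two stages on the (N+M)-node graph built from the
block-symmetrized bipartite adjacency:

1. local propagation — the same symmetric-normalized rule used by the
   contact-graph encoder, applied to [[0, A], [A^T, 0]] with self-loops;
2. global exchange — per-type virtual hub nodes gather the arithmetic
   mean of their population's states and broadcast it back additively
   through a learnable per-type linear map with a tanh squashing:
   h <- h + tanh(h_hub @ B_type).

With both broadcast maps held at zero the layer reduces exactly to a
vanilla GCN on the block graph, which is the basis of the ablation
switch.  The additive broadcast gives every node, including isolated
ones, a whole-graph receptive field after a single layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import InteractionTable
from .mirna import _ACTIVATIONS, normalized_adjacency

__all__ = [
    "BipartiteGraph",
    "GeGcnState",
    "TopologyEmbeddings",
    "build_bipartite_graph",
    "block_adjacency",
    "local_propagate",
    "global_gather",
    "broadcast_update",
    "run_ge_gcn",
]


@dataclass
class BipartiteGraph:
    """lncRNA/miRNA node sets with an N x M binary interaction adjacency."""

    A_I: np.ndarray
    lnc_index: dict[str, int]
    mi_index: dict[str, int]

    def __post_init__(self):
        A = np.asarray(self.A_I, dtype=np.float64)
        if not np.isin(A, (0.0, 1.0)).all():
            raise ValueError("interaction adjacency must be binary")
        if A.shape != (len(self.lnc_index), len(self.mi_index)):
            raise ValueError("adjacency shape does not match index maps")
        for name, index, n in (("lnc", self.lnc_index, A.shape[0]),
                               ("mi", self.mi_index, A.shape[1])):
            if sorted(index.values()) != list(range(n)):
                raise ValueError(f"{name}_index is not a bijection onto 0..{n - 1}")
        self.A_I = A

    @property
    def N(self) -> int:
        return self.A_I.shape[0]

    @property
    def M(self) -> int:
        return self.A_I.shape[1]


def build_bipartite_graph(table: InteractionTable) -> BipartiteGraph:
    """A_I[u, v] = 1 iff (u, v) is a positive pair of the table."""
    lnc_index = {lid: i for i, lid in enumerate(table.lnc_ids)}
    mi_index = {mid: j for j, mid in enumerate(table.mi_ids)}
    A = np.zeros((len(lnc_index), len(mi_index)))
    for lnc, mi, label in table.pairs:
        if label == 1:
            A[lnc_index[lnc], mi_index[mi]] = 1.0
    return BipartiteGraph(A_I=A, lnc_index=lnc_index, mi_index=mi_index)


def block_adjacency(graph: BipartiteGraph) -> np.ndarray:
    """Homogeneous (N+M) x (N+M) block-symmetric adjacency [[0,A],[A^T,0]]."""
    N, M = graph.N, graph.M
    B = np.zeros((N + M, N + M))
    B[:N, N:] = graph.A_I
    B[N:, :N] = graph.A_I.T
    return B


@dataclass
class GeGcnState:
    """Node matrix plus hub states and per-layer weights (reference path).

    Rows 0..N-1 are lncRNA nodes, rows N..N+M-1 miRNA nodes.
    """

    H: np.ndarray
    N: int
    M: int
    layer_weights: list[np.ndarray] = field(default_factory=list)
    broadcast_lnc: np.ndarray | None = None
    broadcast_mi: np.ndarray | None = None
    h_g_lnc: np.ndarray | None = None
    h_g_mi: np.ndarray | None = None

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.shape[0] != self.N + self.M:
            raise ValueError(f"state has {self.H.shape[0]} rows, expected N+M={self.N + self.M}")
        if not np.all(np.isfinite(self.H)):
            raise ValueError("non-finite node states")


def local_propagate(state: GeGcnState, graph: BipartiteGraph,
                    W: np.ndarray, activation: str = "tanh") -> np.ndarray:
    """Normalized propagation over the block-symmetrized bipartite graph."""
    if graph.N != state.N or graph.M != state.M:
        raise ValueError("state and graph disagree on N/M")
    W = np.asarray(W, dtype=np.float64)
    if state.H.shape[1] != W.shape[0]:
        raise ValueError(f"state width {state.H.shape[1]} != weight rows {W.shape[0]}")
    act = _ACTIVATIONS[activation]
    return act(normalized_adjacency(block_adjacency(graph)) @ state.H @ W)


def global_gather(state: GeGcnState) -> tuple[np.ndarray, np.ndarray]:
    """Per-type hub states: arithmetic means over each node population."""
    if state.N < 1 or state.M < 1:
        raise ValueError("both node populations must be non-empty")
    h_g_lnc = state.H[:state.N].sum(axis=0) / state.N
    h_g_mi = state.H[state.N:].sum(axis=0) / state.M
    return h_g_lnc, h_g_mi


def broadcast_update(state: GeGcnState) -> np.ndarray:
    """Additive residual broadcast: h <- h + tanh(h_hub @ B_type).

    With B_type = 0 the update is the identity (tanh(0) = 0), so zero
    broadcast weights recover the vanilla GCN exactly.
    """
    if state.h_g_lnc is None or state.h_g_mi is None:
        raise ValueError("hub states not computed; call global_gather first")
    B_lnc = state.broadcast_lnc
    B_mi = state.broadcast_mi
    if B_lnc is None or B_mi is None:
        raise ValueError("broadcast weights not set")
    H = state.H.copy()
    H[:state.N] += np.tanh(state.h_g_lnc @ B_lnc)
    H[state.N:] += np.tanh(state.h_g_mi @ B_mi)
    return H


@dataclass
class TopologyEmbeddings:
    """Final interaction-topology embeddings, row-aligned with the graph."""

    E_lnc: np.ndarray
    E_mi: np.ndarray


def run_ge_gcn(graph: BipartiteGraph, init: np.ndarray,
               layer_weights: list[np.ndarray],
               broadcast_lnc: np.ndarray, broadcast_mi: np.ndarray,
               activation: str = "tanh") -> TopologyEmbeddings:
    """Alternate local propagation, gather, and broadcast for each layer.

    Hub states are recomputed from the freshly propagated node matrix in
    every layer.  ``layer_weights`` may be empty, in which case the split
    initial matrix is returned unchanged.
    """
    init = np.asarray(init, dtype=np.float64)
    N, M = graph.N, graph.M
    if init.shape[0] != N + M:
        raise ValueError(f"init has {init.shape[0]} rows, expected {N + M}")
    state = GeGcnState(H=init, N=N, M=M,
                       broadcast_lnc=broadcast_lnc, broadcast_mi=broadcast_mi)
    for W in layer_weights:
        state.H = local_propagate(state, graph, W, activation)
        state.h_g_lnc, state.h_g_mi = global_gather(state)
        state.H = broadcast_update(state)
    return TopologyEmbeddings(E_lnc=state.H[:N], E_mi=state.H[N:])
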