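"""Windowed dual-relation temporal graph over a session's utterances.

Nodes are utterances in time order.  Two typed edge families connect them
inside a context window of ``Nw`` utterances (``Nw/2`` on each side of a
central utterance, truncated at session boundaries):

* **FFC** (forward-full-connection): past source → later destination,
  carrying the chronological development of the session forward;
* **BFC** (backward-full-connection): future source → earlier destination,
  letting intermittent later events inform earlier ones.

Every node also carries a **SELF** loop, which the relational convolution
treats as its own relation.  Because the window slides with step 1, the
union over all center positions is exactly one graph in which node ``i``
receives edges from every ``j`` with ``1 ≤ |i−j| ≤ Nw/2`` — so a single
graph per session is built, never one sub-graph per center.

Edge weights α are initialised with a bilinear attention score
``c_iᵀ W_er c_j`` softmax-normalised per (destination, relation), giving
α ∈ (0, 1] that sum to one within each neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._tensor import Tensor, segment_softmax
from .encoder import ContextMatrix

FFC, BFC, SELF = 0, 1, 2
RELATION_NAMES = ("FFC", "BFC", "SELF")
N_RELATIONS = 3


@dataclass
class TemporalGraph:
    """Edge-list graph: parallel arrays (src, dst, rel) plus weights α."""

    n_nodes: int
    src: np.ndarray
    dst: np.ndarray
    rel: np.ndarray
    nw: int
    alpha: Tensor | None = None
    # per-edge |N_dst^rel| neighborhood sizes (SELF counts as 1)
    degree: np.ndarray = field(default=None, repr=False)

    @property
    def n_edges(self) -> int:
        return len(self.src)

    def edges_of(self, relation: int) -> np.ndarray:
        return np.flatnonzero(self.rel == relation)

    def counts(self) -> dict[str, int]:
        return {RELATION_NAMES[r]: int(np.sum(self.rel == r))
                for r in range(N_RELATIONS)}


def _finalize(n: int, src, dst, rel, nw: int) -> TemporalGraph:
    src = np.asarray(src, dtype=np.intp)
    dst = np.asarray(dst, dtype=np.intp)
    rel = np.asarray(rel, dtype=np.intp)
    degree = np.zeros(len(src), dtype=np.float64)
    for r in range(N_RELATIONS):
        mask = rel == r
        counts = np.bincount(dst[mask], minlength=n)
        degree[mask] = counts[dst[mask]]
    return TemporalGraph(n_nodes=n, src=src, dst=dst, rel=rel, nw=nw,
                         degree=degree)


def build_edges(n: int, nw: int, include_bfc: bool = True) -> TemporalGraph:
    """Construct the window-constrained edge set for an ``n``-utterance
    session (weights unset).

    ``nw`` is the *total* window, split ``nw/2`` per side, so it must be
    even and non-negative.  ``include_bfc=False`` drops the backward
    relation (the "sequential-only" ablation).
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if nw < 0 or nw % 2 != 0:
        raise ValueError(f"Nw must be even and >= 0 (halved per side), got {nw}")
    half = nw // 2
    src, dst, rel = [], [], []
    for i in range(n):
        for j in range(max(0, i - half), i):
            src.append(j); dst.append(i); rel.append(FFC)
        if include_bfc:
            for j in range(i + 1, min(n - 1, i + half) + 1):
                src.append(j); dst.append(i); rel.append(BFC)
        src.append(i); dst.append(i); rel.append(SELF)
    return _finalize(n, src, dst, rel, nw)


def batch_graphs(graphs: list[TemporalGraph]) -> tuple[TemporalGraph, np.ndarray]:
    """Stack per-session graphs into one block-diagonal graph.

    Returns the merged graph and the node offset of each session.
    """
    offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
    src = np.concatenate([g.src + off for g, off in zip(graphs, offsets)])
    dst = np.concatenate([g.dst + off for g, off in zip(graphs, offsets)])
    rel = np.concatenate([g.rel for g in graphs])
    nw = graphs[0].nw if graphs else 0
    return _finalize(int(offsets[-1]), src, dst, rel, nw), offsets[:-1]


@dataclass
class EdgeInitParams:
    """One bilinear score matrix W_er per relation type."""

    W: dict[int, Tensor]

    @classmethod
    def init(cls, d_node: int, rng: np.random.Generator | None = None,
             relations: tuple[int, ...] = (FFC, BFC, SELF)) -> "EdgeInitParams":
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (2 * d_node))
        return cls(W={r: Tensor(rng.uniform(-limit, limit, size=(d_node, d_node)),
                                requires_grad=True)
                      for r in relations})

    def named(self, prefix: str = "edge_init") -> dict[str, Tensor]:
        return {f"{prefix}_W_{RELATION_NAMES[r]}": t for r, t in self.W.items()}


def init_edge_weights(g: TemporalGraph, C: ContextMatrix | Tensor,
                      params: EdgeInitParams) -> TemporalGraph:
    """Set α by softmax of bilinear scores per (destination, relation).

    Score for edge j→i under relation r is ``c_iᵀ W_er c_j``; the softmax
    runs over the window-restricted incident edges of (i, r), so α sums to
    one within each neighborhood and the SELF loop always gets α = 1.
    """
    feats = C.C if isinstance(C, ContextMatrix) else C
    if feats.shape[0] != g.n_nodes:
        raise ValueError(
            f"context rows ({feats.shape[0]}) != graph nodes ({g.n_nodes})")
    d = feats.shape[1]
    present = set(int(r) for r in np.unique(g.rel))
    missing = present - set(params.W)
    if missing:
        raise ValueError(
            f"no W_er for relations {[RELATION_NAMES[r] for r in sorted(missing)]}")
    logits_parts, order = [], []
    for r in sorted(present):
        W = params.W[r]
        if W.shape != (d, d):
            raise ValueError(
                f"W_er[{RELATION_NAMES[r]}] shape {W.shape} incompatible "
                f"with node width {d}")
        idx = g.edges_of(r)
        # c_dst^T W c_src, batched over the relation's edges
        proj = feats @ W
        s = (proj.take_rows(g.dst[idx]) * feats.take_rows(g.src[idx])).sum(axis=1)
        logits_parts.append(s)
        order.append(idx)
    order = np.concatenate(order)
    logits = Tensor.concat(logits_parts, axis=0)
    groups = g.dst[order] * N_RELATIONS + g.rel[order]
    alpha_shuffled = segment_softmax(logits, groups, g.n_nodes * N_RELATIONS)
    # scatter back to the graph's edge order
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    alpha = alpha_shuffled.take_rows(inverse)
    return TemporalGraph(n_nodes=g.n_nodes, src=g.src, dst=g.dst, rel=g.rel,
                         nw=g.nw, alpha=alpha, degree=g.degree)


def dump_edges(g: TemporalGraph, path: str | Path) -> Path:
    """Write the edge list (src, dst, relation, alpha) as TSV."""
    path = Path(path)
    alpha = (g.alpha.data if g.alpha is not None
             else np.full(g.n_edges, np.nan))
    with open(path, "w") as fh:
        fh.write("src\tdst\trelation\talpha\n")
        for s, d, r, a in zip(g.src, g.dst, g.rel, alpha):
            fh.write(f"{s}\t{d}\t{RELATION_NAMES[r]}\t{a:.10g}\n")
    return path
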