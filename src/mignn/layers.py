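"""Relational graph convolution and multi-head graph attention.

The relational convolution (RGCN) aggregates each node's window
neighborhood with relation-specific weight matrices,

    h_i = σ( Σ_r Σ_{j∈N_i^r} (α_ij / |N_i^r|) W_r c_j  +  α_ii W_0 c_i ),

where α are the softmax-normalised edge weights carried by the graph and
|N_i^r| is the relation-r neighborhood size (the α are already normalised
per neighborhood; the additional 1/|N| factor is kept as the model defines
it and can be disabled with ``degree_norm=False``).

The attention layer (GAT) then re-weights the same edge structure from the
updated features: per head k,

    e_ij = aᵀ LeakyReLU([W h_i ⊕ W h_j]),   α'_ij = softmax_j(e_ij),
    h'_i = α'_ii W h_i + Σ_j α'_ij W h_j,

with the K head outputs concatenated.  By default every head attends over
the union of both relations' neighborhoods plus the self loop (the
relation distinction is already encoded upstream by the RGCN);
``per_relation=True`` normalises within each relation instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._tensor import Tensor, segment_softmax
from .encoder import ContextMatrix
from .graph import BFC, FFC, RELATION_NAMES, SELF, N_RELATIONS, TemporalGraph

_ACTIVATIONS = {
    "relu": lambda t: t.relu(),
    "tanh": lambda t: t.tanh(),
    "identity": lambda t: t,
}


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class RGCNParams:
    """Relation-specific convolution weights W_r plus the self weight W_0."""

    W_rel: dict[int, Tensor]  # relation -> (d_node, d_h)
    W_self: Tensor            # (d_node, d_h)
    activation: str = "relu"

    @classmethod
    def init(cls, d_node: int, d_h: int, activation: str = "relu",
             relations: tuple[int, ...] = (FFC, BFC),
             rng: np.random.Generator | None = None) -> "RGCNParams":
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        rng = rng or np.random.default_rng()
        return cls(
            W_rel={r: Tensor(_glorot(rng, d_node, d_h), requires_grad=True)
                   for r in relations},
            W_self=Tensor(_glorot(rng, d_node, d_h), requires_grad=True),
            activation=activation)

    def named(self, prefix: str = "rgcn") -> dict[str, Tensor]:
        out = {f"{prefix}_W_{RELATION_NAMES[r]}": t for r, t in self.W_rel.items()}
        out[f"{prefix}_W0"] = self.W_self
        return out


def rgcn_forward(g: TemporalGraph, C: ContextMatrix | Tensor,
                 params: RGCNParams, degree_norm: bool = True) -> Tensor:
    """Relational convolution over the weighted temporal graph → (n, d_h)."""
    if g.alpha is None:
        raise ValueError("graph has no edge weights; call init_edge_weights first")
    feats = C.C if isinstance(C, ContextMatrix) else C
    if feats.shape[0] != g.n_nodes:
        raise ValueError("context/graph size mismatch")
    n = g.n_nodes
    total = None
    for r, W in params.W_rel.items():
        idx = g.edges_of(r)
        if len(idx) == 0:
            continue
        coef = g.alpha.take_rows(idx)
        if degree_norm:
            coef = coef * Tensor(1.0 / g.degree[idx])
        msg = coef.reshape(-1, 1) * (feats @ W).take_rows(g.src[idx])
        agg = msg.segment_sum(g.dst[idx], n)
        total = agg if total is None else total + agg
    self_idx = g.edges_of(SELF)
    order = np.argsort(g.dst[self_idx])  # one SELF edge per node
    alpha_self = g.alpha.take_rows(self_idx[order]).reshape(-1, 1)
    self_term = alpha_self * (feats @ params.W_self)
    total = self_term if total is None else total + self_term
    return _ACTIVATIONS[params.activation](total)


@dataclass
class GATParams:
    """K independent attention heads: per-head transform W and logit vector a."""

    W: list[Tensor]   # K × (d_h, d_head)
    a: list[Tensor]   # K × (2·d_head,)
    leaky_slope: float = 0.2

    @classmethod
    def init(cls, d_h: int, d_head: int, heads: int = 4,
             leaky_slope: float = 0.2,
             rng: np.random.Generator | None = None) -> "GATParams":
        if heads < 1:
            raise ValueError("need at least one attention head")
        rng = rng or np.random.default_rng()
        return cls(
            W=[Tensor(_glorot(rng, d_h, d_head), requires_grad=True)
               for _ in range(heads)],
            a=[Tensor(rng.uniform(-0.1, 0.1, size=2 * d_head), requires_grad=True)
               for _ in range(heads)],
            leaky_slope=leaky_slope)

    @property
    def heads(self) -> int:
        return len(self.W)

    @property
    def d_head(self) -> int:
        return self.W[0].shape[1]

    def named(self, prefix: str = "gat") -> dict[str, Tensor]:
        out = {}
        for k in range(self.heads):
            out[f"{prefix}_W_{k}"] = self.W[k]
            out[f"{prefix}_a_{k}"] = self.a[k]
        return out


def _attention_groups(g: TemporalGraph, per_relation: bool) -> tuple[np.ndarray, int]:
    if per_relation:
        return g.dst * N_RELATIONS + g.rel, g.n_nodes * N_RELATIONS
    return g.dst, g.n_nodes


def gat_reweight(g: TemporalGraph, H1: Tensor, params: GATParams, head: int,
                 per_relation: bool = False) -> Tensor:
    """Head-``head`` attention weights α' for every edge of ``g``.

    Softmax groups are destinations over the union neighborhood (self loop
    included) by default, or (destination, relation) when ``per_relation``.
    """
    if H1.shape[0] != g.n_nodes:
        raise ValueError("feature/graph size mismatch")
    W, a = params.W[head], params.a[head]
    if W.shape[0] != H1.shape[1]:
        raise ValueError(
            f"GAT weight expects width {W.shape[0]}, features have {H1.shape[1]}")
    d_head = W.shape[1]
    wh = (H1 @ W).leaky_relu(params.leaky_slope)
    a_dst = a.take_rows(np.arange(d_head)).reshape(1, -1)
    a_src = a.take_rows(np.arange(d_head, 2 * d_head)).reshape(1, -1)
    s_dst = (wh * a_dst).sum(axis=1)
    s_src = (wh * a_src).sum(axis=1)
    logits = s_dst.take_rows(g.dst) + s_src.take_rows(g.src)
    groups, n_groups = _attention_groups(g, per_relation)
    return segment_softmax(logits, groups, n_groups)


def gat_forward(g: TemporalGraph, H1: Tensor, params: GATParams,
                per_relation: bool = False) -> Tensor:
    """Multi-head attention update → (n, K·d_head), heads concatenated."""
    outputs = []
    for k in range(params.heads):
        alpha = gat_reweight(g, H1, params, k, per_relation=per_relation)
        wh = H1 @ params.W[k]
        msg = alpha.reshape(-1, 1) * wh.take_rows(g.src)
        outputs.append(msg.segment_sum(g.dst, g.n_nodes))
    return Tensor.concat(outputs, axis=1) if len(outputs) > 1 else outputs[0]


def dump_attention(g: TemporalGraph, H1: Tensor, params: GATParams,
                   path: str | Path, per_relation: bool = False) -> Path:
    """Write per-head attention weights as TSV (head, src, dst, alpha)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("head\tsrc\tdst\talpha\n")
        for k in range(params.heads):
            alpha = gat_reweight(g, H1, params, k, per_relation=per_relation)
            for s, d, a_val in zip(g.src, g.dst, alpha.data):
                fh.write(f"{k}\t{s}\t{d}\t{a_val:.10g}\n")
    return path


# -- dense multi-head self-attention (graph-free fusion baseline) ------------

@dataclass
class MHAParams:
    """Per-head query/key/value projections for plain self-attention."""

    Wq: list[Tensor]
    Wk: list[Tensor]
    Wv: list[Tensor]

    @classmethod
    def init(cls, d_in: int, d_head: int, heads: int = 4,
             rng: np.random.Generator | None = None) -> "MHAParams":
        rng = rng or np.random.default_rng()
        mk = lambda: Tensor(_glorot(rng, d_in, d_head), requires_grad=True)
        return cls(Wq=[mk() for _ in range(heads)],
                   Wk=[mk() for _ in range(heads)],
                   Wv=[mk() for _ in range(heads)])

    @property
    def heads(self) -> int:
        return len(self.Wq)

    def named(self, prefix: str = "mha") -> dict[str, Tensor]:
        out = {}
        for k in range(self.heads):
            out[f"{prefix}_Wq_{k}"] = self.Wq[k]
            out[f"{prefix}_Wk_{k}"] = self.Wk[k]
            out[f"{prefix}_Wv_{k}"] = self.Wv[k]
        return out


def mha_forward(C: Tensor, session_ids: np.ndarray, params: MHAParams) -> Tensor:
    """Scaled-dot-product self-attention within each session (full
    bidirectional connectivity, no window, no typed edges)."""
    n = C.shape[0]
    ids = np.asarray(session_ids, dtype=np.intp)
    # all intra-session ordered pairs as an edge list
    src_parts, dst_parts = [], []
    for s in np.unique(ids):
        nodes = np.flatnonzero(ids == s)
        grid_dst, grid_src = np.meshgrid(nodes, nodes, indexing="ij")
        dst_parts.append(grid_dst.ravel())
        src_parts.append(grid_src.ravel())
    src = np.concatenate(src_parts)
    dst = np.concatenate(dst_parts)
    outputs = []
    scale = 1.0 / np.sqrt(params.Wq[0].shape[1])
    for k in range(params.heads):
        q, key, v = C @ params.Wq[k], C @ params.Wk[k], C @ params.Wv[k]
        logits = (q.take_rows(dst) * key.take_rows(src)).sum(axis=1) * scale
        alpha = segment_softmax(logits, dst, n)
        outputs.append((alpha.reshape(-1, 1) * v.take_rows(src)).segment_sum(dst, n))
    return Tensor.concat(outputs, axis=1) if len(outputs) > 1 else outputs[0]
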