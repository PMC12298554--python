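"""Multimodal context encoding.

Each modality's utterance sequence is passed through its own bidirectional
gated recurrent (GRU) layer — weights are *not* shared across modalities —
and the forward and backward outputs are concatenated along the channel
axis, giving every utterance a representation informed by the whole
session.  The per-modality contexts are then concatenated in the fixed
order (A, V, T) and linearly projected to the graph node width ``d_node``.

The projection reconciles the width mismatch between the concatenated
bidirectional encoders (3 modalities × 2H = 1200 at the reference setting
H = 200) and the 160-dimensional node embeddings the temporal graph
operates on; it can be disabled (``project=False``) when the node width is
meant to equal the raw concatenation.

Sequences of different lengths are encoded together by padding to the
batch maximum and reversing each sequence within its own valid length for
the backward pass, so padding never leaks into valid positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor

_GATES = ("z", "r", "h")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


@dataclass
class EncoderParams:
    """Per-modality recurrent weights plus the fusion projection.

    ``params`` maps flat names to trainable tensors:
    ``gru_<m>_<fw|bw>_{W,U,b}{z,r,h}`` and optionally ``W_p``.
    """

    hidden_units: int
    node_dim: int
    modalities: tuple[str, ...]
    dims: dict[str, int]
    project: bool
    params: dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, modalities: tuple[str, ...], dims: dict[str, int],
             hidden_units: int = 200, node_dim: int = 160,
             project: bool | None = None,
             rng: np.random.Generator | None = None) -> "EncoderParams":
        if hidden_units <= 0 or node_dim <= 0:
            raise ValueError("hidden_units and node_dim must be positive")
        rng = rng or np.random.default_rng()
        concat_width = 2 * hidden_units * len(modalities)
        if project is None:
            project = node_dim != concat_width
        if not project and node_dim != concat_width:
            raise ValueError(
                f"project=False requires node_dim == {concat_width}")
        params: dict[str, Tensor] = {}
        for m in modalities:
            d = dims[m]
            for direction in ("fw", "bw"):
                for gate in _GATES:
                    key = f"gru_{m}_{direction}_"
                    params[key + "W" + gate] = Tensor(
                        _glorot(rng, d, hidden_units), requires_grad=True)
                    params[key + "U" + gate] = Tensor(
                        _orthogonal(rng, hidden_units), requires_grad=True)
                    params[key + "b" + gate] = Tensor(
                        np.zeros(hidden_units), requires_grad=True)
        if project:
            params["W_p"] = Tensor(_glorot(rng, concat_width, node_dim),
                                   requires_grad=True)
        return cls(hidden_units=hidden_units, node_dim=node_dim,
                   modalities=tuple(modalities), dims=dict(dims),
                   project=project, params=params)


@dataclass
class ContextMatrix:
    """Fused per-utterance contextual embeddings for one or more sessions.

    ``C`` has one row per utterance (sessions stacked in order);
    ``per_modality`` holds the pre-projection bidirectional contexts.
    """

    C: Tensor
    per_modality: dict[str, Tensor]
    session_ids: np.ndarray  # node -> session index within the batch
    lengths: np.ndarray      # utterances per session

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]


def _gru_direction(x_padded: np.ndarray, lengths: np.ndarray,
                   params: dict[str, Tensor], prefix: str) -> Tensor:
    """Run one GRU direction over a zero-padded (T, B, d) batch.

    Returns the hidden sequence as a (T*B, H) tensor (time-major flat).
    Padding rows produce garbage that callers must not gather.
    """
    T, B, d = x_padded.shape
    H = params[prefix + "Uz"].shape[0]
    x_flat = Tensor(x_padded.reshape(T * B, d))
    # input-to-hidden products for every step at once
    pre = {g: x_flat @ params[prefix + "W" + g] + params[prefix + "b" + g]
           for g in _GATES}
    h = Tensor(np.zeros((B, H)))
    rows = np.arange(B)
    outputs = []
    for t in range(T):
        idx = t * B + rows
        xz = pre["z"].take_rows(idx)
        xr = pre["r"].take_rows(idx)
        xh = pre["h"].take_rows(idx)
        z = (xz + h @ params[prefix + "Uz"]).sigmoid()
        r = (xr + h @ params[prefix + "Ur"]).sigmoid()
        h_cand = (xh + (r * h) @ params[prefix + "Uh"]).tanh()
        h = (1.0 - z) * h + z * h_cand
        outputs.append(h)
    return Tensor.concat(outputs, axis=0)  # (T*B, H) time-major


def _pad_batch(mats: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    lengths = np.array([m.shape[0] for m in mats], dtype=np.intp)
    T, B, d = int(lengths.max()), len(mats), mats[0].shape[1]
    padded = np.zeros((T, B, d))
    for b, m in enumerate(mats):
        padded[: lengths[b], b, :] = m
    return padded, lengths


def encode_modality_batch(mats: list[np.ndarray], params: EncoderParams,
                          modality: str) -> Tensor:
    """Bidirectionally encode a batch of variable-length sequences.

    Returns a (ΣN, 2H) tensor of concatenated forward/backward states,
    rows ordered session by session, utterance by utterance.
    """
    if modality not in params.modalities:
        raise ValueError(f"modality {modality!r} not in encoder set "
                         f"{params.modalities}")
    for m in mats:
        if m.shape[0] < 1:
            raise ValueError("empty utterance sequence")
        if not np.all(np.isfinite(m)):
            raise ValueError(f"non-finite input in modality {modality!r}")
        if m.shape[1] != params.dims[modality]:
            raise ValueError(
                f"modality {modality!r}: expected width "
                f"{params.dims[modality]}, got {m.shape[1]}")
    padded, lengths = _pad_batch([np.asarray(m, dtype=np.float64) for m in mats])
    T, B, _ = padded.shape
    # reverse each sequence within its own length for the backward pass
    rev = np.zeros_like(padded)
    for b, n in enumerate(lengths):
        rev[:n, b, :] = padded[:n, b, :][::-1]
    h_fw = _gru_direction(padded, lengths, params.params, f"gru_{modality}_fw_")
    h_bw = _gru_direction(rev, lengths, params.params, f"gru_{modality}_bw_")
    # gather valid rows back into session order
    fw_idx, bw_idx = [], []
    for b, n in enumerate(lengths):
        t = np.arange(n)
        fw_idx.append(t * B + b)
        bw_idx.append((n - 1 - t) * B + b)
    fw_idx = np.concatenate(fw_idx)
    bw_idx = np.concatenate(bw_idx)
    return Tensor.concat([h_fw.take_rows(fw_idx), h_bw.take_rows(bw_idx)], axis=1)


def encode_modality(X_m: np.ndarray, params: EncoderParams, modality: str) -> Tensor:
    """Encode a single session's (n × d_m) matrix to its (n × 2H) context."""
    return encode_modality_batch([np.asarray(X_m, dtype=np.float64)], params, modality)


def fuse_context(contexts: dict[str, Tensor], params: EncoderParams,
                 session_ids: np.ndarray | None = None,
                 lengths: np.ndarray | None = None) -> ContextMatrix:
    """Concatenate per-modality contexts in (A, V, T) order and project.

    ``contexts`` must cover exactly the encoder's declared modality set and
    share a row count.
    """
    missing = set(params.modalities) - set(contexts)
    if missing:
        raise ValueError(f"missing modality contexts: {sorted(missing)}")
    ordered = [contexts[m] for m in params.modalities]
    n = ordered[0].shape[0]
    for m, c in zip(params.modalities, ordered):
        if c.shape[0] != n:
            raise ValueError(
                f"row-count mismatch in fuse_context: modality {m!r} has "
                f"{c.shape[0]} rows, expected {n}")
    raw = Tensor.concat(ordered, axis=1) if len(ordered) > 1 else ordered[0]
    C = raw @ params.params["W_p"] if params.project else raw
    if session_ids is None:
        session_ids = np.zeros(n, dtype=np.intp)
        lengths = np.array([n], dtype=np.intp)
    return ContextMatrix(C=C, per_modality=dict(contexts),
                         session_ids=np.asarray(session_ids, dtype=np.intp),
                         lengths=np.asarray(lengths, dtype=np.intp))


def encode_sessions(features_by_modality: dict[str, list[np.ndarray]],
                    params: EncoderParams) -> ContextMatrix:
    """Full encoding path for a batch of sessions: per-modality BiGRU,
    fixed-order fusion, projection.  Rows of the result are utterances,
    sessions stacked in input order."""
    lengths = np.array(
        [m.shape[0] for m in next(iter(features_by_modality.values()))],
        dtype=np.intp)
    contexts = {m: encode_modality_batch(mats, params, m)
                for m, mats in features_by_modality.items()}
    session_ids = np.repeat(np.arange(len(lengths), dtype=np.intp), lengths)
    return fuse_context(contexts, params, session_ids=session_ids, lengths=lengths)
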