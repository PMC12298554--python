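"""Utterance-level scoring, bag-mean aggregation and concordance metrics.

Supervision is multiple-instance: only the subject (the *bag* of all
utterances in a session) carries a severity label.  Each utterance gets a
scalar score from a linear head over its concatenated context and graph
features, and the subject-level prediction is exactly the arithmetic mean
of the utterance scores — no learned pooling.

Agreement between predicted and true severities is measured with Lin's
concordance correlation coefficient, computed in covariance form with
population (1/N) moments:

    CCC = 2·cov(f, y) / (σ_f² + σ_y² + (μ_f − μ_y)²) ∈ [−1, 1],

and the training loss is 1 − CCC, which rewards correlation *and* matching
means/variances, making it scale-aware without label normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, segment_mean

_EPS_NOTE = "degenerate CCC: both vectors constant"


@dataclass
class HeadParams:
    """Linear read-out: W_c (width × 1), scalar bias, output activation."""

    W_c: Tensor
    b_c: Tensor
    activation: str = "identity"       # identity | relu | sigmoid_scaled
    label_range: tuple[float, float] = (0.0, 24.0)

    @classmethod
    def init(cls, width: int, activation: str = "identity",
             label_range: tuple[float, float] = (0.0, 24.0),
             rng: np.random.Generator | None = None) -> "HeadParams":
        if activation not in ("identity", "relu", "sigmoid_scaled"):
            raise ValueError(f"unknown head activation {activation!r}")
        rng = rng or np.random.default_rng()
        limit = np.sqrt(6.0 / (width + 1))
        return cls(W_c=Tensor(rng.uniform(-limit, limit, size=(width, 1)),
                              requires_grad=True),
                   b_c=Tensor(np.zeros(1), requires_grad=True),
                   activation=activation, label_range=label_range)

    def named(self, prefix: str = "head") -> dict[str, Tensor]:
        return {f"{prefix}_Wc": self.W_c, f"{prefix}_bc": self.b_c}


@dataclass
class PredictionResult:
    """Per-utterance scores and their bag mean for one session."""

    per_utterance: np.ndarray
    subject_score: float


def score_utterances(C: Tensor, H2: Tensor | None, params: HeadParams) -> Tensor:
    """ŷ_i = σ(W_c [c_i ⊕ h_i^(2)] + b_c) for every utterance row."""
    feats = C if H2 is None else Tensor.concat([C, H2], axis=1)
    if feats.shape[1] != params.W_c.shape[0]:
        raise ValueError(
            f"head expects width {params.W_c.shape[0]}, got {feats.shape[1]}")
    raw = (feats @ params.W_c + params.b_c).reshape(-1)
    if params.activation == "identity":
        return raw
    if params.activation == "relu":
        return raw.relu()
    lo, hi = params.label_range
    return raw.sigmoid() * (hi - lo) + lo


def bag_scores(y_utt: Tensor, session_ids: np.ndarray, n_sessions: int) -> Tensor:
    """Subject scores: exact arithmetic mean of each bag's utterance scores."""
    return segment_mean(y_utt.reshape(-1, 1), session_ids, n_sessions).reshape(-1)


def predict_session(C: Tensor | np.ndarray, H2: Tensor | np.ndarray | None,
                    params: HeadParams) -> PredictionResult:
    """Score a single session and aggregate by the bag mean."""
    C = C if isinstance(C, Tensor) else Tensor(C)
    if H2 is not None and not isinstance(H2, Tensor):
        H2 = Tensor(H2)
    if H2 is not None and H2.shape[0] != C.shape[0]:
        raise ValueError("C and H2 row counts differ")
    y = score_utterances(C, H2, params)
    return PredictionResult(per_utterance=y.numpy(),
                            subject_score=float(y.data.mean()))


def _coerce_pair(preds, labels) -> tuple[Tensor, Tensor]:
    f = preds if isinstance(preds, Tensor) else Tensor(np.asarray(preds, dtype=float))
    y = labels if isinstance(labels, Tensor) else Tensor(np.asarray(labels, dtype=float))
    if f.shape != y.shape:
        raise ValueError(f"length mismatch: {f.shape} vs {y.shape}")
    if f.data.ndim != 1 or f.data.size < 2:
        raise ValueError("CCC requires 1-D vectors of length >= 2")
    return f, y


def ccc(preds, labels) -> Tensor:
    """Concordance correlation coefficient (population moments).

    Differentiable w.r.t. ``preds`` wherever the denominator is positive.
    The denominator vanishes only when both vectors are constants with
    equal value; that degenerate case returns 1 (identical constants).
    """
    f, y = _coerce_pair(preds, labels)
    mu_f, mu_y = f.mean(), y.mean()
    df, dy = f - mu_f, y - mu_y
    cov = (df * dy).mean()
    var_f, var_y = (df * df).mean(), (dy * dy).mean()
    denom = var_f + var_y + (mu_f - mu_y) ** 2.0
    if denom.data == 0.0:
        return Tensor(1.0)  # identical constant vectors
    return 2.0 * cov / denom

def ccc_loss(preds, labels) -> Tensor:
    """1 − CCC, in [0, 2]; 0 at perfect concordance."""
    return 1.0 - ccc(preds, labels)


@dataclass
class MetricsReport:
    """Cohort-level agreement metrics over subject predictions."""

    mae: float
    rmse: float
    ccc: float
    n_subjects: int

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "ccc": self.ccc,
                "n_subjects": self.n_subjects}


def evaluate(preds, labels) -> MetricsReport:
    """MAE, RMSE and CCC over aligned subject-level vectors."""
    f = np.asarray(preds if not isinstance(preds, Tensor) else preds.data,
                   dtype=float).ravel()
    y = np.asarray(labels if not isinstance(labels, Tensor) else labels.data,
                   dtype=float).ravel()
    if f.size == 0:
        raise ValueError("empty cohort")
    if f.size != y.size:
        raise ValueError(f"length mismatch: {f.size} vs {y.size}")
    err = f - y
    return MetricsReport(
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err ** 2))),
        ccc=float(ccc(f, y).data) if f.size >= 2 else float("nan"),
        n_subjects=int(f.size))
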