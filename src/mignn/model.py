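"""Session-graph severity regression: model and results objects.

``DepressionMIGNN`` is built from cohorts of :class:`~mignn.data.SessionSample`
and a :class:`TrainConfig`; ``fit()`` optimises every trainable tensor
against the concordance loss and returns a :class:`MIGNNResults` carrying
the fitted parameters, the training history, prediction/evaluation methods
and a ``summary()`` table — the usual model/results split.

The full forward path per batch of sessions is

    per-modality BiGRU → fuse+project (C) → windowed FFC/BFC graph
    → bilinear edge softmax (α) → relational convolution (H1)
    → multi-head graph attention (H2) → linear head on [C ⊕ H2]
    → bag mean per session → CCC loss over the batch's subject scores.

Ablation variants reuse the same machinery:

=============  ==========================================================
``full``       the complete path above
``no_mil``     per-session mean-pooled features, single pseudo-utterance,
               no graph (removes the multiple-instance structure)
``no_gnn``     head reads C directly (no graph layers)
``gcn_only``   head reads [C ⊕ H1] (attention layer removed)
``no_bfc``     backward relation dropped from the graph
``mha_fusion`` graph layers replaced by dense per-session multi-head
               self-attention over C
=============  ==========================================================
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._tensor import Adam, Tensor, no_grad
from .data import SCALE_RANGES, SessionSample, validate_cohort
from .encoder import ContextMatrix, EncoderParams, encode_sessions
from .graph import EdgeInitParams, FFC, BFC, SELF, TemporalGraph, batch_graphs, \
    build_edges, init_edge_weights
from .head import HeadParams, MetricsReport, bag_scores, ccc_loss, evaluate, \
    score_utterances
from .layers import GATParams, MHAParams, RGCNParams, gat_forward, mha_forward, \
    rgcn_forward

VARIANTS = ("full", "no_mil", "no_gnn", "gcn_only", "no_bfc", "mha_fusion")


@dataclass
class TrainConfig:
    """Hyperparameters.  Class defaults are the reference configuration
    (GRU 200 units, node width 160, Nw=20, 4 heads, lr 1e-4, weight decay
    1e-8, 500 epochs, batch 50); :meth:`desk` returns the small-scale
    preset used for synthetic experiments."""

    hidden_units: int = 200
    node_dim: int = 160
    d_h: int = 160
    head_dim: int = 40
    heads: int = 4
    nw: int = 20
    lr: float = 1e-4
    weight_decay: float = 1e-8
    epochs: int = 500
    batch_size: int = 50
    seed: int = 0
    variant: str = "full"
    loss: str = "ccc"                  # ccc | mse
    head_activation: str = "identity"
    rgcn_activation: str = "relu"
    rgcn_degree_norm: bool = True
    gat_per_relation: bool = False
    project: bool = True
    eval_every: int = 1
    patience: int | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        if self.loss not in ("ccc", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if min(self.lr, self.epochs, self.batch_size,
               self.hidden_units, self.heads) <= 0:
            raise ValueError("lr, epochs, batch_size, hidden_units, heads "
                             "must be positive")
        if self.nw < 0 or self.nw % 2:
            raise ValueError("nw must be even and >= 0")

    @classmethod
    def desk(cls, **overrides) -> "TrainConfig":
        """Desk-scale preset: small widths and an Adam step size suited to
        a few hundred updates, keeping full training in CPU minutes."""
        base = dict(hidden_units=16, node_dim=32, d_h=32, head_dim=8,
                    heads=4, nw=20, lr=1e-2, epochs=100, batch_size=50)
        base.update(overrides)
        return cls(**base)


class ModelParameters:
    """All trainable tensors of one variant, addressable by name."""

    def __init__(self, config: TrainConfig, modalities: tuple[str, ...],
                 dims: dict[str, int], label_range: tuple[float, float],
                 rng: np.random.Generator):
        self.config = config
        self.modalities = tuple(modalities)
        self.dims = dict(dims)
        self.label_range = label_range
        cfg = config
        self.encoder = EncoderParams.init(
            self.modalities, self.dims, hidden_units=cfg.hidden_units,
            node_dim=cfg.node_dim, project=cfg.project, rng=rng)
        d_node = self.encoder.node_dim if self.encoder.project \
            else 2 * cfg.hidden_units * len(self.modalities)
        self.edge: EdgeInitParams | None = None
        self.rgcn: RGCNParams | None = None
        self.gat: GATParams | None = None
        self.mha: MHAParams | None = None
        if cfg.variant in ("full", "no_bfc", "gcn_only"):
            rels = (FFC, SELF) if cfg.variant == "no_bfc" else (FFC, BFC, SELF)
            conv_rels = (FFC,) if cfg.variant == "no_bfc" else (FFC, BFC)
            self.edge = EdgeInitParams.init(d_node, rng=rng, relations=rels)
            self.rgcn = RGCNParams.init(d_node, cfg.d_h,
                                        activation=cfg.rgcn_activation,
                                        relations=conv_rels, rng=rng)
            if cfg.variant != "gcn_only":
                self.gat = GATParams.init(cfg.d_h, cfg.head_dim,
                                          heads=cfg.heads, rng=rng)
        elif cfg.variant == "mha_fusion":
            self.mha = MHAParams.init(d_node, cfg.head_dim, heads=cfg.heads,
                                      rng=rng)
        graph_width = {
            "full": cfg.heads * cfg.head_dim,
            "no_bfc": cfg.heads * cfg.head_dim,
            "mha_fusion": cfg.heads * cfg.head_dim,
            "gcn_only": cfg.d_h,
            "no_gnn": 0,
            "no_mil": 0,
        }[cfg.variant]
        self.head = HeadParams.init(d_node + graph_width,
                                    activation=cfg.head_activation,
                                    label_range=label_range, rng=rng)

    def named(self) -> dict[str, Tensor]:
        out = dict(self.encoder.params)
        if self.edge is not None:
            out.update(self.edge.named())
        if self.rgcn is not None:
            out.update(self.rgcn.named())
        if self.gat is not None:
            out.update(self.gat.named())
        if self.mha is not None:
            out.update(self.mha.named())
        out.update(self.head.named())
        return out

    @property
    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.named().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.named().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        named = self.named()
        for k, v in state.items():
            named[k].data[...] = v


def _pool_sessions(samples: list[SessionSample]) -> list[SessionSample]:
    """Collapse each session to one mean-pooled pseudo-utterance."""
    return [replace(s, features={m: x.mean(axis=0, keepdims=True)
                                 for m, x in s.features.items()})
            for s in samples]


class DepressionMIGNN:
    """Multiple-instance temporal-graph regression model.

    Parameters
    ----------
    cohort_train : list of SessionSample
    cohort_dev : list of SessionSample, optional
        Used for per-epoch model selection on CCC; without it the final
        epoch's parameters are returned.
    config : TrainConfig, optional
    """

    def __init__(self, cohort_train: list[SessionSample],
                 cohort_dev: list[SessionSample] | None = None,
                 config: TrainConfig | None = None):
        if not cohort_train:
            raise ValueError("empty training cohort")
        validate_cohort(cohort_train)
        if cohort_dev:
            validate_cohort(cohort_dev)
        self.cohort_train = cohort_train
        self.cohort_dev = cohort_dev or []
        self.config = config or TrainConfig()
        self.modalities = cohort_train[0].modalities
        self.dims = {m: cohort_train[0].features[m].shape[1]
                     for m in self.modalities}
        self.scale = cohort_train[0].scale
        self._graph_cache: dict[tuple[int, int, bool], TemporalGraph] = {}

    @classmethod
    def from_manifest(cls, train_path, dev_path=None,
                      config: TrainConfig | None = None) -> "DepressionMIGNN":
        from .data import read_cohort
        dev = read_cohort(dev_path) if dev_path else None
        return cls(read_cohort(train_path), dev, config)

    # -- forward pass ---------------------------------------------------------

    def _session_graph(self, n: int) -> TemporalGraph:
        cfg = self.config
        key = (n, cfg.nw, cfg.variant != "no_bfc")
        g = self._graph_cache.get(key)
        if g is None:
            g = build_edges(n, cfg.nw, include_bfc=cfg.variant != "no_bfc")
            self._graph_cache[key] = g
        return g

    def forward(self, samples: list[SessionSample],
                params: ModelParameters) -> Tensor:
        """Subject-level scores for a batch of sessions (one per sample)."""
        cfg = self.config
        if cfg.variant == "no_mil":
            samples = _pool_sessions(samples)
        feats = {m: [s.features[m] for s in samples] for m in self.modalities}
        ctx = encode_sessions(feats, params.encoder)
        H2 = self._graph_features(ctx, params)
        y_utt = score_utterances(ctx.C, H2, params.head)
        return bag_scores(y_utt, ctx.session_ids, len(samples))

    def _graph_features(self, ctx: ContextMatrix,
                        params: ModelParameters) -> Tensor | None:
        cfg = self.config
        if cfg.variant in ("no_gnn", "no_mil"):
            return None
        if cfg.variant == "mha_fusion":
            return mha_forward(ctx.C, ctx.session_ids, params.mha)
        graphs = [self._session_graph(int(n)) for n in ctx.lengths]
        g, _ = batch_graphs(graphs)
        g = init_edge_weights(g, ctx, params.edge)
        H1 = rgcn_forward(g, ctx, params.rgcn,
                          degree_norm=cfg.rgcn_degree_norm)
        if cfg.variant == "gcn_only":
            return H1
        return gat_forward(g, H1, params.gat,
                           per_relation=cfg.gat_per_relation)

    # -- training -------------------------------------------------------------

    def initialize_parameters(self, seed: int | None = None) -> ModelParameters:
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        return ModelParameters(self.config, self.modalities, self.dims,
                               SCALE_RANGES[self.scale], rng)

    def _batches(self, rng: np.random.Generator) -> list[np.ndarray]:
        idx = rng.permutation(len(self.cohort_train))
        bs = self.config.batch_size
        batches = [idx[i: i + bs] for i in range(0, len(idx), bs)]
        if len(batches) > 1 and len(batches[-1]) < 2:
            # CCC needs >= 2 bags; fold a trailing singleton into its neighbor
            batches[-2] = np.concatenate([batches[-2], batches[-1]])
            batches.pop()
        return batches

    def _loss(self, scores: Tensor, labels: np.ndarray) -> Tensor:
        if self.config.loss == "mse" or scores.data.size < 2:
            diff = scores - Tensor(labels)
            return (diff * diff).mean()
        return ccc_loss(scores, labels)

    def fit(self, seed: int | None = None, verbose: bool = False) -> "MIGNNResults":
        """Train with Adam against the configured loss; returns results
        holding the best-dev-CCC parameters (or final, without a dev set).

        Deterministic given the seed: initialisation and batch order both
        derive from it.
        """
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        params = self.initialize_parameters(seed)
        named = params.named()
        opt = Adam(named, lr=cfg.lr, weight_decay=cfg.weight_decay)
        batch_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        labels_all = np.array([s.label for s in self.cohort_train])
        history: list[dict] = []
        best = {"score": -np.inf, "epoch": -1, "state": params.state_dict()}
        dev_labels = np.array([s.label for s in self.cohort_dev]) \
            if self.cohort_dev else None
        epochs_since_best = 0
        for epoch in range(cfg.epochs):
            epoch_losses = []
            for b, batch_idx in enumerate(self._batches(batch_rng)):
                batch = [self.cohort_train[i] for i in batch_idx]
                scores = self.forward(batch, params)
                loss = self._loss(scores, labels_all[batch_idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch {b}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_losses.append(loss.item())
            entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
            if self.cohort_dev and (epoch % cfg.eval_every == 0
                                    or epoch == cfg.epochs - 1):
                with no_grad():
                    dev_scores = self.forward(self.cohort_dev, params).data
                m = evaluate(dev_scores, dev_labels)
                entry.update(dev_ccc=m.ccc, dev_rmse=m.rmse, dev_mae=m.mae)
                score = m.ccc
            elif not self.cohort_dev:
                score = -entry["train_loss"]
            else:
                score = None
            history.append(entry)
            if verbose:  # pragma: no cover - console convenience
                print(f"epoch {epoch:4d}  " + "  ".join(
                    f"{k}={v:.4f}" for k, v in entry.items() if k != "epoch"))
            if score is not None:
                if score > best["score"]:
                    best = {"score": score, "epoch": epoch,
                            "state": params.state_dict()}
                    epochs_since_best = 0
                else:
                    epochs_since_best += 1
                if cfg.patience is not None and epochs_since_best >= cfg.patience:
                    break
        params.load_state_dict(best["state"])
        return MIGNNResults(model=self, params=params, history=history,
                            best_epoch=best["epoch"], seed=seed)


@dataclass
class MIGNNResults:
    """Fitted model: parameters, training history, prediction/metrics."""

    model: DepressionMIGNN
    params: ModelParameters
    history: list[dict]
    best_epoch: int
    seed: int

    @property
    def config(self) -> TrainConfig:
        return self.model.config

    @property
    def n_parameters(self) -> int:
        return self.params.n_parameters

    def predict(self, cohort: list[SessionSample] | None = None) -> pd.DataFrame:
        cohort = cohort if cohort is not None else self.model.cohort_train
        with no_grad():
            scores = self.model.forward(cohort, self.params).data
        return pd.DataFrame({
            "session_id": [s.session_id for s in cohort],
            "y_true": [s.label for s in cohort],
            "y_pred": scores,
        })

    def evaluate(self, cohort: list[SessionSample]) -> MetricsReport:
        df = self.predict(cohort)
        return evaluate(df["y_pred"].to_numpy(), df["y_true"].to_numpy())

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "DepressionMIGNN results",
            "=" * 47,
            f"{'variant':<24}{cfg.variant:>23}",
            f"{'modalities':<24}{'+'.join(self.model.modalities):>23}",
            f"{'trainable parameters':<24}{self.n_parameters:>23d}",
            f"{'epochs run':<24}{len(self.history):>23d}",
            f"{'best epoch':<24}{self.best_epoch:>23d}",
            f"{'final train loss':<24}{self.history[-1]['train_loss']:>23.4f}",
        ]
        dev_entries = [h for h in self.history if "dev_ccc" in h]
        if dev_entries:
            at_best = max(dev_entries, key=lambda h: h["dev_ccc"])
            lines += [
                f"{'best dev CCC':<24}{at_best['dev_ccc']:>23.4f}",
                f"{'dev RMSE at best':<24}{at_best['dev_rmse']:>23.4f}",
                f"{'dev MAE at best':<24}{at_best['dev_mae']:>23.4f}",
            ]
        lines.append("=" * 47)
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Loss / dev-CCC trajectories (requires matplotlib)."""
        import matplotlib.pyplot as plt  # deferred: plotting is optional
        if ax is None:
            _, ax = plt.subplots()
        epochs = [h["epoch"] for h in self.history]
        ax.plot(epochs, [h["train_loss"] for h in self.history],
                label="train loss")
        dev = [(h["epoch"], h["dev_ccc"]) for h in self.history
               if "dev_ccc" in h]
        if dev:
            ax.plot(*zip(*dev), label="dev CCC")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        from . import __version__
        meta = {
            "format": f"mignn-checkpoint-{__version__}",
            "config": asdict(self.config),
            "modalities": list(self.model.modalities),
            "dims": self.params.dims,
            "label_range": list(self.params.label_range),
            "best_epoch": self.best_epoch,
            "seed": self.seed,
            "history": self.history,
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8),
            **self.params.state_dict())
        return path if path.suffix == ".npz" else path.with_suffix(
            path.suffix + ".npz")


def run_variant(cohort_train: list[SessionSample],
                cohort_dev: list[SessionSample],
                cohort_test: list[SessionSample],
                config: TrainConfig) -> tuple[MetricsReport, MIGNNResults]:
    """Train one configuration and report test-split metrics."""
    model = DepressionMIGNN(cohort_train, cohort_dev, config)
    res = model.fit()
    return res.evaluate(cohort_test), res


def sweep(cohort_train: list[SessionSample],
          cohort_dev: list[SessionSample],
          cohort_test: list[SessionSample] | None = None,
          nw_grid: tuple[int, ...] = (0, 10, 16, 20, 24, 30, 40),
          heads_grid: tuple[int, ...] = (3, 4, 5, 6),
          config: TrainConfig | None = None) -> pd.DataFrame:
    """Grid over (window, heads) with shared seeds; one row per cell.

    Per-cell failures are recorded in the ``error`` column and do not
    abort the sweep.
    """
    base = config or TrainConfig()
    rows = []
    eval_cohort = cohort_test if cohort_test is not None else cohort_dev
    for nw in nw_grid:
        for heads in heads_grid:
            row = {"nw": nw, "heads": heads, "seed": base.seed,
                   "mae": np.nan, "rmse": np.nan, "ccc": np.nan, "error": ""}
            try:
                cfg = replace(base, nw=nw, heads=heads)
                model = DepressionMIGNN(cohort_train, cohort_dev, cfg)
                res = model.fit()
                m = res.evaluate(eval_cohort)
                row.update(mae=m.mae, rmse=m.rmse, ccc=m.ccc)
            except Exception as exc:  # noqa: BLE001 - sweep must not abort
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)
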