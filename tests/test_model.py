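"""Model/results objects: training loop, variants, sweep, determinism."""

import numpy as np
import pytest

from mignn._tensor import Tensor
from mignn.graph import BFC
from mignn.head import score_utterances
from mignn.model import (DepressionMIGNN, MIGNNResults, TrainConfig, VARIANTS,
                         run_variant, sweep)
from mignn.synthetic import SyntheticConfig, generate_cohort, make_splits, \
    strong_signal_config


def tiny_cfg(**kw):
    base = dict(hidden_units=4, node_dim=6, d_h=6, head_dim=3, heads=2,
                nw=4, epochs=1, batch_size=4, lr=1e-2)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = SyntheticConfig(n_subjects=6, n_utterances=(3, 6), seed=0)
    samples, _ = generate_cohort(cfg)
    return samples


class TestFit:
    def test_one_epoch_smoke(self, small_cohort):
        model = DepressionMIGNN(small_cohort[:4], small_cohort[4:], tiny_cfg())
        res = model.fit(seed=0)
        assert len(res.history) == 1
        assert np.isfinite(res.history[0]["train_loss"])
        assert "dev_ccc" in res.history[0]

    def test_same_seed_same_trajectory(self, small_cohort):
        cfg = tiny_cfg(epochs=3)
        runs = []
        for _ in range(2):
            model = DepressionMIGNN(small_cohort[:4], small_cohort[4:], cfg)
            runs.append([h["train_loss"] for h in model.fit(seed=7).history])
        assert runs[0] == runs[1]

    def test_different_seeds_differ(self, small_cohort):
        cfg = tiny_cfg(epochs=2)
        losses = []
        for seed in (0, 1):
            model = DepressionMIGNN(small_cohort[:4], small_cohort[4:], cfg)
            losses.append(model.fit(seed=seed).history[-1]["train_loss"])
        assert losses[0] != losses[1]

    def test_loss_decreases_on_strong_signal(self):
        tr, dev, _ = make_splits(strong_signal_config(seed=3,
                                                      n_utterances=(5, 10)),
                                 24, 8)
        cfg = tiny_cfg(epochs=12, batch_size=12)
        res = DepressionMIGNN(tr, dev, cfg).fit(seed=0)
        losses = [h["train_loss"] for h in res.history]
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_nan_loss_aborts_with_location(self, small_cohort, monkeypatch):
        model = DepressionMIGNN(small_cohort[:4], config=tiny_cfg())
        original = model.initialize_parameters

        def poisoned(seed=None):
            params = original(seed)
            params.head.b_c.data[...] = np.nan
            return params

        monkeypatch.setattr(model, "initialize_parameters", poisoned)
        with pytest.raises(RuntimeError, match="epoch 0, batch 0"):
            model.fit(seed=0)

    def test_bimodal_cohort_trains(self):
        """Cohorts that lack a modality (audio+video only) run end to end
        over their declared modality set."""
        cfg_s = SyntheticConfig(n_subjects=5, n_utterances=(3, 5), seed=2,
                                modalities=("A", "V"),
                                snr={"A": 0.6, "V": 0.3})
        samples, _ = generate_cohort(cfg_s)
        model = DepressionMIGNN(samples[:4], samples[4:], tiny_cfg())
        res = model.fit(seed=0)
        assert model.modalities == ("A", "V")
        assert np.isfinite(res.history[0]["train_loss"])

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            DepressionMIGNN([], config=tiny_cfg())

    def test_singleton_trailing_batch_is_merged(self, small_cohort):
        # 5 sessions with batch 4 would leave a 1-bag batch; the loop must
        # still produce a finite CCC loss every step
        model = DepressionMIGNN(small_cohort[:5], config=tiny_cfg(batch_size=4))
        res = model.fit(seed=0)
        assert np.isfinite(res.history[0]["train_loss"])


@pytest.fixture(scope="module")
def fitted(small_cohort):
    model = DepressionMIGNN(small_cohort[:4], small_cohort[4:],
                            tiny_cfg(epochs=2))
    return model.fit(seed=0)


@pytest.fixture(scope="module")
def models(small_cohort):
    out = {}
    for variant in VARIANTS:
        model = DepressionMIGNN(small_cohort[:4],
                                config=tiny_cfg(variant=variant))
        out[variant] = (model, model.initialize_parameters(0))
    return out


class TestResults:
    def test_predict_dataframe(self, fitted, small_cohort):
        df = fitted.predict(small_cohort[4:])
        assert list(df.columns) == ["session_id", "y_true", "y_pred"]
        assert len(df) == 2 and np.isfinite(df["y_pred"]).all()

    def test_evaluate_report(self, fitted, small_cohort):
        m = fitted.evaluate(small_cohort[4:])
        assert m.n_subjects == 2 and m.rmse >= m.mae

    def test_summary_mentions_variant_and_params(self, fitted):
        text = fitted.summary()
        assert "full" in text and str(fitted.n_parameters) in text

    def test_save_writes_checkpoint(self, fitted, tmp_path):
        path = fitted.save(tmp_path / "ckpt.npz")
        with np.load(path) as bundle:
            assert "head_Wc" in bundle


class TestVariants:
    def test_all_variants_forward(self, models, small_cohort):
        for variant, (model, params) in models.items():
            scores = model.forward(small_cohort[:4], params)
            assert scores.shape == (4,) and np.isfinite(scores.data).all()

    def test_parameter_containment(self, models):
        n = {v: p.n_parameters for v, (m, p) in models.items()}
        assert n["no_bfc"] < n["full"]
        assert n["gcn_only"] < n["full"]
        assert n["no_gnn"] < n["gcn_only"]
        assert n["no_mil"] == n["no_gnn"]

    def test_no_bfc_graph_has_no_backward_edges(self, models):
        model, _ = models["no_bfc"]
        g = model._session_graph(6)
        assert g.counts()["BFC"] == 0
        full_model, _ = models["full"]
        assert full_model._session_graph(6).counts()["FFC"] == \
            g.counts()["FFC"]

    def test_no_gnn_equals_head_over_context(self, models, small_cohort):
        """The no_gnn variant is definitionally the head applied to C."""
        from mignn.encoder import encode_sessions
        from mignn.head import bag_scores
        model, params = models["no_gnn"]
        batch = small_cohort[:4]
        scores = model.forward(batch, params)
        feats = {m: [s.features[m] for s in batch] for m in model.modalities}
        ctx = encode_sessions(feats, params.encoder)
        manual = bag_scores(score_utterances(ctx.C, None, params.head),
                            ctx.session_ids, 4)
        np.testing.assert_allclose(scores.data, manual.data, atol=1e-12)

    def test_no_mil_collapses_bags_to_one_instance(self, models, small_cohort):
        model, params = models["no_mil"]
        from mignn.model import _pool_sessions
        pooled = _pool_sessions(small_cohort[:2])
        assert all(s.n_utterances == 1 for s in pooled)
        scores = model.forward(small_cohort[:2], params)
        assert scores.shape == (2,)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            tiny_cfg(variant="bogus")


class TestSweepAndRunVariant:
    def test_run_variant_returns_metrics(self, small_cohort):
        report, res = run_variant(small_cohort[:4], small_cohort[4:],
                                  small_cohort[4:], tiny_cfg())
        assert report.n_subjects == 2
        assert isinstance(res, MIGNNResults)

    def test_sweep_grid_shape_and_determinism(self, small_cohort):
        kw = dict(nw_grid=(0, 2), heads_grid=(1,), config=tiny_cfg())
        t1 = sweep(small_cohort[:4], small_cohort[4:], **kw)
        t2 = sweep(small_cohort[:4], small_cohort[4:], **kw)
        assert len(t1) == 2
        assert (t1["error"] == "").all()
        assert t1.equals(t2)

    def test_sweep_survives_cell_failure(self, small_cohort):
        t = sweep(small_cohort[:4], small_cohort[4:], nw_grid=(0, 3),
                  heads_grid=(1,), config=tiny_cfg())
        bad = t[t["nw"] == 3].iloc[0]
        assert bad["error"] != "" and np.isnan(bad["ccc"])
        assert (t[t["nw"] == 0]["error"] == "").all()
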