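"""Autoencoder construction, training, heads, and the stratified bank."""

import numpy as np
import pytest

from lprscreen.autoencoder import (
    AEConfig,
    TensorRecord,
    build_autoencoder,
    classify,
    encode,
    load_bank,
    reconstruction_error,
    save_bank,
    train_autoencoder,
    train_bank,
    train_head,
)
from lprscreen.preprocess import PhaseTensor
from lprscreen.stats import ActivityState
from lprscreen.synthetic_data import (
    BehaviorParams,
    simulate_tracks_array,
)
from lprscreen.track_data import AssaySchedule, Phase

TOY = AEConfig(
    input_dim=6, encoder_layers=(4, 2), decoder_layers=(4,), epochs=5, seed=0
)


class TestConfig:
    def test_full_scale_defaults(self):
        cfg = AEConfig()
        assert len(cfg.encoder_layers) == 8
        assert len(cfg.decoder_layers) == 6
        assert cfg.bottleneck == 250
        assert cfg.input_dim == 4500 * 5
        assert (cfg.dropout, cfg.l1, cfg.l2) == (0.2, 1e-5, 1e-5)
        assert (cfg.learning_rate, cfg.rho, cfg.epsilon) == (0.001, 0.95, 1e-7)

    def test_non_decreasing_encoder_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            AEConfig(input_dim=10, encoder_layers=(4, 4), decoder_layers=())

    def test_dropout_and_epoch_bounds(self):
        with pytest.raises(ValueError):
            AEConfig(dropout=1.0)
        with pytest.raises(ValueError):
            AEConfig(epochs=0)


class TestBuild:
    def test_toy_shapes(self):
        m = build_autoencoder(TOY)
        dims = [(w.shape, b.shape) for w, b in zip(m.weights, m.biases)]
        assert dims == [
            ((6, 4), (4,)),
            ((4, 2), (2,)),
            ((2, 4), (4,)),
            ((4, 6), (6,)),
        ]

    def test_toy_parameter_count(self):
        m = build_autoencoder(TOY)
        # hand sum of in*out + out over the four layers
        expected = (6 * 4 + 4) + (4 * 2 + 2) + (2 * 4 + 4) + (4 * 6 + 6)
        assert m.n_parameters == expected

    def test_encoder_and_decoder_output_dims(self):
        m = build_autoencoder(TOY)
        x = np.zeros((3, 6))
        assert m.encode_array(x).shape == (3, 2)
        assert m.reconstruct(x).shape == (3, 6)


class TestTraining:
    def test_zero_input_reconstructed_immediately(self):
        m = train_autoencoder([np.zeros(6)] * 4, TOY)
        assert m.loss_history[-1] == pytest.approx(0.0, abs=1e-12)

    def test_loss_halves_on_structured_controls(self, mini_schedule):
        # 200 simulated control larvae, desk-scale config, 300 epochs
        rng = np.random.default_rng(0)
        p = BehaviorParams(missing_frame_prob=0)
        arr = simulate_tracks_array(
            np.full(200, p.light_step_mean),
            np.full(200, p.dark_burst_amplitude),
            np.zeros(200),
            np.zeros(200),
            p,
            mini_schedule,
            10.0,
            3.25,
            rng,
        )
        i0, i1 = 1800, 2400  # cycle-2 dark at 10 fps
        t = np.broadcast_to(arr["t"][i0:i1], (200, i1 - i0))
        M = np.stack(
            [t] + [arr[k][:, i0:i1] for k in ("x", "y", "dist", "vel")], axis=-1
        )
        mu = M.reshape(-1, 5).mean(0)
        sd = M.reshape(-1, 5).std(0)
        X = ((M - mu) / sd).reshape(200, -1)
        cfg = AEConfig(
            input_dim=X.shape[1],
            encoder_layers=(128, 32),
            decoder_layers=(128,),
            epochs=300,
            learning_rate=1.0,
            seed=1,
        )
        m = build_autoencoder(cfg).fit(X)
        assert m.loss_history[-1] < 0.5 * m.loss_history[0]

    def test_same_seed_gives_identical_history(self):
        rng = np.random.default_rng(3)
        X = [rng.normal(size=6) for _ in range(8)]
        cfg = AEConfig(
            input_dim=6, encoder_layers=(4, 2), decoder_layers=(4,), epochs=20, seed=5
        )
        a = train_autoencoder(X, cfg)
        b = train_autoencoder(X, cfg)
        assert a.loss_history == b.loss_history

    def test_mixed_phases_rejected(self):
        t_light = PhaseTensor("a", Phase.LIGHT, 2, np.zeros((3, 5)))
        t_dark = PhaseTensor("b", Phase.DARK, 2, np.zeros((3, 5)))
        cfg = AEConfig(input_dim=15, encoder_layers=(4,), decoder_layers=(), epochs=1)
        with pytest.raises(ValueError, match="phases"):
            train_autoencoder([t_light, t_dark], cfg)


class TestEncode:
    def test_bottleneck_length_and_determinism(self):
        m = build_autoencoder(TOY)
        x = np.arange(6.0)
        z1, z2 = encode(m, x), encode(m, x)
        assert z1.shape == (2,)
        np.testing.assert_array_equal(z1, z2)

    def test_identity_codec_recovers_input(self):
        # 1-layer linear codec with identity weights: plumbing oracle
        cfg = AEConfig(
            input_dim=4,
            encoder_layers=(4,),
            decoder_layers=(),
            activation="linear",
            dropout=0.0,
            epochs=1,
        )
        m = build_autoencoder(cfg)
        m.weights[0] = np.eye(4)
        m.weights[1] = np.eye(4)
        m.biases[0][:] = 0
        m.biases[1][:] = 0
        x = np.array([1.0, -2.0, 3.0, 0.5])
        np.testing.assert_allclose(m.reconstruct(x)[0], x, atol=1e-15)
        np.testing.assert_allclose(encode(m, x), x, atol=1e-15)

    def test_shape_mismatch_rejected(self):
        m = build_autoencoder(TOY)
        with pytest.raises(ValueError, match="features"):
            encode(m, np.zeros(7))


class TestHead:
    def test_separable_clouds_perfect_accuracy(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(30, 2))
        b = rng.normal(5, 0.1, size=(30, 2))
        head = train_head(a, b, folds=5, seed=0)
        X = np.vstack([a, b])
        y = np.r_[np.zeros(30), np.ones(30)]
        assert head.estimator.score(X, y) == 1.0

    def test_shuffled_labels_give_chance_cv(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 4))
        half = rng.permutation(200)
        a, b = X[half[:100]], X[half[100:]]
        head = train_head(a, b, folds=10, seed=1)
        assert 0.35 <= head.cv_scores.mean() <= 0.65

    def test_identical_points_score_majority_fraction(self):
        a = np.zeros((8, 2))
        b = np.zeros((2, 2))
        head = train_head(a, b, folds=2, seed=0)
        X = np.zeros((10, 2))
        y = np.r_[np.zeros(8), np.ones(2)]
        assert head.estimator.score(X, y) == pytest.approx(0.8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_head(np.zeros((5, 2)), np.zeros((0, 2)))

    def test_fold_reduction_warns(self, caplog):
        import logging

        rng = np.random.default_rng(2)
        with caplog.at_level(logging.WARNING, logger="lprscreen.autoencoder"):
            head = train_head(
                rng.normal(size=(20, 2)), rng.normal(2, 1, size=(5, 2)), folds=100
            )
        assert head.folds == 5
        assert "reducing CV folds" in caplog.text


class TestClassify:
    def _fitted(self):
        rng = np.random.default_rng(4)
        m = build_autoencoder(TOY)
        normals = rng.normal(0, 0.3, size=(40, 6))
        abnormals = rng.normal(3, 0.3, size=(40, 6))
        zn = m.encode_array(normals)
        za = m.encode_array(abnormals)
        head = train_head(zn, za, folds=5, seed=0)
        return m, head, normals, abnormals

    def test_centroids_fall_on_their_sides(self):
        m, head, normals, abnormals = self._fitted()
        p_n, label_n = classify(m, head, normals.mean(axis=0))
        p_a, label_a = classify(m, head, abnormals.mean(axis=0))
        assert p_n < 0.5 and not label_n
        assert p_a > 0.5 and label_a

    def test_threshold_zero_flags_everything(self):
        m, head, normals, _ = self._fitted()
        _, label = classify(m, head, normals.mean(axis=0), threshold=0.0)
        assert label


def _phase_records(rng, n, phase, plate, scale=1.0, is_control=True, prefix="s"):
    t = np.arange(30) / 10.0
    recs = []
    for i in range(n):
        mat = np.column_stack(
            [
                t,
                rng.normal(0, 1, 30),
                rng.normal(0, 1, 30),
                rng.gamma(2, 0.05 * scale, 30),
                rng.gamma(2, 0.05 * scale, 30) * 10,
            ]
        )
        sid = f"{prefix}{plate}-{phase.value}-{i}"
        recs.append(
            TensorRecord(
                subject_id=sid,
                plate_id=plate,
                phase=phase,
                tensor=PhaseTensor(sid, phase, 2, mat),
                is_control=is_control,
            )
        )
    return recs


class TestBank:
    cfg = AEConfig(
        input_dim=150,
        encoder_layers=(16, 8),
        decoder_layers=(16,),
        epochs=10,
        learning_rate=1.0,
        seed=0,
    )

    def _records_and_strata(self, states):
        rng = np.random.default_rng(0)
        records, strat = [], {}
        for p, state in enumerate(states):
            plate = f"P{p}"
            strat[plate] = {Phase.LIGHT: state, Phase.DARK: state}
            for phase in Phase:
                records += _phase_records(rng, 12, phase, plate)
                records += _phase_records(
                    rng, 3, phase, plate, scale=4.0, is_control=False, prefix="abn"
                )
        abnormal_ids = {r.subject_id for r in records if not r.is_control}
        return records, strat, abnormal_ids

    def test_all_states_present_gives_six_pairs(self):
        records, strat, abnormal = self._records_and_strata(list(ActivityState))
        bank = train_bank(records, strat, abnormal, self.cfg, min_controls=10, head_folds=3)
        assert len(bank) == 6
        assert bank.complete
        assert not bank.missing

    def test_normal_only_study_gives_two_entries_and_four_missing(self, caplog):
        import logging

        records, strat, abnormal = self._records_and_strata(
            [ActivityState.NORMAL, ActivityState.NORMAL]
        )
        with caplog.at_level(logging.WARNING, logger="lprscreen.autoencoder"):
            bank = train_bank(
                records, strat, abnormal, self.cfg, min_controls=10, head_folds=3
            )
        assert len(bank) == 2
        assert len(bank.missing) == 4
        assert caplog.text.count("skipped") == 4

    def test_same_seed_reproduces_classifications(self):
        records, strat, abnormal = self._records_and_strata([ActivityState.NORMAL])
        banks = [
            train_bank(records, strat, abnormal, self.cfg, min_controls=10, head_folds=3)
            for _ in range(2)
        ]
        probe = records[0]
        p1, _ = banks[0].classify_record(probe)
        p2, _ = banks[1].classify_record(probe)
        assert p1 == p2
        h1 = banks[0].entries[(ActivityState.NORMAL, Phase.LIGHT)].model.loss_history
        h2 = banks[1].entries[(ActivityState.NORMAL, Phase.LIGHT)].model.loss_history
        assert h1 == h2

    def test_save_load_roundtrip(self, tmp_path):
        records, strat, abnormal = self._records_and_strata([ActivityState.NORMAL])
        bank = train_bank(records, strat, abnormal, self.cfg, min_controls=10, head_folds=3)
        save_bank(bank, tmp_path / "bank")
        back = load_bank(tmp_path / "bank")
        assert set(back.entries) == set(bank.entries)
        p0, l0 = bank.classify_record(records[5])
        p1, l1 = back.classify_record(records[5])
        assert p0 == pytest.approx(p1, abs=1e-12) and l0 == l1

    def test_missing_stratum_classification_raises(self):
        records, strat, abnormal = self._records_and_strata([ActivityState.NORMAL])
        bank = train_bank(records, strat, abnormal, self.cfg, min_controls=10, head_folds=3)
        strat_probe = TensorRecord(
            subject_id="x",
            plate_id="P0",
            phase=Phase.LIGHT,
            tensor=records[0].tensor,
            is_control=True,
        )
        bank.stratification["P0"][Phase.LIGHT] = ActivityState.HYPERACTIVE
        with pytest.raises(KeyError):
            bank.classify_record(strat_probe)


class TestSemiSupervisedPremise:
    def test_anomalies_reconstruct_worse_than_heldout_controls(self, mini_schedule):
        """Controls held out of training reconstruct better than strong anomalies."""
        rng = np.random.default_rng(6)
        p = BehaviorParams(missing_frame_prob=0)

        def batch(n, scale):
            arr = simulate_tracks_array(
                np.full(n, p.light_step_mean * scale),
                np.full(n, p.dark_burst_amplitude * scale),
                np.zeros(n),
                np.zeros(n),
                p,
                mini_schedule,
                10.0,
                3.25,
                rng,
            )
            i0, i1 = 1800, 2400
            return np.stack(
                [arr[k][:, i0:i1] for k in ("x", "y", "dist", "vel")], axis=-1
            ).reshape(n, -1)

        train = batch(80, 1.0)
        held = batch(30, 1.0)
        anom = batch(30, 3.0)
        mu, sd = train.mean(0), train.std(0)
        cfg = AEConfig(
            input_dim=train.shape[1],
            encoder_layers=(32, 8),
            decoder_layers=(32,),
            epochs=150,
            learning_rate=1.0,
            seed=2,
        )
        m = build_autoencoder(cfg).fit((train - mu) / sd)
        err_h = np.mean([reconstruction_error(m, (x - mu) / sd) for x in held])
        err_a = np.mean([reconstruction_error(m, (x - mu) / sd) for x in anom])
        assert err_h < err_a
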