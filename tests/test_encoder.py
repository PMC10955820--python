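"""Encoder objective: the exact truth table of the sequence loss, the
column-confidence encoding loss, their surrogate forms, and the encoder
network contracts."""

import itertools

import numpy as np
import pytest

from hybriclass import encoder
from hybriclass.encoder import (
    Encoder,
    EncoderConfig,
    LossConfig,
    PairContext,
    encoder_loss,
    encoding_loss,
    sequence_loss,
)

LN4 = float(np.log(4.0))


def confident_matrix(length: int = 59) -> np.ndarray:
    """A soft matrix whose every column has max 0.7 (>= 0.5)."""
    m = np.full((4, length), 0.1)
    m[2] = 0.7
    return m


class TestEncodingLoss:
    def test_zero_when_all_columns_confident(self):
        assert encoding_loss(confident_matrix()) == 0.0

    def test_uniform_column_contributes_ln4(self):
        m = confident_matrix()
        m[:, 7] = 0.25
        assert encoding_loss(m) == pytest.approx(LN4, abs=1e-9)
        assert encoding_loss(m) == pytest.approx(1.3863, abs=1e-4)

    def test_just_below_threshold_column(self):
        m = confident_matrix()
        m[:, 0] = [0.49, 0.17, 0.17, 0.17]
        assert encoding_loss(m) == pytest.approx(-np.log(0.49), abs=1e-9)
        assert encoding_loss(m) == pytest.approx(0.7133, abs=1e-4)

    def test_at_threshold_is_confident(self):
        # max exactly 0.5 does not trigger the penalty (strict inequality)
        m = confident_matrix()
        m[:, 3] = [0.5, 0.3, 0.1, 0.1]
        assert encoding_loss(m) == 0.0

    def test_positive_iff_some_column_ambiguous(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.random((4, 10))
            m /= m.sum(axis=0)
            loss = encoding_loss(m)
            if np.all(m.max(axis=0) >= 0.5):
                assert loss == 0.0
            else:
                assert loss > 0.0

    def test_unnormalized_column_rejected(self):
        m = confident_matrix()
        m[0, 0] += 0.5
        with pytest.raises(ValueError):
            encoding_loss(m)


class TestSequenceLossLiteral:
    CFG = LossConfig(t1=16.0, t2=0.8, mode="literal")

    @pytest.mark.parametrize(
        "e,y,same,expected",
        # exhaustive truth table: (E vs T1) x (Y vs T2) x (label equality);
        # the (close, low-yield, different-label) case carries loss 0
        [
            (10.0, 0.5, True, 1.0),
            (10.0, 0.5, False, 0.0),
            (10.0, 0.9, True, 0.0),
            (10.0, 0.9, False, 0.0),
            (20.0, 0.5, True, 0.0),
            (20.0, 0.5, False, 0.0),
            (20.0, 0.9, True, 0.0),
            (20.0, 0.9, False, 1.0),
            # boundary: E == T1 counts as "far", Y == T2 counts as "high"
            (16.0, 0.8, False, 1.0),
            (16.0, 0.8, True, 0.0),
            (15.999, 0.8, True, 0.0),
            (16.0, 0.799, True, 0.0),
        ],
    )
    def test_truth_table(self, e, y, same, expected):
        ctx = PairContext(E=e, Y=y, L1=3, L2=3 if same else 5)
        assert sequence_loss(ctx, self.CFG) == expected


class TestSequenceLossSurrogate:
    CFG = LossConfig(t1=16.0, t2=0.8, mode="surrogate")

    def test_close_same_label_hinge(self):
        ctx = PairContext(E=10.0, Y=0.5, L1=1, L2=1)
        assert sequence_loss(ctx, self.CFG) == pytest.approx(0.3)

    def test_far_different_label_hinge(self):
        # repulsion hinge runs to the strict margin t_low, not to T2
        ctx = PairContext(E=20.0, Y=0.95, L1=1, L2=2)
        assert sequence_loss(ctx, self.CFG) == pytest.approx(0.95 - self.CFG.t_low)
        satisfied = PairContext(E=20.0, Y=0.04, L1=1, L2=2)
        assert sequence_loss(satisfied, self.CFG) == 0.0

    def test_zero_on_unconstrained_branches(self):
        # close-but-different and far-but-same pairs carry no loss for any Y
        rng = np.random.default_rng(1)
        for _ in range(200):
            y = float(rng.uniform(0, 1))
            assert sequence_loss(PairContext(E=5.0, Y=y, L1=0, L2=1), self.CFG) == 0.0
            assert sequence_loss(PairContext(E=25.0, Y=y, L1=2, L2=2), self.CFG) == 0.0

    def test_zero_once_targets_reached(self):
        assert sequence_loss(PairContext(E=5.0, Y=0.85, L1=0, L2=0), self.CFG) == 0.0
        assert sequence_loss(PairContext(E=25.0, Y=0.02, L1=0, L2=1), self.CFG) == 0.0

    def test_nonnegative_and_continuous_in_y(self):
        for same in (True, False):
            ys = np.linspace(0, 1, 101)
            vals = [
                sequence_loss(PairContext(E=10.0 if same else 20.0, Y=float(y),
                                          L1=0, L2=0 if same else 1), self.CFG)
                for y in ys
            ]
            assert all(v >= 0 for v in vals)
            diffs = np.abs(np.diff(vals))
            assert diffs.max() <= 0.011  # Lipschitz-1 on a 0.01 grid


class TestEncoderLoss:
    def test_both_terms_vanish(self):
        ctx = PairContext(E=10.0, Y=0.9, L1=1, L2=1)
        cfg = LossConfig(mode="literal")
        assert encoder_loss((confident_matrix(), confident_matrix()), ctx, cfg) == 0.0

    def test_literal_unit_branch_additivity(self):
        ctx = PairContext(E=10.0, Y=0.5, L1=1, L2=1)
        cfg = LossConfig(mode="literal")
        assert encoder_loss((confident_matrix(), confident_matrix()), ctx, cfg) == 1.0

    def test_uniform_output_contributes_59_ln4(self):
        uniform = np.full((4, 59), 0.25)
        ctx = PairContext(E=10.0, Y=0.9, L1=1, L2=1)
        cfg = LossConfig(mode="literal")
        total = encoder_loss((uniform, confident_matrix()), ctx, cfg)
        assert total == pytest.approx(59 * LN4, abs=1e-9)
        assert total == pytest.approx(81.79, abs=0.01)


class TestEncoderNetwork:
    def test_forward_columns_are_distributions(self):
        enc = Encoder(EncoderConfig(seed=0))
        rng = np.random.default_rng(2)
        out = enc.forward(rng.normal(size=50))
        assert out.shape == (4, 59)
        np.testing.assert_allclose(out.sum(axis=0), 1.0, atol=1e-6)
        assert np.all(out >= 0)

    def test_batch_shape(self):
        enc = Encoder(EncoderConfig(seed=0))
        rng = np.random.default_rng(3)
        out = enc.forward(rng.normal(size=(7, 50)))
        assert out.shape == (7, 4, 59)

    def test_same_seed_same_init(self):
        a = Encoder(EncoderConfig(seed=4)).net.state_dict()
        b = Encoder(EncoderConfig(seed=4)).net.state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_loss_config_validation(self):
        with pytest.raises(ValueError):
            LossConfig(t1=-1.0)
        with pytest.raises(ValueError):
            LossConfig(t2=1.5)
        with pytest.raises(ValueError):
            LossConfig(mode="fuzzy")

    def test_training_requires_trained_upstream(self, glyph_corpus):
        from hybriclass import features as feat_mod
        from hybriclass import predictor as pred_mod

        fresh_extractor = feat_mod.build_feature_extractor()
        fresh_predictor = pred_mod.build_predictor()
        with pytest.raises(ValueError, match="trained"):
            encoder.train_encoder(
                fresh_extractor, fresh_predictor,
                glyph_corpus["train_x"][:10], glyph_corpus["train_y"][:10],
            )
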