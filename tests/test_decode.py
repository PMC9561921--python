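"""Splits, decoding rules, metrics, and the training loop."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import avbci
from avbci.decode import (
    DataError,
    SingleTrialERPModel,
    TrainConfig,
    UndefinedStatisticError,
    attention_report,
    decode_stage1,
    decode_stage2,
    grand_average,
    paired_ttest,
    score_epoch,
    sign_test,
    split_and_oversample,
)
from avbci.montage import default_montage
from avbci.preprocess import EpochSet


def _toy_epochs(n_chars, stage, seed=0, separation=0.0):
    """Synthetic epoch stack with provenance, optionally separable."""
    rng = np.random.default_rng(seed)
    rows, datas = [], []
    per_char = 3 if stage == 1 else 5
    for ci in range(n_chars):
        target_idx = rng.integers(0, per_char)
        for k in range(per_char):
            is_target = (k == target_idx) if stage == 2 else (k % 2 == 0)
            x = rng.standard_normal((62, 100)).astype(np.float32)
            if is_target:
                # localized ERP-like deflection, not a global shift (a
                # common-mode offset would distort batch-norm statistics
                # between the oversampled train and natural eval mixes)
                x[8:18, 30:50] += 3.0 * separation
            datas.append(x)
            rows.append(
                {"stage": stage, "is_target": bool(is_target),
                 "char_index": ci, "index": k, "character": "A",
                 "group": 0, "shown": None}
            )
    return EpochSet(data=np.stack(datas), info=pd.DataFrame(rows),
                    montage=default_montage())


class TestSplitAndOversample:
    def test_stage2_counts_before_oversampling(self):
        epochs = _toy_epochs(360, stage=2, seed=1)
        cfg = TrainConfig(oversample_extra_copies=0, seed=0)
        train, val, test = split_and_oversample(epochs, cfg,
                                                n_train_chars=300)
        # 300 characters -> 300 target + 1200 nontarget, minus 10% val
        n_trainval_targets = (train.labels == 1).sum() + (val.labels == 1).sum()
        n_trainval_nontargets = ((train.labels == 0).sum()
                                 + (val.labels == 0).sum())
        assert n_trainval_targets == 300
        assert n_trainval_nontargets == 1200
        assert test.info["char_index"].nunique() == 60

    def test_oversampling_balances_classes(self):
        epochs = _toy_epochs(310, stage=2, seed=2)
        cfg = TrainConfig(oversample_extra_copies=3, seed=0)
        train, val, _ = split_and_oversample(epochs, cfg, n_train_chars=300)
        n_t = (train.labels == 1).sum()
        n_n = (train.labels == 0).sum()
        assert n_t == 4 * (300 - (val.labels == 1).sum())
        assert n_t == pytest.approx(n_n, rel=0.02)

    def test_no_oversampling_when_disabled(self):
        epochs = _toy_epochs(310, stage=2, seed=2)
        base = TrainConfig(oversample_extra_copies=0, seed=0)
        train, val, _ = split_and_oversample(epochs, base, n_train_chars=300)
        assert (train.labels == 1).sum() + (val.labels == 1).sum() == 300

    def test_insufficient_characters(self):
        epochs = _toy_epochs(100, stage=2)
        with pytest.raises(DataError):
            split_and_oversample(epochs, TrainConfig(), n_train_chars=300)

    def test_split_is_by_character_block(self):
        epochs = _toy_epochs(320, stage=2, seed=3)
        _, _, test = split_and_oversample(epochs, TrainConfig(),
                                          n_train_chars=300)
        assert test.info["char_index"].min() == 300


class TestDecodeStage1:
    def test_perfect_101_pattern(self, codebook):
        gi = decode_stage1([0.9, 0.1, 0.9], codebook)
        assert codebook.codes[gi] == "101"

    def test_all_low_scores_pick_zero_code(self, codebook):
        gi = decode_stage1([0.1, 0.1, 0.1], codebook)
        assert codebook.codes[gi] == "000"

    def test_scores_clipped_not_rejected(self, codebook):
        gi = decode_stage1([1.0, 0.0, 1.0], codebook)
        assert codebook.codes[gi] == "101"

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.001, 0.999), min_size=3, max_size=3))
    def test_matches_exhaustive_enumeration(self, scores):
        """Likelihood decoding equals brute force over all 8 codes."""
        cb = avbci.build_codebook()
        p = np.asarray(scores)
        lls = []
        for code in cb.codes:
            ll = sum(
                np.log(p[k]) if bit == "1" else np.log(1 - p[k])
                for k, bit in enumerate(code)
            )
            lls.append(ll)
        lls = np.asarray(lls)
        expected = int(np.flatnonzero(lls >= lls.max() - 1e-9)[0])
        assert decode_stage1(scores, cb) == expected

    def test_hamming_variant(self, codebook):
        gi = decode_stage1([0.9, 0.2, 0.8], codebook, method="hamming")
        assert codebook.codes[gi] == "101"


class TestDecodeStage2:
    def test_argmax(self):
        assert decode_stage2([0.1, 0.9, 0.2, 0.3, 0.1]) == 1

    def test_tie_breaks_to_lowest(self):
        assert decode_stage2([0.5, 0.5, 0.5, 0.5, 0.5]) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=5, max_size=5))
    def test_matches_max_scan(self, scores):
        best, best_i = -1.0, 0
        for i, s in enumerate(scores):
            if s > best:
                best, best_i = s, i
        assert decode_stage2(scores) == best_i


class TestStatistics:
    def test_paired_t_closed_form(self):
        """t = mean(d) / (sd(d)/sqrt(n)) on a worked example."""
        t, p = paired_ttest([1, 2, 3], [0, 2, 2])
        assert t == pytest.approx(2.0)
        assert 0 < p < 1

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            paired_ttest([1, 2, 3], [0, 1, 2])

    def test_sign_test_counts(self):
        wins, losses, p = sign_test([2, 3, 4, 5], [1, 1, 1, 9])
        assert (wins, losses) == (3, 1)
        assert 0 < p <= 1

    def test_sign_test_all_ties(self):
        assert sign_test([1, 1], [1, 1]) == (0, 0, 1.0)


class TestTraining:
    def test_separable_toy_data_learns(self):
        """Two linearly separable classes reach high validation accuracy."""
        epochs = _toy_epochs(40, stage=2, seed=5, separation=1.0)
        # small batches: eval-mode batch-norm statistics need enough
        # optimizer steps to track the converging weights
        cfg = TrainConfig(max_iterations=5, seed=0,
                          oversample_extra_copies=3, batch_size=16)
        model, test = SingleTrialERPModel.from_epochs(
            epochs, cfg, n_train_chars=30
        )
        res = model.fit(cfg)
        assert res.history["val_acc"].max() > 0.95
        assert res.evaluate_epochs(test)["accuracy"] > 0.9

    def test_checkpoint_has_min_val_loss(self):
        epochs = _toy_epochs(40, stage=2, seed=6, separation=0.5)
        cfg = TrainConfig(max_iterations=3, seed=1)
        model, _ = SingleTrialERPModel.from_epochs(epochs, cfg,
                                                   n_train_chars=30)
        res = model.fit(cfg)
        assert res.best_iteration == res.history["val_loss"].idxmin()

    def test_seeded_training_reproducible(self):
        epochs = _toy_epochs(36, stage=2, seed=7, separation=0.5)
        cfg = TrainConfig(max_iterations=2, seed=3)
        hists = []
        for _ in range(2):
            model, _ = SingleTrialERPModel.from_epochs(epochs, cfg,
                                                       n_train_chars=30)
            hists.append(model.fit(cfg).history)
        pd.testing.assert_frame_equal(hists[0], hists[1])

    def test_score_epoch_matches_softmax_oracle(self):
        epochs = _toy_epochs(36, stage=2, seed=8, separation=0.5)
        cfg = TrainConfig(max_iterations=1, seed=0)
        model, test = SingleTrialERPModel.from_epochs(epochs, cfg,
                                                      n_train_chars=30)
        res = model.fit(cfg)
        x = test.data[0]
        logits = res.net.forward(x[None])[0]
        expect = np.exp(logits[1]) / np.exp(logits).sum()
        assert score_epoch(res.net, x) == pytest.approx(expect, abs=1e-6)
        p = res.predict_proba(test.data[:4])
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestReports:
    def test_attention_report_normalized(self):
        epochs = _toy_epochs(4, stage=2, seed=9)
        net = avbci.STACNN()
        rep = attention_report(net, epochs)
        assert rep["a_t"].shape == (100,)
        assert rep["a_s"].shape == (62,)
        assert rep["a_t"].sum() == pytest.approx(1.0, abs=1e-5)
        assert rep["a_s"].sum() == pytest.approx(1.0, abs=1e-5)

    def test_attention_report_empty_set(self):
        epochs = _toy_epochs(2, stage=2)
        with pytest.raises(DataError):
            attention_report(avbci.STACNN(), epochs.select([False] * 10))

    def test_grand_average_identities(self):
        epochs = _toy_epochs(4, stage=1, seed=10)
        one = epochs.select([True] + [False] * 11)
        np.testing.assert_allclose(grand_average(one), one.data[0])
        x = epochs.data[0]
        paired = EpochSet(
            data=np.stack([x, -x]),
            info=epochs.info.iloc[:2].reset_index(drop=True),
            montage=epochs.montage,
        )
        np.testing.assert_allclose(grand_average(paired), 0.0, atol=1e-7)
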