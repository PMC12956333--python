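"""Masking, constrained loss, accuracy, schedule and the training loop."""

import math

import numpy as np
import pytest

from syncodon import (
    TrainConfig,
    constrain_logits,
    lr_at_step,
    mask_batch,
    masked_accuracy,
    mlm_loss,
    uniform_constraint_baseline,
)
from syncodon.codon_core import CodonTokenizer
from syncodon.model import EncoderConfig, init_model
from syncodon.pretraining import (
    IGNORE,
    SynCodonMLM,
    _masked_forward,
    _softmax_rows,
    evaluate_masked,
    train,
)

from conftest import random_cds


def _random_token_grid(rng, B=50, L=30, tokenizer=None):
    tok = tokenizer or CodonTokenizer()
    inner = rng.integers(0, 64, size=(B, L - 2))
    return np.concatenate(
        [np.full((B, 1), tok.start_id), inner, np.full((B, 1), tok.end_id)], axis=1
    )


class TestMaskBatch:
    def test_probability_zero_masks_nothing(self, tokenizer, rng):
        ids = _random_token_grid(rng)
        batch = mask_batch(ids, 1e-12, rng, tokenizer)
        assert batch.n_masked == 0
        assert np.array_equal(batch.input_ids, ids)
        assert (batch.labels == IGNORE).all()

    def test_probability_one_masks_every_codon(self, tokenizer, rng):
        ids = _random_token_grid(rng)
        batch = mask_batch(ids, 1 - 1e-12, rng, tokenizer)
        is_codon = ids < 64
        assert batch.mask.sum() == is_codon.sum()
        assert (batch.input_ids[is_codon] == tokenizer.mask_id).all()
        assert (batch.input_ids[~is_codon] == ids[~is_codon]).all()
        assert np.array_equal(batch.labels[batch.mask], ids[is_codon])

    def test_empirical_rate_at_default(self, tokenizer):
        """Over 10^6 codon positions the rate concentrates at 15% +/- 0.2pp."""
        rng = np.random.default_rng(2024)
        ids = _random_token_grid(rng, B=5000, L=202)
        batch = mask_batch(ids, 0.15, rng, tokenizer)
        rate = batch.n_masked / (ids < 64).sum()
        assert (ids < 64).sum() >= 1_000_000
        assert rate == pytest.approx(0.15, abs=0.002)

    def test_padding_never_masked(self, tokenizer, rng):
        ids = np.full((4, 10), tokenizer.pad_id)
        ids[:, 0] = 5
        valid = ids != tokenizer.pad_id
        batch = mask_batch(ids, 0.999999, rng, tokenizer, valid=valid)
        assert batch.mask[:, 1:].sum() == 0


class TestConstrainLogits:
    def test_probability_outside_family_exactly_zero(self, tokenizer, code, mask_matrix, rng):
        """1,000 random logit vectors, every codon label: exact zero leakage."""
        logits = rng.normal(scale=5.0, size=(1000, 69))
        labels = rng.integers(0, 64, size=1000)
        z = constrain_logits(logits, labels, mask_matrix)
        p = _softmax_rows(z)
        for i in range(1000):
            family_ids = {tokenizer.token_to_id[c]
                          for c in code.synonymous_set(tokenizer.codons[labels[i]])}
            outside = [v for v in range(69) if v not in family_ids]
            assert p[i, outside].sum() == 0.0
            assert p[i].sum() == pytest.approx(1.0)

    def test_synonymous_entries_unchanged(self, tokenizer, mask_matrix, rng):
        logits = rng.normal(size=(10, 69))
        labels = np.full(10, tokenizer.token_to_id["GCT"])  # alanine, 4-fold
        z = constrain_logits(logits, labels, mask_matrix)
        finite = np.isfinite(z[0])
        assert np.array_equal(z[:, finite], logits[:, finite])

    def test_special_token_label_rejected(self, mask_matrix):
        with pytest.raises(ValueError):
            constrain_logits(np.zeros((1, 69)), np.array([64]), mask_matrix)


class TestMLMLoss:
    def test_uniform_logits_give_log_degeneracy(self, tokenizer, mask_matrix):
        """Closed form: -log(1/n_i); ln 6 for leucine, ln 2 for 2-fold."""
        for codon, n in [("CTG", 6), ("AGT", 6), ("CGT", 6), ("AAT", 2), ("GCT", 4)]:
            labels = np.array([tokenizer.token_to_id[codon]])
            z = constrain_logits(np.zeros((1, 69)), labels, mask_matrix)
            assert mlm_loss(z, labels) == pytest.approx(math.log(n), rel=1e-12)

    def test_singleton_family_loss_exactly_zero(self, tokenizer, mask_matrix, rng):
        labels = np.array([tokenizer.token_to_id["ATG"]])
        z = constrain_logits(rng.normal(size=(1, 69)), labels, mask_matrix)
        assert mlm_loss(z, labels) == 0.0

    def test_batch_loss_is_mean_of_positions(self, tokenizer, mask_matrix, rng):
        logits = rng.normal(size=(2, 69))
        labels = np.array([tokenizer.token_to_id["CTG"], tokenizer.token_to_id["GCT"]])
        z = constrain_logits(logits, labels, mask_matrix)
        a = mlm_loss(z[:1], labels[:1])
        b = mlm_loss(z[1:], labels[1:])
        assert mlm_loss(z, labels) == pytest.approx((a + b) / 2)

    def test_constrained_never_exceeds_unconstrained(self, mask_matrix, rng):
        """Removing mass from non-synonymous tokens can only help the truth."""
        for _ in range(50):
            logits = rng.normal(scale=3.0, size=(20, 69))
            labels = rng.integers(0, 64, size=20)
            z = constrain_logits(logits, labels, mask_matrix)
            assert mlm_loss(z, labels) <= mlm_loss(logits, labels) + 1e-12

    def test_empty_mask_set_rejected(self):
        with pytest.raises(ValueError):
            mlm_loss(np.zeros((0, 69)), np.zeros(0, dtype=int))


class TestMaskedAccuracy:
    def test_one_hot_logits_are_perfect(self, rng):
        labels = rng.integers(0, 64, size=30)
        z = np.eye(69)[labels] * 10
        assert masked_accuracy(z, labels) == 1.0

    def test_jittered_uniform_two_fold_is_half(self, tokenizer, mask_matrix):
        """With i.i.d. noise on a 2-fold family the constrained argmax is a coin."""
        rng = np.random.default_rng(0)
        n = 100_000
        labels = np.full(n, tokenizer.token_to_id["AAT"])  # asparagine, 2-fold
        z = constrain_logits(rng.normal(scale=1e-6, size=(n, 69)), labels, mask_matrix)
        assert masked_accuracy(z, labels) == pytest.approx(0.5, abs=0.01)

    def test_constraint_no_worse_than_unconstrained(self, mask_matrix, rng):
        logits = rng.normal(size=(2000, 69))
        labels = rng.integers(0, 64, size=2000)
        z = constrain_logits(logits, labels, mask_matrix)
        assert masked_accuracy(z, labels) >= masked_accuracy(logits, labels)


class TestSchedule:
    def test_anchor_points(self):
        T = 1000
        assert lr_at_step(0, T) == 0.0
        assert lr_at_step(100, T) == pytest.approx(2e-4)
        assert lr_at_step(T, T) == pytest.approx(0.0, abs=1e-20)
        midpoint = 100 + (T - 100) / 2
        assert lr_at_step(midpoint, T) == pytest.approx(1e-4)

    def test_continuous_and_bounded(self):
        T = 500
        values = [lr_at_step(s, T) for s in range(T + 1)]
        assert max(values) == pytest.approx(2e-4)
        diffs = np.abs(np.diff(values))
        assert diffs.max() < 2e-4 / (0.1 * T) + 1e-12


class TestUniformBaseline:
    def test_pure_singleton_corpus(self, code):
        counts = np.zeros(64)
        counts[code.codons.index("ATG")] = 10
        assert uniform_constraint_baseline(counts, code) == 1.0

    def test_mixed_corpus_weighted_mean(self, code):
        counts = np.zeros(64)
        counts[code.codons.index("ATG")] = 1   # 1/1
        counts[code.codons.index("AAT")] = 1   # 1/2
        counts[code.codons.index("CTG")] = 2   # 1/6 twice
        expected = (1 + 0.5 + 2 / 6) / 4
        assert uniform_constraint_baseline(counts, code) == pytest.approx(expected)


class TestTrainingStep:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        cfg = EncoderConfig(hidden_size=16, intermediate_size=32, num_layers=1,
                            num_heads=2, max_positions=32, num_token_types=2,
                            dropout=0.0, relative_position_buckets=4)
        tok = CodonTokenizer(max_positions=32)
        from syncodon import build_synonym_mask

        return cfg, tok, build_synonym_mask(tok)

    def test_gradient_zero_at_excluded_logits(self, tiny_setup, rng):
        """d loss / d logits is exactly 0 wherever the constraint adds -inf."""
        cfg, tok, mm = tiny_setup
        state = init_model(cfg, seed=0)
        ids = _random_token_grid(rng, B=4, L=12, tokenizer=tok)
        batch = mask_batch(ids, 0.4, rng, tok, token_type_ids=np.zeros_like(ids))
        _, _, _, _, labels, z = _masked_forward(state, batch, mm, train=False, rng=None)
        p = _softmax_rows(z)
        dlogits = p.copy()
        dlogits[np.arange(labels.size), labels] -= 1.0
        excluded = ~np.isfinite(mm.mask[labels])
        assert np.all(dlogits[excluded] == 0.0)

    def test_initial_loss_matches_log_degeneracy_average(self, tiny_setup, code, rng):
        """At (near-uniform) init the constrained loss is ~ mean ln n_i over M."""
        cfg, tok, mm = tiny_setup
        state = init_model(cfg, seed=1)
        ids = np.stack([tok.encode(random_cds(rng, 20)) for _ in range(50)])
        batch = mask_batch(ids, 0.15, rng, tok, token_type_ids=np.zeros_like(ids))
        _, _, _, _, labels, z = _masked_forward(state, batch, mm, train=False, rng=None)
        loss = mlm_loss(z, labels)
        expected = np.mean(
            [math.log(code.degeneracy[code.codons[t]]) for t in labels]
        )
        assert loss == pytest.approx(expected, rel=0.05)

    def test_train_logs_and_determinism(self, tiny_setup, rng):
        cfg, tok, mm = tiny_setup
        seqs = [tok.encode(random_cds(np.random.default_rng(i), 10)) for i in range(20)]
        tcfg = TrainConfig(epochs=2, batch_size=8, seed=5, max_lr=1e-3)
        s1 = init_model(cfg, seed=2)
        log1 = train(s1, seqs, [0] * 20, tcfg, tok, mm)
        s2 = init_model(cfg, seed=2)
        log2 = train(s2, seqs, [0] * 20, tcfg, tok, mm)
        assert [r["loss"] for r in log1] == [r["loss"] for r in log2]
        assert all(np.array_equal(s1.params[k], s2.params[k]) for k in s1.params)
        assert {"step", "loss", "masked_accuracy", "lr"} <= set(log1[0])

    def test_empty_corpus_rejected(self, tiny_setup):
        cfg, tok, mm = tiny_setup
        with pytest.raises(ValueError):
            train(init_model(cfg, seed=0), [], [], TrainConfig(), tok, mm)


class TestSynCodonMLMEstimator:
    def test_get_set_params_roundtrip(self):
        mlm = SynCodonMLM(epochs=3)
        params = mlm.get_params()
        assert params["epochs"] == 3
        mlm.set_params(epochs=7, constraint_enabled=False)
        assert mlm.epochs == 7 and not mlm.constraint_enabled
        with pytest.raises(ValueError):
            mlm.set_params(bogus=1)

    def test_fit_transform_shapes(self, rng):
        seqs = [random_cds(rng, 12) for _ in range(16)]
        mlm = SynCodonMLM(hidden_size=16, intermediate_size=32, num_layers=1,
                          num_heads=2, max_positions=32, num_token_types=2,
                          epochs=1, batch_size=8, seed=0)
        emb = mlm.fit(seqs).transform(seqs)
        assert emb.shape == (16, 16)
        assert np.isfinite(emb).all()
        # transform is deterministic once fitted
        assert np.array_equal(emb, mlm.transform(seqs))

    def test_transform_before_fit_rejected(self):
        with pytest.raises(RuntimeError):
            SynCodonMLM().transform(["ATGTAA"])
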