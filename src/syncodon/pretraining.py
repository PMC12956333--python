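"""Synonym-constrained masked-language-model pretraining.

The objective: mask a fraction of codon tokens, add the constraint-matrix
row of each masked position's TRUE codon to the model's logits (0 over the
synonymous family, -inf elsewhere), take the softmax over the full
vocabulary — the -inf entries carry exactly zero probability — and average
the negative log likelihood of the true codons over the |M| masked
positions. The constraint removes amino-acid identity from the prediction
problem: the model is graded only on choosing *which synonymous codon*,
never on recovering the protein.

Ablation switches: ``constraint_enabled`` turns the additive mask off
(plain MLM over all 69 tokens), and ``token_type_mode`` selects
species-level ids, coarse taxon ids, or no type signal at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .codon_core import (
    CodonTokenizer,
    GeneticCode,
    SynonymConstraintMatrix,
    build_synonym_mask,
    standard_code,
)
from . import model as M

__all__ = [
    "MaskedBatch",
    "TrainConfig",
    "mask_batch",
    "constrain_logits",
    "mlm_loss",
    "masked_accuracy",
    "lr_at_step",
    "uniform_constraint_baseline",
    "AdamW",
    "train",
    "evaluate_masked",
    "SynCodonMLM",
]

IGNORE = -100  # label sentinel at unmasked positions


@dataclass
class MaskedBatch:
    input_ids: np.ndarray      # (B, L) with masked positions -> [MASK] id
    token_type_ids: np.ndarray  # (B, L)
    labels: np.ndarray          # (B, L); IGNORE everywhere except masked
    mask: np.ndarray            # (B, L) bool, the set M
    valid: np.ndarray           # (B, L) bool, False at padding

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


@dataclass
class TrainConfig:
    mask_probability: float = 0.15
    max_lr: float = 2e-4
    warmup_fraction: float = 0.10
    weight_decay: float = 0.01
    dropout: float = 0.1
    batch_size: int = 64
    epochs: int = 30
    seed: int = 0
    constraint_enabled: bool = True
    token_type_mode: str = "species-500"  # or "taxon-9", "none"
    mask_style: str = "mask-only"  # or "bert-80-10-10"

    def __post_init__(self):
        if not 0.0 < self.mask_probability < 1.0:
            raise ValueError("mask_probability must be in (0, 1)")
        if not 0.0 < self.warmup_fraction < 1.0:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.token_type_mode not in ("species-500", "taxon-9", "none"):
            raise ValueError(f"unknown token_type_mode {self.token_type_mode!r}")
        if self.mask_style not in ("mask-only", "bert-80-10-10"):
            raise ValueError(f"unknown mask_style {self.mask_style!r}")


def mask_batch(
    token_ids: np.ndarray,
    mask_probability: float,
    rng: np.random.Generator,
    tokenizer: CodonTokenizer,
    token_type_ids: Optional[np.ndarray] = None,
    valid: Optional[np.ndarray] = None,
    mask_style: str = "mask-only",
) -> MaskedBatch:
    """Independently select codon positions with ``mask_probability``.

    Special tokens (start/end/pad) are never selected. Default corruption is
    pure mask-token replacement; the BERT-style 80/10/10 variant is offered
    behind ``mask_style`` (10% random codon, 10% kept).
    """
    ids = np.atleast_2d(np.asarray(token_ids)).copy()
    B, L = ids.shape
    if valid is None:
        valid = ids != tokenizer.pad_id
    valid = np.atleast_2d(np.asarray(valid, dtype=bool))
    if token_type_ids is None:
        token_type_ids = np.zeros_like(ids)
    is_codon = (ids >= 0) & (ids < 64) & valid
    selected = is_codon & (rng.random((B, L)) < mask_probability)
    labels = np.full_like(ids, IGNORE)
    labels[selected] = ids[selected]
    if mask_style == "mask-only":
        ids[selected] = tokenizer.mask_id
    else:
        u = rng.random((B, L))
        to_mask = selected & (u < 0.8)
        to_rand = selected & (u >= 0.8) & (u < 0.9)
        ids[to_mask] = tokenizer.mask_id
        ids[to_rand] = rng.integers(0, 64, size=int(to_rand.sum()))
    return MaskedBatch(
        input_ids=ids,
        token_type_ids=np.atleast_2d(np.asarray(token_type_ids)),
        labels=labels,
        mask=selected,
        valid=valid,
    )


def constrain_logits(
    logits: np.ndarray,
    labels: np.ndarray,
    mask_matrix: SynonymConstraintMatrix,
) -> np.ndarray:
    """Add the true codon's constraint row to each masked position's logits."""
    logits = np.asarray(logits, dtype=np.float64)
    labels = np.asarray(labels)
    if logits.shape[:-1] != labels.shape:
        raise ValueError("logits and labels shapes do not align")
    if (labels >= 64).any() or (labels < 0).any():
        raise ValueError("labels must be codon token ids (special tokens are never targets)")
    return logits + mask_matrix.mask[labels]


def _log_softmax(z: np.ndarray) -> np.ndarray:
    zmax = np.max(z, axis=-1, keepdims=True)
    s = z - zmax
    # exp(-inf) underflows to exactly 0, so excluded tokens carry zero mass
    with np.errstate(invalid="ignore"):
        lse = np.log(np.exp(s).sum(axis=-1, keepdims=True))
    return s - lse


def mlm_loss(z: np.ndarray, labels: np.ndarray) -> float:
    """Average negative log likelihood of the true codons over masked positions."""
    z = np.asarray(z, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("|M| = 0: no masked positions")
    logp = _log_softmax(z)
    rows = np.arange(labels.size)
    return float(-logp.reshape(labels.size, -1)[rows, labels.ravel()].mean())


def masked_accuracy(z: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of masked positions whose argmax logit is the true codon.

    Ties resolve to the lowest token id (numpy argmax convention)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("|M| = 0: no masked positions")
    pred = np.argmax(np.asarray(z).reshape(labels.size, -1), axis=-1)
    return float((pred == labels.ravel()).mean())


def lr_at_step(
    step: int, total_steps: int, max_lr: float = 2e-4, warmup_fraction: float = 0.10
) -> float:
    """Linear warmup from 0 to ``max_lr``, then cosine decay back to 0."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    step = float(np.clip(step, 0, total_steps))
    warm = warmup_fraction * total_steps
    if step <= warm:
        return max_lr * step / warm
    progress = (step - warm) / (total_steps - warm)
    return max_lr * 0.5 * (1.0 + math.cos(math.pi * progress))


def uniform_constraint_baseline(
    codon_counts: np.ndarray, code: Optional[GeneticCode] = None
) -> float:
    """Expected constrained accuracy of an uninformed (uniform-logit) model.

    With uniform logits the constrained softmax is uniform over the true
    codon's family, so accuracy at a masked codon of degeneracy n_i is
    1/n_i; average with the corpus's codon composition as weights.
    """
    code = code or standard_code()
    counts = np.asarray(codon_counts, dtype=np.float64)
    if counts.shape != (64,) or counts.sum() <= 0:
        raise ValueError("need a positive 64-vector of codon counts")
    inv_n = np.array([1.0 / code.degeneracy[c] for c in code.codons])
    return float((counts * inv_n).sum() / counts.sum())


class AdamW:
    """Decoupled-weight-decay Adam over a named-parameter dict.

    Decay is applied only to weight matrices (2-D arrays); biases, layer-norm
    gains/offsets and other 1-D parameters are exempt, the usual convention.
    """

    def __init__(self, params: Dict[str, np.ndarray], weight_decay: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1 ** self.t
        c2 = 1.0 - b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            update = (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
            if p.ndim >= 2 and self.weight_decay > 0:
                update = update + self.weight_decay * p
            p -= lr * update


def _pad_batch(
    seqs: Sequence[np.ndarray], type_ids: Sequence[int], pad_id: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = max(len(s) for s in seqs)
    B = len(seqs)
    ids = np.full((B, L), pad_id, dtype=np.int64)
    valid = np.zeros((B, L), dtype=bool)
    tids = np.zeros((B, L), dtype=np.int64)
    for i, (s, t) in enumerate(zip(seqs, type_ids)):
        ids[i, : len(s)] = s
        valid[i, : len(s)] = True
        tids[i, :] = t
    return ids, tids, valid


def _masked_forward(
    state: M.ModelState,
    batch: MaskedBatch,
    mask_matrix: Optional[SynonymConstraintMatrix],
    train: bool,
    rng: Optional[np.random.Generator],
):
    """Forward pass + constrained softmax at the masked positions only."""
    h, cache = M.forward_with_cache(
        state, batch.input_ids, batch.token_type_ids, batch.valid,
        train=train, rng=rng,
    )
    rows = np.nonzero(batch.mask)
    hm = h[rows]                                   # (N, H)
    labels = batch.labels[rows]                    # (N,)
    logits = hm @ state.params["E"].T + state.params["head_b"]
    z = constrain_logits(logits, labels, mask_matrix) if mask_matrix else logits
    return h, cache, rows, hm, labels, z


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    s = z - z.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def train(
    state: M.ModelState,
    sequences: Sequence[np.ndarray],
    type_ids: Sequence[int],
    config: TrainConfig,
    tokenizer: CodonTokenizer,
    mask_matrix: Optional[SynonymConstraintMatrix] = None,
) -> List[Dict[str, float]]:
    """AdamW training loop; returns the per-step metrics log.

    ``sequences`` are encoded token-id arrays (start/codons/end); batches are
    padded to their longest member. When the constraint is enabled, softmax
    mass outside each masked codon's family is exactly zero, so gradients at
    those logit entries are exactly zero as well.
    """
    if len(sequences) == 0:
        raise ValueError("empty corpus")
    if config.constraint_enabled and mask_matrix is None:
        mask_matrix = build_synonym_mask(tokenizer)
    mm = mask_matrix if config.constraint_enabled else None
    if config.token_type_mode == "none":
        type_ids = [0] * len(sequences)
    rng = np.random.default_rng(config.seed)
    opt = AdamW(state.params, weight_decay=config.weight_decay)
    n = len(sequences)
    steps_per_epoch = math.ceil(n / config.batch_size)
    total_steps = steps_per_epoch * config.epochs
    log: List[Dict[str, float]] = []
    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for b0 in range(0, n, config.batch_size):
            idx = order[b0 : b0 + config.batch_size]
            ids, tids, valid = _pad_batch(
                [sequences[i] for i in idx], [type_ids[i] for i in idx],
                tokenizer.pad_id,
            )
            batch = mask_batch(
                ids, config.mask_probability, rng, tokenizer,
                token_type_ids=tids, valid=valid, mask_style=config.mask_style,
            )
            step += 1
            if batch.n_masked == 0:
                continue
            h, cache, rows, hm, labels, z = _masked_forward(
                state, batch, mm, train=True, rng=rng,
            )
            p = _softmax_rows(z)
            N = labels.size
            loss = float(-np.log(p[np.arange(N), labels]).mean())
            acc = masked_accuracy(z, labels)
            dlogits = p.copy()
            dlogits[np.arange(N), labels] -= 1.0
            dlogits /= N
            dh = np.zeros_like(h)
            dh[rows] = dlogits @ state.params["E"]
            grads = M.backward(state, cache, dh)
            grads["E"] += dlogits.T @ hm
            grads["head_b"] += dlogits.sum(axis=0)
            lr = lr_at_step(step, total_steps, config.max_lr, config.warmup_fraction)
            opt.step(grads, lr)
            log.append(dict(step=step, loss=loss, masked_accuracy=acc, lr=lr))
    return log


def evaluate_masked(
    state: M.ModelState,
    sequences: Sequence[np.ndarray],
    type_ids: Sequence[int],
    tokenizer: CodonTokenizer,
    mask_matrix: Optional[SynonymConstraintMatrix] = None,
    mask_probability: float = 0.15,
    seed: int = 0,
    batch_size: int = 64,
) -> Tuple[float, float]:
    """(loss, masked accuracy) under a fixed masking RNG, dropout off.

    Accuracy is computed with the constraint applied when ``mask_matrix`` is
    given, matching the training objective."""
    rng = np.random.default_rng(seed)
    losses, correct, total = [], 0, 0
    for b0 in range(0, len(sequences), batch_size):
        seqs = sequences[b0 : b0 + batch_size]
        tids_b = type_ids[b0 : b0 + batch_size]
        ids, tids, valid = _pad_batch(seqs, tids_b, tokenizer.pad_id)
        batch = mask_batch(ids, mask_probability, rng, tokenizer,
                           token_type_ids=tids, valid=valid)
        if batch.n_masked == 0:
            continue
        _, _, _, _, labels, z = _masked_forward(
            state, batch, mask_matrix, train=False, rng=None,
        )
        losses.append(mlm_loss(z, labels) * labels.size)
        pred = np.argmax(z, axis=-1)
        correct += int((pred == labels).sum())
        total += labels.size
    if total == 0:
        raise ValueError("no masked positions in evaluation corpus")
    return sum(losses) / total, correct / total


class SynCodonMLM:
    """sklearn-style estimator: fit = constrained MLM pretraining on CDS,
    transform = frozen mean-pooled embeddings.

    Parameters mirror :class:`~syncodon.model.EncoderConfig` and
    :class:`TrainConfig`; all are plain constructor arguments so the
    estimator composes with sklearn model selection.

    Attributes (after fit)
    ----------------------
    state_ : ModelState — trained parameters
    tokenizer_ : CodonTokenizer
    mask_matrix_ : SynonymConstraintMatrix
    history_ : list of per-step dicts (step, loss, masked_accuracy, lr)
    """

    def __init__(
        self,
        hidden_size: int = 64,
        intermediate_size: int = 256,
        num_layers: int = 2,
        num_heads: int = 4,
        max_positions: int = 256,
        num_token_types: int = 501,
        relative_position_buckets: int = 32,
        mask_probability: float = 0.15,
        max_lr: float = 2e-4,
        warmup_fraction: float = 0.10,
        weight_decay: float = 0.01,
        dropout: float = 0.1,
        batch_size: int = 64,
        epochs: int = 30,
        constraint_enabled: bool = True,
        token_type_mode: str = "species-500",
        seed: int = 0,
        dtype: str = "float32",
    ):
        self.hidden_size = hidden_size
        self.intermediate_size = intermediate_size
        self.num_layers = num_layers
        self.num_heads = num_heads
        self.max_positions = max_positions
        self.num_token_types = num_token_types
        self.relative_position_buckets = relative_position_buckets
        self.mask_probability = mask_probability
        self.max_lr = max_lr
        self.warmup_fraction = warmup_fraction
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.batch_size = batch_size
        self.epochs = epochs
        self.constraint_enabled = constraint_enabled
        self.token_type_mode = token_type_mode
        self.seed = seed
        self.dtype = dtype

    # minimal get/set_params so sklearn clone/model-selection work without
    # inheriting BaseEstimator's full validation machinery
    def get_params(self, deep: bool = True) -> Dict:
        return {k: getattr(self, k) for k in self.__init__.__code__.co_varnames[1:]
                if hasattr(self, k)}

    def set_params(self, **kwargs):
        for k, v in kwargs.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def _encoder_config(self) -> M.EncoderConfig:
        return M.EncoderConfig(
            hidden_size=self.hidden_size,
            intermediate_size=self.intermediate_size,
            num_layers=self.num_layers,
            num_heads=self.num_heads,
            max_positions=self.max_positions,
            num_token_types=self.num_token_types,
            dropout=self.dropout,
            relative_position_buckets=self.relative_position_buckets,
            dtype=self.dtype,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            mask_probability=self.mask_probability,
            max_lr=self.max_lr,
            warmup_fraction=self.warmup_fraction,
            weight_decay=self.weight_decay,
            dropout=self.dropout,
            batch_size=self.batch_size,
            epochs=self.epochs,
            seed=self.seed,
            constraint_enabled=self.constraint_enabled,
            token_type_mode=self.token_type_mode,
        )

    def fit(self, sequences: Sequence[str], type_ids: Optional[Sequence[int]] = None):
        """Pretrain on CDS strings (validated/tokenized internally)."""
        self.tokenizer_ = CodonTokenizer(max_positions=self.max_positions)
        self.mask_matrix_ = build_synonym_mask(self.tokenizer_)
        encoded = [self.tokenizer_.encode(s) for s in sequences]
        if type_ids is None:
            type_ids = [0] * len(encoded)
        self.state_ = M.init_model(self._encoder_config(), seed=self.seed)
        self.history_ = train(
            self.state_, encoded, list(type_ids), self._train_config(),
            self.tokenizer_, self.mask_matrix_,
        )
        return self

    def transform(
        self, sequences: Sequence[str], type_ids: Optional[Sequence[int]] = None,
        batch_size: int = 64,
    ) -> np.ndarray:
        """Frozen mean-pooled final-hidden embeddings, one row per CDS."""
        if not hasattr(self, "state_"):
            raise RuntimeError("SynCodonMLM is not fitted")
        encoded = [self.tokenizer_.encode(s) for s in sequences]
        if type_ids is None:
            type_ids = [0] * len(encoded)
        out = []
        for b0 in range(0, len(encoded), batch_size):
            seqs = encoded[b0 : b0 + batch_size]
            tids_b = list(type_ids[b0 : b0 + batch_size])
            ids, tids, valid = _pad_batch(seqs, tids_b, self.tokenizer_.pad_id)
            h = M.forward_hidden(self.state_, ids, tids, valid)
            out.append(M.mean_pool(h, valid))
        return np.vstack(out)

    def fit_transform(self, sequences, type_ids=None):
        return self.fit(sequences, type_ids).transform(sequences, type_ids)

    def score(self, sequences: Sequence[str], type_ids=None, seed: int = 0) -> float:
        """Constrained masked accuracy on held-out CDS."""
        encoded = [self.tokenizer_.encode(s) for s in sequences]
        if type_ids is None:
            type_ids = [0] * len(encoded)
        mm = self.mask_matrix_ if self.constraint_enabled else None
        _, acc = evaluate_masked(
            self.state_, encoded, list(type_ids), self.tokenizer_, mm,
            mask_probability=self.mask_probability, seed=seed,
        )
        return acc
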