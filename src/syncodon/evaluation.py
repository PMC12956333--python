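"""Frozen-embedding benchmarking: linear probes, repeated CV, paired tests.

Protocol: fitness targets are scaled once on the full dataset (min-max by
default, Yeo-Johnson for heavily skewed targets); mean-pooled embeddings of
each CDS feed a single affine regression head trained by gradient descent
on MSE with both L1 and L2 penalties; five-fold cross-validation is
repeated over many seeds, per-seed fold-averaged R² values form the paired
samples for two-sided paired t-tests between models. The
mutation-sensitivity scan fits probes on unmutated training folds and
scores them on synonymously mutated test folds at increasing mutation
levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import r2_score
from sklearn.model_selection import KFold
from sklearn.preprocessing import PowerTransformer

from .synthetic import mutate_synonymously

__all__ = [
    "ProbeResult",
    "DegenerateInputError",
    "scale_targets",
    "EmbeddingProbe",
    "fit_probe",
    "repeated_cv",
    "paired_t_test",
    "mutation_sensitivity_scan",
]


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined (e.g. zero-variance differences)."""


def scale_targets(y: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Scale fitness targets: 'minmax' to [0, 1] or 'yeo-johnson' (then z-scored)."""
    y = np.asarray(y, dtype=np.float64).reshape(-1, 1)
    if y.shape[0] < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(y) == 0:
        raise ValueError("constant targets cannot be scaled")
    if method == "minmax":
        # direct form (y - min)/(max - min): endpoints are exactly 0 and 1
        y = y.ravel()
        return (y - y.min()) / (y.max() - y.min())
    if method == "yeo-johnson":
        return PowerTransformer(method="yeo-johnson", standardize=True) \
            .fit_transform(y).ravel()
    raise ValueError(f"unknown scaling method {method!r}")


class EmbeddingProbe(BaseEstimator, RegressorMixin):
    """Affine regression head trained by Adam on MSE + l1|w| + l2|w|^2.

    Matches the benchmarking protocol: batch size 16, 100 epochs by default,
    with both penalties active. Deterministic given ``seed``.
    """

    def __init__(self, l1: float = 1e-4, l2: float = 1e-4, epochs: int = 100,
                 batch_size: int = 16, lr: float = 1e-3, seed: int = 0):
        self.l1 = l1
        self.l2 = l2
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X and y dimensions do not match")
        n, d = X.shape
        rng = np.random.default_rng(self.seed)
        w = np.zeros(d)
        b = float(y.mean())  # start at the mean predictor (R² = 0 baseline)
        mw, vw = np.zeros(d), np.zeros(d)
        mb = vb = 0.0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            for b0 in range(0, n, self.batch_size):
                idx = order[b0 : b0 + self.batch_size]
                Xb, yb = X[idx], y[idx]
                r = Xb @ w + b - yb
                gw = 2.0 * Xb.T @ r / len(idx) + self.l1 * np.sign(w) + 2.0 * self.l2 * w
                gb = 2.0 * r.mean()
                t += 1
                mw = beta1 * mw + (1 - beta1) * gw
                vw = beta2 * vw + (1 - beta2) * gw * gw
                mb = beta1 * mb + (1 - beta1) * gb
                vb = beta2 * vb + (1 - beta2) * gb * gb
                c1, c2 = 1 - beta1 ** t, 1 - beta2 ** t
                w -= self.lr * (mw / c1) / (np.sqrt(vw / c2) + eps)
                b -= self.lr * (mb / c1) / (math.sqrt(vb / c2) + eps)
        self.coef_ = w
        self.intercept_ = b
        return self

    def predict(self, X):
        return np.asarray(X, dtype=np.float64) @ self.coef_ + self.intercept_


def fit_probe(
    embeddings, y, l1: float = 1e-4, l2: float = 1e-4, epochs: int = 100,
    batch_size: int = 16, seed: int = 0,
) -> EmbeddingProbe:
    """Functional wrapper over :class:`EmbeddingProbe`."""
    return EmbeddingProbe(l1=l1, l2=l2, epochs=epochs, batch_size=batch_size,
                          seed=seed).fit(embeddings, y)


@dataclass
class ProbeResult:
    """Per-(seed, fold) R² records and their aggregates."""

    model: str = ""
    dataset: str = ""
    per_fold: Dict[int, List[float]] = field(default_factory=dict)  # seed -> 5 R²

    @property
    def per_seed(self) -> Dict[int, float]:
        return {s: float(np.mean(v)) for s, v in self.per_fold.items()}

    @property
    def per_seed_array(self) -> np.ndarray:
        return np.array([self.per_seed[s] for s in sorted(self.per_fold)])

    @property
    def mean_r2(self) -> float:
        return float(self.per_seed_array.mean())


def repeated_cv(
    embeddings: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seeds: Sequence[int] = tuple(range(30)),
    probe_kwargs: Optional[dict] = None,
    model: str = "",
    dataset: str = "",
) -> ProbeResult:
    """Repeated k-fold CV of the linear probe; R² on each held-out fold.

    R² = 1 - SS_res/SS_tot with SS_tot around the held-out fold's own mean,
    so the trivial mean predictor scores 0 on its own fold.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if len(y) < folds:
        raise ValueError("fewer samples than folds")
    kw = probe_kwargs or {}
    result = ProbeResult(model=model, dataset=dataset)
    for seed in seeds:
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(seed))
        r2s = []
        for train_idx, test_idx in kf.split(X):
            probe = EmbeddingProbe(seed=int(seed), **kw).fit(X[train_idx], y[train_idx])
            r2s.append(r2_score(y[test_idx], probe.predict(X[test_idx])))
        result.per_fold[int(seed)] = r2s
    return result


def paired_t_test(r2_a: Sequence[float], r2_b: Sequence[float]):
    """Two-sided paired t-test on per-seed R² values (pairing by seed).

    Returns (t, p) with t = mean(d) / (sd(d)/sqrt(n)), sd the n-1 sample
    standard deviation, and p from the Student t distribution with n-1 df.
    """
    a = np.asarray(r2_a, dtype=np.float64)
    b = np.asarray(r2_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero-variance differences: t undefined")
    t = d.mean() / (sd / math.sqrt(d.size))
    p = 2.0 * stats.t.sf(abs(t), df=d.size - 1)
    return float(t), float(p)


def mutation_sensitivity_scan(
    encoder,
    sequences: Sequence[str],
    y: np.ndarray,
    levels: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    folds: int = 5,
    seeds: Sequence[int] = tuple(range(10)),
    batch_size: int = 64,
    probe_kwargs: Optional[dict] = None,
    rng: Optional[np.random.Generator] = None,
    type_ids: Optional[Sequence[int]] = None,
) -> Dict[float, float]:
    """Probe R² as a function of synonymous mutation level in the test folds.

    Probes are fitted on embeddings of *unmutated* training folds (larger
    batch size, default 64); at each level the held-out sequences are
    synonymously mutated before embedding, and the fold R² is recorded. The
    returned dict includes level 0.0 (the unmutated baseline, identical to
    plain repeated CV).
    """
    if not hasattr(encoder, "transform"):
        raise ValueError("encoder must expose .transform(sequences) -> embeddings")
    y = np.asarray(y, dtype=np.float64).ravel()
    rng = rng or np.random.default_rng(0)
    kw = dict(probe_kwargs or {})
    kw.setdefault("batch_size", batch_size)
    seqs = list(sequences)
    all_levels = [0.0] + [float(l) for l in levels]
    # mutate each sequence once per level so every fold sees the same variant
    mutated: Dict[float, List[str]] = {0.0: seqs}
    for level in all_levels[1:]:
        mutated[level] = [mutate_synonymously(s, level, rng) for s in seqs]
    emb: Dict[float, np.ndarray] = {
        level: np.asarray(encoder.transform(mutated[level], type_ids))
        for level in all_levels
    }
    sums = {level: 0.0 for level in all_levels}
    count = 0
    for seed in seeds:
        kf = KFold(n_splits=folds, shuffle=True, random_state=int(seed))
        for train_idx, test_idx in kf.split(emb[0.0]):
            probe = EmbeddingProbe(seed=int(seed), **kw).fit(
                emb[0.0][train_idx], y[train_idx]
            )
            count += 1
            for level in all_levels:
                pred = probe.predict(emb[level][test_idx])
                sums[level] += r2_score(y[test_idx], pred)
    return {level: sums[level] / count for level in all_levels}
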