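"""Geometry of the learned codon embeddings.

A constrained-trained model is expected to organize its 64 codon input
embeddings by nucleotide-level features — the wobble (third) base and the
suffix dinucleotide — rather than by amino-acid identity, because the
training objective never rewards recovering the amino acid. The tools here
make that claim testable: label the codons by wobble base / suffix /
amino acid, test group separation with PERMANOVA on the full-dimensional
embedding space (Euclidean distances; a permutation null), and project to
2-D (t-SNE or PCA) for visualization only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .codon_core import GeneticCode, standard_code, codon_features
from .model import ModelState

__all__ = [
    "PermanovaResult",
    "extract_codon_embeddings",
    "permanova",
    "grouping_labels",
    "project_2d",
    "perplexity_sweep",
    "plot_projection",
]


def extract_codon_embeddings(state: ModelState, tokenizer) -> np.ndarray:
    """Input-embedding rows for the 64 codon tokens (no contextual pass).

    By weight tying these are simultaneously the LM-head projection rows.
    """
    ids = [tokenizer.token_to_id[c] for c in tokenizer.codons]
    return state.params["E"][ids].copy()


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    group_sizes: Dict[str, int]


def _pairwise_sq(points: np.ndarray) -> np.ndarray:
    sq = (points * points).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * points @ points.T
    np.fill_diagonal(d2, 0.0)
    return np.maximum(d2, 0.0)


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    n = d2.shape[0]
    g = len(groups)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for grp in groups:
        idx = np.nonzero(labels == grp)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    ss_between = ss_total - ss_within
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    points: np.ndarray,
    labels: Sequence,
    n_permutations: int = 999,
    seed: int = 0,
    is_distance_matrix: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on Euclidean distances.

    pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)) from pairwise squared
    distances; the p-value is (1 + #{permuted F >= observed F}) /
    (1 + n_permutations) under seeded label permutation. Every group must
    have at least 2 members.
    """
    labels = np.asarray(labels)
    pts = np.asarray(points, dtype=np.float64)
    if is_distance_matrix:
        if pts.shape[0] != pts.shape[1]:
            raise ValueError("distance matrix must be square")
        d2 = pts ** 2
    else:
        d2 = _pairwise_sq(pts)
    n = d2.shape[0]
    if labels.shape != (n,):
        raise ValueError("labels length must match number of points")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    f_obs = _pseudo_f(d2, labels, groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if _pseudo_f(d2, lab, groups) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        p_value=float(p),
        n_permutations=n_permutations,
        group_sizes={str(g): int(c) for g, c in zip(groups, counts)},
    )


def grouping_labels(
    codons: Sequence[str],
    scheme: str,
    code: Optional[GeneticCode] = None,
    drop_singletons: bool = False,
) -> List[str]:
    """Group labels per codon: 'wobble' (4x16), 'suffix' (16x4) or 'amino_acid'.

    With ``drop_singletons`` amino-acid labels for single-member groups are
    replaced by None so callers can exclude them (PERMANOVA requires groups
    of at least 2; ATG and TGG form singleton groups under the standard code).
    """
    code = code or standard_code()
    if scheme == "wobble":
        return [codon_features(c)[0] for c in codons]
    if scheme == "suffix":
        return [codon_features(c)[1] for c in codons]
    if scheme == "amino_acid":
        labels = [code.translate(c) for c in codons]
        if drop_singletons:
            from collections import Counter

            sizes = Counter(labels)
            return [l if sizes[l] >= 2 else None for l in labels]
        return labels
    raise ValueError(f"unknown grouping scheme {scheme!r}")


def project_2d(
    points: np.ndarray,
    method: str = "tsne",
    perplexity: float = 30.0,
    seed: int = 0,
) -> np.ndarray:
    """2-D projection for visualization (never for significance testing)."""
    X = np.asarray(points, dtype=np.float64)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if method == "pca":
        return PCA(n_components=2, svd_solver="full").fit_transform(X)
    if method == "tsne":
        if perplexity >= X.shape[0]:
            raise ValueError("perplexity must be smaller than the number of points")
        return TSNE(
            n_components=2, perplexity=perplexity, random_state=seed, init="pca"
        ).fit_transform(X)
    raise ValueError(f"unknown projection method {method!r}")


def plot_projection(coords, labels, path, title: str = "", annotate=None):
    """Scatter of a 2-D projection colored by group label; saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4.2))
    for grp in np.unique(labels):
        idx = labels == grp
        ax.scatter(coords[idx, 0], coords[idx, 1], s=28, label=str(grp),
                   edgecolor="none", alpha=0.85)
    if annotate is not None:
        for (x, y), text in zip(coords, annotate):
            ax.annotate(text, (x, y), fontsize=5, alpha=0.6)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, ncols=2, frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def perplexity_sweep(
    points: np.ndarray,
    labels: Sequence,
    perplexities: Sequence[float] = (5, 10, 20, 30),
    seed: int = 0,
) -> Dict[float, float]:
    """Silhouette of the label grouping in the t-SNE plane per perplexity.

    A stability harness for the projection: consistent positive silhouettes
    across perplexities indicate the grouping is not a projection artifact.
    """
    labels = np.asarray(labels)
    out = {}
    for perp in perplexities:
        coords = project_2d(points, method="tsne", perplexity=perp, seed=seed)
        out[float(perp)] = float(silhouette_score(coords, labels))
    return out
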