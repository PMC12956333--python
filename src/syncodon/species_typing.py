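"""Species-aware token typing from relative synonymous codon usage (RSCU).

Each species gets a token-type id by (1) computing its RSCU vector over the
59 codons that belong to degenerate (size >= 2), non-stop families,
(2) allocating a budget of cluster ids across taxon groups in proportion to
their CDS counts, and (3) k-means clustering the species of each taxon in
RSCU space. One extra id is reserved for "unknown" so the model can be used
on species absent from the clustering.

RSCU follows the classical convention: for codon j in a family of size n_i
with family total T_i, RSCU_ij = n_i * X_ij / T_i — 1 means unbiased usage,
n_i means all of the family's mass on that codon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .codon_core import GeneticCode, standard_code, STOP_SYMBOL
from .curation import CDSRecord

__all__ = [
    "RSCUVector",
    "SpeciesTypeModel",
    "SpeciesClusterTyper",
    "codon_counts",
    "rscu_vector",
    "rscu_codon_order",
    "allocate_type_ids",
    "cluster_species",
    "project_type_embeddings",
]


def rscu_codon_order(code: Optional[GeneticCode] = None) -> List[str]:
    """The 59 codons carried by RSCU vectors, in fixed lexicographic order.

    Excluded: singleton families (ATG, TGG under the standard code) — their
    RSCU is identically 1 — and the stop codons.
    """
    code = code or standard_code()
    return [
        c
        for c in code.codons
        if code.degeneracy[c] >= 2 and code.codon_to_aa[c] != STOP_SYMBOL
    ]


def codon_counts(records: Sequence[CDSRecord], code: Optional[GeneticCode] = None) -> np.ndarray:
    """64-vector of codon counts over all CDS of one species."""
    if len(records) == 0:
        raise ValueError("empty record set")
    code = code or standard_code()
    index = {c: i for i, c in enumerate(code.codons)}
    counts = np.zeros(64, dtype=np.int64)
    for r in records:
        s = r.sequence.upper()
        for i in range(0, len(s) - len(s) % 3, 3):
            counts[index[s[i : i + 3]]] += 1
    return counts


@dataclass
class RSCUVector:
    species: str
    values: np.ndarray  # length 59, order = rscu_codon_order()
    total_codons: int
    taxon_group: str = ""


def rscu_vector(
    counts: np.ndarray,
    code: Optional[GeneticCode] = None,
    species: str = "",
    taxon_group: str = "",
) -> RSCUVector:
    """RSCU over degenerate non-stop codons; zero-count families filled with 1.

    The neutral fill keeps vectors well-defined for sparsely sampled species
    and is exactly the no-bias value, so it cannot fake a usage signal.
    """
    code = code or standard_code()
    counts = np.asarray(counts)
    if counts.shape != (64,):
        raise ValueError("counts must be a 64-vector")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    index = {c: i for i, c in enumerate(code.codons)}
    order = rscu_codon_order(code)
    values = np.empty(len(order), dtype=np.float64)
    for k, codon in enumerate(order):
        family = sorted(code.synonymous_set(codon))
        total = sum(counts[index[f]] for f in family)
        if total == 0:
            values[k] = 1.0
        else:
            values[k] = len(family) * counts[index[codon]] / total
    return RSCUVector(
        species=species,
        values=values,
        total_codons=int(counts.sum()),
        taxon_group=taxon_group,
    )


def allocate_type_ids(
    cds_counts_per_taxon: Mapping[str, int], total_cluster_ids: int = 500
) -> Dict[str, int]:
    """Split the cluster-id budget across taxa proportionally to CDS counts.

    Largest-remainder apportionment with a floor of one id per taxon;
    allocations always sum to ``total_cluster_ids``.
    """
    taxa = list(cds_counts_per_taxon)
    if not taxa:
        raise ValueError("no taxa")
    if any(cds_counts_per_taxon[t] <= 0 for t in taxa):
        raise ValueError("CDS counts must be positive")
    if total_cluster_ids < len(taxa):
        raise ValueError("fewer cluster ids than taxa")
    counts = np.array([cds_counts_per_taxon[t] for t in taxa], dtype=np.float64)
    quota = total_cluster_ids * counts / counts.sum()
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    # hand out the leftover ids to the largest remainders (ties: input order)
    leftover = total_cluster_ids - int(alloc.sum())
    for i in sorted(range(len(taxa)), key=lambda i: (-remainder[i], i))[:leftover]:
        alloc[i] += 1
    # enforce the floor, taking from the currently largest allocation
    for i in range(len(taxa)):
        while alloc[i] < 1:
            j = int(np.argmax(alloc))
            alloc[j] -= 1
            alloc[i] += 1
    return {t: int(a) for t, a in zip(taxa, alloc)}


@dataclass
class SpeciesTypeModel:
    """Fitted species -> token-type-id assignment."""

    species_to_type_id: Dict[str, int]
    cluster_centroids: Dict[str, np.ndarray]  # per taxon, shape (k, 59)
    taxon_id_offset: Dict[str, int]
    unknown_id: int
    total_ids: int
    allocation: Dict[str, int] = field(default_factory=dict)

    def lookup(self, species: str) -> int:
        return self.species_to_type_id.get(species, self.unknown_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "species_to_type_id": self.species_to_type_id,
                "cluster_centroids": {
                    t: c.tolist() for t, c in self.cluster_centroids.items()
                },
                "taxon_id_offset": self.taxon_id_offset,
                "unknown_id": self.unknown_id,
                "total_ids": self.total_ids,
                "allocation": self.allocation,
            },
            indent=1,
        )


class SpeciesClusterTyper(BaseEstimator):
    """Assign token-type ids to species by per-taxon k-means on RSCU vectors.

    Parameters
    ----------
    n_cluster_ids : total id budget shared by all taxa (default 500; with the
        reserved unknown id the embedding table holds 501 rows).
    seed : RNG seed for k-means (k-means++ init, 10 restarts).

    After ``fit``, ``model_`` holds the :class:`SpeciesTypeModel`;
    ``predict`` maps species names to ids, returning the unknown id for
    species never seen.
    """

    def __init__(self, n_cluster_ids: int = 500, seed: int = 0):
        self.n_cluster_ids = n_cluster_ids
        self.seed = seed

    def fit(self, rscu_vectors: Sequence[RSCUVector], y=None):
        if len(rscu_vectors) == 0:
            raise ValueError("no RSCU vectors supplied")
        by_taxon: Dict[str, List[RSCUVector]] = {}
        for v in rscu_vectors:
            by_taxon.setdefault(v.taxon_group, []).append(v)
        # species-count proxy for CDS counts when only vectors are given:
        # weight taxa by their total codon mass
        weights = {
            t: max(1, sum(v.total_codons for v in vs)) for t, vs in by_taxon.items()
        }
        alloc = allocate_type_ids(weights, self.n_cluster_ids)
        species_to_id: Dict[str, int] = {}
        centroids: Dict[str, np.ndarray] = {}
        offsets: Dict[str, int] = {}
        next_id = 0
        for taxon in sorted(by_taxon):
            vs = sorted(by_taxon[taxon], key=lambda v: v.species)
            k = min(alloc[taxon], len(vs))
            X = np.stack([v.values for v in vs])
            km = KMeans(n_clusters=k, n_init=10, random_state=self.seed)
            labels = km.fit_predict(X)
            offsets[taxon] = next_id
            centroids[taxon] = km.cluster_centers_
            for v, lab in zip(vs, labels):
                species_to_id[v.species] = next_id + int(lab)
            next_id += k
        self.model_ = SpeciesTypeModel(
            species_to_type_id=species_to_id,
            cluster_centroids=centroids,
            taxon_id_offset=offsets,
            unknown_id=next_id,
            total_ids=next_id + 1,
            allocation=alloc,
        )
        return self

    def predict(self, species_names: Sequence[str]) -> np.ndarray:
        return np.array([self.model_.lookup(s) for s in species_names], dtype=np.int64)


def cluster_species(
    rscu_vectors: Sequence[RSCUVector],
    n_cluster_ids: int = 500,
    seed: int = 0,
) -> SpeciesTypeModel:
    """Functional wrapper over :class:`SpeciesClusterTyper`."""
    return SpeciesClusterTyper(n_cluster_ids=n_cluster_ids, seed=seed).fit(
        rscu_vectors
    ).model_


def project_type_embeddings(embeddings: np.ndarray) -> np.ndarray:
    """First two PCA scores of the learned token-type embedding rows."""
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 embedding rows")
    return PCA(n_components=2, svd_solver="full").fit_transform(X)
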