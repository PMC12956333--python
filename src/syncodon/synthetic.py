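"""Synthetic coding-sequence generators.

These emulate the statistical structure the modeling stack assumes, at desk
scale: (1) species-specific codon-usage profiles drawn around taxon-level
Dirichlet means, so RSCU clustering has planted, recoverable taxa; (2) CDS
whose codon choice can carry a first-order wobble-base Markov dependence —
a learnable codon-level signal that is invisible at the protein level;
(3) synonymous-variant libraries whose fitness depends on the CDS only
through a declared codon-level feature (default GC3, the fraction of G/C
wobble bases), protein held constant; and (4) a silent-mutation generator
that rewrites a chosen fraction of the degenerate codon positions with a
*different* synonymous codon.

What these generators do not emulate: mRNA secondary structure, ribosome
dynamics, amino-acid composition bias, or any organism-specific expression
machinery. A model that performs well here has learned codon-usage and
wobble statistics — nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .codon_core import GeneticCode, standard_code, STOP_SYMBOL, codon_features
from .curation import CDSRecord, validate_cds

__all__ = [
    "SpeciesProfile",
    "VariantLibrary",
    "make_species_profiles",
    "sample_cds",
    "make_corpus",
    "make_variant_library",
    "mutate_synonymously",
    "gc3",
]

_NUC = "ACGT"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SpeciesProfile:
    """Per-family codon probabilities plus an optional wobble-transition matrix.

    ``family_probs`` maps each amino-acid symbol (and ``*`` for stop) to a
    probability vector over its codons in sorted order. The transition
    matrix, when present, makes a codon's wobble base depend on the previous
    codon's wobble base (rows/columns in A,C,G,T order; rows sum to 1).
    """

    species: str
    taxon_group: str
    family_probs: Dict[str, np.ndarray]
    wobble_transition: Optional[np.ndarray] = None
    code: GeneticCode = field(default_factory=standard_code, repr=False)

    def family(self, aa: str) -> List[str]:
        return sorted(c for c, a in self.code.codon_to_aa.items() if a == aa)


def _families(code: GeneticCode) -> Dict[str, List[str]]:
    fams: Dict[str, List[str]] = {}
    for c, aa in code.codon_to_aa.items():
        fams.setdefault(aa, []).append(c)
    return {aa: sorted(cs) for aa, cs in fams.items()}


def make_species_profiles(
    n_species: int,
    n_taxa: int,
    dirichlet_concentration: float = 20.0,
    seed: int = 0,
    wobble_persistence: Optional[float] = None,
    code: Optional[GeneticCode] = None,
) -> List[SpeciesProfile]:
    """Seeded species profiles grouped into taxa with shared Dirichlet means.

    Each taxon draws a mean usage vector per codon family from a flat
    Dirichlet; each species then draws its own vector from
    Dirichlet(concentration x taxon mean), so larger concentrations pull
    species toward their taxon archetype (the default 20 gives clearly
    clusterable but non-degenerate within-taxon spread). Optional
    ``wobble_persistence`` p installs a transition matrix with p on the
    diagonal and (1-p)/3 elsewhere.
    """
    if not n_species >= n_taxa >= 1:
        raise ValueError("need n_species >= n_taxa >= 1")
    if dirichlet_concentration <= 0:
        raise ValueError("dirichlet_concentration must be positive")
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    fams = _families(code)
    taxon_means = []
    for _t in range(n_taxa):
        taxon_means.append(
            {aa: rng.dirichlet(np.ones(len(cs)) * 2.0) for aa, cs in fams.items()}
        )
    transition = None
    if wobble_persistence is not None:
        p = float(wobble_persistence)
        if not 0.0 <= p <= 1.0:
            raise ValueError("wobble_persistence must be in [0, 1]")
        transition = np.full((4, 4), (1.0 - p) / 3.0)
        np.fill_diagonal(transition, p)
    profiles = []
    for s in range(n_species):
        taxon = s % n_taxa
        probs = {}
        for aa, cs in fams.items():
            alpha = dirichlet_concentration * taxon_means[taxon][aa] + 1e-6
            probs[aa] = rng.dirichlet(alpha) if len(cs) > 1 else np.ones(1)
        profiles.append(
            SpeciesProfile(
                species=f"sp{s:04d}",
                taxon_group=f"taxon{taxon}",
                family_probs=probs,
                wobble_transition=transition,
                code=code,
            )
        )
    return profiles


def sample_cds(
    profile: SpeciesProfile,
    protein_length: int,
    rng: np.random.Generator,
    protein: Optional[str] = None,
    aa_persistence: float = 0.0,
) -> str:
    """Sample one CDS: ATG + codons for the protein + a stop codon.

    Codons are drawn per family from the profile; with a wobble-transition
    matrix, family probabilities are reweighted by the transition row of the
    previous codon's wobble base, planting a first-order codon-level
    dependence that never alters the protein.

    ``aa_persistence`` plants protein-level context: each residue repeats
    the previous one with that probability (otherwise uniform draw), giving
    the amino-acid sequence the kind of local predictability real proteins
    have. Without it the protein is i.i.d. uniform and amino-acid identity
    is unlearnable from context — which makes constrained/unconstrained
    comparisons of embedding geometry vacuous.
    """
    if protein_length < 1:
        raise ValueError("protein_length must be >= 1")
    if not 0.0 <= aa_persistence < 1.0:
        raise ValueError("aa_persistence must be in [0, 1)")
    if protein is None:
        residues = ["M"]
        prev = None
        for _ in range(protein_length - 1):
            if prev is not None and rng.random() < aa_persistence:
                residues.append(prev)
            else:
                residues.append(str(rng.choice(list(_AA20))))
            prev = residues[-1]
        protein = "".join(residues)
    elif not protein.startswith("M"):
        raise ValueError("protein must start with methionine")
    codons = []
    prev_wobble = None
    for aa in protein + STOP_SYMBOL:
        fam = profile.family(aa)
        p = np.asarray(profile.family_probs[aa], dtype=np.float64).copy()
        if profile.wobble_transition is not None and prev_wobble is not None:
            w_idx = [_NUC.index(c[2]) for c in fam]
            p = p * profile.wobble_transition[_NUC.index(prev_wobble)][w_idx]
            if p.sum() <= 0:
                p = np.ones(len(fam))
        p = p / p.sum()
        codon = fam[rng.choice(len(fam), p=p)]
        codons.append(codon)
        prev_wobble = codon[2]
    return "".join(codons)


def make_corpus(
    profiles: Sequence[SpeciesProfile],
    n_cds_per_species: int,
    protein_length: int = 50,
    seed: int = 0,
    aa_persistence: float = 0.0,
) -> List[CDSRecord]:
    """A validated multi-species CDS corpus drawn from the given profiles."""
    rng = np.random.default_rng(seed)
    records = []
    for prof in profiles:
        for j in range(n_cds_per_species):
            cds = sample_cds(prof, protein_length, rng,
                             aa_persistence=aa_persistence)
            assert validate_cds(cds) is None
            records.append(
                CDSRecord(
                    id=f"{prof.species}_cds{j:05d}",
                    species=prof.species,
                    taxon_group=prof.taxon_group,
                    sequence=cds,
                )
            )
    return records


def gc3(cds: str) -> float:
    """Fraction of codons whose wobble (third) base is G or C."""
    s = cds.upper()
    wobbles = s[2::3]
    return sum(1 for w in wobbles if w in "GC") / len(wobbles)


@dataclass
class VariantLibrary:
    """Synonymous variants of one protein with codon-feature-driven fitness."""

    protein: str
    sequences: List[str]
    fitness: np.ndarray
    feature: np.ndarray  # the generating codon-level feature (default GC3)
    beta: float
    noise_sd: float


def make_variant_library(
    protein_length: int = 60,
    n_variants: int = 200,
    beta: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    feature=gc3,
    code: Optional[GeneticCode] = None,
) -> VariantLibrary:
    """Fitness-labelled synonymous-variant library: y = beta * g(CDS) + eps.

    All variants encode the same (random) protein. Each variant draws its
    own G/C-wobble preference from Uniform(0.05, 0.95) so the feature (GC3
    by default) spans a wide range, giving the linear signal real variance.
    """
    if n_variants < 2:
        raise ValueError("need at least 2 variants")
    code = code or standard_code()
    rng = np.random.default_rng(seed)
    protein = "M" + "".join(rng.choice(list(_AA20)) for _ in range(protein_length - 1))
    fams = _families(code)
    seqs = []
    for _v in range(n_variants):
        q = rng.uniform(0.05, 0.95)  # this variant's G/C wobble preference
        codons = []
        for aa in protein + STOP_SYMBOL:
            fam = fams[aa]
            w = np.array([q if c[2] in "GC" else 1.0 - q for c in fam])
            codons.append(fam[rng.choice(len(fam), p=w / w.sum())])
        seqs.append("".join(codons))
    g = np.array([feature(s) for s in seqs])
    y = beta * g + rng.normal(0.0, noise_sd, size=n_variants)
    return VariantLibrary(
        protein=protein, sequences=seqs, fitness=y, feature=g,
        beta=beta, noise_sd=noise_sd,
    )


def mutate_synonymously(
    cds: str,
    level: float,
    rng: np.random.Generator,
    code: Optional[GeneticCode] = None,
) -> str:
    """Replace round(level * D) degenerate codons with different synonyms.

    D counts the codon positions whose family size is >= 2; positions are
    chosen uniformly without replacement and each selected codon is replaced
    by a codon drawn uniformly from its family minus itself, so at level 1.0
    every degenerate codon differs from the original. The translation is
    unchanged by construction.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError("level must be in [0, 1]")
    code = code or standard_code()
    rule = validate_cds(cds, code)
    if rule is not None:
        raise ValueError(f"invalid CDS ({rule})")
    s = cds.upper()
    codons = [s[i : i + 3] for i in range(0, len(s), 3)]
    degenerate = [i for i, c in enumerate(codons) if code.degeneracy[c] >= 2]
    n_mut = int(np.round(level * len(degenerate)))
    if n_mut == 0:
        return s
    chosen = rng.choice(len(degenerate), size=n_mut, replace=False)
    for j in chosen:
        i = degenerate[j]
        alternatives = sorted(code.synonymous_set(codons[i]) - {codons[i]})
        codons[i] = alternatives[rng.choice(len(alternatives))]
    return "".join(codons)
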