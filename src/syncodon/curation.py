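"""CDS validation, per-species deduplication, taxon stratification, splitting.

The curation pipeline mirrors how a large multi-species pre-training corpus
is assembled: keep only clean in-frame coding sequences, drop exact
duplicates within a species, cap every organismal group's codon total at
the reference group's total (so no group dominates the token budget), and
take a seeded random train/test partition. Similarity clustering at 90%
identity / 80% coverage is delegated to an external tool (e.g.
``mmseqs easy-cluster --min-seq-id 0.9 -c 0.8``); this module consumes its
output through the same record interface and removes only exact duplicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .codon_core import GeneticCode, standard_code, NUCLEOTIDES, STOP_SYMBOL

__all__ = [
    "CDSRecord",
    "CurationReport",
    "validate_cds",
    "dedupe_within_species",
    "stratify_by_codons",
    "split_train_test",
    "curate",
]


@dataclass
class CDSRecord:
    """One coding sequence with its species/taxon metadata."""

    id: str
    species: str
    taxon_group: str
    sequence: str

    @property
    def codon_count(self) -> int:
        return len(self.sequence) // 3

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, line: str) -> "CDSRecord":
        d = json.loads(line)
        return cls(
            id=d["id"],
            species=d["species"],
            taxon_group=d["taxon_group"],
            sequence=d["sequence"],
        )


@dataclass
class CurationReport:
    """Counts of records rejected per rule plus stratification bookkeeping."""

    input_count: int = 0
    retained: int = 0
    rejected: Dict[str, int] = field(default_factory=dict)
    codons_per_group_before: Dict[str, int] = field(default_factory=dict)
    codons_per_group_after: Dict[str, int] = field(default_factory=dict)

    def reject(self, rule: str) -> None:
        self.rejected[rule] = self.rejected.get(rule, 0) + 1

    @property
    def balanced(self) -> bool:
        return self.retained + sum(self.rejected.values()) == self.input_count

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def validate_cds(sequence: str, code: Optional[GeneticCode] = None) -> Optional[str]:
    """Check the three curation rules; return None on pass, the failed rule name otherwise.

    Rules: canonical alphabet (A/C/G/T), length divisible by three, and no
    internal stop codon (a terminal stop is allowed).
    """
    code = code or standard_code()
    if not sequence:
        return "empty"
    s = sequence.upper()
    if any(ch not in NUCLEOTIDES for ch in s):
        return "alphabet"
    if len(s) % 3 != 0:
        return "length"
    n = len(s) // 3
    for i in range(n - 1):  # last codon exempt: terminal stop is legitimate
        if code.codon_to_aa[s[3 * i : 3 * i + 3]] == STOP_SYMBOL:
            return "internal_stop"
    return None


def dedupe_within_species(records: Sequence[CDSRecord]) -> List[CDSRecord]:
    """Keep the first occurrence of each exact (species, sequence) pair."""
    seen = set()
    out = []
    for r in records:
        key = (r.species, r.sequence.upper())
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out


def _codons_per_group(records: Iterable[CDSRecord]) -> Dict[str, int]:
    totals: Dict[str, int] = {}
    for r in records:
        totals[r.taxon_group] = totals.get(r.taxon_group, 0) + r.codon_count
    return totals


def stratify_by_codons(
    records: Sequence[CDSRecord],
    reference_group: str,
    seed: int = 0,
) -> List[CDSRecord]:
    """Subsample over-represented taxon groups down to the reference group's codon total.

    Groups whose codon total exceeds the reference group's have whole records
    removed by seeded uniform sampling (never sequence truncation) until the
    group total is at or below the cap. The reference group and groups
    already under the cap are returned unchanged; input order is preserved.
    """
    totals = _codons_per_group(records)
    if reference_group not in totals:
        raise ValueError(f"reference group {reference_group!r} not present")
    cap = totals[reference_group]
    rng = np.random.default_rng(seed)
    drop: set = set()
    by_group: Dict[str, List[int]] = {}
    for idx, r in enumerate(records):
        by_group.setdefault(r.taxon_group, []).append(idx)
    for group in sorted(by_group):
        if group == reference_group or totals[group] <= cap:
            continue
        indices = np.array(by_group[group])
        order = rng.permutation(len(indices))
        total = totals[group]
        for j in order:
            if total <= cap:
                break
            idx = int(indices[j])
            drop.add(idx)
            total -= records[idx].codon_count
    return [r for i, r in enumerate(records) if i not in drop]


def split_train_test(
    records: Sequence[CDSRecord],
    train_fraction: float = 0.98,
    seed: int = 0,
) -> Tuple[List[CDSRecord], List[CDSRecord]]:
    """Seeded random partition into train/test; train size = round(n * fraction)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    # banker's rounding on n * fraction; clamp so both sides are non-empty
    n_train = int(np.round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = set(perm[:n_train].tolist())
    train = [r for i, r in enumerate(records) if i in train_idx]
    test = [r for i, r in enumerate(records) if i not in train_idx]
    return train, test


def curate(
    records: Sequence[CDSRecord],
    reference_group: str,
    seed: int = 0,
    train_fraction: float = 0.98,
    code: Optional[GeneticCode] = None,
) -> Tuple[List[CDSRecord], List[CDSRecord], CurationReport]:
    """Full pipeline: validate -> dedupe -> stratify -> split.

    Similarity clustering, when used, happens externally between the dedupe
    and stratify stages; pass its representative records here.
    """
    report = CurationReport(input_count=len(records))
    valid: List[CDSRecord] = []
    for r in records:
        rule = validate_cds(r.sequence, code)
        if rule is None:
            valid.append(
                CDSRecord(r.id, r.species, r.taxon_group, r.sequence.upper())
            )
        else:
            report.reject(rule)
    deduped = dedupe_within_species(valid)
    for _ in range(len(valid) - len(deduped)):
        report.reject("duplicate")
    report.codons_per_group_before = _codons_per_group(deduped)
    stratified = stratify_by_codons(deduped, reference_group, seed=seed)
    for _ in range(len(deduped) - len(stratified)):
        report.reject("stratified_out")
    report.codons_per_group_after = _codons_per_group(stratified)
    report.retained = len(stratified)
    train, test = split_train_test(stratified, train_fraction, seed=seed)
    return train, test, report


def read_jsonl(path) -> List[CDSRecord]:
    with open(path) as fh:
        return [CDSRecord.from_json(line) for line in fh if line.strip()]


def write_jsonl(records: Iterable[CDSRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(r.to_json() + "\n")
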