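"""Genetic code, codon tokenizer and the synonym-constraint matrix.

The constraint matrix is the additive logit mask at the heart of
synonym-constrained masked language modeling: row ``t`` (the true codon at a
masked position) is 0 over codons synonymous with ``t`` and ``-inf``
elsewhere, so after adding it to the model's logits the softmax places
exactly zero probability outside the synonymous family.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Tuple

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "InvalidCodonError",
    "CDSValidationError",
    "GeneticCode",
    "CodonTokenizer",
    "SynonymConstraintMatrix",
    "STOP_SYMBOL",
    "SPECIAL_TOKENS",
    "translate_codon",
    "synonymous_set",
    "codon_features",
    "encode_cds",
    "decode_ids",
    "build_synonym_mask",
]

STOP_SYMBOL = "*"
NUCLEOTIDES = "ACGT"

#: start/end mirror [CLS]/[SEP]; mask/pad/unknown complete an MLM vocabulary.
SPECIAL_TOKENS = ("[CLS]", "[SEP]", "[MASK]", "[PAD]", "[UNK]")


class InvalidCodonError(ValueError):
    """Raised for strings that are not a canonical DNA codon."""


class CDSValidationError(ValueError):
    """Raised when a coding sequence fails a validation rule."""

    def __init__(self, rule: str, message: str):
        self.rule = rule
        super().__init__(f"{rule}: {message}")


def _all_codons() -> List[str]:
    return [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]


def _check_codon(codon: str) -> str:
    if not isinstance(codon, str):
        raise InvalidCodonError(f"codon must be a string, got {type(codon).__name__}")
    c = codon.upper()
    if len(c) != 3 or any(ch not in NUCLEOTIDES for ch in c):
        raise InvalidCodonError(
            f"{codon!r} is not a 3-letter codon over the DNA alphabet A/C/G/T"
        )
    return c


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus its synonymous-family structure.

    Parameters
    ----------
    table_id : NCBI translation table identifier. Table 1 (the standard
        code) is the default; alternative nuclear/organellar tables are
        accepted so the constraint structure can follow a non-standard code.
    stops_are_synonymous : treat the stop codons as one synonymous family
        (they all "encode" translation termination). Disabling it puts each
        stop codon in a singleton family.

    Attributes
    ----------
    codon_to_aa : mapping of all 64 codons to a 1-letter amino-acid symbol,
        with ``*`` for stop.
    families : mapping codon -> frozen set of codons in its synonymous family.
    degeneracy : mapping codon -> family size ``n_i``.
    """

    table_id: int = 1
    stops_are_synonymous: bool = True
    codon_to_aa: Dict[str, str] = field(init=False, repr=False)
    families: Dict[str, FrozenSet[str]] = field(init=False, repr=False)
    degeneracy: Dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        table = CodonTable.unambiguous_dna_by_id[self.table_id]
        codon_to_aa = {}
        for codon in _all_codons():
            if codon in table.stop_codons:
                codon_to_aa[codon] = STOP_SYMBOL
            else:
                codon_to_aa[codon] = table.forward_table[codon]
        by_aa: Dict[str, List[str]] = {}
        for codon, aa in codon_to_aa.items():
            by_aa.setdefault(aa, []).append(codon)
        families: Dict[str, FrozenSet[str]] = {}
        for aa, members in by_aa.items():
            if aa == STOP_SYMBOL and not self.stops_are_synonymous:
                for c in members:
                    families[c] = frozenset({c})
            else:
                fam = frozenset(members)
                for c in members:
                    families[c] = fam
        object.__setattr__(self, "codon_to_aa", codon_to_aa)
        object.__setattr__(self, "families", families)
        object.__setattr__(
            self, "degeneracy", {c: len(f) for c, f in families.items()}
        )

    @property
    def codons(self) -> List[str]:
        return _all_codons()

    def translate(self, codon: str) -> str:
        return self.codon_to_aa[_check_codon(codon)]

    def synonymous_set(self, codon: str) -> FrozenSet[str]:
        return self.families[_check_codon(codon)]

    def translate_cds(self, cds: str) -> str:
        """Translate a validated-frame CDS codon by codon (stops as ``*``)."""
        s = cds.upper()
        if len(s) % 3 != 0:
            raise CDSValidationError("length", "sequence length not divisible by 3")
        return "".join(self.translate(s[i : i + 3]) for i in range(0, len(s), 3))

    def to_tsv(self) -> str:
        return "\n".join(f"{c}\t{self.codon_to_aa[c]}" for c in self.codons) + "\n"


def translate_codon(codon: str, code: GeneticCode | None = None) -> str:
    """Translate one codon under the standard genetic code (or ``code``)."""
    return (code or _STANDARD_CODE).translate(codon)


def synonymous_set(codon: str, code: GeneticCode | None = None) -> FrozenSet[str]:
    """All codons encoding the same amino acid/stop, the input included."""
    return (code or _STANDARD_CODE).synonymous_set(codon)


def codon_features(codon: str) -> Tuple[str, str]:
    """(wobble base, suffix dinucleotide) = (position 3, positions 2-3)."""
    c = _check_codon(codon)
    return c[2], c[1:]


class CodonTokenizer:
    """Fixed 69-token vocabulary: 64 codons plus 5 special tokens.

    Token ids are dense ``0..68``; the specials occupy ids ``64..68`` in the
    order start/end/mask/pad/unknown. Encoding prepends the start token and
    appends the end token, truncating overlong sequences from the right
    before the end token.
    """

    def __init__(self, max_positions: int = 1024):
        if max_positions < 3:
            raise ValueError("max_positions must allow at least one codon")
        self.max_positions = max_positions
        self.codons = _all_codons()
        self.vocab: List[str] = self.codons + list(SPECIAL_TOKENS)
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}

    vocab_size = property(lambda self: len(self.vocab))

    @property
    def start_id(self) -> int:
        return self.token_to_id["[CLS]"]

    @property
    def end_id(self) -> int:
        return self.token_to_id["[SEP]"]

    @property
    def mask_id(self) -> int:
        return self.token_to_id["[MASK]"]

    @property
    def pad_id(self) -> int:
        return self.token_to_id["[PAD]"]

    @property
    def unk_id(self) -> int:
        return self.token_to_id["[UNK]"]

    @property
    def codon_ids(self) -> np.ndarray:
        return np.arange(64)

    def is_codon_id(self, token_id: int) -> bool:
        return 0 <= token_id < 64

    def encode(self, cds: str) -> np.ndarray:
        s = validate_frame(cds)
        ids = [self.start_id]
        ids.extend(self.token_to_id[s[i : i + 3]] for i in range(0, len(s), 3))
        if len(ids) + 1 > self.max_positions:
            ids = ids[: self.max_positions - 1]
        ids.append(self.end_id)
        return np.asarray(ids, dtype=np.int64)

    def decode(self, ids) -> str:
        out = []
        for i in ids:
            tok = self.id_to_token[int(i)]
            if tok in SPECIAL_TOKENS:
                continue
            out.append(tok)
        return "".join(out)

    def vocab_json(self) -> str:
        return json.dumps(self.token_to_id, indent=1)


def validate_frame(cds: str) -> str:
    """Uppercase and check alphabet/frame (not the internal-stop rule)."""
    if not isinstance(cds, str):
        raise CDSValidationError("type", "sequence must be a string")
    s = cds.upper()
    if any(ch not in NUCLEOTIDES for ch in s):
        raise CDSValidationError(
            "alphabet", "sequence contains non-canonical nucleotides"
        )
    if len(s) % 3 != 0:
        raise CDSValidationError("length", "sequence length not divisible by 3")
    return s


def encode_cds(tokenizer: CodonTokenizer, cds: str) -> np.ndarray:
    """Token-id sequence ``[start] + codons + [end]`` for a valid CDS."""
    return tokenizer.encode(cds)


def decode_ids(tokenizer: CodonTokenizer, ids) -> str:
    return tokenizer.decode(ids)


NEG_INF = -np.inf


@dataclass(frozen=True)
class SynonymConstraintMatrix:
    """V x V additive logit mask: 0 where synonymous, -inf elsewhere.

    Row ``t`` is indexed by the TRUE codon token at a masked position;
    column ``v`` by the candidate prediction. Rows for special tokens are
    all -inf (specials are never prediction targets).
    """

    mask: np.ndarray

    def row(self, token_id: int) -> np.ndarray:
        return self.mask[token_id]

    @property
    def n_finite_codon_entries(self) -> int:
        return int(np.isfinite(self.mask[:64, :64]).sum())


def build_synonym_mask(
    tokenizer: CodonTokenizer, code: GeneticCode | None = None
) -> SynonymConstraintMatrix:
    """Construct the additive constraint matrix over the full vocabulary."""
    code = code or _STANDARD_CODE
    missing = set(code.codons) - set(tokenizer.codons)
    if missing or set(tokenizer.codons) != set(code.codons):
        raise ValueError("tokenizer and genetic code must cover the same 64 codons")
    V = tokenizer.vocab_size
    mask = np.full((V, V), NEG_INF, dtype=np.float64)
    for codon in code.codons:
        t = tokenizer.token_to_id[codon]
        for syn in code.synonymous_set(codon):
            mask[t, tokenizer.token_to_id[syn]] = 0.0
    return SynonymConstraintMatrix(mask=mask)


_STANDARD_CODE = GeneticCode()


def standard_code() -> GeneticCode:
    """The shared standard-code (NCBI table 1) instance."""
    return _STANDARD_CODE
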