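"""Standard genetic code, IUPAC degeneracy expansion, and sequence utilities.

All probabilities derived from codon expansions are exact rationals
(:class:`fractions.Fraction`); downstream statistics convert to floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "AMINO_ACIDS",
    "STOP",
    "GeneticCode",
    "STANDARD_CODE",
    "DegenerateCodon",
    "VariantDistribution",
    "translate_codon",
    "expand_degenerate_codon",
    "amino_acid_distribution",
    "reverse_complement",
    "IUPAC_NUCLEOTIDES",
]

#: The 20 proteinogenic amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: Tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Variant symbol for a translational stop.
STOP = "*"

# NCBI translation table 1, bases ordered T, C, A, G per position.
_BASES_TCAG = "TCAG"
_AA_STRING = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)

# IUPAC nucleotide ambiguity codes -> set of concrete bases.
IUPAC_NUCLEOTIDES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

# Complement at the ambiguity-code level (complement of the base set).
_COMPLEMENT: Dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> variant-symbol table (amino acid one-letter code or '*')."""

    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must have 64 entries, got {len(self.table)}")
        stops = sum(1 for v in self.table.values() if v == STOP)
        if stops != 3:
            raise ValueError(f"expected 3 stop codons, got {stops}")
        missing = set(AMINO_ACIDS) - set(self.table.values())
        if missing:
            raise ValueError(f"amino acids never encoded: {sorted(missing)}")

    def translate(self, codon: str) -> str:
        """Translate a concrete codon; raises on non-ACGT characters."""
        key = codon.upper()
        if key not in self.table:
            raise ValueError(
                f"invalid codon {codon!r}: expected 3 letters from A/C/G/T"
            )
        return self.table[key]


def _build_standard_table() -> Dict[str, str]:
    table = {}
    for (b1, b2, b3), aa in zip(product(_BASES_TCAG, repeat=3), _AA_STRING):
        table[b1 + b2 + b3] = aa
    return table


#: The standard genetic code (translation table 1).
STANDARD_CODE = GeneticCode(table=_build_standard_table())


@dataclass(frozen=True)
class DegenerateCodon:
    """A 3-letter IUPAC degenerate codon, e.g. ``NNK``."""

    symbols: str

    def __post_init__(self) -> None:
        sym = self.symbols.upper()
        if len(sym) != 3:
            raise ValueError(f"degenerate codon must be 3 symbols, got {self.symbols!r}")
        for ch in sym:
            if ch not in IUPAC_NUCLEOTIDES:
                raise ValueError(
                    f"invalid IUPAC nucleotide code {ch!r} in {self.symbols!r}"
                )
        object.__setattr__(self, "symbols", sym)

    @property
    def expansion_size(self) -> int:
        n = 1
        for ch in self.symbols:
            n *= len(IUPAC_NUCLEOTIDES[ch])
        return n

    def __str__(self) -> str:
        return self.symbols


@dataclass(frozen=True)
class VariantDistribution:
    """Probability of each variant symbol produced by a codon scheme.

    ``probs`` maps every symbol in the 20-amino-acid + stop space to an
    exact :class:`~fractions.Fraction` (zero entries included).
    """

    probs: Mapping[str, Fraction]
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        allowed = set(AMINO_ACIDS) | {STOP}
        unknown = set(self.probs) - allowed
        if unknown:
            raise ValueError(f"unknown variant symbols: {sorted(unknown)}")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("probabilities must be nonnegative")
        total = sum(self.probs.values())
        if abs(float(total) - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {float(total)}, expected 1")

    @classmethod
    def from_probs(cls, probs: Mapping[str, float | Fraction], source: str = "") -> "VariantDistribution":
        exact = {k: Fraction(v).limit_denominator(10**12) if not isinstance(v, Fraction) else v
                 for k, v in probs.items()}
        return cls(probs=exact, source=source)

    def p(self, symbol: str) -> Fraction:
        """Probability of ``symbol`` (0 if absent from the mapping)."""
        if symbol not in set(AMINO_ACIDS) | {STOP}:
            raise ValueError(f"unknown variant symbol {symbol!r}")
        return self.probs.get(symbol, Fraction(0))

    @property
    def reachable(self) -> frozenset:
        """Symbols with strictly positive probability."""
        return frozenset(s for s, p in self.probs.items() if p > 0)

    @property
    def reachable_amino_acids(self) -> frozenset:
        return self.reachable - {STOP}

    def as_floats(self, include_zero: bool = False) -> Dict[str, float]:
        out = {s: float(p) for s, p in self.probs.items() if include_zero or p > 0}
        if include_zero:
            for s in (*AMINO_ACIDS, STOP):
                out.setdefault(s, 0.0)
        return out


def translate_codon(codon: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a concrete 3-letter codon to its variant symbol."""
    return code.translate(codon)


def expand_degenerate_codon(deg: DegenerateCodon | str) -> List[Tuple[str, Fraction]]:
    """Expand a degenerate codon into (concrete codon, probability) pairs.

    Codons are lexicographically sorted; each carries probability
    1/expansion_size, so the probabilities sum to exactly 1.
    """
    if isinstance(deg, str):
        deg = DegenerateCodon(deg)
    sets = [IUPAC_NUCLEOTIDES[ch] for ch in deg.symbols]
    codons = sorted("".join(bases) for bases in product(*sets))
    p = Fraction(1, len(codons))
    return [(c, p) for c in codons]


def amino_acid_distribution(
    deg: DegenerateCodon | str, code: GeneticCode = STANDARD_CODE
) -> VariantDistribution:
    """Per-variant probabilities induced by a degenerate codon scheme.

    Each variant's probability is (codons translating to it) / expansion
    size; unreachable variants carry probability 0 and the stop symbol
    ``'*'`` is a first-class outcome.
    """
    if isinstance(deg, str):
        deg = DegenerateCodon(deg)
    probs: Dict[str, Fraction] = {s: Fraction(0) for s in (*AMINO_ACIDS, STOP)}
    for codon, p in expand_degenerate_codon(deg):
        probs[code.translate(codon)] += p
    return VariantDistribution(probs=probs, source=str(deg))


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string, preserving case."""
    out = []
    for ch in reversed(seq):
        up = ch.upper()
        if up not in _COMPLEMENT:
            raise ValueError(f"invalid nucleotide character {ch!r}")
        comp = _COMPLEMENT[up]
        out.append(comp if ch.isupper() else comp.lower())
    return "".join(out)
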