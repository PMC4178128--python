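"""QuikChange-style mutagenic primer design.

Builds a complementary degenerate primer pair around one codon of a
template CDS, and individual completion primers (one concrete codon per
still-missing variant) sharing the same flanks.  Flanks are emitted in
lowercase and the mutated codon in uppercase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

from .genetic_code import (
    DegenerateCodon,
    GeneticCode,
    STANDARD_CODE,
    reverse_complement,
    translate_codon,
)

__all__ = [
    "TemplateCDS",
    "PrimerPair",
    "CompletionPrimer",
    "design_degenerate_primer_pair",
    "design_completion_primers",
    "published_codon_table",
    "W373_REGION_TEMPLATE",
    "W373_REGION_CODON",
    "W373_FLANKS",
]


@dataclass(frozen=True)
class TemplateCDS:
    """A coding sequence with 1-based codon (amino-acid) indexing.

    Codon k occupies bases ``frame_offset + 3(k-1) .. frame_offset + 3k``
    (1-based, inclusive).
    """

    id: str
    sequence: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 3:
            raise ValueError("template must be at least one codon long")
        if not 0 <= self.frame_offset < len(self.sequence):
            raise ValueError("frame_offset out of range")

    @property
    def n_codons(self) -> int:
        return (len(self.sequence) - self.frame_offset) // 3

    def codon_slice(self, codon_pos: int) -> slice:
        """0-based base slice of the given 1-based codon index."""
        if not 1 <= codon_pos <= self.n_codons:
            raise ValueError(
                f"codon position {codon_pos} out of range 1..{self.n_codons}"
            )
        start = self.frame_offset + 3 * (codon_pos - 1)
        return slice(start, start + 3)

    def codon(self, codon_pos: int) -> str:
        return self.sequence[self.codon_slice(codon_pos)].upper()

    def translate(self, code: GeneticCode = STANDARD_CODE) -> str:
        return "".join(
            code.translate(self.codon(k)) for k in range(1, self.n_codons + 1)
        )


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    codon_pos: int
    codon: str
    wildtype_codon: str
    flank_up: int
    flank_dn: int


@dataclass(frozen=True)
class CompletionPrimer:
    variant: str
    codon: str
    reverse: str
    forward: str


def _flanks(template: TemplateCDS, codon_pos: int, flank_up: int, flank_dn: int):
    sl = template.codon_slice(codon_pos)
    if flank_up < 0 or flank_dn < 0:
        raise ValueError("flank lengths must be nonnegative")
    if sl.start - flank_up < 0 or sl.stop + flank_dn > len(template.sequence):
        raise ValueError(
            f"flanks ({flank_up}, {flank_dn}) around codon {codon_pos} "
            "exceed the template bounds"
        )
    up = template.sequence[sl.start - flank_up : sl.start].lower()
    dn = template.sequence[sl.stop : sl.stop + flank_dn].lower()
    return up, dn


def design_degenerate_primer_pair(
    template: TemplateCDS,
    codon_pos: int,
    scheme: DegenerateCodon | str,
    flank_up: int = 18,
    flank_dn: int = 21,
) -> PrimerPair:
    """Complementary forward/reverse primers carrying a degenerate codon."""
    if isinstance(scheme, str):
        scheme = DegenerateCodon(scheme)
    up, dn = _flanks(template, codon_pos, flank_up, flank_dn)
    forward = up + scheme.symbols + dn
    return PrimerPair(
        forward=forward,
        reverse=reverse_complement(forward),
        codon_pos=codon_pos,
        codon=scheme.symbols,
        wildtype_codon=template.codon(codon_pos),
        flank_up=flank_up,
        flank_dn=flank_dn,
    )


def design_completion_primers(
    template: TemplateCDS,
    codon_pos: int,
    missing_variants: Iterable[str],
    codon_choice: Mapping[str, str],
    flank_up: int = 18,
    flank_dn: int = 21,
    code: GeneticCode = STANDARD_CODE,
) -> List[CompletionPrimer]:
    """One concrete-codon primer per missing variant, ordered by symbol.

    Every chosen codon must translate to its variant; flanks are the same
    as the degenerate design so all primers target the same site.
    """
    up, dn = _flanks(template, codon_pos, flank_up, flank_dn)
    primers = []
    for variant in sorted(set(missing_variants)):
        if variant not in codon_choice:
            raise ValueError(f"no codon supplied for missing variant {variant!r}")
        codon = codon_choice[variant].upper()
        got = code.translate(codon)
        if got != variant:
            raise ValueError(
                f"codon {codon} translates to {got!r}, not target {variant!r}"
            )
        forward = up + codon + dn
        primers.append(
            CompletionPrimer(
                variant=variant,
                codon=codon,
                reverse=reverse_complement(forward),
                forward=forward,
            )
        )
    return primers


def published_codon_table() -> Dict[str, str]:
    """Published codon choices for the Zm-p60.1 W373 completion primers.

    The eight printed reverse-strand primers plus the Ser/Leu codon
    substitutions made to fix expression problems.
    """
    return {
        "C": "TGC",
        "E": "GAA",
        "I": "ATT",
        "M": "ATG",
        "N": "AAC",
        "Q": "CAG",
        "V": "GTG",
        "Y": "TAT",
        "S": "TCC",
        "L": "CTG",
    }


# 42-nt in-frame fragment of the Zm-p60.1 CDS around the randomized Trp
# codon, reconstructed from the published degenerate primer (the Trp codon
# is the 7th codon of the fragment; the published primers use 18 nt
# upstream and 21 nt downstream flanks).
W373_REGION_TEMPLATE = TemplateCDS(
    id="Zm-p60.1_W373_region",
    sequence="cctcctatgggaaatccaTGGatctacatgtaccctgagggc",
)
W373_REGION_CODON = 7
W373_FLANKS = (18, 21)
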