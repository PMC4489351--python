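"""Scanning-model prediction of translation products from reporter constructs.

The model encodes the logic validated by in vitro translation of
first-exon::Renilla fusions: ribosomes scan 5'->3' and preferentially
initiate at the first start site encountered. Candidate sites are every
ATG plus near-cognate codons (one substitution away from ATG, e.g. AAG)
in strong Kozak context. Product strengths are ordinal classes, not
rates: the first potent ATG gives a strong product, a downstream
in-frame ATG a leaky product; near-cognate sites yield faint products
only when no intact ATG lies upstream; ATGs internal to the reporter
ORF give background products only when no potent upstream ATG exists.
Only sites in frame with the reporter produce fusion products.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .features import KozakClass, classify_context

NEAR_COGNATE = frozenset(
    {"CTG", "GTG", "TTG", "AAG", "ACG", "AGG", "ATA", "ATC", "ATT"}
)


class Strength(str, enum.Enum):
    STRONG = "strong"
    LEAKY = "leaky"
    FAINT = "faint"
    BACKGROUND = "background"


_RANK = {
    Strength.BACKGROUND: 0,
    Strength.FAINT: 1,
    Strength.LEAKY: 2,
    Strength.STRONG: 3,
}


def strength_rank(strength: Strength) -> int:
    """Ordinal intensity of a product class (higher = stronger band)."""
    return _RANK[strength]


@dataclass(frozen=True)
class Construct:
    """An mRNA reporter construct: 5'UTR + exon-derived segment + reporter ORF."""

    label: str
    sequence: str  # 5'->3', DNA or RNA alphabet
    reporter_start: int  # position of the reporter's own first in-frame ATG

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if set(seq) - set("ACGTN"):
            raise ValueError("construct sequence must be nucleotides")
        if not (0 <= self.reporter_start <= len(seq) - 3):
            raise ValueError("reporter_start out of range")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class InitiationSite:
    position: int
    codon: str
    kozak_class: KozakClass
    frame_relative_to_reporter: int


@dataclass(frozen=True)
class Product:
    site: InitiationSite
    strength: Strength


def find_candidate_sites(construct: Construct) -> list[InitiationSite]:
    """5'->3' scan for candidate initiation sites.

    All ATGs qualify regardless of context; near-cognate codons qualify
    only in strong Kozak context.
    """
    seq = construct.sequence
    sites = []
    for pos in range(len(seq) - 2):
        codon = seq[pos : pos + 3]
        kozak = classify_context(seq, pos)
        if codon == "ATG" or (codon in NEAR_COGNATE and kozak is KozakClass.STRONG):
            sites.append(
                InitiationSite(
                    position=pos,
                    codon=codon,
                    kozak_class=kozak,
                    frame_relative_to_reporter=(pos - construct.reporter_start) % 3,
                )
            )
    return sites


def predict_products(construct: Construct) -> list[Product]:
    """Predict the set and relative strength of translation products."""
    sites = find_candidate_sites(construct)
    in_frame = [s for s in sites if s.frame_relative_to_reporter == 0]
    upstream_atgs = [
        s for s in sites if s.codon == "ATG" and s.position < construct.reporter_start
    ]

    products: list[Product] = []
    seen_atg = False
    for site in in_frame:
        if site.position < construct.reporter_start:
            if site.codon == "ATG":
                # the first potent (strong/adequate-context) ATG gives the
                # strong product; later or weak-context ATGs are leaky
                potent = not seen_atg and site.kozak_class is not KozakClass.WEAK
                products.append(
                    Product(site, Strength.STRONG if potent else Strength.LEAKY)
                )
                seen_atg = True
            else:  # near-cognate: masked by any intact ATG upstream of it
                if not any(a.position < site.position for a in upstream_atgs):
                    products.append(Product(site, Strength.FAINT))
        else:
            # reporter-internal ATGs: background only without a potent
            # upstream ATG (the first potent site dominates scanning)
            if site.codon == "ATG" and not upstream_atgs:
                products.append(Product(site, Strength.BACKGROUND))
    return products


def product_lengths(products: list[Product], construct: Construct) -> list[tuple[Product, int]]:
    """Products with their size rank: 1 = longest (most 5' start).

    All products terminate at the reporter stop, so size ordering is the
    descending distance from the initiation site to the end; sites k
    codons apart differ by exactly k residues.
    """
    ordered = sorted(products, key=lambda p: p.site.position)
    return [(p, rank) for rank, p in enumerate(ordered, start=1)]


def residue_difference(a: Product, b: Product) -> int:
    """Length difference (in residues) between two in-frame products."""
    return abs(a.site.position - b.site.position) // 3
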