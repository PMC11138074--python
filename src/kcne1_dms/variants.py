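"""Codon-level model of a saturation mutagenesis library.

A single NNK degenerate codon per residue introduces all 20 sense amino
acids plus one stop (TAG) at each position, so the single-amino-acid
outcome space of an L-residue protein has 21*L members: 19 missense, one
synonymous, and one nonsense outcome per residue.  This module models
variant identity, enumerates that outcome space, evaluates how many
single-nucleotide changes are needed to reach each outcome from the
reference codon, and produces protein-level variant names.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

#: standard genetic code, codon -> one-letter amino acid ('*' for stop)
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TABLE.update({c: STOP for c in standard_dna_table.stop_codons})

TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _vclass(ref_aa: str, alt_aa: str) -> str:
    if alt_aa == STOP:
        return "nonsense"
    if alt_aa == ref_aa or alt_aa == "=":
        return "synonymous"
    return "missense"


@dataclass(frozen=True, order=True)
class VariantId:
    """A single-amino-acid change, 1-based residue indexing.

    ``alt_aa`` is a one-letter amino acid, ``*`` for stop, or equal to
    ``ref_aa`` for a synonymous outcome.  The variant class is derived,
    never stored independently.
    """

    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_aa not in AMINO_ACIDS:
            raise ValueError(f"invalid reference residue {self.ref_aa!r}")
        if self.alt_aa not in AMINO_ACIDS + STOP + "=":
            raise ValueError(f"invalid alternate residue {self.alt_aa!r}")

    @property
    def vclass(self) -> str:
        return _vclass(self.ref_aa, self.alt_aa)

    @property
    def is_synonymous(self) -> bool:
        return self.vclass == "synonymous"


@dataclass(frozen=True)
class ReferenceModel:
    """Reference coding sequence and its translation."""

    cds: str
    protein: str

    @classmethod
    def from_cds(cls, cds: str) -> "ReferenceModel":
        cds = cds.upper().replace("U", "T")
        if len(cds) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        protein = str(Seq(cds).translate())
        if protein.endswith(STOP):
            protein = protein[:-1]
        if STOP in protein:
            raise ValueError("internal stop codon in reference CDS")
        return cls(cds=cds, protein=protein)

    def __len__(self) -> int:
        return len(self.protein)

    def codon(self, position: int) -> str:
        """Reference codon at a 1-based residue position."""
        if not 1 <= position <= len(self.protein):
            raise ValueError(f"residue {position} outside 1..{len(self.protein)}")
        return self.cds[3 * (position - 1) : 3 * position]


def name_variant(v: VariantId, long_form: bool = False) -> str:
    """Protein-level variant name, e.g. ``L51H``, ``D76N``, ``G10=``.

    ``long_form`` prepends ``p.`` and spells stop as ``Ter``.
    """
    if v.is_synonymous:
        alt = "="
    elif v.alt_aa == STOP:
        alt = "Ter" if long_form else STOP
    else:
        alt = v.alt_aa
    body = f"{v.ref_aa}{v.position}{alt}"
    return f"p.{body}" if long_form else body


def parse_variant_name(name: str) -> VariantId:
    """Inverse of :func:`name_variant` for short and ``p.`` forms."""
    body = name.removeprefix("p.")
    ref = body[0]
    if body.endswith("Ter"):
        alt, pos = STOP, body[1:-3]
    else:
        alt, pos = body[-1], body[1:-1]
    if alt == "=":
        alt = ref
    return VariantId(position=int(pos), ref_aa=ref, alt_aa=alt)


def enumerate_site_outcomes(protein: str | Iterable[str] | int) -> pd.DataFrame:
    """All 21 single-amino-acid outcomes per residue.

    Accepts a protein sequence, or an integer length (a poly-A dummy
    sequence is used, which preserves the per-class counts: 19 missense,
    1 synonymous, 1 nonsense per residue).
    """
    if isinstance(protein, int):
        if protein < 1:
            raise ValueError("protein length must be positive")
        protein = "A" * protein
    else:
        protein = "".join(protein)
    rows = []
    for pos, ref in enumerate(protein, start=1):
        for alt in AMINO_ACIDS + STOP:
            v = VariantId(position=pos, ref_aa=ref, alt_aa=alt)
            rows.append((pos, ref, alt, v.vclass, name_variant(v)))
    return pd.DataFrame(rows, columns=["position", "ref_aa", "alt_aa", "vclass", "name"])


def nnk_codons() -> pd.DataFrame:
    """The 32 NNK codons (N = A/C/G/T, K = G/T) with their translations."""
    rows = [
        ("".join(c), CODON_TABLE["".join(c)])
        for c in itertools.product("ACGT", "ACGT", "GT")
    ]
    return pd.DataFrame(rows, columns=["codon", "aa"])


def _mutation_type(b1: str, b2: str) -> str:
    return "transition" if frozenset((b1, b2)) in TRANSITIONS else "transversion"


def snv_accessibility(variant: VariantId, ref_codon: str) -> dict:
    """Minimum single-nucleotide steps from ``ref_codon`` to the variant.

    Returns ``min_snvs`` (1-3), whether the outcome is reachable by one
    substitution, and the transition/transversion label of each 1-SNV
    path.  For synonymous outcomes the reference codon itself (distance
    0 path) is excluded: distance is taken over *other* codons of the
    same amino acid, matching what a mutagenized codon can encode.
    """
    ref_codon = ref_codon.upper()
    if CODON_TABLE.get(ref_codon) != variant.ref_aa:
        raise ValueError(
            f"codon {ref_codon} encodes {CODON_TABLE.get(ref_codon)}, "
            f"not {variant.ref_aa}"
        )
    target_aa = variant.ref_aa if variant.is_synonymous else variant.alt_aa
    alt_codons = [
        c for c, aa in CODON_TABLE.items() if aa == target_aa and c != ref_codon
    ]
    if not alt_codons:
        raise ValueError(f"no alternative codon encodes {target_aa!r}")
    dists = {
        c: sum(a != b for a, b in zip(ref_codon, c)) for c in alt_codons
    }
    min_snvs = min(dists.values())
    paths = []
    for c, d in dists.items():
        if d == 1:
            (i,) = [i for i in range(3) if ref_codon[i] != c[i]]
            paths.append(
                {"alt_codon": c, "pos": i, "type": _mutation_type(ref_codon[i], c[i])}
            )
    return {
        "accessible_by_1_snv": min_snvs == 1,
        "min_snvs": min_snvs,
        "mutation_types": paths,
    }
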