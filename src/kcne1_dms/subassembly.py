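"""Barcode-to-variant linkage ("subassembly").

The plasmid library carries a random 18-mer barcode next to the
mutagenized coding region; deep sequencing of the library yields, per
barcode, a set of observed coding sequences.  Since the mutagenesis
design produces single-codon substitutions only, each read either
matches the reference, differs in exactly one codon, or is rejected.
A barcode is retained when its read support and plurality-call
consensus clear configurable thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .variants import CODON_TABLE, ReferenceModel, VariantId, name_variant

WT = "WT"

DEFAULT_MIN_READS = 5
DEFAULT_MIN_CONSENSUS = 0.9


@dataclass
class BarcodeEvidence:
    """Reads observed for one barcode: (coding sequence, count) pairs."""

    barcode: str
    observations: list[tuple[str, int]] = field(default_factory=list)


def call_variant(read_seq: str, ref: ReferenceModel) -> VariantId | str:
    """Call the single-codon change in a full-length read.

    Returns ``"WT"`` for an exact match or a :class:`VariantId` when
    exactly one codon differs.  Length mismatches (the design has no
    indels) and multi-codon changes raise ``ValueError`` with reasons
    ``indel/length`` and ``multi-codon`` respectively.
    """
    read_seq = read_seq.upper()
    if len(read_seq) != len(ref.cds):
        raise ValueError("indel/length")
    changed = [
        i
        for i in range(len(ref.protein))
        if read_seq[3 * i : 3 * i + 3] != ref.cds[3 * i : 3 * i + 3]
    ]
    if not changed:
        return WT
    if len(changed) > 1:
        raise ValueError("multi-codon")
    (i,) = changed
    codon = read_seq[3 * i : 3 * i + 3]
    alt_aa = CODON_TABLE.get(codon)
    if alt_aa is None:
        raise ValueError(f"unrecognized codon {codon!r}")
    return VariantId(position=i + 1, ref_aa=ref.protein[i], alt_aa=alt_aa)


def build_barcode_map(
    evidence: list[BarcodeEvidence],
    ref: ReferenceModel,
    min_reads: int = DEFAULT_MIN_READS,
    min_consensus: float = DEFAULT_MIN_CONSENSUS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Resolve each barcode to its plurality variant call.

    A barcode is retained iff its total reads reach ``min_reads`` and
    the plurality call's fraction of total reads reaches
    ``min_consensus``.  Ties at the top are broken lexicographically by
    variant name; a barcode whose reads are all unparseable is rejected.
    Returns ``(map, rejects)``; together they partition the input.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if not 0.5 < min_consensus <= 1:
        raise ValueError("min_consensus must be in (0.5, 1]")
    kept, rejected = [], []
    for ev in evidence:
        total = sum(count for _, count in ev.observations)
        if total < min_reads:
            rejected.append((ev.barcode, total, "low reads"))
            continue
        votes: dict[str, int] = {}
        for seq, count in ev.observations:
            try:
                call = call_variant(seq, ref)
            except ValueError:
                continue  # uninterpretable read: drops out of the vote
            name = call if call == WT else name_variant(call)
            votes[name] = votes.get(name, 0) + count
        if not votes:
            rejected.append((ev.barcode, total, "no callable reads"))
            continue
        best = min(votes, key=lambda k: (-votes[k], k))
        fraction = votes[best] / total
        if fraction < min_consensus:
            rejected.append((ev.barcode, total, "low consensus"))
            continue
        kept.append((ev.barcode, best, total, fraction))
    bc_map = pd.DataFrame(
        kept, columns=["barcode", "variant", "reads", "consensus"]
    ).set_index("barcode")
    rejects = pd.DataFrame(
        rejected, columns=["barcode", "reads", "reason"]
    ).set_index("barcode")
    return bc_map, rejects


def evidence_from_table(table: pd.DataFrame) -> list[BarcodeEvidence]:
    """Group a (barcode, read_seq, count) TSV table into evidence records."""
    out: list[BarcodeEvidence] = []
    for barcode, grp in table.groupby("barcode", sort=True):
        out.append(
            BarcodeEvidence(
                barcode=str(barcode),
                observations=list(zip(grp["read_seq"], grp["count"].astype(int))),
            )
        )
    return out
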