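"""Fixed-length synthesis-oligo encoding of library peptides.

Every library member is encoded as a 300-base oligonucleotide: a
codon-optimized coding sequence, in-frame Pro-Ala-Ser (PAS) linker padding
bringing the insert to exactly 270 bases, and 15-base primer-binding arms on
each side.  The PAS repeat is an inert, low-complexity spacer, so padding
extends the linker side of the displayed fusion without adding structure.

Encoding is fully deterministic: each amino acid takes its rank-1 codon from
a preference-ranked E. coli usage table, except the minimal leftmost set of
rank demotions needed to remove forbidden restriction-site motifs (EcoRI
GAATTC and HindIII AAGCTT by default, the cloning sites of the display
vector).  Both default sites are palindromic, so scanning the given strand
covers the double-stranded recognition sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "CodonTable",
    "ECOLI_RANKED",
    "EncoderConfig",
    "OligoDesign",
    "EncodingError",
    "reverse_translate",
    "pad_with_pas",
    "assemble_oligo",
    "encode_library",
    "translate",
    "find_motifs",
    "write_designs",
]

PAS_CYCLE = "PAS"


class EncodingError(ValueError):
    """A peptide (or a primer junction) could not be encoded without a
    forbidden motif."""


@dataclass(frozen=True)
class CodonTable:
    """Preference-ranked codons per amino acid (rank 0 = most preferred)."""

    name: str
    codons: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for aa, cods in self.codons.items():
            if not cods:
                raise ValueError(f"{aa}: no codons")
            for c in cods:
                if len(c) != 3 or set(c) - set("ACGT"):
                    raise ValueError(f"{aa}: bad codon {c!r}")
                if str(Seq(c).translate()) != aa:
                    raise ValueError(f"{aa}: codon {c} translates to {Seq(c).translate()}")


# E. coli K-12 codon preferences, most-used first.
ECOLI_RANKED = CodonTable(
    name="ecoli-k12",
    codons={
        "A": ("GCG", "GCC", "GCA", "GCT"),
        "R": ("CGT", "CGC", "CGG", "CGA", "AGA", "AGG"),
        "N": ("AAC", "AAT"),
        "D": ("GAT", "GAC"),
        "C": ("TGC", "TGT"),
        "Q": ("CAG", "CAA"),
        "E": ("GAA", "GAG"),
        "G": ("GGC", "GGT", "GGG", "GGA"),
        "H": ("CAT", "CAC"),
        "I": ("ATT", "ATC", "ATA"),
        "L": ("CTG", "TTA", "TTG", "CTC", "CTT", "CTA"),
        "K": ("AAA", "AAG"),
        "M": ("ATG",),
        "F": ("TTT", "TTC"),
        "P": ("CCG", "CCA", "CCT", "CCC"),
        "S": ("AGC", "TCT", "TCC", "AGT", "TCG", "TCA"),
        "T": ("ACC", "ACA", "ACG", "ACT"),
        "W": ("TGG",),
        "Y": ("TAT", "TAC"),
        "V": ("GTG", "GTT", "GTC", "GTA"),
    },
)

DEFAULT_FORBIDDEN = ("GAATTC", "AAGCTT")  # EcoRI, HindIII


@dataclass(frozen=True)
class EncoderConfig:
    forbidden_motifs: tuple[str, ...] = DEFAULT_FORBIDDEN
    primer5: str = "ACACGACGCTCTTCC"
    primer3: str = "GTGACTGGAGTTCAG"
    insert_len: int = 270
    oligo_len: int = 300

    def __post_init__(self) -> None:
        if self.insert_len % 3:
            raise ValueError("insert_len must be divisible by 3")
        if self.oligo_len != self.insert_len + len(self.primer5) + len(self.primer3):
            raise ValueError("oligo_len must equal insert_len + primer arm lengths")

    @property
    def max_peptide_len(self) -> int:
        return self.insert_len // 3


@dataclass(frozen=True)
class OligoDesign:
    """A peptide's encoded synthesis oligo.

    ``insert = coding + padding`` (exactly ``insert_len`` bases);
    ``oligo = primer5 + insert + primer3`` (exactly ``oligo_len`` bases).
    """

    peptide_id: str
    peptide: str
    coding: str
    padding: str
    insert: str
    oligo: str


def translate(dna: str) -> str:
    """Standard-code translation of an in-frame DNA string."""
    if len(dna) % 3:
        raise ValueError("length not divisible by 3")
    return str(Seq(dna).translate()) if dna else ""


def find_motifs(dna: str, motifs: Sequence[str]) -> list[tuple[int, str]]:
    """All (0-based position, motif) occurrences in ``dna``, sorted."""
    hits = []
    for m in motifs:
        start = dna.find(m)
        while start != -1:
            hits.append((start, m))
            start = dna.find(m, start + 1)
    return sorted(hits)


def _repair(
    codons: list[str],
    ranks: list[int],
    residues: str,
    table: CodonTable,
    motifs: Sequence[str],
    mutable_from: int = 0,
) -> None:
    """Remove forbidden motifs from ``codons`` in place by leftmost-first
    minimal rank demotions.  Only codon positions >= ``mutable_from`` may be
    demoted (used to keep an already-final coding region fixed while
    repairing padding).  Raises :class:`EncodingError` when no demotion
    removes the leftmost occurrence.
    """
    while True:
        seq = "".join(codons)
        occ = find_motifs(seq, motifs)
        if not occ:
            return
        pos, motif = occ[0]
        first_codon = max(pos // 3, mutable_from)
        last_codon = (pos + len(motif) - 1) // 3
        repaired = False
        for ci in range(first_codon, last_codon + 1):
            options = table.codons[residues[ci]]
            for rank in range(ranks[ci] + 1, len(options)):
                trial = codons.copy()
                trial[ci] = options[rank]
                trial_occ = find_motifs("".join(trial), motifs)
                # accept iff the leftmost occurrence is gone and no new one
                # appeared at or before it
                if not trial_occ or trial_occ[0][0] > pos:
                    codons[ci] = options[rank]
                    ranks[ci] = rank
                    repaired = True
                    break
            if repaired:
                break
        if not repaired:
            raise EncodingError(
                f"cannot remove motif {motif} at base {pos + 1} "
                f"(residues {first_codon + 1}-{last_codon + 1})"
            )


def reverse_translate(
    peptide: str,
    table: CodonTable = ECOLI_RANKED,
    forbidden: Sequence[str] = DEFAULT_FORBIDDEN,
) -> str:
    """Deterministic codon-optimized reverse translation.

    Each residue takes its rank-1 codon; forbidden motifs are broken by the
    minimal leftmost set of rank demotions.  ``translate`` of the result is
    always the input peptide.
    """
    if not peptide:
        return ""
    bad = set(peptide) - set(table.codons)
    if bad:
        raise EncodingError(f"residues without codons: {sorted(bad)}")
    codons = [table.codons[aa][0] for aa in peptide]
    ranks = [0] * len(peptide)
    _repair(codons, ranks, peptide, table, forbidden)
    return "".join(codons)


def pad_with_pas(
    coding: str,
    insert_len: int = 270,
    table: CodonTable = ECOLI_RANKED,
    forbidden: Sequence[str] = DEFAULT_FORBIDDEN,
) -> tuple[str, str]:
    """Pad a coding sequence to ``insert_len`` with in-frame PAS codons.

    Returns ``(padding, insert)``.  The padding translates to a prefix of
    the infinite repeat ``PASPAS...``; rank-1 codons are used, demoted only
    where a motif spans the coding/padding junction or the padding itself.
    The already-encoded coding region is never altered.
    """
    if len(coding) % 3 or insert_len % 3:
        raise ValueError("coding and insert_len must be divisible by 3")
    if len(coding) > insert_len:
        raise ValueError(
            f"coding length {len(coding)} exceeds insert capacity {insert_len}"
        )
    n_pad = (insert_len - len(coding)) // 3
    pad_residues = "".join(PAS_CYCLE[i % 3] for i in range(n_pad))
    residues = translate(coding) + pad_residues
    codons = [coding[i : i + 3] for i in range(0, len(coding), 3)]
    codons += [table.codons[aa][0] for aa in pad_residues]
    ranks = [0] * len(codons)
    _repair(codons, ranks, residues, table, forbidden, mutable_from=len(coding) // 3)
    insert = "".join(codons)
    return insert[len(coding) :], insert


def assemble_oligo(insert: str, cfg: EncoderConfig) -> str:
    """Flank an insert with the primer arms, re-scanning the junctions.

    Raises :class:`EncodingError` when a forbidden motif spans a
    primer/insert junction (the insert itself is assumed motif-free).
    """
    if len(insert) != cfg.insert_len:
        raise ValueError(f"insert length {len(insert)} != {cfg.insert_len}")
    oligo = cfg.primer5 + insert + cfg.primer3
    j5 = len(cfg.primer5)
    j3 = j5 + len(insert)
    for pos, motif in find_motifs(oligo, cfg.forbidden_motifs):
        end = pos + len(motif)
        if pos < j5 < end:
            raise EncodingError(f"motif {motif} spans the 5' primer junction")
        if pos < j3 < end:
            raise EncodingError(f"motif {motif} spans the 3' primer junction")
    return oligo


def encode_peptide(
    peptide_id: str,
    peptide: str,
    cfg: EncoderConfig = EncoderConfig(),
    table: CodonTable = ECOLI_RANKED,
) -> OligoDesign:
    """Encode one peptide end to end (reverse-translate, pad, assemble)."""
    if len(peptide) > cfg.max_peptide_len:
        raise EncodingError(
            f"{peptide_id}: {len(peptide)} aa exceeds insert capacity "
            f"of {cfg.max_peptide_len} aa"
        )
    coding = reverse_translate(peptide, table, cfg.forbidden_motifs)
    padding, insert = pad_with_pas(coding, cfg.insert_len, table, cfg.forbidden_motifs)
    oligo = assemble_oligo(insert, cfg)
    return OligoDesign(
        peptide_id=peptide_id,
        peptide=peptide,
        coding=coding,
        padding=padding,
        insert=insert,
        oligo=oligo,
    )


def encode_library(
    peptides: Iterable[tuple[str, str]],
    cfg: EncoderConfig = EncoderConfig(),
    table: CodonTable = ECOLI_RANKED,
) -> tuple[list[OligoDesign], list[tuple[str, str]]]:
    """Encode a batch of ``(id, peptide)`` pairs.

    Per-peptide failures are collected as ``(id, reason)`` without aborting
    the batch; returns ``(designs, failures)``.
    """
    designs: list[OligoDesign] = []
    failures: list[tuple[str, str]] = []
    for pid, pep in peptides:
        try:
            designs.append(encode_peptide(pid, pep, cfg, table))
        except (EncodingError, ValueError) as exc:
            failures.append((pid, str(exc)))
    return designs, failures


def write_designs(designs: Sequence[OligoDesign], fasta: str | Path, table_tsv: str | Path) -> None:
    """Emit designs as an oligo FASTA and a TSV design table."""
    with Path(fasta).open("w") as fh:
        for d in designs:
            fh.write(f">{d.peptide_id}\n{d.oligo}\n")
    with Path(table_tsv).open("w") as fh:
        fh.write("peptide_id\tpeptide\tcoding\tpadding\toligo\n")
        for d in designs:
            fh.write(f"{d.peptide_id}\t{d.peptide}\t{d.coding}\t{d.padding}\t{d.oligo}\n")
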