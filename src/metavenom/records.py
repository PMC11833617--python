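"""Annotated venom protein records and mature-peptide extraction.

Venom polypeptides are deposited as precursor proteins whose functional
(mature/active) regions are marked by processing annotations — CHAIN and
PEPTIDE features with 1-based inclusive coordinates, the UniProt convention.
This module parses a tabular dialect of such records, excises the annotated
mature peptides, applies the library length filter (<= 90 aa by default so a
peptide fits a fixed-length synthesis oligo), and summarizes library
composition (length and cysteine statistics).

Records whose feature coordinates are unresolved in the source (``?``,
``<1`` ...) are retained but contribute no mature peptides.  Sequences with
nonstandard residues (U, O, B, Z, J) are rejected at parse time because they
cannot be reverse translated unambiguously.
"""

from __future__ import annotations

import logging
import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_AA = CANONICAL_AA | {"X"}
FEATURE_KINDS = ("CHAIN", "PEPTIDE")

COLUMNS = ("accession", "organism", "lineage", "sequence", "features")

__all__ = [
    "ProcessingFeature",
    "ParentRecord",
    "MaturePeptide",
    "LibraryStats",
    "RecordFormatError",
    "parse_records",
    "write_records",
    "extract_mature",
    "length_filter",
    "collapse_by_sequence",
    "library_stats",
    "cys_pair_correlation",
    "write_fasta",
    "read_fasta",
]


class RecordFormatError(ValueError):
    """Raised when a record table is structurally malformed (e.g. a
    mandatory column is missing)."""


@dataclass(frozen=True)
class ProcessingFeature:
    """A CHAIN or PEPTIDE processing annotation.

    ``begin``/``end`` are 1-based inclusive when ``resolved``; the raw source
    tokens are kept so tables round-trip byte-identically even for
    unresolved coordinates such as ``?`` or ``<1``.
    """

    kind: str
    begin: int | None
    end: int | None
    resolved: bool
    begin_raw: str = ""
    end_raw: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.resolved and (self.begin is None or self.end is None or self.begin > self.end):
            raise ValueError("resolved feature requires begin <= end")

    def token(self) -> str:
        b = self.begin_raw or (str(self.begin) if self.begin is not None else "?")
        e = self.end_raw or (str(self.end) if self.end is not None else "?")
        return f"{self.kind}:{b}..{e}"


@dataclass(frozen=True)
class ParentRecord:
    """An annotated source protein with processing features."""

    accession: str
    organism: str
    lineage: tuple[str, ...]
    sequence: str
    features: tuple[ProcessingFeature, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - ALLOWED_AA
        if bad:
            raise ValueError(f"{self.accession}: non-canonical residues {sorted(bad)}")
        for f in self.features:
            if f.resolved and not (1 <= f.begin and f.end <= len(self.sequence)):
                raise ValueError(
                    f"{self.accession}: feature {f.token()} outside sequence of length {len(self.sequence)}"
                )


@dataclass(frozen=True)
class MaturePeptide:
    """A processed (mature/active) peptide excised from a parent record.

    ``id`` is ``accession|begin-end``.  ``parents`` accumulates source
    accessions when identical sequences from different parents are collapsed
    into a single library member.
    """

    id: str
    parent_accession: str
    sequence: str
    begin: int = 0
    end: int = 0
    parents: tuple[str, ...] = ()

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_cys(self) -> int:
        return self.sequence.count("C")


@dataclass(frozen=True)
class LibraryStats:
    n_members: int
    length_median: float
    cys_histogram: dict[int, int]
    frac_no_cys: float
    frac_odd_cys: float
    frac_even_cys: float
    frac_ge2_cys: float


def _parse_coord(tok: str) -> tuple[int | None, bool]:
    tok = tok.strip()
    if tok.isdigit():
        return int(tok), True
    return None, False


def _parse_feature(token: str) -> ProcessingFeature:
    kind, _, span = token.partition(":")
    if not span or ".." not in span:
        raise ValueError(f"malformed feature token {token!r}")
    b_tok, _, e_tok = span.partition("..")
    begin, b_ok = _parse_coord(b_tok)
    end, e_ok = _parse_coord(e_tok)
    return ProcessingFeature(
        kind=kind.strip(),
        begin=begin,
        end=end,
        resolved=b_ok and e_ok,
        begin_raw=b_tok.strip(),
        end_raw=e_tok.strip(),
    )


def parse_records(path: str | Path) -> list[ParentRecord]:
    """Parse a TSV record table into :class:`ParentRecord` objects.

    The dialect has a header row with columns ``accession``, ``organism``,
    ``lineage`` (semicolon-delimited taxon names), ``sequence`` and
    ``features`` (comma-delimited ``KIND:begin..end`` tokens; may be empty).

    Structural problems (missing mandatory columns) raise
    :class:`RecordFormatError`.  Row-level problems — out-of-range feature
    coordinates, non-canonical residues, duplicate accessions — skip the
    offending record and log a warning with its line number.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in COLUMNS if c not in header]
        if missing:
            raise RecordFormatError(f"{path}: missing mandatory columns {missing}")
        idx = {c: header.index(c) for c in COLUMNS}
        records: list[ParentRecord] = []
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                if len(parts) < len(header):
                    raise ValueError(f"expected {len(header)} columns, got {len(parts)}")
                accession = parts[idx["accession"]]
                if accession in seen:
                    raise ValueError(f"duplicate accession {accession!r}")
                lineage = tuple(t for t in parts[idx["lineage"]].split(";") if t)
                feat_col = parts[idx["features"]]
                feats = tuple(_parse_feature(t) for t in feat_col.split(",") if t)
                rec = ParentRecord(
                    accession=accession,
                    organism=parts[idx["organism"]],
                    lineage=lineage,
                    sequence=parts[idx["sequence"]],
                    features=feats,
                )
            except ValueError as exc:
                logger.warning("%s line %d: skipping record (%s)", path, lineno, exc)
                continue
            seen.add(accession)
            records.append(rec)
    return records


def write_records(records: Iterable[ParentRecord], path: str | Path) -> None:
    """Write records in the same TSV dialect :func:`parse_records` reads;
    parse/write round-trips are byte-identical on valid tables."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    (
                        r.accession,
                        r.organism,
                        ";".join(r.lineage),
                        r.sequence,
                        ",".join(f.token() for f in r.features),
                    )
                )
                + "\n"
            )


def extract_mature(record: ParentRecord) -> list[MaturePeptide]:
    """Excise one mature peptide per resolved CHAIN/PEPTIDE feature.

    Coordinates are 1-based inclusive.  Records lacking resolved features
    yield an empty list; overlapping features each yield their own peptide.
    """
    peptides = []
    for f in record.features:
        if not f.resolved:
            continue
        seq = record.sequence[f.begin - 1 : f.end]
        peptides.append(
            MaturePeptide(
                id=f"{record.accession}|{f.begin}-{f.end}",
                parent_accession=record.accession,
                sequence=seq,
                begin=f.begin,
                end=f.end,
                parents=(record.accession,),
            )
        )
    return peptides


def length_filter(
    peptides: Sequence[MaturePeptide], max_len: int, *, collapse: bool = False
) -> list[MaturePeptide]:
    """Retain peptides with ``length <= max_len`` (order preserved).

    With ``collapse=True``, identical sequences from different parents are
    merged into one library member (see :func:`collapse_by_sequence`).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    kept = [p for p in peptides if p.length <= max_len]
    return collapse_by_sequence(kept) if collapse else kept


def collapse_by_sequence(peptides: Sequence[MaturePeptide]) -> list[MaturePeptide]:
    """Collapse duplicate sequences into single members, accumulating parent
    accessions; the first occurrence supplies the member id."""
    by_seq: dict[str, MaturePeptide] = {}
    order: list[str] = []
    for p in peptides:
        if p.sequence not in by_seq:
            by_seq[p.sequence] = p
            order.append(p.sequence)
        else:
            prev = by_seq[p.sequence]
            merged = tuple(dict.fromkeys(prev.parents + p.parents))
            by_seq[p.sequence] = MaturePeptide(
                id=prev.id,
                parent_accession=prev.parent_accession,
                sequence=prev.sequence,
                begin=prev.begin,
                end=prev.end,
                parents=merged,
            )
    return [by_seq[s] for s in order]


def library_stats(peptides: Sequence[MaturePeptide]) -> LibraryStats:
    """Length median, cysteine-count histogram and cysteine-class fractions.

    The three fractions (no cysteine / odd count / even nonzero count)
    partition the library and sum to 1.
    """
    if not peptides:
        raise ValueError("library_stats requires a non-empty library")
    n = len(peptides)
    counts = [p.n_cys for p in peptides]
    hist = dict(sorted(Counter(counts).items()))
    no = sum(1 for c in counts if c == 0)
    odd = sum(1 for c in counts if c % 2 == 1)
    even_nz = sum(1 for c in counts if c > 0 and c % 2 == 0)
    ge2 = sum(1 for c in counts if c >= 2)
    return LibraryStats(
        n_members=n,
        length_median=float(statistics.median(p.length for p in peptides)),
        cys_histogram=hist,
        frac_no_cys=no / n,
        frac_odd_cys=odd / n,
        frac_even_cys=even_nz / n,
        frac_ge2_cys=ge2 / n,
    )


def cys_pair_correlation(
    pairs: Sequence[tuple[MaturePeptide, MaturePeptide]]
) -> tuple[float, np.ndarray]:
    """Pearson correlation of cysteine counts across (source, homolog) pairs.

    Returns ``(r, joint)`` where ``joint`` is the 2-D joint histogram of
    cysteine counts backing a heat-map display.  Raises ``ValueError`` when a
    margin has zero variance (correlation undefined).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([a.n_cys for a, _ in pairs], dtype=float)
    y = np.array([b.n_cys for _, b in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a margin; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    joint, _, _ = np.histogram2d(
        x, y, bins=[np.arange(x.max() + 2) - 0.5, np.arange(y.max() + 2) - 0.5]
    )
    return r, joint


def write_fasta(peptides: Iterable[MaturePeptide], path: str | Path) -> None:
    """Write a mature-peptide library as FASTA (header = member id)."""
    with Path(path).open("w") as fh:
        for p in peptides:
            fh.write(f">{p.id}\n{p.sequence}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
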