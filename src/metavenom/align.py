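"""Local pairwise alignment with Karlin–Altschul statistics.

This module is the shared alignment engine for metavenome expansion,
similarity networks and best-hit annotation.  Alignments are optimal local
(Smith–Waterman) alignments under an affine gap model: a gap of length g
costs ``gap_open + g * gap_extend`` (the BLAST convention, so the default
(11, 1) scheme charges 12 for a length-1 gap).  Raw scores are converted to
bit scores and E-values with tabulated Karlin–Altschul parameters for the
scoring scheme rather than estimated per search; this keeps desk-scale runs
deterministic.

The dynamic programming itself is delegated to Biopython's
:class:`Bio.Align.PairwiseAligner` (an exact affine-gap implementation);
identity, coverage and the gapped alignment strings reported here are
computed in this module from the returned alignment path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "smith_waterman",
    "bit_score",
    "evalue",
    "shares_kmer",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin–Altschul parameters.

    The default (BLOSUM62, gap open 11, gap extend 1, lambda 0.267, K 0.041)
    matches the gapped blastp defaults for protein search.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")


@dataclass
class LocalAlignment:
    """An optimal local alignment between a query and a target sequence.

    Spans are 1-based inclusive; ``(0, 0)`` denotes the empty alignment.
    ``identity`` uses all alignment columns (including gap columns) as the
    denominator.  ``coverage_*`` is the aligned span length over the full
    sequence length, per sequence.
    """

    score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    aligned_query: str
    aligned_target: str
    identity: float
    coverage_query: float
    coverage_target: float

    @property
    def is_empty(self) -> bool:
        return self.query_span == (0, 0)


@lru_cache(maxsize=8)
def _pairwise_aligner(matrix: str, gap_open: float, gap_extend: float, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode=mode)
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython charges open_gap_score for the first gapped position; shift by
    # one extension so a length-g gap costs gap_open + g * gap_extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bit_score(raw_score: float, scheme: ScoringScheme) -> float:
    """Normalized (bit) score: ``(lambda * S - ln K) / ln 2``."""
    return (scheme.lam * raw_score - math.log(scheme.k)) / LN2


def evalue(bits: float, m: int, n: int) -> float:
    """Karlin–Altschul expectation ``E = m * n * 2**(-bits)``.

    ``m`` and ``n`` are the query length and the total database length in
    residues.  No edge-effect (effective length) correction is applied.
    """
    if m <= 0 or n <= 0:
        raise ValueError("search-space sizes must be positive")
    return m * n * math.pow(2.0, -bits)


def _empty_alignment(scheme: ScoringScheme, m: int, n: int) -> LocalAlignment:
    bits = bit_score(0.0, scheme)
    return LocalAlignment(
        score=0.0,
        bit_score=bits,
        evalue=evalue(bits, m, n),
        query_span=(0, 0),
        target_span=(0, 0),
        aligned_query="",
        aligned_target="",
        identity=0.0,
        coverage_query=0.0,
        coverage_target=0.0,
    )


def smith_waterman(
    query: str,
    target: str,
    scheme: ScoringScheme | None = None,
    *,
    m: int | None = None,
    n: int | None = None,
) -> LocalAlignment:
    """Optimal local alignment of ``query`` against ``target``.

    Parameters
    ----------
    query, target
        Amino-acid strings (non-empty).
    scheme
        Scoring scheme; defaults to gapped BLOSUM62.
    m, n
        Search-space sizes for the E-value.  Default to the two sequence
        lengths (single pairwise comparison); callers searching a database
        should pass the total database length as ``n``.

    When several alignments share the optimal score the first traceback
    reported by the engine is used, which is deterministic for fixed inputs.
    A pair with no positive-scoring cell yields the empty alignment
    (score 0, identity and coverage 0).
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    m = m if m is not None else len(query)
    n = n if n is not None else len(target)
    aligner = _pairwise_aligner(scheme.matrix, scheme.gap_open, scheme.gap_extend, "local")
    score = aligner.score(target, query)
    if score <= 0:
        return _empty_alignment(scheme, m, n)
    aln = aligner.align(target, query)[0]
    target_blocks, query_blocks = (aln.aligned[0], aln.aligned[1])

    gapped_q: list[str] = []
    gapped_t: list[str] = []
    prev_t = target_blocks[0][0]
    prev_q = query_blocks[0][0]
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        if qs > prev_q:  # insertion in query relative to target
            gapped_q.append(query[prev_q:qs])
            gapped_t.append("-" * (qs - prev_q))
        if ts > prev_t:  # deletion in query relative to target
            gapped_q.append("-" * (ts - prev_t))
            gapped_t.append(target[prev_t:ts])
        gapped_q.append(query[qs:qe])
        gapped_t.append(target[ts:te])
        prev_q, prev_t = qe, te
    aligned_query = "".join(gapped_q)
    aligned_target = "".join(gapped_t)
    assert len(aligned_query) == len(aligned_target)

    columns = len(aligned_query)
    matches = sum(1 for x, y in zip(aligned_query, aligned_target) if x == y and x != "-")
    q_start, q_end = int(query_blocks[0][0]) + 1, int(query_blocks[-1][1])
    t_start, t_end = int(target_blocks[0][0]) + 1, int(target_blocks[-1][1])
    bits = bit_score(score, scheme)
    return LocalAlignment(
        score=float(score),
        bit_score=bits,
        evalue=evalue(bits, m, n),
        query_span=(q_start, q_end),
        target_span=(t_start, t_end),
        aligned_query=aligned_query,
        aligned_target=aligned_target,
        identity=matches / columns,
        coverage_query=(q_end - q_start + 1) / len(query),
        coverage_target=(t_end - t_start + 1) / len(target),
    )


def local_score(query: str, target: str, scheme: ScoringScheme | None = None) -> float:
    """Optimal local alignment score only (no traceback); faster than
    :func:`smith_waterman` when identity/coverage are not needed."""
    scheme = scheme or ScoringScheme()
    aligner = _pairwise_aligner(scheme.matrix, scheme.gap_open, scheme.gap_extend, "local")
    return float(aligner.score(target, query))


def global_alignment(a: str, b: str, scheme: ScoringScheme | None = None) -> tuple[str, str]:
    """Global (Needleman–Wunsch, affine) alignment of two sequences,
    returned as a pair of equal-length gapped strings."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    aligner = _pairwise_aligner(scheme.matrix, scheme.gap_open, scheme.gap_extend, "global")
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def shares_kmer(a: str, b: str, k: int = 4) -> bool:
    """Exact shared k-mer test used as an optional alignment prefilter."""
    if len(a) < k or len(b) < k:
        return a in b or b in a
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))
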