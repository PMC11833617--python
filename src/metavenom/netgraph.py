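"""Sequence-similarity networks, center-star alignments and consensus
motifs over biopanning hit lists.

Hits from a screen are arranged in an undirected graph: peptides are nodes
(tagged with their originating library) and two peptides are connected when
their optimal local alignment reaches an E-value below the build threshold
(0.001 by default), with the bit score as the edge weight.  Clusters are
the connected components with at least three members; each cluster's
sequences are multiply aligned with a center-star procedure (all sequences
aligned pairwise to the sequence with the highest summed pairwise score,
gaps merged under "once a gap, always a gap"), from which a
position-frequency matrix, a majority consensus and the set of fully
conserved cysteine columns are derived.  Parity with progressive aligners
such as Clustal Omega is not claimed; the center-star construction is a
deterministic, in-repo approximation whose sum-of-pairs score is within a
factor of two of optimal.

Best-hit annotation against an annotated reference switches stringency on
query length: queries of at most 30 aa keep their best hit regardless of
E-value (short peptides cannot reach conventional significance), longer
queries require E <= 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .align import ScoringScheme, bit_score, evalue, global_alignment, local_score, smith_waterman

__all__ = [
    "ConsensusMotif",
    "build_graph",
    "extract_clusters",
    "center_star_msa",
    "consensus_motif",
    "annotate_best_hit",
    "write_graph",
]

GAP = "-"
SHORT_QUERY_MAX = 30


@dataclass
class ConsensusMotif:
    """Consensus description of one cluster's alignment.

    ``pfm`` has one column per MSA position and one row per symbol
    (residues and the gap); each column sums to 1.  ``consensus`` marks
    positions without a majority symbol as ``x``; ``conserved_cys`` lists
    0-based columns where every row has a cysteine.
    """

    cluster_id: str
    pfm: pd.DataFrame
    consensus: str
    conserved_cys: list[int]


def build_graph(
    peptides: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
    evalue_threshold: float = 1e-3,
    *,
    libraries: Mapping[str, str] | None = None,
) -> nx.Graph:
    """All-vs-all similarity graph over (id, sequence) pairs.

    E-values use the query length against the summed length of all
    peptides (the database the screen hits were drawn from).  Nodes carry
    ``sequence`` and optional ``library`` attributes; edges carry
    ``bit_score`` and ``evalue``.  Node order is canonicalized so the graph
    is invariant to input order.
    """
    if not peptides:
        raise ValueError("need at least one peptide")
    scheme = scheme or ScoringScheme()
    items = sorted(peptides)
    db_len = sum(len(s) for _, s in items)
    g = nx.Graph()
    for pid, seq in items:
        g.add_node(pid, sequence=seq, library=(libraries or {}).get(pid, ""))
    for i in range(len(items)):
        pid, pseq = items[i]
        for j in range(i + 1, len(items)):
            qid, qseq = items[j]
            score = local_score(pseq, qseq, scheme)
            if score <= 0:
                continue
            bits = bit_score(score, scheme)
            e = evalue(bits, len(pseq), db_len)
            if e < evalue_threshold:
                g.add_edge(pid, qid, bit_score=bits, evalue=e)
    return g


def extract_clusters(g: nx.Graph, min_size: int = 3) -> list[list[str]]:
    """Connected components with at least ``min_size`` members, each sorted,
    ordered by (descending size, first member)."""
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= min_size]
    return sorted(comps, key=lambda c: (-len(c), c[0]))


def _merge_into_master(master: list[str], aln_center: str, aln_other: str) -> tuple[list[str], str]:
    """Merge one pairwise (center, other) alignment into the master gapped
    center; returns gap positions to insert into existing rows and the
    other row padded to the master width."""
    out_master: list[str] = []
    out_other: list[str] = []
    inserts: list[int] = []  # columns inserted into the existing master
    i = j = 0
    while i < len(master) or j < len(aln_center):
        mc = master[i] if i < len(master) else None
        ac = aln_center[j] if j < len(aln_center) else None
        if mc == GAP and ac != GAP:
            out_master.append(GAP)
            out_other.append(GAP)
            i += 1
        elif ac == GAP and (mc != GAP or mc is None):
            out_master.append(GAP)
            out_other.append(aln_other[j])
            inserts.append(len(out_master) - 1)
            j += 1
        elif mc == GAP and ac == GAP:
            out_master.append(GAP)
            out_other.append(aln_other[j])
            i += 1
            j += 1
        else:
            out_master.append(mc)
            out_other.append(aln_other[j])
            i += 1
            j += 1
    return inserts, "".join(out_other)


def center_star_msa(
    seqs: Sequence[tuple[str, str]],
    scheme: ScoringScheme | None = None,
) -> list[tuple[str, str]]:
    """Center-star multiple alignment of (id, sequence) pairs.

    The center is the sequence maximizing the summed global pairwise
    alignment score against all others (ties: lexicographically smaller
    id).  Every other sequence is aligned to the center globally; center
    gaps are merged across pairwise alignments ("once a gap, always a
    gap").  Rows are returned in the input order, all of equal width;
    removing gaps from any row recovers its input sequence.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    scheme = scheme or ScoringScheme()
    from .align import _pairwise_aligner  # reuse the cached engine

    aligner = _pairwise_aligner(scheme.matrix, scheme.gap_open, scheme.gap_extend, "global")
    n = len(seqs)
    sums = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            s = float(aligner.score(seqs[i][1], seqs[j][1]))
            sums[i] += s
            sums[j] += s
    center_idx = min(range(n), key=lambda i: (-sums[i], seqs[i][0]))
    center_id, center_seq = seqs[center_idx]

    master = list(center_seq)
    rows: dict[str, str] = {center_id: ""}  # filled at the end from master
    for sid, seq in seqs:
        if sid == center_id:
            continue
        aln_c, aln_s = global_alignment(center_seq, seq, scheme)
        inserts, padded = _merge_into_master(master, aln_c, aln_s)
        if inserts:
            for rid, row in rows.items():
                if rid == center_id:
                    continue
                chars = list(row)
                for col in inserts:
                    chars.insert(col, GAP)
                rows[rid] = "".join(chars)
            new_master = []
            k = 0
            for col in range(len(master) + len(inserts)):
                if col in set(inserts):
                    new_master.append(GAP)
                else:
                    new_master.append(master[k])
                    k += 1
            master = new_master
        rows[sid] = padded
    rows[center_id] = "".join(master)
    width = len(rows[center_id])
    for sid in rows:
        rows[sid] = rows[sid].ljust(width, GAP)
    return [(sid, rows[sid]) for sid, _ in seqs]


def consensus_motif(
    msa: Sequence[tuple[str, str]],
    min_fraction: float = 0.5,
    cluster_id: str = "",
) -> ConsensusMotif:
    """Position-frequency matrix and majority consensus of an MSA.

    Each PFM column sums to 1 over residues plus the gap symbol.  The
    consensus takes the most frequent symbol per column when its fraction
    reaches ``min_fraction`` (ties broken toward the lexicographically
    smaller symbol, with the gap sorting after residues), else ``x``.
    ``conserved_cys`` lists columns where the cysteine fraction is exactly
    1.
    """
    if not msa:
        raise ValueError("empty alignment")
    rows = [s for _, s in msa]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment")
    symbols = sorted({c for r in rows for c in r} - {GAP}) + [GAP]
    counts = np.zeros((len(symbols), width))
    index = {c: i for i, c in enumerate(symbols)}
    for r in rows:
        for col, c in enumerate(r):
            counts[index[c], col] += 1
    freqs = counts / len(rows)
    pfm = pd.DataFrame(freqs, index=symbols)
    consensus = []
    for col in range(width):
        order = sorted(range(len(symbols)), key=lambda i: (-freqs[i, col], symbols[i]))
        top = order[0]
        consensus.append(symbols[top] if freqs[top, col] >= min_fraction else "x")
    cys = [
        col
        for col in range(width)
        if "C" in index and counts[index["C"], col] == len(rows)
    ]
    return ConsensusMotif(
        cluster_id=cluster_id, pfm=pfm, consensus="".join(consensus), conserved_cys=cys
    )


def annotate_best_hit(
    queries: Sequence[tuple[str, str]],
    reference: Sequence[tuple[str, str]],
    metadata: Mapping[str, Mapping[str, str]] | None = None,
    scheme: ScoringScheme | None = None,
    *,
    strict_evalue: float = 1e-3,
    short_query_max: int = SHORT_QUERY_MAX,
) -> pd.DataFrame:
    """Best-hit annotation of queries against an annotated reference.

    For each query the reference entry with the lowest E-value is taken.
    Queries up to ``short_query_max`` residues accept their best hit
    regardless of E-value (reported verbatim); longer queries require
    ``E <= strict_evalue``.  ``metadata`` maps reference ids to fields such
    as ``name`` and ``lineage`` copied onto annotated queries.  Queries
    without an accepted hit get an empty annotation.
    """
    scheme = scheme or ScoringScheme()
    metadata = metadata or {}
    db_len = sum(len(s) for _, s in reference)
    rows = []
    for qid, qseq in queries:
        best = None
        for rid, rseq in reference:
            aln = smith_waterman(qseq, rseq, scheme, n=db_len)
            if aln.score <= 0:
                continue
            if best is None or aln.evalue < best[1].evalue:
                best = (rid, aln)
        accepted = best is not None and (
            len(qseq) <= short_query_max or best[1].evalue <= strict_evalue
        )
        meta = metadata.get(best[0], {}) if accepted else {}
        rows.append(
            {
                "query": qid,
                "hit": best[0] if accepted else "",
                "name": meta.get("name", ""),
                "lineage": meta.get("lineage", ""),
                "evalue": best[1].evalue if accepted else np.nan,
                "bit_score": best[1].bit_score if accepted else np.nan,
                "identity": best[1].identity if accepted else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("query")


def write_graph(g: nx.Graph, edge_tsv: str | Path, graphml: str | Path | None = None) -> None:
    """Emit the similarity graph as an edge-list TSV (and GraphML)."""
    with Path(edge_tsv).open("w") as fh:
        fh.write("source\ttarget\tbit_score\tevalue\n")
        for u, v, d in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['bit_score']:.4g}\t{d['evalue']:.4g}\n")
    if graphml is not None:
        nx.write_graphml(g, str(graphml))
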