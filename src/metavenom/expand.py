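"""Metavenome expansion: recruit venom-like sequences from a metagenomic
candidate pool and reduce them to a compact, deduplicated library.

The cascade mirrors the library-design funnel of the display platform:

1. homology search of the parent venom library against the pool (bounded
   iterative re-query: sequences accepted in one round become queries for
   the next, capturing transitive recruitment);
2. prefilter: drop pool sequences identical to a parent and those longer
   than 100 aa;
3. greedy clustering at 50% identity and 95% bidirectional coverage
   (CD-HIT-style: longest sequence founds a cluster, later sequences join
   the first representative meeting both thresholds);
4. removal of representatives that still overlap a parent at the same
   thresholds, then the final <= 90 aa length filter.

All ordering rules are deterministic, so the pipeline output is invariant
to input permutation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .align import LocalAlignment, ScoringScheme, local_score, bit_score, evalue, shares_kmer, smith_waterman

__all__ = [
    "ClusterParams",
    "HomologyHit",
    "Cluster",
    "find_homologs",
    "hits_per_query",
    "prefilter",
    "greedy_cluster",
    "dedup_against_parents",
    "build_metavenome",
]

Seq = tuple[str, str]  # (id, sequence)


@dataclass(frozen=True)
class ClusterParams:
    """Threshold bundle for the expansion cascade."""

    min_identity: float = 0.50
    min_coverage: float = 0.95  # bidirectional
    prefilter_max_len: int = 100
    final_max_len: int = 90
    search_rounds: int = 2
    search_evalue: float = 1e-3
    kmer_prefilter: int | None = None  # e.g. 4 to require a shared 4-mer

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1 or not 0 < self.min_coverage <= 1:
            raise ValueError("identity and coverage thresholds must be in (0, 1]")
        if self.prefilter_max_len < self.final_max_len:
            raise ValueError("prefilter_max_len must be >= final_max_len")


@dataclass
class HomologyHit:
    query_id: str
    target_id: str
    alignment: LocalAlignment


@dataclass
class Cluster:
    representative: str
    members: list[str]
    member_stats: dict[str, tuple[float, float, float]]  # id -> (identity, cov_rep, cov_member)


def _passes(aln: LocalAlignment, params: ClusterParams) -> bool:
    return (
        aln.identity >= params.min_identity
        and aln.coverage_query >= params.min_coverage
        and aln.coverage_target >= params.min_coverage
    )


def find_homologs(
    queries: Sequence[Seq],
    pool: Sequence[Seq],
    params: ClusterParams = ClusterParams(),
    scheme: ScoringScheme | None = None,
) -> list[HomologyHit]:
    """Iterative homology search of the queries against the pool.

    Each pool sequence is reported at most once, with its best-scoring
    originating query (for sequences recruited in a later round, the root
    query whose chain recruited them).  Hits must have
    ``E <= params.search_evalue`` with the E-value computed against the
    total pool length.
    """
    if not queries or not pool:
        raise ValueError("queries and pool must be non-empty")
    scheme = scheme or ScoringScheme()
    db_len = sum(len(s) for _, s in pool)
    remaining = dict(pool)
    accepted: dict[str, tuple[str, float]] = {}  # target -> (root query, score)
    round_queries: list[tuple[str, str, str]] = [(qid, seq, qid) for qid, seq in queries]
    for _ in range(max(1, params.search_rounds)):
        newly: list[tuple[str, str, str]] = []
        for qid, qseq, root in round_queries:
            for tid, tseq in list(remaining.items()):
                if params.kmer_prefilter and not shares_kmer(qseq, tseq, params.kmer_prefilter):
                    continue
                score = local_score(qseq, tseq, scheme)
                if score <= 0:
                    continue
                e = evalue(bit_score(score, scheme), len(qseq), db_len)
                if e > params.search_evalue:
                    continue
                prev = accepted.get(tid)
                if prev is None or score > prev[1]:
                    accepted[tid] = (root, score)
                if prev is None:
                    newly.append((tid, tseq, root))
                    del remaining[tid]
        if not newly:
            break
        round_queries = newly
    qseqs = dict(queries)
    pool_seqs = dict(pool)
    hits = []
    for tid in sorted(accepted):
        root, _ = accepted[tid]
        qseq = qseqs.get(root)
        if qseq is None:  # root was itself recruited; fall back to its sequence
            qseq = pool_seqs[root]
        aln = smith_waterman(qseq, pool_seqs[tid], scheme, n=db_len)
        hits.append(HomologyHit(query_id=root, target_id=tid, alignment=aln))
    return hits


def hits_per_query(hits: Sequence[HomologyHit]) -> Counter:
    """Number of recruited pool sequences per originating query."""
    return Counter(h.query_id for h in hits)


def prefilter(
    hits: Sequence[HomologyHit],
    queries: Sequence[Seq],
    pool: Sequence[Seq],
    params: ClusterParams = ClusterParams(),
) -> list[Seq]:
    """Drop hit targets identical to any query or longer than the prefilter
    length cap; returns the surviving (id, sequence) pairs in hit order."""
    query_seqs = {s for _, s in queries}
    pool_seqs = dict(pool)
    out = []
    for h in hits:
        seq = pool_seqs[h.target_id]
        if seq in query_seqs or len(seq) > params.prefilter_max_len:
            continue
        out.append((h.target_id, seq))
    return out


def greedy_cluster(
    seqs: Sequence[Seq],
    params: ClusterParams = ClusterParams(),
    scheme: ScoringScheme | None = None,
) -> list[Cluster]:
    """CD-HIT-style greedy clustering.

    Sequences are visited longest first (ties by id); each joins the first
    existing representative it matches at ``min_identity`` and bidirectional
    ``min_coverage`` (measured on the optimal local alignment), else founds
    a new cluster.  Every input sequence lands in exactly one cluster.
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    scheme = scheme or ScoringScheme()
    ordered = sorted(seqs, key=lambda p: (-len(p[1]), p[0]))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    for sid, seq in ordered:
        placed = False
        for cluster, rseq in zip(clusters, rep_seqs):
            if params.kmer_prefilter and not shares_kmer(rseq, seq, params.kmer_prefilter):
                continue
            aln = smith_waterman(rseq, seq, scheme)
            if _passes(aln, params):
                cluster.members.append(sid)
                cluster.member_stats[sid] = (
                    aln.identity, aln.coverage_query, aln.coverage_target,
                )
                placed = True
                break
        if not placed:
            clusters.append(
                Cluster(representative=sid, members=[sid], member_stats={sid: (1.0, 1.0, 1.0)})
            )
            rep_seqs.append(seq)
    return clusters


def dedup_against_parents(
    representatives: Sequence[Seq],
    parents: Sequence[Seq],
    params: ClusterParams = ClusterParams(),
    scheme: ScoringScheme | None = None,
) -> tuple[list[Seq], pd.DataFrame]:
    """Drop representatives that overlap any parent at the clustering
    thresholds, then apply the final length filter.

    Returns the surviving (id, sequence) pairs and a provenance table with
    each survivor's best-scoring parent (by bit score) and its identity and
    coverage to that parent.
    """
    scheme = scheme or ScoringScheme()
    survivors: list[Seq] = []
    rows = []
    for rid, rseq in representatives:
        excluded = False
        best: tuple[float, str, LocalAlignment] | None = None
        for pid, pseq in parents:
            aln = smith_waterman(rseq, pseq, scheme)
            if _passes(aln, params):
                excluded = True
                break
            if aln.score > 0 and (best is None or aln.score > best[0]):
                best = (aln.score, pid, aln)
        if excluded or len(rseq) > params.final_max_len:
            continue
        survivors.append((rid, rseq))
        rows.append(
            {
                "id": rid,
                "best_parent": best[1] if best else "",
                "identity": best[2].identity if best else float("nan"),
                "coverage": min(best[2].coverage_query, best[2].coverage_target)
                if best
                else float("nan"),
                "bit_score": best[2].bit_score if best else float("nan"),
            }
        )
    prov = pd.DataFrame(rows, columns=["id", "best_parent", "identity", "coverage", "bit_score"])
    return survivors, prov.set_index("id") if len(prov) else prov


def build_metavenome(
    parents: Sequence[Seq],
    pool: Sequence[Seq],
    params: ClusterParams = ClusterParams(),
    scheme: ScoringScheme | None = None,
) -> dict:
    """Run the full expansion cascade; returns a dict of stage outputs
    (hits, prefiltered, clusters, metavenome, provenance)."""
    hits = find_homologs(parents, pool, params, scheme)
    surviving = prefilter(hits, parents, pool, params)
    if not surviving:
        return {
            "hits": hits,
            "prefiltered": [],
            "clusters": [],
            "metavenome": [],
            "provenance": pd.DataFrame(),
        }
    clusters = greedy_cluster(surviving, params, scheme)
    seq_by_id = dict(surviving)
    reps = [(c.representative, seq_by_id[c.representative]) for c in clusters]
    final, prov = dedup_against_parents(reps, parents, params, scheme)
    return {
        "hits": hits,
        "prefiltered": surviving,
        "clusters": clusters,
        "metavenome": final,
        "provenance": prov,
    }
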