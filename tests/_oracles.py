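"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's alignment engine: the local-alignment
oracle is a plain three-state (Gotoh) dynamic program in pure Python, and
the conditional binomial tail is an explicit summation.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def sw_score_bruteforce(a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0) -> float:
    """Optimal local alignment score, affine gaps (length-g gap costs
    ``gap_open + g * gap_extend``), by explicit three-state DP."""
    la, lb = len(a), len(b)
    first = gap_open + gap_extend
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]  # ends in a match/mismatch
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # ends in gap in b
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # ends in gap in a
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1], 0.0) + s
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def conditional_binomial_tail(y_target: int, y_control: int, frac: float) -> float:
    """P(Y >= y_target | Y + Y' = s) for Y ~ Binom(s, frac), by explicit
    summation of binomial probabilities."""
    s = y_target + y_control
    total = 0.0
    for y in range(y_target, s + 1):
        total += math.comb(s, y) * frac**y * (1 - frac) ** (s - y)
    return total


def greedy_cluster_reference(seqs, min_identity, min_coverage, align_fn):
    """Reference implementation of the greedy clustering rule: visit longest
    first (ties by id), join the first representative meeting identity and
    bidirectional coverage thresholds, else found a new cluster.  Returns a
    list of (representative id, member id list)."""
    ordered = sorted(seqs, key=lambda p: (-len(p[1]), p[0]))
    clusters: list[tuple[str, str, list[str]]] = []  # (rep id, rep seq, members)
    for sid, seq in ordered:
        for k, (rid, rseq, members) in enumerate(clusters):
            aln = align_fn(rseq, seq)
            if (
                aln.identity >= min_identity
                and aln.coverage_query >= min_coverage
                and aln.coverage_target >= min_coverage
            ):
                members.append(sid)
                break
        else:
            clusters.append((sid, seq, [sid]))
    return [(rid, members) for rid, _, members in clusters]


def connected_components_dfs(nodes, edges):
    """Brute-force connected components by iterative DFS."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen: set = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        stack, comp = [n], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)
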