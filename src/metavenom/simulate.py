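"""Synthetic fixtures for the whole pipeline: venom-like annotated parent
records, metagenomic candidate pools with planted homologs, and
NB-distributed screen count matrices with spiked enrichments.

All generators are pure functions of (configuration, seed).  Defaults are
chosen to emulate the shape of real venom libraries: parent precursors with
a median length near 110 aa whose annotated mature region has a median near
62 aa; a cysteine-class mix of roughly 8% cysteine-free, 22% odd-count and
70% even-count members (so ~90% of members carry at least two cysteines and
can form disulfide bonds); about seven recruited metagenomic homologs per
parent; and log-normally skewed clone abundances in sequencing libraries.

What these generators deliberately do not model: sequencing errors and
quality scores, PCR amplification bias, and real phylogenetic structure
among homologs (homologs are i.i.d. mutated copies of their source).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrich import CountMatrix, CONTROL, TARGET
from .records import MaturePeptide, ParentRecord, ProcessingFeature

__all__ = [
    "make_parent_db",
    "mutate_to_identity",
    "PoolSimConfig",
    "make_homolog_pool",
    "ScreenSimConfig",
    "simulate_screen",
    "emit_reads",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_CYS = AA20.replace("C", "")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def make_parent_db(
    n: int,
    seed: int | np.random.Generator,
    *,
    parent_median: float = 110.0,
    parent_sigma: float = 0.6,
    mature_median: float = 62.0,
    mature_sigma: float = 0.35,
    cys_fracs: tuple[float, float, float] = (0.08, 0.22, 0.70),
    frac_unresolved: float = 0.0,
) -> list[ParentRecord]:
    """Generate venom-like parent records with one mature feature each.

    The mature length is log-normal with median ``mature_median``; each
    parent is the mature region plus a log-normal pro/signal extension sized
    so the parent length median sits near ``parent_median``.
    ``cys_fracs`` gives the probabilities of the (no-cysteine, odd-count,
    even-count) classes for the mature region; cysteines are placed at
    random positions inside the mature window.  With ``frac_unresolved`` a
    fraction of records carries an unresolved feature (begin ``?``) and so
    contributes no mature peptide, emulating precursors without processing
    annotations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    p_no, p_odd, p_even = cys_fracs
    records = []
    for i in range(n):
        # precursor = mature region + pro/signal extension, so the mature
        # length keeps its log-normal marginal while the parent median sits
        # near its own target
        mlen = max(10, int(round(rng.lognormal(math.log(mature_median), mature_sigma))))
        pad = max(5, int(round(rng.lognormal(math.log(max(parent_median - mature_median, 10.0)), parent_sigma))))
        plen = mlen + pad
        begin = int(rng.integers(1, plen - mlen + 2))
        end = begin + mlen - 1
        seq = list(rng.choice(list(AA_NO_CYS), size=plen))
        cls = rng.choice(3, p=[p_no, p_odd, p_even])
        if cls == 1:
            n_cys = 1 if rng.random() < 0.08 else int(rng.choice([3, 5, 7]))
        elif cls == 2:
            n_cys = int(rng.choice([2, 4, 6, 8]))
        else:
            n_cys = 0
        n_cys = min(n_cys, mlen)
        for pos in rng.choice(np.arange(begin - 1, end), size=n_cys, replace=False):
            seq[pos] = "C"
        if rng.random() < frac_unresolved:
            feature = ProcessingFeature(
                kind="PEPTIDE", begin=None, end=end, resolved=False,
                begin_raw="?", end_raw=str(end),
            )
        else:
            feature = ProcessingFeature(
                kind="PEPTIDE", begin=begin, end=end, resolved=True,
                begin_raw=str(begin), end_raw=str(end),
            )
        records.append(
            ParentRecord(
                accession=f"SYN{i:05d}",
                organism=f"Synthetica venomosa {i % 7}",
                lineage=("Synthozoa", f"Class{i % 5}"),
                sequence="".join(seq),
                features=(feature,),
            )
        )
    return records


def mutate_to_identity(
    seq: str,
    target_identity: float,
    seed: int | np.random.Generator,
    *,
    model: str = "substitution",
    indel_rate: float = 0.02,
    preserve_cys: bool = False,
    anchor: int = 2,
    full_coverage: bool = True,
) -> str:
    """Derive a homolog of ``seq`` at a controlled sequence identity.

    The default model applies exactly ``round((1 - target) * len)`` point
    substitutions at distinct positions (each to a uniformly drawn different
    residue), so the ungapped identity to the source equals the target by
    construction.  ``anchor`` terminal residues at each end are never
    mutated.  With ``full_coverage`` (the default) the planted homolog is
    additionally verified to align to its source end to end under the
    default local-alignment scheme, redrawing mutation positions otherwise;
    without this a dense mismatch run near a terminus can be trimmed by
    local alignment, silently breaking the full-coverage planting contract.
    With ``preserve_cys`` cysteine positions are kept and no substitution
    introduces a cysteine, conserving the disulfide signature.  The
    ``substitution+indel`` model additionally applies single-residue
    insertions/deletions at ``indel_rate`` per position, which loosens the
    identity guarantee slightly.
    """
    if not 0 < target_identity <= 1:
        raise ValueError("target_identity must be in (0, 1]")
    if model not in ("substitution", "substitution+indel"):
        raise ValueError(f"unknown mutation model {model!r}")
    rng = _rng(seed)
    n_mut = int(round((1.0 - target_identity) * len(seq)))
    mutable = [
        i
        for i in range(len(seq))
        if anchor <= i < len(seq) - anchor and not (preserve_cys and seq[i] == "C")
    ]
    n_mut = min(n_mut, len(mutable))
    alphabet = AA_NO_CYS if preserve_cys else AA20
    candidate = seq
    for _ in range(50):
        chars = list(seq)
        for i in rng.choice(mutable, size=n_mut, replace=False):
            choices = alphabet.replace(chars[i], "")
            chars[i] = choices[rng.integers(len(choices))]
        if model == "substitution+indel":
            out = []
            for i, c in enumerate(chars):
                if anchor <= i < len(chars) - anchor and rng.random() < indel_rate:
                    if rng.random() < 0.5:
                        continue  # deletion
                    out.append(alphabet[rng.integers(len(alphabet))])
                out.append(c)
            chars = out
        candidate = "".join(chars)
        if not full_coverage or _aligns_end_to_end(seq, candidate):
            return candidate
    return candidate


def _aligns_end_to_end(source: str, homolog: str) -> bool:
    from .align import smith_waterman

    aln = smith_waterman(source, homolog)
    return (
        not aln.is_empty
        and aln.query_span == (1, len(source))
        and aln.target_span == (1, len(homolog))
    )


@dataclass(frozen=True)
class PoolSimConfig:
    """Configuration for a metagenomic candidate pool with planted homologs."""

    homologs_per_parent_mean: float = 7.0
    identity_levels: tuple[float, ...] = (0.6, 0.7, 0.8)
    model: str = "substitution"
    indel_rate: float = 0.02
    preserve_cys: bool = True
    n_decoys: int = 200
    decoy_median_len: float = 62.0
    decoy_sigma: float = 0.35
    seed: int = 0


def make_homolog_pool(
    parents: Sequence[tuple[str, str]],
    cfg: PoolSimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Build a candidate pool of planted homologs plus random decoys.

    Each parent sequence receives ``Poisson(homologs_per_parent_mean)``
    homologs at identities drawn from ``identity_levels``; decoy sequences
    are unrelated random peptides.  Returns ``(pool, truth)`` where ``truth``
    records each planted homolog's source parent and target identity (decoys
    have source ``""``).  The pool is shuffled deterministically.
    """
    rng = _rng(cfg.seed)
    pool: list[tuple[str, str]] = []
    rows = []
    for pid, seq in parents:
        for h in range(rng.poisson(cfg.homologs_per_parent_mean)):
            ident = float(rng.choice(cfg.identity_levels))
            hom = mutate_to_identity(
                seq, ident, rng, model=cfg.model, indel_rate=cfg.indel_rate,
                preserve_cys=cfg.preserve_cys,
            )
            hid = f"MG_{pid}_{h}"
            pool.append((hid, hom))
            rows.append({"id": hid, "source": pid, "target_identity": ident})
    for d in range(cfg.n_decoys):
        dlen = max(15, int(round(rng.lognormal(math.log(cfg.decoy_median_len), cfg.decoy_sigma))))
        seq = "".join(rng.choice(list(AA20), size=dlen))
        did = f"DECOY{d:05d}"
        pool.append((did, seq))
        rows.append({"id": did, "source": "", "target_identity": np.nan})
    order = rng.permutation(len(pool))
    pool = [pool[i] for i in order]
    truth = pd.DataFrame(rows).set_index("id").loc[[p[0] for p in pool]]
    return pool, truth


@dataclass(frozen=True)
class ScreenSimConfig:
    """Configuration for a simulated single-round screen.

    Counts for clone i in sample j are NB with mean
    ``depth * pi_i * fc_i`` (``fc_i`` applies in target samples only) and
    dispersion ``phi``; baseline clone abundances ``pi`` are log-normal with
    shape ``abundance_sigma``, normalized to sum to 1.
    """

    n_clones: int = 2000
    n_target_reps: int = 3
    n_control_reps: int = 3
    depth: int = 100_000
    abundance_sigma: float = 1.0
    phi: float = 0.2
    spiked: tuple[tuple[int, float], ...] = ()  # (clone index, true fold-change)
    seed: int = 0


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def simulate_screen(cfg: ScreenSimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a triplicate target-vs-control screen with known truth.

    Returns the count matrix and a ground-truth table (clone, baseline
    abundance, true fold-change, is_spiked).
    """
    rng = _rng(cfg.seed)
    pi = rng.lognormal(0.0, cfg.abundance_sigma, cfg.n_clones)
    pi /= pi.sum()
    fc = np.ones(cfg.n_clones)
    for idx, f in cfg.spiked:
        if f <= 0:
            raise ValueError("spiked fold-changes must be positive")
        fc[idx] = f
    clones = [f"clone{i:05d}" for i in range(cfg.n_clones)]
    data = {}
    meta = []
    for r in range(cfg.n_control_reps):
        name = f"control_{r + 1}"
        data[name] = _nb_draw(rng, cfg.depth * pi, cfg.phi)
        meta.append({"sample": name, "group": CONTROL, "replicate": r + 1})
    for r in range(cfg.n_target_reps):
        name = f"target_{r + 1}"
        data[name] = _nb_draw(rng, cfg.depth * pi * fc, cfg.phi)
        meta.append({"sample": name, "group": TARGET, "replicate": r + 1})
    counts = pd.DataFrame(data, index=clones, dtype=np.int64)
    samples = pd.DataFrame(meta).set_index("sample")
    truth = pd.DataFrame(
        {"baseline": pi, "true_fc": fc, "is_spiked": fc != 1.0}, index=clones
    )
    return CountMatrix(counts=counts, samples=samples), truth


def emit_reads(
    inserts: Mapping[str, str],
    m: CountMatrix,
    out_dir: str | Path,
    *,
    shuffle_seed: int | np.random.Generator | None = 0,
) -> dict[str, Path]:
    """Write error-free per-sample FASTQ files realizing a count matrix.

    Each clone contributes its insert sequence verbatim, repeated per count,
    with dummy ``I`` qualities; read order is shuffled deterministically.
    Returns the per-sample file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = set(m.counts.index) - set(inserts)
    if missing:
        raise ValueError(f"clones without insert sequences: {sorted(missing)[:3]} ...")
    rng = _rng(shuffle_seed) if shuffle_seed is not None else None
    paths = {}
    for sample in m.counts.columns:
        col = m.counts[sample]
        reads = []
        for clone, count in col.items():
            reads.extend([(clone, inserts[clone])] * int(count))
        if rng is not None and reads:
            reads = [reads[i] for i in rng.permutation(len(reads))]
        path = out_dir / f"{sample}.fastq"
        with path.open("w") as fh:
            for i, (clone, seq) in enumerate(reads):
                fh.write(f"@{sample}.{i} {clone}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample] = path
    return paths
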