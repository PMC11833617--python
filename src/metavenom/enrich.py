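"""Single-round biopanning enrichment analysis.

After one round of affinity selection, each displayed clone is quantified by
counting sequencing reads that perfectly match its encoded insert, in
triplicate target and negative-control samples.  Enrichment of a clone is
then assessed with a negative-binomial (NB) model of the read counts:

* library-size normalization (total-count scaling, with a trimmed
  mean-of-ratios variant for matrices dominated by a few clones);
* a common NB dispersion estimated by method of moments on within-group
  replicate counts, with per-clone estimates shrunk toward the common value;
* a conditional two-group NB exact test of the target group sum against the
  control group sum, one-sided in the enrichment direction (the test
  conditions on the pooled sum of library-size-equalized counts and sums NB
  probabilities of outcomes at least as extreme); with dispersion 0 this
  reduces to the conditional binomial (Poisson two-sample) test;
* a maximum-likelihood style fold-change, the ratio of normalized group
  sums with a 0.5 pseudocount per group.

A clone is called a *hit* when it passes three simultaneous thresholds:
p-value below 0.001, fold-change of at least 5, and a raw read count of at
least 15 in at least two of the three target replicates.  The support rule
deliberately uses raw (not normalized) counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "HitCallCriteria",
    "DispersionModel",
    "count_reads",
    "read_fastq_sequences",
    "normalize",
    "estimate_dispersion",
    "exact_test",
    "score_enrichment",
    "call_hits",
    "representation_qc",
]

TARGET = "target"
CONTROL = "control"


@dataclass
class CountMatrix:
    """Clone x sample integer read counts with sample-group labels.

    ``counts`` has clone ids as the index and sample ids as columns;
    ``samples`` is indexed by sample id with columns ``group`` (``target`` or
    ``control``) and ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.counts.values.dtype, np.integer):
            raise ValueError("counts must be integer")
        unlabeled = set(self.counts.columns) - set(self.samples.index)
        if unlabeled:
            raise ValueError(f"unlabeled samples: {sorted(unlabeled)}")
        bad = set(self.samples["group"]) - {TARGET, CONTROL}
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")

    def group_columns(self, group: str) -> list[str]:
        labeled = self.samples.index[self.samples["group"] == group]
        return [s for s in self.counts.columns if s in set(labeled)]

    @classmethod
    def from_tsv(cls, counts_path: str | Path, groups_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = pd.read_csv(groups_path, sep="\t", index_col=0)
        return cls(counts=counts.astype(np.int64), samples=samples)

    def to_tsv(self, counts_path: str | Path, groups_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        self.samples.to_csv(groups_path, sep="\t")


@dataclass(frozen=True)
class HitCallCriteria:
    """The three-threshold replicate-consensus hit rule."""

    max_p: float = 0.001
    min_fold_change: float = 5.0
    min_support_count: int = 15
    min_support_reps: int = 2
    n_reps: int = 3

    def __post_init__(self) -> None:
        if min(self.max_p, self.min_fold_change, self.min_support_count) <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_support_reps > self.n_reps:
            raise ValueError("min_support_reps cannot exceed n_reps")


@dataclass
class DispersionModel:
    """Common NB dispersion with per-clone estimates shrunk toward it.

    ``phi(clone)`` returns ``(1 - weight) * phi_clone + weight * common``.
    """

    common: float
    per_clone: pd.Series
    weight: float = 0.8

    def phi(self, clone: str) -> float:
        raw = float(self.per_clone.get(clone, self.common))
        return (1.0 - self.weight) * raw + self.weight * self.common


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read sequences from a FASTQ file (qualities ignored)."""
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def count_reads(
    reads: Mapping[str, Iterable[str]],
    reference: Mapping[str, str],
    samples: pd.DataFrame,
    *,
    prefix_len: int | None = None,
) -> tuple[CountMatrix, pd.Series]:
    """Perfect-match read counting against the clone reference inserts.

    A read increments exactly one clone iff its sequence (or its
    ``prefix_len``-base prefix, when set) equals the clone's reference insert
    exactly; anything else is tallied as unmapped.  Returns the count matrix
    and the per-sample unmapped totals.
    """
    lookup: dict[str, str] = {}
    for clone, insert in reference.items():
        key = insert[:prefix_len] if prefix_len else insert
        if key in lookup:
            raise ValueError(
                f"ambiguous reference: clones {lookup[key]!r} and {clone!r} share an insert"
            )
        lookup[key] = clone
    clones = list(reference)
    data = {}
    unmapped = {}
    for sample, seqs in reads.items():
        col = dict.fromkeys(clones, 0)
        miss = 0
        for seq in seqs:
            key = seq[:prefix_len] if prefix_len else seq
            clone = lookup.get(key)
            if clone is None:
                miss += 1
            else:
                col[clone] += 1
        data[sample] = col
        unmapped[sample] = miss
    counts = pd.DataFrame(data, dtype=np.int64).reindex(index=clones, columns=list(reads))
    return CountMatrix(counts=counts, samples=samples), pd.Series(unmapped, dtype=np.int64)


def normalize(m: CountMatrix, method: str = "total", trim: float = 0.2) -> pd.Series:
    """Per-sample size factors; normalized counts are ``counts * factor``.

    ``total``: scale each sample to the mean library size, i.e.
    ``factor = mean(totals) / total``.  ``trimmed``: a trimmed
    mean-of-ratios variant (ratios to the geometric-mean reference clone
    profile, trimming ``trim`` of each tail) that is insensitive to a few
    dominant clones; factors are rescaled to geometric mean 1.
    """
    totals = m.counts.sum(axis=0).astype(float)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    if method == "total":
        return totals.mean() / totals
    if method == "trimmed":
        logref = np.log(m.counts.values + 0.5).mean(axis=1)
        ratios = np.log(m.counts.values + 0.5) - logref[:, None]
        r = np.exp(
            np.array([stats.trim_mean(ratios[:, j], trim) for j in range(ratios.shape[1])])
        )
        factors = 1.0 / r
        factors /= np.exp(np.mean(np.log(factors)))
        return pd.Series(factors, index=m.counts.columns)
    raise ValueError(f"unknown normalization method {method!r}")


def estimate_dispersion(
    m: CountMatrix,
    factors: pd.Series | None = None,
    *,
    weight: float = 0.8,
    prior: float = 0.1,
) -> DispersionModel:
    """Method-of-moments NB dispersion from within-group replicate counts.

    For each clone and each group with >= 2 replicates, the normalized
    counts give a sample mean ``mu`` and variance ``s2``; under the NB model
    ``E[s2] = mu + phi * mu**2``.  The common dispersion pools numerator
    ``s2 - mu`` and denominator ``mu**2 - s2/n`` (the unbiased estimate of
    ``mu**2``) over all clones and groups, clipped at 0.  Per-clone estimates
    use the same ratio per clone and are shrunk toward the common value with
    the given weight.  With no replicated group the configured prior is used.
    """
    if factors is None:
        factors = normalize(m)
    norm = m.counts * factors
    num = pd.Series(0.0, index=m.counts.index)
    den = pd.Series(0.0, index=m.counts.index)
    replicated = False
    for group in (TARGET, CONTROL):
        cols = m.group_columns(group)
        if len(cols) < 2:
            continue
        replicated = True
        sub = norm[cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        num += s2 - mu
        den += (mu**2 - s2 / len(cols)).clip(lower=0.0)
    if not replicated:
        logger.warning("no replicated group; falling back to prior dispersion %.3g", prior)
        return DispersionModel(common=prior, per_clone=pd.Series(prior, index=m.counts.index), weight=weight)
    total_den = float(den.sum())
    common = max(0.0, float(num.sum()) / total_den) if total_den > 0 else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        per = (num / den).replace([np.inf, -np.inf], np.nan).fillna(0.0).clip(lower=0.0)
    return DispersionModel(common=common, per_clone=per, weight=weight)


def _group_sum_logpmf(y: np.ndarray, mean: float, n_reps: int, phi: float) -> np.ndarray:
    """log pmf of a sum of ``n_reps`` iid NB(mean/n_reps, phi) counts, which
    is NB(mean, phi/n_reps); Poisson when phi == 0."""
    if phi <= 0:
        return stats.poisson.logpmf(y, mean)
    r = n_reps / phi
    return stats.nbinom.logpmf(y, r, r / (r + mean))


def exact_test(
    y_target: float,
    y_control: float,
    n_target: int,
    n_control: int,
    phi: float,
    *,
    pseudocount: float = 0.5,
) -> tuple[float, float]:
    """Conditional NB exact test of enrichment for one clone.

    ``y_target``/``y_control`` are the library-size-equalized (normalized)
    group sums, rounded to integers for the conditional distribution.
    Conditioning on ``s = y_t + y_c``, the null splits ``s`` between the
    groups in proportion to replicate numbers; the one-sided p-value sums
    the conditional probabilities of target sums at least as large as the
    one observed.  Returns ``(p_value, ml_fold_change)``.
    """
    fc = (y_target + pseudocount) / (y_control + pseudocount) * (n_control / n_target)
    yt = int(round(y_target))
    yc = int(round(y_control))
    s = yt + yc
    if s == 0:
        return 1.0, 1.0
    frac = n_target / (n_target + n_control)
    if phi <= 0:
        p = float(stats.binom.sf(yt - 1, s, frac))
        return min(p, 1.0), fc
    y = np.arange(s + 1)
    logp = _group_sum_logpmf(y, s * frac, n_target, phi) + _group_sum_logpmf(
        s - y, s * (1 - frac), n_control, phi
    )
    logz = logsumexp(logp)
    p = float(np.exp(logsumexp(logp[yt:]) - logz))
    return min(p, 1.0), fc


def score_enrichment(
    m: CountMatrix,
    *,
    dispersion: DispersionModel | None = None,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Run the NB exact test for every clone, target vs control.

    Returns a DataFrame indexed by clone with columns ``mean_target``,
    ``mean_control`` (normalized per-replicate means), ``ml_fold_change``,
    ``p_value``, ``bh_q`` (Benjamini-Hochberg adjusted p-values, reported
    for reference only; the hit rule thresholds the raw p-value).
    """
    if factors is None:
        factors = normalize(m)
    if dispersion is None:
        dispersion = estimate_dispersion(m, factors)
    t_cols = m.group_columns(TARGET)
    c_cols = m.group_columns(CONTROL)
    if not t_cols or not c_cols:
        raise ValueError("need at least one target and one control sample")
    norm = m.counts * factors
    sum_t = norm[t_cols].sum(axis=1)
    sum_c = norm[c_cols].sum(axis=1)
    pvals = np.empty(len(m.counts.index))
    fcs = np.empty(len(m.counts.index))
    for i, clone in enumerate(m.counts.index):
        pvals[i], fcs[i] = exact_test(
            float(sum_t.iloc[i]),
            float(sum_c.iloc[i]),
            len(t_cols),
            len(c_cols),
            dispersion.phi(clone),
            pseudocount=pseudocount,
        )
    out = pd.DataFrame(
        {
            "mean_target": sum_t / len(t_cols),
            "mean_control": sum_c / len(c_cols),
            "ml_fold_change": fcs,
            "p_value": pvals,
        },
        index=m.counts.index,
    )
    out["bh_q"] = stats.false_discovery_control(out["p_value"].values, method="bh")
    return out


def call_hits(
    results: pd.DataFrame,
    m: CountMatrix,
    criteria: HitCallCriteria = HitCallCriteria(),
) -> pd.DataFrame:
    """Apply the replicate-consensus hit rule.

    Adds ``support_reps`` (number of target replicates with raw count at
    least ``min_support_count``) and ``is_hit``.  Calls are invariant to row
    and column order.
    """
    t_cols = m.group_columns(TARGET)
    raw = m.counts.loc[results.index, t_cols]
    support = (raw >= criteria.min_support_count).sum(axis=1)
    out = results.copy()
    out["support_reps"] = support
    out["is_hit"] = (
        (out["p_value"] < criteria.max_p)
        & (out["ml_fold_change"] >= criteria.min_fold_change)
        & (support >= criteria.min_support_reps)
    )
    return out


def representation_qc(
    lib_a: pd.Series,
    lib_b: pd.Series,
    *,
    pseudocount: float = 0.5,
) -> tuple[pd.Series, dict[str, float]]:
    """Per-member representation ratio of library ``a`` relative to ``b``.

    The ratio is the member's relative abundance (read frequency, 0.5-read
    pseudocount) in ``a`` over its relative abundance in ``b``.  The summary
    reports the median ratio, the percentage of members detected (count > 0)
    in ``a``, and the percentage of members whose ratio lies within one
    log10 (plus or minus) of the median ratio.
    """
    lib_a, lib_b = lib_a.align(lib_b, join="inner")
    fa = (lib_a + pseudocount) / (lib_a + pseudocount).sum()
    fb = (lib_b + pseudocount) / (lib_b + pseudocount).sum()
    ratio = fa / fb
    med = float(ratio.median())
    within = (np.abs(np.log10(ratio) - math.log10(med)) <= 1.0).mean()
    summary = {
        "median_ratio": med,
        "pct_detected": float((lib_a > 0).mean() * 100.0),
        "pct_within_one_log": float(within * 100.0),
    }
    return ratio, summary
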