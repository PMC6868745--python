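"""Gene-pair REO screening: Fisher enrichment, apparent accuracy, rank spread.

Each candidate pair is oriented so that the within-sample pattern
``E(gene_a) > E(gene_b)`` is the SCC-indicating ordering; the orientation is
fixed on training data and stored with the pair.  Ties never satisfy the
pattern — equality falls to the ADC branch of the classification rule.
"""
from __future__ import annotations

import dataclasses
import logging
from itertools import combinations
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import fisher_exact, rankdata

from ._stats import bh_fdr
from .core_io import ADC, SCC, ExpressionMatrix
from .subtype_opposite import OppositeGeneSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GenePair:
    """Oriented gene pair: ``gene_a > gene_b`` within a sample indicates SCC."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"gene pair must involve two distinct genes, got {self.gene_a!r}")

    @property
    def unordered(self) -> frozenset[str]:
        return frozenset((self.gene_a, self.gene_b))

    def flipped(self) -> "GenePair":
        return GenePair(self.gene_b, self.gene_a)


@dataclasses.dataclass
class PairStats:
    """Screening statistics for one oriented pair."""

    pair: GenePair
    n_scc_pattern: int
    n_scc: int
    n_adc_pattern: int
    n_adc: int
    p: float
    fdr: float
    apparent_accuracy: float
    rank_diff: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_scc_pattern <= self.n_scc):
            raise ValueError("n_scc_pattern out of range")
        if not (0 <= self.n_adc_pattern <= self.n_adc):
            raise ValueError("n_adc_pattern out of range")


@dataclasses.dataclass
class AccuracyReport:
    """C/M-style agreement bookkeeping between signature calls and pathology."""

    C: int
    M: int
    accuracy: float
    sensitivity: float | None  # fraction of pADC called ADC
    specificity: float | None  # fraction of pSCC called SCC
    reclassified_to_scc: list[str]  # pADC samples called SCC
    reclassified_to_adc: list[str]  # pSCC samples called ADC
    n_adc: int = 0
    n_scc: int = 0

    def __post_init__(self) -> None:
        if self.C > self.M:
            raise ValueError("C cannot exceed M")
        if set(self.reclassified_to_scc) & set(self.reclassified_to_adc):
            raise ValueError("reclassification lists must be disjoint")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def reo_counts(m: ExpressionMatrix, pair: GenePair) -> tuple[int, int, int, int]:
    """Count samples per class exhibiting the strict SCC pattern Ea > Eb.

    Returns ``(n_scc_pattern, n_scc, n_adc_pattern, n_adc)``.
    """
    a = m.gene_row(pair.gene_a)
    b = m.gene_row(pair.gene_b)
    scc_idx = m.label_indices(SCC)
    adc_idx = m.label_indices(ADC)
    if len(scc_idx) == 0 or len(adc_idx) == 0:
        raise ValueError("reo_counts requires at least one sample of each tumor class")
    gt = a > b
    return int(gt[scc_idx].sum()), len(scc_idx), int(gt[adc_idx].sum()), len(adc_idx)


def fisher_one_sided(
    n_scc_pattern: int, n_scc: int, n_adc_pattern: int, n_adc: int
) -> float:
    """One-sided (greater-in-SCC) Fisher exact p for the 2x2 pattern table."""
    if n_scc <= 0 or n_adc <= 0:
        raise ValueError("fisher_one_sided requires non-empty groups")
    if not (0 <= n_scc_pattern <= n_scc and 0 <= n_adc_pattern <= n_adc):
        raise ValueError("invalid 2x2 table")
    table = [
        [n_scc_pattern, n_scc - n_scc_pattern],
        [n_adc_pattern, n_adc - n_adc_pattern],
    ]
    return float(fisher_exact(table, alternative="greater")[1])


def enumerate_pairs(gene_ids: Sequence[str]) -> list[GenePair]:
    """All unordered pairs as (lexicographically first, second) — n*(n-1)/2 of them."""
    ids = list(gene_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene ids")
    return [GenePair(a, b) for a, b in combinations(ids, 2)]


def pair_apparent_accuracy(m: ExpressionMatrix, pair: GenePair) -> AccuracyReport:
    """Apparent accuracy C/M of a single pair's REO rule against pathology labels.

    A sample is called SCC iff Ea > Eb.  Unlabeled (non-ADC/SCC) samples are
    excluded from the report and logged.
    """
    a = m.gene_row(pair.gene_a)
    b = m.gene_row(pair.gene_b)
    calls_scc = a > b
    return _accuracy_report(m, calls_scc)


def _accuracy_report(m: ExpressionMatrix, calls_scc: np.ndarray) -> AccuracyReport:
    labels = np.asarray(m.labels)
    labeled = (labels == ADC) | (labels == SCC)
    n_excluded = int((~labeled).sum())
    if n_excluded:
        logger.info("excluding %d unlabeled samples from accuracy report", n_excluded)
    if not labeled.any():
        raise ValueError("no ADC/SCC-labeled samples to score")
    is_scc = labels == SCC
    correct = calls_scc == is_scc
    C = int((correct & labeled).sum())
    M = int(labeled.sum())
    adc_mask = labeled & ~is_scc
    scc_mask = labeled & is_scc
    sens = float((correct & adc_mask).sum() / adc_mask.sum()) if adc_mask.any() else None
    spec = float((correct & scc_mask).sum() / scc_mask.sum()) if scc_mask.any() else None
    ids = np.asarray(m.sample_ids)
    return AccuracyReport(
        C=C,
        M=M,
        accuracy=C / M,
        sensitivity=sens,
        specificity=spec,
        reclassified_to_scc=[str(s) for s in ids[adc_mask & calls_scc]],
        reclassified_to_adc=[str(s) for s in ids[scc_mask & ~calls_scc]],
        n_adc=int(adc_mask.sum()),
        n_scc=int(scc_mask.sum()),
    )


def rank_diff_stat(m: ExpressionMatrix, pair: GenePair) -> float:
    """Between-class geometric-mean absolute within-sample rank difference.

    Genes are ranked within each sample over the full gene universe of the
    matrix (average ranks on ties).  Per class the statistic is the geometric
    mean over samples of |rank(a) - rank(b)|; the result is the square root
    of the product of the two class values.  A zero rank difference in a
    sample contributes 1 so the geometric mean stays defined.
    """
    ranks = rankdata(m.values, axis=0)
    return _rank_diff_from_ranks(m, ranks, pair)


def _rank_diff_from_ranks(m: ExpressionMatrix, ranks: np.ndarray, pair: GenePair) -> float:
    for g in (pair.gene_a, pair.gene_b):
        if not m.has_gene(g):
            raise KeyError(f"gene {g!r} not present in matrix")
    a = ranks[m._gene_index[pair.gene_a]]
    b = ranks[m._gene_index[pair.gene_b]]
    diff = np.maximum(np.abs(a - b), 1.0)
    vals = []
    for label in (ADC, SCC):
        idx = m.label_indices(label)
        if len(idx) == 0:
            raise ValueError(f"rank_diff_stat requires samples of class {label}")
        vals.append(float(np.exp(np.mean(np.log(diff[idx])))))
    return float(np.sqrt(vals[0] * vals[1]))


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def screen_pairs(
    m: ExpressionMatrix,
    genes: OppositeGeneSet | Iterable[str],
    fdr_alpha: float = 0.05,
    keep_all: bool = False,
) -> list[PairStats]:
    """Enumerate, orient, and Fisher-screen all pairs of candidate genes.

    All ``n*(n-1)/2`` unordered pairs are enumerated and oriented so the SCC
    pattern frequency is at least the ADC pattern frequency in the training
    data.  FDR is Benjamini-Hochberg over the full enumeration; pairs with
    ``fdr < fdr_alpha`` are retained (or all of them with ``keep_all``),
    sorted by apparent accuracy descending.
    """
    ids = list(genes.gene_ids) if isinstance(genes, OppositeGeneSet) else list(genes)
    if len(ids) < 2:
        raise ValueError("screen_pairs requires at least 2 candidate genes")
    missing = [g for g in ids if not m.has_gene(g)]
    if missing:
        raise KeyError(f"candidate genes not in matrix: {missing[:5]}")
    scc_idx = m.label_indices(SCC)
    adc_idx = m.label_indices(ADC)
    if len(scc_idx) == 0 or len(adc_idx) == 0:
        raise ValueError("screen_pairs requires labeled samples of both tumor classes")
    n_scc, n_adc = len(scc_idx), len(adc_idx)
    ranks = rankdata(m.values, axis=0)

    rows = {g: m.gene_row(g) for g in ids}
    stats: list[PairStats] = []
    pvals: list[float] = []
    for ga, gb in combinations(ids, 2):
        a, b = rows[ga], rows[gb]
        a_gt_b = a > b
        b_gt_a = b > a
        fwd_scc, fwd_adc = int(a_gt_b[scc_idx].sum()), int(a_gt_b[adc_idx].sum())
        rev_scc, rev_adc = int(b_gt_a[scc_idx].sum()), int(b_gt_a[adc_idx].sum())
        # orient to maximize (SCC pattern freq - ADC pattern freq); integers only
        if rev_scc * n_adc - rev_adc * n_scc > fwd_scc * n_adc - fwd_adc * n_scc:
            pair = GenePair(gb, ga)
            nsp, nap = rev_scc, rev_adc
        else:
            pair = GenePair(ga, gb)
            nsp, nap = fwd_scc, fwd_adc
        p = fisher_one_sided(nsp, n_scc, nap, n_adc)
        acc = (nsp + (n_adc - nap)) / (n_scc + n_adc)
        rd = _rank_diff_from_ranks(m, ranks, pair)
        stats.append(
            PairStats(
                pair=pair,
                n_scc_pattern=nsp,
                n_scc=n_scc,
                n_adc_pattern=nap,
                n_adc=n_adc,
                p=p,
                fdr=1.0,
                apparent_accuracy=acc,
                rank_diff=rd,
            )
        )
        pvals.append(p)
    fdrs = bh_fdr(pvals)
    for s, q in zip(stats, fdrs):
        s.fdr = float(q)
    if not keep_all:
        stats = [s for s in stats if s.fdr < fdr_alpha]
    stats.sort(key=lambda s: (-s.apparent_accuracy, s.fdr, s.pair.gene_a, s.pair.gene_b))
    logger.info("screen_pairs: %d candidate genes, %d pairs retained", len(ids), len(stats))
    return stats


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_pair_stats(stats: Sequence[PairStats], path: str | PathLike) -> None:
    """Write screening statistics as TSV, sorted by apparent accuracy descending."""
    ordered = sorted(
        stats, key=lambda s: (-s.apparent_accuracy, s.fdr, s.pair.gene_a, s.pair.gene_b)
    )
    with open(path, "w") as fh:
        fh.write(
            "gene_a\tgene_b\tn_scc_pattern\tn_scc\tn_adc_pattern\tn_adc\t"
            "p\tfdr\tapparent_accuracy\trank_diff\n"
        )
        for s in ordered:
            fh.write(
                f"{s.pair.gene_a}\t{s.pair.gene_b}\t{s.n_scc_pattern}\t{s.n_scc}\t"
                f"{s.n_adc_pattern}\t{s.n_adc}\t{s.p:.6g}\t{s.fdr:.6g}\t"
                f"{s.apparent_accuracy:.6f}\t{s.rank_diff:.6f}\n"
            )
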