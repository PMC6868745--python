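"""Per-gene tumor-vs-normal direction calls and subtype-opposite gene sets.

A *subtype-opposite* gene is significantly dysregulated versus normal
controls in both tumor subtypes but in opposite directions.  Sets discovered
in different cohorts are integrated by union, excluding any gene whose
unthresholded dysregulation direction in another cohort conflicts.
"""
from __future__ import annotations

import dataclasses
import logging
from os import PathLike
from typing import Callable, Mapping, Sequence

import numpy as np

from ._stats import bh_fdr, rank_sum_test
from .core_io import ExpressionMatrix

logger = logging.getLogger(__name__)

UP = "UP"
DOWN = "DOWN"

#: a two-sample test taking (tumor_values, normal_values) -> two-sided p
DETest = Callable[[np.ndarray, np.ndarray], float]


@dataclasses.dataclass(frozen=True)
class DirectionCall:
    """Tumor-vs-normal dysregulation direction for one gene in one subtype.

    ``direction`` is the sign of the median tumor-minus-normal shift and is
    defined (possibly ``None`` on an exact tie) for every gene regardless of
    significance — the unthresholded direction feeds the cross-cohort
    consistency check at integration time.
    """

    gene_id: str
    subtype: str
    direction: str | None
    p: float
    fdr: float
    significant: bool


@dataclasses.dataclass
class OppositeGeneSet:
    """Genes dysregulated in opposite directions in the two tumor subtypes."""

    dataset_id: str
    entries: list[tuple[str, str, str]]  # (gene_id, direction_in_ADC, direction_in_SCC)

    def __post_init__(self) -> None:
        for gene, d_adc, d_scc in self.entries:
            if d_adc == d_scc:
                raise ValueError(f"gene {gene!r} has identical directions in both subtypes")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _, _ in self.entries]

    def directions(self) -> dict[str, tuple[str, str]]:
        return {g: (a, s) for g, a, s in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


def median_shift_direction(tumor: np.ndarray, normal: np.ndarray) -> str | None:
    """Sign of (median tumor - median normal); ``None`` on an exact tie."""
    shift = float(np.median(tumor) - np.median(normal))
    if shift > 0:
        return UP
    if shift < 0:
        return DOWN
    return None


def call_directions(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    subtype: str,
    alpha: float = 0.05,
    test: DETest | None = None,
) -> list[DirectionCall]:
    """Call per-gene dysregulation direction of ``tumor`` vs ``normal``.

    The differential-expression engine is pluggable; the default is a
    two-sided Wilcoxon rank-sum test.  FDR is Benjamini-Hochberg over all
    genes tested.  Genes are aligned on the shared universe of the two
    matrices (order follows ``tumor``).
    """
    if tumor.n_samples < 2 or normal.n_samples < 2:
        raise ValueError("call_directions requires >= 2 samples in each group")
    if test is None:
        test = lambda t, n: rank_sum_test(t, n, alternative="two-sided")
    shared = [g for g in tumor.gene_ids if normal.has_gene(g)]
    if not shared:
        raise ValueError("tumor and normal matrices share no genes")
    pvals = np.empty(len(shared))
    directions: list[str | None] = []
    for i, g in enumerate(shared):
        t, n = tumor.gene_row(g), normal.gene_row(g)
        pvals[i] = test(t, n)
        directions.append(median_shift_direction(t, n))
    fdrs = bh_fdr(pvals)
    return [
        DirectionCall(
            gene_id=g,
            subtype=subtype,
            direction=d,
            p=float(p),
            fdr=float(q),
            significant=bool(q < alpha and d is not None),
        )
        for g, d, p, q in zip(shared, directions, pvals, fdrs)
    ]


def direction_table(calls: Sequence[DirectionCall]) -> dict[str, str | None]:
    return {c.gene_id: c.direction for c in calls}


def find_subtype_opposite(
    adc_calls: Sequence[DirectionCall],
    scc_calls: Sequence[DirectionCall],
    dataset_id: str = "",
) -> OppositeGeneSet:
    """Genes significant in both subtypes with opposite directions."""
    scc_by_gene = {c.gene_id: c for c in scc_calls}
    entries: list[tuple[str, str, str]] = []
    for a in adc_calls:
        s = scc_by_gene.get(a.gene_id)
        if s is None or not (a.significant and s.significant):
            continue
        if a.direction is None or s.direction is None:
            continue
        if a.direction != s.direction:
            entries.append((a.gene_id, a.direction, s.direction))
    return OppositeGeneSet(dataset_id=dataset_id, entries=entries)


def integrate_opposite_sets(
    sets: Sequence[OppositeGeneSet],
    all_directions: Mapping[str, Mapping[str, tuple[str | None, str | None]]],
) -> OppositeGeneSet:
    """Union the per-cohort subtype-opposite sets with a consistency filter.

    ``all_directions`` maps dataset_id -> gene -> (direction_in_ADC,
    direction_in_SCC) *without* statistical control.  A gene is excluded when

    * it appears in multiple input sets with conflicting stored directions, or
    * any cohort's unthresholded direction pair disagrees with its stored
      directions (an undefined direction — exact zero shift — counts as a
      conflict).

    The result is independent of the order in which the sets are supplied.
    """
    if not sets:
        raise ValueError("integrate_opposite_sets requires at least one input set")
    stored: dict[str, tuple[str, str]] = {}
    conflicted: set[str] = set()
    for s in sets:
        for gene, d_adc, d_scc in s.entries:
            prev = stored.get(gene)
            if prev is not None and prev != (d_adc, d_scc):
                conflicted.add(gene)
            stored.setdefault(gene, (d_adc, d_scc))
    excluded: list[str] = []
    entries: list[tuple[str, str, str]] = []
    for gene in sorted(stored):
        if gene in conflicted:
            excluded.append(gene)
            continue
        d_adc, d_scc = stored[gene]
        ok = True
        for ds_id, table in all_directions.items():
            if gene not in table:
                continue
            o_adc, o_scc = table[gene]
            if o_adc != d_adc or o_scc != d_scc:
                ok = False
                break
        if ok:
            entries.append((gene, d_adc, d_scc))
        else:
            excluded.append(gene)
    if excluded:
        logger.info(
            "integrate_opposite_sets: excluded %d direction-inconsistent genes", len(excluded)
        )
    return OppositeGeneSet(dataset_id="integrated", entries=entries)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_direction_calls(calls: Sequence[DirectionCall], path: str | PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tsubtype\tdirection\tp\tfdr\tsignificant\n")
        for c in calls:
            d = c.direction if c.direction is not None else "NA"
            fh.write(f"{c.gene_id}\t{c.subtype}\t{d}\t{c.p:.6g}\t{c.fdr:.6g}\t{int(c.significant)}\n")


def read_direction_calls(path: str | PathLike) -> list[DirectionCall]:
    calls: list[DirectionCall] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValueError("direction-call table missing header")
        for line in fh:
            gene, subtype, d, p, fdr, sig = line.rstrip("\n").split("\t")
            calls.append(
                DirectionCall(
                    gene_id=gene,
                    subtype=subtype,
                    direction=None if d == "NA" else d,
                    p=float(p),
                    fdr=float(fdr),
                    significant=bool(int(sig)),
                )
            )
    return calls
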