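"""Corroborating statistics: proliferation score, IHC staining index, marker contrasts.

These support reclassification calls made by the signature: a proliferation
score (mean of a configurable gene panel), a 16-point immunostaining index
with low/medium/high binning, crosstab percentages with Fisher exact tests,
and rank-based marker-gene contrasts between sample groups.
"""
from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import fisher_exact

from ._stats import rank_sum_test
from ._util import percent
from .core_io import ExpressionMatrix
from .pair_screen import fisher_one_sided
from .subtype_opposite import median_shift_direction

logger = logging.getLogger(__name__)

#: default subtype marker panel
DEFAULT_MARKER_PANEL: dict[str, tuple[str, ...]] = {
    "SCC": ("KRT5", "TP63"),
    "ADC": ("NAPSA", "TTF1"),
    "NE": ("CD56", "SYP", "CHGA"),
}


@dataclasses.dataclass(frozen=True)
class IHCScore:
    """Multiplicative staining index: intensity (1-4) x extent (1-4)."""

    intensity: int
    extent: int
    index: int
    category: str  # low / medium / high


def ihc_category(intensity: int, extent: int) -> IHCScore:
    """Score a staining read-out.

    index < 5 is low, 5-10 medium, 11-16 high; together the three bins
    partition the full 1..16 index range.
    """
    for name, v in (("intensity", intensity), ("extent", extent)):
        if not isinstance(v, (int, np.integer)) or not 1 <= v <= 4:
            raise ValueError(f"{name} must be an integer in 1..4, got {v!r}")
    index = int(intensity) * int(extent)
    if index < 5:
        category = "low"
    elif index <= 10:
        category = "medium"
    else:
        category = "high"
    return IHCScore(intensity=int(intensity), extent=int(extent), index=index, category=category)


def ihc_crosstab(
    high_a: int, total_a: int, high_b: int, total_b: int
) -> dict[str, float]:
    """Percentages and Fisher exact p-values for a two-class high/not-high table."""
    for name, v in (("high_a", high_a), ("total_a", total_a), ("high_b", high_b), ("total_b", total_b)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    if total_a <= 0 or total_b <= 0:
        raise ValueError("group totals must be positive")
    if high_a > total_a or high_b > total_b:
        raise ValueError("high counts cannot exceed group totals")
    table = [[high_a, total_a - high_a], [high_b, total_b - high_b]]
    return {
        "pct_a": percent(high_a, total_a),
        "pct_b": percent(high_b, total_b),
        "p_greater": fisher_one_sided(high_a, total_a, high_b, total_b),
        "p_two_sided": float(fisher_exact(table, alternative="two-sided")[1]),
    }


def proliferation_score(
    m: ExpressionMatrix,
    gene_list: Sequence[str],
    allow_missing: bool = False,
) -> dict[str, float]:
    """Per-sample mean expression over a proliferation gene panel.

    Higher scores indicate more proliferative activity.  Missing panel genes
    are an error unless ``allow_missing``, in which case the available subset
    is averaged with a warning.
    """
    genes = list(gene_list)
    if not genes:
        raise ValueError("proliferation gene list is empty")
    missing = [g for g in genes if not m.has_gene(g)]
    if missing:
        if not allow_missing:
            raise KeyError(f"proliferation genes missing from matrix: {missing[:5]}")
        logger.warning("proliferation_score: %d/%d panel genes missing", len(missing), len(genes))
        genes = [g for g in genes if m.has_gene(g)]
        if not genes:
            raise KeyError("no proliferation panel genes present in matrix")
    sub = np.vstack([m.gene_row(g) for g in genes])
    scores = sub.mean(axis=0)
    return dict(zip(m.sample_ids, map(float, scores)))


@dataclasses.dataclass(frozen=True)
class MarkerResult:
    gene_id: str
    direction: str | None  # UP/DOWN in group_a relative to group_b
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def marker_contrast(
    m: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    markers: Sequence[str] | Mapping[str, Sequence[str]] | None = None,
) -> list[MarkerResult]:
    """Rank-based differential expression of marker genes between two groups.

    ``direction`` is the sign of the median shift of group_a versus group_b;
    p-values come from a two-sided Wilcoxon rank-sum test.
    """
    a_ids, b_ids = list(group_a), list(group_b)
    if not a_ids or not b_ids:
        raise ValueError("both groups must be non-empty")
    if set(a_ids) & set(b_ids):
        raise ValueError("groups must be disjoint")
    if markers is None:
        markers = DEFAULT_MARKER_PANEL
    if isinstance(markers, Mapping):
        genes = [g for panel in markers.values() for g in panel]
    else:
        genes = list(markers)
    sindex = {s: i for i, s in enumerate(m.sample_ids)}
    for s in a_ids + b_ids:
        if s not in sindex:
            raise KeyError(f"sample {s!r} not present in matrix")
    ia = [sindex[s] for s in a_ids]
    ib = [sindex[s] for s in b_ids]
    out: list[MarkerResult] = []
    for g in genes:
        row = m.gene_row(g)
        va, vb = row[ia], row[ib]
        out.append(
            MarkerResult(
                gene_id=g,
                direction=median_shift_direction(va, vb),
                p=rank_sum_test(va, vb, alternative="two-sided"),
            )
        )
    return out
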