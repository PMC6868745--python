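"""Seed-based forward selection of gene-pair signatures.

A signature is an ordered set of oriented gene pairs with a strict-majority
voting rule: a sample is SCC iff more than half of its pairs' REOs vote SCC,
otherwise ADC (a tied vote falls to ADC).  Selection is fully deterministic:
the forward search is greedy with fixed candidate ordering and every tie is
broken by explicit, documented keys.
"""
from __future__ import annotations

import dataclasses
import json
import statistics
from os import PathLike
from typing import Any, Sequence

import numpy as np

from .core_io import ADC, SCC, ExpressionMatrix
from .pair_screen import GenePair, PairStats, _accuracy_report, rank_diff_stat

RULE_STRICT_MAJORITY = "strict_majority"


@dataclasses.dataclass
class Signature:
    """Oriented gene-pair set plus the strict-majority voting rule."""

    pairs: list[GenePair]
    rule: str = RULE_STRICT_MAJORITY
    provenance: dict[str, Any] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("signature must contain at least one pair")
        if self.rule != RULE_STRICT_MAJORITY:
            raise ValueError(f"unknown voting rule {self.rule!r}")
        seen = set()
        for p in self.pairs:
            if p.unordered in seen:
                raise ValueError(f"duplicate pair {sorted(p.unordered)} in signature")
            seen.add(p.unordered)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for p in self.pairs:
            for g in (p.gene_a, p.gene_b):
                if g not in out:
                    out.append(g)
        return out


#: the frozen published rule: a sample is SCC iff KRT5 expression exceeds AGR2
BUILTIN_SIGNATURE = Signature(
    pairs=[GenePair("KRT5", "AGR2")],
    provenance={"source": "built-in frozen KRT5/AGR2 rule"},
)


# ---------------------------------------------------------------------------
# voting helpers
# ---------------------------------------------------------------------------

def _vote_matrix(m: ExpressionMatrix, pairs: Sequence[GenePair]) -> np.ndarray:
    """Boolean (n_pairs, n_samples): pair votes SCC iff Ea strictly > Eb."""
    return np.vstack([m.gene_row(p.gene_a) > m.gene_row(p.gene_b) for p in pairs])


def majority_scc_calls(m: ExpressionMatrix, pairs: Sequence[GenePair]) -> np.ndarray:
    """Per-sample boolean SCC call under strict-majority voting."""
    votes = _vote_matrix(m, pairs)
    return votes.sum(axis=0) > len(pairs) / 2


def set_apparent_accuracy(m: ExpressionMatrix, pairs: Sequence[GenePair]) -> float:
    """Apparent accuracy of a pair set on the labeled samples of ``m``."""
    return _accuracy_report(m, majority_scc_calls(m, pairs)).accuracy


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

def forward_select(
    m: ExpressionMatrix,
    seed: GenePair,
    candidates: Sequence[PairStats],
) -> tuple[list[GenePair], float]:
    """Greedy growth of a pair set from ``seed``.

    At each step the candidate whose addition maximizes the set's apparent
    accuracy (strict-majority voting) is added; growth stops when no addition
    strictly increases accuracy.  Candidate order breaks ties, so the result
    is deterministic for a fixed candidate list.
    """
    labels = np.asarray(m.labels)
    labeled = (labels == ADC) | (labels == SCC)
    if not labeled.any():
        raise ValueError("forward_select requires labeled training samples")
    is_scc = (labels == SCC)[labeled]

    pool = [s.pair for s in candidates]
    votes = {
        p.unordered: (m.gene_row(p.gene_a) > m.gene_row(p.gene_b))[labeled] for p in pool
    }
    if seed.unordered not in votes:
        votes[seed.unordered] = (m.gene_row(seed.gene_a) > m.gene_row(seed.gene_b))[labeled]

    def accuracy(vote_sum: np.ndarray, k: int) -> float:
        calls_scc = vote_sum > k / 2
        return float((calls_scc == is_scc).mean())

    selected = [seed]
    chosen = {seed.unordered}
    vote_sum = votes[seed.unordered].astype(int)
    best_acc = accuracy(vote_sum, 1)
    while True:
        step_best: tuple[float, int] | None = None  # (accuracy, candidate index)
        for i, p in enumerate(pool):
            if p.unordered in chosen:
                continue
            acc = accuracy(vote_sum + votes[p.unordered], len(selected) + 1)
            if step_best is None or acc > step_best[0]:
                step_best = (acc, i)
        if step_best is None or step_best[0] <= best_acc:
            break
        acc, i = step_best
        pair = pool[i]
        selected.append(pair)
        chosen.add(pair.unordered)
        vote_sum = vote_sum + votes[pair.unordered]
        best_acc = acc
    return selected, best_acc


def select_signature(
    m: ExpressionMatrix,
    pair_stats: Sequence[PairStats],
    n_seeds: int = 50,
) -> Signature:
    """Run forward selection from the top ``n_seeds`` pairs and pick the winner.

    Seeds are the top pairs ranked by apparent accuracy (ties: FDR ascending,
    then gene ids).  Among the grown sets the maximum-accuracy ones win; ties
    are broken by (1) fewest pairs, (2) largest median per-pair rank-difference
    statistic, (3) lexicographic order of the sets' gene-id tuples.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    if not pair_stats:
        raise ValueError("no significant pairs available for signature selection")
    ordered = sorted(
        pair_stats, key=lambda s: (-s.apparent_accuracy, s.fdr, s.pair.gene_a, s.pair.gene_b)
    )
    rank_diff_by_pair = {s.pair.unordered: s.rank_diff for s in ordered}

    def median_rank_diff(pairs: Sequence[GenePair]) -> float:
        vals = [
            rank_diff_by_pair.get(p.unordered, None) for p in pairs
        ]
        vals = [v if v is not None else rank_diff_stat(m, p) for p, v in zip(pairs, vals)]
        return float(statistics.median(vals))

    seen_sets: set[frozenset[frozenset[str]]] = set()
    results: list[tuple[list[GenePair], float]] = []
    for seed_stat in ordered[:n_seeds]:
        pairs, acc = forward_select(m, seed_stat.pair, ordered)
        key = frozenset(p.unordered for p in pairs)
        if key in seen_sets:
            continue
        seen_sets.add(key)
        results.append((pairs, acc))

    def sort_key(item: tuple[list[GenePair], float]):
        pairs, acc = item
        lex = tuple(sorted((p.gene_a, p.gene_b) for p in pairs))
        return (-acc, len(pairs), -median_rank_diff(pairs), lex)

    pairs, acc = min(results, key=sort_key)
    return Signature(
        pairs=pairs,
        provenance={
            "dataset_id": m.dataset_id,
            "n_training_samples": int(
                sum(l in (ADC, SCC) for l in m.labels)
            ),
            "apparent_accuracy": acc,
            "rank_diff_median": median_rank_diff(pairs),
            "n_seeds": n_seeds,
            "n_candidate_pairs": len(pair_stats),
        },
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_signature(s: Signature, path: str | PathLike) -> None:
    payload = {
        "pairs": [{"scc_high": p.gene_a, "scc_low": p.gene_b} for p in s.pairs],
        "rule": s.rule,
        "provenance": s.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def load_signature(path: str | PathLike) -> Signature:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        pairs = [GenePair(p["scc_high"], p["scc_low"]) for p in payload["pairs"]]
        rule = payload.get("rule", RULE_STRICT_MAJORITY)
        provenance = payload.get("provenance", {})
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed signature file {path}: {exc}") from exc
    return Signature(pairs=pairs, rule=rule, provenance=provenance)
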