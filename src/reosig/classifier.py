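"""Apply a gene-pair signature to single samples and whole cohorts.

The call for a sample depends only on that sample's own expression values —
no pooling, no normalization, no reference distribution — which is what makes
the rule applicable at the individual level and invariant to any per-sample
strictly increasing transform of expression.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

from ._util import percent
from .core_io import ADC, SCC, ExpressionMatrix
from .pair_screen import AccuracyReport, _accuracy_report
from .signature_select import Signature, majority_scc_calls


@dataclasses.dataclass
class ClassificationResult:
    sample_id: str
    call: str  # ADC or SCC
    votes_scc: int
    votes_total: int
    pathology_label: str | None = None

    def __post_init__(self) -> None:
        if self.votes_scc > self.votes_total:
            raise ValueError("votes_scc cannot exceed votes_total")
        expected = SCC if self.votes_scc > self.votes_total / 2 else ADC
        if self.call != expected:
            raise ValueError("call inconsistent with strict-majority vote")


def classify_sample(
    expr: Mapping[str, float], signature: Signature, sample_id: str = ""
) -> ClassificationResult:
    """Classify one sample from its gene -> expression mapping.

    Each pair votes SCC iff its scc_high gene strictly exceeds its scc_low
    gene; a strict majority of SCC votes calls SCC, otherwise ADC.
    """
    votes = 0
    for p in signature.pairs:
        for g in (p.gene_a, p.gene_b):
            if g not in expr:
                raise KeyError(f"signature gene {g!r} missing from sample {sample_id!r}")
        if expr[p.gene_a] > expr[p.gene_b]:
            votes += 1
    k = len(signature.pairs)
    call = SCC if votes > k / 2 else ADC
    return ClassificationResult(
        sample_id=sample_id, call=call, votes_scc=votes, votes_total=k
    )


def classify_cohort(
    m: ExpressionMatrix, signature: Signature
) -> tuple[list[ClassificationResult], AccuracyReport | None]:
    """Classify every sample of a cohort and summarize agreement with pathology.

    Sensitivity is the fraction of pADC samples called ADC, specificity the
    fraction of pSCC called SCC, accuracy C/M over labeled samples.
    Unlabeled samples are classified but excluded from the report; with no
    labeled samples the report is ``None``.
    """
    for g in signature.genes:
        if not m.has_gene(g):
            raise KeyError(f"signature gene {g!r} not present in matrix")
    results = []
    for i, sid in enumerate(m.sample_ids):
        r = classify_sample(m.sample_mapping(i), signature, sample_id=sid)
        lab = m.labels[i]
        r.pathology_label = lab if lab in (ADC, SCC) else None
        results.append(r)
    if not any(l in (ADC, SCC) for l in m.labels):
        return results, None
    calls_scc = majority_scc_calls(m, signature.pairs)
    report = _accuracy_report(m, calls_scc)
    return results, report


def format_report(report: AccuracyReport) -> str:
    """Human-readable cohort summary: counts plus percentages to 2 decimals."""
    lines = [
        f"pADC: {report.n_adc}\tpSCC: {report.n_scc}",
        f"samples classified (M): {report.M}",
        f"concordant with pathology (C): {report.C}",
        f"A-Acc: {percent(report.C, report.M):.2f}%",
    ]
    if report.n_adc:
        n_re = len(report.reclassified_to_scc)
        lines.append(f"A-Sen (pADC): {percent(report.n_adc - n_re, report.n_adc):.2f}%")
        lines.append(f"Re(SCC): {n_re} ({percent(n_re, report.n_adc):.2f}%)")
    if report.n_scc:
        n_re = len(report.reclassified_to_adc)
        lines.append(f"A-Spe (pSCC): {percent(report.n_scc - n_re, report.n_scc):.2f}%")
        lines.append(f"Re(ADC): {n_re} ({percent(n_re, report.n_scc):.2f}%)")
    return "\n".join(lines)


def write_calls(results: Sequence[ClassificationResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcall\tvotes_scc\tvotes_total\tpathology_label\n")
        for r in results:
            lab = r.pathology_label if r.pathology_label is not None else "NA"
            fh.write(f"{r.sample_id}\t{r.call}\t{r.votes_scc}\t{r.votes_total}\t{lab}\n")
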