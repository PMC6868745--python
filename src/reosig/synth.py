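"""Synthetic two-subtype expression data with planted REO structure.

The generator emulates the statistical structure the discovery pipeline
assumes: normals are baseline Gaussian noise on a log-like scale; a block of
*subtype-opposite* genes is mean-shifted up in one tumor subtype and down in
the other; everything else is null.  One designated pair of oppositely
shifted genes — the *planted pair* — is made dominant: its within-sample
ordering is forced to the subtype-correct pattern and then violated
independently per tumor sample with probability ``flip_rate`` (a value swap,
preserving marginals).  The remaining opposite genes are degraded coherently:
with probability ``decoy_flip_factor * flip_rate`` a tumor sample has all of
their shift signs inverted at once — emulating a pathologically mislabeled
sample, whose subtype-informative orderings all point the wrong way.  Because
those errors are perfectly correlated across decoy pairs, majority voting
cannot repair them, and the planted pair is the single dominant pair at any
flip_rate > 0; at flip_rate = 0 the structure is noise-free.
"""
from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from .core_io import ADC, NORMAL, SCC, ExpressionMatrix
from .pair_screen import screen_pairs
from .signature_select import select_signature
from .subtype_opposite import call_directions, find_subtype_opposite


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of a synthetic dataset."""

    n_adc: int = 50
    n_scc: int = 50
    n_normal: int = 20
    n_genes: int = 200
    n_opposite: int = 20
    effect: float = 2.0  # mean shift in noise-SD units
    flip_rate: float = 0.05  # per-sample probability of violating the planted REO
    seed: int = 0
    baseline: float = 8.0
    noise_sd: float = 1.0
    planted_boost: float = 4.0  # extra shift factor for the planted pair's genes
    decoy_flip_factor: float = 5.0  # decoy scramble rate as a multiple of flip_rate
    planted_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if min(self.n_adc, self.n_scc) < 1 or self.n_normal < 0:
            raise ValueError("sample counts must be positive (normals may be 0)")
        if self.n_genes < 1 or not 0 <= self.n_opposite <= self.n_genes:
            raise ValueError("need 0 <= n_opposite <= n_genes and n_genes >= 1")
        if not 0 <= self.flip_rate < 0.5:
            raise ValueError("flip_rate must lie in [0, 0.5)")
        if self.effect < 0 or self.noise_sd <= 0:
            raise ValueError("effect must be >= 0 and noise_sd > 0")
        if self.decoy_flip_factor < 0 or self.planted_boost <= 0:
            raise ValueError("decoy_flip_factor must be >= 0 and planted_boost > 0")

    def gene_ids(self) -> list[str]:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]

    def opposite_directions(self) -> dict[str, tuple[str, str]]:
        """Planted gene -> (direction_in_ADC, direction_in_SCC).

        The first half of the opposite block is UP in SCC / DOWN in ADC, the
        second half the reverse.
        """
        ids = self.gene_ids()[: self.n_opposite]
        half = self.n_opposite // 2
        out: dict[str, tuple[str, str]] = {}
        for i, g in enumerate(ids):
            out[g] = ("DOWN", "UP") if i < half else ("UP", "DOWN")
        return out

    def resolved_planted_pair(self) -> tuple[str, str] | None:
        """(scc_high, scc_low) gene pair; None when fewer than 2 opposite genes."""
        if self.planted_pair is not None:
            dirs = self.opposite_directions()
            hi, lo = self.planted_pair
            if hi not in dirs or lo not in dirs or dirs[hi] == dirs[lo]:
                raise ValueError(
                    "planted_pair genes must be opposite genes with opposite directions"
                )
            if dirs[hi][1] != "UP":
                hi, lo = lo, hi
            return hi, lo
        dirs = self.opposite_directions()
        scc_up = [g for g, d in dirs.items() if d[1] == "UP"]
        adc_up = [g for g, d in dirs.items() if d[1] == "DOWN"]
        if not scc_up or not adc_up:
            return None
        return scc_up[0], adc_up[0]


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, dict[str, Any]]:
    """Generate a labeled matrix plus a ground-truth record, deterministically."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    gi = {g: i for i, g in enumerate(genes)}
    n_tumor = spec.n_adc + spec.n_scc
    n_total = n_tumor + spec.n_normal
    sample_ids = (
        [f"ADC_{i + 1:03d}" for i in range(spec.n_adc)]
        + [f"SCC_{i + 1:03d}" for i in range(spec.n_scc)]
        + [f"N_{i + 1:03d}" for i in range(spec.n_normal)]
    )
    labels = [ADC] * spec.n_adc + [SCC] * spec.n_scc + [NORMAL] * spec.n_normal

    values = spec.baseline + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n_total))

    dirs = spec.opposite_directions()
    planted = spec.resolved_planted_pair()
    planted_genes = set(planted) if planted else set()
    adc_cols = np.arange(spec.n_adc)
    scc_cols = np.arange(spec.n_adc, n_tumor)

    # shared decoy scramble: samples whose non-planted opposite orderings all invert
    scrambled = np.zeros(n_tumor, dtype=bool)
    if spec.flip_rate > 0:
        decoy_rate = min(0.49, spec.decoy_flip_factor * spec.flip_rate)
        scrambled = rng.random(n_tumor) < decoy_rate
    for g, (d_adc, d_scc) in dirs.items():
        shift = spec.effect * spec.noise_sd
        if g in planted_genes:
            shift *= spec.planted_boost
        per_sample = np.zeros(n_total)
        per_sample[adc_cols] = shift if d_adc == "UP" else -shift
        per_sample[scc_cols] = shift if d_scc == "UP" else -shift
        if g not in planted_genes:
            per_sample[:n_tumor][scrambled] *= -1
        values[gi[g]] += per_sample

    pair_flips = np.zeros(n_tumor, dtype=bool)
    if planted is not None:
        hi, lo = planted
        r_hi, r_lo = gi[hi], gi[lo]
        pair_flips = rng.random(n_tumor) < spec.flip_rate
        for j in range(n_tumor):
            v_hi, v_lo = values[r_hi, j], values[r_lo, j]
            want_hi_above = (j >= spec.n_adc)  # SCC pattern: hi > lo
            if pair_flips[j]:
                want_hi_above = not want_hi_above
            top, bot = max(v_hi, v_lo), min(v_hi, v_lo)
            if top == bot:  # measure-zero guard
                top = bot + 1e-9
            values[r_hi, j], values[r_lo, j] = (top, bot) if want_hi_above else (bot, top)

    m = ExpressionMatrix(values, genes, sample_ids, labels, dataset_id=f"synthetic-{spec.seed}")
    truth: dict[str, Any] = {
        "opposite_genes": {g: list(d) for g, d in dirs.items()},
        "planted_pair": list(planted) if planted else None,
        "flipped_tumor_samples": [sample_ids[j] for j in range(n_tumor) if pair_flips[j]],
        "scrambled_tumor_samples": [sample_ids[j] for j in range(n_tumor) if scrambled[j]],
        "spec": dataclasses.asdict(spec),
    }
    return m, truth


def recovery_experiment(
    spec: SyntheticSpec,
    reps: int,
    alpha: float = 0.05,
    n_seeds: int = 50,
) -> float:
    """Fraction of replicates whose discovered signature contains the planted pair.

    Each replicate regenerates data with an offset seed and runs the full
    pipeline: direction calls vs normals for both subtypes, subtype-opposite
    extraction, pair screening, and seed-based forward selection.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    hits = 0
    for r in range(reps):
        rep_spec = dataclasses.replace(spec, seed=spec.seed + r)
        m, truth = generate_dataset(rep_spec)
        normal = m.subset_label(NORMAL)
        adc_calls = call_directions(m.subset_label(ADC), normal, ADC, alpha=alpha)
        scc_calls = call_directions(m.subset_label(SCC), normal, SCC, alpha=alpha)
        opposite = find_subtype_opposite(adc_calls, scc_calls, dataset_id=m.dataset_id)
        tumors = m.subset_samples(
            [i for i, l in enumerate(m.labels) if l in (ADC, SCC)]
        )
        stats = screen_pairs(tumors, opposite, fdr_alpha=alpha)
        signature = select_signature(tumors, stats, n_seeds=n_seeds)
        planted = truth["planted_pair"]
        if planted is not None:
            target = frozenset(planted)
            if any(p.unordered == target for p in signature.pairs):
                hits += 1
    return hits / reps


def opposite_set_integration_fixture(
    n_a_only: int,
    n_shared: int,
    n_b_only: int,
    n_conflicts: int,
) -> tuple[list, dict]:
    """Two overlapping opposite-gene sets plus cross-cohort direction tables.

    Builds dataset A with ``n_a_only + n_shared`` genes and dataset B with
    ``n_b_only + n_shared`` genes (all stored as UP-in-ADC / DOWN-in-SCC);
    shared genes are direction-concordant, and exactly ``n_conflicts`` of the
    non-shared union members are given conflicting unthresholded directions
    in the *other* dataset.  Feeding the result to
    :func:`reosig.integrate_opposite_sets` therefore yields
    ``n_a_only + n_shared + n_b_only - n_conflicts`` genes.
    """
    from .subtype_opposite import OppositeGeneSet

    if n_conflicts > n_a_only + n_b_only:
        raise ValueError("cannot plant more conflicts than non-shared genes")
    a_only = [f"A{i:04d}" for i in range(n_a_only)]
    shared = [f"S{i:04d}" for i in range(n_shared)]
    b_only = [f"B{i:04d}" for i in range(n_b_only)]
    entry = ("UP", "DOWN")
    set_a = OppositeGeneSet("dsA", [(g, *entry) for g in a_only + shared])
    set_b = OppositeGeneSet("dsB", [(g, *entry) for g in b_only + shared])
    conflicts = set((a_only + b_only)[:n_conflicts])
    table_a = {g: entry for g in a_only + shared}
    table_b = {g: entry for g in b_only + shared}
    # the other dataset sees each non-shared gene without statistical control;
    # conflicted genes point the wrong way there
    for g in b_only:
        table_a[g] = ("DOWN", "DOWN") if g in conflicts else entry
    for g in a_only:
        table_b[g] = ("DOWN", "DOWN") if g in conflicts else entry
    return [set_a, set_b], {"dsA": table_a, "dsB": table_b}


def two_gene_cohort(
    n_adc: int,
    n_scc: int,
    miscalled_adc: int = 0,
    miscalled_scc: int = 0,
    genes: tuple[str, str] = ("KRT5", "AGR2"),
    seed: int = 0,
    n_noise_genes: int = 0,
) -> ExpressionMatrix:
    """Cohort with exact per-class counts of REO-discordant samples.

    Builds an (optionally padded) matrix over ``genes = (scc_high, scc_low)``
    in which exactly ``miscalled_adc`` pADC samples show the SCC pattern and
    exactly ``miscalled_scc`` pSCC samples show the ADC pattern; values are
    otherwise random.  Useful for reproducing printed C/M bookkeeping.
    """
    if not 0 <= miscalled_adc <= n_adc or not 0 <= miscalled_scc <= n_scc:
        raise ValueError("miscalled counts must not exceed class sizes")
    rng = np.random.default_rng(seed)
    hi, lo = genes
    n = n_adc + n_scc
    sample_ids = [f"ADC_{i + 1:03d}" for i in range(n_adc)] + [
        f"SCC_{i + 1:03d}" for i in range(n_scc)
    ]
    labels = [ADC] * n_adc + [SCC] * n_scc
    # SCC pattern (hi > lo) must hold for: miscalled ADC + concordant SCC samples
    pattern = np.array(
        [i < miscalled_adc for i in range(n_adc)]
        + [i >= miscalled_scc for i in range(n_scc)]
    )
    draws = rng.normal(8.0, 1.0, size=(2, n))
    top = np.maximum(draws[0], draws[1])
    bot = np.minimum(draws[0], draws[1])
    eq = top == bot
    top[eq] = bot[eq] + 1e-9
    v_hi = np.where(pattern, top, bot)
    v_lo = np.where(pattern, bot, top)
    rows = [v_hi, v_lo]
    gene_ids = [hi, lo]
    if n_noise_genes:
        rows.append(rng.normal(8.0, 1.0, size=(n_noise_genes, n)))
        gene_ids += [f"NOISE_{i + 1:04d}" for i in range(n_noise_genes)]
    values = np.vstack(rows)
    return ExpressionMatrix(values, gene_ids, sample_ids, labels, dataset_id="two-gene-cohort")
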