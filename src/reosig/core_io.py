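"""Expression-matrix I/O and probe-to-gene collapsing.

The canonical on-disk format is a plain TSV with gene rows and sample
columns; GCT v1.2 is accepted read-only.  Sample class labels travel in a
two-column sidecar TSV (sample_id, label).  Expression is assumed to be
already normalized on a log-like scale — the downstream method is rank-based
within each sample, so no cross-sample normalization is ever applied here.
"""
from __future__ import annotations

import dataclasses
import logging
from os import PathLike
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ADC = "ADC"
SCC = "SCC"
NORMAL = "NORMAL"
UNKNOWN = "UNKNOWN"
VALID_LABELS = frozenset({ADC, SCC, NORMAL, UNKNOWN})


@dataclasses.dataclass
class ExpressionMatrix:
    """Numeric gene-by-sample matrix with per-sample class labels.

    Parameters
    ----------
    values
        ``(n_genes, n_samples)`` float array, no missing values.
    gene_ids, sample_ids
        Unique, non-empty identifier lists matching the matrix dimensions.
    labels
        Per-sample class in ``{ADC, SCC, NORMAL, UNKNOWN}``; defaults to
        all-``UNKNOWN``.
    dataset_id
        Free-form provenance tag (e.g. a cohort accession).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: list[str] | None = None
    dataset_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.labels is None:
            self.labels = [UNKNOWN] * len(self.sample_ids)
        self.labels = [str(l) for l in self.labels]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if any(g == "" for g in self.gene_ids):
            raise ValueError("empty gene identifier")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length does not match samples")
        bad = sorted(set(self.labels) - VALID_LABELS)
        if bad:
            raise ValueError(f"invalid sample labels: {bad}")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix contains missing/non-finite values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- accessors ---------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene_id]]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not present in matrix") from None

    def has_gene(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def sample_mapping(self, i: int) -> dict[str, float]:
        """Single-sample gene -> value mapping (column ``i``)."""
        return dict(zip(self.gene_ids, self.values[:, i]))

    def label_indices(self, label: str) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.labels) if l == label], dtype=int)

    # -- slicing -----------------------------------------------------------
    def subset_samples(self, indices: Sequence[int]) -> "ExpressionMatrix":
        idx = list(indices)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
            [self.labels[i] for i in idx],
            self.dataset_id,
        )

    def subset_label(self, label: str) -> "ExpressionMatrix":
        return self.subset_samples(self.label_indices(label))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self._gene_index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        idx = [self._gene_index[g] for g in genes]
        return ExpressionMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            list(self.sample_ids),
            list(self.labels),
            self.dataset_id,
        )

    def with_labels(self, labels: Mapping[str, str]) -> "ExpressionMatrix":
        new = [labels.get(s, UNKNOWN) for s in self.sample_ids]
        return ExpressionMatrix(
            self.values, list(self.gene_ids), list(self.sample_ids), new, self.dataset_id
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclasses.dataclass(frozen=True)
class ProbeMap:
    """Probe -> gene mapping; probes mapping to zero or multiple genes are dropped."""

    mapping: dict[str, str]
    dropped: frozenset[str] = frozenset()


def _check_unique(ids: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} {x!r}")
        seen.add(x)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _check_raw_header(path: str | PathLike, skip: int) -> None:
    # pandas silently renames duplicate columns; inspect the raw header line
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample id")


def read_expression(
    path: str | PathLike,
    format: Literal["tsv", "gct"] = "tsv",
    labels: str | PathLike | Mapping[str, str] | None = None,
    on_missing: Literal["error", "drop"] = "error",
    dataset_id: str | None = None,
) -> ExpressionMatrix:
    """Read a gene-by-sample expression table.

    ``on_missing`` controls rows with missing cells: ``error`` rejects the
    file, ``drop`` removes the incomplete gene rows (never imputes).
    """
    if format == "tsv":
        _check_raw_header(path, skip=0)
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif format == "gct":
        _check_raw_header(path, skip=2)
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, skiprows=2)
        df = df.drop(columns=[c for c in df.columns if c.lower() == "description"])
    else:
        raise ValueError(f"unknown format {format!r}")

    _check_unique([str(i) for i in df.index], "gene id")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {df.iat[r, c]!r} at "
            f"gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    missing_rows = numeric.isna().any(axis=1)
    if missing_rows.any():
        if on_missing == "drop":
            logger.warning("dropping %d gene rows with missing values", int(missing_rows.sum()))
            numeric = numeric.loc[~missing_rows]
        else:
            first = numeric.index[missing_rows.to_numpy()][0]
            raise ValueError(
                f"missing expression values (first offending gene {first!r}); "
                "pass on_missing='drop' to discard incomplete rows"
            )
    if dataset_id is None:
        dataset_id = str(path)

    m = ExpressionMatrix(
        numeric.to_numpy(dtype=float),
        [str(i) for i in numeric.index],
        [str(c) for c in numeric.columns],
        dataset_id=dataset_id,
    )
    if labels is not None:
        if not isinstance(labels, Mapping):
            labels = read_labels(labels)
        m = m.with_labels(labels)
    return m


def write_expression(m: ExpressionMatrix, path: str | PathLike) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_labels(path: str | PathLike) -> dict[str, str]:
    """Read a two-column (sample_id, label) TSV; '#' lines and a header row are skipped."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed label line {line!r}")
            sid, lab = parts[0].strip(), parts[1].strip().upper()
            if sid == "sample_id" and lab not in VALID_LABELS:
                continue  # header
            if lab not in VALID_LABELS:
                raise ValueError(f"invalid label {lab!r} for sample {sid!r}")
            out[sid] = lab
    return out


def write_labels(labels: Mapping[str, str], path: str | PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def read_probe_map(path: str | PathLike) -> ProbeMap:
    """Read a two-column (probe_id, gene_id) TSV.

    A probe with an empty gene field, or seen with more than one distinct
    gene, is flagged for removal.
    """
    assignments: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            probe = parts[0].strip()
            gene = parts[1].strip() if len(parts) > 1 else ""
            if probe == "probe_id":
                continue  # header
            assignments.setdefault(probe, set())
            if gene:
                assignments[probe].add(gene)
    mapping: dict[str, str] = {}
    dropped: set[str] = set()
    for probe, genes in assignments.items():
        if len(genes) == 1:
            mapping[probe] = next(iter(genes))
        else:
            dropped.add(probe)
    return ProbeMap(mapping=mapping, dropped=frozenset(dropped))


def collapse_probes(m: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-keyed matrix to gene level.

    Probes mapping to zero genes or to multiple genes are deleted; the
    measurements of all probes sharing a gene are averaged.
    """
    gene_to_rows: dict[str, list[int]] = {}
    n_dropped = 0
    for i, probe in enumerate(m.gene_ids):
        gene = probe_map.mapping.get(probe)
        if gene is None or probe in probe_map.dropped:
            n_dropped += 1
            continue
        gene_to_rows.setdefault(gene, []).append(i)
    if not gene_to_rows:
        raise ValueError("all probes were unmapped or multi-mapped; empty output")
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped/multi-mapped probes", n_dropped)
    genes = list(gene_to_rows)
    values = np.vstack([m.values[rows].mean(axis=0) for rows in gene_to_rows.values()])
    return ExpressionMatrix(values, genes, list(m.sample_ids), list(m.labels), m.dataset_id)
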