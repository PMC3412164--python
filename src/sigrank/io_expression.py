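"""Expression-matrix, gene-set and mapping file I/O plus matrix preprocessing.

This module owns the on-disk formats used throughout the package:

* expression matrices — TSV (first column = feature ids, header = sample
  ids) or the value block of a GEO series-matrix file;
* gene sets — standard GMT (name, description, genes; tab separated);
* probe→gene maps and sample→group maps — two-column TSV.

It also implements the two preprocessing steps applied before any scoring:
quantile normalization of already-summarized log2 matrices, and
probe-to-gene collapse keeping, per gene, the probe with the highest
standard deviation across all samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "ExpressionMatrix",
    "SampleGrouping",
    "GeneSetCollection",
    "ProbeGeneMap",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_sample_groups",
    "read_probe_map",
    "quantile_normalize",
    "collapse_probes_max_sd",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Dense log2 expression values, features in rows, samples in columns.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
    level
        Either ``"probe"`` (probe-set level, duplicate gene measurements
        possible) or ``"gene"`` (one row per gene symbol).

    Notes
    -----
    Sample ids must be unique; at gene level feature ids must be unique as
    well.  Infinite values are rejected.  ``NaN`` entries are tolerated at
    construction time (downstream operations that cannot handle them raise
    explicitly), but the bundled readers only produce complete matrices.
    """

    values: pd.DataFrame
    level: str = "gene"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError(f"level must be 'probe' or 'gene', got {self.level!r}")
        cols = self.values.columns
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.level == "gene":
            idx = self.values.index
            if idx.duplicated().any():
                dups = sorted(set(idx[idx.duplicated()]))
                raise ValueError(f"duplicate gene ids at gene level: {dups}")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValueError("expression values must be finite where observed")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def has_missing(self) -> bool:
        return bool(self.values.isna().to_numpy().any())


@dataclass
class SampleGrouping:
    """Mapping from sample id to replicate-group label.

    Group order follows first appearance; replicate order within a group
    follows input order.
    """

    assignments: dict[str, str]

    @property
    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, group in self.assignments.items():
            out.setdefault(group, []).append(sample)
        return out

    @property
    def group_labels(self) -> list[str]:
        return list(self.groups.keys())

    def samples_of(self, group: str) -> list[str]:
        try:
            return self.groups[group]
        except KeyError:
            raise KeyError(f"unknown group {group!r}; known: {self.group_labels}") from None

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check that every matrix sample has exactly one group."""
        missing = [s for s in matrix.sample_ids if s not in self.assignments]
        if missing:
            raise ValueError(f"samples without group assignment: {missing}")
        for group, samples in self.groups.items():
            if not samples:
                raise ValueError(f"group {group!r} has no samples")


@dataclass
class GeneSetCollection:
    """Named, ordered gene-symbol sets with optional descriptions."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @property
    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ProbeGeneMap:
    """Many-to-one probe-id → gene-symbol mapping."""

    mapping: dict[str, str]

    def __getitem__(self, probe: str) -> str:
        return self.mapping[probe]

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _parse_table(lines: list[tuple[int, list[str]]], path: Path) -> pd.DataFrame:
    """Build a numeric DataFrame from (line_number, fields) rows; first row
    is the header.  Raises :class:`ParseError` naming the offending cell."""
    if not lines:
        raise ParseError(f"{path}: empty file (no header line)")
    header_no, header = lines[0]
    if len(header) < 2:
        raise ParseError(f"{path}:{header_no}: malformed header (need feature-id column plus at least one sample)")
    sample_ids = header[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ParseError(f"{path}:{header_no}: duplicate sample id {sid!r} in header")
        seen.add(sid)
    n = len(sample_ids)
    features: list[str] = []
    rows: list[list[float]] = []
    for line_no, fields in lines[1:]:
        if len(fields) != n + 1:
            raise ParseError(
                f"{path}:{line_no}: expected {n + 1} fields, found {len(fields)}"
            )
        fid = fields[0]
        row: list[float] = []
        for sid, cell in zip(sample_ids, fields[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise ParseError(
                    f"{path}:{line_no}: non-numeric cell {cell!r} (feature {fid!r}, sample {sid!r})"
                ) from None
        features.append(fid)
        rows.append(row)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return pd.DataFrame(rows, index=pd.Index(features, name="feature_id"), columns=sample_ids)


def read_expression_matrix(
    path: str | Path, dialect: str = "tsv", level: str = "gene"
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or a GEO series-matrix file.

    Parameters
    ----------
    path
        Input file.  For ``dialect="tsv"`` the first row is
        ``feature_id<TAB>sample1<TAB>...`` and every following row a feature.
        For ``dialect="geo_series_matrix"`` only the value table between
        ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` is
        read; metadata lines are skipped.
    dialect
        ``"tsv"`` or ``"geo_series_matrix"``.
    level
        The level to declare on the returned matrix (``"probe"`` or
        ``"gene"``); file formats carry no level information.
    """
    path = Path(path)
    if dialect not in ("tsv", "geo_series_matrix"):
        raise ValueError(f"unknown dialect {dialect!r}")
    raw = path.read_text()
    lines: list[tuple[int, list[str]]] = []
    if dialect == "tsv":
        for i, line in enumerate(raw.splitlines(), start=1):
            if not line.strip():
                continue
            lines.append((i, line.rstrip("\n").split("\t")))
    else:
        in_table = False
        for i, line in enumerate(raw.splitlines(), start=1):
            stripped = line.strip()
            if stripped.lower().startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if stripped.lower().startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table and stripped:
                fields = [f.strip().strip('"') for f in line.split("\t")]
                lines.append((i, fields))
        if not lines:
            raise ParseError(f"{path}: no series_matrix_table block found")
    frame = _parse_table(lines, path)
    matrix = ExpressionMatrix(frame, level=level)
    log.info("read %d features x %d samples from %s", *matrix.shape, path)
    return matrix


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with a ``feature_id`` header column."""
    frame = matrix.values.copy()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from a GMT file.

    Each line is ``name<TAB>description<TAB>gene1[<TAB>gene2...]``.
    Duplicate genes within a line are dropped (keeping first occurrence)
    with a warning; a duplicated set name is an error.
    """
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{i}: GMT line needs name, description and >=1 gene")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        if not genes:
            raise ParseError(f"{path}:{i}: gene set {name!r} has no genes")
        if name in sets:
            raise ParseError(f"{path}:{i}: duplicate gene set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            log.warning(
                "%s:%d: gene set %r contains %d duplicate gene entries; deduplicated",
                path, i, name, len(genes) - len(deduped),
            )
        sets[name] = tuple(deduped)
        descriptions[name] = desc
    if not sets:
        raise ParseError(f"{path}: empty GMT file")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def _read_two_column(path: Path, what: str) -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{i}: expected 2 tab-separated fields for {what}")
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise ParseError(f"{path}: empty {what} file")
    return pairs


def read_sample_groups(path: str | Path) -> SampleGrouping:
    """Read a two-column (sample_id, group) TSV.  A header line with first
    field ``sample_id`` is tolerated and skipped."""
    path = Path(path)
    pairs = _read_two_column(path, "sample→group map")
    if pairs and pairs[0][0].lower() in ("sample_id", "sample"):
        pairs = pairs[1:]
    assignments: dict[str, str] = {}
    for sample, group in pairs:
        if sample in assignments:
            raise ParseError(f"{path}: sample {sample!r} assigned to more than one group")
        assignments[sample] = group
    return SampleGrouping(assignments)


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column (probe_id, gene_symbol) TSV."""
    path = Path(path)
    pairs = _read_two_column(path, "probe→gene map")
    if pairs and pairs[0][0].lower() in ("probe_id", "probe"):
        pairs = pairs[1:]
    mapping: dict[str, str] = {}
    for probe, gene in pairs:
        if probe in mapping:
            raise ParseError(f"{path}: probe {probe!r} mapped more than once")
        mapping[probe] = gene
    return ProbeGeneMap(mapping)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column's k-th order statistic is replaced by the mean of the k-th
    order statistics across all columns; row and column labels are
    preserved.  The operation is idempotent.

    Raises
    ------
    ValueError
        If the matrix has fewer than 2 samples or contains missing values
        (impute before normalizing).
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if matrix.has_missing():
        raise ValueError(
            "matrix contains missing values; impute before quantile normalization"
        )
    vals = matrix.values.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    row_means = sorted_vals.mean(axis=1)
    # a constant row must map to itself exactly (keeps the op idempotent;
    # the float mean of identical values can be off by an ulp)
    constant = (sorted_vals == sorted_vals[:, :1]).all(axis=1)
    row_means[constant] = sorted_vals[constant, 0]
    out = np.empty_like(vals)
    np.put_along_axis(out, order, np.broadcast_to(row_means[:, None], vals.shape), axis=0)
    frame = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(frame, level=matrix.level)


def collapse_probes_max_sd(
    matrix: ExpressionMatrix, probe_map: ProbeGeneMap
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level by maximal standard deviation.

    For every gene with at least one mapped probe present in the matrix, the
    probe whose values have the largest sample standard deviation (ddof=1)
    across all samples is retained; its row becomes the gene row.  Ties are
    broken by the lexicographically smaller probe id so the result does not
    depend on input row order.  Unmapped probes are dropped (count logged).
    Output rows are sorted by gene symbol.
    """
    if matrix.level != "probe":
        raise ValueError("collapse requires a probe-level matrix")
    vals = matrix.values
    present = [p for p in vals.index if p in probe_map]
    if not present:
        raise ValueError("no probe in the matrix is covered by the probe→gene map")
    n_dropped = matrix.shape[0] - len(present)
    if n_dropped:
        log.info("dropping %d unmapped probes", n_dropped)
    sub = vals.loc[present]
    sds = sub.std(axis=1, ddof=1).fillna(0.0)
    best: dict[str, str] = {}
    for probe in present:
        gene = probe_map[probe]
        cur = best.get(gene)
        if cur is None:
            best[gene] = probe
            continue
        sd_new, sd_cur = sds[probe], sds[cur]
        if sd_new > sd_cur or (sd_new == sd_cur and probe < cur):
            best[gene] = probe
    genes = sorted(best)
    frame = sub.loc[[best[g] for g in genes]].copy()
    frame.index = pd.Index(genes, name="gene")
    log.info("collapsed %d probes to %d genes", len(present), len(genes))
    return ExpressionMatrix(frame, level="gene")
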