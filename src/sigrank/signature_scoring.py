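"""Gene-set signature scoring, rank tables and PCA projection.

The scoring procedure: gene-wise zero-centering across the full compendium,
per-sample set-average scores, replicate averaging within groups, then a
per-signature descending rank (rank 1 = strongest signal).

Centering is computed over ALL samples supplied — adding or removing
samples from the compendium changes every score.  Keep the compendium fixed
when comparing rank tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_expression import ExpressionMatrix, GeneSetCollection, SampleGrouping

log = logging.getLogger(__name__)

__all__ = [
    "ScoreTable",
    "RankTable",
    "PCAResult",
    "center_genes",
    "score_samples",
    "score_gene_set",
    "build_rank_table",
    "derive_fold_change_signature",
    "pca_project",
]


@dataclass
class RankTable:
    """Groups × signatures score and rank matrices.

    ``scores`` holds set-average centered expression per (group, signature);
    ``ranks`` the per-signature descending rank (1 = highest score).  Each
    rank column is a permutation of 1..G.
    """

    scores: pd.DataFrame
    ranks: pd.DataFrame

    def __post_init__(self) -> None:
        g = len(self.ranks.index)
        for sig in self.ranks.columns:
            col = self.ranks[sig].to_numpy()
            if sorted(col) != list(range(1, g + 1)):
                raise ValueError(f"rank column {sig!r} is not a permutation of 1..{g}")

    def rank_of(self, group: str, signature: str) -> int:
        return int(self.ranks.at[group, signature])

    def write_tsv(self, path: str | Path, what: str = "ranks") -> None:
        frame = self.ranks if what == "ranks" else self.scores
        frame = frame.copy()
        frame.index.name = "group"
        frame.to_csv(path, sep="\t")


# scores kept on the same object; alias documents the two-layer structure
ScoreTable = RankTable


@dataclass
class PCAResult:
    """Principal components of sample profiles after gene-wise centering."""

    scores: pd.DataFrame          # samples × components
    loadings: pd.DataFrame        # components × genes
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")
        if evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must sum to <= 1")


def center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across all samples (gene-wise zero-centering)."""
    if matrix.level != "gene":
        raise ValueError("center_genes requires a gene-level matrix")
    vals = matrix.values
    centered = vals.sub(vals.mean(axis=1), axis=0)
    return ExpressionMatrix(centered, level="gene")


def score_samples(centered: ExpressionMatrix, genes: Iterable[str], name: str | None = None) -> pd.Series:
    """Per-sample signature score: mean of centered values over set∩matrix genes.

    Genes absent from the matrix are dropped (count logged); an empty
    intersection is an error naming the set.
    """
    genes = list(genes)
    present = [g for g in genes if g in centered.values.index]
    label = name or "<unnamed set>"
    if not present:
        raise ValueError(f"gene set {label} shares no genes with the matrix")
    n_missing = len(genes) - len(present)
    if n_missing:
        log.warning("gene set %s: %d/%d genes absent from matrix", label, n_missing, len(genes))
    return centered.values.loc[present].mean(axis=0)


def score_gene_set(
    centered: ExpressionMatrix,
    genes: Iterable[str],
    grouping: SampleGrouping,
    name: str | None = None,
) -> pd.Series:
    """Per-group signature score: replicate samples scored individually, then
    averaged within each group.  Returns a Series indexed by group label in
    grouping order."""
    grouping.validate_against(centered)
    per_sample = score_samples(centered, genes, name=name)
    out = {
        group: float(per_sample[samples].mean())
        for group, samples in grouping.groups.items()
    }
    return pd.Series(out, name=name)


def build_rank_table(
    centered: ExpressionMatrix,
    sets: GeneSetCollection,
    grouping: SampleGrouping,
) -> RankTable:
    """Score every signature per group and rank groups per signature.

    Ranks are assigned by descending score; ties are broken by group order
    (the grouping's first-appearance order), making the table deterministic.
    """
    groups = grouping.group_labels
    scores = pd.DataFrame(index=pd.Index(groups, name="group"), columns=sets.names, dtype=float)
    for sig in sets.names:
        scores[sig] = score_gene_set(centered, sets[sig], grouping, name=sig)
    ranks = pd.DataFrame(index=scores.index, columns=scores.columns, dtype=int)
    for sig in scores.columns:
        order = np.argsort(-scores[sig].to_numpy(), kind="stable")
        col = np.empty(len(groups), dtype=int)
        col[order] = np.arange(1, len(groups) + 1)
        ranks[sig] = col
    return RankTable(scores=scores, ranks=ranks)


def derive_fold_change_signature(
    matrix: ExpressionMatrix,
    grouping: SampleGrouping,
    target: str,
    reference: str,
    family_prefix: str,
    min_fold: float = 2.0,
) -> tuple[str, ...]:
    """Rule-based signature: family-prefix genes up at least ``min_fold``-fold
    in ``target`` versus ``reference`` (difference of group means on the log2
    scale compared with ``log2(min_fold)``).  Returns gene ids in matrix order.
    """
    if matrix.level != "gene":
        raise ValueError("signature derivation requires a gene-level matrix")
    t_samples = grouping.samples_of(target)
    r_samples = grouping.samples_of(reference)
    family = [g for g in matrix.values.index if str(g).startswith(family_prefix)]
    if not family:
        log.warning("no gene id matches family prefix %r", family_prefix)
        return ()
    diff = (
        matrix.values.loc[family, t_samples].mean(axis=1)
        - matrix.values.loc[family, r_samples].mean(axis=1)
    )
    selected = tuple(g for g in family if diff[g] >= np.log2(min_fold))
    log.info(
        "fold-change signature %s>=%.3g-fold (%s vs %s): %d/%d family genes",
        family_prefix, min_fold, target, reference, len(selected), len(family),
    )
    return selected


def pca_project(
    matrix: ExpressionMatrix, feature_filter: Sequence[str] | None = None
) -> PCAResult:
    """Project sample profiles onto principal components.

    Rows are gene-wise centered first, so with ``n`` samples at most
    ``n − 1`` non-trivial components exist; components with (numerically)
    zero variance are dropped.  Sign convention: each loading vector is
    flipped so its largest-magnitude entry is positive.
    """
    vals = matrix.values
    if vals.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if feature_filter is not None:
        keep = [g for g in vals.index if g in set(feature_filter)]
        if not keep:
            raise ValueError("feature filter eliminates every row")
        vals = vals.loc[keep]
    centered = vals.sub(vals.mean(axis=1), axis=0)
    x = centered.to_numpy(dtype=float).T  # samples × genes
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    keep_k = int((s > tol).sum())
    u, s, vt = u[:, :keep_k], s[:keep_k], vt[:keep_k]
    # sign convention: largest-|loading| entry positive per component
    for i in range(keep_k):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    total = float((s**2).sum())
    evr = (s**2) / total if total > 0 else np.zeros(0)
    comp_idx = pd.Index([f"PC{i+1}" for i in range(keep_k)], name="component")
    scores = pd.DataFrame(u * s, index=vals.columns, columns=comp_idx)
    loadings = pd.DataFrame(vt, index=comp_idx, columns=vals.index)
    return PCAResult(scores=scores, loadings=loadings, explained_variance_ratio=evr)
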