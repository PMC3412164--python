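"""GI50-based chemosensitivity mining.

Correlates −log(GI50) drug-response profiles with log2 gene expression
across a cell-line panel, selects genes whose |correlation| exceeds a
threshold for a minimum number of compounds, splits the selected genes into
positively and negatively response-associated signatures by average-linkage
clustering of their correlation profiles, and summarizes per-set median
correlations and signature-rank vs response associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import rankdata, spearmanr

from .io_expression import ExpressionMatrix, ParseError

log = logging.getLogger(__name__)

__all__ = [
    "DrugResponseMatrix",
    "ResponseSignaturePair",
    "read_gi50_matrix",
    "filter_drug_panel",
    "gene_drug_correlations",
    "select_correlated_genes",
    "split_response_signatures",
    "median_set_correlation",
    "rank_response_association",
]

#: minimum pairwise-complete observations for a correlation to be defined
MIN_OBS = 3


@dataclass
class DrugResponseMatrix:
    """−log(GI50) values, drugs in rows, cell lines in columns.

    Larger values mean greater sensitivity.  ``NaN`` marks a missing
    drug/line measurement.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate drug ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate cell-line ids")
        arr = self.values.to_numpy()
        if np.isinf(arr).any():
            raise ValueError("-log(GI50) values must be finite where observed")

    @property
    def drug_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """True where a value is observed."""
        return self.values.notna()


@dataclass
class ResponseSignaturePair:
    """Disjoint positively / negatively response-associated gene sets with
    their per-drug median correlation profiles."""

    positive: tuple[str, ...]
    negative: tuple[str, ...]
    median_by_drug: pd.DataFrame  # rows: 'positive', 'negative'; columns: drugs

    def __post_init__(self) -> None:
        if set(self.positive) & set(self.negative):
            raise ValueError("positive and negative signatures must be disjoint")


def read_gi50_matrix(
    path: str | Path, already_neglog: bool = False, log_base: float = 10.0
) -> DrugResponseMatrix:
    """Read a drugs × cell-lines TSV of GI50 (molar) or −log(GI50) values.

    Raw GI50 concentrations are converted to −log(GI50) (base 10 by
    default); empty cells and ``NA`` become missing.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.shape[1] == 0:
        raise ParseError(f"{path}: no cell-line columns")
    frame = frame.apply(pd.to_numeric, errors="coerce").astype(float)
    if not already_neglog:
        if (frame.to_numpy() <= 0).any():
            raise ValueError("raw GI50 concentrations must be positive; use already_neglog=True for transformed data")
        frame = -np.log(frame) / np.log(log_base)
    frame.index = frame.index.astype(str)
    return DrugResponseMatrix(frame)


def filter_drug_panel(
    drugs: DrugResponseMatrix, require_complete: bool = True, min_sd: float = 0.0
) -> DrugResponseMatrix:
    """Keep drugs measured in every line (optional) with −log(GI50) SD > ``min_sd``."""
    vals = drugs.values
    keep = pd.Series(True, index=vals.index)
    if require_complete:
        keep &= vals.notna().all(axis=1)
    sds = vals.std(axis=1, ddof=1)
    keep &= sds > min_sd
    removed = int((~keep).sum())
    if removed:
        log.info("filter_drug_panel: removed %d/%d drugs", removed, len(keep))
    if not keep.any():
        raise ValueError("drug-panel filter removed every drug")
    return DrugResponseMatrix(vals.loc[keep].copy())


def gene_drug_correlations(
    expr: ExpressionMatrix, drugs: DrugResponseMatrix, method: str = "pearson"
) -> pd.DataFrame:
    """Genes × drugs correlation matrix across shared cell lines.

    For every (gene, drug) pair the correlation is computed over lines with
    both values observed; pairs with fewer than 3 complete observations or
    zero variance in either vector are set missing.

    Returns a DataFrame of coefficients in [−1, 1] (NaN = undefined).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    shared = [s for s in expr.sample_ids if s in set(drugs.cell_line_ids)]
    if not shared:
        raise ValueError(
            f"no shared cell lines between expression ({expr.sample_ids}) "
            f"and drug response ({drugs.cell_line_ids})"
        )
    if len(shared) < MIN_OBS:
        raise ValueError(f"need >= {MIN_OBS} shared cell lines, found {len(shared)}")
    e = expr.values[shared].to_numpy(dtype=float)        # genes × lines
    d = drugs.values[shared].to_numpy(dtype=float)       # drugs × lines
    n_genes, n_drugs = e.shape[0], d.shape[0]
    out = np.full((n_genes, n_drugs), np.nan)
    for j in range(n_drugs):
        obs = np.isfinite(d[j])
        if obs.sum() < MIN_OBS:
            continue
        x = e[:, obs]
        y = d[j, obs]
        if method == "spearman":
            x = np.apply_along_axis(rankdata, 1, x)
            y = rankdata(y)
        xm = x - x.mean(axis=1, keepdims=True)
        ym = y - y.mean()
        sy = np.sqrt((ym**2).sum())
        sx = np.sqrt((xm**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xm @ ym) / (sx * sy)
        r[(sx == 0) | (sy == 0)] = np.nan
        out[:, j] = np.clip(r, -1.0, 1.0)
    n_degenerate = int(np.isnan(out).all(axis=1).sum())
    if n_degenerate:
        log.warning("%d genes have no defined correlation with any drug", n_degenerate)
    return pd.DataFrame(out, index=expr.values.index, columns=drugs.values.index)


def select_correlated_genes(
    correlations: pd.DataFrame, threshold: float = 0.5, min_drugs: int = 3
) -> list[str]:
    """Genes with |r| strictly above ``threshold`` for at least ``min_drugs`` drugs."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if min_drugs < 1:
        raise ValueError("min_drugs must be >= 1")
    exceed = (correlations.abs() > threshold).sum(axis=1)
    selected = [g for g in correlations.index if exceed[g] >= min_drugs]
    log.info("selected %d/%d genes (|r| > %g for >= %d drugs)",
             len(selected), correlations.shape[0], threshold, min_drugs)
    return selected


def _profile_distances(profiles: np.ndarray, distance: str) -> np.ndarray:
    if distance == "spearman":
        profiles = np.apply_along_axis(rankdata, 1, profiles)
    elif distance != "centered_correlation":
        raise ValueError(f"unknown distance {distance!r}")
    dists = pdist(profiles, metric="correlation")
    if not np.all(np.isfinite(dists)):
        raise ValueError(
            "correlation distance undefined for constant profiles; "
            "remove degenerate genes first"
        )
    return dists


def split_response_signatures(
    correlations: pd.DataFrame,
    genes: Sequence[str] | None = None,
    linkage_method: str = "average",
    distance: str = "centered_correlation",
) -> ResponseSignaturePair:
    """Split selected genes into positive/negative response signatures.

    Gene correlation profiles are clustered hierarchically (average linkage,
    centered-correlation or Spearman distance) and the tree is cut at its
    root into exactly two clusters.  The cluster with the larger mean
    profile value is labeled positive.  All-identical profiles are an error
    (the correlation distance is undefined there).
    """
    if genes is not None:
        correlations = correlations.loc[list(genes)]
    profiles = correlations.to_numpy(dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 genes to split into two signatures")
    if np.isnan(profiles).any():
        raise ValueError("correlation profiles of selected genes must be complete")
    dists = _profile_distances(profiles, distance)
    tree = linkage(dists, method=linkage_method)
    labels = fcluster(tree, t=2, criterion="maxclust")
    if len(set(labels)) < 2:
        raise ValueError("clustering produced a single cluster; profiles may be degenerate")
    gene_ids = np.array(correlations.index)
    means = {lab: profiles[labels == lab].mean() for lab in (1, 2)}
    pos_label = 1 if means[1] >= means[2] else 2
    positive = tuple(gene_ids[labels == pos_label])
    negative = tuple(gene_ids[labels != pos_label])
    med = pd.DataFrame(
        {
            drug: {
                "positive": float(np.median(correlations.loc[list(positive), drug])),
                "negative": float(np.median(correlations.loc[list(negative), drug])),
            }
            for drug in correlations.columns
        }
    )
    return ResponseSignaturePair(positive, negative, med)


def median_set_correlation(
    correlations: pd.DataFrame, gene_set: Iterable[str]
) -> tuple[pd.Series, float]:
    """Per-drug median correlation over the set's genes, plus the median of
    those per-drug medians.  Even-sized medians are the mean of the middle
    two values."""
    present = [g for g in gene_set if g in correlations.index]
    if not present:
        raise ValueError("gene set shares no genes with the correlation matrix")
    per_drug = correlations.loc[present].median(axis=0)
    overall = float(per_drug.median())
    return per_drug, overall


def rank_response_association(
    ranks: pd.Series, drugs: DrugResponseMatrix
) -> pd.Series:
    """Spearman correlation between a signature rank order and −log(GI50),
    per drug, across the shared cell lines.

    ``ranks`` is one rank-table column restricted to a line panel (index =
    cell-line ids).  Drugs with fewer than 3 observed shared lines get NaN.
    """
    shared = [s for s in ranks.index if s in set(drugs.cell_line_ids)]
    if len(shared) < MIN_OBS:
        raise ValueError(f"need >= {MIN_OBS} shared cell lines, found {len(shared)}")
    out = {}
    for drug in drugs.drug_ids:
        y = drugs.values.loc[drug, shared]
        obs = y.notna()
        if obs.sum() < MIN_OBS:
            out[drug] = float("nan")
            continue
        rho = spearmanr(ranks[shared][obs.to_numpy()], y[obs]).statistic
        out[drug] = float(rho)
    return pd.Series(out, name="spearman_r")
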