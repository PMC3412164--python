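"""Gene set enrichment analysis with a gene-set resampling null.

The enrichment score is the weighted Kolmogorov–Smirnov-style running-sum
statistic of Subramanian et al. (hits increment by |metric|^p normalized
over hits, misses decrement by 1/(N−Nh); ES = signed maximum deviation).
Significance, however, is assessed against a null distribution built by
drawing random gene sets of the same cardinality from the ranked list —
NOT by phenotype permutation.

NES = ES / mean(|null ES|) over the same-sign null scores; the p-value uses
the add-one estimator so it can never be exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_expression import ExpressionMatrix, GeneSetCollection, SampleGrouping

log = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "rank_genes_vs_reference",
    "make_ranked_list",
    "enrichment_score",
    "gsea_with_geneset_null",
    "gsea_two_condition",
]


@dataclass
class RankedGeneList:
    """Genes ordered by a ranking metric (non-increasing)."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.shape[0]:
            raise ValueError("genes and metric lengths differ")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if np.any(np.diff(self.metric) > 1e-12):
            raise ValueError("metric must be non-increasing down the list")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class EnrichmentResult:
    """GSEA outcome for one gene set under the resampling null."""

    name: str
    size: int                 # |set ∩ ranked list|
    es: float
    nes: float
    p_value: float
    fdr: float                # NaN unless computed across a collection
    n_resamples: int
    stable: bool = True       # False when no same-sign nulls were observed

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise ValueError(f"ES out of [-1, 1]: {self.es}")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")
        if self.stable and not math.isnan(self.nes) and self.nes * self.es < 0:
            raise ValueError("NES must share the sign of ES")


def make_ranked_list(genes: Iterable[str], metric: Iterable[float]) -> RankedGeneList:
    """Sort (gene, metric) pairs by descending metric, ties lexicographic."""
    pairs = sorted(zip(genes, metric), key=lambda gm: (-gm[1], gm[0]))
    return RankedGeneList([g for g, _ in pairs], np.array([m for _, m in pairs]))


def rank_genes_vs_reference(
    matrix: ExpressionMatrix,
    grouping: SampleGrouping,
    target: str,
    reference_groups: Sequence[str],
) -> RankedGeneList:
    """Rank genes by mean(target replicates) − mean(pooled reference samples)."""
    if not reference_groups:
        raise ValueError("reference pool is empty")
    t_samples = grouping.samples_of(target)
    r_samples = [s for g in reference_groups for s in grouping.samples_of(g)]
    if not r_samples:
        raise ValueError("reference pool is empty")
    vals = matrix.values
    metric = vals[t_samples].mean(axis=1) - vals[r_samples].mean(axis=1)
    return make_ranked_list(vals.index, metric.to_numpy())


# ---------------------------------------------------------------------------
# Enrichment score
# ---------------------------------------------------------------------------


def _hit_weights(abs_metric_p: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Normalized hit increments; uniform fallback when all weights are zero."""
    w = abs_metric_p[positions]
    total = w.sum()
    if total == 0.0:
        return np.full(len(positions), 1.0 / len(positions))
    return w / total


def _es_from_positions(
    abs_metric_p: np.ndarray, positions: np.ndarray, n: int
) -> float:
    """ES evaluated from sorted hit positions in O(|set|).

    Candidate extrema of the running sum occur at hit positions (maxima)
    and immediately before hit positions (minima).  The signed extreme of
    larger magnitude wins; magnitudes equal to within a small relative
    tolerance (exact rational ties blurred by float rounding) resolve to
    the positive extreme.
    """
    k = len(positions)
    if k == 0:
        raise ValueError("gene set shares no genes with the ranked list")
    if k >= n:
        raise ValueError("gene set covers the entire ranked list")
    d = 1.0 / (n - k)
    w = _hit_weights(abs_metric_p, positions)
    cumw = np.cumsum(w)
    i = np.arange(k)
    misses_before = positions - i
    at_hit = cumw - misses_before * d                    # value at index positions[i]
    before_hit = cumw - w - misses_before * d            # value at index positions[i]-1
    max_val = float(at_hit.max())
    valid = positions > 0
    min_val = float(before_hit[valid].min()) if valid.any() else 0.0
    return _pick_extreme(max_val, min_val)


def _pick_extreme(max_val: float, min_val: float) -> float:
    """Signed maximum deviation; |ties| (to 1e-9 relative) go positive."""
    tol = 1e-9 * max(1.0, abs(max_val), abs(min_val))
    return max_val if abs(max_val) - abs(min_val) >= -tol else min_val


def enrichment_score(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Enrichment score and full running-sum profile for one gene set.

    Returns ``(es, running)`` where ``running[j]`` is the running sum after
    the gene at rank ``j`` (0-based).  ES is the running-sum value of
    largest magnitude; positive/negative magnitude ties resolve positive.
    """
    members = set(gene_set)
    n = len(ranked)
    hits = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    k = int(hits.sum())
    if k == 0:
        raise ValueError("gene set shares no genes with the ranked list")
    if k == n:
        raise ValueError("gene set covers the entire ranked list (miss penalty undefined)")
    abs_p = np.abs(ranked.metric) ** weight_exponent
    positions = np.flatnonzero(hits)
    w = _hit_weights(abs_p, positions)
    steps = np.full(n, -1.0 / (n - k))
    steps[positions] = w
    running = np.cumsum(steps)
    es = _es_from_positions(abs_p, positions, n)
    return es, running


# ---------------------------------------------------------------------------
# Resampling null
# ---------------------------------------------------------------------------


def _null_scores(
    abs_p: np.ndarray,
    n: int,
    k: int,
    n_resamples: int,
    rng: np.random.Generator,
    with_replacement: bool,
) -> np.ndarray:
    out = np.empty(n_resamples)
    for i in range(n_resamples):
        pos = rng.choice(n, size=k, replace=with_replacement)
        pos = np.unique(pos) if with_replacement else np.sort(pos)
        out[i] = _es_from_positions(abs_p, pos, n)
    return out


def _gsea_single(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    name: str,
    n_resamples: int,
    rng: np.random.Generator,
    weight_exponent: float,
    with_replacement: bool,
) -> tuple[EnrichmentResult, np.ndarray]:
    members = set(gene_set)
    positions = np.flatnonzero(np.fromiter((g in members for g in ranked.genes), dtype=bool, count=len(ranked)))
    k = len(positions)
    n = len(ranked)
    if k == 0:
        raise ValueError(f"gene set {name!r} shares no genes with the ranked list")
    abs_p = np.abs(ranked.metric) ** weight_exponent
    es = _es_from_positions(abs_p, positions, n)
    null = _null_scores(abs_p, n, k, n_resamples, rng, with_replacement)
    if es == 0.0:
        result = EnrichmentResult(name, k, 0.0, 0.0, 1.0, float("nan"), n_resamples)
        return result, null
    same_sign = null[np.sign(null) == np.sign(es)]
    if same_sign.size == 0:
        log.warning("gene set %r: no same-sign null scores; NES unstable", name)
        result = EnrichmentResult(
            name, k, es, float("nan"), 1.0 / (n_resamples + 1), float("nan"),
            n_resamples, stable=False,
        )
        return result, null
    p = (1 + int((np.abs(same_sign) >= abs(es)).sum())) / (1 + same_sign.size)
    nes = es / float(np.abs(same_sign).mean())
    result = EnrichmentResult(name, k, es, nes, p, float("nan"), n_resamples)
    return result, null


def gsea_with_geneset_null(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    n_resamples: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    with_replacement: bool = False,
    name: str = "set",
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Test one gene set against the gene-set resampling null.

    The null distribution is the ES of ``n_resamples`` random gene sets of
    the same cardinality drawn (by default without replacement) from the
    genes of the ranked list itself.  The p-value is the add-one tail
    estimate among same-sign null scores; NES divides ES by the mean
    magnitude of same-sign null scores.  Fixed ``seed`` gives bit-identical
    results.
    """
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    result, _ = _gsea_single(
        ranked, gene_set, name, n_resamples, rng, weight_exponent, with_replacement
    )
    return result


def _fdr_q(observed_nes: list[float], pooled_null_nes: np.ndarray) -> list[float]:
    """Subramanian-style FDR q-values from pooled normalized null scores."""
    obs = np.array(observed_nes)
    qs: list[float] = []
    for nes in obs:
        if math.isnan(nes):
            qs.append(float("nan"))
            continue
        if nes >= 0:
            null_pos = pooled_null_nes[pooled_null_nes >= 0]
            num = (null_pos >= nes).mean() if null_pos.size else 0.0
            obs_pos = obs[obs >= 0]
            den = (obs_pos >= nes).mean() if obs_pos.size else 1.0
        else:
            null_neg = pooled_null_nes[pooled_null_nes < 0]
            num = (null_neg <= nes).mean() if null_neg.size else 0.0
            obs_neg = obs[obs < 0]
            den = (obs_neg <= nes).mean() if obs_neg.size else 1.0
        qs.append(min(1.0, num / den) if den > 0 else float("nan"))
    return qs


def gsea_two_condition(
    matrix: ExpressionMatrix,
    grouping: SampleGrouping,
    cond_a: str,
    cond_b: str,
    sets: GeneSetCollection,
    n_resamples: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    with_replacement: bool = False,
) -> list[EnrichmentResult]:
    """GSEA of every set for condition ``cond_a`` versus ``cond_b``.

    Genes are ranked by the difference of group means (a − b); each set is
    evaluated against its own resampling null; FDR q-values pool the
    normalized null scores across sets.  Results are sorted by descending
    NES.
    """
    a_samples = grouping.samples_of(cond_a)
    b_samples = grouping.samples_of(cond_b)
    vals = matrix.values
    metric = vals[a_samples].mean(axis=1) - vals[b_samples].mean(axis=1)
    ranked = make_ranked_list(vals.index, metric.to_numpy())
    if len(sets) == 0:
        return []
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    pooled: list[np.ndarray] = []
    for set_name in sets.names:
        res, null = _gsea_single(
            ranked, sets[set_name], set_name, n_resamples, rng,
            weight_exponent, with_replacement,
        )
        results.append(res)
        pos = null[null > 0]
        neg = null[null < 0]
        norm = np.concatenate([
            pos / pos.mean() if pos.size else pos,
            neg / np.abs(neg).mean() if neg.size else neg,
        ])
        pooled.append(norm)
    qs = _fdr_q([r.nes for r in results], np.concatenate(pooled))
    results = [replace(r, fdr=q) for r, q in zip(results, qs)]
    results.sort(key=lambda r: (math.isnan(r.nes), -(r.nes if not math.isnan(r.nes) else 0.0)))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate results (set, size, ES, NES, p, FDR) for TSV output."""
    return pd.DataFrame(
        {
            "set": [r.name for r in results],
            "size": [r.size for r in results],
            "ES": [r.es for r in results],
            "NES": [r.nes for r in results],
            "p": [r.p_value for r in results],
            "FDR": [r.fdr for r in results],
        }
    )
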