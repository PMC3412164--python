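"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use explicit Python loops and textbook
definitions so they stay independent of the vectorized implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sigrank.io_expression import ExpressionMatrix, GeneSetCollection, SampleGrouping


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def es_oracle(genes, metric, members, p):
    """Step-by-step running-sum enrichment score.

    ES = the signed running-sum extreme of larger magnitude; magnitude ties
    (to 1e-9 relative, covering exact rational ties blurred by rounding)
    resolve to the positive extreme — the documented package convention.
    """
    members = set(members)
    n = len(genes)
    hits = [g in members for g in genes]
    n_hits = sum(hits)
    assert 0 < n_hits < n
    weights = [abs(m) ** p for m in metric]
    total = sum(w for w, h in zip(weights, hits) if h)
    running = []
    s = 0.0
    for i in range(n):
        if hits[i]:
            s += (weights[i] / total) if total > 0 else 1.0 / n_hits
        else:
            s -= 1.0 / (n - n_hits)
        running.append(s)
    running = np.array(running)
    max_val, min_val = float(running.max()), float(min(running.min(), 0.0))
    tol = 1e-9 * max(1.0, abs(max_val), abs(min_val))
    es = max_val if abs(max_val) - abs(min_val) >= -tol else min_val
    return es, running


def rank_table_oracle(centered: ExpressionMatrix, sets: GeneSetCollection,
                      grouping: SampleGrouping) -> pd.DataFrame:
    """Explicit-loop score + rank computation."""
    groups = grouping.group_labels
    ranks = pd.DataFrame(index=groups, columns=sets.names, dtype=int)
    for sig in sets.names:
        genes = [g for g in sets[sig] if g in centered.values.index]
        assert genes
        scores = []
        for group in groups:
            sample_scores = []
            for sample in grouping.samples_of(group):
                vals = [centered.values.at[g, sample] for g in genes]
                sample_scores.append(sum(vals) / len(vals))
            scores.append(sum(sample_scores) / len(sample_scores))
        # descending, ties by group order
        order = sorted(range(len(groups)), key=lambda i: (-scores[i], i))
        for rank, i in enumerate(order, start=1):
            ranks.loc[groups[i], sig] = rank
    return ranks


def collapse_oracle(values: pd.DataFrame, mapping: dict[str, str]) -> dict[str, str]:
    """Per-gene argmax-SD probe choice by enumeration (ddof=1, lexicographic ties)."""
    by_gene: dict[str, list[str]] = {}
    for probe in values.index:
        if probe in mapping:
            by_gene.setdefault(mapping[probe], []).append(probe)
    chosen = {}
    for gene, probes in by_gene.items():
        best, best_sd = None, -1.0
        for probe in sorted(probes):
            x = values.loc[probe].to_numpy(dtype=float)
            sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
            if sd > best_sd:
                best, best_sd = probe, sd
        chosen[gene] = best
    return chosen


def logrank_oracle(t1, e1, t2, e2):
    """Per-event-time 2x2 hypergeometric log-rank chi-square."""
    t1, e1, t2, e2 = (np.asarray(a, dtype=float) for a in (t1, e1, t2, e2))
    event_times = sorted(set(t1[e1 == 1]) | set(t2[e2 == 1]))
    obs = exp = var = 0.0
    for t in event_times:
        n1 = float((t1 >= t).sum())
        n2 = float((t2 >= t).sum())
        d1 = float(((t1 == t) & (e1 == 1)).sum())
        d2 = float(((t2 == t) & (e2 == 1)).sum())
        n, d = n1 + n2, d1 + d2
        obs += d1
        exp += d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (obs - exp) ** 2 / var


def km_oracle(times, events):
    """Hand product-limit estimator over distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    grid = sorted(set(times[events == 1]))
    surv = []
    s = 1.0
    for t in grid:
        at_risk = float((times >= t).sum())
        d = float(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        surv.append(s)
    return np.array(grid), np.array(surv)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def rng():
    return np.random.default_rng(20120622)


@pytest.fixture
def small_matrix():
    frame = pd.DataFrame(
        {
            "s1": [2.0, 0.0, 5.0],
            "s2": [4.0, 0.0, 5.0],
            "s3": [6.0, 0.0, 5.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    return ExpressionMatrix(frame, level="gene")


@pytest.fixture
def singleton_grouping(small_matrix):
    return SampleGrouping({s: s for s in small_matrix.sample_ids})


def random_gene_matrix(rng, n_genes=20, n_samples=6, prefix="g") -> ExpressionMatrix:
    frame = pd.DataFrame(
        rng.normal(7.0, 1.0, size=(n_genes, n_samples)),
        index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(frame, level="gene")
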