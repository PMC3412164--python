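"""Synthetic expression compendia, GI50 panels and survival cohorts with
planted ground truth, so every pipeline stage can be scored against a known
answer.  All generators are pure functions of (spec, seed)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_expression import (
    ExpressionMatrix,
    GeneSetCollection,
    ProbeGeneMap,
    SampleGrouping,
)
from .survival_analysis import SurvivalCohort

__all__ = [
    "SignatureSpec",
    "Gi50Spec",
    "SurvivalSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_expression_compendium",
    "generate_gi50_matrix",
    "generate_drug_response_scenario",
    "generate_survival_cohort",
]


@dataclass(frozen=True)
class SignatureSpec:
    """A planted gene set: ``size`` genes receiving a per-group mean shift.

    ``group_shifts`` has one log2 shift per group.  With ``bipolar=True``
    the first half of the set's genes get ``+shift`` and the second half
    ``-shift`` (used to plant anti-correlated response signatures).
    """

    name: str
    size: int
    group_shifts: tuple[float, ...]
    bipolar: bool = False


@dataclass(frozen=True)
class Gi50Spec:
    n_drugs: int = 50
    n_lines: int = 59
    n_coupled: int = 60          # half positively, half negatively coupled
    slope: float = 1.0
    slope_jitter: float = 0.5    # per-drug slope spread (fraction of slope)
    noise_sd: float = 0.3
    line_effect_sd: float = 1.0  # SD of the planted per-line latent shift


@dataclass(frozen=True)
class SurvivalSpec:
    baseline_hazard: float = 0.05
    log_hazard_per_score: float = 0.0
    censor_fraction: float = 0.0  # per-patient probability of censoring


@dataclass(frozen=True)
class SyntheticSpec:
    n_genes: int = 500
    n_groups: int = 6
    replicates: int = 3
    signatures: tuple[SignatureSpec, ...] = ()
    noise_sd: float = 0.5
    baseline: float = 7.0
    baseline_sd: float = 1.0
    probes_per_gene: tuple[int, int] = (2, 4)     # inclusive range
    probe_sd_spread: tuple[float, float] = (0.5, 2.0)  # × noise_sd
    gi50: Gi50Spec = field(default_factory=Gi50Spec)
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_groups, self.replicates) < 1:
            raise ValueError("all counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.survival.censor_fraction < 1.0:
            raise ValueError("censor_fraction must be in [0, 1)")
        for sig in self.signatures:
            if len(sig.group_shifts) != self.n_groups:
                raise ValueError(
                    f"signature {sig.name!r}: {len(sig.group_shifts)} shifts "
                    f"for {self.n_groups} groups"
                )
        if sum(s.size for s in self.signatures) > self.n_genes:
            raise ValueError("planted signature genes exceed n_genes")


@dataclass
class GroundTruth:
    """Everything needed to score pipeline recovery without re-derivation."""

    group_order: dict[str, list[str]]          # signature -> groups, strongest first
    memberships: dict[str, list[str]]          # signature -> genes
    signs: dict[str, dict[str, int]]           # signature -> gene -> +1/-1
    response_positive: list[str] = field(default_factory=list)
    response_negative: list[str] = field(default_factory=list)
    hazard_ratio_per_score: float = 1.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_order": self.group_order,
            "memberships": self.memberships,
            "signs": self.signs,
            "response_positive": self.response_positive,
            "response_negative": self.response_negative,
            "hazard_ratio_per_score": self.hazard_ratio_per_score,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _planted_gene_matrix(
    spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[pd.DataFrame, SampleGrouping, GroundTruth]:
    genes = _gene_ids(spec.n_genes)
    groups = [f"GRP{i:02d}" for i in range(spec.n_groups)]
    samples = [f"{g}_r{j}" for g in groups for j in range(spec.replicates)]
    grouping = SampleGrouping({s: s.rsplit("_r", 1)[0] for s in samples})

    baseline = spec.baseline + rng.normal(0.0, spec.baseline_sd, size=spec.n_genes)
    shift = np.zeros((spec.n_genes, spec.n_groups))
    memberships: dict[str, list[str]] = {}
    signs: dict[str, dict[str, int]] = {}
    order: dict[str, list[str]] = {}
    cursor = 0
    for sig in spec.signatures:
        members = genes[cursor : cursor + sig.size]
        cursor += sig.size
        memberships[sig.name] = members
        sgn = {
            g: (-1 if sig.bipolar and i >= sig.size // 2 else 1)
            for i, g in enumerate(members)
        }
        signs[sig.name] = sgn
        start = cursor - sig.size
        for i, g in enumerate(members):
            shift[start + i] = sgn[g] * np.asarray(sig.group_shifts)
        # strongest group first; ties keep group order (stable sort)
        order[sig.name] = [
            groups[i] for i in np.argsort(-np.asarray(sig.group_shifts), kind="stable")
        ]
    group_of = np.repeat(np.arange(spec.n_groups), spec.replicates)
    mean = baseline[:, None] + shift[:, group_of]
    values = mean + rng.normal(0.0, spec.noise_sd, size=mean.shape)
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    truth = GroundTruth(group_order=order, memberships=memberships, signs=signs)
    return frame, grouping, truth


def generate_expression_compendium(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, SampleGrouping, ProbeGeneMap, GeneSetCollection, GroundTruth]:
    """Replicate-structured probe-level compendium with planted set shifts.

    Gene-level truth = baseline + per-group shift (signature genes) +
    Gaussian(0, noise_sd).  Each gene is expanded to several probes sharing
    the gene signal but differing in constant offset and in extra noise SD
    (scaled by ``noise_sd``, so the noise-free limit stays exact), which
    makes the max-SD collapse rule non-trivial.
    """
    rng = np.random.default_rng(spec.seed)
    gene_frame, grouping, truth = _planted_gene_matrix(spec, rng)
    lo, hi = spec.probes_per_gene
    probe_rows = []
    probe_ids = []
    mapping: dict[str, str] = {}
    n_samples = gene_frame.shape[1]
    for gene in gene_frame.index:
        m = int(rng.integers(lo, hi + 1))
        offsets = rng.normal(0.0, 0.5, size=m)
        sd_lo, sd_hi = spec.probe_sd_spread
        probe_sds = rng.uniform(sd_lo, sd_hi, size=m) * spec.noise_sd
        base = gene_frame.loc[gene].to_numpy()
        for j in range(m):
            pid = f"{gene}_p{j}"
            probe_ids.append(pid)
            mapping[pid] = str(gene)
            probe_rows.append(base + offsets[j] + rng.normal(0.0, probe_sds[j], size=n_samples))
    probe_frame = pd.DataFrame(
        np.array(probe_rows), index=pd.Index(probe_ids, name="probe"), columns=gene_frame.columns
    )
    matrix = ExpressionMatrix(probe_frame, level="probe")
    sets = GeneSetCollection(
        {name: tuple(members) for name, members in truth.memberships.items()},
        {name: "planted" for name in truth.memberships},
    )
    return matrix, grouping, ProbeGeneMap(mapping), sets, truth


def generate_gi50_matrix(
    spec: SyntheticSpec,
    expr: ExpressionMatrix,
    coupled: tuple[Sequence[str], Sequence[str]] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple["DrugResponseMatrix", GroundTruth]:
    """−log(GI50) panel linearly coupled to planted genes of ``expr``.

    Response(drug, line) = slope_d × driver(line) + Gaussian(0, noise_sd),
    where driver = mean(centered positive genes) − mean(centered negative
    genes) and slope_d = slope × (1 + U(−jitter, +jitter)) gives each drug
    its own coupling strength (shared across-drug structure that makes the
    two mined clusters separable by profile shape, not just level).  If
    ``coupled`` is not given, genes are drawn at random (half positive,
    half negative).
    """
    from .drug_sensitivity import DrugResponseMatrix  # avoid cycle at import time

    g = spec.gi50
    if expr.shape[1] < 2:
        raise ValueError("GI50 coupling needs at least 2 cell lines (columns)")
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    gene_index = list(expr.values.index)
    if coupled is None:
        if g.n_coupled > len(gene_index):
            raise ValueError("coupled-gene count exceeds available genes")
        chosen = rng.choice(len(gene_index), size=g.n_coupled, replace=False)
        half = g.n_coupled // 2
        pos = [gene_index[i] for i in chosen[:half]]
        neg = [gene_index[i] for i in chosen[half:]]
    else:
        pos, neg = [list(c) for c in coupled]
    centered = expr.values.sub(expr.values.mean(axis=1), axis=0)
    driver = (centered.loc[pos].mean(axis=0) - centered.loc[neg].mean(axis=0)).to_numpy()
    lines = expr.sample_ids
    drugs = [f"D{i:03d}" for i in range(g.n_drugs)]
    drug_slopes = g.slope * (1.0 + rng.uniform(-g.slope_jitter, g.slope_jitter, size=g.n_drugs))
    response = drug_slopes[:, None] * driver[None, :] + rng.normal(
        0.0, g.noise_sd, size=(g.n_drugs, len(lines))
    )
    frame = pd.DataFrame(response, index=pd.Index(drugs, name="drug"), columns=lines)
    truth = GroundTruth(
        group_order={}, memberships={}, signs={},
        response_positive=list(pos), response_negative=list(neg),
    )
    return DrugResponseMatrix(frame), truth


def generate_drug_response_scenario(
    spec: SyntheticSpec,
) -> tuple[ExpressionMatrix, "DrugResponseMatrix", GroundTruth]:
    """Self-contained mining test bed: a gene-level line panel in which the
    coupled genes share a per-line latent shift (positively coupled genes
    +shift, negatively coupled −shift), plus a GI50 matrix driven by it."""
    g = spec.gi50
    rng = np.random.default_rng(spec.seed)
    shifts = tuple(rng.normal(0.0, g.line_effect_sd, size=g.n_lines))
    panel_spec = SyntheticSpec(
        n_genes=spec.n_genes,
        n_groups=g.n_lines,
        replicates=1,
        signatures=(SignatureSpec("coupled", g.n_coupled, shifts, bipolar=True),),
        noise_sd=spec.noise_sd,
        baseline=spec.baseline,
        baseline_sd=spec.baseline_sd,
        seed=spec.seed,
    )
    frame, _grouping, truth = _planted_gene_matrix(panel_spec, np.random.default_rng(spec.seed))
    frame.columns = [f"LINE{i:02d}" for i in range(g.n_lines)]
    expr = ExpressionMatrix(frame, level="gene")
    members = truth.memberships["coupled"]
    sgn = truth.signs["coupled"]
    pos = [m for m in members if sgn[m] > 0]
    neg = [m for m in members if sgn[m] < 0]
    gi50, gi_truth = generate_gi50_matrix(
        spec, expr, coupled=(pos, neg), rng=np.random.default_rng(spec.seed + 1)
    )
    gi_truth.memberships = truth.memberships
    gi_truth.signs = truth.signs
    return expr, gi50, gi_truth


def generate_survival_cohort(
    spec: SyntheticSpec,
    scores: Sequence[float],
    rng: np.random.Generator | None = None,
) -> SurvivalCohort:
    """Exponential event times with rate baseline × exp(loghr × score).

    Censoring times are independent exponentials tuned so each patient is
    censored with probability ``censor_fraction``; at 0 every record is an
    event.
    """
    s = spec.survival
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    scores = np.asarray(scores, dtype=float)
    rates = s.baseline_hazard * np.exp(s.log_hazard_per_score * scores)
    event_times = rng.exponential(1.0 / rates)
    if s.censor_fraction > 0:
        c = s.censor_fraction
        censor_rates = rates * c / (1.0 - c)
        censor_times = rng.exponential(1.0 / censor_rates)
        times = np.minimum(event_times, censor_times)
        events = (event_times <= censor_times).astype(int)
    else:
        times, events = event_times, np.ones(len(scores), dtype=int)
    data = pd.DataFrame(
        {
            "time": times,
            "event": events,
            "score": scores,
        },
        index=pd.Index([f"P{i:04d}" for i in range(len(scores))], name="patient_id"),
    )
    return SurvivalCohort(data)
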