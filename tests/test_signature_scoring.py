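import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from sigrank.io_expression import ExpressionMatrix, GeneSetCollection, SampleGrouping
from sigrank.signature_scoring import (
    build_rank_table,
    center_genes,
    derive_fold_change_signature,
    pca_project,
    score_gene_set,
    score_samples,
)
from sigrank.synthetic_data import SignatureSpec, SyntheticSpec, generate_expression_compendium
from sigrank.io_expression import collapse_probes_max_sd, quantile_normalize

from conftest import random_gene_matrix, rank_table_oracle


# ---------------------------------------------------------------------------
# centering
# ---------------------------------------------------------------------------


def test_center_genes_hand_examples():
    frame = pd.DataFrame(
        {"s1": [2.0, -1.0, 5.0], "s2": [4.0, 0.0, 5.0], "s3": [6.0, 1.0, 5.0]},
        index=["a", "b", "c"],
    )
    out = center_genes(ExpressionMatrix(frame, level="gene"))
    assert np.allclose(out.values.loc["a"], [-2.0, 0.0, 2.0])
    assert np.allclose(out.values.loc["b"], [-1.0, 0.0, 1.0])  # already centered
    assert np.allclose(out.values.loc["c"], [0.0, 0.0, 0.0])   # constant row
    assert np.allclose(out.values.mean(axis=1), 0.0)


def test_center_genes_requires_gene_level():
    frame = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["p"])
    with pytest.raises(ValueError):
        center_genes(ExpressionMatrix(frame, level="probe"))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def test_score_gene_set_arithmetic(small_matrix, singleton_grouping):
    centered = center_genes(small_matrix)
    scores = score_gene_set(centered, ["g1", "g2"], singleton_grouping)
    assert np.allclose(scores[["s1", "s2", "s3"]], [-1.0, 0.0, 1.0])


def test_score_gene_set_drops_missing_genes_with_warning(small_matrix, singleton_grouping, caplog):
    centered = center_genes(small_matrix)
    with caplog.at_level("WARNING"):
        scores = score_gene_set(centered, ["g1", "gX"], singleton_grouping, name="S")
    only_g1 = score_gene_set(centered, ["g1"], singleton_grouping)
    assert np.allclose(scores, only_g1)
    assert any("absent" in r.message for r in caplog.records)


def test_score_gene_set_empty_intersection_names_set(small_matrix, singleton_grouping):
    centered = center_genes(small_matrix)
    with pytest.raises(ValueError, match="MYSET"):
        score_gene_set(centered, ["nope"], singleton_grouping, name="MYSET")


def test_score_single_group_of_all_samples_is_zero(small_matrix):
    centered = center_genes(small_matrix)
    grouping = SampleGrouping({s: "all" for s in small_matrix.sample_ids})
    scores = score_gene_set(centered, ["g1"], grouping)
    assert abs(scores["all"]) < 1e-12


# ---------------------------------------------------------------------------
# rank table
# ---------------------------------------------------------------------------


def _three_group_matrix(scores_by_group):
    """One-gene matrix whose centered values realize the given group scores."""
    frame = pd.DataFrame({g: [v] for g, v in scores_by_group.items()}, index=["g1"])
    return ExpressionMatrix(frame, level="gene"), SampleGrouping(
        {g: g for g in scores_by_group}
    )


def test_rank_table_sort_order():
    m, grouping = _three_group_matrix({"A": 0.5, "B": -1.2, "C": 3.0})
    sets = GeneSetCollection({"S": ("g1",)})
    table = build_rank_table(center_genes(m), sets, grouping)
    assert table.ranks["S"].tolist() == [2, 3, 1]


def test_rank_table_tie_break_follows_group_order():
    m, grouping = _three_group_matrix({"B": 1.0, "A": 1.0, "C": 0.0})
    sets = GeneSetCollection({"S": ("g1",)})
    table = build_rank_table(center_genes(m), sets, grouping)
    # B appears first in the grouping, so it wins the tie
    assert table.rank_of("B", "S") == 1
    assert table.rank_of("A", "S") == 2
    assert table.rank_of("C", "S") == 3


def test_rank_columns_are_permutations(rng):
    m = random_gene_matrix(rng, n_genes=40, n_samples=12)
    grouping = SampleGrouping({s: f"grp{i // 3}" for i, s in enumerate(m.sample_ids)})
    sets = GeneSetCollection({f"S{k}": tuple(rng.choice(m.feature_ids, 8, replace=False))
                              for k in range(5)})
    table = build_rank_table(center_genes(m), sets, grouping)
    for sig in sets.names:
        assert sorted(table.ranks[sig]) == [1, 2, 3, 4]


def test_rank_table_matches_bruteforce_oracle(rng):
    for _ in range(10):
        m = random_gene_matrix(rng, n_genes=200, n_samples=12)
        grouping = SampleGrouping({s: f"grp{i // 3}" for i, s in enumerate(m.sample_ids)})
        sets = GeneSetCollection(
            {f"S{k}": tuple(rng.choice(m.feature_ids, rng.integers(3, 30), replace=False))
             for k in range(4)}
        )
        centered = center_genes(m)
        table = build_rank_table(centered, sets, grouping)
        expected = rank_table_oracle(centered, sets, grouping)
        assert table.ranks.equals(expected.astype(int))


def test_scores_invariant_to_global_constant_shift(rng):
    m = random_gene_matrix(rng, n_genes=30, n_samples=9)
    grouping = SampleGrouping({s: f"grp{i // 3}" for i, s in enumerate(m.sample_ids)})
    sets = GeneSetCollection({"S": tuple(m.feature_ids[:10])})
    base = build_rank_table(center_genes(m), sets, grouping)
    shifted = ExpressionMatrix(m.values + 7.25, level="gene")
    moved = build_rank_table(center_genes(shifted), sets, grouping)
    assert np.allclose(base.scores.to_numpy(), moved.scores.to_numpy())


def test_planted_order_recovered_noise_free():
    spec = SyntheticSpec(
        n_genes=100, n_groups=3, replicates=2,
        signatures=(SignatureSpec("S", 20, (2.0, 0.0, 4.0)),),
        noise_sd=1e-12, seed=11,
    )
    probes, grouping, pmap, sets, truth = generate_expression_compendium(spec)
    gene = collapse_probes_max_sd(quantile_normalize(probes), pmap)
    table = build_rank_table(center_genes(gene), sets, grouping)
    recovered = table.ranks["S"].sort_values().index.tolist()
    assert recovered == truth.group_order["S"] == ["GRP02", "GRP00", "GRP01"]


# ---------------------------------------------------------------------------
# fold-change signature rule
# ---------------------------------------------------------------------------


def test_fold_change_signature_rule():
    frame = pd.DataFrame(
        {
            "t1": [4.0, 2.3, 6.0],
            "t2": [4.0, 2.3, 6.0],
            "r1": [1.5, 1.5, 3.0],
            "r2": [1.5, 1.5, 3.0],
        },
        index=["SLC7A5", "SLC2A1", "KRT20"],
    )
    m = ExpressionMatrix(frame, level="gene")
    grouping = SampleGrouping({"t1": "SI", "t2": "SI", "r1": "pool", "r2": "pool"})
    sig = derive_fold_change_signature(m, grouping, "SI", "pool", "SLC", min_fold=2.0)
    # SLC7A5 diff 2.5 >= 1 -> in; SLC2A1 diff 0.8 -> out; KRT20 fails prefix
    assert sig == ("SLC7A5",)


def test_fold_change_signature_no_prefix_match_warns(caplog):
    frame = pd.DataFrame({"t": [5.0], "r": [1.0]}, index=["KRT20"])
    m = ExpressionMatrix(frame, level="gene")
    grouping = SampleGrouping({"t": "A", "r": "B"})
    with caplog.at_level("WARNING"):
        sig = derive_fold_change_signature(m, grouping, "A", "B", "SLC")
    assert sig == ()
    assert any("prefix" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def _pca_oracle(matrix: ExpressionMatrix):
    """Direct eigendecomposition of the sample-profile covariance."""
    centered = matrix.values.sub(matrix.values.mean(axis=1), axis=0).to_numpy().T
    cov = centered @ centered.T
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > max(1e-10, evals[0] * 1e-12)
    evals, evecs = evals[keep], evecs[:, keep]
    scores = evecs * np.sqrt(evals)
    loadings = (centered.T @ evecs) / np.sqrt(evals)
    for i in range(scores.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, i])))
        if loadings[j, i] < 0:
            loadings[:, i] *= -1
            scores[:, i] *= -1
    return scores, evals / (centered ** 2).sum()


def test_pca_matches_eigendecomposition_oracle(rng):
    for _ in range(5):
        m = random_gene_matrix(rng, n_genes=20, n_samples=6)
        res = pca_project(m)
        scores, evr = _pca_oracle(m)
        assert np.allclose(res.scores.to_numpy(), scores, atol=1e-8)
        assert np.allclose(res.explained_variance_ratio, evr, atol=1e-10)


def test_pca_two_samples_single_component(rng):
    m = random_gene_matrix(rng, n_genes=15, n_samples=2)
    res = pca_project(m)
    assert res.scores.shape[1] == 1
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_duplicated_samples_share_coordinates(rng):
    m = random_gene_matrix(rng, n_genes=25, n_samples=3)
    dup = pd.concat([m.values, m.values.add_suffix("_copy")], axis=1)
    res = pca_project(ExpressionMatrix(dup, level="gene"))
    for s in m.sample_ids:
        assert np.allclose(res.scores.loc[s], res.scores.loc[f"{s}_copy"], atol=1e-8)


def test_pca_planted_clusters_separate_on_pc1(rng):
    n = 40
    cluster = np.repeat([0.0, 8.0], 4)
    frame = pd.DataFrame(
        rng.normal(0, 0.2, size=(n, 8)) + cluster[None, :],
        index=[f"g{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(8)],
    )
    res = pca_project(ExpressionMatrix(frame, level="gene"))
    pc1 = res.scores.iloc[:, 0].to_numpy()
    assert max(pc1[:4]) < min(pc1[4:]) or min(pc1[:4]) > max(pc1[4:])


def test_pca_feature_filter(rng):
    m = random_gene_matrix(rng, n_genes=30, n_samples=5)
    res = pca_project(m, feature_filter=m.feature_ids[:10])
    direct = pca_project(
        ExpressionMatrix(m.values.iloc[:10], level="gene")
    )
    assert np.allclose(res.scores.to_numpy(), direct.scores.to_numpy(), atol=1e-10)
    with pytest.raises(ValueError, match="eliminates"):
        pca_project(m, feature_filter=["absent"])


# ---------------------------------------------------------------------------
# rank-recovery property (small version; full size in acceptance suite)
# ---------------------------------------------------------------------------


def test_rank_recovery_spearman_small():
    rhos = []
    for seed in range(10):
        sigma = 0.5
        spec = SyntheticSpec(
            n_genes=120, n_groups=6, replicates=3,
            signatures=(SignatureSpec("S", 30, tuple(2 * sigma * i for i in range(6))),),
            noise_sd=sigma, seed=seed,
        )
        probes, grouping, pmap, sets, truth = generate_expression_compendium(spec)
        gene = collapse_probes_max_sd(quantile_normalize(probes), pmap)
        table = build_rank_table(center_genes(gene), sets, grouping)
        planted = {g: r for r, g in enumerate(truth.group_order["S"], start=1)}
        rho = spearmanr(
            [planted[g] for g in table.ranks.index],
            table.ranks["S"].to_numpy(),
        ).statistic
        rhos.append(rho)
    assert np.median(rhos) >= 0.9
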