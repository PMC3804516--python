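"""Normalization, candidate selection, DE testing, clustering."""

import numpy as np
import pandas as pd
import pytest

from alemut.expression import (
    benjamini_hochberg,
    cluster_de_genes,
    normalize_counts,
    select_candidate_genes,
    upper_quartile_factors,
)
from alemut.expression import test_differential_expression as de_test
from alemut.effects import EffectAnnotation
from alemut.simulate import generate_counts, make_design
from alemut.types import ExpressionMatrix, Gene, GenomeAnnotation, ValidationError


def _matrix(counts: dict, conditions=None):
    df = pd.DataFrame(counts)
    design = pd.DataFrame(
        {
            "sample": list(df.columns),
            "condition": conditions or list(df.columns),
            "replicate": [1] * df.shape[1],
        }
    )
    return ExpressionMatrix(counts=df, design=design)


def test_identical_samples_normalize_identically():
    m = _matrix({"a": [10, 0, 30, 40], "b": [10, 0, 30, 40]})
    norm = normalize_counts(m)
    pd.testing.assert_series_equal(norm.counts["a"], norm.counts["b"], check_names=False)


def test_normalization_hand_arithmetic():
    # sample a: nonzero {8, 16} -> 75th pct 14; sample b: {2, 4} -> 3.5
    m = _matrix({"a": [8.0, 16.0, 0.0], "b": [2.0, 4.0, 0.0]})
    norm = normalize_counts(m)
    fa, fb = 14.0, 3.5
    scale = np.sqrt(fa * fb)
    expected_a = np.log2(np.array([8, 16, 0]) / fa * scale + 1)
    np.testing.assert_allclose(norm.counts["a"].to_numpy(), expected_a)
    expected_b = np.log2(np.array([2, 4, 0]) / fb * scale + 1)
    np.testing.assert_allclose(norm.counts["b"].to_numpy(), expected_b)


def test_post_scaling_upper_quartiles_equalize():
    design = make_design(["x", "y"], 3)
    m, _ = generate_counts(200, design, seed=3)
    norm = normalize_counts(m)
    pre_log = ExpressionMatrix(
        counts=2.0**norm.counts - 1.0, design=norm.design, normalized=True
    )
    f = upper_quartile_factors(pre_log)
    np.testing.assert_allclose(f, f[0])


def test_scaling_is_equivariant_up_to_the_global_factor():
    """Scaling one raw sample by c leaves the scaled matrix unchanged up to
    the common geometric-mean rescale c**(1/m) shared by every column."""
    design = make_design(["x", "y"], 2)
    m, _ = generate_counts(100, design, seed=4)
    c = 7.0
    m2 = ExpressionMatrix(counts=m.counts.copy(), design=m.design.copy())
    m2.counts = m2.counts.astype(float)
    m2.counts.iloc[:, 0] = m2.counts.iloc[:, 0] * c
    s1 = 2.0 ** normalize_counts(m).counts - 1.0
    s2 = 2.0 ** normalize_counts(m2).counts - 1.0
    ratio = (s2 / s1).to_numpy()
    np.testing.assert_allclose(ratio[s1.to_numpy() > 0], c ** (1 / 4), rtol=1e-9)


def test_all_zero_sample_rejected():
    with pytest.raises(ValidationError):
        normalize_counts(_matrix({"a": [1.0, 2.0], "b": [0.0, 0.0]}))


# ---------------------------------------------------------------------------
# candidate genes

def _annotation():
    genes = [Gene(f"g{i}", 1 + 500 * i, 300 + 500 * i, "+") for i in range(6)]
    return GenomeAnnotation(
        genes=genes,
        operons={"op1": ["g0", "g1"]},
        reference_length=4000,
    )


def test_no_mutations_no_candidates():
    assert select_candidate_genes([], _annotation()).genes == []


def test_candidate_rules_enumeration():
    ann = _annotation()
    effects = [EffectAnnotation("v1", "NONSYN", locus_tag="g0")]
    cand = select_candidate_genes(
        effects,
        ann,
        paralog_map={"g0": ["g5"]},
        regulon_map={"g0": ["g2", "g3", "g4"]},
    )
    assert set(cand.genes) == {"g0", "g1", "g2", "g3", "g4", "g5"}
    assert cand.reasons["g0"] == {"mutated"}
    assert "downstream_or_operon" in cand.reasons["g1"]
    assert cand.reasons["g5"] == {"paralog_copy"}
    assert cand.reasons["g2"] == {"regulatory_target"}


# ---------------------------------------------------------------------------
# differential expression

def test_identical_conditions_not_significant():
    df = {"a1": [100, 50], "a2": [100, 50], "b1": [100, 50], "b2": [100, 50]}
    m = _matrix(df, conditions=["base", "base", "trt", "trt"])
    calls = de_test(normalize_counts(m), baseline="base")
    assert all(c.log2_diff == 0 for c in calls)
    assert not any(c.significant for c in calls)


def test_planted_fold_change_power_and_fdr():
    detected, null_calls, null_hits = 0, 0, 0
    n_de_total = 0
    for s in range(40):
        # multi-condition layout as in a hydrolysate dose series
        design = make_design(["base", "mid", "high"], 3)
        m, truth = generate_counts(
            60, design, de_fraction=0.2, log2_fold_change=2.0, dispersion=0.05, seed=500 + s
        )
        calls = de_test(normalize_counts(m), baseline="base")
        sig = {c.locus_tag for c in calls if c.significant}
        de = {g for g, d in zip(m.genes, truth.is_de) if d}
        detected += len(sig & de)
        n_de_total += len(de)
        null_hits += len(sig - de)
        null_calls += len(m.genes) - len(de)
    assert detected / n_de_total >= 0.9
    assert null_hits / null_calls <= 0.05


def test_single_replicate_fallback_has_no_p_values():
    m = _matrix({"a": [100, 4], "b": [400, 4]}, conditions=["base", "trt"])
    calls = de_test(normalize_counts(m), baseline="base")
    assert all(c.p_value is None for c in calls)
    assert any(c.significant for c in calls)  # fold-change-only rule


def test_bh_matches_brute_force():
    def brute(ps, alpha=0.05):
        n = len(ps)
        order = np.argsort(ps)
        reject = np.zeros(n, dtype=bool)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if ps[idx] <= alpha * rank / n:
                k_max = rank
        for rank, idx in enumerate(order, start=1):
            if rank <= k_max:
                reject[idx] = True
        return reject

    rng = np.random.default_rng(8)
    for _ in range(30):
        n = int(rng.integers(1, 101))
        ps = rng.uniform(size=n) ** rng.uniform(0.3, 3)
        np.testing.assert_array_equal(benjamini_hochberg(ps), brute(ps))


def test_null_simulations_respect_significance_budget():
    """Under a global null the full rule fires on well under 7% of genes."""
    hits, total = 0, 0
    for s in range(60):
        design = make_design(["base", "trt"], 3)
        m, _ = generate_counts(50, design, de_fraction=0.0, seed=900 + s)
        calls = de_test(normalize_counts(m), baseline="base")
        hits += sum(c.significant for c in calls)
        total += len(calls)
    assert hits / total <= 0.07


# ---------------------------------------------------------------------------
# clustering

def test_identical_rows_merge_first_at_zero():
    mat = pd.DataFrame(
        [[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]], index=["a", "b", "c"], columns=["c1", "c2"]
    )
    link, order, nwk = cluster_de_genes(mat)
    assert link[0, 2] == 0.0 and {int(link[0, 0]), int(link[0, 1])} == {0, 1}
    assert set(order) == {"a", "b", "c"}


def test_average_linkage_merge_order_hand_trace():
    # distances: a-b=1, c-d=2, (ab)-c etc. large
    mat = pd.DataFrame(
        [[0.0], [1.0], [10.0], [12.0]], index=list("abcd"), columns=["x"]
    )
    link, order, nwk = cluster_de_genes(mat)
    # merge 1: a,b at height 1; merge 2: c,d at height 2;
    # merge 3: average linkage height = mean(|a-c|,|a-d|,|b-c|,|b-d|) = 10.5
    assert {int(link[0, 0]), int(link[0, 1])} == {0, 1} and link[0, 2] == 1.0
    assert {int(link[1, 0]), int(link[1, 1])} == {2, 3} and link[1, 2] == 2.0
    assert link[2, 2] == pytest.approx(10.5)
    assert order in (["a", "b", "c", "d"], ["b", "a", "d", "c"], ["a", "b", "d", "c"], ["b", "a", "c", "d"])


def test_clustering_is_deterministic():
    rng = np.random.default_rng(1)
    mat = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"g{i}" for i in range(8)])
    l1, o1, n1 = cluster_de_genes(mat)
    l2, o2, n2 = cluster_de_genes(mat.copy())
    np.testing.assert_array_equal(l1, l2)
    assert o1 == o2 and n1 == n2


def test_single_gene_trivial_tree():
    mat = pd.DataFrame([[1.0, 2.0]], index=["only"])
    link, order, nwk = cluster_de_genes(mat)
    assert order == ["only"] and nwk == "only;"
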