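import itertools
import math

import numpy as np
import pandas as pd
import pytest

from netatrophy.spins import generate_spins
from netatrophy.transcriptomics import (
    celltype_correlations,
    celltype_scores,
    genewise_screen,
    overrepresentation,
)


def _expr_frame(values, genes, regions=None):
    values = np.asarray(values, dtype=float)
    if regions is None:
        regions = [f"r{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=regions, columns=genes)


# -------------------------------------------------------------- cell scores

def test_class_score_of_identical_columns_is_the_column(rng):
    v = rng.standard_normal(12)
    expr = _expr_frame(np.column_stack([v, v, rng.standard_normal(12)]), ["g1", "g2", "g3"])
    scores = celltype_scores(expr, {"c": ["g1", "g2"]})
    assert np.allclose(scores["c"], v)


def test_single_gene_class_and_missing_genes(rng, caplog):
    v = rng.standard_normal(10)
    expr = _expr_frame(v[:, None], ["g1"])
    with caplog.at_level("WARNING"):
        scores = celltype_scores(expr, {"c": ["g1", "absent"]})
    assert np.allclose(scores["c"], v)
    assert any("missing" in r.message for r in caplog.records)
    with pytest.raises(ValueError, match="empty"):
        celltype_scores(expr, {"empty": ["nope"]})


def test_class_scores_match_per_region_loop(rng):
    """Vectorised class means agree exactly with an explicit loop."""
    n_regions, n_genes = 60, 120
    expr = _expr_frame(
        rng.standard_normal((n_regions, n_genes)), [f"g{i}" for i in range(n_genes)]
    )
    sets = {
        f"c{k}": list(rng.choice(expr.columns, size=rng.integers(3, 15), replace=False))
        for k in range(7)
    }
    scores = celltype_scores(expr, sets)
    for cname, genes in sets.items():
        for i in range(n_regions):
            expected = np.mean([expr.iloc[i][g] for g in genes])
            assert scores[cname].iloc[i] == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------- class correlations

def test_class_identical_to_progression_r_one(small_atlas, rng):
    prog = rng.standard_normal(68)
    scores = pd.DataFrame({"c": prog})
    spins = generate_spins(small_atlas, 20, seed=1)
    res = celltype_correlations(scores, prog, spins)
    assert res["r"].iloc[0] == pytest.approx(1.0)


def test_class_correlation_affine_invariance(small_atlas, rng):
    prog = rng.standard_normal(68)
    s = rng.standard_normal(68)
    spins = generate_spins(small_atlas, 50, seed=2)
    r1 = celltype_correlations(pd.DataFrame({"c": s}), prog, spins)
    r2 = celltype_correlations(pd.DataFrame({"c": 3.0 * s - 7.0}), prog, spins)
    assert r1["r"].iloc[0] == pytest.approx(r2["r"].iloc[0], abs=1e-12)
    assert r1["p_spin"].iloc[0] == r2["p_spin"].iloc[0]


# -------------------------------------------------------------- gene screen

def test_screen_trivial_survivor_and_exclusion(small_atlas, rng, caplog):
    prog = rng.standard_normal(68)
    expr = _expr_frame(
        np.column_stack([prog, rng.standard_normal(68), np.ones(68)]),
        ["match", "noise", "flat"],
        regions=list(small_atlas.region_ids),
    )
    spins = generate_spins(small_atlas, 199, seed=3)
    with caplog.at_level("WARNING"):
        res = genewise_screen(expr, prog, spins)
    assert "match" in res.positive
    assert "flat" not in set(res.table["gene"])
    assert any("constant" in r.message for r in caplog.records)


def test_screen_null_expression_rarely_survives():
    """Pure-noise expression against an independent progression map yields
    (almost) no survivors."""
    from netatrophy.synth import make_atlas

    atlas = make_atlas(110, seed=4)
    good = 0
    for rep in range(10):
        rng = np.random.default_rng(700 + rep)
        expr = _expr_frame(
            rng.standard_normal((220, 500)),
            [f"g{i}" for i in range(500)],
            regions=list(atlas.region_ids),
        )
        prog = rng.standard_normal(220)
        spins = generate_spins(atlas, 200, seed=rng)
        res = genewise_screen(expr, prog, spins)
        if len(res.positive) + len(res.negative) <= 1:
            good += 1
    assert good >= 9


def test_screen_recovers_planted_genes():
    """Genes built from the progression map plus small noise survive in the
    positive list."""
    from netatrophy.synth import make_atlas

    atlas = make_atlas(110, seed=5)
    recovered = []
    for rep in range(5):
        rng = np.random.default_rng(800 + rep)
        prog = rng.standard_normal(220)
        n_genes, n_planted = 1000, 50
        x = rng.standard_normal((220, n_genes))
        x[:, :n_planted] = prog[:, None] + 0.3 * rng.standard_normal((220, n_planted))
        expr = _expr_frame(x, [f"g{i}" for i in range(n_genes)],
                           regions=list(atlas.region_ids))
        spins = generate_spins(atlas, 300, seed=rng)
        res = genewise_screen(expr, prog, spins)
        hits = sum(1 for i in range(n_planted) if f"g{i}" in set(res.positive))
        recovered.append(hits)
    assert all(h >= 45 for h in recovered)


def test_screen_lists_disjoint_and_consistent(small_atlas, rng):
    prog = rng.standard_normal(68)
    expr = _expr_frame(rng.standard_normal((68, 40)), [f"g{i}" for i in range(40)],
                       regions=list(small_atlas.region_ids))
    spins = generate_spins(small_atlas, 99, seed=6)
    res = genewise_screen(expr, prog, spins)
    assert not (set(res.positive) & set(res.negative))
    tbl = res.table.set_index("gene")
    for g in res.positive + res.negative:
        assert tbl.loc[g, "survives"]
        assert tbl.loc[g, "p_fdr"] < 0.05 and tbl.loc[g, "p_spin"] < 0.05


# ------------------------------------------------------- overrepresentation

def test_enrichment_arithmetic_example():
    """Background 100, term 10, target 20, overlap 6: expected 2, fold 3."""
    background = [f"g{i}" for i in range(100)]
    term = background[:10]
    target = background[:6] + background[50:64]
    res = overrepresentation(target, background, {"t": term}).iloc[0]
    assert res["expected"] == pytest.approx(2.0)
    assert res["fold_enrichment"] == pytest.approx(3.0)
    assert res["n_observed"] == 6


def test_enrichment_fold_one_when_overlap_equals_expected():
    background = [f"g{i}" for i in range(100)]
    term = background[:10]
    target = background[:2] + background[20:38]  # overlap 2 = 20*10/100
    res = overrepresentation(target, background, {"t": term}).iloc[0]
    assert res["fold_enrichment"] == pytest.approx(1.0)


def test_enrichment_background_as_target_fold_one():
    background = [f"g{i}" for i in range(60)]
    ann = {"a": background[:10], "b": background[15:40]}
    res = overrepresentation(background, background, ann)
    assert np.allclose(res["fold_enrichment"], 1.0)


def test_hypergeometric_matches_exhaustive_enumeration(rng):
    """On toy tables the upper-tail p equals enumeration over all possible
    overlap counts."""
    for _ in range(20):
        m = int(rng.integers(10, 30))
        k_term = int(rng.integers(2, m - 1))
        n_target = int(rng.integers(2, m - 1))
        background = [f"g{i}" for i in range(m)]
        term = list(rng.choice(background, size=k_term, replace=False))
        target = list(rng.choice(background, size=n_target, replace=False))
        res = overrepresentation(target, background, {"t": term}, min_term_size=1).iloc[0]
        obs = res["n_observed"]
        total = math.comb(m, n_target)
        p_enum = sum(
            math.comb(k_term, k) * math.comb(m - k_term, n_target - k)
            for k in range(obs, min(k_term, n_target) + 1)
            if n_target - k <= m - k_term
        ) / total
        assert res["p_hyper"] == pytest.approx(p_enum, rel=1e-10)


def test_hypergeometric_equals_fisher_tail(rng):
    for _ in range(20):
        m = int(rng.integers(20, 200))
        background = [f"g{i}" for i in range(m)]
        term = list(rng.choice(background, size=int(rng.integers(5, m // 2)), replace=False))
        target = list(rng.choice(background, size=int(rng.integers(5, m // 2)), replace=False))
        res = overrepresentation(target, background, {"t": term}).iloc[0]
        assert abs(res["p_hyper"] - res["p_fisher"]) <= 1e-12


def test_enrichment_validation():
    background = ["a", "b", "c"]
    with pytest.raises(ValueError, match="not in background"):
        overrepresentation(["z"], background, {})
    with pytest.raises(ValueError, match="empty background"):
        overrepresentation([], [], {})
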