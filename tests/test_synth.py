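import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netatrophy.datatypes import CohortParams, SpreadParams
from netatrophy.synth import (
    disease_trajectory,
    make_atlas,
    make_cohort,
    make_connectome,
    make_dataset,
    make_expression,
    simulate_spread,
)

from conftest import path_graph


# ---------------------------------------------------------------------- atlas

def test_atlas_construction_counts_and_norms():
    atlas = make_atlas(34, seed=0)
    assert atlas.n_regions == 68
    assert (atlas.hemisphere == "L").sum() == 34
    assert np.allclose(np.linalg.norm(atlas.coords, axis=1), 1.0, atol=1e-12)


def test_atlas_mirror_symmetry():
    atlas = make_atlas(50, seed=1)
    left = atlas.coords[atlas.hemisphere == "L"]
    right = atlas.coords[atlas.hemisphere == "R"]
    assert np.allclose(right, left * np.array([-1.0, 1.0, 1.0]), atol=1e-9)


def test_atlas_deterministic_and_label_partition():
    a1 = make_atlas(34, seed=3)
    a2 = make_atlas(34, seed=3)
    assert np.allclose(a1.coords, a2.coords)
    assert list(a1.network) == list(a2.network)
    assert set(a1.cortical_type) == {"paralimbic", "heteromodal", "unimodal", "idiotypic"}
    with pytest.raises(ValueError):
        make_atlas(10, n_networks=11)


# ----------------------------------------------------------------- connectome

def test_connectome_density_and_connectivity():
    atlas = make_atlas(34, seed=2)
    conn = make_connectome(atlas, target_density=0.15, seed=4)
    n = atlas.n_regions
    density = conn.sc.sum() / (n * (n - 1))
    assert 0.135 <= density <= 0.165
    import scipy.sparse.csgraph as csg

    assert csg.connected_components(conn.sc, directed=False)[0] == 1


def test_connectome_infinite_decay_removes_distance_dependence():
    """With decay_length -> infinity edge probabilities are uniform, so
    edge presence is uncorrelated with distance."""
    atlas = make_atlas(224, seed=5)
    conn = make_connectome(atlas, decay_length=1e9, seed=6)
    d = atlas.great_circle_distances()
    iu = np.triu_indices(atlas.n_regions, k=1)
    r = np.corrcoef(d[iu], conn.sc[iu])[0, 1]
    assert abs(r) < 0.1


def test_connectome_noiseless_fc_is_monotone_in_communicability():
    from scipy.stats import spearmanr

    from netatrophy.synth import _normalized_communicability

    atlas = make_atlas(34, seed=7)
    conn = make_connectome(atlas, fc_noise_sd=0.0, seed=8)
    comm = _normalized_communicability(conn.sc)
    iu = np.triu_indices(atlas.n_regions, k=1)
    rho = spearmanr(conn.fc[iu], comm[iu]).statistic
    assert rho == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------------------------- spread

def test_spread_eta_zero_returns_seed_indicator():
    sc = path_graph(5)
    out = simulate_spread(sc, SpreadParams(seed_regions=[2], eta=0.0, n_steps=7))
    assert np.array_equal(out, np.eye(5)[2])


def test_spread_one_hop_support():
    sc = path_graph(5)
    out = simulate_spread(sc, SpreadParams(seed_regions=[0], eta=0.5, n_steps=1))
    assert np.all(out[:2] > 0) and np.all(out[2:] == 0)


def test_spread_hand_computed_path_graph():
    """Path 0-1-2, seed 0, eta 0.5, one step: node 1 receives
    0.5 * (1/2) * 1 under degree normalisation."""
    sc = path_graph(3)
    out = simulate_spread(sc, SpreadParams(seed_regions=[0], eta=0.5, n_steps=1))
    assert np.allclose(out, [1.0, 0.25, 0.0])


def test_spread_rejects_nan():
    sc = path_graph(3)
    sc[0, 1] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        simulate_spread(sc, SpreadParams(seed_regions=[0], eta=0.1, n_steps=1))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    eta=st.floats(0.0, 1.0),
    steps=st.integers(0, 6),
    seed=st.integers(0, 10_000),
)
def test_spread_monotone_in_steps_and_eta(eta, steps, seed):
    rng = np.random.default_rng(seed)
    n = 8
    sc = (rng.random((n, n)) < 0.4).astype(float)
    sc = np.triu(sc, 1)
    sc = sc + sc.T
    seed_region = int(rng.integers(n))
    base = simulate_spread(sc, SpreadParams(seed_regions=[seed_region], eta=eta, n_steps=steps))
    more_steps = simulate_spread(
        sc, SpreadParams(seed_regions=[seed_region], eta=eta, n_steps=steps + 1)
    )
    more_eta = simulate_spread(
        sc, SpreadParams(seed_regions=[seed_region], eta=eta + 0.2, n_steps=steps)
    )
    assert np.all(more_steps >= base - 1e-12)
    assert np.all(more_eta >= base - 1e-12)


# --------------------------------------------------------------------- cohort

def test_cohort_noiseless_limit_matches_linear_prediction(small_atlas, small_connectome):
    params = CohortParams(
        n_hc=10, n_pd=5, noise_sd=1e-12, subject_sd=0.0, site_sd=0.0,
        disease_effect_scale=0.0,
    )
    spread = SpreadParams(seed_regions=[0], eta=0.0, n_steps=0)
    cohort = make_cohort(small_atlas, small_connectome.sc, params, spread, seed=11)
    demo = cohort.demographics
    expected = (
        params.beta_intercept
        + params.beta_age * demo["age"].to_numpy()[:, None]
        + params.beta_sex * demo["sex"].to_numpy()[:, None]
    )
    assert np.allclose(cohort.values, expected, atol=1e-9)


def test_cohort_structure(small_cohort):
    demo = small_cohort.demographics
    assert (demo.loc[demo["group"] == "HC", "session"] == "baseline").all()
    pd_sessions = demo.loc[demo["group"] == "PD"].groupby("subject_id")["session"].count()
    assert (pd_sessions == 4).all()
    with pytest.raises(ValueError):
        CohortParams(n_hc=3)


def test_cohort_planted_spread_raises_progression_in_targeted_regions(
    small_atlas, small_connectome
):
    """Regions with high true spread load show higher mean decline at y4."""
    params = CohortParams(n_hc=20, n_pd=40, disease_effect_scale=3.0)
    spread = SpreadParams(seed_regions=[0, 34], eta=0.3, n_steps=2)
    cohort = make_cohort(small_atlas, small_connectome.sc, params, spread, seed=12)
    truth = disease_trajectory(small_connectome.sc, spread, small_atlas)["y4"]
    pd_bl = cohort.subset(group="PD", session="baseline").values
    pd_y4 = cohort.subset(group="PD", session="y4").values
    decline = (pd_bl - pd_y4).mean(axis=0)
    top = truth >= np.quantile(truth, 0.8)
    assert decline[top].mean() > decline[~top].mean()


# ----------------------------------------------------------------- expression

def test_expression_zscored_per_gene(small_atlas):
    bundle = make_expression(small_atlas, n_genes=100, class_size=5, seed=13)
    vals = bundle.expr.to_numpy()
    assert np.allclose(vals.mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(vals.std(axis=0), 1.0, atol=1e-9)


def test_expression_white_noise_limit_has_no_spatial_autocorrelation():
    """With a vanishing lengthscale, Moran's I of gene maps is near zero."""
    atlas = make_atlas(224, seed=14)
    bundle = make_expression(
        atlas, n_genes=100, class_size=0, class_names=(), lengthscale=0.0, seed=15
    )
    d = atlas.great_circle_distances()
    w = 1.0 / (d + np.eye(atlas.n_regions))
    np.fill_diagonal(w, 0.0)
    vals = bundle.expr.to_numpy()
    n = atlas.n_regions
    morans = []
    for g in range(vals.shape[1]):
        z = vals[:, g] - vals[:, g].mean()
        morans.append((n / w.sum()) * (z @ w @ z) / (z @ z))
    assert abs(np.mean(morans)) < 0.05


def test_expression_planted_class_genes_correlate(small_atlas):
    """Two genes of the same planted class correlate more than random genes."""
    bundle = make_expression(small_atlas, n_genes=300, seed=16)
    expr = bundle.expr
    within, between = [], []
    rng = np.random.default_rng(0)
    for cname, genes in bundle.cell_sets.items():
        g = expr[genes].to_numpy()
        c = np.corrcoef(g, rowvar=False)
        within.append(c[np.triu_indices(len(genes), 1)].mean())
    free = [g for g in expr.columns if not any(g in s for s in bundle.cell_sets.values())]
    pick = rng.choice(free, size=40, replace=False)
    c = np.corrcoef(expr[list(pick)].to_numpy(), rowvar=False)
    between = c[np.triu_indices(len(pick), 1)].mean()
    assert np.mean(within) > between + 0.2


def test_expression_planted_set_too_large(small_atlas):
    with pytest.raises(ValueError):
        make_expression(small_atlas, n_genes=30, class_size=10, seed=1)


# -------------------------------------------------------------------- dataset

def test_make_dataset_deterministic():
    s1 = make_dataset(seed=21, n_per_hemisphere=20, n_genes=200, cohort_params=CohortParams(n_hc=10, n_pd=5))
    s2 = make_dataset(seed=21, n_per_hemisphere=20, n_genes=200, cohort_params=CohortParams(n_hc=10, n_pd=5))
    assert np.allclose(s1.cohort.values, s2.cohort.values)
    assert np.allclose(s1.expression.expr.to_numpy(), s2.expression.expr.to_numpy())
    assert s1.seed_regions == s2.seed_regions
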