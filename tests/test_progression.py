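import numpy as np
import pandas as pd
import pingouin as pg
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from netatrophy.progression import (
    cortical_type_anova,
    p_adjust,
    partial_spearman,
    partial_spearman_battery,
    progression_map,
    regional_progression_test,
    rm_anova_clinical,
)


# ----------------------------------------------------------- progression map

def test_progression_sign_convention():
    """W dropping from -0.5 to -1.0 means atrophy worsened: score +0.5."""
    score = progression_map(np.array([-0.5]), np.array([-1.0]))
    assert score[0] == pytest.approx(0.5)


def test_progression_identical_sessions_zero(rng):
    w = rng.standard_normal((6, 10))
    assert np.allclose(progression_map(w, w), 0.0)


def test_progression_antisymmetric_and_linear(rng):
    bl = rng.standard_normal((8, 12))
    fu = rng.standard_normal((8, 12))
    fwd = progression_map(bl, fu, aggregate="subject")
    rev = progression_map(fu, bl, aggregate="subject")
    assert np.allclose(fwd, -rev)
    group = progression_map(bl, fu, aggregate="group-mean")
    assert np.allclose(group, fwd.mean(axis=0), atol=1e-12)


def test_progression_subject_mismatch():
    with pytest.raises(ValueError, match="subject sets differ"):
        progression_map(
            np.zeros((2, 3)), np.zeros((2, 3)),
            subjects_baseline=["a", "b"], subjects_followup=["a", "c"],
        )


# ------------------------------------------------------- regional progression

def test_regional_test_null_when_sessions_identical(rng):
    base = rng.standard_normal((10, 1, 5))
    y = np.repeat(base, 3, axis=1)
    res = regional_progression_test(
        y, sex=rng.integers(0, 2, 10), n_perm=50, seed=0
    )
    assert np.allclose(res.table["F"], 0.0)
    assert not res.table["sig_fwe"].any()


def test_regional_test_recovers_planted_decline():
    """A strong planted decline in 10 regions is flagged at the FWE
    threshold with no false positives in most replicates."""
    n, regions, planted = 40, 220, 10
    good = 0
    for rep in range(25):
        rng = np.random.default_rng(300 + rep)
        noise = rng.standard_normal((n, 4, regions))
        subj = rng.standard_normal((n, 1, regions)) * 0.5
        y = noise + subj
        effect = np.linspace(0, 1.5, 4)  # grows over sessions, in noise-SD units
        y[:, :, :planted] -= effect[None, :, None]
        res = regional_progression_test(
            y, sex=rng.integers(0, 2, n), n_perm=250, seed=rep
        )
        sig = res.table["sig_fwe"].to_numpy()
        if sig[:planted].sum() >= 8 and sig[planted:].sum() == 0:
            good += 1
    assert good >= 0.9 * 25


def test_regional_test_site_singleton_warning(rng, caplog):
    y = rng.standard_normal((8, 2, 4))
    site = np.array(["a"] * 7 + ["b"], dtype=object)
    with caplog.at_level("WARNING"):
        regional_progression_test(y, sex=rng.integers(0, 2, 8), site=site, n_perm=20, seed=0)
    assert any("single subject" in r.message for r in caplog.records)


# -------------------------------------------------------- cortical-type ANOVA

def test_anova_hand_computed_example():
    """Classes [1,2,3], [2,3,4], [3,4,5]: SSB=6 (df 2), SSW=6 (df 6), F=3."""
    values = np.array([1, 2, 3, 2, 3, 4, 3, 4, 5], dtype=float)
    types = np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 3, dtype=object)
    res = cortical_type_anova(values, types)
    assert res.f == pytest.approx(3.0)
    # independent oracle: explicit sums-of-squares decomposition
    gm = values.mean()
    ssb = sum(3 * (values[types == c].mean() - gm) ** 2 for c in "ABC")
    ssw = sum(((values[types == c] - values[types == c].mean()) ** 2).sum() for c in "ABC")
    f_oracle = (ssb / 2) / (ssw / 6)
    assert res.f == pytest.approx(f_oracle)


def test_anova_equal_means():
    values = np.array([1, 2, 3, 1, 2, 3], dtype=float)
    types = np.array(["A"] * 3 + ["B"] * 3, dtype=object)
    res = cortical_type_anova(values, types)
    assert res.f == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_anova_errors():
    with pytest.raises(ValueError, match="at least 2"):
        cortical_type_anova(np.ones(4), np.array(["A"] * 4, dtype=object))
    with pytest.raises(ValueError, match="zero within-class variance"):
        cortical_type_anova(
            np.array([1.0, 1.0, 2.0, 2.0]), np.array(["A", "A", "B", "B"], dtype=object)
        )


def test_anova_matches_brute_force_on_random_instances(rng):
    for _ in range(20):
        k = rng.integers(2, 5)
        sizes = rng.integers(3, 8, k)
        values = rng.standard_normal(sizes.sum())
        types = np.repeat([f"c{i}" for i in range(k)], sizes).astype(object)
        res = cortical_type_anova(values, types)
        gm = values.mean()
        ssb = sum(len(values[types == c]) * (values[types == c].mean() - gm) ** 2
                  for c in np.unique(types))
        ssw = sum(((values[types == c] - values[types == c].mean()) ** 2).sum()
                  for c in np.unique(types))
        f_oracle = (ssb / (k - 1)) / (ssw / (len(values) - k))
        assert res.f == pytest.approx(f_oracle, rel=1e-10)


# ------------------------------------------------------------ partial Spearman

def test_partial_spearman_perfect_monotone(rng):
    x = rng.standard_normal(30)
    cov = rng.standard_normal(30)
    rho, p = partial_spearman(x, x, cov)
    assert rho == pytest.approx(1.0, abs=1e-9)


def test_partial_spearman_removes_covariate_effect(rng):
    cov = rng.standard_normal(200)
    x = rng.standard_normal(200)
    rho, _ = partial_spearman(x, cov + 0.01 * rng.standard_normal(200), cov)
    assert abs(rho) < 0.15


def test_partial_spearman_no_covariates_equals_plain_spearman(rng):
    for _ in range(20):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25) + 0.5 * x
        rho, p = partial_spearman(x, y)
        ref = scipy.stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


def test_partial_spearman_matches_pingouin(rng):
    """Independent oracle for the covariate-adjusted case."""
    for _ in range(10):
        df = pd.DataFrame(
            {
                "x": rng.standard_normal(40),
                "y": rng.standard_normal(40),
                "c1": rng.standard_normal(40),
                "c2": rng.standard_normal(40),
            }
        )
        df["y"] += 0.5 * df["x"] + 0.3 * df["c1"]
        rho, _ = partial_spearman(
            df["x"].to_numpy(), df["y"].to_numpy(), df[["c1", "c2"]].to_numpy()
        )
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)


def test_partial_spearman_constant_variable():
    with pytest.raises(ValueError, match="zero rank variance"):
        partial_spearman(np.ones(20), np.arange(20.0))


def test_battery_fdr_and_min_n(rng):
    xs = pd.DataFrame({"a": rng.standard_normal(30), "b": rng.standard_normal(30)})
    ys = pd.DataFrame({"c": rng.standard_normal(30)})
    cov = pd.DataFrame({"age": rng.standard_normal(30)})
    out = partial_spearman_battery(xs, ys, cov)
    assert len(out) == 2
    assert np.all(out["p_fdr"] >= out["p_raw"] - 1e-12)
    short = pd.DataFrame({"a": rng.standard_normal(5)})
    with pytest.raises(ValueError, match="complete cases"):
        partial_spearman_battery(short, pd.DataFrame({"c": rng.standard_normal(5)}))


# ----------------------------------------------------------------- p_adjust

def test_p_adjust_worked_examples():
    assert np.allclose(p_adjust([0.01, 0.04, 0.03], "holm"), [0.03, 0.06, 0.06])
    assert np.allclose(p_adjust([0.01, 0.02, 0.03], "bh_fdr"), [0.03, 0.03, 0.03])
    for method in ("bonferroni", "holm", "bh_fdr"):
        assert p_adjust([0.2], method)[0] == pytest.approx(0.2)
    with pytest.raises(ValueError):
        p_adjust([1.2], "holm")
    with pytest.raises(ValueError):
        p_adjust([0.5], "nope")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
def test_p_adjust_ordering_invariant(ps):
    """bonferroni >= holm >= raw, elementwise, and all clipped at 1."""
    ps = np.array(ps)
    bonf = p_adjust(ps, "bonferroni")
    holm = p_adjust(ps, "holm")
    assert np.all(bonf >= holm - 1e-12)
    assert np.all(holm >= ps - 1e-12)
    assert np.all(bonf <= 1.0) and np.all(holm <= 1.0)


# --------------------------------------------------------- clinical RM-ANOVA

def test_rm_anova_identical_sessions():
    data = np.tile(np.arange(5.0)[:, None], (1, 4))
    res = rm_anova_clinical(data)
    assert res.f == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_rm_anova_two_sessions_equals_squared_paired_t(rng):
    data = rng.standard_normal((12, 2))
    res = rm_anova_clinical(data, sessions=("baseline", "y1"))
    t, _ = scipy.stats.ttest_rel(data[:, 1], data[:, 0])
    assert res.f == pytest.approx(t**2, rel=1e-9)


def test_rm_anova_matches_pingouin(rng):
    data = rng.standard_normal((15, 4)) + np.array([0.0, 0.2, 0.4, 0.6])
    res = rm_anova_clinical(data)
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(15), 4),
            "session": np.tile(np.arange(4), 15),
            "value": data.ravel(),
        }
    )
    ref = pg.rm_anova(data=long, dv="value", within="session", subject="subject")
    assert res.f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
    assert res.p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)


def test_rm_anova_detects_planted_worsening():
    """A monotone 1-SD worsening at n=74 is detected nearly always."""
    hits = 0
    for rep in range(60):
        rng = np.random.default_rng(500 + rep)
        data = rng.standard_normal((74, 4)) + np.array([0.0, 0.33, 0.66, 1.0])
        if rm_anova_clinical(data).p < 0.05:
            hits += 1
    assert hits >= 0.95 * 60


def test_rm_anova_too_few_subjects():
    with pytest.raises(ValueError, match="at least 3"):
        rm_anova_clinical(np.ones((2, 4)))
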