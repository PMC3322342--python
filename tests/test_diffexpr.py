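"""Moderated t-test checks: gene-wise layer, prior estimation, moderation,
BH adjustment, degenerate limits."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm, t as t_dist

import nichexpress as nx
from nichexpress.diffexpr import (
    PriorEstimate,
    genewise_stats_two_color,
    genewise_stats_two_group,
)
from nichexpress.normalize import MATable


def _ma_from_m(m_rows):
    """MATable from a gene x replicate array of M values (A constant)."""
    m = pd.DataFrame(
        np.asarray(m_rows, dtype=float),
        index=pd.Index([f"g{i}" for i in range(len(m_rows))], name="gene_id"),
    )
    m.columns = [f"rep{j + 1}" for j in range(m.shape[1])]
    a = pd.DataFrame(9.0, index=m.index, columns=m.columns)
    return MATable(m, a)


@pytest.mark.parametrize(
    "m_rows, effect, s2, df",
    [
        ([[1.0, 1.0, 1.0, 1.0]], 1.0, 0.0, 3),
        ([[0.0, 2.0]], 1.0, 2.0, 1),
    ],
)
def test_two_color_genewise_stats(m_rows, effect, s2, df):
    stats = genewise_stats_two_color(_ma_from_m(m_rows))
    assert stats["effect"].iloc[0] == pytest.approx(effect)
    assert stats["s2"].iloc[0] == pytest.approx(s2)
    assert stats["df"].iloc[0] == df
    assert stats.attrs["n_eff"] == len(m_rows[0])


def test_two_group_genewise_stats_orientation():
    mat = pd.DataFrame(
        {"a1": [0.0], "a2": [0.0], "b1": [1.0], "b2": [1.0]},
        index=pd.Index(["g0"], name="gene_id"),
    )
    stats = genewise_stats_two_group(mat, ["a", "a", "b", "b"])
    assert stats["effect"].iloc[0] == pytest.approx(-1.0)
    stats = genewise_stats_two_group(mat, ["a", "a", "b", "b"], positive_group="b")
    assert stats["effect"].iloc[0] == pytest.approx(1.0)
    assert stats["s2"].iloc[0] == pytest.approx(0.0)
    assert stats["df"].iloc[0] == 2
    with pytest.raises(ValueError, match=">= 2 samples"):
        genewise_stats_two_group(mat[["a1", "b1", "b2"]], ["a", "b", "b"])


def test_estimate_prior_zero_dispersion_limit():
    s2 = np.full(50, 0.25)
    prior = nx.estimate_prior(s2, df=3)
    assert np.isinf(prior.d0)
    assert prior.s0_2 == pytest.approx(0.25)


def test_estimate_prior_scale_equivariance():
    rng = np.random.default_rng(0)
    s2 = 0.04 * rng.chisquare(3, 500) / 3
    p1 = nx.estimate_prior(s2, df=3)
    p2 = nx.estimate_prior(2 * s2, df=3)
    assert p2.d0 == pytest.approx(p1.d0, rel=1e-9)
    assert p2.s0_2 == pytest.approx(2 * p1.s0_2, rel=1e-9)


def test_estimate_prior_parameter_recovery():
    """Variances drawn from the scaled-F model with d0=4, s0_2=0.04 are
    recovered within +-25% (d0) and +-10% (s0_2) at 10,000 genes."""
    rng = np.random.default_rng(7)
    d0_true, s0_true, df = 4.0, 0.04, 4
    sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 10_000)
    s2 = sigma2 * rng.chisquare(df, 10_000) / df
    prior = nx.estimate_prior(s2, df=df)
    assert prior.d0 == pytest.approx(d0_true, rel=0.25)
    assert prior.s0_2 == pytest.approx(s0_true, rel=0.10)


def test_estimate_prior_degenerate_errors():
    with pytest.raises(ValueError, match="positive residual variance"):
        nx.estimate_prior(np.zeros(100), df=3)
    with pytest.raises(ValueError, match="20 genes"):
        nx.estimate_prior(np.full(10, 0.1), df=3)


def test_moderated_t_null_effect():
    t, p, _ = nx.moderated_t(0.0, 0.5, 3, PriorEstimate(4.0, 0.1), n_eff=4)
    assert t[0] == 0.0
    assert p[0] == pytest.approx(1.0)


def test_moderated_t_limits_match_classical_tests():
    rng = np.random.default_rng(3)
    effect = rng.normal(0, 1, 20)
    s2 = 0.2 * rng.chisquare(3, 20) / 3
    df, n = 3, 4
    # d0 = 0: ordinary gene-wise t
    t0, p0, dft = nx.moderated_t(effect, s2, df, PriorEstimate(0.0, 1.0), n_eff=n)
    np.testing.assert_allclose(t0, effect / np.sqrt(s2 / n), rtol=1e-12)
    np.testing.assert_allclose(p0, 2 * t_dist.sf(np.abs(t0), df), rtol=1e-12)
    # d0 = inf: common-variance z-test
    s0 = 0.3
    tz, pz, _ = nx.moderated_t(effect, s2, df, PriorEstimate(np.inf, s0), n_eff=n)
    np.testing.assert_allclose(tz, effect / np.sqrt(s0 / n), rtol=1e-12)
    np.testing.assert_allclose(pz, 2 * norm.sf(np.abs(tz)), rtol=1e-12)


def test_moderated_t_shrinkage_brackets_classical_statistics():
    rng = np.random.default_rng(4)
    effect = rng.normal(0, 1, 200)
    s2 = 0.1 * rng.chisquare(3, 200) / 3
    prior = PriorEstimate(4.0, 0.1)
    t_mod, _, _ = nx.moderated_t(effect, s2, 3, prior, n_eff=4)
    t_gene = np.abs(effect / np.sqrt(s2 / 4))
    t_prior = np.abs(effect / np.sqrt(prior.s0_2 / 4))
    lo = np.minimum(t_gene, t_prior)
    hi = np.maximum(t_gene, t_prior)
    assert (np.abs(t_mod) >= lo - 1e-9).all()
    assert (np.abs(t_mod) <= hi + 1e-9).all()


def _bh_oracle(p):
    """Step-up definition evaluated literally."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def test_bh_adjust_examples_and_oracle():
    np.testing.assert_allclose(
        nx.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(nx.bh_adjust([0.42]), [0.42])
    np.testing.assert_allclose(nx.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
    rng = np.random.default_rng(5)
    for _ in range(10):
        p = rng.uniform(0, 1, rng.integers(1, 60))
        np.testing.assert_allclose(nx.bh_adjust(p), _bh_oracle(p), atol=1e-12)
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        nx.bh_adjust([0.5, 1.5])


def test_bh_adjust_monotone_and_dominates_p():
    rng = np.random.default_rng(6)
    p = rng.uniform(0, 1, 100)
    adj = nx.bh_adjust(p)
    assert (adj >= p - 1e-15).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()


def test_two_color_estimator_results_contract(small_atlas, mixtures):
    arrays = nx.simulate_two_color(
        small_atlas, mixtures["germarium"], mixtures["testis_apex"],
        n_reps=4, n_flips=2, noise_log2_sd=0.35, dye_bias_coeffs=(0.0,), seed=8,
    )
    model = nx.TwoColorModeratedTTest().fit(nx.MATable.from_arrays(arrays))
    res = model.results_
    assert list(res.columns) == [
        "M", "A", "t_mod", "p", "p_adj", "mean_group1", "mean_group2"
    ]
    assert ((res["p"] <= res["p_adj"]) | np.isclose(res["p"], res["p_adj"])).all()
    assert (np.sign(res["t_mod"]) == np.sign(res["M"])).all()
    assert model.prior_d0_ > 0 and model.prior_s0_2_ > 0
    assert model.n_eff_ == 4
    # sklearn param plumbing
    assert nx.TwoGroupModeratedTTest(positive_group="x").get_params() == {
        "positive_group": "x"
    }


def test_zero_noise_degenerate_limit(small_atlas, mixtures):
    """With arithmetically identical replicates, nonzero effects are exact
    discoveries and null effects are exact non-discoveries."""
    arrays = nx.simulate_two_color(
        small_atlas, mixtures["germarium"], mixtures["testis_apex"],
        n_reps=4, n_flips=2, noise_log2_sd=0.0, dye_bias_coeffs=(0.0,), seed=0,
    )
    model = nx.TwoColorModeratedTTest().fit(nx.MATable.from_arrays(arrays))
    res = model.results_
    nonnull = res["M"].abs() > 1e-8
    assert (res.loc[nonnull, "p"] == 0.0).all()
    assert (res.loc[~nonnull, "p"] == 1.0).all()
    assert np.isinf(res.loc[nonnull, "t_mod"]).all()
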