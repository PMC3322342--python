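"""Generator checks: seeded determinism, planted structure, mixtures."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import nichexpress as nx
from nichexpress.config import (
    FEMALE_GSC,
    KC_REFERENCE,
    LOW_EXPRESSED,
    MALE_GSC_GONIALBLAST,
    SHARED_GSC,
    AtlasConfig,
    ConfigError,
    MixtureDesign,
)


def test_atlas_seeded_determinism(small_config):
    a1 = nx.build_atlas(small_config.atlas)
    a2 = nx.build_atlas(small_config.atlas)
    assert a1.true_expression.to_csv() == a2.true_expression.to_csv()
    assert a1.truth_class.to_csv() == a2.truth_class.to_csv()


def test_atlas_class_counts_rounding_exact():
    cfg = AtlasConfig(n_genes=1000, seed=1)
    atlas = nx.build_atlas(cfg)
    counts = atlas.truth_class.value_counts()
    assert counts[SHARED_GSC] == 50  # 0.05 * 1000 exactly
    assert counts.sum() == 1000


def test_planted_enrichment_ratio_before_noise():
    cfg = AtlasConfig(n_genes=200, effect_log2fc=2.0, seed=3)
    atlas = nx.build_atlas(cfg)
    shared = atlas.truth_class == SHARED_GSC
    expr = atlas.true_expression
    ratio_f = expr.loc[shared, FEMALE_GSC] / expr.loc[shared, KC_REFERENCE]
    ratio_m = expr.loc[shared, MALE_GSC_GONIALBLAST] / expr.loc[shared, KC_REFERENCE]
    assert np.allclose(ratio_f, 4.0)
    assert np.allclose(ratio_m, 4.0)


def test_low_expressed_class_sits_below_intensity_gate():
    atlas = nx.build_atlas(AtlasConfig(n_genes=500, seed=2))
    low = atlas.truth_class == LOW_EXPRESSED
    assert low.sum() > 0
    assert (atlas.true_expression.loc[low] < 64).all().all()
    assert (atlas.true_expression.values >= 0).all()


def test_invalid_proportions_name_offending_field():
    cfg = AtlasConfig(class_proportions={SHARED_GSC: 0.5, "housekeeping": 0.4})
    with pytest.raises(ConfigError, match="class_proportions"):
        nx.build_atlas(cfg)


def test_mix_expression_identity_mean_and_zero(tiny_atlas):
    pure = MixtureDesign("pure", {FEMALE_GSC: 1.0})
    out = nx.mix_expression(tiny_atlas, pure)
    assert out.tolist() == tiny_atlas.true_expression[FEMALE_GSC].tolist()

    half = MixtureDesign("half", {FEMALE_GSC: 0.5, KC_REFERENCE: 0.5})
    out = nx.mix_expression(tiny_atlas, half)
    assert out["gA"] == pytest.approx(20.0)  # (10 + 30) / 2
    assert out["gC"] == 0.0  # all-zero gene stays zero in any mixture


def test_mix_expression_unknown_population_lists_valid_names(tiny_atlas):
    bad = MixtureDesign("bad", {"not_a_population": 1.0})
    with pytest.raises(ConfigError, match="female_gsc"):
        nx.mix_expression(tiny_atlas, bad)


def test_two_color_noiseless_identity(small_atlas, mixtures):
    arrays = nx.simulate_two_color(
        small_atlas, mixtures["germarium"], mixtures["testis_apex"],
        n_reps=2, n_flips=0, noise_log2_sd=0.0, dye_bias_coeffs=(0.0,), seed=0,
    )
    germ = nx.mix_expression(small_atlas, mixtures["germarium"])
    test = nx.mix_expression(small_atlas, mixtures["testis_apex"])
    for arr in arrays:
        np.testing.assert_allclose(
            arr.intensity_ch1 / arr.intensity_ch2, germ / test, rtol=1e-12
        )


def test_two_color_constant_dye_bias_and_flip_symmetry(small_atlas, mixtures):
    """A constant dye bias shifts corrected M by +c on unflipped and -c on
    flipped arrays, so a flip-balanced average cancels it exactly."""
    arrays = nx.simulate_two_color(
        small_atlas, mixtures["germarium"], mixtures["testis_apex"],
        n_reps=2, n_flips=1, noise_log2_sd=0.0, dye_bias_coeffs=(0.5,), seed=0,
    )
    germ = nx.mix_expression(small_atlas, mixtures["germarium"])
    test = nx.mix_expression(small_atlas, mixtures["testis_apex"])
    m_true = np.log2(germ / test)
    ma = nx.MATable.from_arrays(arrays)
    flipped = {f"rep{a.replicate_id}": a.dye_flipped for a in arrays}
    for rep in ma.M.columns:
        shift = -0.5 if flipped[rep] else 0.5
        np.testing.assert_allclose(ma.M[rep], m_true + shift, atol=1e-9)
    np.testing.assert_allclose(ma.M.mean(axis=1), m_true, atol=1e-9)


def test_two_color_seeded_determinism(small_atlas, mixtures):
    kwargs = dict(
        germarium_mix=mixtures["germarium"], testis_mix=mixtures["testis_apex"],
        n_reps=4, n_flips=2, noise_log2_sd=0.35,
        dye_bias_coeffs=(3.24, -0.72, 0.04), seed=42,
    )
    a1 = nx.simulate_two_color(small_atlas, **kwargs)
    a2 = nx.simulate_two_color(small_atlas, **kwargs)
    for x, y in zip(a1, a2):
        pd.testing.assert_series_equal(x.intensity_ch1, y.intensity_ch1)
        pd.testing.assert_series_equal(x.intensity_ch2, y.intensity_ch2)
        assert x.dye_flipped == y.dye_flipped
    assert [a.dye_flipped for a in a1] == [True, True, False, False]


def test_two_color_rejects_bad_parameters(small_atlas, mixtures):
    with pytest.raises(ConfigError, match="n_flips"):
        nx.simulate_two_color(
            small_atlas, mixtures["germarium"], mixtures["testis_apex"],
            n_reps=2, n_flips=3, noise_log2_sd=0.1, dye_bias_coeffs=(0.0,), seed=0,
        )
    with pytest.raises(ConfigError, match="noise"):
        nx.simulate_two_color(
            small_atlas, mixtures["germarium"], mixtures["testis_apex"],
            n_reps=2, n_flips=0, noise_log2_sd=-0.1, dye_bias_coeffs=(0.0,), seed=0,
        )


def test_single_channel_noiseless_groups_and_planted_effect(small_atlas, mixtures):
    sc = nx.simulate_single_channel(
        small_atlas, (mixtures["female_gsc"], mixtures["kc"]),
        n_per_group=3, noise_log2_sd=0.0, tag="female_gsc_vs_kc", seed=0,
    )
    labels = np.array(sc.group_labels)
    for group in sc.groups:
        cols = sc.matrix.loc[:, labels == group]
        assert (cols.nunique(axis=1) == 1).all()  # noiseless replicates identical
    diff = np.log2(sc.matrix.iloc[:, 0]) - np.log2(sc.matrix.iloc[:, -1])
    shared = small_atlas.truth_class == "shared_gsc"
    np.testing.assert_allclose(diff[shared.values], 1.5, atol=1e-9)


def test_single_channel_determinism_and_min_samples(small_atlas, mixtures):
    kwargs = dict(
        group_mixes=(mixtures["os_bgcn"], mixtures["bgcn"]),
        noise_log2_sd=0.35, tag="os_bgcn_vs_bgcn", seed=9,
    )
    s1 = nx.simulate_single_channel(small_atlas, n_per_group=3, **kwargs)
    s2 = nx.simulate_single_channel(small_atlas, n_per_group=3, **kwargs)
    pd.testing.assert_frame_equal(s1.matrix, s2.matrix)
    with pytest.raises(ConfigError, match="n_per_group"):
        nx.simulate_single_channel(small_atlas, n_per_group=1, **kwargs)


def test_planted_contrast_under_noise(small_atlas, mixtures):
    """The mean log2(female GSC / Kc) over shared-GSC genes recovers the
    planted effect within the simulation's sampling band."""
    noise = 0.35
    sc = nx.simulate_single_channel(
        small_atlas, (mixtures["female_gsc"], mixtures["kc"]),
        n_per_group=3, noise_log2_sd=noise, tag="female_gsc_vs_kc", seed=5,
    )
    labels = np.array(sc.group_labels)
    log2 = np.log2(sc.matrix)
    diff = (
        log2.loc[:, labels == sc.groups[0]].mean(axis=1)
        - log2.loc[:, labels == sc.groups[1]].mean(axis=1)
    )
    shared = small_atlas.truth_class == "shared_gsc"
    mean_diff = diff[shared.values].mean()
    band = 3 * noise / np.sqrt(3)
    assert abs(mean_diff - 1.5) < band


def test_truth_sets_partition(small_atlas):
    sets = nx.truth_sets(small_atlas)
    union = set().union(*sets.values())
    assert union == set(small_atlas.gene_ids)
    assert sum(len(s) for s in sets.values()) == len(small_atlas.gene_ids)
    counts = small_atlas.truth_class.value_counts()
    for cls, genes in sets.items():
        assert len(genes) == counts.get(cls, 0)


def test_truth_sets_empty_class_present():
    cfg = AtlasConfig(
        n_genes=200,
        class_proportions={"housekeeping": 1.0, SHARED_GSC: 0.0},
        seed=0,
    )
    sets = nx.truth_sets(nx.build_atlas(cfg))
    assert sets[SHARED_GSC] == set()
    assert len(sets["housekeeping"]) == 200
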