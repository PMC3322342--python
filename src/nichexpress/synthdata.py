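"""Seeded synthetic data with planted ground truth.

The generator builds a gene-by-cell-population expression atlas in which each
gene carries a truth-class label, then realizes three experiments on top of
it:

* a two-color microarray comparison of two tissue mixtures (germarium vs
  apex of the testis) with replicate noise, dye-swap design, and a smooth
  intensity-dependent dye bias;
* two single-channel two-group experiments (female GSC-enriched germ cells
  vs Kc cells; Os+bgcn- vs bgcn- testes).

Every sampling step flows from an explicit integer seed, so identical
configurations produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import (
    FEMALE_DIFF_GERM,
    FEMALE_GERM_GENERAL,
    FEMALE_GSC,
    FEMALE_SOMA,
    GERMARIUM_NOT_GSC,
    HOUSEKEEPING,
    KC_REFERENCE,
    LOW_EXPRESSED,
    MALE_DIFF_GERM,
    MALE_GERM_GENERAL,
    MALE_GSC_GONIALBLAST,
    MALE_SOMA,
    POPULATIONS,
    SHARED_GSC,
    TESTIS_NOT_GSC,
    AtlasConfig,
    ConfigError,
    MixtureDesign,
)

# Cap (log2) for low_expressed baselines: strictly below the 64-intensity
# gate in every population.
_LOW_EXPRESSED_LOG2_CAP = 5.9


@dataclass
class PopulationAtlas:
    """Ground-truth linear-scale mean expression per gene and population.

    Attributes
    ----------
    true_expression:
        DataFrame (genes x populations) of nonnegative linear-scale means.
    truth_class:
        Per-gene planted class label, aligned with ``true_expression``.
    class_order:
        The configured class order (classes with zero proportion included).
    """

    true_expression: pd.DataFrame
    truth_class: pd.Series
    class_order: Tuple[str, ...]

    @property
    def gene_ids(self) -> pd.Index:
        return self.true_expression.index

    @property
    def populations(self) -> List[str]:
        return list(self.true_expression.columns)

    def truth_sets(self) -> Dict[str, Set[str]]:
        """Partition of gene ids by truth class (empty classes included)."""
        sets: Dict[str, Set[str]] = {cls: set() for cls in self.class_order}
        for gene, cls in self.truth_class.items():
            sets[cls].add(gene)
        return sets


@dataclass
class TwoColorArray:
    """One two-color hybridization.

    ``dye_flipped=True`` means the germarium sample was labeled in channel 2
    (channel 1 then carries the testis sample).
    """

    replicate_id: int
    intensity_ch1: pd.Series
    intensity_ch2: pd.Series
    dye_flipped: bool

    def __post_init__(self) -> None:
        for name, chan in (("ch1", self.intensity_ch1), ("ch2", self.intensity_ch2)):
            bad = chan.index[~(chan.values > 0)]
            if len(bad):
                raise ValueError(
                    f"replicate {self.replicate_id}: nonpositive intensity in "
                    f"channel {name} for gene(s) {list(bad[:5])}"
                )
        if not self.intensity_ch1.index.equals(self.intensity_ch2.index):
            raise ValueError("channel gene orders differ")


@dataclass
class SingleChannelSet:
    """A gene x sample matrix of positive intensities with two groups."""

    matrix: pd.DataFrame
    group_labels: List[str]
    experiment_tag: str

    def __post_init__(self) -> None:
        groups = pd.Series(self.group_labels)
        counts = groups.value_counts()
        if len(counts) != 2:
            raise ValueError(
                f"expected exactly two group labels, got {sorted(counts.index)}"
            )
        if (counts < 2).any():
            raise ValueError(f"each group needs >= 2 samples, got {counts.to_dict()}")
        if len(self.group_labels) != self.matrix.shape[1]:
            raise ValueError("group_labels length must match sample count")

    @property
    def groups(self) -> List[str]:
        # first-appearance order; group 1 is the enriched/positive side
        seen: List[str] = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen


def _class_profile(cls: str, effect_log2fc: float, soma_level: float) -> np.ndarray:
    """Per-population expression multiplier for one truth class.

    Germline classes are elevated by 2**effect_log2fc in their defining germ
    populations and depleted (``soma_level``) in same-sex somatic
    populations; somatic/differentiation classes are elevated in their tissue
    compartments; housekeeping and low_expressed are flat.
    """
    f = 2.0 ** effect_log2fc
    prof = {pop: 1.0 for pop in POPULATIONS}
    if cls == SHARED_GSC:
        prof[FEMALE_GSC] = f
        prof[MALE_GSC_GONIALBLAST] = f
        prof[FEMALE_SOMA] = soma_level
        prof[MALE_SOMA] = soma_level
    elif cls == GERMARIUM_NOT_GSC:
        prof[FEMALE_DIFF_GERM] = f
        prof[FEMALE_SOMA] = f
    elif cls == TESTIS_NOT_GSC:
        prof[MALE_DIFF_GERM] = f
        prof[MALE_SOMA] = f
    elif cls == FEMALE_GERM_GENERAL:
        prof[FEMALE_GSC] = f
        prof[FEMALE_DIFF_GERM] = f
        prof[FEMALE_SOMA] = soma_level
    elif cls == MALE_GERM_GENERAL:
        prof[MALE_GSC_GONIALBLAST] = f
        prof[MALE_DIFF_GERM] = f
        prof[MALE_SOMA] = soma_level
    elif cls in (HOUSEKEEPING, LOW_EXPRESSED):
        pass
    else:  # pragma: no cover - guarded by AtlasConfig.validate
        raise ConfigError(f"unknown truth class {cls!r}")
    return np.array([prof[pop] for pop in POPULATIONS])


def _class_counts(proportions: Dict[str, float], n_genes: int) -> Dict[str, int]:
    """Largest-remainder apportionment so counts sum exactly to n_genes."""
    items = list(proportions.items())
    raw = np.array([p * n_genes for _, p in items])
    counts = np.floor(raw).astype(int)
    remainder = n_genes - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return {cls: int(c) for (cls, _), c in zip(items, counts)}


def build_atlas(config: AtlasConfig) -> PopulationAtlas:
    """Construct the ground-truth atlas for a validated configuration.

    Baseline means are log-normal (log2 location/scale from the config);
    planted classes are realized as multiplicative enrichments of
    ``2**effect_log2fc`` in their defining populations.  Deterministic for a
    fixed seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = _class_counts(config.class_proportions, config.n_genes)

    labels: List[str] = []
    for cls in config.class_proportions:
        labels.extend([cls] * counts[cls])
    labels_arr = np.array(labels)

    width = max(5, len(str(config.n_genes)))
    gene_ids = pd.Index(
        [f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)], name="gene_id"
    )

    log2_base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    low_mask = labels_arr == LOW_EXPRESSED
    if low_mask.any():
        low_draw = rng.normal(
            config.low_expressed_log2_mean, config.low_expressed_log2_sd, low_mask.sum()
        )
        log2_base[low_mask] = np.minimum(low_draw, _LOW_EXPRESSED_LOG2_CAP)
    baseline = 2.0 ** log2_base

    profiles = {
        cls: _class_profile(cls, config.effect_log2fc, config.germline_soma_level)
        for cls in config.class_proportions
    }
    matrix = np.empty((config.n_genes, len(POPULATIONS)))
    for cls, prof in profiles.items():
        mask = labels_arr == cls
        matrix[mask] = baseline[mask, None] * prof[None, :]

    expr = pd.DataFrame(matrix, index=gene_ids, columns=list(POPULATIONS))
    truth = pd.Series(labels_arr, index=gene_ids, name="truth_class")
    return PopulationAtlas(expr, truth, tuple(config.class_proportions))


def mix_expression(atlas: PopulationAtlas, design: MixtureDesign) -> pd.Series:
    """Expected linear expression of a tissue mixture: the weighted sum of
    population means per gene."""
    design.validate(atlas.populations)
    weights = pd.Series(design.weights, dtype=float).reindex(atlas.populations).fillna(0.0)
    mixed = atlas.true_expression.values @ weights.values
    return pd.Series(mixed, index=atlas.gene_ids, name=design.sample_name)


def truth_sets(atlas: PopulationAtlas) -> Dict[str, Set[str]]:
    return atlas.truth_sets()


def simulate_two_color(
    atlas: PopulationAtlas,
    germarium_mix: MixtureDesign,
    testis_mix: MixtureDesign,
    n_reps: int,
    n_flips: int,
    noise_log2_sd: float,
    dye_bias_coeffs: Sequence[float],
    seed: int,
) -> List[TwoColorArray]:
    """Simulate replicate two-color hybridizations of two tissue mixtures.

    Per gene and replicate, channel intensities are the mixture expectations
    perturbed by independent multiplicative log-normal noise
    (``noise_log2_sd`` on the log2 scale) and a smooth dye bias: the log2
    channel-1/channel-2 ratio is shifted by ``polyval(dye_bias_coeffs, A)``
    (ascending coefficients), split anti-symmetrically between the channels
    so A is unchanged.  Because the bias is attached to the *dyes*, the
    orientation-corrected M is shifted by +poly(A) on unflipped arrays and
    -poly(A) on dye-flipped ones; the first ``n_flips`` replicates are
    flagged as flipped.
    """
    if n_flips > n_reps:
        raise ConfigError(f"n_flips ({n_flips}) must be <= n_reps ({n_reps})")
    if noise_log2_sd < 0:
        raise ConfigError(f"noise_log2_sd must be nonnegative, got {noise_log2_sd}")
    rng = np.random.default_rng(seed)
    germ = mix_expression(atlas, germarium_mix).values
    test = mix_expression(atlas, testis_mix).values
    coeffs = np.asarray(dye_bias_coeffs, dtype=float)

    arrays: List[TwoColorArray] = []
    for rep in range(n_reps):
        flipped = rep < n_flips
        noise_g = 2.0 ** (noise_log2_sd * rng.standard_normal(len(germ)))
        noise_t = 2.0 ** (noise_log2_sd * rng.standard_normal(len(test)))
        ig = germ * noise_g
        it = test * noise_t
        ch1, ch2 = (it, ig) if flipped else (ig, it)
        a = 0.5 * (np.log2(ch1) + np.log2(ch2))
        delta = np.polynomial.polynomial.polyval(a, coeffs)
        ch1 = ch1 * 2.0 ** (0.5 * delta)
        ch2 = ch2 * 2.0 ** (-0.5 * delta)
        arrays.append(
            TwoColorArray(
                replicate_id=rep + 1,
                intensity_ch1=pd.Series(ch1, index=atlas.gene_ids, name="ch1"),
                intensity_ch2=pd.Series(ch2, index=atlas.gene_ids, name="ch2"),
                dye_flipped=flipped,
            )
        )
    return arrays


def simulate_single_channel(
    atlas: PopulationAtlas,
    group_mixes: Tuple[MixtureDesign, MixtureDesign],
    n_per_group: int,
    noise_log2_sd: float,
    tag: str,
    seed: int,
) -> SingleChannelSet:
    """Simulate a two-group single-channel experiment.

    Each sample equals its group's mixture expectation under independent
    multiplicative log-normal noise.  The first mixture is group 1 (the
    stem-cell-enriched side by pipeline convention).
    """
    if n_per_group < 2:
        raise ConfigError(
            f"n_per_group must be >= 2 (variance undefined downstream), got {n_per_group}"
        )
    if noise_log2_sd < 0:
        raise ConfigError(f"noise_log2_sd must be nonnegative, got {noise_log2_sd}")
    rng = np.random.default_rng(seed)
    columns = {}
    labels: List[str] = []
    for mix in group_mixes:
        expected = mix_expression(atlas, mix).values
        for i in range(n_per_group):
            noise = 2.0 ** (noise_log2_sd * rng.standard_normal(len(expected)))
            columns[f"{mix.sample_name}_{i + 1}"] = expected * noise
            labels.append(mix.sample_name)
    matrix = pd.DataFrame(columns, index=atlas.gene_ids)
    return SingleChannelSet(matrix=matrix, group_labels=labels, experiment_tag=tag)
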