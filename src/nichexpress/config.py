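"""Configuration objects for the synthetic gonad-expression study.

All tunable parameters of the simulation and of the downstream analysis live
in small validating dataclasses so that a whole run is reproducible from a
single JSON document plus a root seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

# Cell populations of the female and male gonad tip, plus the Kc-cell
# reference line used by the female stem-cell comparison.
FEMALE_GSC = "female_gsc"
FEMALE_DIFF_GERM = "female_diff_germ"
FEMALE_SOMA = "female_soma"
MALE_GSC_GONIALBLAST = "male_gsc_gonialblast"
MALE_DIFF_GERM = "male_diff_germ"
MALE_SOMA = "male_soma"
KC_REFERENCE = "kc_reference"

POPULATIONS: Tuple[str, ...] = (
    FEMALE_GSC,
    FEMALE_DIFF_GERM,
    FEMALE_SOMA,
    MALE_GSC_GONIALBLAST,
    MALE_DIFF_GERM,
    MALE_SOMA,
    KC_REFERENCE,
)

MALE_POPULATIONS = frozenset({MALE_GSC_GONIALBLAST, MALE_DIFF_GERM, MALE_SOMA})
FEMALE_POPULATIONS = frozenset({FEMALE_GSC, FEMALE_DIFF_GERM, FEMALE_SOMA})

# Planted truth classes.  Each gene carries exactly one label; the three
# cross-dataset filters are each targeted at one of the first three classes,
# the *_germ_general classes exercise the exclusion arms, low_expressed
# exercises the baseline-intensity gate, and housekeeping genes are null.
SHARED_GSC = "shared_gsc"
GERMARIUM_NOT_GSC = "germarium_not_gsc"
TESTIS_NOT_GSC = "testis_not_gsc"
FEMALE_GERM_GENERAL = "female_germ_general"
MALE_GERM_GENERAL = "male_germ_general"
HOUSEKEEPING = "housekeeping"
LOW_EXPRESSED = "low_expressed"

TRUTH_CLASSES: Tuple[str, ...] = (
    SHARED_GSC,
    GERMARIUM_NOT_GSC,
    TESTIS_NOT_GSC,
    FEMALE_GERM_GENERAL,
    MALE_GERM_GENERAL,
    HOUSEKEEPING,
    LOW_EXPRESSED,
)

DEFAULT_CLASS_PROPORTIONS: Dict[str, float] = {
    SHARED_GSC: 0.05,
    GERMARIUM_NOT_GSC: 0.08,
    TESTIS_NOT_GSC: 0.08,
    FEMALE_GERM_GENERAL: 0.05,
    MALE_GERM_GENERAL: 0.05,
    HOUSEKEEPING: 0.59,
    LOW_EXPRESSED: 0.10,
}


class ConfigError(ValueError):
    """A configuration field failed validation."""


@dataclass
class AtlasConfig:
    """Ground-truth expression atlas parameters.

    Parameters
    ----------
    n_genes:
        Number of genes simulated; at least 100 for default runs.
    class_proportions:
        Fraction of genes per truth class; must sum to 1.
    baseline_log2_mean, baseline_log2_sd:
        Location and spread (log2 scale) of the log-normal baseline
        expression shared by all populations before class enrichment.
    effect_log2fc:
        Planted enrichment magnitude in log2 units: a class's defining
        populations express the gene 2**effect_log2fc above baseline.
    germline_soma_level:
        Relative level of germline-class genes in same-sex somatic
        populations (germline transcripts are depleted in soma).
    low_expressed_log2_mean, low_expressed_log2_sd:
        Baseline distribution for the low_expressed class; draws are capped
        just below log2(64) so the class always sits under the intensity
        gate.
    seed:
        Seed for the atlas random stream.
    """

    n_genes: int = 5000
    class_proportions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    baseline_log2_mean: float = 9.0
    baseline_log2_sd: float = 1.0
    effect_log2fc: float = 1.5
    germline_soma_level: float = 0.1
    low_expressed_log2_mean: float = 4.0
    low_expressed_log2_sd: float = 0.5
    seed: int = 0

    def validate(self) -> "AtlasConfig":
        if self.n_genes < 100:
            raise ConfigError(f"n_genes must be >= 100 for default runs, got {self.n_genes}")
        if self.effect_log2fc <= 0:
            raise ConfigError(f"effect_log2fc must be > 0, got {self.effect_log2fc}")
        if self.baseline_log2_sd <= 0:
            raise ConfigError(f"baseline_log2_sd must be > 0, got {self.baseline_log2_sd}")
        unknown = set(self.class_proportions) - set(TRUTH_CLASSES)
        if unknown:
            raise ConfigError(
                f"class_proportions contains unknown classes {sorted(unknown)}; "
                f"valid classes are {list(TRUTH_CLASSES)}"
            )
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class_proportions must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.class_proportions.values()):
            raise ConfigError("class_proportions must be nonnegative")
        if not 0 < self.germline_soma_level:
            raise ConfigError("germline_soma_level must be positive")
        return self


@dataclass
class MixtureDesign:
    """A tissue sample as a weighted mixture of cell populations."""

    sample_name: str
    weights: Dict[str, float]

    def validate(self, populations: Sequence[str] = POPULATIONS) -> "MixtureDesign":
        unknown = set(self.weights) - set(populations)
        if unknown:
            raise ConfigError(
                f"mixture '{self.sample_name}' names unknown populations "
                f"{sorted(unknown)}; valid names are {list(populations)}"
            )
        if any(w < 0 for w in self.weights.values()):
            raise ConfigError(f"mixture '{self.sample_name}' has negative weights")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(
                f"mixture '{self.sample_name}' weights must sum to 1 (got {total!r})"
            )
        return self

    def check_single_sex(self, sex: str) -> "MixtureDesign":
        """Tissue mixtures are single-sex: a germarium sample carries no male
        populations and a testis sample no female populations."""
        forbidden = MALE_POPULATIONS if sex == "female" else FEMALE_POPULATIONS
        bad = {p for p, w in self.weights.items() if p in forbidden and w > 0}
        if bad:
            raise ConfigError(
                f"mixture '{self.sample_name}' is a {sex} tissue but weights "
                f"{sorted(bad)} are nonzero"
            )
        return self


@dataclass
class FilterConfig:
    """Thresholds for the three cross-dataset filtering analyses."""

    alpha: float = 0.01
    intensity_threshold: float = 64.0

    def validate(self) -> "FilterConfig":
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.intensity_threshold <= 0:
            raise ConfigError(
                f"intensity_threshold must be > 0, got {self.intensity_threshold}"
            )
        return self


@dataclass
class TwoColorConfig:
    """Replicate structure and noise of the two-color tissue comparison.

    Defaults reproduce the study design shape: four replicate
    hybridizations of germarium vs testis apex, two of them dye-flipped.
    The default dye bias is a centered quadratic in A, 0.04*(A-9)^2,
    expressed in raw ascending polynomial coefficients.
    """

    n_reps: int = 4
    n_flips: int = 2
    noise_log2_sd: float = 0.35
    dye_bias_coeffs: Tuple[float, ...] = (3.24, -0.72, 0.04)

    def validate(self) -> "TwoColorConfig":
        if self.n_reps < 2:
            raise ConfigError("n_reps must be >= 2")
        if not 0 <= self.n_flips <= self.n_reps:
            raise ConfigError(f"n_flips must be in [0, n_reps], got {self.n_flips}")
        if self.noise_log2_sd < 0:
            raise ConfigError("noise_log2_sd must be nonnegative")
        return self


@dataclass
class SingleChannelConfig:
    n_per_group: int = 3
    noise_log2_sd: float = 0.35

    def validate(self) -> "SingleChannelConfig":
        if self.n_per_group < 2:
            raise ConfigError(
                f"n_per_group must be >= 2 (variance undefined otherwise), "
                f"got {self.n_per_group}"
            )
        if self.noise_log2_sd < 0:
            raise ConfigError("noise_log2_sd must be nonnegative")
        return self


@dataclass
class EnrichmentConfig:
    n_terms: int = 50
    term_size_min: int = 20
    term_size_max: int = 100
    planted_purity: float = 0.9
    alpha: float = 0.01

    def validate(self) -> "EnrichmentConfig":
        if self.n_terms < 1:
            raise ConfigError("n_terms must be >= 1")
        if not 1 <= self.term_size_min <= self.term_size_max:
            raise ConfigError("term size range invalid")
        if not 0 < self.planted_purity <= 1:
            raise ConfigError("planted_purity must be in (0, 1]")
        return self


def default_mixtures() -> Dict[str, MixtureDesign]:
    """Study-shaped mixture designs for the three experiments.

    The wild-type tissues carry a small stem-cell fraction; the two
    single-channel experiments contrast genetically stem-cell-enriched
    samples against their references (Kc cells for females; bgcn-mutant
    testes for males).
    """
    return {
        "germarium": MixtureDesign(
            "germarium",
            {FEMALE_GSC: 0.1, FEMALE_DIFF_GERM: 0.5, FEMALE_SOMA: 0.4},
        ),
        "testis_apex": MixtureDesign(
            "testis_apex",
            {MALE_GSC_GONIALBLAST: 0.2, MALE_DIFF_GERM: 0.5, MALE_SOMA: 0.3},
        ),
        "female_gsc": MixtureDesign("female_gsc", {FEMALE_GSC: 1.0}),
        "kc": MixtureDesign("kc", {KC_REFERENCE: 1.0}),
        "os_bgcn": MixtureDesign(
            "os_bgcn",
            {MALE_GSC_GONIALBLAST: 0.8, MALE_DIFF_GERM: 0.15, MALE_SOMA: 0.05},
        ),
        "bgcn": MixtureDesign(
            "bgcn",
            {MALE_GSC_GONIALBLAST: 0.3, MALE_DIFF_GERM: 0.1, MALE_SOMA: 0.6},
        ),
    }


@dataclass
class RunConfig:
    """Top-level configuration of a full simulate -> enrich run."""

    atlas: AtlasConfig = field(default_factory=AtlasConfig)
    mixtures: Dict[str, MixtureDesign] = field(default_factory=default_mixtures)
    two_color: TwoColorConfig = field(default_factory=TwoColorConfig)
    single_channel: SingleChannelConfig = field(default_factory=SingleChannelConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    loess_span: float = 0.3
    loess_iterations: int = 3
    seed: int = 0

    REQUIRED_MIXTURES = (
        "germarium",
        "testis_apex",
        "female_gsc",
        "kc",
        "os_bgcn",
        "bgcn",
    )

    def validate(self) -> "RunConfig":
        self.atlas.validate()
        self.two_color.validate()
        self.single_channel.validate()
        self.filters.validate()
        self.enrichment.validate()
        missing = set(self.REQUIRED_MIXTURES) - set(self.mixtures)
        if missing:
            raise ConfigError(f"missing mixture designs: {sorted(missing)}")
        for mix in self.mixtures.values():
            mix.validate()
        self.mixtures["germarium"].check_single_sex("female")
        self.mixtures["testis_apex"].check_single_sex("male")
        if not 0 < self.loess_span <= 1:
            raise ConfigError(f"loess_span must be in (0, 1], got {self.loess_span}")
        return self

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        kwargs: Dict[str, object] = {}
        if "atlas" in raw:
            kwargs["atlas"] = AtlasConfig(**raw["atlas"])
        if "mixtures" in raw:
            kwargs["mixtures"] = {
                name: MixtureDesign(**mix) for name, mix in raw["mixtures"].items()
            }
        if "two_color" in raw:
            tc = dict(raw["two_color"])
            if "dye_bias_coeffs" in tc:
                tc["dye_bias_coeffs"] = tuple(tc["dye_bias_coeffs"])
            kwargs["two_color"] = TwoColorConfig(**tc)
        if "single_channel" in raw:
            kwargs["single_channel"] = SingleChannelConfig(**raw["single_channel"])
        if "filters" in raw:
            kwargs["filters"] = FilterConfig(**raw["filters"])
        if "enrichment" in raw:
            kwargs["enrichment"] = EnrichmentConfig(**raw["enrichment"])
        for key in ("loess_span", "loess_iterations", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs).validate()
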