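"""Cross-dataset filtering analyses and rank-sum ordering.

Three filters combine the wild-type tissue comparison (E1: germarium vs
testis apex, positive M = germarium-enriched) with the two stem-cell
contrasts (E2: female GSC-enriched germ cells vs Kc cells, positive M =
GSC-high; E3: Os+bgcn- vs bgcn- testes, positive M = Os+bgcn--high):

* shared-GSC: significant and enriched in both stem-cell comparisons, with
  a baseline intensity above the gate in both tissues, ordered by the sum
  of the two M-value rank orders;
* germarium-not-GSC: germarium-enriched in E1 but not GSC-enriched in E2,
  ordered by germarium M;
* testis-not-GSC: testis-enriched in E1 but not stem-cell-enriched in E3,
  ordered by |M_E1| rank plus the ascending M_E3 rank (bgcn--enriched
  first), highlighting later differentiating stages.

Membership is strict at both thresholds (adjusted p < alpha, mean log2
intensity > log2(threshold)) and invariant to input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import FilterConfig

DE_REQUIRED_COLUMNS = ("M", "A", "t_mod", "p", "p_adj", "mean_group1", "mean_group2")


class SchemaError(ValueError):
    pass


def _check_de(de: pd.DataFrame, needed: Sequence[str] = ("M", "p_adj")) -> None:
    missing = [c for c in needed if c not in de.columns]
    if missing:
        raise SchemaError(f"DE table is missing required column(s) {missing}")


def select_enriched(de: pd.DataFrame, alpha: float, direction: str) -> Set[str]:
    """Genes significant (adjusted p < alpha, strict) with M of the given
    sign ('positive' or 'negative')."""
    _check_de(de)
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")
    sig = de["p_adj"].values < alpha
    signed = de["M"].values > 0 if direction == "positive" else de["M"].values < 0
    return set(de.index[sig & signed])


def mean_intensity_pass(de: pd.DataFrame, which_group: str, threshold: float) -> Set[str]:
    """Genes whose mean log2 intensity in the named group exceeds
    log2(threshold), strictly."""
    col = {"group1": "mean_group1", "group2": "mean_group2"}.get(which_group)
    if col is None:
        raise ValueError(
            f"unknown group {which_group!r}; expected 'group1' or 'group2'"
        )
    _check_de(de, (col,))
    return set(de.index[de[col].values > np.log2(threshold)])


def rank_by(values: pd.Series, order: str = "descending") -> pd.Series:
    """Ranks with 1 = most extreme in the requested order; ties get the
    average of the tied positions."""
    if order not in ("descending", "ascending"):
        raise ValueError(f"order must be 'descending' or 'ascending', got {order!r}")
    arr = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~np.isfinite(arr))
    if len(bad):
        raise ValueError(f"non-finite value for gene(s) {list(values.index[bad][:5])}")
    ranks = rankdata(-arr if order == "descending" else arr, method="average")
    return pd.Series(ranks, index=values.index, name="rank")


@dataclass
class RankedGeneList:
    """A filter's surviving genes with component ranks and final order.

    ``entries`` is ordered by ascending rank sum (ties broken
    lexicographically by gene id) with ``final_position`` = 1..k.
    """

    entries: pd.DataFrame
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def gene_ids(self) -> list:
        return list(self.entries.index)

    def __len__(self) -> int:
        return len(self.entries)


def _assemble(
    included: Set[str],
    rank_components: Dict[str, pd.Series],
    extras: Dict[str, pd.Series],
    provenance: Dict[str, object],
) -> RankedGeneList:
    genes = pd.Index(sorted(included), name="gene_id")
    frame = pd.DataFrame(index=genes)
    rank_sum = pd.Series(0.0, index=genes)
    for name, ranks in rank_components.items():
        frame[f"rank_{name}"] = ranks.reindex(genes)
        rank_sum = rank_sum + frame[f"rank_{name}"]
    frame["rank_sum"] = rank_sum
    for name, col in extras.items():
        frame[name] = col.reindex(genes)
    frame = frame.sort_values(["rank_sum", "gene_id"], kind="stable")
    frame["final_position"] = np.arange(1, len(frame) + 1)
    return RankedGeneList(entries=frame, provenance=provenance)


def _universe(*tables: pd.DataFrame) -> pd.Index:
    universe = tables[0].index
    for t in tables[1:]:
        universe = universe.intersection(t.index)
    if len(universe) == 0:
        raise ValueError("empty shared gene universe across DE tables")
    return universe


def filter_shared_gsc(
    de_e2: pd.DataFrame,
    de_e3: pd.DataFrame,
    de_e1: pd.DataFrame,
    cfg: Optional[FilterConfig] = None,
) -> RankedGeneList:
    """Genes enriched in both stem-cell comparisons with baseline tissue
    expression, rank-sum ordered by their E2 and E3 M values."""
    cfg = (cfg or FilterConfig()).validate()
    for de in (de_e1, de_e2, de_e3):
        _check_de(de, ("M", "p_adj", "mean_group1", "mean_group2"))
    universe = _universe(de_e1, de_e2, de_e3)
    e1 = de_e1.loc[universe]
    e2 = de_e2.loc[universe]
    e3 = de_e3.loc[universe]
    included = (
        select_enriched(e2, cfg.alpha, "positive")
        & select_enriched(e3, cfg.alpha, "positive")
        & mean_intensity_pass(e1, "group1", cfg.intensity_threshold)
        & mean_intensity_pass(e1, "group2", cfg.intensity_threshold)
    )
    genes = pd.Index(sorted(included))
    ranks = {
        "e2_m": rank_by(e2.loc[genes, "M"], "descending") if len(genes) else pd.Series(dtype=float),
        "e3_m": rank_by(e3.loc[genes, "M"], "descending") if len(genes) else pd.Series(dtype=float),
    }
    extras = {
        "M_e2": e2["M"],
        "p_adj_e2": e2["p_adj"],
        "M_e3": e3["M"],
        "p_adj_e3": e3["p_adj"],
        "M_e1": e1["M"],
    }
    return _assemble(
        included,
        ranks,
        extras,
        {"filter": "shared_gsc", "alpha": cfg.alpha, "intensity_threshold": cfg.intensity_threshold},
    )


def filter_germarium_not_gsc(
    de_e1: pd.DataFrame, de_e2: pd.DataFrame, cfg: Optional[FilterConfig] = None
) -> RankedGeneList:
    """Germarium-enriched genes that are not GSC-enriched in the female
    stem-cell comparison, ordered by germarium M."""
    cfg = (cfg or FilterConfig()).validate()
    universe = _universe(de_e1, de_e2)
    e1 = de_e1.loc[universe]
    e2 = de_e2.loc[universe]
    included = select_enriched(e1, cfg.alpha, "positive") - select_enriched(
        e2, cfg.alpha, "positive"
    )
    genes = pd.Index(sorted(included))
    ranks = {
        "e1_m": rank_by(e1.loc[genes, "M"], "descending") if len(genes) else pd.Series(dtype=float)
    }
    extras = {"M_e1": e1["M"], "p_adj_e1": e1["p_adj"], "p_adj_e2": e2["p_adj"]}
    return _assemble(
        included, ranks, extras, {"filter": "germarium_not_gsc", "alpha": cfg.alpha}
    )


def filter_testis_not_gsc(
    de_e1: pd.DataFrame, de_e3: pd.DataFrame, cfg: Optional[FilterConfig] = None
) -> RankedGeneList:
    """Testis-enriched genes that are not stem-cell/gonialblast-enriched in
    the male comparison; ordering favors strong tissue bias and
    bgcn--enriched (later-stage) expression."""
    cfg = (cfg or FilterConfig()).validate()
    universe = _universe(de_e1, de_e3)
    e1 = de_e1.loc[universe]
    e3 = de_e3.loc[universe]
    included = select_enriched(e1, cfg.alpha, "negative") - select_enriched(
        e3, cfg.alpha, "positive"
    )
    genes = pd.Index(sorted(included))
    ranks = {
        "e1_abs_m": rank_by(e1.loc[genes, "M"].abs(), "descending")
        if len(genes)
        else pd.Series(dtype=float),
        "e3_m": rank_by(e3.loc[genes, "M"], "ascending") if len(genes) else pd.Series(dtype=float),
    }
    extras = {"M_e1": e1["M"], "p_adj_e1": e1["p_adj"], "M_e3": e3["M"], "p_adj_e3": e3["p_adj"]}
    return _assemble(
        included, ranks, extras, {"filter": "testis_not_gsc", "alpha": cfg.alpha}
    )
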