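"""Term over-representation by the exact hypergeometric test.

Given a query gene set and generic term annotations over a background (all
genes on the array), each term's one-sided upper-tail p-value
P(X >= observed overlap) is computed from the hypergeometric distribution
and adjusted across terms by Benjamini-Hochberg; terms with adjusted
p < 0.01 (strict) are flagged over-represented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .synthdata import PopulationAtlas


@dataclass
class AnnotationMap:
    """term_id -> gene set annotations over a background universe."""

    terms: Dict[str, FrozenSet[str]]
    background: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("annotation map has no terms")
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} annotates no genes")
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} annotates gene(s) outside the background: "
                    f"{sorted(stray)[:5]}"
                )


def overrepresentation(
    query: Iterable[str], ann: AnnotationMap, alpha: float = 0.01
) -> pd.DataFrame:
    """One row per term: overlap counts, hypergeometric upper-tail p and
    BH-adjusted p, sorted by significance.

    The test is P(X >= count) for X ~ Hypergeometric(background_size,
    population_hits, query_size); count = 0 gives p = 1.
    """
    query_set = set(query)
    stray = query_set - ann.background
    if stray:
        raise ValueError(
            f"query gene(s) outside the background: {sorted(stray)[:10]}"
        )
    bg_size = len(ann.background)
    q_size = len(query_set)
    rows = []
    for term in sorted(ann.terms):
        genes = ann.terms[term]
        hits = len(genes)
        count = len(query_set & genes)
        # upper tail including the observed count
        p = float(hypergeom.sf(count - 1, bg_size, hits, q_size))
        rows.append((term, count, hits, q_size, bg_size, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=["term_id", "count", "population_hits", "query_size", "background_size", "p"],
    ).set_index("term_id")
    table["p_adj"] = bh_adjust(table["p"])
    table["significant"] = table["p_adj"] < alpha
    return table.sort_values(["p_adj", "p", "term_id"], kind="stable")


def simulate_annotations(
    atlas: PopulationAtlas,
    n_terms: int,
    planted_terms: Mapping[str, str],
    term_size_range: Tuple[int, int],
    seed: int,
    purity: float = 0.9,
) -> AnnotationMap:
    """Random annotation terms plus planted terms enriched for truth classes.

    A planted term for a truth class draws ``purity`` of its members from
    that class's genes and the rest from the remaining background.  Fully
    seeded; identical seeds give identical maps.
    """
    lo, hi = term_size_range
    background = list(atlas.gene_ids)
    if not 1 <= lo <= hi <= len(background):
        raise ValueError(f"term sizes {term_size_range} invalid for background of "
                         f"{len(background)} genes")
    truth = atlas.truth_sets()
    for cls in planted_terms:
        if cls not in truth:
            raise ValueError(f"planted class {cls!r} absent from atlas classes "
                             f"{sorted(truth)}")
        if not truth[cls]:
            raise ValueError(f"planted class {cls!r} has no genes in this atlas")
    rng = np.random.default_rng(seed)
    terms: Dict[str, FrozenSet[str]] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(background, size=size, replace=False)
        terms[f"T{i + 1:04d}"] = frozenset(members)
    for cls in sorted(planted_terms):
        term_id = planted_terms[cls]
        size = int(rng.integers(lo, hi + 1))
        class_genes = sorted(truth[cls])
        n_class = min(int(round(purity * size)), len(class_genes))
        members = set(rng.choice(class_genes, size=n_class, replace=False))
        others = sorted(set(background) - set(class_genes))
        n_other = min(size - n_class, len(others))
        if n_other > 0:
            members |= set(rng.choice(others, size=n_other, replace=False))
        terms[term_id] = frozenset(members)
    return AnnotationMap(terms=terms, background=frozenset(background))


def write_annotations_tsv(ann: AnnotationMap, path) -> None:
    """Two-column TSV (term_id, gene_id), one row per annotation."""
    with open(path, "w") as fh:
        fh.write("term_id\tgene_id\n")
        for term in sorted(ann.terms):
            for gene in sorted(ann.terms[term]):
                fh.write(f"{term}\t{gene}\n")


def read_annotations_tsv(path, background: Optional[Iterable[str]] = None) -> AnnotationMap:
    """Read two-column (term_id, gene_id) TSV or GMT-style lines.

    GMT lines are term_id <tab> description <tab> gene1 <tab> gene2 ...;
    the format is auto-detected per file from the header.  The background
    defaults to the union of annotated genes.
    """
    terms: Dict[str, Set[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        is_tsv = first.strip().lower().startswith("term_id\t")
        lines = [] if is_tsv else [first]
        lines += fh.readlines()
    for line in lines:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0]:
            continue
        if is_tsv:
            terms.setdefault(parts[0], set()).add(parts[1])
        else:
            terms.setdefault(parts[0], set()).update(g for g in parts[2:] if g)
    bg = frozenset(background) if background is not None else frozenset(
        g for genes in terms.values() for g in genes
    )
    return AnnotationMap(
        terms={t: frozenset(g) for t, g in terms.items()}, background=bg
    )
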