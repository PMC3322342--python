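"""End-to-end orchestration: simulate -> normalize -> DE -> integrate ->
enrich, with recovery evaluation against the planted truth.

Every intermediate table is written as TSV (gene_id first), and a JSON
manifest records the configuration, the root seed, and a content hash of
every file, so a run is reproducible and verifiable byte-for-byte.  All
randomness flows from the root seed through named per-stage streams, so
stages can be re-run independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import numpy as np
import pandas as pd

from .config import (
    GERMARIUM_NOT_GSC,
    SHARED_GSC,
    TESTIS_NOT_GSC,
    RunConfig,
)
from .diffexpr import TwoColorModeratedTTest, TwoGroupModeratedTTest
from .enrich import overrepresentation, simulate_annotations, write_annotations_tsv
from .integrate import (
    RankedGeneList,
    SchemaError,
    filter_germarium_not_gsc,
    filter_shared_gsc,
    filter_testis_not_gsc,
)
from .normalize import LoessNormalizer, MATable, QuantileNormalizer
from .synthdata import (
    PopulationAtlas,
    SingleChannelSet,
    build_atlas,
    simulate_single_channel,
    simulate_two_color,
)

logger = logging.getLogger("nichexpress")

_STAGE_NAMES = ("atlas", "two_color", "female_gsc_vs_kc", "os_bgcn_vs_bgcn", "annotations")

# Truth class targeted by each filter.
FILTER_TRUTH = {
    "shared_gsc": SHARED_GSC,
    "germarium_not_gsc": GERMARIUM_NOT_GSC,
    "testis_not_gsc": TESTIS_NOT_GSC,
}

ORIENTATION_NOTE = "# orientation: positive M = germarium-enriched (E1) / stem-cell-enriched (E2, E3)"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def stage_seeds(root_seed: int) -> Dict[str, int]:
    """Named per-stage integer seeds (< 2**31) derived from the root seed."""
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(_STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGE_NAMES, children)
    }


def write_table(df: pd.DataFrame, path: Union[str, Path], header_note: Optional[str] = None) -> None:
    """TSV with gene_id first; floats use shortest round-trip decimal text
    so write -> read reproduces every value exactly and hashes are stable."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_note:
            fh.write(header_note.rstrip("\n") + "\n")
        df.to_csv(
            fh, sep="\t", lineterminator="\n", float_format=lambda v: repr(float(v))
        )


def read_table(
    path: Union[str, Path], required: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Read a TSV with a header row and gene_id in the first column."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#", float_precision="round_trip"
    )
    if df.index.name != "gene_id":
        raise SchemaError(
            f"{path}: first column must be 'gene_id', got {df.index.name!r}"
        )
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise SchemaError(f"{path}: duplicate gene_id(s) {list(dups[:5])}")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


@dataclass
class RecoveryEntry:
    precision: float
    recall: float
    precision_at_k: Dict[int, float]
    list_size: int
    truth_size: int
    empty_list: bool = False


def evaluate_recovery(
    ranked: Union[RankedGeneList, Sequence[str]], truth: Set[str]
) -> RecoveryEntry:
    """Precision/recall of a ranked list against its planted truth set.

    An empty list reports precision 1.0 by convention but is flagged so the
    degenerate case stays visible.  precision_at_k is reported for
    k in {10, 25, 50, list size} restricted to k <= list size.
    """
    if not truth:
        raise ValueError("truth set is empty")
    genes = list(ranked.gene_ids if isinstance(ranked, RankedGeneList) else ranked)
    if isinstance(ranked, RankedGeneList) and len(ranked):
        genes = list(ranked.entries.sort_values("final_position").index)
    hits = [g in truth for g in genes]
    size = len(genes)
    if size == 0:
        return RecoveryEntry(1.0, 0.0, {}, 0, len(truth), empty_list=True)
    precision = sum(hits) / size
    recall = sum(hits) / len(truth)
    p_at_k = {}
    for k in sorted({10, 25, 50, size}):
        if k <= size:
            p_at_k[k] = sum(hits[:k]) / k
    return RecoveryEntry(precision, recall, p_at_k, size, len(truth))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_atlas(atlas: PopulationAtlas, outdir: Path) -> List[Path]:
    table = atlas.true_expression.copy()
    table["truth_class"] = atlas.truth_class
    p1 = outdir / "atlas.tsv"
    write_table(table, p1)
    return [p1]


def _write_two_color(arrays, outdir: Path) -> List[Path]:
    cols = {}
    flips = {}
    for arr in arrays:
        cols[f"rep{arr.replicate_id}_ch1"] = arr.intensity_ch1
        cols[f"rep{arr.replicate_id}_ch2"] = arr.intensity_ch2
        flips[f"rep{arr.replicate_id}"] = arr.dye_flipped
    p1 = outdir / "two_color_raw.tsv"
    write_table(pd.DataFrame(cols), p1)
    p2 = outdir / "two_color_design.json"
    with open(p2, "w") as fh:
        json.dump({"dye_flipped": flips}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return [p1, p2]


def _run_single_channel_de(
    sc: SingleChannelSet, positive_group: str
) -> TwoGroupModeratedTTest:
    # quantile-normalize within each group: aligns replicate distributions
    # without forcing the two biological groups onto common order statistics
    matrix = sc.matrix
    labels = np.array(sc.group_labels)
    log2_cols = {}
    for group in sc.groups:
        sub = matrix.loc[:, labels == group]
        log2_cols[group] = QuantileNormalizer().fit_transform(sub)
    log2_matrix = pd.concat(log2_cols.values(), axis=1)[matrix.columns]
    model = TwoGroupModeratedTTest(positive_group=positive_group)
    model.fit(log2_matrix.T, sc.group_labels)
    return model


def run_all(config: RunConfig, outdir: Union[str, Path]) -> Dict:
    """Execute every stage in order and return the manifest dict."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    files: List[Path] = []
    mixtures = config.mixtures

    def _stage(name):
        logger.info("stage %s", name)

    try:
        _stage("atlas")
        atlas_cfg = dataclasses.replace(config.atlas, seed=seeds["atlas"])
        atlas = build_atlas(atlas_cfg)
        truth = atlas.truth_sets()
        files += _write_atlas(atlas, outdir)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("atlas", str(exc)) from exc

    try:
        _stage("two_color")
        arrays = simulate_two_color(
            atlas,
            mixtures["germarium"],
            mixtures["testis_apex"],
            n_reps=config.two_color.n_reps,
            n_flips=config.two_color.n_flips,
            noise_log2_sd=config.two_color.noise_log2_sd,
            dye_bias_coeffs=config.two_color.dye_bias_coeffs,
            seed=seeds["two_color"],
        )
        files += _write_two_color(arrays, outdir)
        ma = MATable.from_arrays(arrays)
        normalizer = LoessNormalizer(
            span=config.loess_span, iterations=config.loess_iterations
        )
        ma_norm = normalizer.fit_transform(ma)
        ma_out = pd.concat(
            {"M": ma_norm.M, "A": ma_norm.A}, axis=1
        )
        ma_out.columns = [f"{stat}_{rep}" for stat, rep in ma_out.columns]
        p = outdir / "two_color_ma_normalized.tsv"
        write_table(ma_out, p, ORIENTATION_NOTE)
        files.append(p)
        e1_model = TwoColorModeratedTTest().fit(ma_norm)
        de_e1 = e1_model.results_
        p = outdir / "de_e1_germarium_vs_testis.tsv"
        write_table(de_e1, p, ORIENTATION_NOTE)
        files.append(p)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("two_color", str(exc)) from exc

    de_sc = {}
    for stage, (mix1, mix2, tag) in {
        "female_gsc_vs_kc": ("female_gsc", "kc", "female_gsc_vs_kc"),
        "os_bgcn_vs_bgcn": ("os_bgcn", "bgcn", "os_bgcn_vs_bgcn"),
    }.items():
        try:
            _stage(stage)
            sc = simulate_single_channel(
                atlas,
                (mixtures[mix1], mixtures[mix2]),
                n_per_group=config.single_channel.n_per_group,
                noise_log2_sd=config.single_channel.noise_log2_sd,
                tag=tag,
                seed=seeds[stage],
            )
            p = outdir / f"single_channel_{tag}.tsv"
            write_table(sc.matrix, p)
            files.append(p)
            model = _run_single_channel_de(sc, positive_group=mixtures[mix1].sample_name)
            de_sc[stage] = model.results_
            p = outdir / f"de_{'e2' if stage == 'female_gsc_vs_kc' else 'e3'}_{tag}.tsv"
            write_table(model.results_, p, ORIENTATION_NOTE)
            files.append(p)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(stage, str(exc)) from exc

    de_e2 = de_sc["female_gsc_vs_kc"]
    de_e3 = de_sc["os_bgcn_vs_bgcn"]

    try:
        _stage("integrate")
        lists = {
            "shared_gsc": filter_shared_gsc(de_e2, de_e3, de_e1, config.filters),
            "germarium_not_gsc": filter_germarium_not_gsc(de_e1, de_e2, config.filters),
            "testis_not_gsc": filter_testis_not_gsc(de_e1, de_e3, config.filters),
        }
        for name, ranked in lists.items():
            entries = ranked.entries.copy()
            entries["truth_class"] = atlas.truth_class.reindex(entries.index)
            p = outdir / f"ranked_{name}.tsv"
            write_table(entries, p, ORIENTATION_NOTE)
            files.append(p)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("integrate", str(exc)) from exc

    try:
        _stage("enrich")
        planted = {
            cls: f"PLANTED_{cls}" for cls in FILTER_TRUTH.values() if truth.get(cls)
        }
        ann = simulate_annotations(
            atlas,
            n_terms=config.enrichment.n_terms,
            planted_terms=planted,
            term_size_range=(config.enrichment.term_size_min, config.enrichment.term_size_max),
            seed=seeds["annotations"],
            purity=config.enrichment.planted_purity,
        )
        p = outdir / "annotations.tsv"
        write_annotations_tsv(ann, p)
        files.append(p)
        enrichment_tables = {}
        for name, ranked in lists.items():
            table = overrepresentation(ranked.gene_ids, ann, alpha=config.enrichment.alpha)
            enrichment_tables[name] = table
            p = outdir / f"enrichment_{name}.tsv"
            with open(p, "w") as fh:
                table.to_csv(fh, sep="\t", lineterminator="\n")
            files.append(p)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("enrich", str(exc)) from exc

    try:
        _stage("evaluate")
        recovery = {}
        for name, ranked in lists.items():
            truth_set = truth.get(FILTER_TRUTH[name], set())
            if truth_set:
                entry = dataclasses.asdict(evaluate_recovery(ranked, truth_set))
            else:
                # nothing planted for this filter (e.g. a null simulation):
                # precision/recall are undefined, but the list size matters
                entry = {
                    "precision": None,
                    "recall": None,
                    "precision_at_k": {},
                    "list_size": len(ranked),
                    "truth_size": 0,
                    "empty_list": len(ranked) == 0,
                }
            recovery[name] = entry
        p = outdir / "recovery.json"
        with open(p, "w") as fh:
            json.dump(recovery, fh, indent=2, sort_keys=True)
            fh.write("\n")
        files.append(p)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("evaluate", str(exc)) from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "stage_seeds": seeds,
        "orientation": ORIENTATION_NOTE.lstrip("# "),
        "files": {f.name: _sha256(f) for f in files},
        "recovery": recovery,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    logger.info("run complete: %d files in %s", len(files) + 1, outdir)
    return manifest
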