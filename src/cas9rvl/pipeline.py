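"""End-to-end orchestration: simulate -> count/filter -> score -> aggregate.

All artifacts are plain text (TSV/JSON), written atomically, with row and
key ordering fixed so that identical config + seed reproduce byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .config import AnalysisBlock, RunConfig
from .counting import CountTable, apply_min_count_filter, library_complexity
from .errors import AnalysisError, ValidationError
from .kinetics import TimeCourse, timecourse, timecourses_tsv
from .library import Species, TargetSpec, sample_library, write_library
from .retention import RetentionTable, build_reference, build_retention_table
from .simulate import SimulationResult, sample_label, simulate_experiment
from .variants import (
    DoubleVariantMatrix,
    SingleVariantSummary,
    double_variant_matrix,
    element_detectability,
    heatmap_normalize,
    single_variant_medians,
    synergy_matrix,
)

logger = logging.getLogger(__name__)


def atomic_write_text(path: str | Path, text: str) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "element") -> None:
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g", index_label=index_label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)


@dataclass
class SimulationOutputs:
    spec: TargetSpec
    library: list[Species]
    result: SimulationResult
    spike_members: tuple[str, ...]


def run_simulation(cfg: RunConfig, seed: int | None = None) -> SimulationOutputs:
    """Generate a library and its paired uncut/cut count table from config."""
    sim = cfg.simulation
    base_seed = sim.seed if seed is None else seed
    spec = cfg.target.build()
    library = sample_library(spec, sim.n_species, base_seed)
    spike: list[Species] = []
    spike_fraction = 0.0
    if sim.spike_in is not None and sim.spike_in.fraction > 0:
        spike_spec = sim.spike_in.build_spec()
        spike = sample_library(spike_spec, sim.spike_in.n_species, base_seed + 1)
        spike_fraction = sim.spike_in.fraction
    profile = sim.build_profile(spec)
    kinetics = sim.kinetics.build(sim.timepoints)
    result = simulate_experiment(
        spec,
        library,
        profile,
        kinetics,
        sim.depth,
        spike_in=spike,
        spike_fraction=spike_fraction,
        sampling=sim.sampling,
        seed=base_seed + 2,
    )
    return SimulationOutputs(spec, library, result, result.spike_sequences)


@dataclass
class AnalysisResult:
    filtered: CountTable
    retention: RetentionTable
    singles: SingleVariantSummary
    heat: pd.Series
    dvm: DoubleVariantMatrix
    synergy: pd.DataFrame
    detectable: dict | None
    report: dict = field(default_factory=dict)


def analyze_counts(
    table: CountTable,
    spec: TargetSpec,
    acfg: AnalysisBlock | None = None,
    spike_members: Sequence[str] | None = None,
    uncleaved_sample: str = "uncut",
) -> AnalysisResult:
    """Filter, score and aggregate a count table into the reporting views."""
    acfg = acfg or AnalysisBlock()
    filtered = apply_min_count_filter(table, uncleaved_sample, acfg.min_count)
    reference = build_reference(
        filtered, acfg.reference_mode, spike_members=spike_members
    )
    rt = build_retention_table(
        filtered, reference, uncleaved_sample, pseudocount=acfg.pseudocount
    )
    if acfg.timepoint is not None:
        focal = sample_label(acfg.timepoint)
        if focal not in rt.cleaved_samples:
            raise ValidationError(f"requested timepoint sample {focal!r} not present")
    else:
        focal = rt.cleaved_samples[-1]
    singles = single_variant_medians(rt, spec, focal)
    try:
        heat = heatmap_normalize(singles)
    except AnalysisError:
        logger.warning("WT median undefined or zero; heat-map ratios unavailable")
        heat = singles.grid["median"] * float("nan")
    dvm = double_variant_matrix(rt, spec, focal, n_min=acfg.n_min)
    detectable = None
    if filtered.is_integral():
        detectable = element_detectability(
            filtered, reference, spec, uncleaved_sample, focal, acfg.alpha
        )
    syn = synergy_matrix(dvm, detectable)
    report = {
        "input_species": table.n_species,
        "retained_species": filtered.n_species,
        "filter_min_count": acfg.min_count,
        "library_complexity": filtered.n_species,
        "reference_mode": reference.mode,
        "reference_size": len(reference.members),
        "focal_sample": focal,
        "undefined_cells": rt.meta.get("undefined_cells", {}),
        "masked_double_cells": int(dvm.lr.isna().to_numpy().sum()),
        "synergy_cells": int(syn.notna().to_numpy().sum()) // 2,
        "wt_median": None if pd.isna(singles.wt_median) else float(singles.wt_median),
        "wt_n": singles.wt_n,
    }
    return AnalysisResult(filtered, rt, singles, heat, dvm, syn, detectable, report)


def write_analysis(result: AnalysisResult, outdir: str | Path) -> dict[str, Path]:
    """Write every reporting artifact under ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "retention": outdir / "retention.tsv",
        "single_variants": outdir / "single_variants.tsv",
        "heatmap": outdir / "heatmap.tsv",
        "double_lr": outdir / "double_lr.tsv",
        "double_n": outdir / "double_n.tsv",
        "synergy": outdir / "synergy.tsv",
        "report": outdir / "report.json",
    }
    result.retention.write_tsv(paths["retention"])
    result.singles.write_tsv(paths["single_variants"])
    heat = result.heat.rename("ratio_to_wt").reset_index()
    heat.to_csv(paths["heatmap"], sep="\t", index=False, na_rep="NA", float_format="%.10g")
    write_matrix_tsv(result.dvm.lr, paths["double_lr"])
    write_matrix_tsv(result.dvm.n, paths["double_n"])
    write_matrix_tsv(result.synergy, paths["synergy"])
    atomic_write_text(paths["report"], json.dumps(result.report, sort_keys=True, indent=1))
    return paths


def run_all(cfg: RunConfig, outdir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """simulate -> analyze -> timecourses, writing all artifacts to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = run_simulation(cfg, seed)
    table = sim.result.counts.sorted()
    write_library(outdir / "library.tsv", *_collapsed(sim.library))
    table.write_tsv(outdir / "counts.tsv")
    gt = sim.result.ground_truth.sort_index()
    atomic_write_text(
        outdir / "ground_truth.json",
        gt.to_json(orient="index", double_precision=12, indent=1),
    )
    spike = sim.spike_members if cfg.analysis.reference == "spikein" else None
    analysis = analyze_counts(table, sim.spec, cfg.analysis, spike_members=spike)
    paths = write_analysis(analysis, outdir)
    courses: list[TimeCourse] = []
    for variant in cfg.analysis.timecourse_variants:
        try:
            courses.append(timecourse(analysis.retention, variant, sim.spec))
        except KeyError:
            logger.warning("timecourse variant %r has no retained species; skipped", variant)
    if courses:
        timecourses_tsv(courses, outdir / "timecourses.tsv")
        paths["timecourses"] = outdir / "timecourses.tsv"
    paths["library"] = outdir / "library.tsv"
    paths["counts"] = outdir / "counts.tsv"
    paths["ground_truth"] = outdir / "ground_truth.json"
    return paths


def _collapsed(library: Sequence[Species]):
    from .library import collapse_library

    unique, counts = collapse_library(library)
    return unique, counts
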