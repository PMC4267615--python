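"""Retention scoring: normalized representation and log2 retention.

For each species X and each sample,

    Representation_X = [reads of X] / [reads of a reference population],

where the reference population is either the aggregate of all species with
4-7 mismatches to the canonical target (assumed essentially uncleavable) or
a designated spike-in control set.  The cleavage readout is then

    Retention[X] = log2(Representation_X[cleaved] / Representation_X[uncleaved]);

0 means no depletion relative to the uncleaved pool, negative values mean
cleavage.  A species with zero reads in a cleaved sample has undefined
retention (marked NA, never -inf); an optional +0.5 pseudocount is available
behind a flag.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import CountTable
from .errors import AnalysisError, NormalizationError, ValidationError

logger = logging.getLogger(__name__)

#: Mismatch-class bounds for the default reference population.
REFERENCE_MISMATCH_RANGE = (4, 7)


@dataclass(frozen=True)
class ReferencePopulation:
    """The normalization denominator: a set of assumed-uncleavable species."""

    mode: str  # "mismatch_class" or "spike_in"
    members: frozenset[str]
    floor: int = 500

    def __post_init__(self) -> None:
        if self.mode not in ("mismatch_class", "spike_in"):
            raise ValidationError(f"unknown reference mode {self.mode!r}")
        if not self.members:
            raise NormalizationError(f"reference population ({self.mode}) is empty")

    def aggregate_counts(self, table: CountTable) -> pd.Series:
        """Per-sample total reads over the member species present in the table."""
        present = table.counts.index.intersection(list(self.members))
        if len(present) == 0:
            raise NormalizationError(
                f"no {self.mode} reference species present in the count table"
            )
        return table.counts.loc[present].sum(axis=0)


def build_reference(
    table: CountTable,
    mode: str = "mismatch_class",
    spike_members: Sequence[str] | None = None,
    mismatch_range: tuple[int, int] = REFERENCE_MISMATCH_RANGE,
    floor: int = 500,
) -> ReferencePopulation:
    """Construct the reference population from a (filtered) count table.

    ``mismatch_class`` membership is computed from each species' signature;
    ``spike_in`` membership comes from the caller's configuration.
    """
    if mode == "mismatch_class":
        lo, hi = mismatch_range
        members = frozenset(
            table.info.index[(table.info["mismatch_count"] >= lo) & (table.info["mismatch_count"] <= hi)]
        )
    elif mode == "spike_in":
        if not spike_members:
            raise ValidationError("spike_in reference requires spike_members")
        members = frozenset(spike_members) & frozenset(table.counts.index)
    else:
        raise ValidationError(f"unknown reference mode {mode!r}")
    return ReferencePopulation(mode, members, floor)


def representation(count_x: float, reference_count: float) -> float:
    """Reads of X over reads of the reference population, same sample."""
    if reference_count < 1:
        raise NormalizationError(
            f"reference population has {reference_count} reads; sample unusable"
        )
    return count_x / reference_count


def retention_score(rep_cleaved: float, rep_uncleaved: float) -> float:
    """log2 of cleaved over uncleaved representation; NaN when cleaved is 0."""
    if rep_uncleaved <= 0:
        raise AnalysisError(
            "uncleaved representation must be positive (read filter violated)"
        )
    if rep_cleaved == 0:
        return math.nan
    return math.log2(rep_cleaved / rep_uncleaved)


@dataclass
class RetentionTable:
    """Species x cleaved-sample log2 retention scores.

    ``scores`` is indexed by sequence with one column per cleaved sample;
    NaN cells mark species with zero cleaved reads.  ``info`` mirrors the
    count table's annotations; ``meta`` records the reference mode/size,
    the undefined-cell tally and any filter settings passed through.
    """

    scores: pd.DataFrame
    info: pd.DataFrame
    reference: ReferencePopulation
    uncleaved_sample: str
    meta: dict = field(default_factory=dict)

    @property
    def cleaved_samples(self) -> list[str]:
        return list(self.scores.columns)

    def write_tsv(self, path: str | Path) -> None:
        path = Path(path)
        out = self.info.join(self.scores).reset_index()
        out.insert(0, "species_id", [f"S{i:06d}" for i in range(len(out))])
        out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
        sidecar = dict(self.meta)
        sidecar.update(
            {
                "reference_mode": self.reference.mode,
                "reference_size": len(self.reference.members),
                "uncleaved_sample": self.uncleaved_sample,
                "cleaved_samples": self.cleaved_samples,
            }
        )
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RetentionTable":
        df = pd.read_csv(
            path, sep="\t", dtype={"sequence": str, "signature": str},
            na_values=["NA"], keep_default_na=False,
        )
        df = df.set_index("sequence")
        info = df[["signature", "mismatch_count"]].copy()
        info["signature"] = info["signature"].fillna("")
        info["mismatch_count"] = info["mismatch_count"].astype(int)
        scores = df.drop(columns=[c for c in ("species_id", "signature", "mismatch_count") if c in df])
        meta_path = Path(str(path) + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        reference = ReferencePopulation(
            meta.get("reference_mode", "mismatch_class"), frozenset({"<unknown>"}),
        )
        return cls(scores, info, reference, meta.get("uncleaved_sample", "uncut"), meta)


def build_retention_table(
    filtered: CountTable,
    reference: ReferencePopulation,
    uncleaved_sample: str = "uncut",
    cleaved_samples: Sequence[str] | None = None,
    pseudocount: float = 0.0,
) -> RetentionTable:
    """Score every retained species in every cleaved sample.

    ``filtered`` should already have passed the minimum-read filter on the
    uncleaved sample.  ``pseudocount`` (e.g. 0.5), when non-zero, is added
    to every raw count before forming representations, turning undefined
    cells into finite (large negative) scores.
    """
    if uncleaved_sample not in filtered.samples:
        raise ValidationError(f"uncleaved sample {uncleaved_sample!r} not in table")
    if cleaved_samples is None:
        cleaved_samples = [s for s in filtered.samples if s != uncleaved_sample]
    missing = [s for s in cleaved_samples if s not in filtered.samples]
    if missing:
        raise ValidationError(f"cleaved samples not in table: {missing}")
    if not cleaved_samples:
        raise ValidationError("no cleaved samples to score")

    ref_counts = reference.aggregate_counts(filtered)
    for s in [uncleaved_sample, *cleaved_samples]:
        if ref_counts[s] < 1:
            raise NormalizationError(f"reference population has zero reads in {s!r}")
        if ref_counts[s] < reference.floor:
            logger.warning(
                "reference population has only %.0f reads in %s (floor %d)",
                ref_counts[s], s, reference.floor,
            )

    counts = filtered.counts.astype(float) + pseudocount
    ref = ref_counts.astype(float) + pseudocount * len(
        filtered.counts.index.intersection(list(reference.members))
    )
    rep_unc = counts[uncleaved_sample] / ref[uncleaved_sample]
    if (rep_unc <= 0).any():
        raise AnalysisError("a retained species has zero uncleaved reads (filter violated)")
    scores = {}
    undefined = {}
    for s in cleaved_samples:
        rep_c = counts[s] / ref[s]
        with np.errstate(divide="ignore"):
            col = np.log2(rep_c / rep_unc)
        col = col.replace(-np.inf, np.nan)
        scores[s] = col
        undefined[s] = int(col.isna().sum())
    meta = {
        "undefined_cells": undefined,
        "pseudocount": pseudocount,
        "reference_counts": {s: float(ref_counts[s]) for s in ref_counts.index},
    }
    return RetentionTable(
        pd.DataFrame(scores, index=filtered.counts.index),
        filtered.info.copy(),
        reference,
        uncleaved_sample,
        meta,
    )
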