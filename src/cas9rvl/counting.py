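"""Species counting: FASTQ/TSV -> count tables, the read filter, complexity.

Species assignment is exact-match over the full 35-mer: reads whose trimmed
insert is not exactly 35 nt of A/C/G/T are tallied as unassigned, never
error-corrected or clustered.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import UnassignableRead, ValidationError
from .library import Species, TargetSpec, classify_species, signature_to_str

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdapterConfig:
    """How to excise the 35 nt insert from a read.

    With empty anchors the read itself must be the 35-mer.  A non-empty
    ``prefix`` is located exactly in the read and the 35 nt following it are
    taken; a non-empty ``suffix`` must follow immediately after the insert.
    """

    prefix: str = ""
    suffix: str = ""

    def extract(self, read: str) -> str:
        from .library import INSERT_LENGTH

        if not self.prefix and not self.suffix:
            return read
        if self.prefix:
            start = read.find(self.prefix)
            if start < 0:
                raise UnassignableRead("adapter prefix not found")
            begin = start + len(self.prefix)
        else:
            begin = 0
        insert = read[begin : begin + INSERT_LENGTH]
        if self.suffix and not read[begin + INSERT_LENGTH :].startswith(self.suffix):
            raise UnassignableRead("adapter suffix not found after insert")
        return insert


@dataclass
class CountTable:
    """Species x sample integer read counts.

    ``counts`` is indexed by the 35-mer sequence with one column per sample
    label; ``info`` (same index) carries ``signature`` (serialized) and
    ``mismatch_count``.  ``unassigned`` tallies per-sample reads that could
    not be classified.  In the simulator's expected-count mode cells are
    floats (noise-free expectations) rather than integers.
    """

    counts: pd.DataFrame
    info: pd.DataFrame
    unassigned: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.info.index):
            self.info = self.info.reindex(self.counts.index)
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("count cells must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_species(self) -> int:
        return len(self.counts)

    def total(self, sample: str) -> float:
        """Reads in a sample including unassigned ones."""
        return float(self.counts[sample].sum()) + self.unassigned.get(sample, 0)

    def is_integral(self) -> bool:
        vals = self.counts.to_numpy()
        return bool(np.all(np.equal(np.mod(vals, 1), 0)))

    def sorted(self) -> "CountTable":
        """Rows ordered by (mismatch_count, sequence) for reproducible diffs."""
        order = self.info.sort_values(["mismatch_count"], kind="stable").index
        order = sorted(self.counts.index, key=lambda s: (int(self.info.at[s, "mismatch_count"]), s))
        return CountTable(self.counts.loc[order], self.info.loc[order], dict(self.unassigned))

    # -- construction -------------------------------------------------------
    @classmethod
    def from_species_counts(
        cls,
        spec: TargetSpec,
        sample_counts: Mapping[str, Mapping[str, float]],
        unassigned: Mapping[str, int] | None = None,
    ) -> "CountTable":
        """Build from ``{sample: {sequence: count}}`` mappings."""
        sequences = sorted({seq for col in sample_counts.values() for seq in col})
        counts = pd.DataFrame(
            {s: [col.get(seq, 0) for seq in sequences] for s, col in sample_counts.items()},
            index=pd.Index(sequences, name="sequence"),
        )
        info = _info_frame(sequences, spec)
        return cls(counts, info, dict(unassigned or {}))

    def write_tsv(self, path: str | Path) -> None:
        """Write the table plus a JSON sidecar (totals, unassigned)."""
        path = Path(path)
        out = self.info.join(self.counts).reset_index()
        out.insert(0, "species_id", [f"S{i:06d}" for i in range(len(out))])
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
        sidecar = {
            "samples": self.samples,
            "totals": {s: self.total(s) for s in self.samples},
            "unassigned": {s: int(v) for s, v in self.unassigned.items()},
            "n_species": self.n_species,
        }
        Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, sort_keys=True, indent=1))

    @classmethod
    def read_tsv(cls, path: str | Path, spec: TargetSpec | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "signature": str}, keep_default_na=False)
        df = df.set_index("sequence")
        meta_cols = [c for c in ("species_id", "signature", "mismatch_count") if c in df.columns]
        counts = df.drop(columns=meta_cols)
        for col in counts.columns:
            counts[col] = pd.to_numeric(counts[col])
        if spec is not None:
            info = _info_frame(list(df.index), spec)
        else:
            info = df[["signature", "mismatch_count"]].copy()
            info["mismatch_count"] = info["mismatch_count"].astype(int)
        unassigned: dict[str, int] = {}
        sidecar = Path(str(path) + ".meta.json")
        if sidecar.exists():
            unassigned = {k: int(v) for k, v in json.loads(sidecar.read_text()).get("unassigned", {}).items()}
        return cls(counts, info, unassigned)


def _info_frame(sequences: Sequence[str], spec: TargetSpec) -> pd.DataFrame:
    sigs, mm = [], []
    for seq in sequences:
        sp = classify_species(seq, spec)
        sigs.append(signature_to_str(sp.signature))
        mm.append(sp.mismatch_count)
    return pd.DataFrame(
        {"signature": sigs, "mismatch_count": mm},
        index=pd.Index(sequences, name="sequence"),
    )


def _iter_reads(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        for record in SeqIO.parse(str(source), "fastq"):
            yield str(record.seq)
    else:
        for item in source:
            yield str(getattr(item, "seq", item))


def count_reads(
    source,
    spec: TargetSpec,
    sample: str = "sample",
    adapter: AdapterConfig | None = None,
) -> CountTable:
    """Count one sample's reads into a single-column table.

    ``source`` is a FASTQ path or any iterable of sequence strings /
    SeqRecords.  Reads failing trimming or classification are tallied as
    unassigned; a > 50% unassigned fraction logs a warning but is not fatal.
    """
    adapter = adapter or AdapterConfig()
    tally: dict[str, int] = {}
    unassigned = 0
    total = 0
    for read in _iter_reads(source):
        total += 1
        try:
            insert = adapter.extract(read.upper())
            classify_species(insert, spec)
        except UnassignableRead:
            unassigned += 1
            continue
        tally[insert] = tally.get(insert, 0) + 1
    if total and unassigned / total > 0.5:
        logger.warning(
            "sample %s: %d/%d reads unassigned (>50%%)", sample, unassigned, total
        )
    return CountTable.from_species_counts(spec, {sample: tally}, {sample: unassigned})


def combine_samples(tables: Sequence[CountTable]) -> CountTable:
    """Outer-join single-sample tables into one species x sample matrix."""
    if not tables:
        raise ValidationError("no tables to combine")
    counts = pd.concat([t.counts for t in tables], axis=1).fillna(0)
    if all(t.is_integral() for t in tables):
        counts = counts.astype(int)
    info = pd.concat([t.info for t in tables])
    info = info[~info.index.duplicated(keep="first")].reindex(counts.index)
    unassigned: dict[str, int] = {}
    for t in tables:
        unassigned.update(t.unassigned)
    return CountTable(counts, info, unassigned)


def apply_min_count_filter(
    table: CountTable, reference_sample: str, min_count: int = 50
) -> CountTable:
    """Keep species with >= ``min_count`` reads in the uncleaved sample.

    Only the designated reference (uncleaved) sample gates the filter; the
    retained rows keep all their other sample columns unchanged.
    """
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    if reference_sample not in table.samples:
        raise ValidationError(f"reference sample {reference_sample!r} not in table")
    mask = table.counts[reference_sample] >= min_count
    return CountTable(
        table.counts.loc[mask], table.info.loc[mask], dict(table.unassigned)
    )


def library_complexity(
    table: CountTable, reference_sample: str, min_count: int = 50
) -> int:
    """Unique species passing the minimum-representation filter."""
    return apply_min_count_filter(table, reference_sample, min_count).n_species
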