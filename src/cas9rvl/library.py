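"""Target coordinate system, doped-library design and species classification.

The assayed molecule is a 35 nt variable insert laid out as::

    positions  -5..0     1..20         21    22 23   24..29
    region     5' flank  protospacer   PAM-N PAM-GG  3' flank

Positions are labelled -5..29 left to right (the first base of guide homology
is position 1); every public surface of the package uses these labels.
Positions 1-20 and 22-23 are *doped*: synthesised mostly as the canonical
base with a small per-position variant rate split evenly over the three
alternatives.  Positions -5..0, 21 and 24..29 are *fully random* (each base
at 25%).  A :class:`Species` is one observed 35-mer together with its variant
signature over the doped positions.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import UnassignableRead, ValidationError

BASES: tuple[str, ...] = ("A", "C", "G", "T")
INSERT_LENGTH = 35
POSITION_MIN, POSITION_MAX = -5, 29

POSITIONS: tuple[int, ...] = tuple(range(POSITION_MIN, POSITION_MAX + 1))
FLANK5_POSITIONS: tuple[int, ...] = tuple(range(-5, 1))
PROTOSPACER_POSITIONS: tuple[int, ...] = tuple(range(1, 21))
PAM_POSITIONS: tuple[int, ...] = (21, 22, 23)
FLANK3_POSITIONS: tuple[int, ...] = tuple(range(24, 30))

#: Doped positions: the protospacer plus the two constrained PAM guanines.
DOPED_POSITIONS: tuple[int, ...] = PROTOSPACER_POSITIONS + (22, 23)
#: Fully random positions: both flanks plus the N of the NGG PAM.
RANDOM_POSITIONS: tuple[int, ...] = FLANK5_POSITIONS + (21,) + FLANK3_POSITIONS

_DOPED_SET = frozenset(DOPED_POSITIONS)
_RANDOM_SET = frozenset(RANDOM_POSITIONS)
_BASE_SET = frozenset(BASES)


def position_to_index(position: int) -> int:
    """Map a -5..29 position label to a 0-based index into the insert."""
    if not POSITION_MIN <= position <= POSITION_MAX:
        raise ValidationError(
            f"position must be in {POSITION_MIN}..{POSITION_MAX}, got {position}"
        )
    return position - POSITION_MIN


def index_to_position(index: int) -> int:
    """Inverse of :func:`position_to_index`."""
    if not 0 <= index < INSERT_LENGTH:
        raise ValidationError(f"index must be in 0..{INSERT_LENGTH - 1}, got {index}")
    return index + POSITION_MIN


def _check_dna(value: str, name: str, length: int | None = None) -> str:
    if not isinstance(value, str):
        raise ValidationError(f"{name} must be a DNA string, got {type(value).__name__}")
    if length is not None and len(value) != length:
        raise ValidationError(f"{name} must be {length} nt, got {len(value)} nt")
    if not set(value) <= _BASE_SET:
        bad = sorted(set(value) - _BASE_SET)
        raise ValidationError(f"{name} contains non-ACGT characters: {bad}")
    return value


@dataclass(frozen=True)
class TargetSpec:
    """The canonical 35 nt insert plus the doping model around it.

    Parameters
    ----------
    canonical_insert
        35 nt over A/C/G/T; positions 22-23 must be G (NGG PAM).
    doping_rate
        Per-doped-position probability of a non-canonical base, split
        evenly across the three alternatives (default 0.10, i.e. ~3.3%
        per alternative base).
    doping_overrides
        Optional per-position doping-rate overrides (paper-style labels),
        e.g. to emulate a library with an unexpectedly high variant rate
        at particular positions.
    """

    canonical_insert: str
    doping_rate: float = 0.10
    doping_overrides: Mapping[int, float] = field(default_factory=dict, hash=False)

    def __post_init__(self) -> None:
        _check_dna(self.canonical_insert, "canonical_insert", INSERT_LENGTH)
        for pam_pos in (22, 23):
            if self.base_at(pam_pos) != "G":
                raise ValidationError(
                    f"canonical_insert position {pam_pos} must be G (NGG PAM), "
                    f"got {self.base_at(pam_pos)}"
                )
        if not 0.0 <= self.doping_rate < 1.0:
            raise ValidationError(f"doping_rate must be in [0, 1), got {self.doping_rate}")
        for pos, rate in self.doping_overrides.items():
            if pos not in _DOPED_SET:
                raise ValidationError(f"doping_overrides position {pos} is not a doped position")
            if not 0.0 <= rate < 1.0:
                raise ValidationError(f"doping_overrides[{pos}] must be in [0, 1), got {rate}")

    # -- coordinate helpers -------------------------------------------------
    def index(self, position: int) -> int:
        return position_to_index(position)

    def base_at(self, position: int) -> str:
        return self.canonical_insert[position_to_index(position)]

    def rate_at(self, position: int) -> float:
        """Doping rate at a doped position (0.0 for fully random positions)."""
        if position in _RANDOM_SET:
            return 0.0
        return float(self.doping_overrides.get(position, self.doping_rate))

    @property
    def per_variant_rate(self) -> float:
        """Default probability of each single alternative base (doping_rate / 3)."""
        return self.doping_rate / 3.0

    @property
    def flank5(self) -> str:
        return self.canonical_insert[0:6]

    @property
    def protospacer(self) -> str:
        return self.canonical_insert[6:26]

    @property
    def pam_n(self) -> str:
        return self.canonical_insert[26]

    @property
    def flank3(self) -> str:
        return self.canonical_insert[29:35]

    @property
    def doped_positions(self) -> tuple[int, ...]:
        return DOPED_POSITIONS

    @property
    def random_positions(self) -> tuple[int, ...]:
        return RANDOM_POSITIONS

    def region_of(self, position: int) -> str:
        """Region role of a position: flank5/protospacer/pam_n/pam_gg/flank3."""
        if position in FLANK5_POSITIONS:
            return "flank5"
        if position in PROTOSPACER_POSITIONS:
            return "protospacer"
        if position == 21:
            return "pam_n"
        if position in (22, 23):
            return "pam_gg"
        if position in FLANK3_POSITIONS:
            return "flank3"
        raise ValidationError(f"position {position} out of range")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "protospacer": self.protospacer,
            "pam_n": self.pam_n,
            "flank5": self.flank5,
            "flank3": self.flank3,
            "doping_rate": self.doping_rate,
            "doping_overrides": {int(k): float(v) for k, v in self.doping_overrides.items()},
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "TargetSpec":
        return make_target_spec(
            data["protospacer"],
            flank5=data.get("flank5", "TCGATG"),
            flank3=data.get("flank3", "CATGCA"),
            pam_n=data.get("pam_n", "A"),
            doping_rate=data.get("doping_rate", 0.10),
            doping_overrides=data.get("doping_overrides") or {},
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TargetSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def make_target_spec(
    protospacer: str,
    *,
    flank5: str = "TCGATG",
    flank3: str = "CATGCA",
    pam_n: str = "A",
    doping_rate: float = 0.10,
    doping_overrides: Mapping[int, float] | None = None,
) -> TargetSpec:
    """Assemble a :class:`TargetSpec` from its parts.

    The insert is ``flank5 + protospacer + pam_n + "GG" + flank3``; the PAM
    positions 22-23 are forced to GG by construction.
    """
    _check_dna(protospacer, "protospacer", 20)
    _check_dna(flank5, "flank5", 6)
    _check_dna(flank3, "flank3", 6)
    _check_dna(pam_n, "pam_n", 1)
    insert = flank5 + protospacer + pam_n + "GG" + flank3
    return TargetSpec(insert, doping_rate=doping_rate, doping_overrides=dict(doping_overrides or {}))


def demo_target_spec(doping_rate: float = 0.10) -> TargetSpec:
    """A synthetic demonstration guide (not from any sequencing dataset).

    The canonical bases at positions 4, 11, 16 and 20 are C, C, G and T so
    that the classic variant names C4T, C11T, G16C/G16T and T20A all exist
    for this target.  Position 0 carries a G, mirroring the extra guanine a
    T7/U6 expression vector prepends to the guide.
    """
    return make_target_spec(
        "ACGCATGCACCTAGCGATCT",
        flank5="TCGATG",
        flank3="CATGCA",
        pam_n="A",
        doping_rate=doping_rate,
    )


def demo_control_spec(doping_rate: float = 0.10) -> TargetSpec:
    """A synthetic unrelated guide used as the spike-in internal control."""
    return make_target_spec(
        "GTTCGAAGGCTTAACCGTGA",
        flank5="AGGTCA",
        flank3="TTGACC",
        pam_n="C",
        doping_rate=doping_rate,
    )


# ---------------------------------------------------------------------------
# Species
# ---------------------------------------------------------------------------

Signature = tuple[tuple[int, str], ...]


@dataclass(frozen=True)
class Species:
    """One observed 35-mer and its derived identity.

    ``signature`` lists (position, observed base) at doped positions where
    the observed base differs from the canonical one, sorted by position;
    ``flank_context`` concatenates the 13 bases at the fully random
    positions (in position order -5..0, 21, 24..29).
    """

    sequence: str
    signature: Signature
    flank_context: str

    @property
    def mismatch_count(self) -> int:
        """Number of non-canonical bases at doped positions (1-20, 22-23)."""
        return len(self.signature)


def signature_to_str(signature: Signature) -> str:
    """Serialize a signature as ``"pos:base;pos:base"`` ("" for WT)."""
    return ";".join(f"{p}:{b}" for p, b in signature)


def signature_from_str(text: str) -> Signature:
    if not text or text in ("WT", "-"):
        return ()
    out = []
    for item in text.split(";"):
        pos_s, base = item.split(":")
        out.append((int(pos_s), base))
    return tuple(sorted(out))


def classify_species(sequence: str, spec: TargetSpec) -> Species:
    """Classify a 35-mer against a target layout.

    Raises
    ------
    UnassignableRead
        If the sequence is not exactly 35 nt of A/C/G/T.
    """
    if not isinstance(sequence, str) or len(sequence) != INSERT_LENGTH:
        raise UnassignableRead(
            f"read length {len(sequence) if isinstance(sequence, str) else '?'} != {INSERT_LENGTH}"
        )
    if not set(sequence) <= _BASE_SET:
        raise UnassignableRead("read contains non-ACGT characters")
    signature = tuple(
        (pos, sequence[pos + 5])
        for pos in DOPED_POSITIONS
        if sequence[pos + 5] != spec.canonical_insert[pos + 5]
    )
    flank_context = "".join(sequence[pos + 5] for pos in RANDOM_POSITIONS)
    return Species(sequence, signature, flank_context)


def reconstruct_sequence(
    spec: TargetSpec, signature: Signature = (), flank_context: str | None = None
) -> str:
    """Build the 35-mer carrying ``signature`` on the given flank context.

    ``flank_context`` defaults to the canonical bases at the random
    positions; reconstruction is the inverse of :func:`classify_species`.
    """
    chars = list(spec.canonical_insert)
    if flank_context is not None:
        _check_dna(flank_context, "flank_context", len(RANDOM_POSITIONS))
        for pos, base in zip(RANDOM_POSITIONS, flank_context):
            chars[pos + 5] = base
    for pos, base in signature:
        if pos not in _DOPED_SET:
            raise ValidationError(f"signature position {pos} is not a doped position")
        if base not in _BASE_SET:
            raise ValidationError(f"signature base {base!r} is not A/C/G/T")
        chars[pos + 5] = base
    return "".join(chars)


def make_species(
    spec: TargetSpec, signature: Signature = (), flank_context: str | None = None
) -> Species:
    """Convenience: reconstruct a sequence and classify it."""
    return classify_species(reconstruct_sequence(spec, signature, flank_context), spec)


# ---------------------------------------------------------------------------
# Library generation and enumeration
# ---------------------------------------------------------------------------


def sample_library(spec: TargetSpec, n_species: int, seed: int | None = None) -> list[Species]:
    """Draw ``n_species`` molecules from the doped-synthesis model.

    Each doped position independently keeps the canonical base with
    probability ``1 - rate`` and takes each alternative with ``rate / 3``;
    each fully random position takes each base with probability 1/4.
    Duplicate sequences may occur; :func:`collapse_library` merges them.
    """
    if n_species < 1:
        raise ValidationError(f"n_species must be >= 1, got {n_species}")
    rng = np.random.default_rng(seed)
    bases_arr = np.array(BASES)
    arr = np.empty((n_species, INSERT_LENGTH), dtype="<U1")
    for pos in POSITIONS:
        j = pos + 5
        if pos in _RANDOM_SET:
            arr[:, j] = bases_arr[rng.integers(0, 4, size=n_species)]
        else:
            rate = spec.rate_at(pos)
            canon = spec.base_at(pos)
            choices = np.array([canon] + [b for b in BASES if b != canon])
            probs = np.array([1.0 - rate, rate / 3.0, rate / 3.0, rate / 3.0])
            arr[:, j] = choices[rng.choice(4, size=n_species, p=probs)]

    signatures: list[list[tuple[int, str]]] = [[] for _ in range(n_species)]
    for pos in DOPED_POSITIONS:
        col = arr[:, pos + 5]
        canon = spec.base_at(pos)
        for i in np.nonzero(col != canon)[0]:
            signatures[i].append((pos, str(col[i])))
    random_idx = [pos + 5 for pos in RANDOM_POSITIONS]
    flank_block = arr[:, random_idx]
    return [
        Species(
            "".join(arr[i]),
            tuple(signatures[i]),
            "".join(flank_block[i]),
        )
        for i in range(n_species)
    ]


def collapse_library(library: Iterable[Species]) -> tuple[list[Species], np.ndarray]:
    """Merge duplicate 35-mers, returning unique species and multiplicities."""
    seen: "OrderedDict[str, tuple[Species, int]]" = OrderedDict()
    for sp in library:
        if sp.sequence in seen:
            prev, n = seen[sp.sequence]
            seen[sp.sequence] = (prev, n + 1)
        else:
            seen[sp.sequence] = (sp, 1)
    unique = [sp for sp, _ in seen.values()]
    counts = np.array([n for _, n in seen.values()], dtype=int)
    return unique, counts


def enumerate_variants(spec: TargetSpec, order: int) -> list[Signature]:
    """All single (order 1) or double (order 2) doped-region signatures.

    Order 1 yields 22 positions x 3 alternatives = 66 signatures; order 2
    yields all unordered pairs at distinct positions, C(22, 2) * 9 pairs.
    """
    if order not in (1, 2):
        raise ValidationError(f"order must be 1 or 2, got {order}")
    singles = [
        ((pos, base),)
        for pos in DOPED_POSITIONS
        for base in BASES
        if base != spec.base_at(pos)
    ]
    if order == 1:
        return singles
    pairs: list[Signature] = []
    for (m1,), (m2,) in combinations(singles, 2):
        if m1[0] != m2[0]:
            pairs.append(tuple(sorted((m1, m2))))
    return pairs


def reporting_elements(spec: TargetSpec) -> list[tuple[int, str]]:
    """The 92-cell reporting grid: positions 1-23 x 4 bases.

    Cells where the base is canonical at a doped position represent WT;
    position-21 cells are context-conditioned (the PAM N is fully random).
    """
    return [(pos, base) for pos in range(1, 24) for base in BASES]


def element_is_wt(spec: TargetSpec, element: tuple[int, str]) -> bool:
    """True for grid cells whose base is the canonical base of a doped position."""
    pos, base = element
    return pos in _DOPED_SET and spec.base_at(pos) == base


def position_base_frequencies(library: Sequence[Species], spec: TargetSpec) -> pd.DataFrame:
    """Empirical base composition: positions -5..29 (rows) x bases (columns)."""
    n = len(library)
    if n == 0:
        raise ValidationError("library is empty")
    arr = np.array([list(sp.sequence) for sp in library])
    data = {
        base: (arr == base).mean(axis=0) for base in BASES
    }
    return pd.DataFrame(data, index=pd.Index(POSITIONS, name="position"))


# ---------------------------------------------------------------------------
# Library TSV I/O
# ---------------------------------------------------------------------------


def write_library(
    path: str | Path, library: Sequence[Species], counts: Sequence[int] | None = None
) -> None:
    """Write a library as headered TSV, sorted by (mismatch_count, sequence)."""
    rows = sorted(
        range(len(library)), key=lambda i: (library[i].mismatch_count, library[i].sequence)
    )
    records = []
    for rank, i in enumerate(rows):
        sp = library[i]
        rec = {
            "species_id": f"S{rank:06d}",
            "sequence": sp.sequence,
            "signature": signature_to_str(sp.signature),
            "mismatch_count": sp.mismatch_count,
        }
        if counts is not None:
            rec["count"] = int(counts[i])
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep="\t", index=False)


def read_library(path: str | Path, spec: TargetSpec) -> tuple[list[Species], np.ndarray | None]:
    """Read a library TSV back into species (re-classified against ``spec``)."""
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str, "signature": str}, keep_default_na=False)
    species = [classify_species(seq, spec) for seq in df["sequence"]]
    counts = df["count"].to_numpy(dtype=int) if "count" in df.columns else None
    return species, counts
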