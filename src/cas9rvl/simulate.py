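"""Ground-truth cleavage simulator: penalty model, biphasic kinetics, sampling.

Each species gets a cleavage weight ``w`` — the product of per-mismatch rate
multipliers over its variant signature (1 for a perfect match).  Survival of
uncut template follows a two-population mixture of exponentials,

    s(w, t) = f * exp(-k_fast * w * t) + (1 - f) * exp(-k_slow * w * t),

reproducing burst-then-slow kinetics: a fraction ``f`` of molecules is
cleaved at the fast rate, the remainder at the slow one, with the mismatch
weight scaling both rates.  Sequencing of the uncut pool is modelled as a
multinomial draw over species proportions (optionally weighted by a static
PCR bias factor); an expected-count mode emits noise-free expectations for
closed-form checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .counting import CountTable
from .errors import ConfigurationError, ValidationError
from .library import (
    BASES,
    DOPED_POSITIONS,
    RANDOM_POSITIONS,
    Species,
    TargetSpec,
    classify_species,
    collapse_library,
)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def is_transition(a: str, b: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine substitution."""
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


@dataclass
class PenaltyProfile:
    """Per-(position, alternative base) cleavage-rate multipliers.

    ``penalty`` maps (doped position, alternative base) -> multiplier in
    [0, max_enhancement]; the canonical base at any position implicitly has
    multiplier 1.  ``flank_modifier`` optionally maps (random position,
    base) -> a multiplier near 1 for modest flanking-sequence effects.
    """

    penalty: dict[tuple[int, str], float]
    flank_modifier: dict[tuple[int, str], float] = field(default_factory=dict)
    max_enhancement: float = 2.0

    def __post_init__(self) -> None:
        for key, value in self.penalty.items():
            if value < 0:
                raise ValidationError(f"penalty{key} must be >= 0, got {value}")
            if value > self.max_enhancement:
                raise ValidationError(
                    f"penalty{key} = {value} exceeds max_enhancement {self.max_enhancement}"
                )
        for key, value in self.flank_modifier.items():
            if value < 0:
                raise ValidationError(f"flank_modifier{key} must be >= 0, got {value}")

    def multiplier(self, position: int, base: str) -> float:
        try:
            return self.penalty[(position, base)]
        except KeyError:
            raise ConfigurationError(
                f"no penalty entry for position {position} -> {base}"
            ) from None


def default_penalty_profile(spec: TargetSpec) -> PenaltyProfile:
    """A plausible synthetic profile for demonstrations and tests.

    The values are fixture constants chosen to exhibit the qualitative
    landscape of Cas9 specificity — near-zero multipliers for PAM
    transversions, strong seed and PAM-distal (positions 3-5) penalties,
    transversions harsher than transitions, and a mild enhancement at
    positions 9-11.  They are NOT measurements; every entry is configurable.
    """
    table: dict[tuple[int, str], float] = {}
    for pos in DOPED_POSITIONS:
        canon = spec.base_at(pos)
        for alt in BASES:
            if alt == canon:
                continue
            transition = is_transition(canon, alt)
            if 9 <= pos <= 11:
                mult = 1.3  # modestly enhanced cleavage
            elif pos == 22:
                mult = 0.3 if transition else 0.01
            elif pos == 23:
                mult = 0.15 if transition else 0.01
            elif 3 <= pos <= 5 or 12 <= pos <= 18:
                mult = 0.5 if transition else 0.05
            elif 6 <= pos <= 8:
                mult = 0.7 if transition else 0.3
            else:  # positions 1, 2, 19, 20: mild effects
                mult = 0.9 if transition else 0.6
            table[(pos, alt)] = mult
    return PenaltyProfile(table)


@dataclass(frozen=True)
class KineticParams:
    """Biphasic cleavage kinetics.

    ``burst_fraction`` f is the fraction of template cleaved at the fast
    rate ``k_fast`` (per minute); the remainder is cleaved at ``k_slow``.
    """

    burst_fraction: float = 0.3
    k_fast: float = 0.5
    k_slow: float = 0.01
    timepoints: tuple[float, ...] = (15.0, 60.0, 180.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.burst_fraction <= 1.0:
            raise ValidationError(f"burst_fraction must be in [0, 1], got {self.burst_fraction}")
        if self.k_slow < 0 or self.k_fast < self.k_slow:
            raise ValidationError(
                f"need k_fast >= k_slow >= 0, got k_fast={self.k_fast}, k_slow={self.k_slow}"
            )
        if any(t < 0 for t in self.timepoints):
            raise ValidationError("timepoints must be non-negative")
        if list(self.timepoints) != sorted(self.timepoints):
            raise ValidationError("timepoints must be increasing")


def cleavage_weight(species: Species, profile: PenaltyProfile) -> float:
    """Product of penalty multipliers over the signature, times flank modifiers."""
    w = 1.0
    for pos, base in species.signature:
        w *= profile.multiplier(pos, base)
    if profile.flank_modifier:
        for pos, base in zip(RANDOM_POSITIONS, species.flank_context):
            w *= profile.flank_modifier.get((pos, base), 1.0)
    return w


def survival_fraction(w: float, t: float, params: KineticParams) -> float:
    """Fraction of template still uncut after ``t`` minutes at weight ``w``."""
    if w < 0:
        raise ValidationError(f"w must be >= 0, got {w}")
    if t < 0:
        raise ValidationError(f"t must be >= 0, got {t}")
    f = params.burst_fraction
    return f * math.exp(-params.k_fast * w * t) + (1.0 - f) * math.exp(-params.k_slow * w * t)


def sample_label(t: float) -> str:
    """Column label for the cleaved sample at ``t`` minutes."""
    return f"cut_t{t:g}"


@dataclass
class SimulationResult:
    """Counts plus the generating ground truth.

    ``ground_truth`` is indexed by sequence with columns ``weight``,
    ``input_proportion``, ``spike_in`` and one ``survival_t<min>`` column
    per timepoint.
    """

    counts: CountTable
    ground_truth: pd.DataFrame
    kinetics: KineticParams
    spike_sequences: tuple[str, ...] = ()


def simulate_experiment(
    spec: TargetSpec,
    library: Sequence[Species],
    profile: PenaltyProfile,
    kinetics: KineticParams,
    depth: int,
    *,
    proportions: Sequence[float] | None = None,
    spike_in: Sequence[Species] = (),
    spike_fraction: float = 0.0,
    pcr_bias: Mapping[str, float] | None = None,
    sampling: str = "multinomial",
    seed: int | None = None,
) -> SimulationResult:
    """Emit one uncut sample and one cut sample per timepoint.

    ``library`` may contain duplicate sequences (multiplicities become input
    proportions unless ``proportions`` is given per unique species).
    ``spike_in`` species are an internal uncleaved control: their cleavage
    weight is 0 by construction and they take up ``spike_fraction`` of the
    input pool, uniformly.  ``pcr_bias`` maps sequence -> a static factor
    applied identically to every sample (so it cancels in retention).
    With ``sampling="expected"`` cells are noise-free expectations
    ``depth * probability`` instead of multinomial draws.
    """
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    if sampling not in ("multinomial", "expected"):
        raise ValidationError(f"unknown sampling mode {sampling!r}")
    if not 0.0 <= spike_fraction < 1.0:
        raise ValidationError(f"spike_fraction must be in [0, 1), got {spike_fraction}")
    if spike_in and spike_fraction == 0.0:
        raise ValidationError("spike_in given but spike_fraction is 0")

    unique, multiplicity = collapse_library(library)
    if proportions is None:
        props = multiplicity / multiplicity.sum()
    else:
        props = np.asarray(proportions, dtype=float)
        if len(props) != len(unique):
            raise ValidationError(
                f"proportions length {len(props)} != {len(unique)} unique species"
            )
        if (props < 0).any() or not math.isclose(props.sum(), 1.0, rel_tol=1e-9):
            raise ValidationError("proportions must be non-negative and sum to 1")

    spike_unique, spike_mult = collapse_library(spike_in) if spike_in else ([], np.array([]))
    overlap = {sp.sequence for sp in unique} & {sp.sequence for sp in spike_unique}
    if overlap:
        raise ValidationError(f"spike-in sequences collide with the main library: {sorted(overlap)[:3]}")

    sequences = [sp.sequence for sp in unique] + [sp.sequence for sp in spike_unique]
    weights = np.array(
        [cleavage_weight(sp, profile) for sp in unique] + [0.0] * len(spike_unique)
    )
    base_props = np.concatenate(
        [
            props * (1.0 - spike_fraction),
            (spike_mult / spike_mult.sum()) * spike_fraction if len(spike_unique) else np.array([]),
        ]
    )
    if pcr_bias:
        bias = np.array([pcr_bias.get(seq, 1.0) for seq in sequences])
        if (bias < 0).any():
            raise ValidationError("pcr_bias factors must be >= 0")
        base_props = base_props * bias
    total = base_props.sum()
    if not total > 0:
        raise ValidationError("input proportions are not normalizable (sum <= 0)")

    rng = np.random.default_rng(seed)
    columns: dict[str, np.ndarray] = {}
    survival = {}
    for label, t in [("uncut", None)] + [(sample_label(t), t) for t in kinetics.timepoints]:
        p = base_props.copy()
        if t is not None:
            s = np.array([survival_fraction(w, t, kinetics) for w in weights])
            survival[t] = s
            p = p * s
        p = p / p.sum()
        if sampling == "multinomial":
            columns[label] = rng.multinomial(depth, p)
        else:
            columns[label] = depth * p

    counts_df = pd.DataFrame(columns, index=pd.Index(sequences, name="sequence"))
    from .counting import _info_frame

    table = CountTable(counts_df, _info_frame(sequences, spec))
    gt = pd.DataFrame(
        {
            "weight": weights,
            "input_proportion": base_props / total,
            "spike_in": [False] * len(unique) + [True] * len(spike_unique),
        },
        index=counts_df.index,
    )
    for t in kinetics.timepoints:
        gt[f"survival_t{t:g}"] = survival[t]
    return SimulationResult(table, gt, kinetics, tuple(sp.sequence for sp in spike_unique))


def write_fastq(
    table: CountTable,
    sample: str,
    path: str | Path,
    *,
    prefix: str = "",
    suffix: str = "",
    error_rate: float = 0.0,
    seed: int | None = None,
) -> int:
    """Expand one integer-count sample column into a FASTQ file (Q40 reads).

    Optional constant adapters are prepended/appended; an optional per-base
    substitution ``error_rate`` corrupts reads (classification then drops or
    misassigns them, as for real sequencing error).  Reads are emitted in a
    deterministic shuffled order under ``seed``.  Returns the read count.
    """
    if sample not in table.samples:
        raise ValidationError(f"sample {sample!r} not in table")
    col = table.counts[sample]
    if not table.is_integral():
        raise ValidationError("FASTQ output requires integer counts")
    rng = np.random.default_rng(seed)
    reads: list[str] = []
    for seq, n in col.items():
        reads.extend([seq] * int(n))
    order = rng.permutation(len(reads))
    records = []
    for i, idx in enumerate(order):
        seq = reads[idx]
        if error_rate > 0:
            chars = list(seq)
            hits = np.nonzero(rng.random(len(chars)) < error_rate)[0]
            for j in hits:
                chars[j] = BASES[rng.integers(0, 4)]
            seq = "".join(chars)
        full = prefix + seq + suffix
        rec = SeqRecord(Seq(full), id=f"read{i:08d}", description="")
        rec.letter_annotations["phred_quality"] = [40] * len(full)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
    return len(records)
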