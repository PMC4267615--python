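"""Time-course summaries: median retention vs time per variant category.

A category is either "WT" (species matching guide and PAM perfectly), a
single doped-region signature such as ``((16, "T"),)``, or a flank element
``(position, base)`` at a fully random position.  Per timepoint the summary
reports the median retention over the category's species, the standard
deviation across those species' retentions (the error bar), and n.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .library import RANDOM_POSITIONS, Signature, TargetSpec, signature_from_str
from .retention import RetentionTable

_SAMPLE_RE = re.compile(r"^cut_t([0-9.]+)$")


def sample_timepoint(label: str) -> float:
    """Minutes encoded in a ``cut_t<minutes>`` sample label."""
    m = _SAMPLE_RE.match(label)
    if not m:
        raise ValidationError(f"sample label {label!r} does not encode a timepoint")
    return float(m.group(1))


@dataclass
class TimeCourse:
    """Median retention vs time for one variant category."""

    label: str
    table: pd.DataFrame  # columns: timepoint, n, median, sd
    n_species: int

    @property
    def timepoints(self) -> list[float]:
        return list(self.table["timepoint"])


def _category_members(
    rt: RetentionTable, variant, spec: TargetSpec
) -> tuple[str, list[str]]:
    """Resolve a variant spec to (label, member sequences)."""
    if isinstance(variant, str) and variant.upper() == "WT":
        sig: Signature | None = ()
        label = "WT"
    elif isinstance(variant, str):
        sig = signature_from_str(variant)
        label = variant
    elif isinstance(variant, tuple) and variant and isinstance(variant[0], tuple):
        sig = tuple(sorted(variant))
        label = ";".join(f"{p}:{b}" for p, b in sig)
    elif isinstance(variant, tuple) and len(variant) == 2 and isinstance(variant[0], int):
        pos, base = variant
        if pos in RANDOM_POSITIONS:
            members = [
                seq
                for seq, sig_str in rt.info["signature"].items()
                if sig_str == "" and seq[pos + 5] == base
            ]
            return f"{pos}:{base}", members
        sig = ((pos, base),)
        label = f"{pos}:{base}"
    else:
        raise ValidationError(f"cannot interpret variant {variant!r}")
    members = [
        seq
        for seq, sig_str in rt.info["signature"].items()
        if signature_from_str(sig_str) == sig
    ]
    if not members:
        available = sorted(
            {
                s
                for s in rt.info["signature"]
                if s and sig and any(s.startswith(f"{p}:") for p, _ in sig)
            }
        )[:10]
        raise KeyError(
            f"no species for variant {label!r}; nearest available signatures: {available}"
        )
    return label, members


def timecourse(
    rt: RetentionTable,
    variant,
    spec: TargetSpec,
    samples: Sequence[str] | None = None,
) -> TimeCourse:
    """Median/SD retention over time for one variant category.

    The species set follows the same rule as the single-variant grid and is
    fixed across timepoints; n counts the finite retentions per timepoint.
    """
    label, members = _category_members(rt, variant, spec)
    if samples is None:
        samples = rt.cleaved_samples
    rows = []
    for s in sorted(samples, key=sample_timepoint):
        t = sample_timepoint(s)
        vals = rt.scores.loc[members, s].to_numpy(dtype=float)
        finite = vals[~np.isnan(vals)]
        rows.append(
            {
                "timepoint": t,
                "n": int(finite.size),
                "median": float(np.median(finite)) if finite.size else math.nan,
                "sd": float(np.std(finite, ddof=1)) if finite.size >= 2 else math.nan,
            }
        )
    return TimeCourse(label, pd.DataFrame(rows), len(members))


def compare_categories(tc_a: TimeCourse, tc_b: TimeCourse) -> pd.DataFrame:
    """Per-timepoint median difference (a - b) with an ordering verdict.

    The returned frame carries attrs ``verdict`` ("a_below_b", "a_above_b",
    "equal" or "mixed") and ``crossings`` (timepoints where the sign of the
    difference changes between consecutive timepoints).
    """
    if tc_a.timepoints != tc_b.timepoints:
        raise ValidationError(
            f"timepoints differ: {tc_a.timepoints} vs {tc_b.timepoints}"
        )
    diff = tc_a.table["median"].to_numpy() - tc_b.table["median"].to_numpy()
    out = pd.DataFrame(
        {
            "timepoint": tc_a.table["timepoint"],
            "median_a": tc_a.table["median"],
            "median_b": tc_b.table["median"],
            "difference": diff,
        }
    )
    finite = diff[~np.isnan(diff)]
    if finite.size == 0 or np.allclose(finite, 0.0):
        verdict = "equal"
    elif (finite < 0).all():
        verdict = "a_below_b"
    elif (finite > 0).all():
        verdict = "a_above_b"
    else:
        verdict = "mixed"
    signs = np.sign(diff)
    crossings = [
        float(out["timepoint"].iloc[i + 1])
        for i in range(len(signs) - 1)
        if signs[i] != 0 and signs[i + 1] != 0 and signs[i] != signs[i + 1]
    ]
    out.attrs["verdict"] = verdict
    out.attrs["crossings"] = crossings
    return out


def timecourses_tsv(courses: Sequence[TimeCourse], path) -> None:
    """Tidy TSV: variant, timepoint_minutes, n, median_retention, sd."""
    frames = []
    for tc in courses:
        df = tc.table.rename(
            columns={
                "timepoint": "timepoint_minutes",
                "median": "median_retention",
            }
        )
        df.insert(0, "variant", tc.label)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.10g"
    )
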