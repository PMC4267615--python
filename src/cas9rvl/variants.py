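"""Aggregation of retention by variant identity.

Two aggregation rules mirror the assay's geometry:

* target-region cells (doped positions 1-20, 22-23; non-canonical base):
  median retention over species whose doped-region signature is exactly the
  one variant of interest, flanking sequence free;
* flank-conditioned cells (positions -5..0, 21, 24..29; any base): median
  over species with a perfectly matched target+PAM region and the indicated
  base at the flank position.

The WT summary is the median over all species matching guide and PAM
perfectly.  The double-variant view is a symmetric 92 x 92 grid (positions
1-23 x 4 bases) of median log retentions whose diagonal carries the single
variants, plus a synergy grid

    synergy = (LR_M12 / LR_WT) / [(LR_M1 / LR_WT) * (LR_M2 / LR_WT)],

equal to 1 when the two variants scale the cleavage rate multiplicatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountTable
from .errors import AnalysisError, NormalizationError, ValidationError
from .library import (
    BASES,
    RANDOM_POSITIONS,
    Signature,
    TargetSpec,
    element_is_wt,
    reporting_elements,
    signature_from_str,
)
from .retention import ReferencePopulation, RetentionTable

Element = tuple[int, str]


def element_label(element: Element) -> str:
    return f"{element[0]}:{element[1]}"


def _nan_median(values: list[float]) -> tuple[float, int, float]:
    """(median, n finite, sd) over finite values; (nan, 0, nan) if none."""
    finite = [v for v in values if not math.isnan(v)]
    if not finite:
        return math.nan, 0, math.nan
    arr = np.asarray(finite, dtype=float)
    sd = float(np.std(arr, ddof=1)) if len(arr) >= 2 else math.nan
    return float(np.median(arr)), len(arr), sd


def _grouped_scores(
    rt: RetentionTable, sample: str
) -> tuple[list[float], dict[Element, list[float]], dict[Element, list[float]], dict]:
    """One pass over species: WT, exact-single, flank-conditioned groups.

    Returns (wt_scores, singles, flank, pair_data) where ``pair_data`` holds
    the double-variant groups: exact two-mismatch signatures plus
    (PAM-N base, single mismatch) combinations.
    """
    scores = rt.scores[sample]
    wt: list[float] = []
    singles: dict[Element, list[float]] = {}
    flank: dict[Element, list[float]] = {}
    pairs: dict[tuple[Element, Element], list[float]] = {}
    for seq, sig_str in rt.info["signature"].items():
        r = float(scores[seq])
        sig = signature_from_str(sig_str)
        if len(sig) == 0:
            wt.append(r)
            for pos in RANDOM_POSITIONS:
                flank.setdefault((pos, seq[pos + 5]), []).append(r)
        elif len(sig) == 1:
            singles.setdefault(sig[0], []).append(r)
            # doubles involving the fully random PAM-N position 21
            pam_el = (21, seq[26])
            key = tuple(sorted((pam_el, sig[0])))
            pairs.setdefault(key, []).append(r)  # type: ignore[arg-type]
        elif len(sig) == 2:
            pairs.setdefault((sig[0], sig[1]), []).append(r)
    return wt, singles, flank, pairs


@dataclass
class SingleVariantSummary:
    """Median retention per (position, base) cell over the full -5..29 grid.

    ``grid`` has a (position, base) MultiIndex and columns median / n / sd /
    rule / is_wt.  Cells with no qualifying species have n = 0 and NaN
    median (reported, not an error).
    """

    grid: pd.DataFrame
    wt_median: float
    wt_n: int
    wt_sd: float
    sample: str

    def cell(self, position: int, base: str) -> pd.Series:
        return self.grid.loc[(position, base)]

    def write_tsv(self, path) -> None:
        out = self.grid.reset_index()
        out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def single_variant_medians(
    rt: RetentionTable, spec: TargetSpec, sample: str | None = None
) -> SingleVariantSummary:
    """Aggregate a retention table into the single-variant grid."""
    if sample is None:
        sample = rt.cleaved_samples[-1]
    if sample not in rt.cleaved_samples:
        raise ValidationError(f"sample {sample!r} not in retention table")
    wt_scores, singles, flank, _ = _grouped_scores(rt, sample)
    wt_median, wt_n, wt_sd = _nan_median(wt_scores)

    records = []
    for pos in sorted(set(spec.random_positions) | set(spec.doped_positions)):
        for base in BASES:
            if pos in spec.doped_positions:
                if base == spec.base_at(pos):
                    median, n, sd = wt_median, wt_n, wt_sd
                    rule, is_wt = "wt", True
                else:
                    median, n, sd = _nan_median(singles.get((pos, base), []))
                    rule, is_wt = "target-region", False
            else:
                median, n, sd = _nan_median(flank.get((pos, base), []))
                rule, is_wt = "flank-conditioned", False
            records.append(
                {"position": pos, "base": base, "median": median, "n": n,
                 "sd": sd, "rule": rule, "is_wt": is_wt}
            )
    grid = pd.DataFrame.from_records(records).set_index(["position", "base"])
    return SingleVariantSummary(grid, wt_median, wt_n, wt_sd, sample)


def heatmap_normalize(
    summary: SingleVariantSummary, wt_median: float | None = None
) -> pd.Series:
    """(median variant retention) / (median WT retention) per grid cell.

    ~1 means WT-like depletion, ~0 uncleaved, > 1 more efficient depletion
    than WT.  Requires a detectably cleaved WT (non-zero median).
    """
    if wt_median is None:
        wt_median = summary.wt_median
    if wt_median == 0 or math.isnan(wt_median):
        raise AnalysisError("WT median retention is zero/undefined; experiment uninterpretable")
    return summary.grid["median"] / wt_median


@dataclass
class DoubleVariantMatrix:
    """Symmetric 92 x 92 grid of median log retentions.

    Rows/columns are labelled ``pos:base`` over positions 1-23 x ACGT.  The
    diagonal carries the single-variant medians (WT median for canonical
    cells, flagged in ``wt_mask``); off-diagonal cells are exact-pair
    medians, NaN where fewer than ``n_min`` species qualify (``n`` grid).
    """

    lr: pd.DataFrame
    n: pd.DataFrame
    wt_mask: pd.DataFrame
    lr_wt: float
    sample: str
    elements: list[Element] = field(default_factory=list)

    def cell(self, e1: Element, e2: Element) -> float:
        return float(self.lr.at[element_label(e1), element_label(e2)])


def double_variant_matrix(
    rt: RetentionTable, spec: TargetSpec, sample: str | None = None, n_min: int = 1
) -> DoubleVariantMatrix:
    """Build the 92 x 92 double-variant median log-retention grid."""
    if sample is None:
        sample = rt.cleaved_samples[-1]
    if n_min < 1:
        raise ValidationError(f"n_min must be >= 1, got {n_min}")
    wt_scores, singles, flank, pairs = _grouped_scores(rt, sample)
    wt_median, _, _ = _nan_median(wt_scores)

    elements = reporting_elements(spec)
    labels = [element_label(e) for e in elements]
    lr = pd.DataFrame(np.nan, index=labels, columns=labels)
    n = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    wt_mask = pd.DataFrame(False, index=labels, columns=labels, dtype=bool)

    def single_cell(el: Element) -> tuple[float, int]:
        pos, base = el
        if el[0] == 21:
            med, cnt, _ = _nan_median(flank.get(el, []))
            return med, cnt
        if element_is_wt(spec, el):
            return wt_median, len([v for v in wt_scores if not math.isnan(v)])
        med, cnt, _ = _nan_median(singles.get(el, []))
        return med, cnt

    for i, e1 in enumerate(elements):
        li = labels[i]
        med, cnt = single_cell(e1)
        if element_is_wt(spec, e1):
            wt_mask.at[li, li] = True
        if cnt >= n_min:
            lr.at[li, li] = med
            n.at[li, li] = cnt
        for j in range(i + 1, len(elements)):
            e2 = elements[j]
            lj = labels[j]
            if e1[0] == e2[0]:
                continue  # same position: not a double variant
            if element_is_wt(spec, e1) or element_is_wt(spec, e2):
                wt_mask.at[li, lj] = wt_mask.at[lj, li] = True
                continue
            key = tuple(sorted((e1, e2)))
            med, cnt, _ = _nan_median(pairs.get(key, []))
            if cnt >= n_min and not math.isnan(med):
                lr.at[li, lj] = lr.at[lj, li] = med
                n.at[li, lj] = n.at[lj, li] = cnt
    return DoubleVariantMatrix(lr, n, wt_mask, wt_median, sample, elements)


def synergy(lr_m12: float, lr_m1: float, lr_m2: float, lr_wt: float) -> float:
    """(LR_M12/LR_WT) / [(LR_M1/LR_WT) * (LR_M2/LR_WT)].

    1 when the double variant's kinetic influence is the product of the two
    singles'; < 1 negative synergy; > 1 residual activity above expectation.
    Requires a cleaved WT (LR_WT < 0); NaN inputs propagate to NaN.
    """
    if math.isnan(lr_wt) or lr_wt >= 0:
        raise AnalysisError(f"WT must be detectably cleaved (LR_WT < 0), got {lr_wt}")
    if any(math.isnan(v) for v in (lr_m12, lr_m1, lr_m2)):
        return math.nan
    if lr_m1 == 0 or lr_m2 == 0:
        return math.nan
    return (lr_m12 / lr_wt) / ((lr_m1 / lr_wt) * (lr_m2 / lr_wt))


def synergy_matrix(
    dvm: DoubleVariantMatrix,
    detectable: Mapping[Element, bool] | None = None,
) -> pd.DataFrame:
    """Synergy per off-diagonal cell of the double-variant grid.

    Cells are NaN (excluded) when the pair median is masked, when either
    single lacks data, or — if a ``detectable`` map is supplied — when
    either single shows no detectable cleavage.
    """
    labels = list(dvm.lr.index)
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    if math.isnan(dvm.lr_wt) or dvm.lr_wt >= 0:
        return out  # WT not detectably cleaved: no synergy is computable
    for i, e1 in enumerate(dvm.elements):
        for j in range(i + 1, len(dvm.elements)):
            e2 = dvm.elements[j]
            li, lj = labels[i], labels[j]
            if dvm.wt_mask.at[li, lj]:
                continue
            lr12 = dvm.lr.at[li, lj]
            lr1 = dvm.lr.at[li, li]
            lr2 = dvm.lr.at[lj, lj]
            if any(math.isnan(v) for v in (lr12, lr1, lr2)):
                continue
            if detectable is not None and not (
                detectable.get(e1, False) and detectable.get(e2, False)
            ):
                continue
            out.at[li, lj] = out.at[lj, li] = synergy(lr12, lr1, lr2, dvm.lr_wt)
    return out


def detectable_cleavage_test(
    species_cleaved: int,
    species_uncleaved: int,
    reference_cleaved: int,
    reference_uncleaved: int,
    alpha: float = 0.05,
) -> bool:
    """Exact conditional test for a detectable drop in representation.

    Two-sided Fisher exact test on the 2x2 table (species vs reference
    aggregate, cleaved vs uncleaved); detectable iff p < alpha AND the
    species' retention is negative (depleted, not enriched).
    """
    if reference_cleaved <= 0 or reference_uncleaved <= 0:
        raise NormalizationError("reference population has zero reads in a sample")
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    table = [[species_cleaved, species_uncleaved], [reference_cleaved, reference_uncleaved]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    rep_c = species_cleaved / reference_cleaved
    rep_u = species_uncleaved / reference_uncleaved
    depleted = rep_c < rep_u
    return bool(p < alpha and depleted)


def element_detectability(
    filtered: CountTable,
    reference: ReferencePopulation,
    spec: TargetSpec,
    uncleaved_sample: str,
    cleaved_sample: str,
    alpha: float = 0.05,
) -> dict[Element, bool]:
    """Detectable-cleavage verdict per reporting-grid single element.

    Aggregates raw counts over the species set each element's single-variant
    rule selects, then applies :func:`detectable_cleavage_test`.  Requires
    integer counts (multinomial mode); canonical (WT-flagged) cells are
    skipped.
    """
    if not filtered.is_integral():
        raise ValidationError("detectability test requires integer counts")
    ref = reference.aggregate_counts(filtered)
    ref_c = int(ref[cleaved_sample])
    ref_u = int(ref[uncleaved_sample])
    groups: dict[Element, list[str]] = {}
    for seq, sig_str in filtered.info["signature"].items():
        sig = signature_from_str(sig_str)
        if len(sig) == 1:
            groups.setdefault(sig[0], []).append(seq)
        elif len(sig) == 0:
            groups.setdefault((21, seq[26]), []).append(seq)
    out: dict[Element, bool] = {}
    for el in reporting_elements(spec):
        if element_is_wt(spec, el):
            continue
        members = groups.get(el, [])
        if not members:
            continue
        sc = int(filtered.counts.loc[members, cleaved_sample].sum())
        su = int(filtered.counts.loc[members, uncleaved_sample].sum())
        out[el] = detectable_cleavage_test(sc, su, ref_c, ref_u, alpha)
    return out
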