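"""Concordance and depth-titration evaluation of AOH calls.

Region-level concordance uses reciprocal overlap: two intervals agree when
min(|a ∩ b|/|a|, |a ∩ b|/|b|) exceeds a cutoff (0.5 by default). Because a
single true region can legitimately be reported as several sub-calls (a
mosaic chromosome fragments into subregions), a truth region is matched
against the *union* of all calls overlapping it: matched iff
min(|U ∩ T|/|T|, |U ∩ T|/|U|) > cutoff where U is the union of the
overlapping calls.

Sample-level accuracy treats a sample as call-positive when it carries at
least one reported segment at or above the reporting floor. The depth-
titration grid thins each sample's reads to a ladder of UAHR budgets
(binomial thinning), re-calls, and tabulates per-size-class region
sensitivity — the machinery behind an optimal-depth recommendation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .likelihood import ModelParams
from .smoothing import AOHSegment, classify_segment
from .simulate import TruthSegment, downsample

__all__ = [
    "EvalReport",
    "reciprocal_overlap",
    "match_regions",
    "sample_confusion",
    "depth_curve",
    "DEFAULT_UAHR_GRID",
]

#: 14-point UAHR ladder (millions of reads) spanning the clinically relevant
#: range up to a typical full-depth run
DEFAULT_UAHR_GRID: tuple[float, ...] = (
    1.25e6,
    2.5e6,
    5e6,
    7.5e6,
    10e6,
    12.5e6,
    15e6,
    20e6,
    25e6,
    30e6,
    40e6,
    50e6,
    60e6,
    70e6,
)

#: a depth is "at plateau" when overall sensitivity is within 0.1 percentage
#: points of the grid maximum
PLATEAU_TOLERANCE = 0.001


@dataclass
class EvalReport:
    """Aggregate accuracy metrics for one evaluation run."""

    n_pos: int = 0
    n_neg: int = 0
    sensitivity: float = float("nan")
    specificity: float = float("nan")
    region_overlap_rate: float = float("nan")
    per_class_sensitivity: dict[str, float] = field(default_factory=dict)
    depth_curves: pd.DataFrame | None = None
    plateau_uahr: float | None = None


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    """min(|a∩b|/|a|, |a∩b|/|b|) for two half-open intervals on one chromosome."""
    a0, a1 = a
    b0, b1 = b
    if a1 <= a0 or b1 <= b0:
        raise ParameterError("intervals must have positive length")
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return min(inter / (a1 - a0), inter / (b1 - b0))


def _as_intervals(regions) -> list[tuple[str, int, int]]:
    out = []
    for reg in regions:
        if isinstance(reg, (AOHSegment, TruthSegment)):
            out.append((reg.chrom, reg.start, reg.end))
        else:
            chrom, start, end = reg[0], int(reg[1]), int(reg[2])
            out.append((chrom, start, end))
    return out


def _union_ro(subset: Sequence[tuple[int, int]], t0: int, t1: int) -> float:
    """Reciprocal overlap of a call subset's union against truth [t0, t1)."""
    merged: list[list[int]] = []
    for c0, c1 in sorted(subset):
        if merged and c0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], c1)
        else:
            merged.append([c0, c1])
    union_len = sum(c1 - c0 for c0, c1 in merged)
    inter = sum(max(0, min(c1, t1) - max(c0, t0)) for c0, c1 in merged)
    return min(inter / (t1 - t0), inter / union_len)


def match_regions(
    calls: Sequence,
    truth: Sequence,
    cutoff: float = 0.5,
) -> np.ndarray:
    """Per-truth-region matched flags under union reciprocal overlap.

    A truth region fragmented into several sub-calls is matched when some
    subset of the calls overlapping it reaches a union reciprocal overlap
    above ``cutoff`` (strict): min(|U∩T|/|T|, |U∩T|/|U|) where U is the
    subset's union. Taking the best subset (rather than always all
    overlapping calls) keeps matching monotone — an additional call, however
    poorly placed, can never unmatch a truth region. Subsets are enumerated
    exactly for up to 12 overlapping calls; beyond that a greedy
    most-contained-first scan of prefixes is used. Accepts
    AOHSegment/TruthSegment objects or (chrom, start, end) triples.
    """
    call_iv = _as_intervals(calls)
    truth_iv = _as_intervals(truth)
    matched = np.zeros(len(truth_iv), dtype=bool)
    for i, (chrom, t0, t1) in enumerate(truth_iv):
        overlapping = [
            (c0, c1)
            for (c, c0, c1) in call_iv
            if c == chrom and min(c1, t1) > max(c0, t0)
        ]
        if not overlapping:
            continue
        best = _union_ro(overlapping, t0, t1)
        if best <= cutoff and len(overlapping) <= 12:
            for mask in range(1, 2 ** len(overlapping) - 1):
                subset = [c for j, c in enumerate(overlapping) if mask >> j & 1]
                best = max(best, _union_ro(subset, t0, t1))
                if best > cutoff:
                    break
        elif best <= cutoff:
            # greedy fallback: prefixes ordered by contained fraction
            ranked = sorted(
                overlapping,
                key=lambda c: (min(c[1], t1) - max(c[0], t0)) / (c[1] - c[0]),
                reverse=True,
            )
            for k in range(1, len(ranked) + 1):
                best = max(best, _union_ro(ranked[:k], t0, t1))
        matched[i] = best > cutoff
    return matched


def sample_confusion(
    call_sets: Sequence[Sequence[AOHSegment]],
    truth_labels: Sequence[bool],
    min_segment_mb: float = 5.0,
) -> EvalReport:
    """Sample-level sensitivity/specificity.

    A sample is call-positive iff it has at least one reported segment of
    at least ``min_segment_mb``.
    """
    if len(call_sets) != len(truth_labels) or not call_sets:
        raise InputError("call_sets and truth_labels must be equal-length, non-empty")
    floor = min_segment_mb * 1e6
    pred = np.array(
        [any((s.end - s.start) >= floor for s in calls) for calls in call_sets]
    )
    labels = np.asarray(truth_labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    report = EvalReport(n_pos=n_pos, n_neg=n_neg)
    if n_pos:
        report.sensitivity = float((pred & labels).sum() / n_pos)
    if n_neg:
        report.specificity = float((~pred & ~labels).sum() / n_neg)
    return report


def _truth_class(seg: TruthSegment, chrom_lengths: Mapping[str, int]) -> str:
    return classify_segment(seg.end - seg.start, int(chrom_lengths[seg.chrom]))


def depth_curve(
    samples: Sequence[Mapping],
    uahr_grid: Sequence[float],
    params: ModelParams,
    chrom_lengths: Mapping[str, int],
    min_segment_mb: float = 1.0,
    cutoff: float = 0.5,
) -> tuple[pd.DataFrame, float | None]:
    """Per-size-class region sensitivity across a ladder of UAHR budgets.

    Each entry of ``samples`` is a mapping with keys ``observations``
    (pre-joined DataFrame chrom, pos, af, r, a), ``truth`` (TruthSegment
    list), ``uahr_source`` (the budget the observations were generated at)
    and ``seed``. For each grid value the reads are binomially thinned to
    the target budget, re-called, and matched against truth.

    Returns the long-form curve table (size_class, uahr, n_regions,
    sensitivity) plus the plateau: the smallest grid budget whose overall
    sensitivity is within 0.1 percentage points of the grid maximum.
    """
    from .pipeline import call_observations  # local import; pipeline uses us too

    grid = sorted(float(u) for u in uahr_grid)
    rows = []
    overall: dict[float, list[int]] = {u: [0, 0] for u in grid}
    per_class: dict[tuple[str, float], list[int]] = {}
    for sample in samples:
        obs = sample["observations"]
        truth = list(sample["truth"])
        source = float(sample["uahr_source"])
        seed = int(sample.get("seed", 0))
        classes = [_truth_class(t, chrom_lengths) for t in truth]
        for u in grid:
            if u > source:
                raise ParameterError(
                    f"grid budget {u:g} exceeds source depth {source:g}"
                )
            keep = u / source
            counts = obs[["chrom", "pos"]].copy()
            counts["ref_count"] = obs["r"].to_numpy()
            counts["alt_count"] = obs["a"].to_numpy()
            if keep < 1.0:
                counts = downsample(counts, keep, seed=seed + int(u) % (2**31))
            thinned = obs[["chrom", "pos", "af"]].copy()
            thinned["r"] = counts["ref_count"].to_numpy()
            thinned["a"] = counts["alt_count"].to_numpy()
            result = call_observations(
                thinned, chrom_lengths, params, min_segment_mb=min_segment_mb
            )
            matched = match_regions(result.segments, truth, cutoff=cutoff)
            for cls, m in zip(classes, matched):
                key = (cls, u)
                per_class.setdefault(key, [0, 0])
                per_class[key][0] += int(m)
                per_class[key][1] += 1
                overall[u][0] += int(m)
                overall[u][1] += 1
    for (cls, u), (hits, total) in sorted(per_class.items()):
        rows.append(
            {
                "size_class": cls,
                "uahr": u,
                "n_regions": total,
                "sensitivity": hits / total,
            }
        )
    curve = pd.DataFrame(rows, columns=["size_class", "uahr", "n_regions", "sensitivity"])
    plateau = None
    totals = {u: h / t for u, (h, t) in overall.items() if t}
    if totals:
        best = max(totals.values())
        for u in grid:
            if u in totals and totals[u] >= best - PLATEAU_TOLERANCE:
                plateau = u
                break
    return curve, plateau
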