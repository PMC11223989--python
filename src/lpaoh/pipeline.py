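"""End-to-end calling: panel + counts -> bins, posteriors, segments, flags."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .copyratio import copy_ratio, flag_possible_cnv
from .errors import InputError
from .likelihood import ModelParams, bin_llrs
from .smoothing import AOHSegment, extract_segments, segments_to_frame, smooth_posteriors

__all__ = ["CallResult", "join_counts", "call_observations", "call_sample"]

logger = logging.getLogger(__name__)


@dataclass
class CallResult:
    """Bins (with llr, posterior, copy_ratio) plus called segments."""

    bins: pd.DataFrame
    segments: list[AOHSegment]
    summary: dict = field(default_factory=dict)


def join_counts(panel: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Attach panel frequencies to per-site counts.

    Count rows at positions absent from the panel are dropped (with a
    logged count); an empty intersection is an error.
    """
    merged = counts.merge(
        panel[["chrom", "pos", "af"]], on=["chrom", "pos"], how="inner"
    )
    dropped = len(counts) - len(merged)
    if dropped:
        logger.warning("%d count rows at positions absent from the panel dropped", dropped)
    if merged.empty:
        raise InputError("no overlap between the panel and the counts")
    obs = merged.rename(columns={"ref_count": "r", "alt_count": "a"})
    return obs[["chrom", "pos", "af", "r", "a"]]


def call_observations(
    observations: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    params: ModelParams,
    min_segment_mb: float | None = None,
) -> CallResult:
    """Call AOH segments from pre-joined observations (chrom, pos, af, r, a)."""
    bins = bin_llrs(observations, chrom_lengths, params)
    bins = smooth_posteriors(bins, params)
    bins = copy_ratio(bins)
    segments = extract_segments(
        bins, params, chrom_lengths=chrom_lengths, min_segment_mb=min_segment_mb
    )
    flag_possible_cnv(segments, bins)
    class_counts = {cls: 0 for cls in ("lt5", "5to10", "gt10", "chromosomal")}
    for seg in segments:
        class_counts[seg.size_class] += 1
    summary = {
        "n_sites": int((observations["r"] + observations["a"] > 0).sum()),
        "n_reads": int((observations["r"] + observations["a"]).sum()),
        "n_segments": len(segments),
        "segment_class_counts": class_counts,
        "n_flagged": sum(1 for s in segments if s.flag),
    }
    return CallResult(bins=bins, segments=segments, summary=summary)


def call_sample(
    panel: pd.DataFrame,
    counts: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    params: ModelParams | None = None,
    min_segment_mb: float | None = None,
) -> CallResult:
    """Full pipeline from a panel and a counts table."""
    params = params or ModelParams()
    obs = join_counts(panel, counts)
    result = call_observations(obs, chrom_lengths, params, min_segment_mb=min_segment_mb)
    result.summary["segments"] = segments_to_frame(result.segments).to_dict("records")
    return result
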