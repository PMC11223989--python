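"""Posterior smoothing of the per-bin LLR track and AOH segment calling.

A two-state hidden Markov model turns the noisy per-bin haploid-vs-diploid
log-likelihood ratios into per-bin AOH prediction likelihoods. The hidden
state of a bin is either *biparental* (normal diploid inheritance) or *AOH*.
The per-bin log emission ratio is exactly the bin's summed LLR; the chain
starts from the prior (1 - pi, pi) on each chromosome, and the expected
segment length ``persistence_mb`` sets a symmetric switching probability
t = 1 - exp(-bin_width / (persistence_mb * 1e6)) per bin boundary:

    P(biparental -> AOH) = P(AOH -> biparental) = t

Exact forward-backward posterior decoding runs independently per chromosome.
Maximal runs of bins whose AOH posterior clears ``posterior_threshold``
become candidate segments; candidates below the reporting floor
``min_segment_mb`` are discarded and runs are never merged across
sub-threshold gaps, so a mosaic or noisy region fragments visibly rather
than being silently bridged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .likelihood import ModelParams

__all__ = [
    "AOHSegment",
    "SIZE_CLASSES",
    "switch_probability",
    "forward_backward",
    "smooth_posteriors",
    "extract_segments",
    "classify_segment",
]

SIZE_CLASSES = ("lt5", "5to10", "gt10", "chromosomal")

#: fraction of a chromosome a segment must cover to count as chromosome-level
CHROMOSOMAL_FRACTION = 0.9


@dataclass
class AOHSegment:
    """One called AOH interval (0-based half-open coordinates)."""

    chrom: str
    start: int
    end: int
    mean_posterior: float
    n_bins: int
    size_class: str
    flag: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError("segment end must exceed start")

    @property
    def size_mb(self) -> float:
        return (self.end - self.start) / 1e6


def switch_probability(bin_width: int, persistence_mb: float) -> float:
    """Per-bin-boundary state-switch base rate t = 1 - exp(-w / (L * 1e6))."""
    return 1.0 - np.exp(-bin_width / (persistence_mb * 1e6))


def forward_backward(llr: np.ndarray, pi: float, t: float) -> np.ndarray:
    """Exact two-state posterior decoding of one chromosome's LLR track.

    Parameters
    ----------
    llr
        Per-bin log emission ratio (AOH minus biparental).
    pi
        AOH prior (the chain's start distribution is (1 - pi, pi)).
    t
        Symmetric switch probability per bin boundary.

    Returns
    -------
    Per-bin posterior probability of the AOH state, in [0, 1].
    """
    llr = np.asarray(llr, dtype=np.float64)
    if llr.size == 0:
        return np.empty(0)
    if not np.all(np.isfinite(llr)):
        raise InputError("non-finite bin LLR in posterior smoothing")
    if not 0.0 < pi < 1.0 or not 0.0 < t < 1.0:
        raise ParameterError("pi and t must be in (0, 1)")

    log_start = np.log([1.0 - pi, pi])
    log_a = np.log([[1.0 - t, t], [t, 1.0 - t]])
    # emissions: state 0 (biparental) has log-emission 0, state 1 carries llr
    emit = np.column_stack([np.zeros_like(llr), llr])
    nb = llr.size

    fwd = np.empty((nb, 2))
    fwd[0] = log_start + emit[0]
    for b in range(1, nb):
        fwd[b] = emit[b] + np.logaddexp(
            fwd[b - 1, 0] + log_a[0], fwd[b - 1, 1] + log_a[1]
        )
    bwd = np.empty((nb, 2))
    bwd[-1] = 0.0
    for b in range(nb - 2, -1, -1):
        nxt = emit[b + 1] + bwd[b + 1]
        bwd[b, 0] = np.logaddexp(log_a[0, 0] + nxt[0], log_a[0, 1] + nxt[1])
        bwd[b, 1] = np.logaddexp(log_a[1, 0] + nxt[0], log_a[1, 1] + nxt[1])

    post = fwd + bwd
    post -= post.max(axis=1, keepdims=True)
    w = np.exp(post)
    return w[:, 1] / w.sum(axis=1)


def smooth_posteriors(bins: pd.DataFrame, params: ModelParams) -> pd.DataFrame:
    """Annotate a bin track with per-bin AOH posteriors.

    ``bins`` must carry chrom, start, end, llr, ordered within each
    chromosome. Returns a copy with a ``posterior`` column; the biparental
    posterior is its complement.
    """
    if bins.empty:
        out = bins.copy()
        out["posterior"] = pd.Series(dtype=float)
        return out
    t = switch_probability(params.bin_width, params.persistence_mb)
    out = bins.reset_index(drop=True).copy()
    post = np.empty(len(out))
    for chrom, grp in out.groupby("chrom", sort=False):
        if np.any(np.diff(grp["start"].to_numpy()) <= 0):
            raise InputError(f"bins out of order on {chrom}")
        post[grp.index.to_numpy()] = forward_backward(
            grp["llr"].to_numpy(), params.prior_aoh, t
        )
    out["posterior"] = post
    return out


def classify_segment(length_bp: int, chrom_len: int) -> str:
    """Size class of a segment of ``length_bp`` bases on a chromosome.

    chromosomal if the segment covers >= 90% of the chromosome; otherwise
    lt5 (< 5 Mb), 5to10 (5-10 Mb inclusive) or gt10 (> 10 Mb).
    """
    if chrom_len <= 0:
        raise ParameterError("chromosome length must be positive")
    if length_bp > chrom_len:
        raise ParameterError("segment longer than its chromosome")
    if length_bp >= CHROMOSOMAL_FRACTION * chrom_len:
        return "chromosomal"
    if length_bp < 5e6:
        return "lt5"
    if length_bp <= 10e6:
        return "5to10"
    return "gt10"


def extract_segments(
    bins: pd.DataFrame,
    params: ModelParams,
    chrom_lengths: Mapping[str, int] | None = None,
    min_segment_mb: float | None = None,
) -> list[AOHSegment]:
    """Call AOH segments from a posterior-annotated bin track.

    Maximal runs of consecutive bins with posterior >= posterior_threshold
    (ties included) become candidates; candidates shorter than the reporting
    floor are dropped; runs are never merged across gaps. ``chrom_lengths``
    supplies chromosome lengths for size classification (defaults to the
    last bin end seen per chromosome).
    """
    if "posterior" not in bins.columns:
        raise InputError("bins lack a posterior column; run smooth_posteriors first")
    floor_bp = (params.min_segment_mb if min_segment_mb is None else min_segment_mb) * 1e6
    segments: list[AOHSegment] = []
    for chrom, grp in bins.groupby("chrom", sort=False):
        post = grp["posterior"].to_numpy()
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        chrom_len = (
            int(chrom_lengths[chrom]) if chrom_lengths is not None else int(ends.max())
        )
        above = post >= params.posterior_threshold
        if not above.any():
            continue
        edges = np.diff(above.astype(np.int8))
        run_starts = list(np.flatnonzero(edges == 1) + 1)
        run_ends = list(np.flatnonzero(edges == -1) + 1)
        if above[0]:
            run_starts.insert(0, 0)
        if above[-1]:
            run_ends.append(len(above))
        for i, j in zip(run_starts, run_ends):
            seg_start, seg_end = int(starts[i]), int(ends[j - 1])
            if seg_end - seg_start < floor_bp:
                continue
            segments.append(
                AOHSegment(
                    chrom=str(chrom),
                    start=seg_start,
                    end=seg_end,
                    mean_posterior=float(post[i:j].mean()),
                    n_bins=int(j - i),
                    size_class=classify_segment(seg_end - seg_start, chrom_len),
                )
            )
    return segments


def segments_to_frame(segments: Sequence[AOHSegment]) -> pd.DataFrame:
    """Tabular view of a segment list (used by writers and reports)."""
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "mean_posterior": s.mean_posterior,
                "n_bins": s.n_bins,
                "size_mb": s.size_mb,
                "size_class": s.size_class,
                "flag": s.flag,
            }
            for s in segments
        ],
        columns=[
            "chrom",
            "start",
            "end",
            "mean_posterior",
            "n_bins",
            "size_mb",
            "size_class",
            "flag",
        ],
    )
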