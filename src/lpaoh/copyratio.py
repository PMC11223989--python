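"""Binned copy-ratio track and mosaic-fraction estimation.

A region of AOH produced by a mosaic cell line attenuates the allelic signal
in proportion to the aberrant fraction f, and — when the aberrant line is
aneuploid — shifts the read-depth of its bins. Normalising each bin's read
count by the genome-wide (autosomal) median gives a copy-ratio track whose
regional median m relates to the aberrant fraction as

    m = 1 - f/2   (mosaic monosomy / loss)
    m = 1 + f/2   (mosaic trisomy / gain)

so f = 2 * |m - 1|. A complementary allele-based maximum-likelihood
estimator grid-searches f using the read counts at panel sites: at a
heterozygous site a fraction f of cells contributes only one of the two
alleles, turning the allele-sampling probability 1/2 into an equal mixture
of (1-f)/2 and (1+f)/2. Sites covered by a single read are provably
uninformative for f, so the estimator requires at least one multi-read site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import InputError, InsufficientDataError, ParameterError
from .likelihood import _check_epsilon
from .smoothing import AOHSegment

__all__ = [
    "MosaicEstimate",
    "copy_ratio",
    "estimate_mosaic_fraction_cr",
    "estimate_mosaic_fraction_allele",
    "flag_possible_cnv",
]

#: copy-ratio deviation beyond which an AOH call is flagged as possible CNV
CNV_FLAG_DEVIATION = 0.1
CNV_FLAG = "possible_cnv_or_mosaic"

_SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class MosaicEstimate:
    """Result of mosaic-fraction estimation over one region."""

    region: tuple[str, int, int] | None
    f_cr: float | None
    f_allele: float | None
    loglik_curve: np.ndarray | None  # columns (f, log-likelihood)


def copy_ratio(
    bins: pd.DataFrame,
    count_col: str = "n_reads",
    bias: np.ndarray | None = None,
) -> pd.DataFrame:
    """Add a ``copy_ratio`` column: bin count / median autosomal bin count.

    ``bias`` is an optional per-bin multiplicative bias track (GC,
    mappability); counts are divided by it before normalisation. Sex
    chromosomes are excluded from the median but still receive ratios.
    """
    if count_col not in bins.columns:
        raise InputError(f"bins lack a {count_col!r} column")
    counts = bins[count_col].to_numpy(dtype=np.float64)
    if bias is not None:
        bias = np.asarray(bias, dtype=np.float64)
        if bias.shape != counts.shape or np.any(bias <= 0):
            raise ParameterError("bias track must be positive and match the bin count")
        counts = counts / bias
    autosomal = ~bins["chrom"].astype(str).isin(_SEX_CHROMS).to_numpy()
    if not autosomal.any():
        raise InputError("no autosomal bins to normalise against")
    med = float(np.median(counts[autosomal]))
    if med <= 0:
        raise InputError("median autosomal bin count is zero; degenerate input")
    out = bins.copy()
    out["copy_ratio"] = counts / med
    return out


def estimate_mosaic_fraction_cr(
    ratios: Sequence[float] | np.ndarray,
    direction: str = "auto",
    min_bins: int = 20,
) -> float:
    """Copy-ratio mosaic fraction: f = 2 * |median(ratios) - 1|, clipped.

    ``direction`` restricts the estimate to a gain (median above 1) or a
    loss (median below 1); ``auto`` takes the observed side. Requires at
    least ``min_bins`` bins for a stable regional median.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    if ratios.size < min_bins:
        raise InsufficientDataError(
            f"need >= {min_bins} bins for a mosaic estimate, got {ratios.size}"
        )
    signed = float(np.median(ratios)) - 1.0
    if direction == "auto":
        dev = abs(signed)
    elif direction == "loss":
        dev = max(0.0, -signed)
    elif direction == "gain":
        dev = max(0.0, signed)
    else:
        raise ParameterError("direction must be 'gain', 'loss' or 'auto'")
    return float(np.clip(2.0 * dev, 0.0, 1.0))


def estimate_mosaic_fraction_allele(
    observations: pd.DataFrame,
    epsilon: float,
    grid_step: float = 0.001,
    region: tuple[str, int, int] | None = None,
) -> MosaicEstimate:
    """Allele-based MLE of the aberrant-cell fraction f over a region.

    ``observations`` needs columns af, r, a (panel frequency plus read
    counts). For each candidate f the log-likelihood marginalises genotypes
    with Hardy-Weinberg priors; heterozygous genotypes emit alt reads with
    probability q(1-eps) + (1-q)eps where q is an equal mixture of
    (1-f)/2 and (1+f)/2. Returns the argmax and the full likelihood curve.
    """
    _check_epsilon(epsilon)
    if not 0 < grid_step <= 0.5:
        raise ParameterError("grid_step must be in (0, 0.5]")
    p = observations["af"].to_numpy(dtype=np.float64)
    r = observations["r"].to_numpy(dtype=np.float64)
    a = observations["a"].to_numpy(dtype=np.float64)
    n = r + a
    keep = n > 0
    p, r, a, n = p[keep], r[keep], a[keep], n[keep]
    if not np.any(n >= 2):
        raise InsufficientDataError(
            "no site covered by >= 2 reads; single-read sites carry no "
            "information about the mosaic fraction"
        )

    coeff = gammaln(n + 1) - gammaln(a + 1) - gammaln(r + 1)
    with np.errstate(divide="ignore"):
        log_prior_rr = 2 * np.log1p(-p)
        log_prior_aa = 2 * np.log(p)
        log_prior_het = np.log(2 * p * (1 - p))

    def _logpmf(q: float) -> np.ndarray:
        return coeff + a * np.log(q) + r * np.log1p(-q)

    # homozygous components do not depend on f
    hom = np.logaddexp(
        log_prior_rr + _logpmf(epsilon), log_prior_aa + _logpmf(1 - epsilon)
    )

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid[-1] = min(grid[-1], 1.0)
    curve = np.empty((grid.size, 2))
    log_half = np.log(0.5)
    for i, f in enumerate(grid):
        q_lo = 0.5 * (1 - f) * (1 - 2 * epsilon) + epsilon
        q_hi = 0.5 * (1 + f) * (1 - 2 * epsilon) + epsilon
        het = log_prior_het + np.logaddexp(
            log_half + _logpmf(q_lo), log_half + _logpmf(q_hi)
        )
        curve[i] = (f, float(np.sum(np.logaddexp(hom, het))))
    best = int(np.argmax(curve[:, 1]))
    return MosaicEstimate(
        region=region,
        f_cr=None,
        f_allele=float(curve[best, 0]),
        loglik_curve=curve,
    )


def flag_possible_cnv(
    segments: Sequence[AOHSegment],
    bins: pd.DataFrame,
    max_deviation: float = CNV_FLAG_DEVIATION,
) -> None:
    """Flag AOH calls whose bins' median copy ratio strays from 1.

    A hemizygous deletion mimics AOH in the allelic signal; a regional
    copy-ratio median deviating from 1 by more than ``max_deviation``
    marks the call as possible CNV / mosaic (flag set in place).
    """
    if "copy_ratio" not in bins.columns:
        raise InputError("bins lack a copy_ratio column")
    for seg in segments:
        sel = (
            (bins["chrom"].astype(str) == seg.chrom)
            & (bins["start"] >= seg.start)
            & (bins["end"] <= seg.end)
        )
        ratios = bins.loc[sel, "copy_ratio"].to_numpy()
        if ratios.size and abs(float(np.median(ratios)) - 1.0) > max_deviation:
            seg.flag = CNV_FLAG
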