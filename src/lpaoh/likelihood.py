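"""Genotype-likelihood machinery for haploid-vs-diploid discrimination.

At ultra-low coverage (<1x) individual genotypes cannot be called, but each
sequenced read still carries information: inside an AOH (absence of
heterozygosity) region every site is homozygous, so two reads covering the
same polymorphic site agree far more often than Hardy-Weinberg genotype
frequencies predict. This module computes, per site, the likelihood of the
observed ref/alt read counts under

* a **diploid** model -- genotypes RR/RA/AA with Hardy-Weinberg priors
  (1-p)^2, 2p(1-p), p^2 from the population alternate-allele frequency p;
* a **haploid** (AOH) model -- effective genotypes RR/AA with priors
  (1-p), p (both haplotypes identical).

Reads are conditionally independent given the genotype; each read reports the
wrong allele with probability ``epsilon``. The per-site log-likelihood ratio
(natural log, haploid minus diploid) is summed over fixed-width genomic bins
to form the evidence track the HMM smoother consumes. Single-read sites are
provably uninformative (the marginal alt-read probability is
p(1-eps) + (1-p)eps under both models), so all signal comes from sites hit by
two or more reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import InputError, ParameterError

__all__ = [
    "PanelSite",
    "SiteObservation",
    "ModelParams",
    "site_loglik",
    "site_llr",
    "site_loglik_arrays",
    "site_llr_arrays",
    "make_bins",
    "bin_llrs",
    "uahr_to_depth",
    "depth_to_uahr",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelSite:
    """One biallelic polymorphic site with population alt-allele frequency."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    p: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.p) or not 0.0 <= self.p <= 1.0:
            raise ParameterError(f"allele frequency must be in [0, 1], got {self.p}")
        if self.pos < 1:
            raise ParameterError(f"positions are 1-based, got {self.pos}")


@dataclass(frozen=True)
class SiteObservation:
    """Ref/alt read counts observed at a panel site for one sample."""

    site: PanelSite
    r: int
    a: int

    def __post_init__(self) -> None:
        if self.r < 0 or self.a < 0:
            raise ParameterError("read counts must be non-negative")

    @property
    def n(self) -> int:
        return self.r + self.a


@dataclass
class ModelParams:
    """Tunable parameters of the caller.

    epsilon
        Per-read allele error probability, in (0, 0.5).
    bin_width
        Genomic bin width in bases; bins tile each chromosome from 0, the
        last bin truncated at the chromosome end.
    prior_aoh
        Stationary prior pi of the AOH state of the HMM smoother, in (0, 1).
    persistence_mb
        Expected AOH segment length L in Mb; the per-bin-boundary switch
        probability is t = 1 - exp(-bin_width / (L * 1e6)).
    posterior_threshold
        Per-bin AOH posterior cutoff for segment extraction, in (0, 1).
    min_segment_mb
        Minimum reported segment size in Mb (clinical reporting floor).
    """

    epsilon: float = 0.01
    bin_width: int = 1_000_000
    prior_aoh: float = 0.01
    persistence_mb: float = 10.0
    posterior_threshold: float = 0.5
    min_segment_mb: float = 5.0

    def __post_init__(self) -> None:
        _check_epsilon(self.epsilon)
        if self.bin_width <= 0:
            raise ParameterError("bin_width must be positive")
        if not 0.0 < self.prior_aoh < 1.0:
            raise ParameterError("prior_aoh must be in (0, 1)")
        if self.persistence_mb <= 0:
            raise ParameterError("persistence_mb must be positive")
        if not 0.0 < self.posterior_threshold < 1.0:
            raise ParameterError("posterior_threshold must be in (0, 1)")
        if self.min_segment_mb <= 0:
            raise ParameterError("min_segment_mb must be positive")


def _check_epsilon(epsilon: float) -> None:
    if not np.isfinite(epsilon) or not 0.0 < epsilon < 0.5:
        raise ParameterError(f"epsilon must be in (0, 0.5), got {epsilon}")


# ---------------------------------------------------------------------------
# per-site likelihoods
# ---------------------------------------------------------------------------


def _binom_logpmf(k: np.ndarray, n: np.ndarray, q: float) -> np.ndarray:
    # q is strictly inside (0, 1) for every genotype component since
    # epsilon is in (0, 0.5), so the logs below are always finite.
    coeff = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return coeff + k * np.log(q) + (n - k) * np.log1p(-q)


def site_loglik_arrays(
    r: np.ndarray,
    a: np.ndarray,
    p: np.ndarray,
    model: str,
    epsilon: float,
) -> np.ndarray:
    """Vectorised log P(r, a | model) marginalised over genotypes.

    The binomial coefficient for read ordering is included consistently in
    both models (it cancels in the ratio). Sites with r = a = 0 return 0.
    """
    _check_epsilon(epsilon)
    r = np.asarray(r, dtype=np.float64)
    a = np.asarray(a, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if not np.all(np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ParameterError("allele frequencies must be finite and in [0, 1]")
    n = r + a
    with np.errstate(divide="ignore"):
        if model == "diploid":
            comps = np.stack(
                [
                    2 * np.log1p(-p) + _binom_logpmf(a, n, epsilon),
                    np.log(2 * p * (1 - p)) + _binom_logpmf(a, n, 0.5),
                    2 * np.log(p) + _binom_logpmf(a, n, 1 - epsilon),
                ]
            )
        elif model == "haploid":
            comps = np.stack(
                [
                    np.log1p(-p) + _binom_logpmf(a, n, epsilon),
                    np.log(p) + _binom_logpmf(a, n, 1 - epsilon),
                ]
            )
        else:
            raise ParameterError(f"model must be 'haploid' or 'diploid', got {model!r}")
    m = comps.max(axis=0)
    # guard p in {0,1}: a -inf component contributes exp(-inf)=0
    out = m + np.log(np.sum(np.exp(comps - m), axis=0))
    return out


def site_loglik(obs: SiteObservation, model: str, epsilon: float) -> float:
    """Log-likelihood of one site's read counts under one model."""
    return float(
        site_loglik_arrays(
            np.array([obs.r]), np.array([obs.a]), np.array([obs.site.p]), model, epsilon
        )[0]
    )


def site_llr_arrays(
    r: np.ndarray, a: np.ndarray, p: np.ndarray, epsilon: float
) -> np.ndarray:
    """Vectorised per-site log-likelihood ratio, haploid minus diploid."""
    return site_loglik_arrays(r, a, p, "haploid", epsilon) - site_loglik_arrays(
        r, a, p, "diploid", epsilon
    )


def site_llr(obs: SiteObservation, epsilon: float) -> float:
    """Per-site log-likelihood ratio (natural log), haploid minus diploid."""
    return site_loglik(obs, "haploid", epsilon) - site_loglik(obs, "diploid", epsilon)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def make_bins(chrom_lengths: Mapping[str, int], bin_width: int) -> pd.DataFrame:
    """Tile each chromosome with half-open bins of ``bin_width`` from 0.

    The last bin of each chromosome is truncated at the chromosome end.
    Columns: chrom, start, end.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ParameterError(f"chromosome {chrom} has non-positive length")
        starts = np.arange(0, length, bin_width, dtype=np.int64)
        ends = np.minimum(starts + bin_width, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


def _check_sorted(obs: pd.DataFrame) -> None:
    chroms = obs["chrom"].to_numpy()
    if len(chroms) == 0:
        return
    # chromosome blocks must be contiguous
    n_blocks = 1 + int(np.count_nonzero(chroms[1:] != chroms[:-1]))
    if n_blocks != len(set(chroms)):
        raise InputError("observations are not grouped by chromosome")
    for _, grp in obs.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if len(pos) > 1 and np.any(np.diff(pos) <= 0):
            raise InputError("positions must be strictly increasing within a chromosome")


def bin_llrs(
    observations: pd.DataFrame,
    chrom_lengths: Mapping[str, int],
    params: ModelParams,
) -> pd.DataFrame:
    """Aggregate per-site LLRs into a per-bin evidence track.

    Parameters
    ----------
    observations
        DataFrame with columns chrom, pos (1-based), af, r, a, sorted by
        (chrom, pos). Sites with r + a = 0 contribute nothing.
    chrom_lengths
        Chromosome name -> length map defining the bin grid.
    params
        Model parameters (epsilon and bin_width are used here).

    Returns
    -------
    DataFrame with columns chrom, start, end, n_sites, n_reads, llr. A site
    at 1-based position pos falls in the bin with start < pos <= end, i.e.
    bin index (pos - 1) // bin_width. Empty bins carry llr = 0, n_sites = 0.
    """
    required = {"chrom", "pos", "af", "r", "a"}
    if not required.issubset(observations.columns):
        raise InputError(f"observations need columns {sorted(required)}")
    _check_sorted(observations)

    bins = make_bins(chrom_lengths, params.bin_width)
    bins["n_sites"] = 0
    bins["n_reads"] = 0
    bins["llr"] = 0.0

    # per-chromosome offsets into the flat bin table
    offsets: dict[str, int] = {}
    counts: dict[str, int] = {}
    off = 0
    for chrom, length in chrom_lengths.items():
        nb = int(np.ceil(length / params.bin_width))
        offsets[chrom] = off
        counts[chrom] = nb
        off += nb

    n_sites_col = bins["n_sites"].to_numpy()
    n_reads_col = bins["n_reads"].to_numpy()
    llr_col = bins["llr"].to_numpy()

    for chrom, grp in observations.groupby("chrom", sort=False):
        if chrom not in offsets:
            raise InputError(f"observations reference unknown chromosome {chrom!r}")
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if np.any(pos < 1) or np.any(pos > chrom_lengths[chrom]):
            raise InputError(f"position outside chromosome {chrom}")
        r = grp["r"].to_numpy(dtype=np.int64)
        a = grp["a"].to_numpy(dtype=np.int64)
        af = grp["af"].to_numpy(dtype=np.float64)
        n = r + a
        covered = n > 0
        idx = (pos - 1) // params.bin_width
        nb = counts[chrom]
        o = offsets[chrom]
        n_sites_col[o : o + nb] += np.bincount(idx[covered], minlength=nb)
        n_reads_col[o : o + nb] += np.bincount(idx, weights=n, minlength=nb).astype(
            np.int64
        )
        multi = n > 1  # single-read sites have llr identically 0
        if multi.any():
            llr = site_llr_arrays(r[multi], a[multi], af[multi], params.epsilon)
            if not np.all(np.isfinite(llr)):
                raise InputError("non-finite per-site LLR encountered")
            llr_col[o : o + nb] += np.bincount(idx[multi], weights=llr, minlength=nb)

    bins["n_sites"] = n_sites_col
    bins["n_reads"] = n_reads_col
    bins["llr"] = llr_col
    return bins


# ---------------------------------------------------------------------------
# coverage arithmetic
# ---------------------------------------------------------------------------


def uahr_to_depth(n_reads: float, read_len: float, genome_len: float) -> float:
    """Fold-coverage from a read budget: n_reads * read_len / genome_len."""
    if genome_len <= 0 or read_len <= 0:
        raise ParameterError("read_len and genome_len must be positive")
    if n_reads < 0:
        raise ParameterError("n_reads must be non-negative")
    return n_reads * read_len / genome_len


def depth_to_uahr(depth: float, read_len: float, genome_len: float) -> float:
    """Inverse of :func:`uahr_to_depth`."""
    if genome_len <= 0 or read_len <= 0:
        raise ParameterError("read_len and genome_len must be positive")
    if depth < 0:
        raise ParameterError("depth must be non-negative")
    return depth * genome_len / read_len
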