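"""Synthetic ultra-low-pass sequencing data with planted AOH segments.

The generator emulates the inputs of the caller: a population allele-
frequency panel (sites placed at a fixed density, alt-allele frequencies
drawn from a truncated Beta — U-shaped by default, like a real site-
frequency spectrum), an individual genome carrying planted constitutional
or mosaic AOH segments, and per-site ref/alt read counts at a given budget
of uniquely aligned high-quality reads (UAHRs).

Model of one sample:

* outside planted segments the genotype at a site is a Hardy-Weinberg draw
  from the panel frequency p;
* inside a planted segment an "AOH line" — derived from the same zygote, so
  homozygous for one of the carried alleles: the genotype's allele at
  homozygous sites, either allele with equal probability at heterozygous
  sites (marginally AA with probability p) — is mixed with the biparental
  line at cell fraction mosaic_f;
* the site's read count is Poisson with mean lambda = uahr * read_len /
  genome_len, scaled by the regional copy state of the mosaic line;
* each read samples a cell line (weighted by its copy number), then one
  allele of that line's genotype, then flips with error probability epsilon.

Everything is deterministic given the configuration seed. Binomial
thinning (`downsample`) emulates lower sequencing depths from one dataset,
reproducing the Poisson marginals of a genuinely shallower run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError
from .smoothing import classify_segment

__all__ = [
    "TruthSegment",
    "SimConfig",
    "DEFAULT_CHROM_LENGTHS",
    "generate_panel",
    "simulate_sample",
    "downsample",
    "mosaic_bin_counts",
    "plan_cohort",
]

#: a compact 300 Mb three-chromosome genome; detection sensitivity depends on
#: per-site depth and SNP density, not genome size
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 120_000_000,
    "chr2": 100_000_000,
    "chr3": 80_000_000,
}

_CN_FACTOR = {"neutral": 1.0, "loss": 0.5, "gain": 1.5}


@dataclass(frozen=True)
class TruthSegment:
    """A planted AOH interval; mosaic_f = 1 means constitutional AOH."""

    chrom: str
    start: int
    end: int
    mosaic_f: float = 1.0
    cn_state: str = "neutral"

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ParameterError("truth segment must satisfy 0 <= start < end")
        if not 0.0 < self.mosaic_f <= 1.0:
            raise ParameterError("mosaic_f must be in (0, 1]")
        if self.cn_state not in _CN_FACTOR:
            raise ParameterError(f"cn_state must be one of {sorted(_CN_FACTOR)}")


@dataclass
class SimConfig:
    """Study conditions for one synthetic sample.

    snp_per_kb 1.0 and Beta(0.8, 0.8) frequencies truncated to [0.01, 0.99]
    emulate a common-SNP panel; read_len 35 matches single-end 35 bp
    sequencing; lambda (mean reads per site) equals the fold-coverage
    uahr * read_len / genome_len.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    snp_per_kb: float = 1.0
    af_alpha: float = 0.8
    af_beta: float = 0.8
    af_bounds: tuple[float, float] = (0.01, 0.99)
    uahr: float = 70_000_000.0
    read_len: int = 35
    epsilon: float = 0.01
    seed: int = 0
    truth: Sequence[TruthSegment] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.chrom_lengths or any(v <= 0 for v in self.chrom_lengths.values()):
            raise ParameterError("chrom_lengths must be positive")
        if self.snp_per_kb <= 0 or self.uahr < 0 or self.read_len <= 0:
            raise ParameterError("densities and budgets must be positive")
        if self.af_alpha <= 0 or self.af_beta <= 0:
            raise ParameterError("Beta parameters must be positive")
        by_chrom: dict[str, list[TruthSegment]] = {}
        for seg in self.truth:
            if seg.chrom not in self.chrom_lengths:
                raise ParameterError(f"truth segment on unknown chromosome {seg.chrom}")
            if seg.end > self.chrom_lengths[seg.chrom]:
                raise ParameterError("truth segment exceeds its chromosome")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for segs in by_chrom.values():
            segs = sorted(segs, key=lambda s: s.start)
            for s0, s1 in zip(segs, segs[1:]):
                if s1.start < s0.end:
                    raise ParameterError("truth segments overlap")

    @property
    def genome_len(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @property
    def lam(self) -> float:
        """Mean read count per panel site (equals fold coverage)."""
        return self.uahr * self.read_len / self.genome_len


def _unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct 1-based positions drawn uniformly from [1, length]."""
    pos: np.ndarray = np.unique(rng.integers(1, length + 1, size=n))
    while pos.size < n:
        extra = rng.integers(1, length + 1, size=n - pos.size)
        pos = np.unique(np.concatenate([pos, extra]))
    return np.sort(pos)


def generate_panel(config: SimConfig) -> pd.DataFrame:
    """Synthetic allele-frequency panel: chrom, pos, ref, alt, af.

    Site counts are fixed (round(length/1000 * snp_per_kb) per chromosome);
    frequencies are inverse-CDF draws from the truncated Beta so the count
    is exact and the distribution is properly truncated, not clipped.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.af_bounds
    dist = stats.beta(config.af_alpha, config.af_beta)
    u_lo, u_hi = dist.cdf(lo), dist.cdf(hi)
    frames = []
    bases = np.array(["A", "C", "G", "T"])
    for chrom, length in config.chrom_lengths.items():
        n = int(round(length / 1000 * config.snp_per_kb))
        if n == 0:
            continue
        pos = _unique_positions(rng, n, length)
        af = dist.ppf(u_lo + (u_hi - u_lo) * rng.random(n))
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": bases[ref_idx],
                    "alt": bases[alt_idx],
                    "af": af,
                }
            )
        )
    if not frames:
        raise ParameterError("zero-length genome: no panel sites to place")
    return pd.concat(frames, ignore_index=True)


def simulate_sample(panel: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Ultra-low-pass allele counts at every panel site for one individual.

    Returns a DataFrame chrom, pos, ref_count, alt_count aligned with the
    panel rows (sites with zero reads included). Deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 1])
    p = panel["af"].to_numpy(dtype=np.float64)
    n_sites = len(panel)

    # Hardy-Weinberg line: alt dosage ~ Binomial(2, p). The AOH line descends
    # from the same zygote: it keeps homozygous genotypes and collapses a
    # heterozygote onto one of its two alleles at random (marginally alt w.p. p)
    g_hwe = rng.binomial(2, p) / 2.0
    pick = rng.integers(0, 2, size=n_sites).astype(np.float64)
    g_aoh = np.where(g_hwe == 0.5, pick, g_hwe)

    f = np.zeros(n_sites)
    cn = np.ones(n_sites)
    chrom_vals = panel["chrom"].to_numpy()
    pos = panel["pos"].to_numpy()
    for seg in config.truth:
        inside = (chrom_vals == seg.chrom) & (pos > seg.start) & (pos <= seg.end)
        f[inside] = seg.mosaic_f
        cn[inside] = _CN_FACTOR[seg.cn_state]

    depth_factor = 1.0 - f + f * cn
    n = rng.poisson(config.lam * depth_factor)
    # reads sample a cell line in proportion to its copy number
    read_frac_aoh = np.divide(f * cn, depth_factor)
    q_mix = read_frac_aoh * g_aoh + (1.0 - read_frac_aoh) * g_hwe
    q_read = q_mix * (1.0 - 2.0 * config.epsilon) + config.epsilon
    a = rng.binomial(n, q_read)
    return pd.DataFrame(
        {
            "chrom": panel["chrom"],
            "pos": panel["pos"],
            "ref_count": n - a,
            "alt_count": a,
        }
    )


def downsample(
    observations: pd.DataFrame, keep_fraction: float, seed: int
) -> pd.DataFrame:
    """Binomial thinning: keep each read independently with ``keep_fraction``.

    Thinning Poisson(lambda) counts by k yields Poisson(k * lambda)
    marginals, so one deep dataset emulates any shallower depth exactly.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ParameterError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    rng = np.random.default_rng([seed, 2])
    out = observations.copy()
    out["ref_count"] = rng.binomial(
        observations["ref_count"].to_numpy(dtype=np.int64), keep_fraction
    )
    out["alt_count"] = rng.binomial(
        observations["alt_count"].to_numpy(dtype=np.int64), keep_fraction
    )
    return out


def mosaic_bin_counts(
    n_bins_genome: int,
    n_bins_region: int,
    mean_count: float,
    mosaic_f: float,
    cn_state: str,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson bin counts for a genome whose last ``n_bins_region`` bins carry
    a mosaic copy-state shift: mean * (1 - f + f * c), c in {0.5, 1, 1.5}.

    Returns (counts, region_mask) for feeding the copy-ratio estimator.
    """
    if cn_state not in _CN_FACTOR:
        raise ParameterError(f"cn_state must be one of {sorted(_CN_FACTOR)}")
    if not 0.0 <= mosaic_f <= 1.0:
        raise ParameterError("mosaic_f must be in [0, 1]")
    if n_bins_region > n_bins_genome or n_bins_region <= 0 or mean_count <= 0:
        raise ParameterError("invalid bin-count geometry")
    rng = np.random.default_rng([seed, 3])
    mean = np.full(n_bins_genome, float(mean_count))
    mask = np.zeros(n_bins_genome, dtype=bool)
    mask[-n_bins_region:] = True
    mean[mask] *= 1.0 - mosaic_f + mosaic_f * _CN_FACTOR[cn_state]
    return rng.poisson(mean).astype(np.int64), mask


def plan_cohort(
    class_counts: Mapping[str, int],
    chrom_lengths: Mapping[str, int],
    seed: int,
    size_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> list[list[TruthSegment]]:
    """Pack a cohort of truth segments with a given size-class mix.

    Regions are assigned round-robin, one per chromosome per sample, so a
    sample carries at most ``len(chrom_lengths)`` planted segments (each on
    its own chromosome). Sizes (Mb) default to lt5 ~ U(2, 5),
    5to10 ~ U(5, 10), gt10 ~ U(10, 40); chromosomal covers the whole
    chromosome. Returns one truth-segment list per sample.
    """
    ranges = {
        "lt5": (2.0, 5.0),
        "5to10": (5.0, 10.0),
        "gt10": (10.0, 40.0),
    }
    if size_ranges:
        ranges.update(size_ranges)
    rng = np.random.default_rng([seed, 4])
    chroms = list(chrom_lengths)
    labels: list[str] = []
    for cls in ("lt5", "5to10", "gt10", "chromosomal"):
        labels.extend([cls] * int(class_counts.get(cls, 0)))
    order = rng.permutation(len(labels))
    samples: list[list[TruthSegment]] = []
    for slot, idx in enumerate(order):
        cls = labels[idx]
        chrom = chroms[slot % len(chroms)]
        length = int(chrom_lengths[chrom])
        if slot % len(chroms) == 0:
            samples.append([])
        if cls == "chromosomal":
            seg = TruthSegment(chrom, 0, length)
        else:
            lo, hi = ranges[cls]
            size = int(rng.uniform(lo, hi) * 1e6)
            start = int(rng.integers(0, length - size + 1))
            seg = TruthSegment(chrom, start, start + size)
            # guard against a draw crossing the class boundary after rounding
            assert classify_segment(size, length) == cls
        samples[-1].append(seg)
    return samples
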