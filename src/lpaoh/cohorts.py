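"""Reusable simulated-cohort harnesses for validation studies.

These functions bundle the generator, the caller and the evaluation metrics
into the study designs exercised by the test suite, the acceptance script
and the examples: sample-level accuracy cohorts (one planted constitutional
AOH per positive sample), region-level depth-titration cohorts with a
prescribed size-class mix, and the whole-chromosome mosaic copy-ratio
experiment. All randomness is derived from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .copyratio import estimate_mosaic_fraction_cr
from .evaluate import match_regions, sample_confusion
from .likelihood import ModelParams, depth_to_uahr
from .pipeline import call_observations
from .simulate import (
    DEFAULT_CHROM_LENGTHS,
    SimConfig,
    TruthSegment,
    downsample,
    generate_panel,
    mosaic_bin_counts,
    plan_cohort,
    simulate_sample,
)
from .smoothing import classify_segment

__all__ = [
    "derive_seed",
    "prejoin",
    "CohortResult",
    "run_sample_level_cohort",
    "run_region_cohort",
    "run_mosaic_recovery",
]


def derive_seed(master_seed: int, *path: int) -> int:
    """A reproducible child seed (< 2**31) from a master seed and a path."""
    ss = np.random.SeedSequence([int(master_seed), *[int(p) for p in path]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class CohortResult:
    """Outcome of one simulated cohort run."""

    n_samples: int
    sensitivity: float | None = None
    specificity: float | None = None
    region_matched: int = 0
    region_total: int = 0
    per_class: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def region_overlap_rate(self) -> float:
        return self.region_matched / self.region_total if self.region_total else float("nan")


def prejoin(panel: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Observations for counts simulated on this panel (row-aligned, no merge)."""
    return pd.DataFrame(
        {
            "chrom": panel["chrom"],
            "pos": panel["pos"],
            "af": panel["af"],
            "r": counts["ref_count"].to_numpy(),
            "a": counts["alt_count"].to_numpy(),
        }
    )


def _one_segment_truth(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    size_range_mb: tuple[float, float],
) -> list[TruthSegment]:
    chroms = list(chrom_lengths)
    chrom = chroms[int(rng.integers(len(chroms)))]
    length = int(chrom_lengths[chrom])
    size = int(rng.uniform(*size_range_mb) * 1e6)
    start = int(rng.integers(0, length - size + 1))
    return [TruthSegment(chrom, start, start + size)]


def run_sample_level_cohort(
    n_positive: int,
    n_negative: int,
    master_seed: int,
    depth: float = 0.8,
    size_range_mb: tuple[float, float] = (10.0, 40.0),
    chrom_lengths: Mapping[str, int] | None = None,
    params: ModelParams | None = None,
) -> CohortResult:
    """Sample-level accuracy study: one constitutional AOH per positive.

    Positive samples carry a single planted segment with size drawn
    uniformly from ``size_range_mb``; negatives carry none. All samples are
    simulated at ``depth``-fold equivalent coverage on a shared panel and
    called with default parameters; a sample is call-positive iff it has a
    reported segment at or above the 5 Mb floor. Region-level concordance
    (>50% union reciprocal overlap against truth) is accumulated over the
    positives.
    """
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    params = params or ModelParams()
    genome_len = sum(chrom_lengths.values())
    uahr = depth_to_uahr(depth, 35, genome_len)
    panel = generate_panel(
        SimConfig(chrom_lengths=chrom_lengths, seed=derive_seed(master_seed, 0))
    )
    call_sets = []
    labels = []
    matched = total = 0
    for i in range(n_positive + n_negative):
        positive = i < n_positive
        seed_i = derive_seed(master_seed, 1, i)
        rng = np.random.default_rng([seed_i, 9])
        truth = (
            _one_segment_truth(rng, chrom_lengths, size_range_mb) if positive else []
        )
        cfg = SimConfig(
            chrom_lengths=chrom_lengths, uahr=uahr, seed=seed_i, truth=truth
        )
        obs = prejoin(panel, simulate_sample(panel, cfg))
        result = call_observations(obs, chrom_lengths, params)
        call_sets.append(result.segments)
        labels.append(positive)
        if positive:
            flags = match_regions(result.segments, truth, cutoff=0.5)
            matched += int(flags.sum())
            total += len(truth)
    report = sample_confusion(call_sets, labels, min_segment_mb=params.min_segment_mb)
    return CohortResult(
        n_samples=n_positive + n_negative,
        sensitivity=report.sensitivity if n_positive else None,
        specificity=report.specificity if n_negative else None,
        region_matched=matched,
        region_total=total,
    )


def run_region_cohort(
    class_counts: Mapping[str, int],
    master_seed: int,
    lam_target: float,
    lam_full: float = 0.8,
    chrom_lengths: Mapping[str, int] | None = None,
    params: ModelParams | None = None,
    min_segment_mb: float = 1.0,
) -> CohortResult:
    """Region-level depth-titration cohort with a prescribed size-class mix.

    Truth regions in the requested class proportions are packed one per
    chromosome per sample, simulated at ``lam_full`` per-site depth on a
    shared panel, binomially thinned to ``lam_target``, and called with the
    reporting floor lowered to ``min_segment_mb`` so that sub-5 Mb truth
    classes are measurable. Matching is >50% union reciprocal overlap.
    """
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    params = params or ModelParams()
    if lam_target > lam_full:
        raise ValueError("target depth exceeds simulated depth")
    genome_len = sum(chrom_lengths.values())
    uahr_full = depth_to_uahr(lam_full, 35, genome_len)
    panel = generate_panel(
        SimConfig(chrom_lengths=chrom_lengths, seed=derive_seed(master_seed, 0))
    )
    cohort = plan_cohort(class_counts, chrom_lengths, derive_seed(master_seed, 2))
    matched_total = 0
    total = 0
    per_class: dict[str, list[int]] = {}
    for i, truth in enumerate(cohort):
        seed_i = derive_seed(master_seed, 3, i)
        cfg = SimConfig(
            chrom_lengths=chrom_lengths, uahr=uahr_full, seed=seed_i, truth=truth
        )
        counts = simulate_sample(panel, cfg)
        keep = lam_target / lam_full
        if keep < 1.0:
            counts = downsample(counts, keep, seed=seed_i)
        obs = prejoin(panel, counts)
        result = call_observations(
            obs, chrom_lengths, params, min_segment_mb=min_segment_mb
        )
        flags = match_regions(result.segments, truth, cutoff=0.5)
        for seg, ok in zip(truth, flags):
            cls = classify_segment(seg.end - seg.start, chrom_lengths[seg.chrom])
            per_class.setdefault(cls, [0, 0])
            per_class[cls][0] += int(ok)
            per_class[cls][1] += 1
            matched_total += int(ok)
            total += 1
    return CohortResult(
        n_samples=len(cohort),
        region_matched=matched_total,
        region_total=total,
        per_class={k: (v[0], v[1]) for k, v in per_class.items()},
    )


def run_mosaic_recovery(
    mosaic_f: float,
    seed: int,
    n_bins_genome: int = 3000,
    n_bins_region: int = 138,
    mean_count: float = 500.0,
    cn_state: str = "loss",
) -> float:
    """Copy-ratio recovery of a whole-chromosome mosaic fraction.

    Simulates Poisson bin counts with the mosaic copy shift over the region,
    normalises against the genome-wide median, and returns the copy-ratio
    estimate of f.
    """
    counts, mask = mosaic_bin_counts(
        n_bins_genome, n_bins_region, mean_count, mosaic_f, cn_state, seed
    )
    ratios = counts / np.median(counts)  # genome-wide median, as in copy_ratio
    return estimate_mosaic_fraction_cr(ratios[mask], direction="auto")
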