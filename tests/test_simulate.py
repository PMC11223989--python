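"""Synthetic-data generator: panel, samples, thinning, cohort planning."""

import numpy as np
import pytest
from scipy import integrate, stats

from lpaoh import (
    ParameterError,
    SimConfig,
    TruthSegment,
    classify_segment,
    downsample,
    generate_panel,
    plan_cohort,
    simulate_sample,
)

GENOME = {"chrA": 10_000_000, "chrB": 6_000_000}


def cfg(**kw):
    base = dict(chrom_lengths=GENOME, uahr=1_000_000, seed=5)
    base.update(kw)
    return SimConfig(**base)


class TestGeneratePanel:
    def test_fixed_site_counts(self):
        panel = generate_panel(cfg())
        assert (panel.chrom == "chrA").sum() == 10_000
        assert (panel.chrom == "chrB").sum() == 6_000

    def test_positions_sorted_unique_in_range(self):
        panel = generate_panel(cfg())
        for chrom, length in GENOME.items():
            pos = panel.loc[panel.chrom == chrom, "pos"].to_numpy()
            assert np.all(np.diff(pos) > 0)
            assert pos.min() >= 1 and pos.max() <= length

    def test_frequencies_truncated(self):
        panel = generate_panel(cfg())
        assert panel.af.between(0.01, 0.99).all()

    def test_determinism(self):
        a = generate_panel(cfg()).to_csv()
        b = generate_panel(cfg()).to_csv()
        assert a == b

    def test_af_mean_matches_truncated_beta(self):
        # oracle: moments of the truncated Beta via numerical integration
        panel = generate_panel(cfg())
        alpha, beta = 0.8, 0.8
        pdf = stats.beta(alpha, beta).pdf
        z, _ = integrate.quad(pdf, 0.01, 0.99)
        mean, _ = integrate.quad(lambda x: x * pdf(x) / z, 0.01, 0.99)
        var, _ = integrate.quad(lambda x: (x - mean) ** 2 * pdf(x) / z, 0.01, 0.99)
        se = np.sqrt(var / len(panel))
        assert abs(panel.af.mean() - mean) < 3 * se

    def test_alleles_differ(self):
        panel = generate_panel(cfg())
        assert (panel.ref != panel.alt).all()


class TestSimulateSample:
    def test_determinism(self):
        c = cfg(truth=[TruthSegment("chrA", 0, 4_000_000)])
        panel = generate_panel(c)
        a = simulate_sample(panel, c).to_csv()
        b = simulate_sample(panel, c).to_csv()
        assert a == b

    def test_constitutional_aoh_has_no_discordant_sites_without_error(self):
        c = cfg(epsilon=1e-12, uahr=20_000_000, truth=[TruthSegment("chrA", 0, 10_000_000)])
        panel = generate_panel(c)
        counts = simulate_sample(panel, c)
        inside = counts[counts.chrom == "chrA"]
        discordant = (inside.ref_count > 0) & (inside.alt_count > 0)
        assert discordant.sum() == 0

    def test_discordance_rate_matches_hardy_weinberg(self):
        # outside AOH a multi-read site is discordant mostly when heterozygous;
        # for a read pair the exact probability is 2p(1-p)/2 at epsilon -> 0
        c = cfg(epsilon=1e-12, uahr=2_000_000, seed=8)
        panel = generate_panel(c)
        counts = simulate_sample(panel, c)
        n = counts.ref_count + counts.alt_count
        pairs = n == 2
        p = panel.af.to_numpy()[pairs]
        expected = np.mean(2 * p * (1 - p) * 0.5)
        observed = (
            (counts.ref_count[pairs] > 0) & (counts.alt_count[pairs] > 0)
        ).mean()
        se = np.sqrt(expected * (1 - expected) / pairs.sum())
        assert abs(observed - expected) < 3 * se

    def test_mean_site_depth_matches_lambda(self):
        c = cfg(uahr=3_000_000)
        panel = generate_panel(c)
        counts = simulate_sample(panel, c)
        n = (counts.ref_count + counts.alt_count).to_numpy()
        lam = c.lam
        se = np.sqrt(lam / len(panel))
        assert abs(n.mean() - lam) < 3 * se

    def test_lambda_arithmetic(self):
        c = SimConfig(
            chrom_lengths={"chr1": 3_000_000_000}, uahr=15e6, read_len=35, snp_per_kb=0.001
        )
        assert c.lam == pytest.approx(0.175)

    def test_mosaic_loss_reduces_regional_depth(self):
        c = cfg(
            uahr=40_000_000,
            truth=[TruthSegment("chrA", 0, 10_000_000, mosaic_f=0.5, cn_state="loss")],
        )
        panel = generate_panel(c)
        counts = simulate_sample(panel, c)
        n = counts.ref_count + counts.alt_count
        inside = n[(counts.chrom == "chrA")].mean()
        outside = n[(counts.chrom == "chrB")].mean()
        # expected depth factor 1 - f/2 = 0.75
        assert inside / outside == pytest.approx(0.75, abs=0.03)

    def test_overlapping_truth_rejected(self):
        with pytest.raises(ParameterError):
            cfg(truth=[TruthSegment("chrA", 0, 2_000_000), TruthSegment("chrA", 1_000_000, 3_000_000)])

    def test_truth_outside_genome_rejected(self):
        with pytest.raises(ParameterError):
            cfg(truth=[TruthSegment("chrA", 0, 11_000_000)])


class TestDownsample:
    def make_counts(self, seed=5, uahr=10_000_000):
        c = cfg(seed=seed, uahr=uahr)
        panel = generate_panel(c)
        return simulate_sample(panel, c)

    def test_keep_all_is_identity(self):
        counts = self.make_counts()
        thinned = downsample(counts, 1.0, seed=1)
        assert thinned.to_csv() == counts.to_csv()

    def test_determinism(self):
        counts = self.make_counts()
        assert downsample(counts, 0.4, 3).to_csv() == downsample(counts, 0.4, 3).to_csv()

    def test_total_reads_binomial(self):
        counts = self.make_counts()
        total = int((counts.ref_count + counts.alt_count).sum())
        kept = downsample(counts, 0.5, seed=2)
        kept_total = int((kept.ref_count + kept.alt_count).sum())
        sd = np.sqrt(total * 0.25)
        assert abs(kept_total - 0.5 * total) < 4 * sd

    def test_thinned_poisson_is_poisson(self):
        # thinning Poisson(lam) by k gives Poisson(k * lam) marginals;
        # chi-square goodness of fit on binned outcome counts (a one-sample
        # KS test is invalid for discrete data — it rejects on ties alone)
        rng = np.random.default_rng(10)
        lam, k = 2.0, 0.4
        base = rng.poisson(lam, 10_000)
        counts = self.make_counts().iloc[:10_000].copy()
        counts["ref_count"] = base
        counts["alt_count"] = 0
        thinned = downsample(counts, k, seed=4)["ref_count"].to_numpy()
        target = stats.poisson(k * lam)
        edges = np.arange(5)
        observed = np.array(
            [(thinned == e).sum() for e in edges] + [(thinned > edges[-1]).sum()]
        )
        probs = np.append(target.pmf(edges), target.sf(edges[-1]))
        res = stats.chisquare(observed, probs * len(thinned))
        assert res.pvalue > 0.01

    def test_invalid_fraction_rejected(self):
        counts = self.make_counts()
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                downsample(counts, bad, seed=1)


class TestPlanCohort:
    def test_class_mix_and_geometry(self):
        genome = {"c1": 120_000_000, "c2": 100_000_000, "c3": 80_000_000}
        mix = {"lt5": 3, "5to10": 5, "gt10": 10, "chromosomal": 4}
        cohort = plan_cohort(mix, genome, seed=0)
        seen = {cls: 0 for cls in mix}
        for truth in cohort:
            chroms = [t.chrom for t in truth]
            assert len(chroms) == len(set(chroms))  # one region per chromosome
            for t in truth:
                assert 0 <= t.start < t.end <= genome[t.chrom]
                seen[classify_segment(t.end - t.start, genome[t.chrom])] += 1
        assert seen == mix

    def test_deterministic(self):
        genome = {"c1": 120_000_000, "c2": 100_000_000}
        a = plan_cohort({"gt10": 6}, genome, seed=3)
        b = plan_cohort({"gt10": 6}, genome, seed=3)
        assert a == b
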