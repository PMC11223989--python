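"""Per-site genotype likelihoods, LLRs, binning and coverage arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lpaoh import (
    InputError,
    ModelParams,
    PanelSite,
    ParameterError,
    SiteObservation,
    bin_llrs,
    depth_to_uahr,
    make_bins,
    site_llr,
    site_llr_arrays,
    site_loglik,
    uahr_to_depth,
)

from conftest import make_obs


def enum_loglik(r: int, a: int, p: float, eps: float, model: str) -> float:
    """Independent oracle: explicit genotype enumeration with math.comb."""
    n = r + a
    if model == "diploid":
        components = [((1 - p) ** 2, eps), (2 * p * (1 - p), 0.5), (p**2, 1 - eps)]
    else:
        components = [(1 - p, eps), (p, 1 - eps)]
    total = sum(
        prior * math.comb(n, a) * q**a * (1 - q) ** r for prior, q in components
    )
    return math.log(total)


def obs(r, a, p):
    return SiteObservation(site=PanelSite("chr1", 1000, "A", "G", p), r=r, a=a)


class TestSiteLoglik:
    def test_no_data_is_log_one(self):
        for model in ("haploid", "diploid"):
            assert site_loglik(obs(0, 0, 0.3), model, 0.01) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "r,a,p,model",
        [
            (0, 2, 0.5, "haploid"),
            (1, 1, 0.5, "diploid"),
            (2, 0, 0.1, "haploid"),
            (3, 1, 0.7, "diploid"),
            (0, 4, 0.25, "haploid"),
        ],
    )
    def test_matches_enumeration_oracle(self, r, a, p, model):
        expected = enum_loglik(r, a, p, 0.01, model)
        assert site_loglik(obs(r, a, p), model, 0.01) == pytest.approx(expected, rel=1e-12)

    def test_alt_homozygote_pair_frozen_value(self):
        # log(0.5 * 0.99^2 + 0.5 * 0.01^2) under the haploid model
        expected = math.log(0.5 * 0.99**2 + 0.5 * 0.01**2)
        assert site_loglik(obs(0, 2, 0.5), "haploid", 0.01) == pytest.approx(expected)

    def test_likelihood_normalises_over_outcomes(self):
        # sum over all (r, a) with r + a = n must be 1 for both models
        for model in ("haploid", "diploid"):
            for p in (0.0, 0.2, 0.5, 0.9, 1.0):
                for n in range(5):
                    total = sum(
                        math.exp(site_loglik(obs(n - a, a, p), model, 0.01))
                        for a in range(n + 1)
                    )
                    assert total == pytest.approx(1.0, abs=1e-10)

    def test_rejects_bad_epsilon(self):
        with pytest.raises(ParameterError):
            site_loglik(obs(1, 1, 0.5), "diploid", 0.7)
        with pytest.raises(ParameterError):
            site_loglik(obs(1, 1, 0.5), "diploid", 0.0)

    def test_rejects_unknown_model(self):
        with pytest.raises(ParameterError):
            site_loglik(obs(1, 1, 0.5), "triploid", 0.01)


class TestSiteLLR:
    @pytest.mark.parametrize(
        "r,a,expected",
        [(2, 0, 0.281), (1, 1, -2.575)],
    )
    def test_frozen_examples_p_half(self, r, a, expected):
        # concordant pairs favour haploid, discordant pairs favour diploid
        assert site_llr(obs(r, a, 0.5), 0.01) == pytest.approx(expected, abs=5e-4)

    def test_single_read_exactly_uninformative(self):
        assert site_llr(obs(1, 0, 0.3), 0.01) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        p=st.floats(0.01, 0.99),
        eps=st.sampled_from([0.001, 0.01, 0.05]),
        alt=st.booleans(),
    )
    def test_single_read_identity_property(self, p, eps, alt):
        r, a = (0, 1) if alt else (1, 0)
        assert abs(site_llr(obs(r, a, p), eps)) < 1e-10

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        r=st.integers(0, 4),
        a=st.integers(0, 4),
        p=st.floats(0.01, 0.99),
        eps=st.sampled_from([0.001, 0.01, 0.05]),
    )
    def test_allele_swap_symmetry(self, r, a, p, eps):
        assert site_llr(obs(r, a, p), eps) == pytest.approx(
            site_llr(obs(a, r, 1 - p), eps), abs=1e-9
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(p=st.floats(0.06, 0.94), eps=st.sampled_from([0.001, 0.01, 0.05]))
    def test_concordant_positive_discordant_negative(self, p, eps):
        assert site_llr(obs(2, 0, p), eps) > 0
        assert site_llr(obs(1, 1, p), eps) < 0

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(0)
        r = rng.integers(0, 5, 50)
        a = rng.integers(0, 5, 50)
        p = rng.uniform(0.01, 0.99, 50)
        vec = site_llr_arrays(r, a, p, 0.01)
        for i in range(50):
            assert vec[i] == pytest.approx(
                site_llr(obs(int(r[i]), int(a[i]), float(p[i])), 0.01), abs=1e-10
            )


class TestBinning:
    def test_make_bins_tiles_and_truncates(self):
        bins = make_bins({"chr1": 2_500_000}, 1_000_000)
        assert bins["start"].tolist() == [0, 1_000_000, 2_000_000]
        assert bins["end"].tolist() == [1_000_000, 2_000_000, 2_500_000]

    def test_bin_llr_is_sum_of_site_llrs(self, default_params):
        p = [0.3, 0.5, 0.7]
        observations = make_obs(
            ["chr1"] * 3, [100, 200_000, 999_999], p, [2, 1, 0], [0, 1, 3]
        )
        bins = bin_llrs(observations, {"chr1": 2_000_000}, default_params)
        expected = sum(
            site_llr(obs(r, a, pp), default_params.epsilon)
            for r, a, pp in [(2, 0, 0.3), (1, 1, 0.5), (0, 3, 0.7)]
        )
        assert bins.loc[0, "llr"] == pytest.approx(expected, abs=1e-10)
        assert bins.loc[0, "n_sites"] == 3
        assert bins.loc[0, "n_reads"] == 7
        # second bin is empty
        assert bins.loc[1, "llr"] == 0.0
        assert bins.loc[1, "n_sites"] == 0

    def test_single_read_sites_leave_bin_at_zero(self, default_params):
        observations = make_obs(
            ["chr1"] * 3, [10, 20, 30], [0.2, 0.5, 0.8], [1, 0, 1], [0, 1, 0]
        )
        bins = bin_llrs(observations, {"chr1": 1_000_000}, default_params)
        assert abs(bins.loc[0, "llr"]) < 1e-12
        assert bins.loc[0, "n_sites"] == 3

    def test_boundary_site_assignment(self, default_params):
        # 1-based position w falls in the first bin [0, w); position w+1 in the next
        w = 1_000_000
        observations = make_obs(["chr1"] * 2, [w, w + 1], [0.5, 0.5], [2, 2], [0, 0])
        bins = bin_llrs(observations, {"chr1": 2 * w}, default_params)
        assert bins.loc[0, "n_sites"] == 1
        assert bins.loc[1, "n_sites"] == 1

    def test_unsorted_positions_rejected(self, default_params):
        observations = make_obs(
            ["chr1"] * 2, [500, 100], [0.5, 0.5], [1, 1], [0, 0]
        )
        with pytest.raises(InputError):
            bin_llrs(observations, {"chr1": 1_000_000}, default_params)

    def test_position_beyond_chromosome_rejected(self, default_params):
        observations = make_obs(["chr1"], [2_000_001], [0.5], [1], [0])
        with pytest.raises(InputError):
            bin_llrs(observations, {"chr1": 2_000_000}, default_params)


class TestCoverageArithmetic:
    def test_cohort_average_fold_coverage(self):
        # 71.48 M single-end 35 bp reads over a 3 Gb genome is ~0.83-fold
        assert round(uahr_to_depth(71.48e6, 35, 3.0e9), 2) == 0.83

    def test_trivial_values(self):
        assert uahr_to_depth(1e6, 35, 35e6) == pytest.approx(1.0)
        assert uahr_to_depth(0, 35, 3e9) == 0.0

    def test_round_trip(self):
        assert depth_to_uahr(uahr_to_depth(15e6, 35, 3e9), 35, 3e9) == pytest.approx(15e6)

    def test_rejects_bad_genome_length(self):
        with pytest.raises(ParameterError):
            uahr_to_depth(1e6, 35, 0)
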