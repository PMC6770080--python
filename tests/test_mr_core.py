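"""Estimator algebra: Wald ratios, IVW pooling, heterogeneity, transforms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr.exceptions import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    ScaleMismatchError,
)
from tsmr.mr_core import (
    Z_975,
    f_statistic,
    heterogeneity,
    instrument_r2,
    ivw_fixed,
    ivw_random,
    pool_with_model_selection,
    to_odds_ratio,
    wald_ratio,
)
from tsmr.summary_io import SnpAssociation

from conftest import make_pairs


def ivw_meta_of_wald_ratios(pairs):
    """Independent oracle: classical inverse-variance meta-analysis of the
    per-SNP Wald ratios, computed without touching the pooled formulas."""
    ratios = np.array([p.outcome.beta / p.exposure.beta for p in pairs])
    ses = np.array([p.outcome.se / abs(p.exposure.beta) for p in pairs])
    w = 1.0 / ses**2
    return float(np.sum(w * ratios) / np.sum(w)), float(math.sqrt(1.0 / np.sum(w)))


# strategy for modest, well-conditioned summary statistics
_e = st.floats(0.005, 0.1)
_d = st.floats(-0.05, 0.05)
_sd = st.floats(1e-3, 0.05)


@st.composite
def pair_inputs(draw, min_k=1, max_k=10):
    k = draw(st.integers(min_k, max_k))
    e = [draw(_e) * draw(st.sampled_from([1.0, -1.0])) for _ in range(k)]
    d = [draw(_d) for _ in range(k)]
    sd = [draw(_sd) for _ in range(k)]
    return make_pairs(e, d, sd)


class TestWaldRatio:
    @pytest.mark.parametrize(
        "e,d,sd,ratio,se",
        [
            (0.04, 0.02, 0.005, 0.5, 0.125),
            (0.04, 0.0, 0.005, 0.0, 0.125),
            (0.03, 0.0015, 0.0004, 0.05, 0.0004 / 0.03),
            (-0.04, 0.02, 0.005, -0.5, 0.125),  # sign follows D*E, SE uses |E|
        ],
    )
    def test_ratio_and_delta_method_se(self, e, d, sd, ratio, se):
        (pair,) = make_pairs([e], [d], [sd])
        est = wald_ratio(pair)
        assert est.ratio == pytest.approx(ratio, abs=1e-15)
        assert est.se == pytest.approx(se, abs=1e-15)
        assert est.se > 0

    def test_zero_exposure_effect_is_degenerate(self):
        (pair,) = make_pairs([0.0], [0.01], [0.005])
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(pair)


class TestIvwFixed:
    def test_single_pair_reduces_to_wald(self):
        (pair,) = make_pairs([0.04], [0.02], [0.005])
        pooled = ivw_fixed([pair])
        wald = wald_ratio(pair)
        assert pooled.beta == pytest.approx(wald.ratio, abs=1e-15)
        assert pooled.se == pytest.approx(wald.se, abs=1e-15)
        assert pooled.k == 1
        assert pooled.het.df == 0
        assert pooled.het.p_het is None

    def test_equal_ratios_symmetric_pool(self):
        # two identical Wald ratios 0.5 with identical Wald SE 0.1
        pairs = make_pairs([0.04, 0.04], [0.02, 0.02], [0.004, 0.004])
        pooled = ivw_fixed(pairs)
        assert pooled.beta == pytest.approx(0.5)
        assert pooled.se == pytest.approx(0.1 / math.sqrt(2))
        assert pooled.het.q == pytest.approx(0.0, abs=1e-20)

    def test_three_snp_example_matches_meta_analysis_oracle(self):
        pairs = make_pairs(
            [0.03, 0.03, 0.04],
            [0.0015, 0.0012, 0.0020],
            [0.0005, 0.0004, 0.0006],
        )
        pooled = ivw_fixed(pairs)
        beta_o, se_o = ivw_meta_of_wald_ratios(pairs)
        assert pooled.beta == pytest.approx(beta_o, abs=1e-12)
        assert pooled.se == pytest.approx(se_o, abs=1e-12)

    def test_empty_input(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw_fixed([])

    @settings(derandomize=True, max_examples=100)
    @given(pair_inputs())
    def test_direct_formula_equals_wald_meta_everywhere(self, pairs):
        pooled = ivw_fixed(pairs)
        beta_o, se_o = ivw_meta_of_wald_ratios(pairs)
        assert abs(pooled.beta - beta_o) <= 1e-12
        assert abs(pooled.se - se_o) <= 1e-12

    @settings(derandomize=True, max_examples=60)
    @given(pair_inputs(min_k=2), st.floats(0.2, 5.0))
    def test_exposure_rescaling_equivariance(self, pairs, c):
        """Changing the exposure unit by factor c divides estimate and SE by c."""
        scaled = make_pairs(
            [p.exposure.beta * c for p in pairs],
            [p.outcome.beta for p in pairs],
            [p.outcome.se for p in pairs],
        )
        a, b = ivw_fixed(pairs), ivw_fixed(scaled)
        assert b.beta == pytest.approx(a.beta / c, rel=1e-10)
        assert b.se == pytest.approx(a.se / c, rel=1e-10)

    @settings(derandomize=True, max_examples=60)
    @given(pair_inputs(min_k=2), st.randoms(use_true_random=False))
    def test_instrument_order_is_irrelevant(self, pairs, rnd):
        shuffled = list(pairs)
        rnd.shuffle(shuffled)
        a = pool_with_model_selection(pairs)
        b = pool_with_model_selection(shuffled)
        assert abs(a.beta - b.beta) <= 1e-12
        assert abs(a.se - b.se) <= 1e-12
        assert a.model == b.model

    def test_ci_is_symmetric_wald_interval(self):
        pooled = ivw_fixed(make_pairs([0.03, 0.04], [0.001, 0.002], [0.004, 0.005]))
        assert pooled.ci_low < pooled.beta < pooled.ci_high
        assert (pooled.ci_high - pooled.ci_low) == pytest.approx(2 * Z_975 * pooled.se, abs=1e-12)


class TestHeterogeneity:
    def test_identical_ratios_no_dispersion(self):
        pairs = make_pairs([0.02, 0.04, 0.05], [0.01, 0.02, 0.025], [0.01, 0.01, 0.01])
        pooled = ivw_fixed(pairs)
        het = heterogeneity(pairs, pooled.beta)
        assert het.q == pytest.approx(0.0, abs=1e-18)
        assert het.i2 == 0.0
        assert het.tau2 == 0.0
        assert het.p_het == pytest.approx(1.0)

    def test_hand_computed_q(self):
        # ratios 0 and 1 with unit weights: Q = 1*(0-0.5)^2 + 1*(1-0.5)^2 = 0.5
        pairs = make_pairs([1.0, 1.0], [0.0, 1.0], [1.0, 1.0])
        het = heterogeneity(pairs, 0.5)
        assert het.q == pytest.approx(0.5, abs=1e-14)
        assert het.df == 1

    def test_needs_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            heterogeneity(make_pairs([0.03], [0.001], [0.004]), 0.0)

    @settings(derandomize=True, max_examples=60)
    @given(pair_inputs(min_k=2))
    def test_q_nonnegative_i2_in_unit_interval(self, pairs):
        pooled = ivw_fixed(pairs)
        het = pooled.het
        assert het.q >= 0
        assert 0.0 <= het.i2 < 1.0
        assert het.tau2 >= 0.0


class TestIvwRandom:
    def test_dersimonian_laird_hand_example(self):
        # Wald ratios 0 and 1, Wald SEs 0.1 each: w = 100, Q = 50,
        # tau2 = (Q - 1)/(sum w - sum w^2 / sum w) = 49/100 = 0.49,
        # random weights 1/(0.01 + 0.49) = 2 -> beta 0.5, se sqrt(1/4).
        pairs = make_pairs([1.0, 1.0], [0.0, 1.0], [0.1, 0.1])
        pooled = ivw_random(pairs)
        assert pooled.het.q == pytest.approx(50.0, abs=1e-10)
        assert pooled.het.tau2 == pytest.approx(0.49, abs=1e-12)
        assert pooled.het.i2 == pytest.approx(0.98, abs=1e-12)
        assert pooled.beta == pytest.approx(0.5, abs=1e-12)
        assert pooled.se == pytest.approx(0.5, abs=1e-12)
        assert pooled.model == "random"

    def test_zero_tau2_reduces_to_fixed(self):
        pairs = make_pairs([0.03, 0.04], [0.0015, 0.0020], [0.01, 0.01])
        fixed, random = ivw_fixed(pairs), ivw_random(pairs)
        assert random.het.tau2 == 0.0
        assert random.beta == pytest.approx(fixed.beta, abs=1e-12)
        assert random.se == pytest.approx(fixed.se, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(pair_inputs(min_k=2))
    def test_random_se_never_below_fixed(self, pairs):
        fixed, random = ivw_fixed(pairs), ivw_random(pairs)
        assert random.se >= fixed.se - 1e-15
        if fixed.het.tau2 == 0.0:
            assert random.se == pytest.approx(fixed.se, abs=1e-12)


class TestModelSelection:
    def test_insignificant_heterogeneity_keeps_fixed(self):
        from scipy.stats import chi2

        # k = 2, unit weights, ratios +/- d chosen so that p_het = 0.15 exactly
        d = math.sqrt(chi2.isf(0.15, 1) / 2.0)
        pairs = make_pairs([1.0, 1.0], [-d, d], [1.0, 1.0])
        pooled = pool_with_model_selection(pairs, het_alpha=0.05)
        assert pooled.het.p_het == pytest.approx(0.15, abs=1e-12)
        assert pooled.model == "fixed"

    def test_strong_heterogeneity_switches_to_random(self):
        from scipy.stats import chi2

        d = math.sqrt(chi2.isf(1e-4, 1) / 2.0)
        pairs = make_pairs([1.0, 1.0], [-d, d], [1.0, 1.0])
        pooled = pool_with_model_selection(pairs, het_alpha=0.05)
        assert pooled.het.p_het < 0.001
        assert pooled.model == "random"

    def test_single_instrument_stays_fixed(self):
        pooled = pool_with_model_selection(make_pairs([0.03], [0.001], [0.004]))
        assert pooled.model == "fixed"
        assert pooled.het.p_het is None


class TestOddsRatioTransform:
    def test_null_effect(self):
        pairs = make_pairs([0.03, 0.04], [0.0, 0.0], [0.004, 0.005])
        pooled = pool_with_model_selection(pairs, scale="log_odds")
        orr = to_odds_ratio(pooled)
        assert orr.or_point == pytest.approx(1.0)
        assert orr.or_ci_low == pytest.approx(math.exp(-Z_975 * pooled.se), rel=1e-12)
        assert orr.or_ci_high == pytest.approx(math.exp(Z_975 * pooled.se), rel=1e-12)

    def test_log_two_gives_or_two(self):
        (pair,) = make_pairs([1.0], [math.log(2.0)], [1e-9])
        pooled = ivw_fixed([pair], scale="log_odds")
        assert to_odds_ratio(pooled).or_point == pytest.approx(2.0, rel=1e-9)

    def test_published_style_interval(self):
        # beta 0.0488, se 0.006 -> OR 1.050, 95% CI (1.038, 1.062)
        (pair,) = make_pairs([1.0], [0.0488], [0.006])
        orr = to_odds_ratio(ivw_fixed([pair], scale="log_odds"))
        assert round(orr.or_point, 3) == 1.050
        assert round(orr.or_ci_low, 3) == 1.038
        assert round(orr.or_ci_high, 3) == 1.062

    def test_continuous_scale_is_rejected(self):
        pooled = ivw_fixed(make_pairs([0.03], [0.001], [0.004]), scale="continuous")
        with pytest.raises(ScaleMismatchError):
            to_odds_ratio(pooled)


class TestInstrumentStrength:
    def test_r2_single_snp_at_half_frequency(self):
        snp = SnpAssociation("rs1", "A", "G", 0.2, 0.01, eaf=0.5)
        assert instrument_r2([snp], 1.0) == pytest.approx(0.2**2 / 2)

    def test_r2_three_snp_arithmetic(self):
        snps = [
            SnpAssociation("rs11057830", "A", "G", 0.03, 0.01, eaf=0.15),
            SnpAssociation("rs2108622", "T", "C", 0.03, 0.01, eaf=0.21),
            SnpAssociation("rs964184", "G", "C", 0.04, 0.01, eaf=0.15),
        ]
        v = 0.0576  # (0.24 mg/L)^2
        expected = (
            2 * 0.15 * 0.85 * 0.0009 + 2 * 0.21 * 0.79 * 0.0009 + 2 * 0.15 * 0.85 * 0.0016
        ) / v
        assert instrument_r2(snps, v) == pytest.approx(expected, rel=1e-14)

    def test_r2_zero_betas(self):
        snp = SnpAssociation("rs1", "A", "G", 0.0, 0.01, eaf=0.3)
        assert instrument_r2([snp], 1.0) == 0.0

    def test_r2_missing_eaf(self):
        snp = SnpAssociation("rs1", "A", "G", 0.03, 0.01)
        with pytest.raises(ValueError, match="supply r2 directly"):
            instrument_r2([snp], 1.0)

    @pytest.mark.parametrize(
        "r2,n,k,f",
        [
            (0.0, 1000, 3, 0.0),
            (0.5, 103, 1, 101.0),
            # inverting F = 48 at n = 7781, k = 3 gives r2 = 144/7921
            (144.0 / 7921.0, 7781, 3, 48.0),
        ],
    )
    def test_f_closed_forms(self, r2, n, k, f):
        strength = f_statistic(r2, n, k)
        assert strength.f == pytest.approx(f, rel=1e-12)

    def test_f_domain_errors(self):
        with pytest.raises(ValueError):
            f_statistic(1.0, 100, 1)
        with pytest.raises(ValueError):
            f_statistic(0.1, 4, 3)


class TestDistributionAgreement:
    """Normal/chi-square tails agree with an independent high-precision
    reference (closed forms evaluated by sympy at 30 digits)."""

    def test_two_sided_normal_p(self):
        sympy = pytest.importorskip("sympy")
        for z in (0.31, 1.0, 1.959964, 3.5, 6.0):
            (pair,) = make_pairs([1.0], [z], [1.0])
            pooled = ivw_fixed([pair])
            ref = float(sympy.erfc(sympy.Float(z, 30) / sympy.sqrt(2)).evalf(30))
            assert pooled.pvalue == pytest.approx(ref, rel=1e-10)

    def test_chi_square_upper_tail(self):
        sympy = pytest.importorskip("sympy")
        # df = 1: P(Q > q) = erfc(sqrt(q/2)); df = 2: exp(-q/2)
        for q in (0.5, 2.0722, 12.0):
            d = math.sqrt(q / 2.0)
            het = heterogeneity(make_pairs([1.0, 1.0], [-d, d], [1.0, 1.0]), 0.0)
            ref = float(sympy.erfc(sympy.sqrt(sympy.Float(q, 30) / 2)).evalf(30))
            assert het.p_het == pytest.approx(ref, rel=1e-10)
        for q in (1.0, 7.3):
            r = math.sqrt(q / 2.0)  # ratios (-r, 0, r) with unit weights give Q = 2r^2
            pairs = make_pairs([1.0] * 3, [-r, 0.0, r], [1.0] * 3)
            het = heterogeneity(pairs, 0.0)
            ref = float(sympy.exp(-sympy.Float(q, 30) / 2).evalf(30))
            assert het.p_het == pytest.approx(ref, rel=1e-10)
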