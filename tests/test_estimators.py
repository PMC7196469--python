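"""Wald ratios, IVW, MR-Egger and weighted-median estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrkit import (
    EstimationError,
    egger,
    estimate_all,
    ivw,
    wald_ratios,
    weighted_median,
)
from mrkit.estimators import _weighted_median
from conftest import make_set


class TestWaldRatios:
    def test_published_snp_arithmetic(self, wc_chd):
        r = {x.rsid: x for x in wald_ratios(wc_chd)}["rs6567160"]
        assert r.theta == pytest.approx(0.058 / 0.05)
        assert r.se_theta == pytest.approx(0.011 / 0.05)
        assert r.weight == pytest.approx(r.se_theta ** -2)

    def test_zero_numerator_gives_zero_ratio(self):
        s = make_set([0.1], [0.01], [0.0], [0.02])
        r = wald_ratios(s)[0]
        assert r.theta == 0.0 and r.se_theta == pytest.approx(0.2)

    def test_sign_cancellation(self):
        a = wald_ratios(make_set([0.1], [0.01], [0.05], [0.02]))[0]
        b = wald_ratios(make_set([-0.1], [0.01], [-0.05], [0.02]))[0]
        assert a.theta == b.theta and a.se_theta == b.se_theta


class TestIvw:
    def test_single_instrument_equals_its_wald_ratio(self):
        s = make_set([0.1], [0.01], [0.05], [0.02])
        est = ivw(s, model="fixed")
        r = wald_ratios(s)[0]
        assert est.beta == pytest.approx(r.theta)
        assert est.se == pytest.approx(r.se_theta)
        assert est.method == "wald_single"

    def test_duplicating_instruments_shrinks_fixed_se_by_sqrt_k(self):
        base = make_set([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.09, 0.14], [0.02] * 3)
        k = 4
        dup = make_set(
            [0.1, 0.2, 0.3] * k, [0.01] * 3 * k, [0.05, 0.09, 0.14] * k, [0.02] * 3 * k
        )
        e1, ek = ivw(base, "fixed"), ivw(dup, "fixed")
        assert ek.beta == pytest.approx(e1.beta)
        assert ek.se == pytest.approx(e1.se / math.sqrt(k))

    def test_fixed_and_random_point_estimates_coincide(self, wc_chd):
        fe, re = ivw(wc_chd, "fixed"), ivw(wc_chd, "multiplicative_random")
        assert fe.beta == re.beta
        assert re.se >= fe.se
        assert re.dispersion >= 1.0
        assert fe.or_point == pytest.approx(math.exp(fe.beta))

    def test_empty_set_rejected(self):
        s = make_set([0.1], [0.01], [0.05], [0.02])
        from mrkit import filter_instruments

        with pytest.raises(EstimationError):
            ivw(filter_instruments(s, 1e-300))


class TestEgger:
    def test_exact_linear_data_recovered_to_machine_precision(self):
        slope, icpt = 0.45, 0.0
        bx = np.array([0.02, 0.03, 0.05, 0.07, 0.04])
        s = make_set(bx, [0.003] * 5, icpt + slope * bx, [0.01] * 5)
        est = egger(s)
        assert est.beta == pytest.approx(slope, abs=1e-12)
        assert est.intercept == pytest.approx(icpt, abs=1e-12)

    def test_directional_pleiotropy_appears_in_intercept(self):
        slope, alpha = 0.45, 0.02
        bx = np.array([0.02, 0.03, 0.05, 0.07, 0.04])
        s = make_set(bx, [0.003] * 5, alpha + slope * bx, [0.01] * 5)
        est = egger(s)
        assert est.intercept == pytest.approx(alpha, abs=1e-12)
        assert est.beta == pytest.approx(slope, abs=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(EstimationError, match=">= 3"):
            egger(make_set([0.1, 0.2], [0.01] * 2, [0.05, 0.09], [0.02] * 2))

    def test_no_spread_is_singular(self):
        with pytest.raises(EstimationError, match="singular"):
            egger(make_set([0.1] * 3, [0.01] * 3, [0.04, 0.05, 0.06], [0.02] * 3))

    def test_dispersion_floored_at_one(self):
        # Nearly-collinear data would give residual scale << 1 without the floor.
        bx = np.array([0.02, 0.03, 0.05, 0.07])
        s = make_set(bx, [0.003] * 4, 0.45 * bx + 1e-8, [0.01] * 4)
        assert egger(s).dispersion == 1.0


class TestWeightedMedian:
    def test_symmetric_equal_weights(self, three_equal_ratios):
        est = weighted_median(three_equal_ratios, n_boot=10, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_point_estimate_deterministic_across_boot_seeds(self, wc_chd):
        a = weighted_median(wc_chd, n_boot=50, seed=1)
        b = weighted_median(wc_chd, n_boot=50, seed=2)
        assert a.beta == b.beta
        assert a.se != b.se  # bootstrap SE is seed-dependent

    def test_bounded_by_extreme_ratios(self, wc_chd):
        thetas = [r.theta for r in wald_ratios(wc_chd)]
        est = weighted_median(wc_chd, n_boot=10, seed=1)
        assert min(thetas) <= est.beta <= max(thetas)

    def test_nboot_validated(self, wc_chd):
        from mrkit import ConfigurationError

        with pytest.raises(ConfigurationError):
            weighted_median(wc_chd, n_boot=0)


def brute_force_weighted_median(theta, weight, rsid):
    """Independent oracle: plain cumulative-weight scan over sorted candidates."""
    pairs = sorted(zip(theta, rsid, weight), key=lambda p: (p[0], p[1]))
    total = sum(w for _, _, w in pairs)
    t = [p[0] for p in pairs]
    p = [w / total for _, _, w in pairs]
    s = []
    run = 0.0
    for pj in p:
        s.append(run + pj / 2)
        run += pj
    if s[0] >= 0.5:
        return t[0]
    if s[-1] <= 0.5:
        return t[-1]
    for j in range(len(s) - 1):
        if s[j] <= 0.5 <= s[j + 1]:
            if s[j + 1] == s[j]:
                return t[j]
            return t[j] + (0.5 - s[j]) * (t[j + 1] - t[j]) / (s[j + 1] - s[j])
    raise AssertionError("unreachable")


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.floats(-3, 3).map(lambda v: round(v, 3)),
            st.floats(0.05, 2.0),
        ),
        min_size=1,
        max_size=6,
    )
)
def test_weighted_median_matches_brute_force_oracle(pairs):
    """Interpolation implementation equals the direct cumulative-weight scan,
    including adversarial ties produced by rounding thetas to 3 decimals."""
    theta = np.array([t for t, _ in pairs])
    weight = np.array([w for _, w in pairs])
    rsid = [f"rs{k}" for k in range(len(pairs))]
    ours = _weighted_median(theta, weight, rsid)
    oracle = brute_force_weighted_median(theta.tolist(), weight.tolist(), rsid)
    assert ours == pytest.approx(oracle, abs=1e-12)


@pytest.mark.parametrize("estimator", ["ivw", "egger", "weighted_median"])
def test_allele_orientation_invariance(wc_chd, rng, estimator):
    """Negating (beta_exp, beta_out) of a random instrument subset leaves
    every estimator's beta/se/p unchanged."""
    flip = rng.random(len(wc_chd)) < 0.5
    flipped = make_set(
        [(-1 if f else 1) * i.beta_exp for i, f in zip(wc_chd, flip)],
        [i.se_exp for i in wc_chd],
        [(-1 if f else 1) * i.beta_out for i, f in zip(wc_chd, flip)],
        [i.se_out for i in wc_chd],
        rsids=list(wc_chd.rsids),
    )
    call = {
        "ivw": lambda s: ivw(s),
        "egger": egger,
        "weighted_median": lambda s: weighted_median(s, n_boot=50, seed=7),
    }[estimator]
    a, b = call(wc_chd), call(flipped)
    assert a.beta == pytest.approx(b.beta, rel=1e-12)
    assert a.se == pytest.approx(b.se, rel=1e-12)
    assert a.pval == pytest.approx(b.pval, rel=1e-9)


@pytest.mark.parametrize("estimator", ["ivw", "egger", "weighted_median"])
def test_scale_equivariance(wc_chd, estimator):
    """Rescaling the exposure by c divides causal beta and se by c exactly."""
    c = 2.5
    scaled = make_set(
        [i.beta_exp * c for i in wc_chd],
        [i.se_exp * c for i in wc_chd],
        [i.beta_out for i in wc_chd],
        [i.se_out for i in wc_chd],
        rsids=list(wc_chd.rsids),
    )
    call = {
        "ivw": lambda s: ivw(s),
        "egger": egger,
        "weighted_median": lambda s: weighted_median(s, n_boot=50, seed=7),
    }[estimator]
    a, b = call(wc_chd), call(scaled)
    assert b.beta == pytest.approx(a.beta / c, rel=1e-12)
    assert b.se == pytest.approx(a.se / c, rel=1e-12)


class TestEstimateAll:
    def test_bundled_set_gives_three_concordant_estimates(self, wc_chd):
        ests = estimate_all(wc_chd, n_boot=50)
        assert [e.method for e in ests] == ["ivw_mre", "egger", "weighted_median"]
        assert all(e.beta > 0 for e in ests)
        assert all(e.n_snp == 46 for e in ests)
        assert all(e.ci_low < e.beta < e.ci_high for e in ests)

    def test_two_snp_set_skips_egger_and_median(self):
        s = make_set([0.1, 0.2], [0.01] * 2, [0.05, 0.09], [0.02] * 2)
        ests = estimate_all(s, n_boot=10)
        assert [e.method for e in ests] == ["ivw_mre"]

    def test_empty_set_errors(self):
        from mrkit import filter_instruments

        s = make_set([0.1], [0.01], [0.05], [0.02])
        with pytest.raises(EstimationError):
            estimate_all(filter_instruments(s, 1e-300))
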