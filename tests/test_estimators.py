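import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate import (
    DataError,
    DomainError,
    SimulationConfig,
    cochran_q,
    egger,
    harmonize,
    ivw,
    leave_one_out,
    simulate_study,
    wald_ratio,
    weighted_median,
)
from mrmediate.harmonize import HarmonizedSet


def hset(beta_exp, se_exp, beta_out, se_out):
    n = len(beta_exp)
    return HarmonizedSet(
        exposure_name="X",
        outcome_name="Y",
        snp_ids=np.array([f"rs{i+1}" for i in range(n)], dtype=object),
        beta_exp=np.asarray(beta_exp, float),
        se_exp=np.asarray(se_exp, float),
        beta_out=np.asarray(beta_out, float),
        se_out=np.asarray(se_out, float),
    )


# ---------------------------------------------------------------- Wald ratio
def test_wald_ratio_hand_values():
    assert wald_ratio(0.1, 0.01, 0.05, 0.01) == pytest.approx((0.5, 0.1))
    assert wald_ratio(0.1, 0.01, 0.0, 0.01)[0] == 0.0
    assert wald_ratio(-0.1, 0.01, 0.05, 0.01) == pytest.approx((-0.5, 0.1))


def test_wald_ratio_zero_exposure_is_domain_error():
    with pytest.raises(DomainError):
        wald_ratio(0.0, 0.01, 0.05, 0.01)


# ---------------------------------------------------------------- IVW
def test_ivw_single_snp_reduces_to_wald_ratio():
    h = hset([0.1], [0.01], [0.05], [0.01])
    est = ivw(h)
    ratio, ratio_se = wald_ratio(0.1, 0.01, 0.05, 0.01)
    assert est.beta == pytest.approx(ratio)
    assert est.se == pytest.approx(ratio_se)
    assert est.q_stat is None


def test_ivw_identical_ratios_closed_form():
    # two SNPs, both ratio 0.5 with ratio SE 0.1 -> Q = 0, se = 0.1/sqrt(2)
    h = hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.01, 0.02])
    est = ivw(h)
    assert est.beta == pytest.approx(0.5)
    assert est.q_stat == pytest.approx(0.0, abs=1e-12)
    assert est.se == pytest.approx(0.1 / np.sqrt(2))
    assert ivw(h, "fixed").se == pytest.approx(est.se)


def test_ivw_two_snp_heterogeneous_hand_values():
    # ratios 0.5 and 1.0 with ratio SE 0.1 each: w = 100 each
    h = hset([0.1, 0.1], [0.01, 0.01], [0.05, 0.10], [0.01, 0.01])
    est = ivw(h)
    fixed = ivw(h, "fixed")
    assert est.beta == pytest.approx(0.75)
    assert est.q_stat == pytest.approx(12.5)
    assert est.q_df == 1
    assert fixed.se == pytest.approx(1.0 / np.sqrt(200))
    assert est.se == pytest.approx(fixed.se * np.sqrt(12.5))


def test_ivw_empty_set_is_data_error():
    h = hset([], [], [], [])
    with pytest.raises(DataError):
        ivw(h)


@settings(deadline=None, max_examples=40)
@given(st.integers(min_value=0, max_value=10_000))
def test_random_effects_se_never_below_fixed(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 12))
    h = hset(
        rng.uniform(0.02, 0.2, n),
        rng.uniform(0.005, 0.02, n),
        rng.normal(0, 0.05, n),
        rng.uniform(0.005, 0.05, n),
    )
    assert ivw(h, "random").se >= ivw(h, "fixed").se - 1e-15


def test_ivw_and_egger_invariant_to_paired_sign_flips(rng):
    n = 12
    h = hset(
        rng.uniform(0.02, 0.2, n),
        rng.uniform(0.005, 0.02, n),
        rng.normal(0.02, 0.05, n),
        rng.uniform(0.005, 0.05, n),
    )
    signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    flipped = hset(h.beta_exp * signs, h.se_exp, h.beta_out * signs, h.se_out)
    assert ivw(h).beta == pytest.approx(ivw(flipped).beta)
    assert egger(h).beta == pytest.approx(egger(flipped).beta)
    assert egger(h).egger_intercept == pytest.approx(egger(flipped).egger_intercept)


# ---------------------------------------------------------------- Egger
def test_egger_recovers_exact_linear_data():
    beta_exp = np.array([0.05, 0.1, 0.15, 0.2])
    beta_out = 0.02 + 0.4 * beta_exp
    h = hset(beta_exp, [0.01] * 4, beta_out, [0.01] * 4)
    est = egger(h)
    assert est.egger_intercept == pytest.approx(0.02)
    assert est.beta == pytest.approx(0.4)
    assert est.q_stat == pytest.approx(0.0, abs=1e-12)


def test_egger_slope_matches_fixed_ivw_with_zero_intercept_exact_data():
    beta_exp = np.array([0.05, 0.1, 0.15, 0.2])
    beta_out = 0.4 * beta_exp  # exactly through the origin
    h = hset(beta_exp, [0.01] * 4, beta_out, [0.01] * 4)
    assert egger(h).beta == pytest.approx(ivw(h, "fixed").beta)


def test_egger_preconditions():
    with pytest.raises(DataError):
        egger(hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))
    with pytest.raises(DataError, match="degenerate"):
        egger(hset([0.1, 0.1, 0.1], [0.01] * 3, [0.05, 0.06, 0.04], [0.01] * 3))


def test_egger_intercept_recovers_directional_pleiotropy():
    # every instrument pleiotropic with mean 0.01 (exposure-increasing frame)
    intercepts = []
    for seed in range(40):
        cfg = SimulationConfig(
            n_snps=200, prop_invalid=1.0, pleiotropy_mean=0.01, pleiotropy_sd=0.005, seed=seed
        )
        s = simulate_study(cfg)
        kept = s.exposure_stats[s.exposure_stats.pval < 5e-5]
        intercepts.append(egger(harmonize(kept, s.mediator_stats)).egger_intercept)
    intercepts = np.array(intercepts)
    mc_sd = intercepts.std(ddof=1) / np.sqrt(len(intercepts))
    assert abs(intercepts.mean() - 0.01) < 3 * mc_sd


# ---------------------------------------------------------------- weighted median
def test_weighted_median_constant_ratios():
    h = hset([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.01] * 3)
    assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(0.5)


def test_weighted_median_equal_weights_interpolates_to_middle():
    h = hset([0.1, 0.1, 0.1], [0.01] * 3, [0.1, 0.2, 0.3], [0.01] * 3)
    assert weighted_median(h, n_boot=50, seed=0).beta == pytest.approx(2.0)


def test_weighted_median_seeded_se_is_reproducible():
    h = hset([0.1, 0.12, 0.2, 0.3], [0.01] * 4, [0.05, 0.07, 0.11, 0.14], [0.01] * 4)
    a = weighted_median(h, n_boot=200, seed=7)
    b = weighted_median(h, n_boot=200, seed=7)
    assert a.se == b.se
    assert a.beta == b.beta


def _cumulative_weight_median_oracle(ratios, weights):
    """Loop-wise weighted median: walk the sorted ratios accumulating
    centred normalized weights and linearly interpolate at 0.5."""
    pairs = sorted(zip(ratios, weights))
    total = sum(w for _, w in pairs)
    cum = 0.0
    grid = []
    for r, w in pairs:
        grid.append((cum + w / 2.0) / total)
        cum += w
    if 0.5 <= grid[0]:
        return pairs[0][0]
    for i in range(len(grid) - 1):
        lo, hi = grid[i], grid[i + 1]
        if lo <= 0.5 <= hi:
            frac = (0.5 - lo) / (hi - lo)
            return pairs[i][0] + frac * (pairs[i + 1][0] - pairs[i][0])
    return pairs[-1][0]


def test_weighted_median_matches_cumulative_weight_oracle(rng):
    for _ in range(200):
        n = int(rng.integers(3, 8))
        beta_exp = rng.uniform(0.05, 0.3, n)
        se_out = rng.uniform(0.005, 0.05, n)
        beta_out = rng.normal(0.02, 0.05, n)
        h = hset(beta_exp, [0.01] * n, beta_out, se_out)
        est = weighted_median(h, n_boot=2, seed=0)
        ratios = beta_out / beta_exp
        weights = (beta_exp / se_out) ** 2
        assert est.beta == pytest.approx(
            _cumulative_weight_median_oracle(list(ratios), list(weights))
        )


# ---------------------------------------------------------------- Cochran's Q
def test_cochran_q_identical_ratios_is_zero():
    h = hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.01, 0.02])
    q, df, p = cochran_q(h)
    assert q == pytest.approx(0.0, abs=1e-12)
    assert df == 1
    assert p == pytest.approx(1.0)


def test_cochran_q_two_snp_hand_value():
    h = hset([0.1, 0.1], [0.01, 0.01], [0.05, 0.10], [0.01, 0.01])
    q, df, _ = cochran_q(h)
    assert q == pytest.approx(12.5)
    assert df == 1


def test_cochran_q_single_snp_is_data_error():
    with pytest.raises(DataError):
        cochran_q(hset([0.1], [0.01], [0.05], [0.01]))


def test_cochran_q_calibrated_under_null():
    # null causal effect, no pleiotropy: Q/df should average about 1
    qdf = []
    for seed in range(30):
        cfg = SimulationConfig(n_snps=100, beta_xm=0.0, seed=seed)
        s = simulate_study(cfg)
        kept = s.exposure_stats[s.exposure_stats.pval < 5e-5]
        q, df, _ = cochran_q(harmonize(kept, s.mediator_stats))
        qdf.append(q / df)
    assert np.mean(qdf) == pytest.approx(1.0, abs=0.1)


# ---------------------------------------------------------------- leave-one-out
def test_leave_one_out_identical_snps_all_equal_full_estimate():
    h = hset([0.1] * 4, [0.01] * 4, [0.05] * 4, [0.01] * 4)
    full = ivw(h)
    entries = leave_one_out(h)
    assert len(entries) == 4
    for e in entries:
        assert e.estimate.beta == pytest.approx(full.beta)
        assert not e.influential


def test_leave_one_out_matches_ivw_on_reduced_set(rng):
    n = 8
    h = hset(
        rng.uniform(0.05, 0.3, n),
        rng.uniform(0.005, 0.02, n),
        rng.normal(0.02, 0.03, n),
        rng.uniform(0.005, 0.05, n),
    )
    entries = leave_one_out(h)
    assert len(entries) == n
    for k, entry in enumerate(entries):
        assert entry.omitted_snp_id == str(h.snp_ids[k])
        expected = ivw(h.without(k))
        assert entry.estimate.beta == expected.beta
        assert entry.estimate.se == expected.se


def test_leave_one_out_needs_three_snps():
    with pytest.raises(DataError):
        leave_one_out(hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2))
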