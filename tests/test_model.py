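"""Closed-form cascade solutions against numerical integration and limits."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rnaflow.model import (
    FOUR_STEP,
    THREE_STEP,
    GeneModel,
    KineticParams,
    delayed_time,
    exit_rates,
    half_life,
    hypoexponential_share,
    predict_gene_curves,
    share_new_analytic,
    steady_state_amounts,
    steady_state_ratios,
)


def integrate_cascade(rates, times):
    """Independent oracle: integrate the relaxation ODEs to each endpoint."""
    rates = np.asarray(rates, dtype=float)

    def rhs(_, x):
        prev = np.concatenate([[1.0], x[:-1]])
        return rates * (prev - x)

    out = np.empty((len(rates), len(times)))
    for k, t in enumerate(times):
        if t == 0:
            out[:, k] = 0.0
            continue
        sol = solve_ivp(rhs, (0.0, t), np.zeros(len(rates)),
                        rtol=1e-12, atol=1e-14, method="DOP853")
        out[:, k] = np.clip(sol.y[:, -1], 0.0, 1.0)
    return out


class TestHypoexponentialShare:
    def test_zero_time_gives_zero_shares(self):
        s = hypoexponential_share([0.1, 0.02, 0.5], 0.0)
        assert np.all(s == 0.0)

    def test_single_stage_half_life(self):
        # one stage at rate ln2/22 reaches half saturation at t = 22
        rate = np.log(2) / 22.0
        s = hypoexponential_share([rate], 22.0)
        assert s[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_saturation_at_long_times(self):
        s = hypoexponential_share([0.05, 0.01, 0.2], 1e5)
        assert np.all(s > 1 - 1e-9)

    def test_matches_ode_oracle_random_rates(self):
        rng = np.random.default_rng(1)
        times = np.linspace(0.0, 300.0, 8)
        for _ in range(15):
            n = int(rng.integers(2, 5))
            rates = np.exp(rng.uniform(np.log(1e-3), np.log(2.0), n))
            ana = hypoexponential_share(rates, times)
            ode = integrate_cascade(rates, times)
            assert np.max(np.abs(ana - ode)) < 1e-8

    @pytest.mark.parametrize("gap", [1e-5, 1e-7, 0.0])
    def test_near_degenerate_rates_stay_accurate(self, gap):
        rates = np.array([0.05, 0.05 * (1 + gap), 0.002])
        times = np.linspace(0.0, 400.0, 8)
        ana = hypoexponential_share(rates, times)
        ode = integrate_cascade(rates, times)
        assert np.max(np.abs(ana - ode)) < 1e-8

    def test_cascade_ordering_and_range(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            rates = np.exp(rng.uniform(np.log(1e-3), np.log(2.0), 4))
            t = np.linspace(0.0, 500.0, 30)
            s = hypoexponential_share(rates, t)
            assert np.all(s >= 0.0) and np.all(s <= 1.0)
            # later stages lag earlier ones (stochastic dominance)
            assert np.all(np.diff(s, axis=0) <= 1e-12)
            # monotone accumulation in time
            assert np.all(np.diff(s, axis=1) >= -1e-12)

    def test_fast_stage_becomes_transparent(self):
        # as r2 -> inf the second stage tracks the first
        t = np.linspace(1.0, 200.0, 10)
        s1 = hypoexponential_share([0.02], t)[0]
        s2 = hypoexponential_share([0.02, 500.0], t)[1]
        assert np.max(np.abs(s1 - s2)) < 1e-3

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            hypoexponential_share([0.1], -1.0)


class TestDelayedTime:
    @pytest.mark.parametrize(
        "t,d,v,delta,expected",
        [(15.0, 10.0, 1.0, 5.0, 0.0),     # clamped negative
         (60.0, 10.0, 1.0, 5.0, 45.0),
         (60.0, 0.0, None, 5.0, 55.0)],   # 3'-terminal exon needs no v
    )
    def test_examples(self, t, d, v, delta, expected):
        assert delayed_time(t, d, v, delta) == expected

    def test_vectorized_clamp(self):
        tt = delayed_time(np.array([0.0, 5.0, 10.0, 100.0]), 2.0, 1.0, 5.0)
        assert np.all(tt >= 0.0)
        assert tt[-1] == 93.0


@pytest.fixture
def four_step_params():
    return KineticParams(k1=0.05, k2=0.01, gamma3=None, k3=0.3, gamma4=0.02,
                         v=1.5, variant=FOUR_STEP)


@pytest.fixture
def three_step_params():
    return KineticParams(k1=0.04, k2=0.012, gamma3=0.08, v=2.0,
                         variant=THREE_STEP)


class TestExitRates:
    def test_nuclear_exit_sums_export_and_decay(self):
        p = KineticParams(k1=0.05, k2=0.01, gamma2=0.03, gamma3=0.1,
                          v=1.0, variant=THREE_STEP)
        r = exit_rates(p)
        assert r[1] == pytest.approx(0.04)

    def test_three_step_has_three_stages(self, three_step_params):
        assert len(exit_rates(three_step_params)) == 3

    def test_four_step_third_rate_is_transport_not_decay(self, four_step_params):
        r = exit_rates(four_step_params)
        assert len(r) == 4
        assert r[2] == four_step_params.k3


class TestPredictGeneCurves:
    def test_everything_zero_before_delay(self):
        gene = GeneModel("g", 10.0, (0.2,), False, "cytosol")
        p = KineticParams(k2=0.01, gamma3=0.05, variant=THREE_STEP)
        curves = predict_gene_curves(gene, p, [5.0])
        assert np.all(curves.share_new == 0.0)

    def test_exon_delay_is_pure_translation(self, three_step_params):
        # an exon at d = v*10 shows the d=0 curve shifted by 10 minutes
        v = three_step_params.v
        gene = GeneModel("g", 30.0, (0.0, v * 10.0), True, "cytosol")
        t = np.array([20.0, 40.0, 80.0, 160.0])
        near = predict_gene_curves(gene, three_step_params, t)
        far = predict_gene_curves(gene, three_step_params, t + 10.0)
        a = near[(near.region == "exon_0") & (near.compartment == "cyto")]
        b = far[(far.region == "exon_1") & (far.compartment == "cyto")]
        np.testing.assert_allclose(
            a.share_new.to_numpy(), b.share_new.to_numpy(), atol=1e-12
        )

    def test_matches_ode_oracle_with_shifted_time(self, four_step_params):
        gene = GeneModel("g", 20.0, (0.5, 6.0), True, "membrane")
        t = np.array([15.0, 30.0, 60.0, 120.0, 180.0])
        curves = predict_gene_curves(gene, four_step_params, t)
        rates = exit_rates(four_step_params)
        for (region, comp), sub in curves.groupby(["region", "compartment"]):
            d = (gene.intron_distance_kb if region == "intronic"
                 else sub.d_kb.iloc[0])
            tt = np.maximum(0.0, t - d / four_step_params.v - 5.0)
            stage = {"intron-nuc": 0}.get(f"{region}-{comp}")
            stage = {("intronic", "nuc"): 0, ("exon_0", "nuc"): 1,
                     ("exon_1", "nuc"): 1, ("exon_0", "cyto"): 2,
                     ("exon_1", "cyto"): 2, ("exon_0", "mem"): 3,
                     ("exon_1", "mem"): 3}[(region, comp)]
            oracle = integrate_cascade(rates[: stage + 1], tt)[stage]
            np.testing.assert_allclose(
                sub.share_new.to_numpy(), oracle, atol=1e-8
            )

    def test_reduced_model_has_no_intron_and_no_elongation(self):
        gene = GeneModel("g", 10.0, (0.2,), False, "membrane")
        p = KineticParams(k2=0.02, k3=0.3, gamma4=0.04, variant=FOUR_STEP)
        curves = predict_gene_curves(gene, p, [30.0, 60.0])
        assert set(curves.compartment) == {"nuc", "cyto", "mem"}
        assert "intronic" not in set(curves.region)


class TestSteadyState:
    def test_membrane_over_cytosol_is_transport_over_decay(self, four_step_params):
        ratios = steady_state_ratios(four_step_params)
        expected = four_step_params.k3 / four_step_params.gamma4
        assert ratios["mem_over_cyto"] == pytest.approx(expected, rel=1e-12)

    def test_tfrc_like_ratio_value(self):
        p = KineticParams(k1=0.05, k2=0.01, k3=0.502, gamma4=0.02,
                          v=1.0, variant=FOUR_STEP)
        assert steady_state_ratios(p)["mem_over_cyto"] == pytest.approx(25.1)

    def test_ratios_match_long_time_ode_of_absolute_system(self, three_step_params):
        # independent check: integrate the absolute cascade with production
        # p = 1 to steady state and compare compartment ratios
        p = three_step_params
        rates_out = [p.k1, p.r2, p.gamma3]
        inflow = [p.k1, p.k2]

        def rhs(_, x):
            dx = np.empty(3)
            dx[0] = 1.0 - rates_out[0] * x[0]
            dx[1] = inflow[0] * x[0] - rates_out[1] * x[1]
            dx[2] = inflow[1] * x[1] - rates_out[2] * x[2]
            return dx

        sol = solve_ivp(rhs, (0, 50000.0), np.zeros(3), rtol=1e-12, atol=1e-12)
        x1, x2, x3 = sol.y[:, -1]
        r = steady_state_ratios(p)
        assert r["nucmat_over_cyto"] == pytest.approx(x2 / x3, rel=1e-6)
        assert r["nuc_total_over_cyto"] == pytest.approx((x1 + x2) / x3, rel=1e-6)
        assert r["nucmat_over_cyto"] == pytest.approx(p.gamma3 / p.k2, rel=1e-12)


class TestHalfLife:
    def test_inverse_pairs(self):
        assert half_life(np.log(2) / 78.0) == pytest.approx(78.0)
        assert half_life(2.0) == pytest.approx(0.34657, abs=1e-4)

    def test_monotone_decreasing(self):
        rates = np.array([0.001, 0.01, 0.1, 1.0])
        hl = np.log(2) / rates
        assert np.all(np.diff(hl) < 0)

    def test_nonpositive_rate_is_missing(self):
        assert np.isnan(half_life(0.0))
        assert np.isnan(half_life(-1.0))


class TestShareNewAnalytic:
    def test_returns_named_compartments(self):
        s = share_new_analytic([0.05, 0.01, 0.1, 0.02], 60.0)
        assert 0 < s.x4_mem < s.x3_cyto < s.x2_nucmat < s.x1_pre < 1

    def test_three_stage_has_no_membrane(self):
        s = share_new_analytic([0.05, 0.01, 0.1], 60.0)
        assert s.x4_mem is None


class TestValidation:
    def test_gene_model_rejects_distance_beyond_length(self):
        with pytest.raises(ValueError):
            GeneModel("g", 5.0, (6.0,), True, "cytosol")

    def test_params_require_variant_consistency(self):
        with pytest.raises(ValueError):
            KineticParams(k2=0.01, gamma3=0.1, k3=0.2, gamma4=0.1,
                          variant=THREE_STEP)
        with pytest.raises(ValueError):
            KineticParams(k2=0.01, variant=FOUR_STEP)
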