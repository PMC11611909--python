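"""Weighting, constraints, multistart recovery, QC and model selection."""

import math

import numpy as np
import pandas as pd
import pytest

from rnaflow.abundance import AbundanceFactors
from rnaflow.fitting import (
    FitConfig,
    FitResult,
    KineticModelFitter,
    build_ratio_constraints,
    classify_localization,
    compare_nuclear_decay_models,
    compute_bic,
    compute_weights,
    multistart_fit,
    quality_control,
)
from rnaflow.model import FOUR_STEP, THREE_STEP, GeneModel, KineticParams
from rnaflow.synthetic import (
    SimulationDesign,
    simulate_labeling_timeseries,
    simulate_steady_state_expression,
)

FACTORS = AbundanceFactors(39 / 99, 15 / 99, 1 - 39 / 99 - 15 / 99,
                           0.004, 0.002, 0.004)


class TestClassifyLocalization:
    @pytest.mark.parametrize(
        "enrichment,expected",
        [(1.0, "cytosol"), (25.1, "membrane"), (2.0, "undefined"),
         (1.49, "cytosol"), (3.0, "membrane")],
    )
    def test_cutoffs(self, enrichment, expected):
        assert classify_localization(enrichment * 10.0, 10.0) == expected

    def test_zero_cytosolic_expression_is_missing(self):
        assert classify_localization(5.0, 0.0) == "missing"


def _obs_frame(se_by_point):
    rows = []
    for (region, comp, t), se in se_by_point.items():
        rows.append({"region": region, "compartment": comp, "time_min": t,
                     "share_mean": 0.5, "share_se": se})
    return pd.DataFrame.from_records(rows)


class TestComputeWeights:
    def test_floor_binds_for_small_ses(self):
        obs = _obs_frame({("e0", "nuc", t): 0.02 for t in (15, 30, 60)})
        w = compute_weights(obs)
        np.testing.assert_allclose(w, 1.0 / 0.06)

    def test_mixed_se_arithmetic(self):
        # one point at 0.10 while the series averages 0.06:
        # mixed = 0.5*0.10 + 0.5*0.06 = 0.08 -> weight 12.5
        obs = _obs_frame({("e0", "nuc", 15): 0.10, ("e0", "nuc", 30): 0.02})
        w = compute_weights(obs)
        assert w[0] == pytest.approx(1.0 / 0.08)
        assert w[0] == pytest.approx(12.5)

    def test_floor_invariance_below_floor(self):
        obs_a = _obs_frame({("e0", "cyto", t): 0.04 for t in (15, 30)})
        obs_b = _obs_frame({("e0", "cyto", t): 0.02 for t in (15, 30)})
        np.testing.assert_allclose(compute_weights(obs_a),
                                   compute_weights(obs_b))


class TestBuildRatioConstraints:
    def test_printed_bound_arithmetic(self):
        # membrane/cytosol ratio 25.1 with SE 1.1 -> [19.6, 30.6]
        row = {"tpm_nuc": 10.0, "se_nuc": 0.5, "tpm_cyto": 1.0,
               "se_cyto": 0.0, "tpm_mem": 25.1, "se_mem": 1.1}
        factors = AbundanceFactors(0.7, 0.15, 0.15, 0, 0, 0)
        cons = build_ratio_constraints(row, factors, FitConfig(), FOUR_STEP)
        lo, hi = cons["mem_over_cyto"]
        assert lo == pytest.approx(19.6, abs=1e-9)
        assert hi == pytest.approx(30.6, abs=1e-9)

    def test_zero_se_widens_to_relative_band(self):
        row = {"tpm_nuc": 10.0, "se_nuc": 0.0, "tpm_cyto": 1.0, "se_cyto": 0.0,
               "tpm_mem": 5.0, "se_mem": 0.0}
        cons = build_ratio_constraints(row, FACTORS, FitConfig(), FOUR_STEP)
        lo, hi = cons["nuc_over_cyto"]
        assert lo < hi
        assert hi / lo - 1 < 1e-5

    def test_negative_lower_bound_clipped_positive(self):
        row = {"tpm_nuc": 1.0, "se_nuc": 2.0, "tpm_cyto": 1.0, "se_cyto": 0.0,
               "tpm_mem": 5.0, "se_mem": 0.0}
        cons = build_ratio_constraints(row, FACTORS, FitConfig(), THREE_STEP)
        assert cons["nuc_over_cyto"][0] > 0


@pytest.fixture(scope="module")
def noise_free_case():
    design = SimulationDesign(seed=0, tpm_noise_cv=0.0)
    gene = GeneModel("gnf", 18.0, (0.2, 4.0, 9.0, 13.0), True, "cytosol")
    params = KineticParams(k1=0.06, k2=0.009, gamma3=0.05, v=1.8,
                           variant=THREE_STEP)
    obs = simulate_labeling_timeseries(params, gene, design, seed=0,
                                       noise=False)
    ss = simulate_steady_state_expression(params, gene, design, seed=0,
                                          noise=False).iloc[0].to_dict()
    return gene, params, obs, ss


class TestMultistartFit:
    def test_noise_free_recovery_within_one_percent(self, noise_free_case):
        gene, truth, obs, ss = noise_free_case
        cfg = FitConfig(seed=1, n_starts=200)
        cons = build_ratio_constraints(ss, FACTORS, cfg, THREE_STEP)
        res = multistart_fit(gene, obs, cons, cfg, THREE_STEP)
        for key in ("k1", "k2", "gamma3", "v"):
            got = getattr(res.params, key)
            want = getattr(truth, key)
            assert abs(got - want) / want < 0.01, key

    def test_same_seed_reproducible(self, noise_free_case):
        gene, _, obs, ss = noise_free_case
        cfg = FitConfig(seed=2, n_starts=50)
        cons = build_ratio_constraints(ss, FACTORS, cfg, THREE_STEP)
        a = multistart_fit(gene, obs, cons, cfg, THREE_STEP)
        b = multistart_fit(gene, obs, cons, cfg, THREE_STEP)
        assert a.params.to_dict() == b.params.to_dict()
        assert a.chi2 == b.chi2

    def test_ratio_constraint_satisfied_by_best_fit(self, noise_free_case):
        gene, _, obs, ss = noise_free_case
        cfg = FitConfig(seed=3, n_starts=50)
        cons = build_ratio_constraints(ss, FACTORS, cfg, THREE_STEP)
        res = multistart_fit(gene, obs, cons, cfg, THREE_STEP)
        p = res.params
        implied = p.gamma3 * (1 + p.r2 / p.k1) / p.k2
        lo, hi = cons["nuc_over_cyto"]
        assert lo * (1 - 1e-9) <= implied <= hi * (1 + 1e-9)

    def test_extended_chi2_never_above_null(self, noise_free_case):
        gene, truth, _, ss = noise_free_case
        design = SimulationDesign(seed=0)
        obs = simulate_labeling_timeseries(truth, gene, design, seed=9)
        cfg = FitConfig(seed=4, n_starts=50)
        cons = build_ratio_constraints(ss, FACTORS, cfg, THREE_STEP)
        null = multistart_fit(gene, obs, cons, cfg, THREE_STEP,
                              with_nuclear_decay=False)
        ext = multistart_fit(gene, obs, cons, cfg, THREE_STEP,
                             with_nuclear_decay=True)
        # nesting: the richer model's optimum can always match the null
        # (the reported fit may trade a sliver of chi2 for boundary distance,
        # and the gamma2 -> 0 direction converges only to optimizer tolerance)
        assert min(ext.pool_chi2) <= null.chi2 * (1 + 1e-4) + 1e-9

    def test_selected_chi2_close_to_pool_minimum(self, noise_free_case):
        gene, _, obs, ss = noise_free_case
        cfg = FitConfig(seed=5, n_starts=50)
        cons = build_ratio_constraints(ss, FACTORS, cfg, THREE_STEP)
        res = multistart_fit(gene, obs, cons, cfg, THREE_STEP)
        # boundary-distance tie-break only picks near-optimal members
        assert res.reduced_chi2 < 1e-3  # noise-free: essentially exact


def _fake_result(reduced_chi2=1.0, params=None, variant=THREE_STEP,
                 localization="cytosol", bic=100.0, se=None, success=True):
    if params is None:
        params = KineticParams(k1=0.05, k2=0.01, gamma3=0.08, v=1.0,
                               variant=THREE_STEP)
    return FitResult(
        gene_id="g", params=params, param_se=se or {}, chi2=50.0,
        reduced_chi2=reduced_chi2, n_points=50, n_params=4, bic=bic,
        variant=variant, includes_nuclear_decay=False,
        localization=localization, qc={}, success=success,
    )


class TestQualityControl:
    def test_high_reduced_chi2_fails(self):
        res = _fake_result(reduced_chi2=4.5)
        flags = quality_control(res, [res.params.to_dict()], FitConfig())
        assert flags["chi2_fail"]

    def test_threshold_is_strictly_above_four(self):
        res = _fake_result(reduced_chi2=4.0)
        flags = quality_control(res, [res.params.to_dict()], FitConfig())
        assert not flags["chi2_fail"]

    def test_identical_pool_is_stable(self):
        res = _fake_result()
        pool = [{"k1": 0.05, "k2": 0.01, "gamma3": 0.08, "v": 1.0}] * 10
        flags = quality_control(res, pool, FitConfig())
        assert not flags["instability_fail"]

    def test_spread_pool_is_unstable(self):
        res = _fake_result()
        pool = [{"k2": 0.01 * (1 + 0.2 * i)} for i in range(10)]
        flags = quality_control(res, pool, FitConfig())
        assert flags["instability_fail"]

    def test_cytosolic_rate_at_upper_bound_fails(self):
        params = KineticParams(k1=0.05, k2=0.01, gamma3=2.0, v=1.0,
                               variant=THREE_STEP)
        res = _fake_result(params=params)
        flags = quality_control(res, [params.to_dict()], FitConfig())
        assert flags["boundary_fail"]

    def test_membrane_rule_checks_gamma4(self):
        params = KineticParams(k1=0.05, k2=0.01, k3=0.5, gamma4=2.0, v=1.0,
                               variant=FOUR_STEP)
        res = _fake_result(params=params, variant=FOUR_STEP,
                           localization="membrane")
        flags = quality_control(res, [params.to_dict()], FitConfig())
        assert flags["boundary_fail"]

    def test_elongation_boundary_is_separate_flag(self):
        params = KineticParams(k1=0.05, k2=0.01, gamma3=0.08, v=10.0,
                               variant=THREE_STEP)
        res = _fake_result(params=params)
        flags = quality_control(res, [params.to_dict()], FitConfig())
        assert flags["v_at_boundary"]
        assert not flags["boundary_fail"]


class TestCompareNuclearDecayModels:
    def _ext(self, bic, gamma2=0.02, se_gamma2=0.01):
        params = KineticParams(k1=0.05, k2=0.01, gamma2=gamma2, gamma3=0.08,
                               v=1.0, variant=THREE_STEP)
        res = _fake_result(params=params, bic=bic,
                           se={"gamma2": se_gamma2})
        res.includes_nuclear_decay = True
        return res

    def test_both_criteria_met_chooses_extended(self):
        null = _fake_result(bic=112.0)
        ext = self._ext(bic=100.0, gamma2=0.02, se_gamma2=0.01)
        chosen, record = compare_nuclear_decay_models(null, ext)
        assert record["chosen"] == "extended"
        assert chosen is ext

    def test_se_criterion_blocks_selection(self):
        null = _fake_result(bic=112.0)
        ext = self._ext(bic=100.0, gamma2=0.02, se_gamma2=0.04)
        chosen, record = compare_nuclear_decay_models(null, ext)
        assert record["chosen"] == "null_model"

    def test_small_bic_gain_keeps_null(self):
        null = _fake_result(bic=105.0)
        ext = self._ext(bic=100.0)
        _, record = compare_nuclear_decay_models(null, ext)
        assert record["chosen"] == "null_model"

    def test_failed_extended_keeps_null(self):
        null = _fake_result(bic=130.0)
        ext = self._ext(bic=100.0)
        ext.success = False
        chosen, record = compare_nuclear_decay_models(null, ext)
        assert chosen is null
        assert "failed" in record["reason"]


class TestComputeBic:
    def test_extra_parameter_penalty(self):
        b1 = compute_bic(80.0, 50, 4)
        b2 = compute_bic(80.0, 50, 5)
        assert b2 - b1 == pytest.approx(math.log(50))

    def test_differences_drop_shared_constant(self):
        # adding any constant to both chi2 leaves the difference unchanged
        d1 = compute_bic(90.0, 40, 5) - compute_bic(80.0, 40, 4)
        d2 = compute_bic(190.0, 40, 5) - compute_bic(180.0, 40, 4)
        assert d1 == pytest.approx(d2)

    def test_requires_degrees_of_freedom(self):
        with pytest.raises(ValueError):
            compute_bic(10.0, 4, 4)


class TestCohortIndependence:
    def test_per_gene_fit_independent_of_cohort(self, small_cohort,
                                                small_cohort_factors):
        from rnaflow.fitting import fit_cohort

        b = small_cohort
        cfg = FitConfig(seed=42, n_starts=30)
        all_fits, _ = fit_cohort(b["genes"][:3], b["labeling"],
                                 b["expression"], small_cohort_factors,
                                 cfg=cfg, compare_decay=False)
        solo_fits, _ = fit_cohort(b["genes"][1:2], b["labeling"],
                                  b["expression"], small_cohort_factors,
                                  cfg=cfg, compare_decay=False)
        a = all_fits[all_fits.gene_id == b["genes"][1].gene_id].iloc[0]
        s = solo_fits.iloc[0]
        for key in ("k2", "chi2", "bic"):
            assert a[key] == s[key]
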