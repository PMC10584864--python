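"""Synthetic-data generator: determinism, truth recovery, censoring realism."""

import numpy as np
import pytest

from lakenfix.profiles import extract_features
from lakenfix.rates import apply_lod, n2_fixation_rate, nloss_rates, summarize_depth
from lakenfix.synthetic import (
    generate_expedition,
    generate_incubation,
    generate_n2_timeseries,
    generate_profile,
    stratified_template,
    upwelling_template,
)


def noiseless(template):
    template.noise = {k: 0.0 for k in template.noise}
    return template


class TestProfileGeneration:
    def test_thermocline_recovered_within_one_interval(self):
        t = stratified_template()
        p = generate_profile(t, depths_m=np.arange(0.0, 201.0, 10.0), seed=5)
        f = extract_features(p)
        assert abs(f.z_thermocline - t.thermocline_depth_m) <= 10.0

    def test_upwelling_has_no_acm(self):
        p = generate_profile(upwelling_template(), seed=3)
        f = extract_features(p)
        assert f.acm_depth is None

    def test_stratified_has_acm_below_anoxic_boundary(self):
        p = generate_profile(stratified_template(), seed=3)
        f = extract_features(p)
        assert f.acm_depth is not None
        assert f.acm_depth > f.z_anoxic

    def test_zero_noise_recovers_template_features(self):
        t = noiseless(stratified_template())
        p = generate_profile(t, depths_m=np.arange(0.0, 201.0, 2.0), seed=0)
        f = extract_features(p)
        assert f.z_eu == pytest.approx(t.euphotic_depth_m, abs=0.1)
        assert abs(f.z_thermocline - t.thermocline_depth_m) <= 2.0
        assert abs(f.z_deficient - t.o2_deficiency_depth_m) <= 2.0

    def test_below_detection_values_censored_at_lod(self):
        p = generate_profile(stratified_template(), seed=11)
        no3 = p.properties["no3"]
        cens = p.censored["no3"]
        assert cens.any()  # surface nitrate depletion
        assert np.all(no3[cens] == p.detection_limits["no3"])

    def test_deterministic_given_seed(self):
        a = generate_profile(stratified_template(), seed=42)
        b = generate_profile(stratified_template(), seed=42)
        for k in a.properties:
            np.testing.assert_array_equal(a.properties[k], b.properties[k])


class TestIncubationGeneration:
    def test_noiseless_inverse_recovers_rate_exactly(self):
        bottles = generate_incubation(7.5, irms_sigma_permil=0.0, seed=0)
        control, treatments = bottles[0], bottles[1:]
        est = summarize_depth([(control, t) for t in treatments])
        assert est.rate == pytest.approx(7.5, rel=1e-9)

    def test_zero_rate_indistinguishable_from_control(self):
        """Mean treatment-minus-control excess over 400 sims is < 3 sigma/sqrt(n)."""
        sigma = 0.2
        excesses = []
        ss = np.random.SeedSequence(9)
        for child in ss.spawn(400):
            b = generate_incubation(
                0.0, irms_sigma_permil=sigma, n_treatments=1,
                seed=np.random.default_rng(child),
            )
            excesses.append(b[1].delta15n_pon - b[0].delta15n_pon)
        threshold = 3 * sigma * np.sqrt(2) / np.sqrt(len(excesses))
        assert abs(np.mean(excesses)) < threshold

    def test_infeasible_rate_rejected(self):
        with pytest.raises(ValueError):
            # would need PON enriched beyond the labelled pool in one day
            generate_incubation(1e6, pon_conc_ug_l=1.0)

    def test_minimum_detectable_rate_positive_with_physical_scaling(self):
        """The 4-permil criterion implies a strictly positive detection floor;
        stronger labelling lowers it, while higher PON concentration raises it
        (a fixed amount of newly fixed N is diluted into more biomass)."""

        def min_detectable(pon_ug_l, label):
            lo, hi = 0.0, 50.0
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                b = generate_incubation(
                    mid, pon_conc_ug_l=pon_ug_l, label_at_percent=label,
                    irms_sigma_permil=0.0, n_treatments=1, seed=0,
                )
                est = apply_lod(b[0], b[1], n2_fixation_rate(b[0], b[1]))
                if est.censored:
                    lo = mid
                else:
                    hi = mid
            return hi

        base = min_detectable(pon_ug_l=14.0, label=4.7)
        stronger_label = min_detectable(pon_ug_l=14.0, label=6.3)
        more_pon = min_detectable(pon_ug_l=28.0, label=4.7)
        assert base > 0 and stronger_label > 0 and more_pon > 0
        assert stronger_label < base
        assert more_pon > base


class TestTimeSeriesGeneration:
    def test_noiseless_slopes_exact(self):
        ts = generate_n2_timeseries(0.3, 0.15, sigma_nmol_l=0.0)
        res = nloss_rates(ts)
        assert res["p29"] == pytest.approx(0.3, rel=1e-12)
        assert res["p30"] == pytest.approx(0.15, rel=1e-12)

    def test_zero_production_censored(self):
        ts = generate_n2_timeseries(0.0, 0.0, sigma_nmol_l=0.05, seed=4)
        res = nloss_rates(ts)
        assert res["p29"] == 0.0 or res["p29"] < 0.1
        assert res["p30"] == 0.0 or res["p30"] < 0.1

    def test_slope_recovery_within_3_se(self):
        """300 noisy series with true slope 0.5: mean OLS estimate unbiased."""
        slopes = []
        ss = np.random.SeedSequence(21)
        for child in ss.spawn(300):
            ts = generate_n2_timeseries(
                0.1, 0.5, sigma_nmol_l=0.05, seed=np.random.default_rng(child)
            )
            slopes.append(nloss_rates(ts)["p30"])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.5) < 3 * se


class TestExpedition:
    def test_byte_for_byte_determinism(self):
        a = generate_expedition(seed=7)
        b = generate_expedition(seed=7)
        assert len(a.incubations) == len(b.incubations)
        for x, y in zip(a.incubations, b.incubations):
            assert x == y
        for s in a.profiles:
            np.testing.assert_array_equal(
                a.profiles[s].properties["no3"], b.profiles[s].properties["no3"]
            )
        assert a.truth.true_contrast_ratio == b.truth.true_contrast_ratio

    def test_truth_contrast_near_injected_5x(self, expedition):
        assert expedition.truth.true_contrast_ratio == pytest.approx(5.0, rel=0.25)

    def test_regime_layout(self, expedition):
        regimes = expedition.truth.station_regime
        assert [regimes[str(i)] for i in range(1, 10)] == (
            ["stratified"] * 6 + ["upwelling"] * 3
        )
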