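"""Tracer mass-balance rates, detection-limit censoring, slope rates."""

import numpy as np
import pytest

from lakenfix.isotopes import delta_from_atom_percent
from lakenfix.rates import (
    IncubationBottle,
    N2TimeSeries,
    apply_lod,
    n2_fixation_rate,
    nloss_rates,
    single_cell_rate,
    summarize_depth,
)
from lakenfix.synthetic import generate_incubation


def bottle(role, delta, label=6.3, pon_ug=14.0067, volume=1.0, duration=1.0, depth=5.0):
    return IncubationBottle(
        station="s",
        depth_m=depth,
        role=role,
        delta15n_pon=delta,
        pon_mass_ug=pon_ug,
        volume_l=volume,
        duration_d=duration,
        label_atom_percent=label if role == "treatment" else None,
    )


def pair_from_atom_percent(ap_control, ap_sample, **kw):
    return (
        bottle("control", delta_from_atom_percent(ap_control), **{k: v for k, v in kw.items() if k != "label"}),
        bottle("treatment", delta_from_atom_percent(ap_sample), **kw),
    )


class TestMassBalance:
    def test_hand_evaluated_rate(self):
        # (0.3773-0.3663)/(6.3-0.3663) * 1000 nmol/L / 1 d
        c, t = pair_from_atom_percent(0.3663, 0.3773)
        expected = (0.3773 - 0.3663) / (6.3 - 0.3663) * 1000.0
        assert n2_fixation_rate(c, t).rate == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.8538, abs=5e-4)

    def test_zero_enrichment_zero_rate(self):
        c, t = pair_from_atom_percent(0.3663, 0.3663)
        assert n2_fixation_rate(c, t).rate == pytest.approx(0.0, abs=1e-12)

    def test_doubling_time_halves_rate(self):
        c1, t1 = pair_from_atom_percent(0.3663, 0.40, duration=1.0)
        c2, t2 = pair_from_atom_percent(0.3663, 0.40, duration=2.0)
        assert n2_fixation_rate(c1, t1).rate == pytest.approx(
            2.0 * n2_fixation_rate(c2, t2).rate
        )

    def test_rate_scales_with_pon_concentration(self):
        c, t1 = pair_from_atom_percent(0.3663, 0.40, pon_ug=14.0)
        _, t2 = pair_from_atom_percent(0.3663, 0.40, pon_ug=42.0)
        assert n2_fixation_rate(c, t2).rate == pytest.approx(
            3.0 * n2_fixation_rate(c, t1).rate
        )

    def test_rate_invariant_to_joint_mass_volume_scaling(self):
        c, t1 = pair_from_atom_percent(0.3663, 0.40, pon_ug=14.0, volume=1.0)
        _, t2 = pair_from_atom_percent(0.3663, 0.40, pon_ug=63.0, volume=4.5)
        assert n2_fixation_rate(c, t1).rate == pytest.approx(n2_fixation_rate(c, t2).rate)

    def test_label_below_control_rejected(self):
        c, t = pair_from_atom_percent(0.3663, 0.3773, label=0.2)
        with pytest.raises(ValueError):
            n2_fixation_rate(c, t)

    def test_missing_control_uses_default_and_flags(self):
        t = bottle("treatment", 30.0)
        est = n2_fixation_rate(None, t)
        assert "default-control" in est.flags
        assert est.rate > 0


class TestCensoring:
    def test_excess_below_4_permil_censored(self):
        c = bottle("control", 0.0)
        t = bottle("treatment", 3.0)
        est = apply_lod(c, t, n2_fixation_rate(c, t))
        assert est.censored and est.rate == 0.0

    def test_excess_above_4_permil_retained(self):
        c = bottle("control", 0.0)
        t = bottle("treatment", 5.0)
        est = apply_lod(c, t, n2_fixation_rate(c, t))
        assert not est.censored and est.rate > 0

    def test_negative_rate_censored_regardless_of_excess(self):
        # treatment depleted below control: negative mass-balance rate
        c = bottle("control", 10.0)
        t = bottle("treatment", 2.0)
        raw = n2_fixation_rate(c, t)
        assert raw.rate < 0
        est = apply_lod(c, t, raw, min_excess_permil=-100.0)
        assert est.censored and est.rate == 0.0

    def test_censoring_monotone_in_threshold(self):
        c = bottle("control", 0.0)
        t = bottle("treatment", 6.0)
        raw = n2_fixation_rate(c, t)
        strict = apply_lod(c, t, raw, min_excess_permil=8.0)
        lax = apply_lod(c, t, raw, min_excess_permil=4.0)
        assert strict.censored and not lax.censored


class TestReplicateSummary:
    def test_two_point_mean_and_se(self):
        # duplicates at hand-built enrichments giving rates 2 and 3 via the
        # summary's own estimator; check the mean/SE arithmetic instead on
        # direct construction of the duplicate rates
        c = bottle("control", 0.0)
        t1 = bottle("treatment", 40.0)
        t2 = bottle("treatment", 60.0)
        est = summarize_depth([(c, t1), (c, t2)])
        r1 = n2_fixation_rate(c, t1).rate
        r2 = n2_fixation_rate(c, t2).rate
        assert est.rate == pytest.approx((r1 + r2) / 2)
        assert est.se == pytest.approx(np.std([r1, r2], ddof=1) / np.sqrt(2))
        assert est.n_replicates == 2

    def test_partial_censoring_keeps_retained_and_flags(self):
        c = bottle("control", 0.0)
        kept = bottle("treatment", 40.0)
        below = bottle("treatment", 2.0)
        est = summarize_depth([(c, kept), (c, below)])
        assert not est.censored
        assert est.rate == pytest.approx(n2_fixation_rate(c, kept).rate)
        assert "partially-censored" in est.flags

    def test_all_censored_summary_censored(self):
        c = bottle("control", 0.0)
        est = summarize_depth([(c, bottle("treatment", 1.0)), (c, bottle("treatment", 2.0))])
        assert est.censored and est.rate == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_depth([])


class TestNlossSlopes:
    def test_exact_line(self):
        ts = N2TimeSeries("15NO3", [0.0, 1.0, 2.0], [0.0, 0.5, 1.0], [0.0, 1.0, 2.0])
        res = nloss_rates(ts)
        assert res["p30"] == pytest.approx(1.0)
        assert res["p29"] == pytest.approx(0.5)
        assert res["r2_30"] == pytest.approx(1.0)

    def test_flat_series_zero_slope(self):
        ts = N2TimeSeries("15NH4", [0.0, 1.0, 2.0], [0.3, 0.3, 0.3], [0.1, 0.1, 0.1])
        res = nloss_rates(ts)
        assert res["p29"] == pytest.approx(0.0, abs=1e-12)
        assert res["p30"] == pytest.approx(0.0, abs=1e-12)

    def test_negative_slope_censored_to_zero(self):
        ts = N2TimeSeries("15NO3", [0.0, 1.0, 2.0], [2.0, 1.0, 0.0], [0.0, 0.1, 0.2])
        res = nloss_rates(ts)
        assert res["p29"] == 0.0 and res["p29_censored"]
        assert not res["p30_censored"]

    def test_matches_closed_form_ols_on_noisy_data(self, rng):
        t = np.linspace(0, 1.25, 6)
        y = 0.5 * t + rng.normal(0, 0.05, 6)
        ts = N2TimeSeries("15NO3", t, np.zeros(6) + 0.01 * t, y)
        res = nloss_rates(ts)
        tc = t - t.mean()
        slope = float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
        assert res["p30"] == pytest.approx(max(slope, 0.0), rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            N2TimeSeries("x", [0.0, 1.0], [0.0, 1.0], [0.0, 1.0])


class TestSingleCellRate:
    def test_hand_arithmetic(self):
        # 10 nmol/L/d over 22 colonies/mL x 30 cells = 6.6e5 cells/L
        v = single_cell_rate(10.0, 22.0, 30.0)
        assert v == pytest.approx(10.0 / 6.6e5 * 1e6, rel=1e-12)
        assert v == pytest.approx(15.15, abs=0.01)

    def test_unit_identity(self):
        # 1 nmol/L/d over 1e6 cells/L -> 1 fmol/cell/d
        assert single_cell_rate(1.0, 1000.0, 1.0) == pytest.approx(1.0)

    def test_doubling_density_halves_rate(self):
        assert single_cell_rate(5.0, 10.0, 30.0) == pytest.approx(
            2.0 * single_cell_rate(5.0, 20.0, 30.0)
        )

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            single_cell_rate(1.0, 0.0, 30.0)


def test_parameter_recovery_small_monte_carlo():
    """Mean estimate over synthetic duplicate incubations is unbiased."""
    true_rate = 5.0
    estimates = []
    ss = np.random.SeedSequence(77)
    for child in ss.spawn(300):
        bottles = generate_incubation(
            true_rate, irms_sigma_permil=0.2, seed=np.random.default_rng(child)
        )
        control, treatments = bottles[0], bottles[1:]
        est = summarize_depth([(control, t) for t in treatments])
        estimates.append(est.rate)
    mean = np.mean(estimates)
    mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(mean - true_rate) < 3 * mc_se
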