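"""Hydrographic feature extraction on constructed and synthetic profiles."""

import numpy as np
import pytest

from lakenfix.profiles import (
    DepthProfile,
    chlorophyll_maxima,
    euphotic_depth,
    extract_features,
    np_ratio_classification,
    oxygen_boundaries,
    thermocline_depth,
)


def make_profile(depths, **properties):
    censored = properties.pop("censored", {})
    return DepthProfile(
        station="t", depths_m=np.asarray(depths, float),
        properties={k: np.asarray(v, float) for k, v in properties.items()},
        censored=censored,
    )


class TestEuphoticDepth:
    @pytest.mark.parametrize("k", [0.0921, 0.05, 0.2])
    def test_exponential_profile_closed_form(self, k):
        z = np.arange(0.0, 201.0, 5.0)
        p = make_profile(z, par=100.0 * np.exp(-k * z))
        assert euphotic_depth(p) == pytest.approx(np.log(100.0) / k, rel=1e-9)

    def test_constant_par_absent(self):
        p = make_profile([0, 10, 20], par=[50.0, 50.0, 50.0])
        assert euphotic_depth(p) is None

    def test_surface_only_par_rejected(self):
        p = make_profile([0, 10], par=[100.0, np.nan])
        with pytest.raises(ValueError):
            euphotic_depth(p)


class TestThermocline:
    def test_single_sharp_interval(self):
        p = make_profile(
            [0, 20, 40, 50, 80], temperature=[27, 27, 27, 24, 24]
        )
        assert thermocline_depth(p) == pytest.approx(45.0)

    def test_tie_broken_to_shallowest(self):
        p = make_profile(
            [0, 10, 20, 30, 40], temperature=[27, 25, 25, 23, 23]
        )
        assert thermocline_depth(p) == pytest.approx(5.0)

    def test_isothermal_absent(self):
        p = make_profile([0, 10, 20, 30], temperature=[25.0, 25.0, 25.0, 25.0])
        assert thermocline_depth(p) is None

    def test_sigmoid_recovered_within_one_interval(self):
        z = np.arange(0.0, 101.0, 5.0)
        temp = 23.5 + 3.5 / (1.0 + np.exp((z - 23.0) / 3.0))
        p = make_profile(z, temperature=temp)
        assert abs(thermocline_depth(p) - 23.0) <= 5.0


class TestOxygenBoundaries:
    def test_linear_decline_interpolated(self):
        z = np.arange(100.0, 151.0, 10.0)
        o2 = 100.0 - 2.0 * (z - 100.0)
        p = make_profile(z, o2=np.maximum(o2, 0.0))
        b = oxygen_boundaries(p)
        assert b["z_deficient"] == pytest.approx(145.0)
        assert b["z_anoxic"] == pytest.approx(149.5)

    def test_fully_oxic_absent(self):
        p = make_profile([0, 50, 100], o2=[250.0, 220.0, 200.0])
        b = oxygen_boundaries(p)
        assert b["z_anoxic"] is None and b["z_deficient"] is None

    def test_surface_anoxic_at_shallowest(self):
        p = make_profile([5, 50, 100], o2=[0.5, 0.2, 0.1])
        b = oxygen_boundaries(p)
        assert b["z_anoxic"] == 5.0 and b["z_deficient"] == 5.0


class TestChlorophyllMaxima:
    def test_single_oxic_peak_no_acm(self):
        z = np.arange(0.0, 201.0, 10.0)
        chl = 0.2 + np.exp(-((z - 30.0) ** 2) / 200.0)
        m = chlorophyll_maxima(make_profile(z, chl=chl), z_anoxic=None)
        assert m["pcm_depth"] == pytest.approx(30.0)
        assert m["acm_depth"] is None

    def test_two_peaks_straddling_anoxic_boundary(self):
        z = np.arange(0.0, 201.0, 10.0)
        chl = (
            0.15
            + np.exp(-((z - 30.0) ** 2) / 200.0)
            + 0.9 * np.exp(-((z - 150.0) ** 2) / 128.0)
        )
        m = chlorophyll_maxima(make_profile(z, chl=chl), z_anoxic=120.0)
        assert m["pcm_depth"] == pytest.approx(30.0)
        assert m["acm_depth"] == pytest.approx(150.0)

    def test_monotone_decay_pcm_at_surface_no_acm(self):
        z = np.arange(0.0, 201.0, 10.0)
        chl = 2.0 * np.exp(-z / 60.0)
        m = chlorophyll_maxima(make_profile(z, chl=chl), z_anoxic=120.0)
        assert m["pcm_depth"] == 0.0
        assert m["acm_depth"] is None


class TestRedfieldClassification:
    def test_counting(self):
        n = 20
        z = np.arange(n) * 10.0
        no3 = np.full(n, 8.0)
        no3[0] = 32.0  # one sample above Redfield
        srp = np.full(n, 1.0)
        res = np_ratio_classification(make_profile(z, no3=no3, srp=srp))
        assert res["fraction_below"] == pytest.approx(0.95)

    def test_ammonium_included_in_din(self):
        p = make_profile([0.0, 10.0], no3=[8.0, 8.0], nh4=[10.0, 10.0], srp=[1.0, 1.0])
        res = np_ratio_classification(p)
        assert res["fraction_below"] == 0.0  # DIN 18 > 16

    def test_all_srp_censored_undefined(self):
        p = make_profile(
            [0.0, 10.0],
            no3=[1.0, 1.0],
            srp=[0.2, 0.2],
            censored={"srp": np.array([True, True])},
        )
        res = np_ratio_classification(p)
        assert res["fraction_below"] is None
        assert "all-srp-censored" in res["flags"]


class TestInvariants:
    def test_duplicated_depth_rows_ignored(self):
        z = np.arange(0.0, 201.0, 10.0)
        par = 100.0 * np.exp(-0.1 * z)
        temp = 23.5 + 3.5 / (1.0 + np.exp((z - 40.0) / 4.0))
        p1 = make_profile(z, par=par, temperature=temp)
        zdup = np.concatenate([z, [50.0]])
        p2 = make_profile(
            zdup,
            par=np.concatenate([par, [100.0 * np.exp(-5.0)]]),
            temperature=np.concatenate([temp, [temp[5]]]),
        )
        assert euphotic_depth(p1) == euphotic_depth(p2)
        assert thermocline_depth(p1) == thermocline_depth(p2)

    def test_features_within_depth_range(self, expedition):
        for profile in expedition.profiles.values():
            f = extract_features(profile)
            lo, hi = profile.depths_m[0], profile.depths_m[-1]
            for val in (f.z_eu, f.z_thermocline, f.z_anoxic, f.z_deficient,
                        f.pcm_depth, f.acm_depth):
                if val is not None:
                    assert lo <= val <= hi
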