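"""Hill curves, regional mixing and algebraic unmixing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npcassembly import (DegenerateMixingError, InvalidParameterError,
                         MixingParams, NupKinetics, hill_curve, mix_curves,
                         mix_forward, unmix)

positive = st.floats(0.3, 20.0)
delays = st.floats(0.0, 6.0)
fractions = st.floats(0.01, 0.99)


class TestHillCurve:
    @pytest.mark.parametrize("n,K,d", [(1.0, 5.0, 0.0), (3.7, 22.0, 2.0),
                                       (0.8, 90.0, 5.0), (12.0, 1.3, 0.0)])
    def test_half_maximum_at_median_time(self, n, K, d):
        assert hill_curve(d + K, n, K, d) == pytest.approx(0.5, abs=1e-15)

    def test_zero_at_and_before_delay(self):
        t = np.array([0.0, 1.0, 2.0, 2.5])
        out = hill_curve(t, 2.0, 10.0, d=2.5)
        assert np.all(out == 0.0)

    def test_direct_substitution(self):
        # (30^2) / (30^2 + 10^2) = 0.9
        assert hill_curve(30.0, 2.0, 10.0) == pytest.approx(0.9, rel=1e-12)

    @given(n=positive, K=positive, d=delays)
    @settings(max_examples=50, derandomize=True)
    def test_monotone_in_time_and_limits(self, n, K, d):
        t = d + np.geomspace(1e-3, 1e5, 200)
        y = hill_curve(t, n, K, d)
        assert np.all(np.diff(y) >= 0)
        unsaturated = y[:-1] < 1 - 1e-12      # strict until float saturation
        assert np.all(np.diff(y)[unsaturated] > 0)
        # approach to 1 at the Hill tail rate (K/t)^n
        assert 1 - y[-1] <= 1.01 * (K / (t[-1] - d)) ** n
        assert 0 <= y[0] < 1

    @given(n=positive, K=positive)
    @settings(max_examples=30, derandomize=True)
    def test_larger_K_means_later_half_time(self, n, K):
        t = np.geomspace(1e-2, 1e4, 500)
        later = hill_curve(t, n, 1.5 * K)
        assert np.all(later <= hill_curve(t, n, K) + 1e-15)

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            hill_curve(1.0, -1.0, 5.0)
        with pytest.raises(InvalidParameterError):
            NupKinetics("x", n_p=2.0, K_p=0.0, n_i=2.0, K_i=5.0)


class TestMixing:
    kin = NupKinetics("Nup107", n_p=2.5, K_p=1.2, n_i=4.0, K_i=30.0)
    t = np.arange(0.0, 120.5, 0.5)

    def test_boundary_weights_select_components(self):
        n, c = mix_forward(self.kin, MixingParams(1.0, 0.0, d_c=2.0), self.t)
        assert np.allclose(n, hill_curve(self.t, 2.5, 1.2))
        assert np.allclose(c, hill_curve(self.t, 4.0, 30.0, d=2.0))

    def test_late_postmitotic_limit_returns_fractions(self):
        # pm -> 1, ip -> 0: observed levels equal the regional fractions
        mix = MixingParams(0.857, 0.295)
        n = mix_curves(1.0, 0.0, mix.f_n)
        c = mix_curves(1.0, 0.0, mix.f_c)
        assert (n, c) == (0.857, 0.295)

    def test_core_curve_zero_before_delay(self):
        mix = MixingParams(0.857, 0.295, d_c=2.0)
        _, c = mix_forward(self.kin, mix, self.t)
        assert np.all(c[self.t < 2.0] == 0.0)

    @given(pm=st.lists(st.floats(0, 1), min_size=3, max_size=10),
           ip=st.lists(st.floats(0, 1), min_size=3, max_size=10),
           f_n=fractions, f_c=fractions)
    @settings(max_examples=100, derandomize=True)
    def test_unmix_inverts_mixing_exactly(self, pm, ip, f_n, f_c):
        """The 2x2 mixing map is inverted to machine precision for any
        curve pair and any distinct fractions."""
        m = min(len(pm), len(ip))
        pm, ip = np.array(pm[:m]), np.array(ip[:m])
        f_lo, f_hi = sorted((f_n, f_c))
        if f_hi - f_lo < 1e-3:
            f_hi = min(f_lo + 0.5, 1.0)
        mix = MixingParams(f_hi, f_lo)
        pair = unmix(mix_curves(pm, ip, f_hi), mix_curves(pm, ip, f_lo), mix)
        assert np.allclose(pair.pm, pm, atol=1e-12)
        assert np.allclose(pair.ip, ip, atol=1e-12)

    def test_roundtrip_through_forward_model(self):
        mix = MixingParams(0.857, 0.295, d_c=0.0)
        n, c = mix_forward(self.kin, mix, self.t)
        pair = unmix(n, c, mix, self.t)
        assert np.allclose(pair.pm, hill_curve(self.t, 2.5, 1.2), atol=1e-12)
        assert np.allclose(pair.ip, hill_curve(self.t, 4.0, 30.0), atol=1e-12)
        assert np.all((pair.pm >= -1e-12) & (pair.pm <= 1 + 1e-12))

    def test_identical_regions_unmix_to_the_common_curve(self):
        # n = c solves to pm = ip = n for any distinct fractions
        y = np.linspace(0, 1, 11)
        pair = unmix(y, y, MixingParams(0.8, 0.3))
        assert np.allclose(pair.pm, y, atol=1e-14)
        assert np.allclose(pair.ip, y, atol=1e-14)

    def test_equal_fractions_are_degenerate(self):
        with pytest.raises(DegenerateMixingError):
            MixingParams(0.5, 0.5)
        mix = MixingParams(0.8, 0.3)
        object.__setattr__(mix, "f_c", 0.8)
        with pytest.raises(DegenerateMixingError):
            unmix(np.ones(3), np.ones(3), mix)

    def test_fraction_ordering_enforced(self):
        with pytest.raises(InvalidParameterError):
            MixingParams(0.3, 0.8)
        with pytest.raises(InvalidParameterError):
            MixingParams(0.8, 0.3, d_c=-1.0)
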