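"""Stopping powers, density effect, slowing-down spectra, averaged ratios."""

import math

import numpy as np
import pytest

from radequiv.constants import ELECTRON_REST_MEV
from radequiv.electron_stopping import (
    collision_stopping_power,
    density_effect,
    evaluate,
    initial_recoil_spectrum,
    mean_stopping_power_ratio,
    restricted_stopping_power,
    slowing_down_spectrum,
)
from radequiv.materials import MaterialComposition, mean_excitation_energy
from radequiv.photon_interactions import compton_edge, klein_nishina
from radequiv.spectra import co60, make_line_spectrum


class TestDensityEffect:
    def test_vanishes_at_low_energy(self, water_mat):
        assert density_effect(water_mat, 0.010) == 0.0

    def test_monotone_in_energy(self, water_mat):
        T = np.geomspace(0.01, 50, 80)
        d = density_effect(water_mat, T)
        assert np.all(np.diff(d) >= 0)
        assert density_effect(water_mat, 10.0) > density_effect(water_mat, 1.0)

    def test_water_at_1mev_near_published(self, water_mat):
        # published water delta(1 MeV) ~ 0.24; the general recipe is close
        assert density_effect(water_mat, 1.0) == pytest.approx(0.24, rel=0.15)


class TestCollisionStoppingPower:
    def test_water_1mev_near_published(self, water_mat):
        # published water S_col at 1 MeV is 1.849 MeV cm^2/g
        assert collision_stopping_power(water_mat, 1.0) == pytest.approx(1.849, rel=0.02)

    def test_silicone_below_water_everywhere(self, silicone_mat, water_mat):
        T = np.geomspace(0.01, 50, 60)
        assert np.all(
            collision_stopping_power(silicone_mat, T) < collision_stopping_power(water_mat, T)
        )

    def test_high_energy_ratio_matches_symbolic_oracle(self, silicone_mat, water_mat):
        """At fixed T the ratio reduces to (Z/A ratio)*(bracket ratio)."""
        T = 40.0
        tau = T / ELECTRON_REST_MEV
        beta2 = 1.0 - 1.0 / (1.0 + tau) ** 2
        f = 1 - beta2 + (tau**2 / 8 - (2 * tau + 1) * math.log(2)) / (tau + 1) ** 2

        def bracket(mat):
            i2 = (mean_excitation_energy(mat) * 1e-6 / ELECTRON_REST_MEV) ** 2
            return math.log(tau**2 * (tau + 2) / (2 * i2)) + f - density_effect(mat, T)

        oracle = (
            silicone_mat.electrons_per_gram_mol() / water_mat.electrons_per_gram_mol()
        ) * (bracket(silicone_mat) / bracket(water_mat))
        full = collision_stopping_power(silicone_mat, T) / collision_stopping_power(
            water_mat, T
        )
        assert full == pytest.approx(oracle, rel=1e-9)

    def test_range_enforced(self, water_mat):
        with pytest.raises(ValueError):
            collision_stopping_power(water_mat, 0.001)


class TestRestrictedStoppingPower:
    def test_equals_unrestricted_at_half_energy_cutoff(self, water_mat):
        for T in (0.05, 0.2, 1.0, 10.0):
            l = restricted_stopping_power(water_mat, T, cutoff=T / 2)
            s = collision_stopping_power(water_mat, T)
            assert l == pytest.approx(s, rel=1e-12)

    def test_monotone_increasing_in_cutoff(self, water_mat):
        T = 1.0
        cuts = [0.005, 0.01, 0.05, 0.1, 0.3, 0.5]
        vals = [restricted_stopping_power(water_mat, T, c) for c in cuts]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_restricted_below_unrestricted(self, silicone_mat):
        T = np.geomspace(0.05, 10, 40)
        l = restricted_stopping_power(silicone_mat, T, cutoff=0.010)
        s = collision_stopping_power(silicone_mat, T)
        assert np.all(l <= s + 1e-12)

    def test_water_1mev_10kev_cutoff_value(self, water_mat):
        # published water L_Delta (Delta = 10 keV) at 1 MeV is ~1.48 MeV cm^2/g,
        # i.e. the restriction removes roughly a fifth of the collision losses
        l = restricted_stopping_power(water_mat, 1.0, 0.010)
        s = collision_stopping_power(water_mat, 1.0)
        assert l == pytest.approx(1.48, rel=0.02)
        assert 0.75 <= l / s <= 0.90

    def test_cutoff_above_half_energy_rejected(self, water_mat):
        with pytest.raises(ValueError):
            restricted_stopping_power(water_mat, 0.015, cutoff=0.010)


class TestSlowingDownSpectrum:
    def test_support_ends_at_compton_edge(self, water_mat):
        spec = make_line_spectrum([(1.0, 1.0)])
        phi = slowing_down_spectrum(spec, water_mat)
        edge = compton_edge(1.0)
        assert phi.energies[-1] == pytest.approx(edge)
        assert phi.fluence[-1] == pytest.approx(0.0, abs=1e-10 * phi.fluence.max())

    def test_recoil_number_conservation(self, co60_spec):
        """Integral of the recoil spectrum equals the weighted KN totals."""
        e, w = co60_spec.as_lines()
        fine = np.linspace(0, compton_edge(float(e[-1])), 40001)
        total = np.trapezoid(initial_recoil_spectrum(co60_spec, fine), fine)
        expected = sum(wi * klein_nishina(float(ei))[0] for ei, wi in zip(e, w))
        assert total == pytest.approx(expected, rel=1e-5)

    def test_fluence_nonnegative_and_soft_spectrum_rejected(self, water_mat):
        phi = slowing_down_spectrum(co60(), water_mat)
        assert np.all(phi.fluence >= 0)
        with pytest.raises(ValueError):
            slowing_down_spectrum(make_line_spectrum([(0.02, 1.0)]), water_mat)


class TestMeanStoppingPowerRatio:
    def test_self_ratio_is_one(self, water_mat, co60_spec):
        assert mean_stopping_power_ratio(
            water_mat, water_mat, co60_spec, cutoff=0.010
        ) == pytest.approx(1.0, rel=1e-12)

    def test_co60_restricted_silicone_value_frozen(self, silicone_mat, water_mat, co60_spec):
        """Regression pin of the CSDA Spencer-Attix-style average."""
        r = mean_stopping_power_ratio(silicone_mat, water_mat, co60_spec, cutoff=0.010)
        assert r == pytest.approx(0.9415, abs=0.002)

    def test_mean_value_property(self, silicone_mat, water_mat, co60_spec):
        """The average lies between the pointwise ratio extremes."""
        r = mean_stopping_power_ratio(silicone_mat, water_mat, co60_spec, cutoff=0.010)
        grid = np.geomspace(0.010, compton_edge(1.33), 200)

        def l_of(m):
            s = collision_stopping_power(m, grid)
            ok = grid >= 0.020
            s[ok] = restricted_stopping_power(m, grid[ok], 0.010)
            return s

        pointwise = l_of(silicone_mat) / l_of(water_mat)
        assert pointwise.min() - 1e-9 <= r <= pointwise.max() + 1e-9

    def test_raising_i_lowers_ratio(self, water_mat, co60_spec):
        """Monotone sensitivity: a larger mean excitation energy lowers S_col."""
        base = MaterialComposition("m", 1.0, {"H": 0.112, "O": 0.888},
                                   mean_excitation_override_eV=80.0)
        harder = MaterialComposition("m2", 1.0, {"H": 0.112, "O": 0.888},
                                     mean_excitation_override_eV=95.0)
        r1 = mean_stopping_power_ratio(base, water_mat, co60_spec, cutoff=0.010)
        r2 = mean_stopping_power_ratio(harder, water_mat, co60_spec, cutoff=0.010)
        assert r2 < r1

    def test_evaluate_bundles_consistently(self, water_mat):
        ev = evaluate(water_mat, 1.0, cutoff=0.010)
        assert ev.l_delta < ev.s_col
        assert ev.delta == pytest.approx(density_effect(water_mat, 1.0))
        assert ev.tau == pytest.approx(1.0 / ELECTRON_REST_MEV)
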