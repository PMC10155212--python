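import numpy as np
import pytest

from mabcluster.formfactors import (
    ClusterModelParams,
    cluster_radius_from_rg,
    debye_structure_factor,
    fc_structure_factor,
    fisher_burford,
    fjc_radius_of_gyration,
    fjc_structure_factor,
    fractal_rg,
    internal_volume_fraction,
    monomer_form_factor,
    polydisperse_average,
    py_hs_structure_factor,
    sphere_form_factor,
    y_bead_form_factor,
)
from mabcluster.hpt import cluster_size_distribution, weight_average


def brute_force_fjc(s, b, q):
    x = np.sinc(q * b / np.pi)
    acc = np.zeros_like(q)
    for i in range(s):
        for j in range(s):
            acc += x ** abs(i - j)
    return acc / s


class TestDebye:
    def test_single_monomer_flat(self):
        q = np.linspace(0.01, 5, 50)
        assert np.all(debye_structure_factor([[0, 0, 0]], q).values == 1.0)

    def test_dimer_closed_form(self):
        q = np.linspace(0.01, 5, 200)
        r = 1.7
        vals = debye_structure_factor([[0, 0, 0], [r, 0, 0]], q).values
        expected = 1.0 + np.sin(q * r) / (q * r)
        assert np.abs(vals - expected).max() < 1e-12

    def test_zero_q_limit_is_s(self, rng):
        pos = rng.normal(size=(7, 3))
        assert debye_structure_factor(pos, np.array([1e-10])).values[0] == pytest.approx(7.0)


class TestFJC:
    def test_monomer_flat(self):
        q = np.linspace(0.0, 3, 50)
        assert np.all(fjc_structure_factor(1, 12.0, q).values == 1.0)

    @pytest.mark.parametrize("s", [2, 3, 10, 27, 50])
    def test_equals_brute_force_double_sum(self, s, rng):
        # independent O(s^2) oracle on a random grid including tiny q;
        # agreement to 1e-12 relative to the curve scale (S(0) = s, so an
        # absolute comparison would demand sub-ulp agreement of the oracle)
        q = np.sort(np.concatenate([[1e-8, 1e-4], rng.uniform(0.0, 3.0, 200)]))
        closed = fjc_structure_factor(s, 12.0, q).values
        brute = brute_force_fjc(s, 12.0, q)
        assert (np.abs(closed - brute) / np.maximum(1.0, np.abs(brute))).max() < 1e-12

    def test_normalization_limits(self):
        vals = fjc_structure_factor(10, 12.0, np.array([1e-12, 1e3])).values
        assert vals[0] == pytest.approx(10.0, abs=1e-9)
        assert vals[-1] == pytest.approx(1.0, abs=1e-3)

    def test_guinier_radius_matches_published_value(self):
        # R_g = b sqrt(s/6) = 15.5 nm for s = 10, b = 12 nm
        assert fjc_radius_of_gyration(10, 12.0) == pytest.approx(15.5, abs=0.05)
        q = np.linspace(1e-3, 0.03, 20)
        vals = fjc_structure_factor(10, 12.0, q).values / 10.0
        rg_fit = np.sqrt(-3.0 * np.polyfit(q**2, np.log(vals), 1)[0])
        # finite-chain Guinier radius b sqrt((s^2-1)/(6s))
        assert rg_fit == pytest.approx(fjc_radius_of_gyration(10, 12.0, asymptotic=False), rel=0.01)


class TestFisherBurford:
    def test_unity_at_zero_q(self):
        assert fisher_burford(np.array([0.0]), 15.0, 2.5).values[0] == 1.0

    def test_direct_substitution(self):
        vals = fisher_burford(np.array([1.0]), 1.0, 2.0).values
        assert vals[0] == pytest.approx(0.75, rel=1e-12)

    def test_asymptotic_log_slope_is_minus_df(self):
        rg, df = 15.0, 2.5
        q = np.geomspace(150 / rg, 1500 / rg, 50)
        slope = np.polyfit(np.log(q), np.log(fisher_burford(q, rg, df).values), 1)[0]
        assert slope == pytest.approx(-df, rel=0.01)


class TestPercusYevick:
    def test_ideal_limit(self):
        q = np.linspace(0.01, 5, 50)
        assert np.all(py_hs_structure_factor(q, 0.0, 12.0).values == 1.0)

    def test_zero_q_compressibility(self):
        val = py_hs_structure_factor(np.array([1e-8]), 0.3, 12.0).values[0]
        assert val == pytest.approx(0.7**4 / 1.6**2, rel=1e-6)
        assert val == pytest.approx(0.0938, abs=2e-4)

    def test_peak_near_two_pi_over_diameter(self):
        d = 12.0
        q = np.linspace(0.05, 1.5, 2000)
        vals = py_hs_structure_factor(q, 0.4, d).values
        q_peak = q[np.argmax(vals)]
        assert q_peak * d == pytest.approx(2 * np.pi, rel=0.15)

    def test_high_packing_rejected(self):
        with pytest.raises(ValueError):
            py_hs_structure_factor(np.array([0.1]), 0.55, 12.0)


class TestFractalGeometry:
    def test_unit_argument(self):
        assert fractal_rg(1, 6.0, 2.5, 1.0) == pytest.approx(6.0)

    def test_published_fc_radius(self):
        # printed inputs; the printed 17.4 nm reflects a rounded prefactor
        assert fractal_rg(10, 6.0, 2.5, 0.71) == pytest.approx(17.4, rel=0.01)

    def test_power_law_doubling(self):
        r1 = fractal_rg(16, 6.0, 2.5, 0.71)
        r2 = fractal_rg(32, 6.0, 2.5, 0.71)
        assert r2 / r1 == pytest.approx(2 ** (1 / 2.5), rel=1e-12)

    def test_embedding_radius_reduces_to_solid_sphere_at_df3(self):
        assert cluster_radius_from_rg(1.0, 3.0) == pytest.approx(np.sqrt(5 / 3), rel=1e-12)


class TestInternalVolumeFraction:
    def test_monomer_identity(self):
        assert internal_volume_fraction(1, 6.0, 6.0, 1.0) == 1.0

    def test_scale_invariance(self):
        a = internal_volume_fraction(10, 6.0, 23.0, 0.8)
        b = internal_volume_fraction(10, 60.0, 230.0, 0.8)
        assert a == pytest.approx(b, rel=1e-14)

    def test_linear_in_a_phi(self):
        full = internal_volume_fraction(10, 6.0, 23.0, 1.0)
        half = internal_volume_fraction(10, 6.0, 23.0, 0.5)
        assert half == pytest.approx(full / 2, rel=1e-14)

    def test_overpacked_rejected(self):
        with pytest.raises(ValueError):
            internal_volume_fraction(50, 6.0, 9.0, 1.0)


class TestFractalColloid:
    def test_normalization_contract(self):
        q = np.array([1e-9, 1e3])
        for s in (5, 10, 15):
            vals = fc_structure_factor(s, ClusterModelParams(), q).values
            assert vals[0] == pytest.approx(s, rel=0.01)
            assert vals[-1] == pytest.approx(1.0, abs=1e-3)

    def test_a_phi_zero_limit_recovers_envelope_only_form(self):
        q = np.linspace(0.01, 1.5, 100)
        params = ClusterModelParams(A_phi=1e-12)
        s = 10
        vals = fc_structure_factor(s, params, q).values
        rg = fractal_rg(s, params.R1, params.dF, params.k)
        envelope = 1.0 + (s - 1) * fisher_burford(q, rg, params.dF).values
        assert np.abs(vals - envelope).max() < 1e-6

    def test_monomer_rejected(self):
        with pytest.raises(ValueError):
            fc_structure_factor(1, ClusterModelParams(), np.array([0.1]))

    def test_agrees_with_fjc_below_correlation_dip(self):
        # both models share the cluster R_g scale, so they coincide between
        # the Guinier regime and the nearest-neighbor dip (qd < ~1.3, d = b)
        q = np.linspace(0.02, 0.105, 40)  # qd in [0.24, 1.26] for b = 12 nm
        fjc = fjc_structure_factor(15, 12.0, q).values
        fc = fc_structure_factor(15, ClusterModelParams(), q).values
        assert np.abs((fc - fjc) / fjc).max() < 0.05


class TestMonomerFormFactor:
    def test_sphere_normalization_and_first_zero(self):
        q = np.linspace(1e-6, 3.0, 4000)
        vals = sphere_form_factor(q, 6.0).values
        assert vals[0] == pytest.approx(1.0, abs=1e-9)
        # the first zero is the first local minimum of the amplitude squared
        first_min = int(np.argmax(np.diff(vals) > 0))
        assert q[first_min] * 6.0 == pytest.approx(4.493, abs=0.01)

    def test_y_bead_guinier_radius_consistent_with_geometry(self, units):
        q = np.linspace(1e-3, 0.05, 20)
        vals = y_bead_form_factor(q, units).values
        rg = np.sqrt(-3.0 * np.polyfit(q**2, np.log(vals), 1)[0])
        assert rg == pytest.approx(1.7297 * units.sigma_nm, rel=0.01)

    def test_tabulated_interpolation_and_range_guard(self):
        q = np.linspace(0.05, 2.0, 80)
        curve = sphere_form_factor(q, 6.0)
        sub = monomer_form_factor(curve, np.linspace(0.1, 1.5, 33))
        assert np.all(sub.values > 0)
        with pytest.raises(ValueError, match="extrapolation"):
            monomer_form_factor(curve, np.linspace(0.01, 1.0, 10))

    def test_y_bead_sphere_convolution_reduces_intensity(self, units):
        q = np.linspace(0.2, 2.0, 30)
        point = y_bead_form_factor(q, units, bead_convention="point").values
        solid = y_bead_form_factor(q, units, bead_convention="sphere").values
        assert np.all(solid <= point + 1e-12)


class TestPolydisperseAverage:
    def test_monomers_only_flat(self):
        dist = cluster_size_distribution(0.0, s_max=5, tail_tol=1.0)
        q = np.linspace(0.01, 2, 30)
        assert np.allclose(polydisperse_average(dist, "fjc", q).values, 1.0)

    def test_zero_q_equals_weight_average(self):
        dist = cluster_size_distribution(0.25)
        val = polydisperse_average(dist, "fjc", np.array([1e-10])).values[0]
        assert val == pytest.approx(weight_average(dist), rel=1e-6)

    def test_degenerate_distribution_equals_single_size(self):
        dist = cluster_size_distribution(0.0, s_max=10, tail_tol=1.0)
        dist.n[:] = 0.0
        dist.n[9] = 1.0  # all clusters have s = 10
        q = np.linspace(0.01, 2, 60)
        avg = polydisperse_average(dist, "fjc", q).values
        single = fjc_structure_factor(10, 12.0, q).values
        assert np.abs(avg - single).max() < 1e-10

    def test_matches_explicit_per_size_sum(self):
        dist = cluster_size_distribution(0.2, s_max=64, tail_tol=1.0)
        q = np.linspace(0.01, 2, 40)
        fast = polydisperse_average(dist, "fjc", q, weight_tail_tol=0.0).values
        w = dist.n * dist.sizes
        explicit = sum(
            ws * fjc_structure_factor(int(s), 12.0, q).values
            for s, ws in zip(dist.sizes, w)
        ) / w.sum()
        assert np.abs(fast - explicit).max() < 1e-10

    def test_fc_model_average(self):
        dist = cluster_size_distribution(0.2, s_max=64, tail_tol=1.0)
        vals = polydisperse_average(dist, "fc", np.array([1e-9])).values
        assert vals[0] == pytest.approx(weight_average(dist), rel=0.01)
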