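import numpy as np
import pytest

from mabcluster.io import ScatteringCurve, read_dat, write_dat
from mabcluster.reduction import (
    SLSRecord,
    apparent_mw,
    cumulant_diffusion,
    effective_structure_factor,
    merge_and_scale,
    microrheology_viscosity,
    optical_constant,
    rayleigh_ratio,
    synthesize_dataset,
)


class TestSLS:
    def test_solvent_equals_sample_scatters_nothing(self):
        rec = SLSRecord(I90_sample=1.0, I90_solvent=1.0, I90_reference=2.0, c=10.0)
        assert rayleigh_ratio(rec) == 0.0

    def test_direct_substitution_with_toluene_reference(self):
        rec = SLSRecord(I90_sample=2.0, I90_solvent=1.0, I90_reference=1.0,
                        c=1.0, n=1.496, n_ref=1.496)
        assert rayleigh_ratio(rec) == pytest.approx(1.37e-5, rel=1e-12)

    def test_linearity_in_excess_intensity(self):
        r1 = rayleigh_ratio(SLSRecord(2.0, 1.0, 1.0, c=1.0))
        r2 = rayleigh_ratio(SLSRecord(3.0, 1.0, 1.0, c=1.0))
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_ratio(SLSRecord(1.0, 0.5, 0.0, c=1.0))

    def test_apparent_mw_roundtrip(self):
        template = SLSRecord(1.0, 0.0, 1.0, c=2.0)
        target = 150_000.0
        r90 = optical_constant(template) * (template.c * 1e-3) * target
        i_sample = (
            template.I90_solvent
            + r90 / template.R_ref / (template.n / template.n_ref) ** 2
        )
        rec = SLSRecord(i_sample, template.I90_solvent, 1.0, c=template.c)
        assert apparent_mw(rec) == pytest.approx(target, rel=1e-10)

    def test_halving_concentration_doubles_mw(self):
        a = SLSRecord(2.0, 1.0, 1.0, c=2.0)
        b = SLSRecord(2.0, 1.0, 1.0, c=1.0)
        assert apparent_mw(b) == pytest.approx(2 * apparent_mw(a), rel=1e-12)

    def test_zero_concentration_rejected(self):
        with pytest.raises(ValueError):
            apparent_mw(SLSRecord(2.0, 1.0, 1.0, c=0.0))


class TestDLS:
    def test_recovers_generated_decay_rate(self):
        tau = np.geomspace(1e-6, 1e-2, 200)
        gamma, q = 3000.0, 2e5
        g2 = 0.9 * np.exp(-2 * gamma * tau)
        d = cumulant_diffusion(tau, g2, q)
        assert d == pytest.approx(gamma / q**2, rel=1e-3)

    def test_gamma_scales_with_q_squared(self):
        tau = np.geomspace(1e-6, 1e-2, 200)
        g2 = 0.9 * np.exp(-2 * 3000.0 * tau)
        d1 = cumulant_diffusion(tau, g2, 1e5)
        d2 = cumulant_diffusion(tau, g2, 2e5)
        assert d1 == pytest.approx(4 * d2, rel=1e-6)

    def test_flat_curve_rejected(self):
        tau = np.linspace(1e-6, 1e-2, 50)
        with pytest.raises(ValueError):
            cumulant_diffusion(tau, np.ones_like(tau), 1e5)

    def test_viscosity_ratios(self):
        assert microrheology_viscosity(2.0, 2.0) == 1.0
        assert microrheology_viscosity(0.5, 4.0) == 8.0
        with pytest.raises(ValueError):
            microrheology_viscosity(0.0, 1.0)

    def test_stokes_einstein_consistency(self):
        # eta from D and R_H equals eta_r * eta_solvent for any tracer size
        kbt, rh = 4.11e-14, 0.5e-4  # [erg], [cm]
        eta_solvent = 0.01  # [poise]
        d_solvent = kbt / (6 * np.pi * eta_solvent * rh)
        eta_r = 5.0
        d_sample = d_solvent / eta_r
        eta_sample = kbt / (6 * np.pi * d_sample * rh)
        assert eta_sample == pytest.approx(
            microrheology_viscosity(d_sample, d_solvent) * eta_solvent, rel=1e-12
        )


class TestMerging:
    def _curves(self, factor=1.0):
        # intensity exponential in q: exactly representable by the
        # (q, log I)-linear interpolation the merge uses, so grid mismatch
        # introduces no interpolation error
        q_ref = np.geomspace(0.007, 0.5, 120)
        ref = ScatteringCurve(q=q_ref, I=100.0 * np.exp(-q_ref * 6), c=3.8)
        q_pin = np.geomspace(0.004, 1.2, 200)
        pin = ScatteringCurve(
            q=q_pin, I=100.0 * np.exp(-q_pin * 6) * factor, c=3.8, scale="relative"
        )
        return pin, ref

    def test_identical_curves_unit_factor(self):
        pin, ref = self._curves(1.0)
        merged, factor = merge_and_scale(pin, ref)
        assert factor == pytest.approx(1.0, rel=1e-12)
        assert np.abs(merged.I - np.interp(merged.q, ref.q, ref.I)).max() < 1e-9

    def test_known_scale_factor_recovered(self):
        pin, ref = self._curves(3.7)
        _merged, factor = merge_and_scale(pin, ref)
        assert factor == pytest.approx(1 / 3.7, rel=1e-10)

    def test_insufficient_overlap_rejected(self):
        pin, ref = self._curves()
        short = ScatteringCurve(q=ref.q[:5], I=ref.I[:5], c=3.8)
        with pytest.raises(ValueError, match="overlap"):
            merge_and_scale(short, ref, q_match_min=0.2)


class TestEffectiveStructureFactor:
    def test_self_ratio_is_unity(self):
        q = np.geomspace(0.01, 0.5, 60)
        curve = ScatteringCurve(q=q, I=np.exp(-q * 3) * 50, c=5.0)
        s = effective_structure_factor(curve, curve)
        assert np.allclose(s.I, 1.0, atol=1e-14)

    def test_constructed_structure_factor_recovered(self):
        q = np.geomspace(0.01, 0.5, 60)
        ff = ScatteringCurve(q=q, I=np.exp(-q * 3) * 50, c=3.8)
        s_true = 1.0 / (1.0 + 5 * np.exp(-((q * 30) ** 2)))
        sample = ScatteringCurve(q=q, I=ff.I / 3.8 * 80.0 * s_true, c=80.0)
        s = effective_structure_factor(sample, ff)
        assert np.abs(s.I - s_true).max() < 1e-12

    def test_concentration_mislabel_scales_inversely(self):
        q = np.geomspace(0.01, 0.5, 60)
        ff = ScatteringCurve(q=q, I=np.exp(-q * 3) * 50, c=3.8)
        sample = ScatteringCurve(q=q, I=ff.I * 10, c=10.0)
        wrong = ScatteringCurve(q=q, I=ff.I * 10, c=20.0)
        s_right = effective_structure_factor(sample, ff)
        s_wrong = effective_structure_factor(wrong, ff)
        assert np.allclose(s_wrong.I, s_right.I / 2)


class TestSyntheticCloseLoop:
    def test_zero_noise_pipeline_recovers_generating_seff(self):
        # the published protocol: fix the pinhole scale on a dilute sample,
        # apply it to the concentrated curves, then ratio out the form factor
        data = synthesize_dataset([26.0, 147.0], noise_level=0.0, seed=0)
        _merged, factor = merge_and_scale(data.pinhole_dilute, data.formfactor,
                                          q_match_min=0.04)
        assert factor == pytest.approx(1 / data.pinhole_scale, rel=1e-10)
        for curve, s_true in zip(data.curves, data.s_eff_true):
            scaled = ScatteringCurve(q=curve.q, I=curve.I * factor, c=curve.c,
                                     scale="absolute")
            s_meas = effective_structure_factor(scaled, data.formfactor)
            s_ref = np.interp(s_meas.q * 10.0, s_true.q, s_true.values)
            assert np.abs(s_meas.I - s_ref).max() < 1e-12

    def test_same_seed_reproduces_dataset(self):
        a = synthesize_dataset([61.7], noise_level=0.05, seed=7)
        b = synthesize_dataset([61.7], noise_level=0.05, seed=7)
        assert np.array_equal(a.curves[0].I, b.curves[0].I)
        assert a.sls_records[0] == b.sls_records[0]

    def test_sls_records_carry_the_model_napp(self):
        from mabcluster.hpt import cluster_size_distribution
        from mabcluster.solution import napp_w
        from mabcluster.wertheim import default_system, mass_action_solve
        from mabcluster.geometry import concentration_to_number_density
        from dataclasses import replace

        c = 100.0
        data = synthesize_dataset([c], noise_level=0.0, seed=0)
        mw = apparent_mw(data.sls_records[0])
        rho = concentration_to_number_density(c)
        dist = cluster_size_distribution(mass_action_solve(replace(default_system(), rho=rho)).p)
        assert mw / 150_000.0 == pytest.approx(napp_w(c, dist), rel=1e-6)

    def test_dls_correlograms_encode_model_viscosity(self):
        data = synthesize_dataset([147.0], noise_level=0.0, seed=0)
        d = cumulant_diffusion(data.dls_tau, data.dls_g2[0], data.dls_q)
        eta_r = microrheology_viscosity(d, data.dls_d_solvent)
        assert eta_r == pytest.approx(data.eta_r_true[0], rel=1e-3)
        assert eta_r > 2.0  # strongly clustered state is markedly viscous

    def test_noise_bounded_recovery(self):
        noise = 0.02
        data = synthesize_dataset([61.7], noise_level=noise, seed=3)
        _m, factor = merge_and_scale(data.pinhole_dilute, data.formfactor,
                                     q_match_min=0.04)
        scaled = ScatteringCurve(q=data.curves[0].q, I=data.curves[0].I * factor,
                                 c=data.curves[0].c, scale="absolute")
        s_meas = effective_structure_factor(scaled, data.formfactor)
        s_ref = np.interp(s_meas.q * 10.0, data.s_eff_true[0].q, data.s_eff_true[0].values)
        rel = np.abs(s_meas.I - s_ref) / s_ref
        assert rel.max() < 10 * noise


class TestIO:
    def test_dat_roundtrip(self, tmp_path):
        q = np.geomspace(0.01, 0.5, 40)
        curve = ScatteringCurve(q=q, I=np.exp(-q) * 7, sigma=0.01 * np.ones_like(q),
                                c=12.5, scale="relative")
        path = tmp_path / "curve.dat"
        write_dat(curve, path)
        back = read_dat(path)
        assert np.allclose(back.q, curve.q)
        assert np.allclose(back.I, curve.I)
        assert back.c == 12.5
        assert back.scale == "relative"
        assert back.sigma is not None

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            ScatteringCurve(q=np.array([0.2, 0.1]), I=np.array([1.0, 2.0]))
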