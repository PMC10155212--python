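"""Experimental data-reduction formulas and the synthetic-fixture generator.

Static light scattering (SLS) gives the apparent weight-average molecular
weight through the excess Rayleigh ratio,

    <M_w>_app = R(90) / (K C),
    K = 4 pi^2 n^2 (dn/dC)^2 / (N_A lambda_0^4),

DLS tracer microrheology turns a first-cumulant diffusion coefficient into
a relative viscosity eta_r = D_solvent/D_sample, and SAXS concentration
series reduce to effective structure factors
S^eff(q) = [I(q)/c] / [I_ff(q)/c_ff] after merging pinhole-camera curves
onto the absolute-scale reference grid.

No public scattering data exist for this antibody, so
:func:`synthesize_dataset` generates a self-consistent concentration
series (SAXS curves, SLS records, DLS correlograms) from the forward
cluster model plus multiplicative log-normal noise; the reduction pipeline
must recover the generating model exactly at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formfactors import ClusterModelParams, FormFactorCurve
from .geometry import UnitSystem
from .hpt import cluster_size_distribution
from .io import ScatteringCurve
from .solution import SolutionParams, effective_solution_structure_factor, napp_w

__all__ = [
    "SLSRecord",
    "rayleigh_ratio",
    "apparent_mw",
    "cumulant_diffusion",
    "microrheology_viscosity",
    "merge_and_scale",
    "effective_structure_factor",
    "SyntheticDataset",
    "synthesize_dataset",
]

AVOGADRO = 6.02214076e23
TOLUENE_RAYLEIGH = 1.37e-5  # [cm^-1] at 25 C, 632.8 nm
DNDC_DEFAULT = 0.192  # [L/g] refractive index increment of the antibody


@dataclass(frozen=True)
class SLSRecord:
    """One static-light-scattering measurement at 90 degrees."""

    I90_sample: float
    I90_solvent: float
    I90_reference: float
    c: float  # [mg/mL]
    n: float = 1.333
    n_ref: float = 1.496  # toluene
    R_ref: float = TOLUENE_RAYLEIGH  # [cm^-1]
    dndc: float = DNDC_DEFAULT  # [L/g]
    lambda0: float = 632.8  # [nm]

    def __post_init__(self) -> None:
        if min(self.I90_sample, self.I90_solvent, self.I90_reference) < 0 or self.c < 0:
            raise ValueError("intensities and concentration must be non-negative")


def rayleigh_ratio(record: SLSRecord) -> float:
    """Excess Rayleigh ratio R(90) [cm^-1].

    R(90) = [(I(90) - I_s(90)) / I_ref(90)] * R_ref * (n/n_ref)^2; zero when
    the sample scatters like the pure solvent.
    """
    if record.I90_reference <= 0:
        raise ValueError("reference intensity must be positive")
    return (
        (record.I90_sample - record.I90_solvent)
        / record.I90_reference
        * record.R_ref
        * (record.n / record.n_ref) ** 2
    )


def optical_constant(record: SLSRecord) -> float:
    """K = 4 pi^2 n^2 (dn/dC)^2 / (N_A lambda_0^4) [cm^2 mol g^-2].

    Units: dn/dC in L/g = 1000 cm^3/g, lambda_0 in cm, so that
    R(90)/(K C) with C in g/mL yields g/mol.
    """
    lam_cm = record.lambda0 * 1e-7
    dndc_cm3 = record.dndc * 1000.0
    return 4.0 * np.pi**2 * record.n**2 * dndc_cm3**2 / (AVOGADRO * lam_cm**4)


def apparent_mw(record: SLSRecord) -> float:
    """Apparent weight-average molecular weight <M_w>_app = R(90)/(K C) [g/mol]."""
    if record.c <= 0:
        raise ValueError("concentration must be positive")
    c_g_ml = record.c * 1e-3
    return rayleigh_ratio(record) / (optical_constant(record) * c_g_ml)


def cumulant_diffusion(
    tau, g2_minus_1, q: float, fit_fraction: float = 0.3
) -> float:
    """Diffusion coefficient from a first-order cumulant fit of g2 - 1.

    Fits ln(g2 - 1) = ln(beta) - 2 Gamma tau on the early-decay window
    where g2 - 1 exceeds ``fit_fraction`` of its initial amplitude, and
    returns D = Gamma / q^2.  Units follow the inputs (q^-2 tau^-1).
    """
    tau = np.asarray(tau, dtype=float)
    g = np.asarray(g2_minus_1, dtype=float)
    if q <= 0:
        raise ValueError("scattering vector must be positive")
    if g[0] <= 0 or g[-1] >= g[0]:
        raise ValueError("correlation curve must decay from a positive amplitude")
    window = g > fit_fraction * g[0]
    if window.sum() < 3:
        raise ValueError("too few points in the early-decay fit window")
    slope, _ = np.polyfit(tau[window], np.log(g[window]), 1)
    gamma = -slope / 2.0
    if gamma <= 0:
        raise ValueError("fitted decay rate is not positive")
    return float(gamma / q**2)


def microrheology_viscosity(D_sample: float, D_solvent: float) -> float:
    """Relative viscosity from tracer diffusion: eta_r = 1/D_r = D_solvent/D_sample."""
    if D_sample <= 0 or D_solvent <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return D_solvent / D_sample


def merge_and_scale(
    pinhole: ScatteringCurve,
    reference: ScatteringCurve,
    q_match_min: float = 0.04,
) -> tuple[ScatteringCurve, float]:
    """Scale a pinhole-camera curve onto the absolute-scale reference.

    The pinhole intensities are interpolated (linear in q, log in I) onto
    the reference grid, and a single multiplicative factor minimizing the
    squared log-intensity difference over the overlap window
    q > ``q_match_min`` is applied.  Returns the rescaled curve on the
    reference grid and the factor.
    """
    lo = max(pinhole.q[0], reference.q[0])
    hi = min(pinhole.q[-1], reference.q[-1])
    grid_mask = (reference.q >= lo) & (reference.q <= hi)
    match_mask = grid_mask & (reference.q > q_match_min)
    if match_mask.sum() < 5:
        raise ValueError(
            f"fewer than 5 overlapping points above q_match_min={q_match_min}"
        )
    q_out = reference.q[grid_mask]
    if np.any(pinhole.I <= 0) or np.any(reference.I[grid_mask] <= 0):
        raise ValueError("log-space merging requires positive intensities")
    log_interp = np.interp(q_out, pinhole.q, np.log(pinhole.I))
    log_ref = np.log(reference.I[grid_mask])
    resid = log_ref[match_mask[grid_mask]] - log_interp[match_mask[grid_mask]]
    log_factor = float(np.mean(resid))  # least squares in log space
    scaled = ScatteringCurve(
        q=q_out,
        I=np.exp(log_interp + log_factor),
        c=pinhole.c,
        scale=reference.scale,
        q_unit=reference.q_unit,
    )
    return scaled, float(np.exp(log_factor))


def effective_structure_factor(
    sample: ScatteringCurve, formfactor: ScatteringCurve
) -> ScatteringCurve:
    """Measured effective structure factor S^eff(q) = [I(q)/c] / [I_ff(q)/c_ff].

    Both curves must share a q support; non-positive form-factor points are
    masked out (dropped) with a warning.
    """
    import warnings

    lo = max(sample.q[0], formfactor.q[0])
    hi = min(sample.q[-1], formfactor.q[-1])
    mask = (sample.q >= lo) & (sample.q <= hi)
    if not mask.any():
        raise ValueError("no common q support")
    q = sample.q[mask]
    ff = np.interp(q, formfactor.q, formfactor.I)
    good = ff > 0
    if not good.all():
        warnings.warn(
            f"masked {int((~good).sum())} points with non-positive form factor",
            stacklevel=2,
        )
    s_eff = (sample.I[mask][good] / sample.c) / (ff[good] / formfactor.c)
    return ScatteringCurve(
        q=q[good], I=s_eff, c=sample.c, scale="relative", q_unit=sample.q_unit
    )


@dataclass
class SyntheticDataset:
    """Forward-model concentration series with matched reduction inputs."""

    curves: list[ScatteringCurve]  # pinhole-style curves, relative scale
    formfactor: ScatteringCurve  # dilute reference on absolute scale
    pinhole_dilute: ScatteringCurve  # dilute curve on the arbitrary pinhole scale
    s_eff_true: list[FormFactorCurve]  # generating S^eff(q) per concentration
    eta_r_true: list[float]  # generating relative viscosities
    sls_records: list[SLSRecord]
    dls_tau: np.ndarray
    dls_g2: list[np.ndarray]  # g2 - 1 correlograms (tracer in each sample)
    dls_q: float
    dls_d_solvent: float  # tracer diffusion coefficient in pure buffer
    concentrations: np.ndarray
    pinhole_scale: float  # the arbitrary factor the pipeline must recover


def synthesize_dataset(
    concentrations,
    noise_level: float = 0.0,
    seed: int = 0,
    q_grid_invA=None,
    params: SolutionParams | None = None,
    cluster_params: ClusterModelParams | None = None,
    units: UnitSystem | None = None,
    pinhole_scale: float = 3.7,
    c_ff: float = 3.8,
    M1: float = 150_000.0,
) -> SyntheticDataset:
    """Generate a self-consistent synthetic concentration series.

    For each concentration the bond probability comes from the calibrated
    Wertheim stage, and I(q)/c = K M_1 P_1(q) <S_c(q)>_w S_c^eff(q) is
    evaluated with the fjc cluster model; the dilute form-factor curve uses
    the same monomer P_1.  Pinhole curves carry an arbitrary overall scale
    factor (to be recovered by merging) and multiplicative log-normal noise
    of width ``noise_level``.  SLS records and single-exponential DLS
    correlograms are generated from the same model state.  Fully seeded.
    """
    from .formfactors import y_bead_form_factor
    from .solution import cluster_volume_fraction, relative_viscosity
    from .wertheim import default_system, mass_action_solve
    from dataclasses import replace as _replace

    rng = np.random.default_rng(seed)
    params = params or SolutionParams()
    cluster_params = cluster_params or ClusterModelParams()
    units = units or UnitSystem()
    concentrations = np.asarray(concentrations, dtype=float)
    if q_grid_invA is None:
        q_grid_invA = np.geomspace(0.00626, 0.45, 120)
    q_nm = np.asarray(q_grid_invA) * 10.0
    p1 = y_bead_form_factor(q_nm, units=units)
    system = default_system(units=units)
    from .geometry import concentration_to_number_density

    curves, s_effs, sls_records, g2_list, etas = [], [], [], [], []
    # optical bookkeeping for the SLS forward model
    template = SLSRecord(1.0, 0.0, 1.0, c=1.0)
    K = optical_constant(template)
    tau_grid = np.geomspace(1e-6, 1e-1, 120)  # [s]
    dls_q = 1.8e5  # [cm^-1], ~632 nm laser at mid angle
    d_solvent = 4.4e-8  # [cm^2/s], 1 um tracer in water
    for c in concentrations:
        rho = concentration_to_number_density(c, units)
        p = mass_action_solve(_replace(system, rho=rho)).p
        dist = cluster_size_distribution(p)
        s_eff = effective_solution_structure_factor(
            q_nm, c, dist, "fjc", cluster_params, params, units
        )
        s_effs.append(s_eff)
        intensity = M1 * p1.values * s_eff.values * c  # relative units, K folded out
        noise = np.exp(rng.normal(0.0, noise_level, size=intensity.shape)) if noise_level else 1.0
        curves.append(
            ScatteringCurve(
                q=np.asarray(q_grid_invA),
                I=intensity * pinhole_scale * noise,
                c=float(c),
                scale="relative",
            )
        )
        # SLS record consistent with <N_app>_w at this concentration
        napp = napp_w(c, dist, params, units)
        r90 = K * (c * 1e-3) * M1 * napp
        i_ref = 1.0
        i_solvent = 0.05
        i_sample = i_solvent + r90 / TOLUENE_RAYLEIGH / (template.n / template.n_ref) ** 2 * i_ref
        if noise_level:
            i_sample *= np.exp(rng.normal(0.0, noise_level))
        sls_records.append(SLSRecord(i_sample, i_solvent, i_ref, c=float(c)))
        # DLS correlogram of the tracer: eta_r slows diffusion by 1/eta_r
        phi_hs = cluster_volume_fraction(c, dist, params, units)
        eta_r = relative_viscosity(min(phi_hs, 0.99 * params.phi_g), params)
        etas.append(eta_r)
        gamma = (d_solvent / eta_r) * dls_q**2
        g2 = 0.8 * np.exp(-2.0 * gamma * tau_grid)
        if noise_level:
            g2 = g2 * np.exp(rng.normal(0.0, noise_level, size=g2.shape))
        g2_list.append(g2)
    ff_I = M1 * p1.values * c_ff  # dilute reference: S^eff == 1 by construction
    formfactor = ScatteringCurve(
        q=np.asarray(q_grid_invA), I=ff_I, c=float(c_ff), scale="absolute"
    )
    noise_d = np.exp(rng.normal(0.0, noise_level, size=ff_I.shape)) if noise_level else 1.0
    pinhole_dilute = ScatteringCurve(
        q=np.asarray(q_grid_invA),
        I=ff_I * pinhole_scale * noise_d,
        c=float(c_ff),
        scale="relative",
    )
    return SyntheticDataset(
        curves=curves,
        formfactor=formfactor,
        pinhole_dilute=pinhole_dilute,
        s_eff_true=s_effs,
        eta_r_true=etas,
        sls_records=sls_records,
        dls_tau=tau_grid,
        dls_g2=g2_list,
        dls_q=dls_q,
        dls_d_solvent=d_solvent,
        concentrations=concentrations,
        pinhole_scale=pinhole_scale,
    )
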