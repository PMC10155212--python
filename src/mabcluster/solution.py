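"""Cluster-fluid thermodynamics and solution-level observables.

After the Wertheim/hyperbranched stage has produced a cluster size
distribution at each concentration, the clusters themselves are treated as
a new colloidal fluid of sticky hard spheres.  This module assembles the
measurable predictions:

* the effective cluster packing fraction
  phi_HS = A * phi * <s>_n^(3/dF - 1), where phi is the nominal antibody
  packing fraction of the Wertheim analysis, A a scale factor (1.4) and
  dF = 2.0 the fractal dimension used for cluster volumes;
* the Baxter sticky-hard-sphere compressibility S_SHS(0) at stickiness tau;
* the random-phase-approximation (RPA) cluster-fluid structure factor
  S_c^eff(q), pinned to the Baxter value at q = 0;
* the apparent weight-average aggregation number
  <N_app>_w = <s>_w * S_c^eff(0) measured by SLS/SAXS forward scattering;
* the full effective solution structure factor
  S^eff(q) = <S_c(q)>_w * S_c^eff(q) and the normalized SAXS intensity
  I(q)/c = K * M_1 * P_1(q) * <S_c(q)>_w * S_c^eff(q);
* the relative viscosity eta_r = (1 - phi_HS/phi_g)^(-gamma) near the
  cluster glass transition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .formfactors import (
    ClusterModelParams,
    FormFactorCurve,
    fc_structure_factor,
    fjc_structure_factor,
    polydisperse_average,
    sphere_form_factor,
)
from .geometry import UnitSystem, concentration_to_number_density
from .hpt import ClusterSizeDistribution, number_average, weight_average
from .io import ScatteringCurve

__all__ = [
    "SolutionParams",
    "BaxterSolution",
    "cluster_volume_fraction",
    "baxter_s0",
    "rpa_effective_structure_factor",
    "napp_w",
    "effective_solution_structure_factor",
    "normalized_intensity",
    "relative_viscosity",
    "sticky_sphere_chain",
]


@dataclass(frozen=True)
class SolutionParams:
    """Cluster-fluid parameters shared across both ionic strengths.

    A          : scale factor on the cluster packing fraction (1.4).
    tau        : Baxter stickiness of the cluster-cluster attraction (2.5).
    dF_cluster : fractal dimension entering cluster volumes (2.0).
    sigma_hs   : effective antibody hard-sphere diameter [sigma] (2.95).
    gamma      : viscosity divergence exponent (3.0; 2.8 for plain hard spheres).
    phi_g      : arrest packing fraction of the cluster glass (0.63).
    """

    A: float = 1.4
    tau: float = 2.5
    dF_cluster: float = 2.0
    sigma_hs: float = 2.95
    gamma: float = 3.0
    phi_g: float = 0.63

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.gamma <= 0:
            raise ValueError("tau and gamma must be positive")
        if not 0.0 < self.phi_g < 0.74:
            raise ValueError("arrest packing fraction must lie in (0, 0.74)")


@dataclass(frozen=True)
class BaxterSolution:
    """Physical-branch solution of the sticky-hard-sphere quadratic."""

    lam: float
    S0: float


def cluster_volume_fraction(
    c: float,
    dist: ClusterSizeDistribution,
    params: SolutionParams | None = None,
    units: UnitSystem | None = None,
) -> float:
    """Effective hard-sphere packing fraction of the cluster fluid.

    phi_HS = A * phi * <s>_n^(3/dF - 1), with phi the nominal antibody
    packing fraction rho * (pi/6) * sigma_hs^3.  Emits a warning when the
    result enters the viscosity-divergence region phi_HS >= phi_g.
    """
    if params is None:
        params = SolutionParams()
    rho = concentration_to_number_density(c, units)
    phi = rho * np.pi / 6.0 * params.sigma_hs**3
    sn = number_average(dist)
    phi_hs = params.A * phi * sn ** (3.0 / params.dF_cluster - 1.0)
    if phi_hs >= params.phi_g:
        warnings.warn(
            f"cluster packing fraction {phi_hs:.3f} >= phi_g={params.phi_g}: "
            "the solution is past the predicted arrest transition",
            stacklevel=2,
        )
    return float(phi_hs)


def baxter_s0(phi_hs: float, tau: float) -> BaxterSolution:
    """Low-q limit of the sticky-hard-sphere structure factor (Percus-Yevick).

    lambda is the physical (smaller) root of

        (phi/12) lambda^2 - (tau + phi/(1-phi)) lambda + (1+phi/2)/(1-phi)^2 = 0

    and with mu = lambda phi (1-phi),

        S_SHS(0) = (1-phi)^4 / (1 + 2 phi - mu)^2.

    tau -> inf recovers the PY hard-sphere compressibility limit; absence
    of a real root signals the adhesive-sphere instability region.
    """
    if not 0.0 <= phi_hs < 0.64:
        raise ValueError("phi_hs must lie in [0, 0.64)")
    if tau <= 0:
        raise ValueError("stickiness must be positive")
    if phi_hs == 0.0:
        return BaxterSolution(lam=1.0 / tau, S0=1.0)
    a = phi_hs / 12.0
    b = tau + phi_hs / (1.0 - phi_hs)
    c0 = (1.0 + phi_hs / 2.0) / (1.0 - phi_hs) ** 2
    disc = b * b - 4.0 * a * c0
    if disc < 0.0:
        raise ArithmeticError(
            f"no real Baxter root at phi={phi_hs:.3f}, tau={tau}: "
            "state lies in the adhesive-sphere instability region"
        )
    lam = (b - np.sqrt(disc)) / (2.0 * a)
    mu = lam * phi_hs * (1.0 - phi_hs)
    s0 = (1.0 - phi_hs) ** 4 / (1.0 + 2.0 * phi_hs - mu) ** 2
    return BaxterSolution(lam=float(lam), S0=float(s0))


def rpa_effective_structure_factor(
    q_grid, s0_target: float, mean_cluster_form: FormFactorCurve
) -> FormFactorCurve:
    """RPA structure factor of the cluster fluid.

    S_c^eff(q) = 1 / (1 + nu * f(q)) with the interaction coefficient
    nu = 1/S0 - 1 fixed so that S_c^eff(0) = ``s0_target`` exactly; f is
    the normalized mean cluster form factor (f(0) = 1, f -> 0 at large q,
    hence S_c^eff -> 1).  Only the repulsion-dominated branch S0 <= 1 is
    admitted.
    """
    if not 0.0 < s0_target <= 1.0:
        raise ValueError("RPA closure requires S(0) in (0, 1]")
    q = np.asarray(q_grid, dtype=float)
    f = np.interp(q, mean_cluster_form.q, mean_cluster_form.values)
    nu = 1.0 / s0_target - 1.0
    return FormFactorCurve(q=q, values=1.0 / (1.0 + nu * f), normalization="S(0)=S0")


def _normalized_cluster_form(
    dist: ClusterSizeDistribution,
    model: str,
    q_grid,
    params: ClusterModelParams,
    mode: str,
) -> tuple[np.ndarray, np.ndarray, float]:
    """<S_c(q)>_w and its normalized inter-monomer part f(q) (both on q_grid)."""
    q = np.asarray(q_grid, dtype=float)
    sw = weight_average(dist)
    if mode == "polydisperse":
        mean_sc = polydisperse_average(dist, model, q, params).values
    elif mode == "monodisperse":
        s_eff = max(1, int(round(sw)))
        if s_eff == 1:
            mean_sc = np.ones_like(q)
        elif model == "fjc":
            mean_sc = fjc_structure_factor(s_eff, params.b, q).values
        else:
            mean_sc = fc_structure_factor(s_eff, params, q).values
        sw = float(s_eff)
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if sw > 1.0 + 1e-9:
        f = (mean_sc - 1.0) / (sw - 1.0)
    else:
        # monomer limit: the scattering objects are the coarse-grained
        # monomer spheres of radius R_1, so their form factor sets the
        # range of the RPA interaction term
        f = sphere_form_factor(q, params.R1).values
    return mean_sc, f, sw


def napp_w(
    c: float,
    dist: ClusterSizeDistribution,
    params: SolutionParams | None = None,
    units: UnitSystem | None = None,
) -> float:
    """Apparent weight-average aggregation number <N_app>_w = <s>_w * S_SHS(0)."""
    if params is None:
        params = SolutionParams()
    phi_hs = cluster_volume_fraction(c, dist, params, units)
    s0 = baxter_s0(phi_hs, params.tau).S0
    return weight_average(dist) * s0


def effective_solution_structure_factor(
    q_grid,
    c: float,
    dist: ClusterSizeDistribution,
    model: str = "fjc",
    cluster_params: ClusterModelParams | None = None,
    params: SolutionParams | None = None,
    units: UnitSystem | None = None,
    mode: str = "polydisperse",
) -> FormFactorCurve:
    """Effective solution structure factor S^eff(q) = <S_c(q)>_w * S_c^eff(q).

    ``mode`` "polydisperse" averages the cluster structure factor over the
    full size distribution; "monodisperse" evaluates it at the nearest
    integer to <s>_w (the two-step comparison of the analysis).  At q = 0
    the curve equals <N_app>_w by construction; q is in nm^-1.
    """
    if cluster_params is None:
        cluster_params = ClusterModelParams()
    if params is None:
        params = SolutionParams()
    q = np.asarray(q_grid, dtype=float)
    mean_sc, f, _ = _normalized_cluster_form(dist, model, q, cluster_params, mode)
    phi_hs = cluster_volume_fraction(c, dist, params, units)
    s0 = baxter_s0(phi_hs, params.tau).S0
    sc_eff = rpa_effective_structure_factor(
        q, s0, FormFactorCurve(q=q, values=f, normalization="P(0)=1")
    ).values
    return FormFactorCurve(q=q, values=mean_sc * sc_eff, normalization="S(0)=N_app_w")


def normalized_intensity(
    q_grid,
    c: float,
    monomer_p1: FormFactorCurve,
    dist: ClusterSizeDistribution,
    model: str = "fjc",
    cluster_params: ClusterModelParams | None = None,
    params: SolutionParams | None = None,
    units: UnitSystem | None = None,
    K: float = 1.0,
    M1: float = 150_000.0,
    interacting: bool = True,
    mode: str = "polydisperse",
) -> ScatteringCurve:
    """Normalized SAXS intensity I(q)/c = K * M_1 * P_1(q) * <S_c(q)>_w * S_c^eff(q).

    With ``interacting=False`` the cluster-fluid structure factor is set to
    one, leaving the single-cluster (dilute) intensity.  q in nm^-1; the
    returned curve carries q in Angstrom^-1 as on disk.
    """
    if cluster_params is None:
        cluster_params = ClusterModelParams()
    if params is None:
        params = SolutionParams()
    q = np.asarray(q_grid, dtype=float)
    p1 = np.interp(q, monomer_p1.q, monomer_p1.values)
    if interacting:
        s_eff = effective_solution_structure_factor(
            q, c, dist, model, cluster_params, params, units, mode
        ).values
    else:
        s_eff = polydisperse_average(dist, model, q, cluster_params).values
    i_over_c = K * M1 * p1 * s_eff
    return ScatteringCurve(
        q=q / 10.0, I=i_over_c * c, c=c, scale="relative", q_unit="A^-1"
    )


def relative_viscosity(phi_hs: float, params: SolutionParams | None = None) -> float:
    """Relative zero-shear viscosity eta_r = (1 - phi_HS/phi_g)^(-gamma).

    Equals 1 in the dilute limit and diverges at the cluster glass
    transition phi_HS -> phi_g; beyond it the model has no finite value.
    """
    if params is None:
        params = SolutionParams()
    if phi_hs < 0:
        raise ValueError("packing fraction must be non-negative")
    if phi_hs >= params.phi_g:
        raise ArithmeticError(
            f"phi_HS={phi_hs:.3f} >= phi_g={params.phi_g}: viscosity diverges"
        )
    return float((1.0 - phi_hs / params.phi_g) ** (-params.gamma))


def sticky_sphere_chain(
    c: float,
    sw: float,
    params: SolutionParams | None = None,
    units: UnitSystem | None = None,
) -> dict:
    """Run the printed-input pipeline from a weight-average cluster size.

    Starting from <s>_w at concentration ``c`` [mg/mL]: invert the
    hyperbranched weight average for the bond probability, build the size
    distribution, form the cluster packing fraction and evaluate the Baxter
    S_SHS(0), <N_app>_w and the relative viscosity.  Returns all
    intermediate quantities keyed by name.
    """
    from .hpt import cluster_size_distribution, invert_weight_average

    if params is None:
        params = SolutionParams()
    p = invert_weight_average(sw)
    dist = cluster_size_distribution(p)
    phi_hs = cluster_volume_fraction(c, dist, params, units)
    bax = baxter_s0(phi_hs, params.tau)
    eta_r = relative_viscosity(phi_hs, params) if phi_hs < params.phi_g else np.inf
    return {
        "c": c,
        "p": p,
        "s_n": number_average(dist),
        "s_w": weight_average(dist),
        "phi_hs": phi_hs,
        "lambda": bax.lam,
        "S0": bax.S0,
        "napp_w": weight_average(dist) * bax.S0,
        "eta_r": eta_r,
    }
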