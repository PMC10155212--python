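"""Form and structure factors of individual antibody clusters.

A cluster of ``s`` monomers scatters as s*P_c(q) = P_1(q)*S_c(q), where
P_1 is the monomer form factor and S_c the intra-cluster structure factor
normalized so that S_c(0) = s and S_c(inf) = 1.  Three routes to S_c are
implemented:

* a generic orientation-averaged Debye double sum over monomer centers,
* the freely-jointed-chain (fjc) closed form for a flexible chain of
  bond length b (= 2 R_1 = 12 nm for this antibody),
* a fractal-colloid (fc) model that embeds the monomers in a fractal
  envelope described by the Fisher-Burford form factor, with
  nearest-neighbor correlations from a Percus-Yevick hard-sphere
  structure factor at the cluster-internal volume fraction.

Internally q is in nm^-1; Angstrom^-1 grids from disk convert by an exact
factor of 10 (see :mod:`mabcluster.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import UnitSystem, build_y_geometry
from .hpt import ClusterSizeDistribution

__all__ = [
    "ClusterModelParams",
    "FormFactorCurve",
    "debye_structure_factor",
    "fjc_structure_factor",
    "fjc_radius_of_gyration",
    "fisher_burford",
    "py_hs_structure_factor",
    "fractal_rg",
    "cluster_radius_from_rg",
    "internal_volume_fraction",
    "fc_structure_factor",
    "sphere_form_factor",
    "y_bead_form_factor",
    "monomer_form_factor",
    "polydisperse_average",
]


@dataclass(frozen=True)
class ClusterModelParams:
    """Geometric parameters of the coarse-grained cluster models.

    b       : fjc bond length [nm]; the monomer sphere diameter 2 R_1.
    R1      : monomer sphere radius [nm].
    dF      : fractal dimension of the fc envelope (2.5 from simulation).
    k       : fractal prefactor in s = k (R_g/R_1)^dF.
    A_phi   : internal-volume-fraction correction in (0, 1]; compensates the
              Y-shaped monomer excluding less volume than a sphere of R_1.
    """

    b: float = 12.0
    R1: float = 6.0
    dF: float = 2.5
    k: float = 0.71
    A_phi: float = 1.0

    def __post_init__(self) -> None:
        if self.b <= 0 or self.R1 <= 0 or self.k <= 0:
            raise ValueError("b, R1 and k must be positive")
        if not 1.0 <= self.dF <= 3.0:
            raise ValueError("fractal dimension must lie in [1, 3]")
        if not 0.0 < self.A_phi <= 1.0:
            raise ValueError("A_phi must lie in (0, 1]")


@dataclass
class FormFactorCurve:
    """A non-negative curve on a strictly increasing q grid."""

    q: np.ndarray
    values: np.ndarray
    normalization: str = ""  # e.g. "P(0)=1" or "S(0)=s"
    q_unit: str = "nm^-1"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.q.ndim != 1 or np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be one-dimensional and strictly increasing")
        if self.q.shape != self.values.shape:
            raise ValueError("q and values must have matching shapes")


def _sinc(x: np.ndarray) -> np.ndarray:
    # sin(x)/x with the x -> 0 limit handled (numpy sinc is sin(pi x)/(pi x))
    return np.sinc(x / np.pi)


def debye_structure_factor(positions, q_grid) -> FormFactorCurve:
    """Orientation-averaged structure factor of fixed monomer centers.

    S_c(q) = (1/s) sum_ij sin(q r_ij)/(q r_ij), with the diagonal terms
    equal to 1, so S_c(0) = s and S_c -> 1 at large q.
    """
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    q = np.asarray(q_grid, dtype=float)
    s = len(pos)
    rij = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    r = rij[np.triu_indices(s, k=1)]
    cross = 2.0 * _sinc(np.outer(q, r)).sum(axis=1) if r.size else np.zeros_like(q)
    vals = (s + cross) / s
    return FormFactorCurve(q=q, values=vals, normalization="S(0)=s")


def _fjc_value(s: int, x: np.ndarray) -> np.ndarray:
    """fjc structure factor (1/s) sum_ij x^|i-j| = 1 + (2/s) sum_k (s-k) x^k.

    The geometric closed form is evaluated by Horner recursion, which is
    algebraically identical to it but free of the catastrophic cancellation
    the explicit (1-x)^-2 expression suffers near x = 1 (small q b).
    """
    x = np.asarray(x, dtype=float)
    if s == 1:
        return np.ones_like(x)
    acc = np.zeros_like(x)
    for m in range(s - 2, -1, -1):  # sum_{m=0}^{s-2} (s-1-m) x^m
        acc = acc * x + (s - 1 - m)
    return 1.0 + (2.0 / s) * x * acc


def fjc_structure_factor(s: int, b: float, q_grid) -> FormFactorCurve:
    """Freely-jointed-chain cluster structure factor.

    Equals (1/s) sum_ij x^|i-j| with x = sin(qb)/(qb), i.e. the Debye sum
    with fjc conformational averaging, evaluated through its geometric-series
    closed form (identical to the explicit double sum to machine precision).
    """
    if s < 1:
        raise ValueError("cluster size must be >= 1")
    if b <= 0:
        raise ValueError("bond length must be positive")
    q = np.asarray(q_grid, dtype=float)
    vals = _fjc_value(int(s), _sinc(q * b))
    return FormFactorCurve(q=q, values=vals, normalization="S(0)=s")


def fjc_radius_of_gyration(s: int, b: float, asymptotic: bool = True) -> float:
    """Radius of gyration of an fjc chain of ``s`` beads and bond length ``b`` [nm].

    The asymptotic relation R_g = 2 R_1 sqrt(s/6) = b sqrt(s/6) is the
    default; the finite-chain form b sqrt((s^2-1)/(6 s)) is also provided.
    """
    if asymptotic:
        return b * np.sqrt(s / 6.0)
    return b * np.sqrt((s * s - 1.0) / (6.0 * s))


def fisher_burford(q_grid, Rg: float, dF: float) -> FormFactorCurve:
    """Fisher-Burford form factor of a fractal aggregate.

    P_L(q) = [1 + (2/(3 dF)) q^2 Rg^2]^(-dF/2): normalized to 1 at q = 0,
    Guinier-consistent at small q, power-law slope -dF at large q Rg.
    """
    if Rg <= 0 or dF <= 0:
        raise ValueError("Rg and dF must be positive")
    q = np.asarray(q_grid, dtype=float)
    vals = (1.0 + 2.0 / (3.0 * dF) * (q * Rg) ** 2) ** (-dF / 2.0)
    return FormFactorCurve(q=q, values=vals, normalization="P(0)=1")


def py_hs_structure_factor(q_grid, phi: float, diameter: float) -> FormFactorCurve:
    """Analytic Percus-Yevick structure factor of a hard-sphere fluid.

    Uses the Wertheim-Thiele direct correlation function; S(0) =
    (1-phi)^4/(1+2 phi)^2 and S -> 1 at large q.  Valid for phi < 0.5.
    """
    if not 0.0 <= phi < 0.5:
        raise ValueError("PY packing fraction must lie in [0, 0.5)")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    q = np.asarray(q_grid, dtype=float)
    if phi == 0.0:
        return FormFactorCurve(q=q, values=np.ones_like(q), normalization="S")
    alpha = (1.0 + 2.0 * phi) ** 2 / (1.0 - phi) ** 4
    beta = -6.0 * phi * (1.0 + phi / 2.0) ** 2 / (1.0 - phi) ** 4
    gamma = phi * alpha / 2.0
    x = q * diameter
    small = x < 1e-4
    xs = np.where(small, 1.0, x)  # avoid 0/0; small-x branch overwritten below
    sx, cx = np.sin(xs), np.cos(xs)
    a1 = alpha * (sx - xs * cx) / xs**3
    a2 = beta * (2.0 * xs * sx - (xs**2 - 2.0) * cx - 2.0) / xs**4
    a3 = gamma * (
        -(xs**4) * cx + 4.0 * ((3.0 * xs**2 - 6.0) * cx + (xs**3 - 6.0 * xs) * sx + 6.0)
    ) / xs**6
    rho_c = -24.0 * phi * (a1 + a2 + a3)
    rho_c0 = -24.0 * phi * (alpha / 3.0 + beta / 4.0 + gamma / 6.0)
    rho_c = np.where(small, rho_c0, rho_c)
    return FormFactorCurve(q=q, values=1.0 / (1.0 - rho_c), normalization="S")


def fractal_rg(s: int, R1: float, dF: float, k: float) -> float:
    """Radius of gyration of a fractal cluster: R_g = R_1 (s/k)^(1/dF) [nm]."""
    if s < 1:
        raise ValueError("cluster size must be >= 1")
    return R1 * (s / k) ** (1.0 / dF)


def cluster_radius_from_rg(Rg: float, dF: float) -> float:
    """Embedding-sphere radius from the fractal radius of gyration.

    R_c = R_g sqrt((dF+2)/dF), the homogeneous-object relation (reduces to
    the solid-sphere R_c = R_g sqrt(5/3) at dF = 3).
    """
    return Rg * np.sqrt((dF + 2.0) / dF)


def internal_volume_fraction(s: int, R1: float, Rc: float, A_phi: float = 1.0) -> float:
    """Volume fraction of monomers inside the embedding sphere.

    phi_int = A_phi * s * (R_1/R_c)^3; depends on R_1 and R_c only through
    their ratio.  Raises for unphysical packing above 0.74.
    """
    if Rc < R1:
        raise ValueError("embedding radius must be at least the monomer radius")
    phi = A_phi * s * (R1 / Rc) ** 3
    if s >= 2 and phi > 0.74:
        # s = 1 is the degenerate monomer "cluster" with phi_int = 1 by
        # construction; for real clusters such packing is unphysical
        raise ValueError(f"internal volume fraction {phi:.3f} exceeds close packing")
    return float(phi)


def fc_structure_factor(
    s: int, params: ClusterModelParams, q_grid
) -> FormFactorCurve:
    """Fractal-colloid cluster structure factor.

    The Debye double sum splits into the self term and a monomer-envelope
    cross term carried by the Fisher-Burford envelope P_L(q); internal
    nearest-neighbor correlations enter through a PY hard-sphere structure
    factor at the internal volume fraction:

        S_c,fc(q) = s P_L(q) + [1 - P_L(q)] S_HS(q, phi_int).

    The form interpolates exactly between S_c(0) = s and S_c(inf) = 1 and
    reduces to 1 + (s-1) P_L(q) when internal correlations are switched off
    (A_phi -> 0).  Meaningless for monomers/dimers of a fractal envelope,
    hence s >= 2 is required and the model is only trusted for larger s.
    """
    if s < 2:
        raise ValueError("the fractal-colloid model needs s >= 2")
    q = np.asarray(q_grid, dtype=float)
    rg = fractal_rg(s, params.R1, params.dF, params.k)
    rc = cluster_radius_from_rg(rg, params.dF)
    phi_int = internal_volume_fraction(s, params.R1, rc, params.A_phi)
    p_l = fisher_burford(q, rg, params.dF).values
    s_hs = py_hs_structure_factor(q, phi_int, 2.0 * params.R1).values
    vals = s * p_l + (1.0 - p_l) * s_hs
    return FormFactorCurve(q=q, values=vals, normalization="S(0)=s")


def sphere_form_factor(q_grid, R: float) -> FormFactorCurve:
    """Form factor of a homogeneous sphere of radius R [nm]: amplitude squared."""
    if R <= 0:
        raise ValueError("radius must be positive")
    q = np.asarray(q_grid, dtype=float)
    x = q * R
    # series below x = 0.01 avoids the (sin x - x cos x)/x^3 cancellation
    small = x < 1e-2
    xs = np.where(small, 1.0, x)
    amp = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    amp = np.where(small, 1.0 - x * x / 10.0 + x**4 / 280.0, amp)
    return FormFactorCurve(q=q, values=amp * amp, normalization="P(0)=1")


def y_bead_form_factor(
    q_grid, units: UnitSystem | None = None, bead_convention: str = "point"
) -> FormFactorCurve:
    """Orientation-averaged form factor of the 9-bead Y in physical units.

    ``bead_convention`` "point" places unit scatterers at the bead centers
    (the convention used for simulation observables, where the bead
    amplitude cancels); "sphere" convolves with the solid-bead amplitude.
    """
    if units is None:
        units = UnitSystem()
    q = np.asarray(q_grid, dtype=float)
    geom = build_y_geometry()
    pos_nm = geom.bead_centers * units.sigma_nm
    s_c = debye_structure_factor(pos_nm, q)
    vals = s_c.values / 9.0
    if bead_convention == "sphere":
        vals = vals * sphere_form_factor(q, 0.5 * units.sigma_nm).values
    elif bead_convention != "point":
        raise ValueError(f"unknown bead convention {bead_convention!r}")
    return FormFactorCurve(q=q, values=vals, normalization="P(0)=1")


def monomer_form_factor(source, q_grid, **kwargs) -> FormFactorCurve:
    """Monomer form factor P_1(q) from one of several sources.

    ``source`` is "sphere" (kwarg ``R``), "y_bead_model" (kwargs ``units``,
    ``bead_convention``), or an existing :class:`FormFactorCurve` holding a
    tabulated (e.g. measured) curve, which is interpolated log-linearly in
    intensity; extrapolation outside its support is an error.
    """
    q = np.asarray(q_grid, dtype=float)
    if isinstance(source, FormFactorCurve):
        if q[0] < source.q[0] or q[-1] > source.q[-1]:
            raise ValueError(
                "requested q grid extends outside the tabulated curve; "
                "extrapolation of measured form factors is not supported"
            )
        vals = np.exp(np.interp(q, source.q, np.log(source.values)))
        return FormFactorCurve(q=q, values=vals, normalization="P(0)=1")
    if source == "sphere":
        return sphere_form_factor(q, kwargs["R"])
    if source == "y_bead_model":
        return y_bead_form_factor(q, **kwargs)
    raise ValueError(f"unknown monomer form factor source {source!r}")


def polydisperse_average(
    dist: ClusterSizeDistribution,
    model: str,
    q_grid,
    params: ClusterModelParams | None = None,
    weight_tail_tol: float = 1e-10,
) -> FormFactorCurve:
    """Weight-averaged cluster structure factor <S_c(q)>_w.

    <S_c(q)>_w = sum_s n(s) s S_c(s, q) / sum_s n(s) s, which equals the
    polydisperse normalized intensity divided by P_1(q) through the
    identity s P_c = P_1 S_c.  At q = 0 it equals <s>_w.  ``model`` is
    "fjc" or "fc"; for "fc" clusters of size 1 contribute S_c = 1 (a
    monomer has no internal structure).
    """
    if params is None:
        params = ClusterModelParams()
    if model not in ("fjc", "fc"):
        raise ValueError("polydisperse averaging supports the fjc and fc models")
    q = np.asarray(q_grid, dtype=float)
    w = dist.n * dist.sizes  # mass-weighted cluster numbers
    total = w.sum()
    # drop the far tail that cannot move the average by more than the tolerance
    keep = np.cumsum(w[::-1])[::-1] / total > weight_tail_tol
    keep[0] = True
    acc = np.zeros_like(q)
    if model == "fjc":
        # recurrence over s: T(s) = sum_k (s-k) x^k obeys T(s+1) = T(s) + G(s)
        # with G(s) = sum_{k<=s} x^k, so the whole size sweep costs O(s_cut nq)
        x = _sinc(q * params.b)
        s_cut = int(dist.sizes[keep][-1])
        t = np.zeros_like(q)  # T(1)
        g = x.copy()  # G(1)
        xp = x.copy()  # x^s
        for s in range(1, s_cut + 1):
            ws = w[s - 1]
            if ws > 0.0:
                acc += ws * (1.0 + 2.0 / s * t)
            t = t + g
            xp = xp * x
            g = g + xp
    else:
        for s, ws in zip(dist.sizes[keep], w[keep]):
            if ws == 0.0:
                continue
            sc = np.ones_like(q) if s == 1 else fc_structure_factor(int(s), params, q).values
            acc += ws * sc
    return FormFactorCurve(q=q, values=acc / total, normalization="S(0)=<s>_w")
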