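"""Rigid-body Metropolis Monte Carlo of patchy 9-bead Y molecules.

Each molecule is the rigid Y of :mod:`mabcluster.geometry`: nine hard
beads of diameter 1 sigma plus one A and two B square-well patch sites.
Two molecules bond (energy -epsilon_0) whenever an A site of one lies
within the patch range (0.2633 sigma site-to-site) of a B site of the
other; bead overlaps are forbidden.  Single-particle translation and
rotation moves are accepted with the Metropolis rule at reduced
temperature T = k_B T / epsilon_0 in a cubic periodic box.

The module also provides the cluster observables used to validate the
analytical chain: the A-B bond graph and its connected components, the
empirical cluster size distribution, per-size radii of gyration and
structure factors, the bead-level effective solution structure factor,
and a Monte Carlo estimate of the pair excluded volume.

Desk-scale defaults (N = 200, 2x10^4 + 2x10^4 sweeps, 4 replicas) keep a
full run in the minutes range; the publication-scale protocol (N = 1000,
10 replicas) is available by overriding :class:`MCConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from .geometry import DEFAULT_PATCH_RANGE, YGeometry, build_y_geometry

__all__ = [
    "MCConfig",
    "Configuration",
    "BondGraph",
    "MCTrajectory",
    "init_random_configuration",
    "total_energy",
    "mc_sweeps",
    "simulate",
    "run_replicas",
    "identify_clusters",
    "bond_statistics",
    "cluster_size_histogram",
    "rg_vs_s",
    "cluster_structure_factor",
    "total_effective_structure_factor",
    "pair_excluded_volume",
]


@dataclass(frozen=True)
class MCConfig:
    """Simulation protocol parameters (desk defaults; see module docstring)."""

    N: int = 200
    rho: float = 5.077e-3  # number density [sigma^-3]
    T: float = 0.11
    patch_range: float = DEFAULT_PATCH_RANGE
    max_translation: float = 0.8  # [sigma]; ~35% acceptance at working densities
    max_rotation: float = 1.0  # [rad]
    sweeps_equil: int = 30_000
    sweeps_prod: int = 20_000
    sample_every: int = 500
    seed: int = 0
    n_replicas: int = 4
    hard_core: bool = True
    patches: bool = True

    def __post_init__(self) -> None:
        if self.N < 1 or self.rho <= 0 or self.T <= 0:
            raise ValueError("invalid MC configuration")
        if self.patch_range >= 0.5:
            raise ValueError("patch range must be below half a bead diameter")

    @property
    def box_length(self) -> float:
        return (self.N / self.rho) ** (1.0 / 3.0)


@dataclass
class Configuration:
    """Instantaneous rigid-body state: centers of mass and unit quaternions."""

    positions: np.ndarray  # (N, 3) [sigma], wrapped into the box
    quaternions: np.ndarray  # (N, 4), normalized, scalar first
    box_length: float


@dataclass
class BondGraph:
    """A-B bond edges and the connected-component labels they induce."""

    edges: np.ndarray  # (n_edges, 3): A-owner index, B-owner index, B-site (1 or 2)
    cluster_labels: np.ndarray  # (N,), label = smallest member index


@dataclass
class MCTrajectory:
    """Sampled production frames of one replica."""

    positions: np.ndarray  # (F, N, 3)
    quaternions: np.ndarray  # (F, N, 4)
    energies: np.ndarray  # (F,) total potential energy [epsilon_0]
    box_length: float
    config: MCConfig
    acceptance: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def frame(self, i: int) -> Configuration:
        return Configuration(self.positions[i], self.quaternions[i], self.box_length)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            positions=self.positions,
            quaternions=self.quaternions,
            energies=self.energies,
            box_length=self.box_length,
        )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _seed_kernel(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _quat_to_rot(q, R):
    w, x, y, z = q[0], q[1], q[2], q[3]
    R[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    R[0, 1] = 2.0 * (x * y - w * z)
    R[0, 2] = 2.0 * (x * z + w * y)
    R[1, 0] = 2.0 * (x * y + w * z)
    R[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    R[1, 2] = 2.0 * (y * z - w * x)
    R[2, 0] = 2.0 * (x * z - w * y)
    R[2, 1] = 2.0 * (y * z + w * x)
    R[2, 2] = 1.0 - 2.0 * (z * z + x * x)


@njit(cache=True, inline="always")
def _rotate_set(R, template, out):
    n = template.shape[0]
    for a in range(n):
        for k in range(3):
            out[a, k] = (
                R[k, 0] * template[a, 0]
                + R[k, 1] * template[a, 1]
                + R[k, 2] * template[a, 2]
            )


@njit(cache=True, inline="always")
def _min_image(d, box):
    return d - box * np.round(d / box)


@njit(cache=True)
def _pair_energy(
    dr, beads_i, beads_j, sites_i, sites_j, hard_core, patches, patch_range2
):
    """Energy of one molecule pair given the min-imaged COM separation dr.

    Returns (energy, overlap).  Site order in the templates: A, B, B.
    """
    if hard_core:
        for a in range(9):
            for b in range(9):
                dx = dr[0] + beads_i[a, 0] - beads_j[b, 0]
                dy = dr[1] + beads_i[a, 1] - beads_j[b, 1]
                dz = dr[2] + beads_i[a, 2] - beads_j[b, 2]
                if dx * dx + dy * dy + dz * dz < 1.0:
                    return 0.0, True
    e = 0.0
    if patches:
        # A of i (site 0) against B of j (sites 1, 2) and vice versa
        for b in range(1, 3):
            dx = dr[0] + sites_i[0, 0] - sites_j[b, 0]
            dy = dr[1] + sites_i[0, 1] - sites_j[b, 1]
            dz = dr[2] + sites_i[0, 2] - sites_j[b, 2]
            if dx * dx + dy * dy + dz * dz < patch_range2:
                e -= 1.0
        for b in range(1, 3):
            dx = -dr[0] + sites_j[0, 0] - sites_i[b, 0]
            dy = -dr[1] + sites_j[0, 1] - sites_i[b, 1]
            dz = -dr[2] + sites_j[0, 2] - sites_i[b, 2]
            if dx * dx + dy * dy + dz * dz < patch_range2:
                e -= 1.0
    return e, False


@njit(cache=True)
def _particle_energy(
    i, pos, rot, box, beads_t, sites_t, hard_core, patches, patch_range2, cut2
):
    n = pos.shape[0]
    beads_i = np.empty((9, 3))
    sites_i = np.empty((3, 3))
    beads_j = np.empty((9, 3))
    sites_j = np.empty((3, 3))
    _rotate_set(rot[i], beads_t, beads_i)
    _rotate_set(rot[i], sites_t, sites_i)
    dr = np.empty(3)
    e = 0.0
    for j in range(n):
        if j == i:
            continue
        d2 = 0.0
        for k in range(3):
            dr[k] = _min_image(pos[i, k] - pos[j, k], box)
            d2 += dr[k] * dr[k]
        if d2 > cut2:
            continue
        _rotate_set(rot[j], beads_t, beads_j)
        _rotate_set(rot[j], sites_t, sites_j)
        epair, overlap = _pair_energy(
            dr, beads_i, beads_j, sites_i, sites_j, hard_core, patches, patch_range2
        )
        if overlap:
            return 0.0, True
        e += epair
    return e, False


@njit(cache=True)
def _system_energy(
    pos, rot, box, beads_t, sites_t, hard_core, patches, patch_range2, cut2
):
    n = pos.shape[0]
    beads_i = np.empty((9, 3))
    sites_i = np.empty((3, 3))
    beads_j = np.empty((9, 3))
    sites_j = np.empty((3, 3))
    dr = np.empty(3)
    e = 0.0
    for i in range(n):
        _rotate_set(rot[i], beads_t, beads_i)
        _rotate_set(rot[i], sites_t, sites_i)
        for j in range(i + 1, n):
            d2 = 0.0
            for k in range(3):
                dr[k] = _min_image(pos[i, k] - pos[j, k], box)
                d2 += dr[k] * dr[k]
            if d2 > cut2:
                continue
            _rotate_set(rot[j], beads_t, beads_j)
            _rotate_set(rot[j], sites_t, sites_j)
            epair, overlap = _pair_energy(
                dr, beads_i, beads_j, sites_i, sites_j, hard_core, patches, patch_range2
            )
            if overlap:
                return 0.0, True
            e += epair
    return e, False


@njit(cache=True)
def _run_sweeps(
    pos,
    quat,
    rot,
    box,
    T,
    n_sweeps,
    dmax,
    rmax,
    beads_t,
    sites_t,
    hard_core,
    patches,
    patch_range2,
    cut2,
    e_start,
):
    """N single-particle moves per sweep; returns (energy, acc_trans, acc_rot, attempts)."""
    n = pos.shape[0]
    e_run = e_start
    acc_t = 0
    acc_r = 0
    att_t = 0
    att_r = 0
    old_pos = np.empty(3)
    old_quat = np.empty(4)
    old_rot = np.empty((3, 3))
    qnew = np.empty(4)
    for _ in range(n_sweeps):
        for _m in range(n):
            i = np.random.randint(0, n)
            e_old, _ov = _particle_energy(
                i, pos, rot, box, beads_t, sites_t, hard_core, patches, patch_range2, cut2
            )
            if np.random.random() < 0.5:
                att_t += 1
                for k in range(3):
                    old_pos[k] = pos[i, k]
                    pos[i, k] = (pos[i, k] + dmax * (2.0 * np.random.random() - 1.0)) % box
                e_new, ov = _particle_energy(
                    i, pos, rot, box, beads_t, sites_t, hard_core, patches, patch_range2, cut2
                )
                de = e_new - e_old
                if (not ov) and (de <= 0.0 or np.random.random() < np.exp(-de / T)):
                    acc_t += 1
                    e_run += de
                else:
                    for k in range(3):
                        pos[i, k] = old_pos[k]
            else:
                att_r += 1
                for k in range(4):
                    old_quat[k] = quat[i, k]
                for a in range(3):
                    for b in range(3):
                        old_rot[a, b] = rot[i, a, b]
                # small-angle axis-angle perturbation, renormalized quaternion
                ax = np.random.normal()
                ay = np.random.normal()
                az = np.random.normal()
                norm = np.sqrt(ax * ax + ay * ay + az * az)
                if norm < 1e-12:
                    ax, ay, az, norm = 1.0, 0.0, 0.0, 1.0
                angle = rmax * (2.0 * np.random.random() - 1.0)
                half = 0.5 * angle
                sw = np.sin(half) / norm
                dw, dx, dy, dz = np.cos(half), ax * sw, ay * sw, az * sw
                w, x, y, z = quat[i, 0], quat[i, 1], quat[i, 2], quat[i, 3]
                qnew[0] = dw * w - dx * x - dy * y - dz * z
                qnew[1] = dw * x + dx * w + dy * z - dz * y
                qnew[2] = dw * y - dx * z + dy * w + dz * x
                qnew[3] = dw * z + dx * y - dy * x + dz * w
                qn = np.sqrt(qnew[0] ** 2 + qnew[1] ** 2 + qnew[2] ** 2 + qnew[3] ** 2)
                for k in range(4):
                    quat[i, k] = qnew[k] / qn
                _quat_to_rot(quat[i], rot[i])
                e_new, ov = _particle_energy(
                    i, pos, rot, box, beads_t, sites_t, hard_core, patches, patch_range2, cut2
                )
                de = e_new - e_old
                if (not ov) and (de <= 0.0 or np.random.random() < np.exp(-de / T)):
                    acc_r += 1
                    e_run += de
                else:
                    for k in range(4):
                        quat[i, k] = old_quat[k]
                    for a in range(3):
                        for b in range(3):
                            rot[i, a, b] = old_rot[a, b]
    return e_run, acc_t, acc_r, att_t, att_r


@njit(cache=True)
def _insert_random(pos, quat, rot, box, beads_t, max_attempts):
    """Sequential random insertion with hard-core rejection; returns success flag."""
    n = pos.shape[0]
    beads_i = np.empty((9, 3))
    beads_j = np.empty((9, 3))
    dr = np.empty(3)
    cut2 = 0.0
    for a in range(beads_t.shape[0]):
        r2 = beads_t[a, 0] ** 2 + beads_t[a, 1] ** 2 + beads_t[a, 2] ** 2
        if r2 > cut2:
            cut2 = r2
    cut = 2.0 * np.sqrt(cut2) + 1.0
    cut2 = cut * cut
    for i in range(n):
        placed = False
        for _try in range(max_attempts):
            for k in range(3):
                pos[i, k] = box * np.random.random()
            # Shoemake uniform random quaternion
            u1, u2, u3 = np.random.random(), np.random.random(), np.random.random()
            quat[i, 0] = np.sqrt(1.0 - u1) * np.sin(2.0 * np.pi * u2)
            quat[i, 1] = np.sqrt(1.0 - u1) * np.cos(2.0 * np.pi * u2)
            quat[i, 2] = np.sqrt(u1) * np.sin(2.0 * np.pi * u3)
            quat[i, 3] = np.sqrt(u1) * np.cos(2.0 * np.pi * u3)
            _quat_to_rot(quat[i], rot[i])
            _rotate_set(rot[i], beads_t, beads_i)
            ok = True
            for j in range(i):
                d2 = 0.0
                for k in range(3):
                    dr[k] = _min_image(pos[i, k] - pos[j, k], box)
                    d2 += dr[k] * dr[k]
                if d2 > cut2:
                    continue
                _rotate_set(rot[j], beads_t, beads_j)
                for a in range(9):
                    if not ok:
                        break
                    for b in range(9):
                        dx = dr[0] + beads_i[a, 0] - beads_j[b, 0]
                        dy = dr[1] + beads_i[a, 1] - beads_j[b, 1]
                        dz = dr[2] + beads_i[a, 2] - beads_j[b, 2]
                        if dx * dx + dy * dy + dz * dz < 1.0:
                            ok = False
                            break
                if not ok:
                    break
            if ok:
                placed = True
                break
        if not placed:
            return False
    return True


@njit(cache=True)
def _bond_pairs(pos, rot, box, sites_t, patch_range2, cut2, out):
    """Collect A-B bonded pairs into ``out`` (rows: A-owner, B-owner, B-site)."""
    n = pos.shape[0]
    sites_i = np.empty((3, 3))
    sites_j = np.empty((3, 3))
    dr = np.empty(3)
    m = 0
    for i in range(n):
        _rotate_set(rot[i], sites_t, sites_i)
        for j in range(n):
            if j == i:
                continue
            d2 = 0.0
            for k in range(3):
                dr[k] = _min_image(pos[i, k] - pos[j, k], box)
                d2 += dr[k] * dr[k]
            if d2 > cut2:
                continue
            _rotate_set(rot[j], sites_t, sites_j)
            for b in range(1, 3):
                dx = dr[0] + sites_i[0, 0] - sites_j[b, 0]
                dy = dr[1] + sites_i[0, 1] - sites_j[b, 1]
                dz = dr[2] + sites_i[0, 2] - sites_j[b, 2]
                if dx * dx + dy * dy + dz * dz < patch_range2:
                    if m < out.shape[0]:
                        out[m, 0] = i
                        out[m, 1] = j
                        out[m, 2] = b
                    m += 1
    return m


@njit(cache=True)
def _structure_amplitudes(all_beads, qvecs, out):
    """|sum_b exp(i q.r_b)|^2 for each wavevector row of ``qvecs``."""
    m = all_beads.shape[0]
    for k in range(qvecs.shape[0]):
        re = 0.0
        im = 0.0
        for b in range(m):
            phase = (
                qvecs[k, 0] * all_beads[b, 0]
                + qvecs[k, 1] * all_beads[b, 1]
                + qvecs[k, 2] * all_beads[b, 2]
            )
            re += np.cos(phase)
            im += np.sin(phase)
        out[k] = re * re + im * im


@njit(cache=True)
def _excluded_volume_hits(beads_t, n_samples, rmax, seed):
    np.random.seed(seed)
    nb = beads_t.shape[0]
    R1 = np.empty((3, 3))
    R2 = np.empty((3, 3))
    b1 = np.empty((nb, 3))
    b2 = np.empty((nb, 3))
    q = np.empty(4)
    hits = 0
    for _ in range(n_samples):
        for mol in range(2):
            u1, u2, u3 = np.random.random(), np.random.random(), np.random.random()
            q[0] = np.sqrt(1.0 - u1) * np.sin(2.0 * np.pi * u2)
            q[1] = np.sqrt(1.0 - u1) * np.cos(2.0 * np.pi * u2)
            q[2] = np.sqrt(u1) * np.sin(2.0 * np.pi * u3)
            q[3] = np.sqrt(u1) * np.cos(2.0 * np.pi * u3)
            if mol == 0:
                _quat_to_rot(q, R1)
            else:
                _quat_to_rot(q, R2)
        _rotate_set(R1, beads_t, b1)
        _rotate_set(R2, beads_t, b2)
        # uniform point in the bounding sphere (rejection from the cube)
        while True:
            dx = rmax * (2.0 * np.random.random() - 1.0)
            dy = rmax * (2.0 * np.random.random() - 1.0)
            dz = rmax * (2.0 * np.random.random() - 1.0)
            if dx * dx + dy * dy + dz * dz <= rmax * rmax:
                break
        overlap = False
        for a in range(nb):
            if overlap:
                break
            for b in range(nb):
                ex = dx + b1[a, 0] - b2[b, 0]
                ey = dy + b1[a, 1] - b2[b, 1]
                ez = dz + b1[a, 2] - b2[b, 2]
                if ex * ex + ey * ey + ez * ez < 1.0:
                    overlap = True
                    break
        if overlap:
            hits += 1
    return hits


# ---------------------------------------------------------------------------
# python-level API
# ---------------------------------------------------------------------------


def _templates(geom: YGeometry | None = None):
    geom = geom or build_y_geometry()
    beads = np.ascontiguousarray(geom.bead_centers - geom.center_of_mass())
    order = {"A": 0, "B": 1}
    sites = np.zeros((3, 3))
    nb = 1
    for s in geom.patch_sites:
        idx = 0 if s.label == "A" else nb
        if s.label == "B":
            nb += 1
        sites[idx] = s.position - geom.center_of_mass()
    return beads, np.ascontiguousarray(sites)


def _cutoffs(beads, sites, patch_range):
    r_bead = np.linalg.norm(beads, axis=1).max()
    r_site = np.linalg.norm(sites, axis=1).max()
    cut = max(2.0 * r_bead + 1.0, 2.0 * r_site + patch_range)
    return cut * cut


def _rot_all(quaternions):
    rot = np.empty((len(quaternions), 3, 3))
    for i, q in enumerate(quaternions):
        _quat_to_rot(q, rot[i])
    return rot


def init_random_configuration(config: MCConfig, max_attempts: int = 100_000) -> Configuration:
    """Overlap-free random configuration by seeded insertion with rejection."""
    beads, _sites = _templates()
    box = config.box_length
    pos = np.empty((config.N, 3))
    quat = np.empty((config.N, 4))
    rot = np.empty((config.N, 3, 3))
    _seed_kernel(config.seed)
    ok = _insert_random(pos, quat, rot, box, beads, max_attempts)
    if not ok:
        raise RuntimeError(
            f"random insertion failed after {max_attempts} attempts per particle: "
            f"density rho={config.rho} too high for rejection sampling"
        )
    return Configuration(positions=pos, quaternions=quat, box_length=box)


def total_energy(configuration: Configuration, config: MCConfig) -> float:
    """Total potential energy [epsilon_0]; +inf flags a hard-core overlap."""
    beads, sites = _templates()
    rot = _rot_all(configuration.quaternions)
    e, overlap = _system_energy(
        configuration.positions,
        rot,
        configuration.box_length,
        beads,
        sites,
        config.hard_core,
        config.patches,
        config.patch_range**2,
        _cutoffs(beads, sites, config.patch_range),
    )
    return np.inf if overlap else float(e)


def mc_sweeps(
    configuration: Configuration,
    config: MCConfig,
    n_sweeps: int,
    energy: float | None = None,
) -> dict:
    """Run ``n_sweeps`` Metropolis sweeps in place.

    Returns acceptance statistics and the incrementally tracked total
    energy (useful for bookkeeping checks against a full recomputation).
    The numba RNG stream continues from its current state; seed it via
    :func:`simulate` or ``_seed_kernel`` for reproducibility.
    """
    beads, sites = _templates()
    rot = _rot_all(configuration.quaternions)
    if energy is None:
        energy = total_energy(configuration, config)
    e_run, acc_t, acc_r, att_t, att_r = _run_sweeps(
        configuration.positions,
        configuration.quaternions,
        rot,
        configuration.box_length,
        config.T,
        n_sweeps,
        config.max_translation,
        config.max_rotation,
        beads,
        sites,
        config.hard_core,
        config.patches,
        config.patch_range**2,
        _cutoffs(beads, sites, config.patch_range),
        energy,
    )
    return {
        "energy": e_run,
        "accept_translation": acc_t / max(att_t, 1),
        "accept_rotation": acc_r / max(att_r, 1),
        "attempts": att_t + att_r,
    }


def simulate(config: MCConfig, verbose: bool = False) -> MCTrajectory:
    """Equilibrate and sample one replica; bit-identical for identical inputs."""
    state = init_random_configuration(config)
    stats = mc_sweeps(state, config, config.sweeps_equil)
    n_frames = max(1, config.sweeps_prod // config.sample_every)
    pos_frames = np.empty((n_frames, config.N, 3))
    quat_frames = np.empty((n_frames, config.N, 4))
    energies = np.empty(n_frames)
    for f in range(n_frames):
        stats = mc_sweeps(state, config, config.sample_every, energy=stats["energy"])
        pos_frames[f] = state.positions
        quat_frames[f] = state.quaternions
        energies[f] = stats["energy"]
        if verbose:  # pragma: no cover
            print(f"frame {f + 1}/{n_frames}: E = {energies[f]:.1f}")
    return MCTrajectory(
        positions=pos_frames,
        quaternions=quat_frames,
        energies=energies,
        box_length=config.box_length,
        config=config,
        acceptance={k: v for k, v in stats.items() if k.startswith("accept")},
    )


def run_replicas(config: MCConfig, verbose: bool = False) -> list[MCTrajectory]:
    """Independent replicas seeded ``seed, seed+1, ...`` (statistics by scatter)."""
    return [
        simulate(replace(config, seed=config.seed + r), verbose=verbose)
        for r in range(config.n_replicas)
    ]


def identify_clusters(configuration: Configuration, config: MCConfig) -> BondGraph:
    """A-B bond graph and its connected components (union-find).

    Cluster labels are deterministic: every molecule is labelled by the
    smallest molecule index in its cluster.
    """
    beads, sites = _templates()
    rot = _rot_all(configuration.quaternions)
    cap = 8 * config.N
    out = np.zeros((cap, 3), dtype=np.int64)
    m = _bond_pairs(
        configuration.positions,
        rot,
        configuration.box_length,
        sites,
        config.patch_range**2,
        _cutoffs(beads, sites, config.patch_range),
        out,
    )
    if m > cap:  # pragma: no cover - would need >8 bonds per molecule
        out = np.zeros((m, 3), dtype=np.int64)
        m = _bond_pairs(
            configuration.positions, rot, configuration.box_length, sites,
            config.patch_range**2, _cutoffs(beads, sites, config.patch_range), out,
        )
    edges = out[:m]
    parent = np.arange(config.N)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j, _b in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    labels = np.array([find(i) for i in range(config.N)])
    return BondGraph(edges=edges, cluster_labels=labels)


def bond_statistics(trajectories, config: MCConfig | None = None) -> dict:
    """Bond probability p (fraction of bonded B sites) and multi-bond fraction."""
    if isinstance(trajectories, MCTrajectory):
        trajectories = [trajectories]
    config = config or trajectories[0].config
    p_vals, multi_vals = [], []
    for traj in trajectories:
        bonded_b = 0
        multi = 0
        total_sites = 0
        for f in range(traj.n_frames):
            g = identify_clusters(traj.frame(f), config)
            if len(g.edges):
                keys = g.edges[:, 1] * 4 + g.edges[:, 2]
                uniq, counts = np.unique(keys, return_counts=True)
                bonded_b += len(uniq)
                multi += int(np.sum(counts > 1))
                # multiply-bonded A sites
                ua, ca = np.unique(g.edges[:, 0], return_counts=True)
                multi += int(np.sum(ca > 2))
            total_sites += 2 * config.N
        p_vals.append(bonded_b / total_sites)
        multi_vals.append(multi / max(total_sites, 1))
    return {
        "p": float(np.mean(p_vals)),
        "p_se": float(np.std(p_vals) / np.sqrt(max(len(p_vals), 1))),
        "multi_bond_fraction": float(np.mean(multi_vals)),
    }


def cluster_size_histogram(trajectories, config: MCConfig | None = None) -> dict:
    """Empirical cluster size distribution n(s), normalized to sum 1.

    Frames are pooled within a replica and the per-bin standard error is
    the scatter across replicas.  Because a handful of replicas estimates
    its own scatter poorly (relative uncertainty ~1/sqrt(2(R-1))), the
    reported ``se`` additionally carries a multinomial counting-error
    floor based on the total number of clusters observed.
    """
    if isinstance(trajectories, MCTrajectory):
        trajectories = [trajectories]
    config = config or trajectories[0].config
    s_max = config.N
    per_replica = []
    n_clusters_total = 0
    for traj in trajectories:
        counts = np.zeros(s_max + 1)
        for f in range(traj.n_frames):
            g = identify_clusters(traj.frame(f), config)
            _lab, sizes = np.unique(g.cluster_labels, return_counts=True)
            for s in sizes:
                counts[s] += 1
        n_clusters_total += int(counts.sum())
        per_replica.append(counts / counts.sum())
    arr = np.asarray(per_replica)
    mean = arr.mean(axis=0)
    if len(arr) > 1:
        se = arr.std(axis=0, ddof=1) / np.sqrt(len(arr))
    else:
        se = np.zeros(s_max + 1)
    counting = np.sqrt(np.clip(mean * (1.0 - mean), 0.0, None) / max(n_clusters_total, 1))
    se = np.maximum(se, counting)
    upto = max(1, int(np.max(np.nonzero(mean)[0])))
    return {"s": np.arange(1, upto + 1), "n": mean[1 : upto + 1], "se": se[1 : upto + 1]}


def _unwrap_cluster(members, edges, positions, box):
    """Unwrap the COM coordinates of one cluster across periodic boundaries."""
    members = list(members)
    index = {m: k for k, m in enumerate(members)}
    adj = {m: [] for m in members}
    for i, j, _b in edges:
        if i in index and j in index:
            adj[i].append(j)
            adj[j].append(i)
    coords = np.zeros((len(members), 3))
    seen = {members[0]}
    coords[0] = positions[members[0]]
    stack = [members[0]]
    while stack:
        a = stack.pop()
        for b in adj[a]:
            if b in seen:
                continue
            d = positions[b] - positions[a]
            d -= box * np.round(d / box)
            coords[index[b]] = coords[index[a]] + d
            seen.add(b)
            stack.append(b)
    return coords


def rg_vs_s(trajectories, config: MCConfig | None = None, s_max: int = 30) -> dict:
    """Mean radius of gyration of clusters, by cluster size (molecule COMs)."""
    if isinstance(trajectories, MCTrajectory):
        trajectories = [trajectories]
    config = config or trajectories[0].config
    sums = np.zeros(s_max + 1)
    counts = np.zeros(s_max + 1)
    for traj in trajectories:
        for f in range(traj.n_frames):
            conf = traj.frame(f)
            g = identify_clusters(conf, config)
            labels = g.cluster_labels
            for lab in np.unique(labels):
                members = np.where(labels == lab)[0]
                s = len(members)
                if s > s_max:
                    continue
                coords = _unwrap_cluster(members, g.edges, conf.positions, conf.box_length)
                com = coords.mean(axis=0)
                rg = np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=1)))
                sums[s] += rg
                counts[s] += 1
    mask = counts > 0
    s_vals = np.nonzero(mask)[0]
    return {"s": s_vals, "rg": sums[s_vals] / counts[s_vals], "count": counts[s_vals]}


def cluster_structure_factor(
    trajectories, s: int, q_grid, config: MCConfig | None = None, min_clusters: int = 20
):
    """Orientation-averaged structure factor of clusters of a given size.

    Debye sum over the molecule centers of mass within each same-size
    cluster, averaged over all such clusters in the trajectory;
    S_c(q -> 0) -> s.  Raises if fewer than ``min_clusters`` samples exist.
    """
    from .formfactors import FormFactorCurve, debye_structure_factor

    if isinstance(trajectories, MCTrajectory):
        trajectories = [trajectories]
    config = config or trajectories[0].config
    q = np.asarray(q_grid, dtype=float)
    acc = np.zeros_like(q)
    n_found = 0
    available = {}
    for traj in trajectories:
        for f in range(traj.n_frames):
            conf = traj.frame(f)
            g = identify_clusters(conf, config)
            labels = g.cluster_labels
            for lab in np.unique(labels):
                members = np.where(labels == lab)[0]
                available[len(members)] = available.get(len(members), 0) + 1
                if len(members) != s:
                    continue
                coords = _unwrap_cluster(members, g.edges, conf.positions, conf.box_length)
                acc += debye_structure_factor(coords, q).values
                n_found += 1
    if n_found < min_clusters:
        raise RuntimeError(
            f"only {n_found} clusters of size {s} sampled (need {min_clusters}); "
            f"available sizes and counts: {dict(sorted(available.items()))}"
        )
    return FormFactorCurve(q=q, values=acc / n_found, normalization="S(0)=s")


def single_y_form_factor(q_grid) -> np.ndarray:
    """Orientation-averaged P_1(q) of one rigid Y with point scatterers [sigma units]."""
    from .formfactors import debye_structure_factor

    beads, _ = _templates()
    return debye_structure_factor(beads, np.asarray(q_grid, dtype=float)).values / 9.0


def _lattice_shells(box: float, q_max: float, max_dirs: int = 48, seed: int = 0):
    """Reciprocal-lattice wavevectors compatible with the periodic box.

    Vectors q = (2 pi / L) n, n integer, are grouped into shells of equal
    |n|^2; shells with many directions are subsampled deterministically to
    ``max_dirs`` vectors to bound the cost.
    """
    dq = 2.0 * np.pi / box
    n_max = int(np.floor(q_max / dq))
    rng = np.random.default_rng(seed)
    shells: dict[int, list] = {}
    for nx in range(-n_max, n_max + 1):
        for ny in range(-n_max, n_max + 1):
            for nz in range(0, n_max + 1):  # +q and -q give identical |F|^2
                if nz == 0 and (ny < 0 or (ny == 0 and nx <= 0)):
                    continue
                n2 = nx * nx + ny * ny + nz * nz
                if 0 < n2 <= n_max * n_max:
                    shells.setdefault(n2, []).append((nx, ny, nz))
    out = []
    for n2 in sorted(shells):
        vecs = shells[n2]
        if len(vecs) > max_dirs:
            idx = rng.choice(len(vecs), size=max_dirs, replace=False)
            vecs = [vecs[i] for i in idx]
        out.append((np.sqrt(n2) * dq, dq * np.asarray(vecs, dtype=float)))
    return out


def total_effective_structure_factor(
    trajectories,
    q_max: float = 3.0,
    config: MCConfig | None = None,
    max_dirs: int = 48,
):
    """Bead-level effective solution structure factor S_sim^eff(q).

    For every reciprocal-lattice shell compatible with the periodic box,
    the squared scattering amplitude over all beads of all molecules is
    averaged over directions and frames and divided by N and the
    orientation-averaged single-molecule P_1(q) (point beads, so the bead
    amplitude cancels).  An isolated molecule -- and an ideal gas of
    molecules -- gives 1 within counting error.
    """
    from .formfactors import FormFactorCurve

    if isinstance(trajectories, MCTrajectory):
        trajectories = [trajectories]
    config = config or trajectories[0].config
    beads_t, _sites = _templates()
    shells = _lattice_shells(trajectories[0].box_length, q_max, max_dirs)
    q_shell = np.array([q for q, _ in shells])
    acc = np.zeros_like(q_shell)
    n_frames = 0
    for traj in trajectories:
        for f in range(traj.n_frames):
            conf = traj.frame(f)
            rot = _rot_all(conf.quaternions)
            all_beads = np.empty((config.N * 9, 3))
            for i in range(config.N):
                all_beads[i * 9 : (i + 1) * 9] = conf.positions[i] + beads_t @ rot[i].T
            for k, (_q, qvecs) in enumerate(shells):
                amps = np.empty(len(qvecs))
                _structure_amplitudes(all_beads, np.ascontiguousarray(qvecs), amps)
                acc[k] += amps.mean()
            n_frames += 1
    p1 = single_y_form_factor(q_shell)
    vals = acc / n_frames / (config.N * 81.0) / p1
    return FormFactorCurve(q=q_shell, values=vals, normalization="S_sim^eff")


def pair_excluded_volume(
    geometry_or_beads=None, n_samples: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte Carlo pair excluded volume of the rigid molecule [sigma^3].

    Averages the overlap indicator over uniformly random relative positions
    (within the bounding sphere of possible contacts) and orientations of
    both molecules.  Returns (estimate, standard error).
    """
    if n_samples < 10_000:
        raise ValueError("need at least 1e4 samples for a meaningful estimate")
    if geometry_or_beads is None:
        beads, _ = _templates()
    elif isinstance(geometry_or_beads, YGeometry):
        g = geometry_or_beads
        beads = np.ascontiguousarray(g.bead_centers - g.center_of_mass())
    else:
        beads = np.ascontiguousarray(np.atleast_2d(geometry_or_beads), dtype=float)
    rmax = 2.0 * np.linalg.norm(beads, axis=1).max() + 1.0 + 1e-9
    hits = _excluded_volume_hits(beads, n_samples, rmax, seed)
    v_sample = 4.0 / 3.0 * np.pi * rmax**3
    frac = hits / n_samples
    err = v_sample * np.sqrt(max(frac * (1.0 - frac), 1e-300) / n_samples)
    return v_sample * frac, err
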