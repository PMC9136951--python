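"""Synthetic systems with known ground truth.

Everything the analyses consume can be generated here: exactly enumerable
lattice grand-canonical systems (the sampler/integration oracle), toy
host-cavity configurations emulating a buried binding site with a handful of
favorable water positions, synthetic GIST frame sets with planted density and
orientation structure, and noisy exponential hydration-relaxation traces.

All generators are reproducible under a seed, and every fixture carries its
planted parameters in a ``provenance`` attribute for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import beta as _beta
from .energetics import (
    ROIRegion,
    RigidWaterConfiguration,
    RigidWaterModel,
    SimulationBox,
)
from .sampler import random_quaternion


# ---------------------------------------------------------------------------
# lattice grand-canonical model (exact oracle)

@dataclass(frozen=True)
class LatticeGCSystem:
    """M discrete sites with occupation energies and pairwise couplings.

    The grand-canonical state space is all 2^M occupancy patterns with weight
    exp(B*N(s) - beta*U(s)), U(s) = sum_m eps_m n_m + sum_{m<n} J_mn n_m n_n.
    Small enough (M <= 20) that the partition function is exactly enumerable.
    """

    energies: np.ndarray  # (M,) kJ/mol
    coupling: np.ndarray = None  # (M, M) symmetric, zero diagonal, kJ/mol
    T: float = 298.0

    def __post_init__(self):
        eps = np.asarray(self.energies, dtype=float).ravel()
        object.__setattr__(self, "energies", eps)
        M = len(eps)
        if M == 0 or M > 20:
            raise ValueError("lattice size must be 1..20 sites")
        J = self.coupling
        J = np.zeros((M, M)) if J is None else np.asarray(J, dtype=float)
        if J.shape != (M, M) or not np.allclose(J, J.T):
            raise ValueError("coupling must be a symmetric (M, M) matrix")
        J = J.copy()
        np.fill_diagonal(J, 0.0)
        object.__setattr__(self, "coupling", J)
        if not (np.all(np.isfinite(eps)) and np.all(np.isfinite(J))):
            raise ValueError("energies must be finite")

    @property
    def M(self) -> int:
        return len(self.energies)

    def state_energy(self, occ: np.ndarray) -> float:
        occ = np.asarray(occ, dtype=float)
        return float(occ @ self.energies + 0.5 * occ @ self.coupling @ occ)


def enumerate_lattice(system: LatticeGCSystem, B: float):
    """Exact (ln Xi, <N>, p(N)) by summation over all 2^M occupancy states.

    Log-sum-exp guarded; ``p(N)`` is the normalized particle-number law.
    """
    M = system.M
    bet = _beta(system.T)
    states = np.arange(2**M, dtype=np.uint32)
    occ = ((states[:, None] >> np.arange(M)) & 1).astype(float)  # (2^M, M)
    U = occ @ system.energies + 0.5 * np.einsum(
        "sm,sm->s", occ, occ @ system.coupling)
    N = occ.sum(axis=1)
    logw = B * N - bet * U
    shift = logw.max()
    w = np.exp(logw - shift)
    Z = w.sum()
    ln_xi = float(shift + math.log(Z))
    mean_n = float((N * w).sum() / Z)
    p_n = np.bincount(N.astype(int), weights=w, minlength=M + 1) / Z
    return ln_xi, mean_n, p_n


def lattice_mean_n_curve(system: LatticeGCSystem, B_values) -> np.ndarray:
    return np.array([enumerate_lattice(system, b)[1] for b in np.asarray(B_values)])


def lattice_b_of_n(system: LatticeGCSystem, target_n: float,
                   b_lo: float = -60.0, b_hi: float = 60.0) -> float:
    """Adams value at which the exact <N>(B) curve passes through target_n
    (bisection; <N>(B) is strictly increasing)."""
    from scipy.optimize import brentq

    f = lambda b: enumerate_lattice(system, b)[1] - target_n
    return float(brentq(f, b_lo, b_hi, xtol=1e-12))


# ---------------------------------------------------------------------------
# toy host cavity

@dataclass(frozen=True)
class ToyHostSpec:
    """A buried-cavity surrogate: attractive hotspot sites inside a spherical
    ROI, an optional repulsive shell forming the cavity wall, and an optional
    "ligand" blocker sterically excluding some hotspots (the apo/holo toggle).

    ``hotspot_depths`` are the target well depths (kJ/mol, positive numbers
    mean attractive) felt by the water oxygen at each hotspot.
    """

    n_hotspots: int = 4
    hotspot_depths: tuple = (30.0, 30.0, 30.0, 30.0)
    hotspot_radius: float = 3.4  # Å from ROI center
    roi_radius: float = 4.7
    blocked_hotspots: tuple = ()  # indices excluded by the "ligand"
    shell: bool = True
    shell_radius: float | None = None  # default: roi_radius + 3 Å
    # small sigma keeps the deep wells short-ranged, so hotspots stay
    # independent single-water sites instead of seeding condensation
    hotspot_sigma: float = 0.5
    blocker_sigma: float = 3.4

    def __post_init__(self):
        if len(self.hotspot_depths) != self.n_hotspots:
            raise ValueError("one depth per hotspot required")
        if any(i >= self.n_hotspots for i in self.blocked_hotspots):
            raise ValueError("blocked hotspot index out of range")
        if self.hotspot_radius >= self.roi_radius:
            raise ValueError("hotspots must lie inside the ROI")


def _tetrahedron_directions(n: int) -> np.ndarray:
    """First n of up to 8 well-separated unit directions (cube vertices)."""
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
                     [-1, -1, -1], [-1, 1, 1], [1, -1, 1], [1, 1, -1]], float)
    if n > len(dirs):
        raise ValueError("at most 8 hotspots supported")
    return dirs[:n] / math.sqrt(3.0)


def _icosahedron_vertices() -> np.ndarray:
    phi = (1 + math.sqrt(5)) / 2
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [[0, a, b], [a, b, 0], [b, 0, a]]
    v = np.array(v)
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_toy_host(spec: ToyHostSpec, model: RigidWaterModel,
                  box: SimulationBox | None = None) -> RigidWaterConfiguration:
    """Deterministic toy cavity configuration from a spec.

    Hotspot LJ epsilons are back-calculated through the Lorentz-Berthelot
    rule so the pair well depth with the water oxygen equals the requested
    hotspot depth.  Blocked hotspots carry an additional purely repulsive
    blocker site at the hotspot position, so insertion there meets a large
    positive dU.
    """
    if box is None:
        box = SimulationBox(lengths=np.array([20.0, 20.0, 20.0]), periodic=True,
                            nonbonded_cutoff=9.0)
    center = box.lengths / 2.0 if box.periodic else np.zeros(3)
    roi = ROIRegion(shape="sphere", center=center, radius=spec.roi_radius)

    eps_o = float(model.epsilons[0])
    if eps_o <= 0:
        raise ValueError("water oxygen needs a nonzero LJ epsilon for the toy host")
    positions, sigmas, epsilons = [], [], []
    dirs = _tetrahedron_directions(spec.n_hotspots)
    blocked = set(spec.blocked_hotspots)
    for i, (d, depth) in enumerate(zip(dirs, spec.hotspot_depths)):
        positions.append(center + d * spec.hotspot_radius)
        if i in blocked:
            # the "ligand" atom occupies the hotspot: repulsive core replaces
            # the attractive site, so insertion there meets a large positive dU
            sigmas.append(spec.blocker_sigma)
            epsilons.append(0.5)
        else:
            sigmas.append(spec.hotspot_sigma)
            epsilons.append(depth**2 / eps_o if depth > 0 else 0.0)
    if spec.shell:
        r_shell = spec.shell_radius or spec.roi_radius + 3.0
        for v in _icosahedron_vertices():
            positions.append(center + v * r_shell)
            sigmas.append(3.2)
            epsilons.append(0.1)
    positions = np.array(positions)
    # reject overlapping host sites (construction error per contract)
    if len(positions) > 1:
        d = np.linalg.norm(positions[:, None] - positions[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if float(d.min()) < 0.5:
            raise ValueError("overlapping host sites in toy spec")

    config = RigidWaterConfiguration(
        box=box, model=model, roi=roi,
        host_positions=positions,
        host_charges=np.zeros(len(positions)),
        host_sigmas=np.array(sigmas),
        host_epsilons=np.array(epsilons),
    )
    config.provenance = {
        "spec": spec,
        "hotspot_positions": center + dirs * spec.hotspot_radius,
        "n_open_hotspots": spec.n_hotspots - len(spec.blocked_hotspots),
    }
    return config


# ---------------------------------------------------------------------------
# synthetic GIST frame sets

@dataclass(frozen=True)
class GaussianPeak:
    """A localized density peak: Gaussian positions around ``center`` with
    std ``width`` (Å), mean count per frame ``amplitude``, and orientations
    drawn as rotation-vector Gaussians of std ``orient_sd`` (rad) about a
    fixed reference orientation (0 => uniform orientations)."""

    center: tuple
    width: float = 0.3
    amplitude: float = 1.0
    orient_sd: float = 0.0  # 0 means uniform random orientations


@dataclass(frozen=True)
class SyntheticGistSpec:
    """Bulk level (as a multiple of the model rho0) plus Gaussian peaks, with
    per-water energies from the stated analytic potential
    U_sw(r) = -sum_p E0_p * exp(-|r - c_p|^2 / (2 w_p^2)), U_ww = const."""

    bulk_scale: float = 1.0
    peaks: tuple = ()
    esw_scale: float = 0.0  # E0 (kJ/mol) applied to every peak
    uww_const: float = 0.0
    n_frames: int = 100

    def __post_init__(self):
        if self.bulk_scale < 0:
            raise ValueError("bulk density scale must be non-negative")
        if self.n_frames < 1:
            raise ValueError("at least one frame required")


def _concentrated_quaternions(rng, n, base_q, sd):
    """Rotation-vector Gaussian perturbations about base_q (scalar-last)."""
    from scipy.spatial.transform import Rotation

    rotvecs = rng.normal(0.0, sd, size=(n, 3))
    return (Rotation.from_rotvec(rotvecs) * Rotation.from_quat(base_q)).as_quat()


def make_gist_frames(spec: SyntheticGistSpec, region_origin, region_lengths,
                     model: RigidWaterModel, T: float = 300.0, seed: int = 0):
    """Generate a :class:`~grandgist.gist.GistFrameSet` with planted structure.

    Bulk waters are Poisson-distributed with density ``bulk_scale * rho0``
    uniformly over the stated cuboid region; each peak adds Poisson-count
    waters at Gaussian positions.  Energies follow the generator's analytic
    potential, so GIST energy-conservation identities are checkable exactly.
    """
    from .gist import GistFrameSet

    rng = np.random.default_rng(seed)
    origin = np.asarray(region_origin, dtype=float)
    lengths = np.asarray(region_lengths, dtype=float)
    volume = float(np.prod(lengths))
    lam_bulk = spec.bulk_scale * model.rho0 * volume
    base_qs = [random_quaternion(rng) for _ in spec.peaks]

    def u_sw(pos: np.ndarray) -> np.ndarray:
        u = np.zeros(len(pos))
        for p in spec.peaks:
            d2 = np.sum((pos - np.asarray(p.center)) ** 2, axis=1)
            u -= spec.esw_scale * np.exp(-d2 / (2.0 * p.width**2))
        return u

    frames = []
    for _ in range(spec.n_frames):
        pos_parts, quat_parts = [], []
        n_bulk = rng.poisson(lam_bulk)
        if n_bulk:
            pos_parts.append(origin + rng.random((n_bulk, 3)) * lengths)
            quat_parts.append(np.array([random_quaternion(rng) for _ in range(n_bulk)]))
        for p, base_q in zip(spec.peaks, base_qs):
            n_p = rng.poisson(p.amplitude)
            if not n_p:
                continue
            pos_parts.append(np.asarray(p.center) + rng.normal(0, p.width, (n_p, 3)))
            if p.orient_sd > 0:
                quat_parts.append(_concentrated_quaternions(rng, n_p, base_q,
                                                            p.orient_sd))
            else:
                quat_parts.append(np.array([random_quaternion(rng)
                                            for _ in range(n_p)]))
        if pos_parts:
            pos = np.concatenate(pos_parts)
            quat = np.concatenate(quat_parts)
        else:
            pos = np.zeros((0, 3))
            quat = np.zeros((0, 4))
        frames.append((pos, quat, u_sw(pos), np.full(len(pos), spec.uww_const)))

    fs = GistFrameSet(frames=frames, T=T, rho0=model.rho0)
    fs.provenance = {"spec": spec, "seed": seed, "region_origin": origin,
                     "region_lengths": lengths, "peak_base_quaternions": base_qs}
    return fs


# ---------------------------------------------------------------------------
# occupancy traces

def make_occupancy_trace(a: float, b: float, k_rate: float, noise_sd: float = 0.0,
                         n_points: int = 200, n_repeats: int = 1, seed: int = 0,
                         t_max: float = 8.0):
    """Noisy exponential hydration-relaxation traces
    N(t) = a + b (1 - e^{-k t}) + Gaussian noise, floored at 0 (ns, waters)."""
    if min(a, b, k_rate) < 0:
        raise ValueError("a, b, k must be non-negative")
    from .compare import OccupancyTrace

    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_max, n_points)
    clean = a + b * (1.0 - np.exp(-k_rate * times))
    series = np.maximum(clean[None, :] + rng.normal(0, noise_sd,
                                                    (n_repeats, n_points)), 0.0)
    trace = OccupancyTrace(times=times, series=series,
                           label=f"synthetic(a={a},b={b},k={k_rate})")
    trace.provenance = {"a": a, "b": b, "k_rate": k_rate, "noise_sd": noise_sd,
                        "seed": seed}
    return trace
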