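"""Rigid-water interaction energies under periodic boundary conditions.

Lennard-Jones (Lorentz-Berthelot combination) plus Coulomb, truncated at the
nonbonded cutoff without shifting or long-range correction.  Site pairs closer
than a hard-core threshold report +inf, which samplers treat as auto-reject.

All energies are in kJ/mol, lengths in Å, charges in e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import COULOMB, HARD_CORE_DIST

SiteKind = Literal["host", "water_oxygen", "water_hydrogen", "water_virtual"]

_WATER_KINDS = ("water_oxygen", "water_hydrogen", "water_virtual")


@dataclass(frozen=True)
class InteractionSite:
    """A single interaction site: position plus LJ and charge parameters."""

    position: np.ndarray
    charge: float
    sigma: float
    epsilon: float
    kind: SiteKind = "host"

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("site position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if self.sigma < 0 or self.epsilon < 0:
            raise ValueError("sigma and epsilon must be non-negative")


@dataclass(frozen=True)
class RigidWaterModel:
    """A rigid water model: local-frame site geometry and parameters.

    ``local_coords`` holds the site positions in the molecular frame (oxygen
    at the origin); ``rho0`` is the bulk number density in Å^-3 used as the
    GIST reference density.
    """

    name: str
    local_coords: np.ndarray  # (n_sites, 3)
    charges: np.ndarray  # (n_sites,)
    sigmas: np.ndarray
    epsilons: np.ndarray
    kinds: tuple[str, ...]
    rho0: float

    def __post_init__(self):
        for attr in ("local_coords", "charges", "sigmas", "epsilons"):
            object.__setattr__(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if abs(float(self.charges.sum())) > 1e-10:
            raise ValueError(f"water model {self.name!r} is not net-neutral")
        if self.rho0 <= 0:
            raise ValueError("bulk density rho0 must be positive")
        if self.kinds[0] != "water_oxygen":
            raise ValueError("first site must be the oxygen")

    @property
    def n_sites(self) -> int:
        return len(self.kinds)

    def place(self, position: np.ndarray, quaternion: np.ndarray) -> np.ndarray:
        """Global site coordinates for a molecule at ``position`` with the
        given orientation (unit quaternion, scalar-last ``[x, y, z, w]``)."""
        rot = Rotation.from_quat(quaternion)
        return rot.apply(self.local_coords) + np.asarray(position, dtype=float)

    @classmethod
    def from_file(cls, path: str | Path) -> "RigidWaterModel":
        """Parse the plain-text key-value water-model format."""
        name = None
        rho0 = None
        coords, charges, sigmas, epsilons, kinds = [], [], [], [], []
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            key = tokens[0]
            if key == "name":
                name = tokens[1]
            elif key == "rho0":
                rho0 = float(tokens[1])
            elif key == "site":
                if len(tokens) != 8:
                    raise ValueError(f"{path}:{lineno}: malformed site record")
                kinds.append(tokens[1])
                coords.append([float(t) for t in tokens[2:5]])
                charges.append(float(tokens[5]))
                sigmas.append(float(tokens[6]))
                epsilons.append(float(tokens[7]))
            else:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        if name is None or rho0 is None or not kinds:
            raise ValueError(f"{path}: incomplete water model file")
        return cls(name, np.array(coords), np.array(charges), np.array(sigmas),
                   np.array(epsilons), tuple(kinds), rho0)

    @classmethod
    def named(cls, name: str) -> "RigidWaterModel":
        """Load one of the bundled models: tip3p_like / tip4p_like / lj_probe."""
        fname = name.lower().replace("-", "_") + ".dat"
        ref = resources.files("grandgist.data").joinpath(fname)
        with resources.as_file(ref) as path:
            return cls.from_file(path)


@dataclass(frozen=True)
class SimulationBox:
    """Orthorhombic box with optional periodicity and a nonbonded cutoff (Å)."""

    lengths: np.ndarray
    periodic: bool = True
    nonbonded_cutoff: float = 10.0

    def __post_init__(self):
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "lengths", lengths)
        if self.nonbonded_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.periodic and np.any(lengths < 2.0 * self.nonbonded_cutoff):
            raise ValueError(
                "periodic box lengths must be at least twice the cutoff "
                f"(lengths {lengths.tolist()}, cutoff {self.nonbonded_cutoff})"
            )

    def displacement(self, dr: np.ndarray) -> np.ndarray:
        """Minimum-image displacement vectors (works on (..., 3) arrays)."""
        if not self.periodic:
            return dr
        return dr - self.lengths * np.round(dr / self.lengths)


@dataclass(frozen=True)
class ROIRegion:
    """Region of interest over which grand-canonical moves act.

    Either a cuboid (``center`` + ``lengths``) or a sphere (``center`` +
    ``radius``), fixed in space.
    """

    shape: Literal["cuboid", "sphere"]
    center: np.ndarray
    lengths: np.ndarray | None = None
    radius: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.shape == "cuboid":
            if self.lengths is None:
                raise ValueError("cuboid ROI needs lengths")
            object.__setattr__(self, "lengths", np.asarray(self.lengths, dtype=float))
            if np.any(self.lengths <= 0):
                raise ValueError("ROI lengths must be positive")
        elif self.shape == "sphere":
            if self.radius is None or self.radius <= 0:
                raise ValueError("sphere ROI needs a positive radius")
        else:
            raise ValueError(f"unknown ROI shape {self.shape!r}")

    @property
    def volume(self) -> float:
        if self.shape == "cuboid":
            return float(np.prod(self.lengths))
        return 4.0 / 3.0 * math.pi * self.radius**3

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        if self.shape == "cuboid":
            inside = np.all(np.abs(pts) <= self.lengths / 2.0, axis=1)
        else:
            inside = np.einsum("ij,ij->i", pts, pts) <= self.radius**2
        return inside

    def sample_point(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform random point inside the region."""
        if self.shape == "cuboid":
            return self.center + (rng.random(3) - 0.5) * self.lengths
        while True:  # rejection from the bounding cube, acceptance ~0.52
            p = (rng.random(3) - 0.5) * 2.0 * self.radius
            if p @ p <= self.radius**2:
                return self.center + p

    def validate_inside(self, box: SimulationBox) -> None:
        """ROI must sit wholly inside the primary cell of a periodic box."""
        if not box.periodic:
            return
        half = self.lengths / 2.0 if self.shape == "cuboid" else self.radius
        lo = self.center - half
        hi = self.center + half
        if np.any(lo < 0.0) or np.any(hi > box.lengths):
            raise ValueError("ROI extends outside the primary periodic cell")


# ---------------------------------------------------------------------------
# proposed-move records consumed by move_delta_energy / the sampler

@dataclass(frozen=True)
class Insertion:
    position: np.ndarray
    quaternion: np.ndarray


@dataclass(frozen=True)
class Deletion:
    index: int


@dataclass(frozen=True)
class Translation:
    index: int
    new_position: np.ndarray


@dataclass(frozen=True)
class RotationMove:
    index: int
    new_quaternion: np.ndarray


@dataclass
class RigidWaterConfiguration:
    """One frame: fixed host sites plus rigid waters in a (periodic) box.

    Waters are stored as oxygen positions and scalar-last unit quaternions;
    the water model supplies local geometry and parameters.  Host sites are
    immutable during sampling.
    """

    box: SimulationBox
    model: RigidWaterModel
    roi: ROIRegion
    host_positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    host_charges: np.ndarray = field(default_factory=lambda: np.zeros(0))
    host_sigmas: np.ndarray = field(default_factory=lambda: np.zeros(0))
    host_epsilons: np.ndarray = field(default_factory=lambda: np.zeros(0))
    positions: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    quaternions: np.ndarray = field(default_factory=lambda: np.zeros((0, 4)))

    def __post_init__(self):
        self.host_positions = np.asarray(self.host_positions, dtype=float).reshape(-1, 3)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.quaternions = np.asarray(self.quaternions, dtype=float).reshape(-1, 4)
        for attr in ("host_charges", "host_sigmas", "host_epsilons"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float).ravel())
        if len(self.positions) != len(self.quaternions):
            raise ValueError("positions and quaternions disagree in length")
        if len(self.quaternions) and np.any(
            np.abs(np.linalg.norm(self.quaternions, axis=1) - 1.0) > 1e-9
        ):
            raise ValueError("orientation quaternions must be unit-norm")
        self.roi.validate_inside(self.box)
        self._site_cache: list[np.ndarray | None] = [None] * len(self.positions)

    @classmethod
    def from_host_sites(cls, box, model, roi, host_sites: Iterable[InteractionSite],
                        positions=None, quaternions=None) -> "RigidWaterConfiguration":
        sites = list(host_sites)
        kw = {}
        if sites:
            kw = dict(
                host_positions=np.array([s.position for s in sites]),
                host_charges=np.array([s.charge for s in sites]),
                host_sigmas=np.array([s.sigma for s in sites]),
                host_epsilons=np.array([s.epsilon for s in sites]),
            )
        if positions is not None:
            kw["positions"] = positions
            kw["quaternions"] = quaternions
        return cls(box=box, model=model, roi=roi, **kw)

    @property
    def n_waters(self) -> int:
        return len(self.positions)

    def host_sites(self) -> list[InteractionSite]:
        return [
            InteractionSite(p, q, s, e, "host")
            for p, q, s, e in zip(self.host_positions, self.host_charges,
                                  self.host_sigmas, self.host_epsilons)
        ]

    def water_sites(self, index: int) -> np.ndarray:
        cached = self._site_cache[index]
        if cached is None:
            cached = self.model.place(self.positions[index], self.quaternions[index])
            self._site_cache[index] = cached
        return cached

    def all_water_sites(self) -> np.ndarray:
        if self.n_waters == 0:
            return np.zeros((0, 3))
        return np.concatenate([self.water_sites(i) for i in range(self.n_waters)])

    def add_water(self, position, quaternion) -> None:
        self.positions = np.vstack([self.positions, np.asarray(position, float)])
        self.quaternions = np.vstack([self.quaternions, np.asarray(quaternion, float)])
        self._site_cache.append(None)

    def remove_water(self, index: int) -> None:
        self.positions = np.delete(self.positions, index, axis=0)
        self.quaternions = np.delete(self.quaternions, index, axis=0)
        del self._site_cache[index]

    def move_water(self, index: int, position=None, quaternion=None) -> None:
        if position is not None:
            self.positions[index] = position
        if quaternion is not None:
            self.quaternions[index] = quaternion
        self._site_cache[index] = None

    def copy(self) -> "RigidWaterConfiguration":
        return RigidWaterConfiguration(
            box=self.box, model=self.model, roi=self.roi,
            host_positions=self.host_positions.copy(),
            host_charges=self.host_charges.copy(),
            host_sigmas=self.host_sigmas.copy(),
            host_epsilons=self.host_epsilons.copy(),
            positions=self.positions.copy(),
            quaternions=self.quaternions.copy(),
        )


# ---------------------------------------------------------------------------
# energy kernels

def _block_energy(pos_a, q_a, sig_a, eps_a, pos_b, q_b, sig_b, eps_b,
                  box: SimulationBox) -> float:
    """Sum of truncated LJ+Coulomb energies over all site pairs (a x b)."""
    if len(pos_a) == 0 or len(pos_b) == 0:
        return 0.0
    dr = box.displacement(pos_a[:, None, :] - pos_b[None, :, :])
    r2 = np.einsum("ijk,ijk->ij", dr, dr)
    if np.any(r2 < HARD_CORE_DIST**2):
        return math.inf
    within = r2 <= box.nonbonded_cutoff**2
    if not np.any(within):
        return 0.0
    r2 = r2[within]
    qq = np.multiply.outer(q_a, q_b)[within]
    sig = (0.5 * np.add.outer(sig_a, sig_b))[within]
    eps = np.sqrt(np.multiply.outer(eps_a, eps_b))[within]
    inv_r2 = 1.0 / r2
    s6 = (sig * sig * inv_r2) ** 3
    u_lj = 4.0 * eps * (s6 * s6 - s6)
    u_coul = COULOMB * qq * np.sqrt(inv_r2)
    return float(np.sum(u_lj) + np.sum(u_coul))


def pair_energy(site_a: InteractionSite, site_b: InteractionSite,
                box: SimulationBox) -> float:
    """Truncated LJ + Coulomb energy of one site pair (minimum image).

    Exactly zero beyond the cutoff; +inf for hard-core overlap (< 1e-6 Å).
    """
    return _block_energy(
        site_a.position[None, :], np.array([site_a.charge]),
        np.array([site_a.sigma]), np.array([site_a.epsilon]),
        site_b.position[None, :], np.array([site_b.charge]),
        np.array([site_b.sigma]), np.array([site_b.epsilon]), box)


def _water_energy_arrays(config: RigidWaterConfiguration, sites: np.ndarray,
                         exclude: int | None) -> tuple[float, float]:
    """(U_sw, U_ww) of a water given its global site coordinates."""
    model, box = config.model, config.box
    u_sw = _block_energy(sites, model.charges, model.sigmas, model.epsilons,
                         config.host_positions, config.host_charges,
                         config.host_sigmas, config.host_epsilons, box)
    others = [j for j in range(config.n_waters) if j != exclude]
    if not others:
        return u_sw, 0.0
    other_sites = np.concatenate([config.water_sites(j) for j in others])
    n_rep = len(others)
    u_ww = _block_energy(sites, model.charges, model.sigmas, model.epsilons,
                         other_sites, np.tile(model.charges, n_rep),
                         np.tile(model.sigmas, n_rep),
                         np.tile(model.epsilons, n_rep), box)
    return u_sw, u_ww


def water_interaction_energy(config: RigidWaterConfiguration,
                             water_index: int) -> tuple[float, float]:
    """Solute-water and water-water interaction energy of one water.

    ``U_ww`` counts every pair involving this water once, so the system total
    water-water energy is half the sum of per-water values.
    """
    if not 0 <= water_index < config.n_waters:
        raise IndexError(f"water index {water_index} out of range")
    sites = config.water_sites(water_index)
    return _water_energy_arrays(config, sites, exclude=water_index)


def total_energy(config: RigidWaterConfiguration) -> float:
    """Total potential energy (host-water + water-water; hosts are fixed,
    their internal energy is a constant left out)."""
    u = 0.0
    for i in range(config.n_waters):
        u_sw, u_ww = water_interaction_energy(config, i)
        u += u_sw + 0.5 * u_ww
    return u


def move_delta_energy(config: RigidWaterConfiguration, move) -> float:
    """Potential-energy change of a proposed move, computed over only the
    affected water's interactions."""
    if isinstance(move, Insertion):
        sites = config.model.place(move.position, move.quaternion)
        u_sw, u_ww = _water_energy_arrays(config, sites, exclude=None)
        return u_sw + u_ww
    if isinstance(move, Deletion):
        u_sw, u_ww = water_interaction_energy(config, move.index)
        return -(u_sw + u_ww)
    if isinstance(move, (Translation, RotationMove)):
        u_old = sum(water_interaction_energy(config, move.index))
        if isinstance(move, Translation):
            sites = config.model.place(move.new_position, config.quaternions[move.index])
        else:
            sites = config.model.place(config.positions[move.index], move.new_quaternion)
        u_sw, u_ww = _water_energy_arrays(config, sites, exclude=move.index)
        u_new = u_sw + u_ww
        if math.isinf(u_new):
            return math.inf
        return u_new - u_old
    raise TypeError(f"unknown move type {type(move).__name__}")
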