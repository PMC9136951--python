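"""Voxel-resolved inhomogeneous solvation thermodynamics (GIST).

Water observations from an ensemble of frames are binned onto a cubic grid;
each voxel accumulates per-frame-averaged solute-water and water-water
interaction energies, a translational entropy from the local density relative
to bulk, and an orientational entropy from a nearest-neighbor estimate of the
orientational distribution.  The density-weighted voxel free energy is

    dG(r_k) = E_sw(k) + E_ww(k) - T * [dS_trans(k) + dS_orient(k)]

and region-of-interest totals are sums over the masked voxels.

Conventions: per-voxel quantities are per-frame averages in kJ/mol, so ROI
sums are directly comparable across grids; water-water pair energies are
half-weighted to each partner's voxel so every pair counts once; entropy
fields hold T*dS (kJ/mol), negative where water is localized relative to
bulk.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

from .constants import KB

#: Euler-Mascheroni constant (the additive nearest-neighbor correction)
EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class GistGrid:
    """Cubic voxel grid: ``origin`` + 0-based half-open voxels of ``spacing``.

    A point x belongs to voxel i iff origin + i*spacing <= x <
    origin + (i+1)*spacing, so boundary points go to the higher-index voxel.
    ``roi_mask`` restricts totals; default is all voxels.
    """

    origin: np.ndarray
    spacing: float = 0.5
    dims: tuple = (10, 10, 10)
    roi_mask: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        mask = self.roi_mask
        if mask is None:
            mask = np.ones(self.dims, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.dims:
                raise ValueError("roi_mask shape must equal dims")
        object.__setattr__(self, "roi_mask", mask)

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def voxel_indices(self, points: np.ndarray) -> np.ndarray:
        """Flat voxel index per point; -1 for points outside the grid."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        ijk = np.floor((pts - self.origin) / self.spacing).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.dims)), axis=1)
        flat = np.full(len(pts), -1, dtype=int)
        flat[inside] = np.ravel_multi_index(ijk[inside].T, self.dims)
        return flat

    def voxel_centers(self) -> np.ndarray:
        axes = [self.origin[d] + (np.arange(self.dims[d]) + 0.5) * self.spacing
                for d in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack([a.ravel() for a in g], axis=1)


@dataclass
class GistFrameSet:
    """Trajectory frames with per-water energies already decomposed.

    Each frame is a tuple ``(positions (n,3), quaternions (n,4), U_sw (n,),
    U_ww (n,))``; ``U_ww`` counts each pair once per participating water, so
    half-weighting at binning time counts every pair exactly once.
    """

    frames: list
    T: float = 300.0
    rho0: float = 0.0329
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("at least one frame required")
        norm_frames = []
        for f in self.frames:
            pos, quat, usw, uww = f
            pos = np.asarray(pos, dtype=float).reshape(-1, 3)
            quat = np.asarray(quat, dtype=float).reshape(-1, 4)
            usw = np.asarray(usw, dtype=float).ravel()
            uww = np.asarray(uww, dtype=float).ravel()
            if not (len(pos) == len(quat) == len(usw) == len(uww)):
                raise ValueError("frame arrays disagree in length")
            if len(quat) and np.any(np.abs(np.linalg.norm(quat, axis=1) - 1) > 1e-9):
                raise ValueError("orientations must be unit quaternions")
            norm_frames.append((pos, quat, usw, uww))
        self.frames = norm_frames

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @classmethod
    def from_configurations(cls, configs, rho0=None):
        """Build a frame set from sampled rigid-water configurations,
        computing per-water U_sw / U_ww with the energetics module."""
        from .energetics import water_interaction_energy

        frames = []
        model = configs[0].model
        for c in configs:
            usw = np.zeros(c.n_waters)
            uww = np.zeros(c.n_waters)
            for i in range(c.n_waters):
                usw[i], uww[i] = water_interaction_energy(c, i)
            frames.append((c.positions.copy(), c.quaternions.copy(), usw, uww))
        return cls(frames=frames, rho0=rho0 if rho0 is not None else model.rho0)


@dataclass
class BinnedWaters:
    """Per-voxel observation bundle produced by :func:`bin_waters`."""

    grid: GistGrid
    counts: np.ndarray  # N_k, flat (n_voxels,)
    voxel_of: np.ndarray  # flat voxel index per kept observation
    quaternions: np.ndarray  # (n_obs, 4) kept observations
    U_sw: np.ndarray
    U_ww: np.ndarray
    order: np.ndarray  # argsort of voxel_of, groups observations by voxel
    n_dropped: int
    n_frames: int


def bin_waters(frames: GistFrameSet, grid: GistGrid) -> BinnedWaters:
    """Assign every water observation to exactly one voxel by oxygen
    position (half-open voxel convention); observations outside the grid are
    dropped and counted."""
    pos = np.concatenate([f[0] for f in frames.frames]) if frames.frames else np.zeros((0, 3))
    quat = np.concatenate([f[1] for f in frames.frames])
    usw = np.concatenate([f[2] for f in frames.frames])
    uww = np.concatenate([f[3] for f in frames.frames])
    idx = grid.voxel_indices(pos) if len(pos) else np.zeros(0, dtype=int)
    keep = idx >= 0
    idx = idx[keep]
    counts = np.bincount(idx, minlength=grid.n_voxels).astype(float)
    return BinnedWaters(
        grid=grid, counts=counts, voxel_of=idx, quaternions=quat[keep],
        U_sw=usw[keep], U_ww=uww[keep], order=np.argsort(idx, kind="stable"),
        n_dropped=int(np.sum(~keep)), n_frames=frames.n_frames)


def voxel_energies(binned: BinnedWaters) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel (E_sw, E_ww) as per-frame averages.

    E_ww gets half weight per observation so the double sum over ordered
    pairs counts each pair once; cross-voxel pair energies thereby split
    equally between the partner voxels.
    """
    n_vox = binned.grid.n_voxels
    e_sw = np.zeros(n_vox)
    e_ww = np.zeros(n_vox)
    np.add.at(e_sw, binned.voxel_of, binned.U_sw)
    np.add.at(e_ww, binned.voxel_of, 0.5 * binned.U_ww)
    return e_sw / binned.n_frames, e_ww / binned.n_frames


def voxel_translational_entropy(binned: BinnedWaters, T: float,
                                rho0: float) -> np.ndarray:
    """T*dS_trans per voxel (kJ/mol): -kT (N_k/N_frame) ln(rho_k/rho0),
    with rho_k = N_k / (V_k N_frame); zero for empty voxels (x ln x -> 0)."""
    if rho0 <= 0:
        raise ValueError("bulk density must be positive")
    n_k = binned.counts
    rho_k = n_k / (binned.grid.voxel_volume * binned.n_frames)
    ts = np.zeros_like(n_k)
    occ = n_k > 0
    ts[occ] = -KB * T * (n_k[occ] / binned.n_frames) * np.log(rho_k[occ] / rho0)
    return ts


def _nn_orientation_distances(quats: np.ndarray, chunk: int = 512) -> np.ndarray:
    """First-nearest-neighbor distance d_i = 2*arccos(|q_i . q_j|) for each
    orientation within a pooled voxel (quaternion double cover handled by the
    absolute dot product).  Chunked so large pools stay within memory."""
    n = len(quats)
    out = np.empty(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        dots = np.abs(quats[start:stop] @ quats.T)
        for r, i in enumerate(range(start, stop)):
            dots[r, i] = -1.0  # exclude self
        np.clip(dots, -1.0, 1.0, out=dots)
        out[start:stop] = 2.0 * np.arccos(dots.max(axis=1))
    return out


def _orientation_ball_fraction(d: np.ndarray) -> np.ndarray:
    """Fraction of orientation space within rotation-angle distance d:
    (d - sin d) / pi (total space pi^2 on the quaternion double cover)."""
    return (d - np.sin(d)) / math.pi


def voxel_orientational_entropy(binned: BinnedWaters, T: float,
                                min_count: int = 2) -> tuple[np.ndarray, dict]:
    """T*dS_orient per voxel (kJ/mol) from the nearest-neighbor estimator.

    For a voxel pooling N_k orientations, -ln g(w_i) is estimated as
    ln V_frac(d_i) + digamma(N_k) + gamma, the Kozachenko-Leonenko form on
    the orientation manifold (the digamma term makes the estimator unbiased
    for uniform orientations even at the small per-voxel counts toy
    ensembles produce; asymptotically it equals the usual ln(N_k - 1)).
    Voxels with fewer than ``min_count`` observations contribute zero and
    are flagged; coincident orientations are floored at 1e-6 rad and
    counted.
    """
    n_vox = binned.grid.n_voxels
    ts = np.zeros(n_vox)
    flags = {"insufficient_observations": 0, "degenerate_orientations": 0}
    sorted_vox = binned.voxel_of[binned.order]
    boundaries = np.flatnonzero(np.diff(sorted_vox)) + 1
    groups = np.split(binned.order, boundaries)
    for grp in groups:
        if len(grp) == 0:
            continue
        k = int(binned.voxel_of[grp[0]])
        n_k = len(grp)
        if n_k < min_count:
            flags["insufficient_observations"] += 1
            continue
        d = _nn_orientation_distances(binned.quaternions[grp])
        degenerate = d < 1e-6
        if np.any(degenerate):
            flags["degenerate_orientations"] += int(degenerate.sum())
            d = np.maximum(d, 1e-6)
        neg_ln_g = np.log(_orientation_ball_fraction(d)) + digamma(n_k) + EULER_GAMMA
        # dS_orient = kB * (N_k/N_frame) * mean(-ln g); negative when ordered
        ts[k] = KB * T * np.sum(neg_ln_g) / binned.n_frames
    return ts, flags


@dataclass
class GistResult:
    """Per-voxel fields (flat arrays) plus ROI totals and optional SEs."""

    grid: GistGrid
    n_frames: int
    T: float
    rho0: float
    counts: np.ndarray
    density: np.ndarray  # rho_k, Å^-3
    E_sw: np.ndarray
    E_ww: np.ndarray
    TS_trans: np.ndarray
    TS_orient: np.ndarray
    dG: np.ndarray
    flags: dict = field(default_factory=dict)
    roi_se: dict = field(default_factory=dict)

    def roi_total(self, name: str) -> float:
        values = getattr(self, name)
        return float(values[self.grid.roi_mask.ravel()].sum())

    @property
    def roi_totals(self) -> dict:
        return {name: self.roi_total(name)
                for name in ("counts", "E_sw", "E_ww", "TS_trans", "TS_orient", "dG")}

    def to_frame(self):
        import pandas as pd

        centers = self.grid.voxel_centers()
        return pd.DataFrame({
            "x": centers[:, 0], "y": centers[:, 1], "z": centers[:, 2],
            "N_k": self.counts, "rho": self.density,
            "E_sw": self.E_sw, "E_ww": self.E_ww,
            "TS_trans": self.TS_trans, "TS_orient": self.TS_orient,
            "dG": self.dG, "in_roi": self.grid.roi_mask.ravel()})


def _compute_fields(binned: BinnedWaters, T: float, rho0: float):
    e_sw, e_ww = voxel_energies(binned)
    ts_trans = voxel_translational_entropy(binned, T, rho0)
    ts_orient, flags = voxel_orientational_entropy(binned, T)
    dg = e_sw + e_ww - (ts_trans + ts_orient)
    return e_sw, e_ww, ts_trans, ts_orient, dg, flags


def voxel_free_energy(frames: GistFrameSet, grid: GistGrid,
                      n_bootstrap: int = 0, n_blocks: int = 10,
                      seed: int = 0) -> GistResult:
    """Full GIST analysis: bin, energies, entropies, and the density-weighted
    voxel free energy dG(k) = E_sw + E_ww - T(dS_trans + dS_orient).

    ``n_bootstrap`` > 0 adds frame-block bootstrap standard errors for the
    ROI totals (frames grouped into ``n_blocks`` contiguous blocks).
    """
    binned = bin_waters(frames, grid)
    e_sw, e_ww, ts_trans, ts_orient, dg, flags = _compute_fields(
        binned, frames.T, frames.rho0)
    flags["observations_outside_grid"] = binned.n_dropped
    density = binned.counts / (grid.voxel_volume * frames.n_frames)
    result = GistResult(grid=grid, n_frames=frames.n_frames, T=frames.T,
                        rho0=frames.rho0, counts=binned.counts, density=density,
                        E_sw=e_sw, E_ww=e_ww, TS_trans=ts_trans,
                        TS_orient=ts_orient, dG=dg, flags=flags)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        n_blocks = min(n_blocks, frames.n_frames)
        blocks = np.array_split(np.arange(frames.n_frames), n_blocks)
        totals = {name: [] for name in ("E_sw", "E_ww", "TS_trans", "TS_orient", "dG")}
        mask = grid.roi_mask.ravel()
        for _ in range(n_bootstrap):
            chosen = rng.integers(0, len(blocks), size=len(blocks))
            frame_ids = np.concatenate([blocks[c] for c in chosen])
            sub = GistFrameSet(frames=[frames.frames[i] for i in frame_ids],
                               T=frames.T, rho0=frames.rho0)
            sb = bin_waters(sub, grid)
            fields = _compute_fields(sb, frames.T, frames.rho0)
            for name, values in zip(("E_sw", "E_ww", "TS_trans", "TS_orient", "dG"),
                                    fields[:5]):
                totals[name].append(values[mask].sum())
        result.roi_se = {name: float(np.std(v, ddof=1))
                         for name, v in totals.items()}
    return result


def density_map(result: GistResult) -> np.ndarray:
    """Normalized density field rho_k / rho0 on the grid (shape = dims)."""
    return (result.density / result.rho0).reshape(result.grid.dims)


def write_dx(field_3d: np.ndarray, grid: GistGrid, path) -> None:
    """Write a per-voxel field as an OpenDX grid file (values at voxel
    centers, C-order)."""
    from gridData import Grid

    g = Grid(np.asarray(field_3d, dtype=float),
             origin=grid.origin + grid.spacing / 2.0,
             delta=[grid.spacing] * 3)
    g.export(str(path), file_format="dx")


def read_dx(path) -> tuple[np.ndarray, GistGrid]:
    """Read an OpenDX file back into (field, grid)."""
    from gridData import Grid

    g = Grid(str(path))
    spacing = float(g.delta[0])
    grid = GistGrid(origin=np.asarray(g.origin) - spacing / 2.0,
                    spacing=spacing, dims=g.grid.shape)
    return np.asarray(g.grid), grid


def pair_voxel_sites(result_a: GistResult, result_b: GistResult,
                     sites_a: np.ndarray, sites_b: np.ndarray,
                     pairing_dist: float = 1.0, fieldname: str = "dG"):
    """Compare per-site voxel values between two runs (restrained-vs-
    perturbed harness): look up ``fieldname`` at the voxel holding each site
    centroid and delegate to the site-pairing metrics."""
    from .compare import pair_and_score_sites

    va = getattr(result_a, fieldname)[result_a.grid.voxel_indices(sites_a)]
    vb = getattr(result_b, fieldname)[result_b.grid.voxel_indices(sites_b)]
    return pair_and_score_sites(sites_a, va, sites_b, vb,
                                pairing_dist=pairing_dist)
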