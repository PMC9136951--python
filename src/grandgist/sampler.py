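"""Grand-canonical Monte Carlo over a region of interest.

Water molecules are inserted into and deleted from the ROI with the Adams
acceptance criteria; translation and rotation moves relax the waters that are
present.  Toy systems are closed over the ROI: there is no explicit bulk
phase, exchange with bulk is represented entirely by the chemical-potential
term B, so N-in-ROI equals N-in-system.

The module also provides the discrete-site (lattice) analogue of the sampler,
whose stationary distribution is exactly the state sum enumerated by
:func:`grandgist.synth.enumerate_lattice` — the correctness gate for the
acceptance rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import KB, beta as _beta
from .energetics import (
    Deletion,
    Insertion,
    ROIRegion,
    RigidWaterConfiguration,
    RotationMove,
    Translation,
    move_delta_energy,
    total_energy,
)


@dataclass(frozen=True)
class AdamsParameters:
    """Thermodynamic inputs of a grand-canonical run.

    ``B`` is the Adams parameter, the dimensionless proxy for the chemical
    potential.  ``mu_ex`` (excess chemical potential of water, kJ/mol) and
    ``V_std`` (standard-state volume of water, Å^3) are only needed to place
    B_equil; ``Lambda`` (thermal wavelength, Å) is carried for completeness
    and cancels once B is specified directly.
    """

    B: float
    T: float = 298.0
    mu_ex: float | None = None
    V_std: float | None = None
    Lambda: float | None = None

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.V_std is not None and self.V_std <= 0:
            raise ValueError("standard-state volume must be positive")

    @property
    def beta(self) -> float:
        return _beta(self.T)

    @property
    def kT(self) -> float:
        return KB * self.T


def equilibrium_adams(params: AdamsParameters, roi: ROIRegion) -> float:
    """Adams value at equilibrium with bulk water.

    B_equil = beta * mu'_sol + ln(V_ROI / V°), where mu'_sol is the excess
    chemical potential of bulk water and V° its standard-state volume.
    """
    if params.mu_ex is None or params.V_std is None:
        raise ValueError("equilibrium_adams needs mu_ex and V_std")
    v_roi = roi.volume
    if v_roi <= 0 or params.V_std <= 0:
        raise ValueError("volumes must be positive")
    return params.beta * params.mu_ex + math.log(v_roi / params.V_std)


def insertion_acceptance(N: int, dU: float, params: AdamsParameters) -> float:
    """P_accept = min[1, exp(B - beta*dU) / (N + 1)] for inserting into a
    state with N waters; the hard-core +inf sentinel gives 0."""
    if N < 0:
        raise ValueError("N must be non-negative")
    if math.isinf(dU):
        return 0.0
    x = params.B - params.beta * dU - math.log(N + 1.0)
    return 1.0 if x >= 0 else math.exp(x)


def deletion_acceptance(N: int, dU: float, params: AdamsParameters) -> float:
    """P_accept = min[1, N * exp(-B - beta*dU)] for deleting one of N waters;
    ``dU`` is the energy change of removing the chosen water."""
    if N < 1:
        raise ValueError("deletion needs at least one water")
    if math.isinf(dU):
        return 0.0
    x = -params.B - params.beta * dU + math.log(N)
    return 1.0 if x >= 0 else math.exp(x)


@dataclass(frozen=True)
class MoveMix:
    """Proposal weights and step sizes for the four GC move types.

    Insert and delete weights must be equal so the B terms in the acceptance
    ratios stay valid without proposal-asymmetry corrections.
    """

    insert: float = 0.25
    delete: float = 0.25
    translate: float = 0.25
    rotate: float = 0.25
    max_translation: float = 0.3  # Å; uniform cube of side 2*max_translation

    def __post_init__(self):
        w = np.array([self.insert, self.delete, self.translate, self.rotate])
        if np.any(w < 0):
            raise ValueError("move weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("at least one move weight must be positive")
        if abs(self.insert - self.delete) > 1e-12 * max(total, 1.0):
            raise ValueError("insert and delete weights must be equal")
        object.__setattr__(self, "_probs", w / total)

    @property
    def probabilities(self) -> np.ndarray:
        return self._probs


@dataclass
class GCTrace:
    """Recorded output of one grand-canonical run."""

    steps: np.ndarray
    N: np.ndarray
    U_total: np.ndarray
    accepted: dict[str, np.ndarray]  # cumulative acceptance counters
    attempted: dict[str, np.ndarray]
    frames: list  # RigidWaterConfiguration snapshots
    seed: int
    params: AdamsParameters
    warnings: dict[str, int] = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return len(self.steps)

    def to_frame(self):
        import pandas as pd

        data = {"step": self.steps, "N": self.N, "U_total": self.U_total}
        for kind in ("insert", "delete", "translate", "rotate"):
            data[f"acc_{kind}"] = self.accepted[kind]
        return pd.DataFrame(data)


def random_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random unit quaternion (Shoemake's subgroup algorithm),
    scalar-last convention."""
    u1, u2, u3 = rng.random(3)
    a, b = math.sqrt(1.0 - u1), math.sqrt(u1)
    return np.array([a * math.sin(2 * math.pi * u2), a * math.cos(2 * math.pi * u2),
                     b * math.sin(2 * math.pi * u3), b * math.cos(2 * math.pi * u3)])


_MOVE_NAMES = ("insert", "delete", "translate", "rotate")


def run_gcmc(config: RigidWaterConfiguration, params: AdamsParameters,
             mix: MoveMix | None = None, n_moves: int = 10_000,
             record_every: int = 10, seed: int = 0,
             frame_every: int = 0) -> GCTrace:
    """Run grand-canonical MC on a rigid-water configuration.

    Insertions propose a uniform point in the ROI with a uniform random
    orientation; deletions pick uniformly among present waters; translations
    that would carry an oxygen outside the ROI are rejected, keeping the
    system closed over the ROI.  Fully reproducible for a given ``seed``.
    """
    if n_moves <= 0:
        raise ValueError("n_moves must be positive")
    mix = mix or MoveMix()
    rng = np.random.default_rng(seed)
    config = config.copy()
    probs = mix.probabilities
    u_total = total_energy(config)

    steps, n_rec, u_rec = [], [], []
    accepted = {k: 0 for k in _MOVE_NAMES}
    attempted = {k: 0 for k in _MOVE_NAMES}
    acc_hist = {k: [] for k in _MOVE_NAMES}
    att_hist = {k: [] for k in _MOVE_NAMES}
    frames = []
    warnings = {"no_water_for_move": 0}

    for step in range(1, n_moves + 1):
        kind = _MOVE_NAMES[rng.choice(4, p=probs)]
        attempted[kind] += 1
        if kind == "insert":
            move = Insertion(config.roi.sample_point(rng), random_quaternion(rng))
            dU = move_delta_energy(config, move)
            if rng.random() < insertion_acceptance(config.n_waters, dU, params):
                config.add_water(move.position, move.quaternion)
                u_total += dU
                accepted[kind] += 1
        elif kind == "delete":
            if config.n_waters == 0:
                warnings["no_water_for_move"] += 1
            else:
                idx = int(rng.integers(config.n_waters))
                dU = move_delta_energy(config, Deletion(idx))
                if rng.random() < deletion_acceptance(config.n_waters, dU, params):
                    config.remove_water(idx)
                    u_total += dU
                    accepted[kind] += 1
        elif kind == "translate":
            if config.n_waters == 0:
                warnings["no_water_for_move"] += 1
            else:
                idx = int(rng.integers(config.n_waters))
                disp = (rng.random(3) - 0.5) * 2.0 * mix.max_translation
                new_pos = config.positions[idx] + disp
                if config.roi.contains(new_pos)[0]:
                    dU = move_delta_energy(config, Translation(idx, new_pos))
                    if dU <= 0 or (not math.isinf(dU)
                                   and rng.random() < math.exp(-params.beta * dU)):
                        config.move_water(idx, position=new_pos)
                        u_total += dU
                        accepted[kind] += 1
        else:  # rotate: uniform random reorientation
            if config.n_waters == 0:
                warnings["no_water_for_move"] += 1
            else:
                idx = int(rng.integers(config.n_waters))
                new_q = random_quaternion(rng)
                dU = move_delta_energy(config, RotationMove(idx, new_q))
                if dU <= 0 or (not math.isinf(dU)
                               and rng.random() < math.exp(-params.beta * dU)):
                    config.move_water(idx, quaternion=new_q)
                    u_total += dU
                    accepted[kind] += 1

        if step % record_every == 0:
            steps.append(step)
            n_rec.append(config.n_waters)
            u_rec.append(u_total)
            for k in _MOVE_NAMES:
                acc_hist[k].append(accepted[k])
                att_hist[k].append(attempted[k])
            if frame_every and (len(steps) % frame_every == 0):
                frames.append(config.copy())

    return GCTrace(
        steps=np.array(steps), N=np.array(n_rec), U_total=np.array(u_rec),
        accepted={k: np.array(v) for k, v in acc_hist.items()},
        attempted={k: np.array(v) for k, v in att_hist.items()},
        frames=frames, seed=seed, params=params, warnings=warnings)


# ---------------------------------------------------------------------------
# Discrete-site (lattice) grand-canonical sampler — the enumeration oracle's
# sampling counterpart.  A state is a subset of M sites; the stationary law
# is pi(s) ∝ exp(B*N(s) - beta*U(s)).  Insertion proposes a uniform site
# (auto-reject if occupied), deletion a uniform occupied site, giving the
# discrete-volume analogue of the Adams criteria with V_ROI -> M sites.

def lattice_insertion_acceptance(M: int, N: int, dU: float, B: float,
                                 beta: float) -> float:
    """min[1, (M / (N+1)) * exp(B - beta*dU)]."""
    x = B - beta * dU + math.log(M / (N + 1.0))
    return 1.0 if x >= 0 else math.exp(x)


def lattice_deletion_acceptance(M: int, N: int, dU: float, B: float,
                                beta: float) -> float:
    """min[1, (N / M) * exp(-B - beta*dU)]."""
    if N < 1:
        raise ValueError("deletion needs an occupied site")
    x = -B - beta * dU + math.log(N / M)
    return 1.0 if x >= 0 else math.exp(x)


def run_lattice_gcmc(system, B: float, n_moves: int = 100_000,
                     record_every: int = 5, seed: int = 0) -> GCTrace:
    """Insertion/deletion MC on a :class:`~grandgist.synth.LatticeGCSystem`."""
    if n_moves <= 0:
        raise ValueError("n_moves must be positive")
    rng = np.random.default_rng(seed)
    M = system.M
    bet = _beta(system.T)
    eps = system.energies
    J = system.coupling
    occ = np.zeros(M, dtype=bool)
    N = 0
    u_total = 0.0

    # pre-drawn randomness in blocks keeps the hot loop cheap
    steps, n_rec, u_rec = [], [], []
    accepted = {k: 0 for k in _MOVE_NAMES}
    attempted = {k: 0 for k in _MOVE_NAMES}
    acc_hist = {k: [] for k in _MOVE_NAMES}
    att_hist = {k: [] for k in _MOVE_NAMES}
    block = 65536
    done = 0
    step = 0
    while done < n_moves:
        n_blk = min(block, n_moves - done)
        coins = rng.random(n_blk)
        sites = rng.integers(0, M, size=n_blk)
        sels = rng.random(n_blk)
        accs = rng.random(n_blk)
        for i in range(n_blk):
            step += 1
            if coins[i] < 0.5:  # insertion
                attempted["insert"] += 1
                m = sites[i]
                if not occ[m]:
                    dU = eps[m] + float(J[m] @ occ)
                    if accs[i] < lattice_insertion_acceptance(M, N, dU, B, bet):
                        occ[m] = True
                        N += 1
                        u_total += dU
                        accepted["insert"] += 1
            else:  # deletion
                attempted["delete"] += 1
                if N > 0:
                    occ_idx = np.flatnonzero(occ)
                    m = occ_idx[min(int(sels[i] * N), N - 1)]
                    dU = -(eps[m] + float(J[m] @ occ) - J[m, m])
                    if accs[i] < lattice_deletion_acceptance(M, N, dU, B, bet):
                        occ[m] = False
                        N -= 1
                        u_total += dU
                        accepted["delete"] += 1
            if step % record_every == 0:
                steps.append(step)
                n_rec.append(N)
                u_rec.append(u_total)
                for k in _MOVE_NAMES:
                    acc_hist[k].append(accepted[k])
                    att_hist[k].append(attempted[k])
        done += n_blk

    params = AdamsParameters(B=B, T=system.T)
    return GCTrace(
        steps=np.array(steps), N=np.array(n_rec), U_total=np.array(u_rec),
        accepted={k: np.array(v) for k, v in acc_hist.items()},
        attempted={k: np.array(v) for k, v in att_hist.items()},
        frames=[], seed=seed, params=params)


def blocked_mean_se(values: np.ndarray, n_blocks: int = 20) -> tuple[float, float]:
    """Mean and standard error from non-overlapping block averages, absorbing
    autocorrelation at the block scale."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("no values")
    n_blocks = max(2, min(n_blocks, n))
    usable = (n // n_blocks) * n_blocks
    blocks = values[n - usable:].reshape(n_blocks, -1).mean(axis=1)
    mean = float(values.mean())
    se = float(blocks.std(ddof=1) / math.sqrt(n_blocks))
    return mean, se
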