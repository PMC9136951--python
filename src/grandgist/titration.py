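"""Titration curves and grand-canonical integration (GCI).

A family of grand-canonical runs over an Adams-value grid yields the mean
occupancy curve <N>(B).  Because <N>(B) = d ln Xi / dB, integrating the
(monotone-smoothed) curve gives free-energy differences between water
networks of different sizes:

    dG_bind(N_i -> N_f) = kT * [ B_f N_f - B_i N_i - Int_{B_i}^{B_f} <N> dB
                                 - (N_f - N_i) * B_equil ]

where B_i, B_f are the Adams values at which the smoothed curve passes
through N_i and N_f, and the B_equil term converts to a binding free energy
relative to bulk water.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .constants import KB
from .sampler import GCTrace, blocked_mean_se


class ExtrapolationError(ValueError):
    """Requested occupancy lies outside the span of the smoothed curve."""


@dataclass
class TitrationCurve:
    """Sampled (B_k, <N>_k, SE_k) points plus smoothing machinery.

    Smoothing is isotonic (monotone) regression through the sampled means
    followed by monotone piecewise-cubic (PCHIP) interpolation, which keeps
    the physics (<N> nondecreasing in B) and makes B(N) inversion
    well-defined.
    """

    B: np.ndarray
    mean_N: np.ndarray
    se_N: np.ndarray
    n_samples: np.ndarray
    T: float
    B_equil: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for attr in ("B", "mean_N", "se_N", "n_samples"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if np.any(np.diff(self.B) <= 0):
            raise ValueError("Adams values must be strictly increasing")
        if np.any(self.mean_N < 0):
            raise ValueError("mean occupancies must be non-negative")
        iso = IsotonicRegression(increasing=True)
        weights = np.where(self.se_N > 0, 1.0 / np.maximum(self.se_N, 1e-12) ** 2, 1.0)
        smoothed = iso.fit_transform(self.B, self.mean_N, sample_weight=weights)
        self.smoothed_N = smoothed
        self._pchip = PchipInterpolator(self.B, smoothed, extrapolate=False)
        self._grid = np.linspace(self.B[0], self.B[-1], 1000)
        self._grid_N = self._pchip(self._grid)

    @property
    def kT(self) -> float:
        return KB * self.T

    def N_of_B(self, b) -> np.ndarray | float:
        """Smoothed mean occupancy at Adams value(s) b (no extrapolation)."""
        b = np.asarray(b, dtype=float)
        if np.any(b < self.B[0]) or np.any(b > self.B[-1]):
            raise ExtrapolationError(
                f"B outside sampled span [{self.B[0]}, {self.B[-1]}]")
        out = self._pchip(b)
        return float(out) if out.ndim == 0 else out

    def B_of_N(self, n: float) -> float:
        """Adams value at which the smoothed curve passes through n.

        If the curve is flat at value n, the midpoint of the flat B interval
        is returned.
        """
        g, gn = self._grid, self._grid_N
        if n < gn[0] - 1e-12 or n > gn[-1] + 1e-12:
            raise ExtrapolationError(
                f"occupancy {n} outside smoothed span [{gn[0]:.4g}, {gn[-1]:.4g}]")
        n = min(max(n, gn[0]), gn[-1])
        i_hi = int(np.searchsorted(gn, n, side="left"))
        i_lo = int(np.searchsorted(gn, n, side="right")) - 1
        if i_lo > i_hi:  # flat stretch exactly at value n
            return float(0.5 * (g[i_hi] + g[i_lo]))
        i_hi = min(i_hi, len(g) - 1)
        if i_hi == 0 or gn[i_hi] == gn[i_hi - 1]:
            return float(g[i_hi])
        f = (n - gn[i_hi - 1]) / (gn[i_hi] - gn[i_hi - 1])
        return float(g[i_hi - 1] + f * (g[i_hi] - g[i_hi - 1]))

    def se_at_B(self, b: float) -> float:
        """Per-point SE linearly interpolated to Adams value b."""
        return float(np.interp(b, self.B, self.se_N))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"B": self.B, "mean_N": self.mean_N,
                             "se_N": self.se_N, "n_samples": self.n_samples})


def build_titration_curve(tagged_traces, discard_fraction: float = 0.2,
                          B_equil: float | None = None,
                          n_blocks: int = 20) -> TitrationCurve:
    """Aggregate grand-canonical traces into a titration curve.

    ``tagged_traces`` is an iterable of ``(B, GCTrace)`` pairs (repeats at the
    same B are pooled).  The first ``discard_fraction`` of the records of each
    trace is discarded as burn-in; per-B standard errors take the larger of
    the pooled block-SE and the between-repeat spread.
    """
    if not 0 <= discard_fraction < 1:
        raise ValueError("discard_fraction must be in [0, 1)")
    groups: dict[float, list[GCTrace]] = {}
    temps = set()
    for b, trace in tagged_traces:
        groups.setdefault(float(b), []).append(trace)
        temps.add(trace.params.T)
    if len(groups) < 4:
        raise ValueError(
            f"need at least 4 distinct Adams values, got {len(groups)}")
    if len(temps) != 1:
        raise ValueError("all traces must share one temperature")
    T = temps.pop()

    rows = []
    for b in sorted(groups):
        repeat_means, ses, n_tot = [], [], 0
        for trace in groups[b]:
            n_skip = int(len(trace.N) * discard_fraction)
            kept = trace.N[n_skip:]
            if len(kept) < 50:
                raise ValueError(
                    f"trace at B={b} has only {len(kept)} post-burn-in records")
            m, se = blocked_mean_se(kept, n_blocks=n_blocks)
            repeat_means.append(m)
            ses.append(se)
            n_tot += len(kept)
        mean = float(np.mean(repeat_means))
        se_within = math.sqrt(sum(s**2 for s in ses)) / len(ses)
        if len(repeat_means) > 1:
            se_between = float(np.std(repeat_means, ddof=1)
                               / math.sqrt(len(repeat_means)))
        else:
            se_between = 0.0
        rows.append((b, mean, max(se_within, se_between), n_tot))

    arr = np.array(rows)
    return TitrationCurve(B=arr[:, 0], mean_N=arr[:, 1], se_N=arr[:, 2],
                          n_samples=arr[:, 3], T=T, B_equil=B_equil,
                          provenance={"discard_fraction": discard_fraction,
                                      "n_blocks": n_blocks,
                                      "seeds": [t.seed for ts in groups.values()
                                                for t in ts]})


def _integral_and_se(curve: TitrationCurve, b_lo: float, b_hi: float,
                     n_grid: int = 1000) -> tuple[float, float]:
    """Trapezoid integral of the smoothed curve over [b_lo, b_hi] and the SE
    propagated from per-point occupancy uncertainties."""
    if b_hi < b_lo:
        val, se = _integral_and_se(curve, b_hi, b_lo, n_grid)
        return -val, se
    grid = np.linspace(b_lo, b_hi, n_grid)
    integral = float(np.trapezoid(curve._pchip(grid), grid))
    # per-point SEs enter through trapezoid weights on the sampled grid
    inside = (curve.B >= b_lo) & (curve.B <= b_hi)
    bs = curve.B[inside]
    if len(bs) >= 2:
        w = np.gradient(bs)
        var = float(np.sum((w * curve.se_N[inside]) ** 2))
    else:
        var = float((curve.se_at_B(0.5 * (b_lo + b_hi)) * (b_hi - b_lo)) ** 2)
    return integral, math.sqrt(var)


#: slack for asymptotic tail completion at the curve ends: N=0 is reachable
#: when <N>(B_min) is below this, and a saturation endpoint when the smoothed
#: maximum is within this of the requested integer
_TAIL_TOL = 0.5


def _grand_potential_term(curve: TitrationCurve, n: float) -> tuple[float, float]:
    """(F(n), effective B endpoint) with F(n) = B(n)*n - ln Xi(B(n)), in kT.

    ln Xi is reconstructed from the smoothed curve via ln Xi(B) =
    Int_{-inf}^{B} <N> dB', with the portion below the sampled range
    completed analytically by the ideal-dilute tail ln Xi(B_min) ~
    <N>(B_min); an endpoint above the smoothed maximum (a saturated network)
    is completed by the mirror-image tail at the top.  dG(N_i -> N_f) is then
    kT*(F(N_f) - F(N_i)) minus the bulk-exchange term, which makes
    antisymmetry and additivity over intermediate sizes exact.
    """
    n_lo = float(curve.smoothed_N[0])
    n_hi = float(curve.smoothed_N[-1])
    if n == 0:
        if n_lo > _TAIL_TOL:
            raise ExtrapolationError(
                f"curve never approaches the empty ROI (min <N> = {n_lo:.3g}); "
                "sample lower Adams values")
        return 0.0, float(curve.B[0])
    if n > n_hi:
        if n - n_hi > _TAIL_TOL:
            raise ExtrapolationError(
                f"occupancy {n} above smoothed maximum {n_hi:.4g}")
        b_max = float(curve.B[-1])
        integral, _ = _integral_and_se(curve, float(curve.B[0]), b_max)
        ln_xi = n_lo + integral
        return b_max * n - ln_xi + (n - n_hi), b_max
    b_n = curve.B_of_N(n)
    integral, _ = _integral_and_se(curve, float(curve.B[0]), b_n)
    ln_xi = n_lo + integral
    return b_n * n - ln_xi, b_n


def gci_binding_free_energy(curve: TitrationCurve, N_i: float, N_f: float,
                            with_se: bool = False):
    """Network binding free energy dG_bind(N_i -> N_f) in kJ/mol.

    Antisymmetric in (N_i, N_f) and additive over intermediate sizes.
    Requires ``curve.B_equil`` to be set.  Endpoints must lie within the
    span of the smoothed curve (up to the analytic tail completions at the
    empty and saturated ends); anything else raises
    :class:`ExtrapolationError` rather than extrapolating.
    """
    if curve.B_equil is None:
        raise ValueError("curve must carry B_equil for binding free energies")
    if N_i == N_f:
        return (0.0, 0.0) if with_se else 0.0
    f_i, b_i = _grand_potential_term(curve, N_i)
    f_f, b_f = _grand_potential_term(curve, N_f)
    dg = curve.kT * (f_f - f_i - (N_f - N_i) * curve.B_equil)
    if not with_se:
        return float(dg)
    # the shared ln Xi segment below min(b_i, b_f) cancels in the difference;
    # only the integral between the two endpoints carries uncertainty
    _, int_se = _integral_and_se(curve, b_i, b_f)
    return float(dg), float(curve.kT * int_se)


@dataclass
class NetworkFreeEnergyProfile:
    """dG_bind(0 -> N) for integer N, its minimum, and <N> at B_equil."""

    N: np.ndarray
    dG: np.ndarray
    dG_se: np.ndarray
    optimal_N: int
    dG_min: float
    N_at_Bequil: float
    se_N_at_Bequil: float
    shallow: bool
    T: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"N": self.N, "dG_kJmol": self.dG,
                             "dG_se": self.dG_se})


def free_energy_profile(curve: TitrationCurve) -> NetworkFreeEnergyProfile:
    """Tabulate dG_bind(0 -> N) for every integer N the curve spans, locate
    the free-energy minimum, and report <N> at the equilibrium Adams value.

    The minimum is flagged ``shallow`` when a neighboring integer lies within
    kT of it.
    """
    if curve.B_equil is None:
        raise ValueError("curve must carry B_equil")
    if not curve.B[0] <= curve.B_equil <= curve.B[-1]:
        raise ExtrapolationError(
            f"B_equil={curve.B_equil:.3g} outside sampled span "
            f"[{curve.B[0]:.3g}, {curve.B[-1]:.3g}]")
    # integers reachable on the smoothed curve, plus a saturated network
    # completed by the asymptotic top tail (within _TAIL_TOL of the maximum)
    n_max = int(math.floor(float(curve.smoothed_N[-1]) + _TAIL_TOL + 1e-9))
    ns = np.arange(0, n_max + 1)
    dgs, ses = [0.0], [0.0]
    for n in ns[1:]:
        dg, se = gci_binding_free_energy(curve, 0, int(n), with_se=True)
        dgs.append(dg)
        ses.append(se)
    dgs = np.array(dgs)
    ses = np.array(ses)
    i_min = int(np.argmin(dgs))
    neighbors = [dgs[j] for j in (i_min - 1, i_min + 1) if 0 <= j < len(dgs)]
    shallow = any(abs(v - dgs[i_min]) < curve.kT for v in neighbors)
    n_beq = curve.N_of_B(curve.B_equil)
    return NetworkFreeEnergyProfile(
        N=ns, dG=dgs, dG_se=ses, optimal_N=int(ns[i_min]),
        dG_min=float(dgs[i_min]), N_at_Bequil=float(n_beq),
        se_N_at_Bequil=curve.se_at_B(curve.B_equil), shallow=shallow, T=curve.T)
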