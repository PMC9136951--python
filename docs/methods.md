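# Methods

This note records the models, estimators, numerical choices, and design
decisions behind `grandgist`, and what the toy-scale validation does and
does not demonstrate.

## Energetics

Interactions are pairwise Lennard-Jones (Lorentz–Berthelot combination:
σ_ij = (σ_i+σ_j)/2, ε_ij = √(ε_i ε_j)) plus Coulomb with the constant
138.935458 kJ·mol⁻¹·Å·e⁻², truncated plainly at the nonbonded cutoff — no
shift, switch, or long-range correction. This mirrors the simplest
Monte-Carlo treatment and makes the cutoff contract exact: any site pair
beyond the cutoff contributes exactly zero. Units are fixed project-wide
(Å, kJ/mol, K, e; k_B = 0.0083144626 kJ·mol⁻¹·K⁻¹). Minimum-image
convention applies in periodic boxes, which must be at least twice the
cutoff in every direction; the ROI must lie wholly inside the primary cell.
Site pairs closer than 10⁻⁶ Å short-circuit to +∞ (hard-core sentinel) so
overlapping insertions auto-reject instead of overflowing.

Water models are rigid and loaded from plain-text parameter files: a
TIP3P-like 3-site model (ρ° = 0.0329 Å⁻³), a TIP4P-like 4-site model with a
virtual charge site (ρ° = 0.0332 Å⁻³), and a single-site neutral LJ probe
used by the toy cavities, where one well holding one "water" keeps
titration curves interpretable. Orientations are scalar-last unit
quaternions; the quaternion double cover is handled everywhere by absolute
dot products.

## Grand-canonical sampler

Moves are insertion, deletion, translation, and rotation with equal
insert/delete proposal weights (so the Adams acceptance ratios need no
proposal-asymmetry correction). Insertions propose a uniform point in the
ROI with a Shoemake-uniform orientation; deletions pick uniformly among
present waters; translations are uniform displacements in a cube of side
2 × 0.3 Å and are rejected if they would carry the oxygen out of the ROI.
Toy systems are therefore closed over the ROI: there is no explicit bulk
phase, and exchange with bulk is represented entirely by the
chemical-potential term B, which is exactly what the grand-canonical
acceptance rules encode. This deliberately diverges from protein
simulations, where translated waters can leave the ROI into explicit bulk.

The discrete-site (lattice) sampler is the continuous sampler's analogue
with volume replaced by site count: insertion proposes one of M sites
uniformly (occupied → auto-reject) with acceptance
min[1, (M/(N+1))·e^{B−βΔU}]; deletion picks an occupied site uniformly with
acceptance min[1, (N/M)·e^{−B−βΔU}]. Its stationary law is exactly
π(s) ∝ exp(B·N(s) − βU(s)), the same measure the enumeration oracle sums,
and an exact detailed-balance test covers every state pair of a coupled
3-site system. One RNG stream per run, keyed by the seed; traces record N,
total energy, and per-move acceptance counters, and standard errors come
from non-overlapping block averages (20 blocks by default), which absorb
autocorrelation at the block scale.

## Titration analysis and grand-canonical integration

⟨N⟩(B) points (mean ± SE per B after discarding a 20% burn-in; repeats
pooled with the larger of within- and between-repeat SE) are smoothed by
isotonic regression — the physics guarantees monotonicity — followed by
monotone piecewise-cubic (PCHIP) interpolation, making the inversion B(N)
well-defined; a flat stretch at exactly N returns the midpoint of its B
interval. Integration uses the trapezoid rule on a 1000-point refined grid.

Free energies are assembled from per-endpoint grand-potential terms
F(N) = B(N)·N − ln Ξ(B(N)) in units of kT, with
ln Ξ(B) = ∫_{−∞}^{B} ⟨N⟩ dB′ reconstructed from the smoothed curve. Two
asymptotic completions close the ends of the sampled range:

- **Empty ROI.** B(0) does not exist on a strictly positive curve; in the
  ideal-dilute regime below the lowest sampled B, ln Ξ ≈ ⟨N⟩, so the missing
  lower tail equals ⟨N⟩(B_min) and F(0) = 0 exactly. This requires
  ⟨N⟩(B_min) < 0.5 (error of order kT·⟨N⟩(B_min)); otherwise the request is
  refused as extrapolation.
- **Saturated network.** An integer up to 0.5 above the smoothed maximum is
  completed by the mirror-image top tail (B·N − ln Ξ approaches its limit
  exponentially as sites saturate). Anything further outside the span
  raises an extrapolation error rather than extrapolating.

Writing ΔG(N_i→N_f) = kT·(F(N_f) − F(N_i)) − (N_f−N_i)·kT·B_equil makes
antisymmetry and additivity over intermediate sizes exact by construction.
ΔG uncertainties propagate the per-point SEs through trapezoid weights over
the integration window (the shared segment below both endpoints cancels in
the difference). The profile tabulates ΔG(0→N) for every reachable integer,
reports the argmin and ⟨N⟩ at B_equil, and flags the minimum as *shallow*
when a neighboring integer lies within kT — in that regime the exact
optimum is not reliably identifiable.

On a 10-site lattice with site energies spanning −20..0 kJ/mol, an 11-point
B grid at 2×10⁵ moves per point reproduces exact enumeration within 3 SE at
every point and exact state-sum free-energy differences within 0.1 kJ/mol
for all 0→N transfers — this is the core correctness gate.

## GIST

Observations are binned by oxygen position into half-open 0.5 Å voxels
(boundary points go to the higher-index voxel). Per voxel k:

- E_sw(k): per-frame average of the solute–water energies of the waters
  observed there; summing over voxels recovers the directly computed total
  exactly.
- E_ww(k): the same with half weight per observation, so every water–water
  pair counts once and cross-voxel pairs split equally between partners.
- TΔS_trans(k) = −kT·(N_k/N_frame)·ln(ρ_k/ρ°), ρ_k = N_k/(V_k·N_frame);
  zero for empty voxels (x ln x → 0) and at bulk density.
- TΔS_orient(k): nearest-neighbor estimate of −⟨ln g(ω)⟩ over the voxel's
  pooled orientations. For each observation the NN distance is
  d_i = 2 arccos|q_i·q_j|, the fraction of orientation space within d is
  (d − sin d)/π (total π² on the quaternion double cover), and
  −ln g(ω_i) ≈ ln V_frac(d_i) + ψ(N_k) + γ with ψ the digamma function and
  γ the Euler–Mascheroni constant. The digamma form (rather than
  ln(N_k − 1)) is the Kozachenko–Leonenko small-sample correction: it makes
  the estimator unbiased for uniform orientations even at the few
  observations per voxel that toy ensembles produce, and coincides with
  ln(N_k−1) asymptotically. A brute-force histogram entropy (binned
  rotation vectors weighted by the exact Haar fraction per bin) serves as
  the independent arbiter; the two agree within 2% at 10⁴ concentrated
  observations. Voxels with fewer than 2 observations contribute zero with
  an `insufficient_observations` flag; coincident orientations are floored
  at 10⁻⁶ rad and counted.

ΔG(k) = E_sw + E_ww − T(ΔS_trans + ΔS_orient); ROI totals are masked sums,
with optional frame-block bootstrap SEs (10 contiguous blocks by default,
clamped to the frame count). Density maps ρ_k/ρ° are written/read as OpenDX
through GridDataFormats.

The translational-entropy formula carries an O(kT·n_voxels/(2·N_frame))
discretization bias at finite frame counts (E[N ln(N/λ)] ≈ 1/2 per voxel);
bulk-limit checks therefore size the uniform fixture (125 voxels, 500
frames) so the bias stays well inside the stated 0.5 kJ/mol tolerance. This
is a property of the standard estimator, not of the fixture.

Site-level comparison between two runs (restrained-vs-perturbed harness)
looks up the voxel value at each site centroid, pairs sites across runs by
distance, and reports R/MAD/Max/MRD as below.

## Comparison statistics

- **Equilibration fits.** Nonlinear least squares of
  N(t) = a + b(1 − e^{−kt}) with positivity bounds;
  t_eq = (1/k)·ln(b/(0.05(a+b))) when b > 0.05(a+b), else 0 (already
  equilibrated); N_eq averages N(t) over t ≥ t_eq. The synthetic trace
  generator adds Gaussian noise (floored at 0) over an 8 ns window sampled
  at 200 points — four relaxation times of the canonical (a=2, b=6,
  k=0.5 ns⁻¹) fixture, chosen by identifiability analysis: denser early
  sampling is what pins down the initial occupancy a. At noise σ = 0.5 with
  10 repeats, mean parameter-recovery errors across 100 seeds are ~2%
  (95th percentile below 5%); individual unlucky draws can exceed 5%, which
  is a Fisher-information floor of the fixture, not an estimator defect.
- **Clustering.** Average-linkage hierarchical clustering of water oxygens
  cut at 2.4 Å, with same-frame pairs set to 10⁶ Å so waters present
  simultaneously never merge; centroids are unweighted member means;
  occupancy is the fraction of frames contributing a member, filtered at
  0.3 by default. Verified against a naive agglomeration oracle on all
  small instances.
- **Matching.** Everywhere a one-to-one greedy match in ascending distance
  order (Tanimoto agreement c at 1.4 Å, crystal recovery over 0.0–2.0 Å
  thresholds, site pairing at 1.0 Å): deterministic, symmetric for
  Tanimoto, and equal to optimal bipartite matching on well-separated
  sites. Distances at a threshold boundary count as within it (10⁻⁹
  tolerance). Two empty cluster sets are identically empty (T = 1); one
  empty gives T = 0.
- **Occupancy distributions.** Two-sample Kruskal–Wallis with tie-corrected
  chi-square p-values, switching to a permutation p-value (5000 resamples)
  when either sample is smaller than 10; identical pooled values give
  p = 1 with H = 0. Significance marks follow the ***/**/*/. convention at
  0.001/0.01/0.05/0.1.
- **Site metrics.** Pearson R, mean absolute deviation, maximum deviation,
  and mean relative deviation (absolute difference over the larger of the
  two absolute values, averaged over pairs).

## Synthetic systems

The lattice model (≤ 20 sites, optional pairwise couplings) is exactly
enumerable by log-sum-exp state sums and is the single source of truth for
the sampler and integration gates. The toy cavity places up to 8 hotspot LJ
sites on cube-vertex directions at 3.4 Å from the center of a 4.7 Å
spherical ROI inside a 20 Å periodic box, with an icosahedral repulsive
shell as the cavity wall. Hotspot epsilons are back-calculated through the
combination rule so the pair well depth equals the requested value
(30 kJ/mol by default, giving per-water binding free energies of a few to
~15 kJ/mol); the hotspot σ is small (0.5 Å) so the deep wells stay
short-ranged, single-water sites — with broad deep wells the r⁻⁶ tails
overlap and the cavity condenses instead of titrating discretely. The
"ligand" blocker replaces a hotspot's attractive site with a repulsive core
(σ = 3.4 Å), so insertion there meets a large positive ΔU: toggling it off
is the apo form, which binds more waters with a more negative network free
energy, and for both forms the profile argmin agrees with the rounded
⟨N⟩(B_equil). Synthetic GIST fields are Poisson bulk plus Gaussian peaks
with rotation-vector-Gaussian orientations and energies from a stated
analytic potential, so all conservation identities are checkable; planted
parameters ride along in a `provenance` attribute.

## Problem sizes and determinism

Validation runs at desk scale: 10⁵–2×10⁵ moves per Adams value on ≤ 10-site
lattices, 3×10⁴ moves per point for the 11-point toy-cavity titrations, 500
frames for bulk-limit GIST checks, 10⁴ observations for estimator
cross-checks. Every stochastic component takes an explicit integer seed and
replays bit-for-bit; output files carry the package version and seed in
their headers.

## Limitations

No explicit bulk phase, protein force fields, flexible or polarizable
waters, Ewald/PME electrostatics, replica exchange over B, or structural
alignment: trajectory analysis assumes a fixed frame of reference and
refuses drifting host coordinates. Passing the toy-scale gates demonstrates
the correctness of the estimators and acceptance rules, not the behavior of
real protein hydration: synthetic fixtures have ideal noise structure
(Gaussian/Poisson, no slow collective modes), so timescale and convergence
conclusions about proteins are outside what these tests can show. GCMC
network binding free energies and GIST ROI totals use different reference
states and are not directly comparable; both are reported as-is.
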