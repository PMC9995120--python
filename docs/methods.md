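# Methods

This note documents the models and numerical choices behind
`pocketensemble`: what each stage computes, the defaults and why, what the
synthetic generators do and do not emulate, and the known limitations.

## Pocket volumes on a grid

A Cartesian grid (default spacing 1.0 Å) is laid over each structure,
padded 2 Å beyond the bounding box of the contributing atoms. A grid point
is *protein-excluded* when its distance to some protein atom is below that
atom's van der Waals radius plus the probe radius; otherwise it is solvent.
The van der Waals table is explicit and configurable (C 1.70, N 1.55,
O 1.52, S 1.80, H 1.20, P 1.80 Å; 1.70 Å fallback). Each solvent point is
scanned along 7 lines — the three grid axes and the four cube diagonals —
and its rank counts the lines with protein-excluded points on *both* sides
(a protein–solvent–protein event). Lines clip at the grid boundary; an
open side is not an event.

The ligand-site volume pipeline is: keep points with rank ≥ 6; drop
26-connected components smaller than 3 points; keep points within 2.5 Å of
a heavy atom of the reference ligand (placed into the frame by local site
alignment, below); single-linkage cluster the survivors at 1.5 Å and keep
the largest cluster, breaking ties toward the cluster whose centroid is
nearest the ligand centroid; volume = point count × spacing³.

Defaults deliberately use a large probe radius (1.4 Å), so reported
volumes are the *core* of a pocket, smaller than the space available to a
ligand; they are meaningful relative to the holo reference volume computed
with identical parameters, not as absolute cavity sizes. The holo
threshold is therefore always computed, never hard-coded.

Numerical choices: the 1.0 Å spacing makes face and edge grid neighbours
(≤ √2 Å) fall inside the 1.5 Å linkage cutoff while corner neighbours
(√3 Å) fall outside, and keeps per-frame cost at the millisecond scale.
The grid origin snaps a grid plane to the atom centroid, which makes
volumes exactly invariant under 90° rotations about grid axes and limits
translation sensitivity to a single surface shell. The small-component
filter runs *before* the ligand-proximity filter (detector
parameterization first, site filtering second). An empty result is volume
0, not an error.

## Superposition and ligand placement

Pairwise superposition is the standard SVD (Kabsch) solution with
reflection correction; collinear or coincident point sets are rejected.
The reference ligand is transferred into each frame by superposing the
holo structure onto the frame using backbone heavy atoms (N, CA, C, O) of
mapped binding-site residues — residues with a heavy atom within 5 Å of
the ligand — then applying that rigid transform to the ligand. Backbone
atoms were chosen because side chains at a cryptic site rearrange; the
atom set is configurable. Residue correspondences are always materialized
as a two-column mapping file for reproducibility across isoforms.

Ensemble alignment (used to define the docking box) iterates
{align every frame to the current mean over the selected atoms; recompute
the mean} until the mean moves less than 1e-6 Å (RMS, max 100 iterations).
The reference mean is kept centred on the selection centroid, making the
aligned coordinate system canonical in translation: the docking-box
center, defined as the selection centroid of the converged mean structure,
sits at the origin regardless of where the input ensemble was. A second
alignment pass is then a no-op.

## Markov state model of the pocket

Features are the sin/cos pairs of backbone (φ, ψ) and side-chain (χ1–χ4)
dihedrals of the binding-site residues — the encoding removes the 2π
discontinuity. tICA solves the generalized eigenproblem on symmetrized
instantaneous/time-lagged covariances (ridge 1e-8 absorbs rank deficiency,
e.g. duplicated features) at a default lag of 10 ns. Components are
commute-mapped — scaled by √(t_i/2) with t_i = −lag/ln|λ_i| — and the
retained dimension is the smallest one reaching 90 % of kinetic variance,
where component i's share is proportional to t_i (equivalently to its
squared commute scale; the cut is computed jointly with the mapping).

Microstates come from k-means (10 restarts, fixed seed) in the
commute-mapped space; held-out frames are assigned to the nearest centroid
by Euclidean distance with ties to the lowest index. The microstate count
is selected by trajectory-level cross-validation: trajectories are split
50/50 (5 repeats, seeded), clustering is fit on the training half, the
test half is assigned and scored with the rank-10 VAMP-2 score of the test
transition statistics (sum of the 10 largest squared singular values of
C₀₀^(−1/2) C₀₁ C₁₁^(−1/2)). The split proportions and repeat count are
package defaults; the selection criterion is the mean test score.

Transition counts use a sliding window at the chosen lag (typically 5–8 ns
for the systems this was designed around, converted from ns via the frame
interval). Estimation restricts to the largest strongly connected set of
the count graph and maximizes the reversible likelihood with the standard
fixed-point iteration on the symmetric flux matrix
(x_ij ← (c_ij + c_ji)/(c_i/x_i + c_j/x_j)), converging when the stationary
distribution moves less than 1e-10 (max 10⁶ sweeps). Detailed balance and
row-stochasticity hold to tight tolerances by construction. A legacy
variant (`pseudocount_rownorm`) adds 1/k to every count and
row-normalizes, with π from the leading left eigenvector; it exists to
reproduce analyses of an older dataset and does not enforce reversibility.
Model adequacy is checked by lag-independence of the implied timescales
t_i = −τ/ln|λ_i|.

Every frame then carries the equilibrium weight π_s/N_s of its state;
weights over active-set frames sum to 1 and frames outside the active set
get 0.

## Opening probability and uncertainty

p_open is the total equilibrium weight of frames whose ligand-site volume
reaches or exceeds the holo volume (inclusive comparison). Volume
distributions P(v) support two weightings: per-frame (π_s/N_s, the default)
and per-state-representative (one volume per state weighted by π_s, for
datasets where only state representatives have volumes). Rolling averages
of volume traces use a centred window with shrinking edges; centred was
chosen over trailing because the traces are used descriptively, not
causally.

Uncertainty comes from a trajectory-level bootstrap (default 250 trials):
whole trajectories are redrawn with replacement, the transition matrix is
re-fit on the resample, and the observable recomputed. Clustering is kept
fixed across trials — re-clustering every trial conflates discretization
variance with statistical variance and is available behind a flag in
spirit by re-running the pipeline; trials whose resample is disconnected
are skipped and counted, with failure above 50 %. The reported "SEM" is
the standard deviation of the bootstrap distribution, matching the
error-bar convention of the analyses this package mirrors.

## Ensemble docking aggregation

Per active state s, N_s = max(3, round(π_s · 2000)) structures are drawn
uniformly without replacement (capped with a warning at the state's frame
count). The sampling rule reads an ambiguous prose description as
"3 structures, or π_i·2000 if that exceeds 3", with round() as the
rounding convention. Docking scores are ingested from CSV tables; multiple
poses of a frame collapse to the best (lowest) score.

The aggregate free energy is
ΔG_total = −RT ln Σ_f (π_s(f)/N_s(f)) e^(−g_f/RT), evaluated with
log-sum-exp. With one structure per state this reduces algebraically to
−RT ln Σ_s π_s K_eq,s. Active states with no docked structure contribute
zero rather than renormalizing π — docking covered only the sampled
structures, but the equilibrium weights remain those of the full MSM. The
estimate obeys soft-min bounds (min_f g_f ≤ ΔG_total ≤ g_f + RT ln(1/w_f))
and is monotone in every score. R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹
throughout; the default temperature is 310 K, the simulation temperature
of the target systems, which is also the temperature at which a
−8.8 kcal/mol prediction and a 0.67 μM dissociation constant are mutually
consistent (at 298 K they are not).

## Experimental conversion and comparison

IC50 → K_i uses the mixed-inhibition relation
IC50 = (S + Km)/(Km/(α·K_i) + S/K_i): a tight site on the
substrate-engaged branch and a weak site scaled by α. For the
characterized skeletal-myosin case (S = 43 μM, Km = 24 μM, α = 10) the
ratio IC50/K_i ≈ 1.48, justifying the `paper_assumption` mode K_i = IC50
used when pooling literature values; the algebraic form is one standard
reading of an argument that is not written out in full in the source
analyses, and is flagged as an interpretation. ΔG_exp = RT ln(K_i in
molar) at the same temperature as the predictions. Prediction–experiment
agreement reports R² as the squared Pearson correlation (headline) and
additionally the coefficient of determination about the identity line,
which penalizes systematic offsets.

## Synthetic generators: what they emulate

`make_cavity_structure` tiles carbon pseudo-atoms on a sphere (Fibonacci
lattice, seeded jitter), with an optional polar aperture (`lid_fraction`,
1 = hemisphere removed) and an optional interior cluster emulating a
gating side chain. The analytic interior estimate is the sphere of radius
R − (r_C + probe); it ignores the aperture and treats the blocker
exclusion crudely, so it is a convergence anchor, not an exact oracle —
exact checks use a brute-force per-point count under the same exclusion
rule.

`simulate_reference_ensemble` draws hidden chains from a known reversible
transition matrix (defaults: 3 states with π = (0.5, 0.3, 0.2), strong
metastability) and emits, conditionally independently given the state:
von Mises dihedral-like angles (κ = 8, well-separated means — mirroring
the premise that pocket dihedrals encode open/closed states), 0-truncated
normal pocket volumes (40/80/150 ų, widths 12/15/20 ų against a 120 ų
holo threshold), and normal docking scores (−3/−5.5/−8 kcal/mol, σ =
0.5). Defaults are 20 trajectories × 10 000 frames at a 20 ps save
interval — 200 000 frames, a deliberately small-scale stand-in for the
~90 μs per-system datasets the method targets. Ground truths (π, p_open at
any threshold via the truncated-normal tail, ΔG via the lognormal mean of
e^(−g/RT)) are deterministic functions of the specification.

What the generator does *not* emulate: atomistic geometry behind the
features (no force field, no real dihedral coupling), non-Markovian memory
from projected dynamics, state-dependent docking-pose failure, or
correlation between volume and score beyond their common hidden state.
Passing the recovery tests therefore demonstrates the statistical
machinery (discretization, reversible estimation, reweighting,
aggregation) is correct and unbiased at realistic sample sizes — not that
any particular force field or scoring function is accurate.

## Problem sizes and determinism

Test and acceptance runs use the 200 000-frame default ensemble, a 10⁵-step
two-state chain, and cages of radius 5–10 Å on 1 Å grids; these sizes were
chosen so every property is resolved an order of magnitude below its
tolerance while the whole suite runs in seconds. All stochastic steps
(k-means, sampling, bootstrap, emission draws) take explicit seeds;
pipeline runs are pure functions of (inputs, config, seed) and reruns
reproduce byte-identical artifacts, which the manifest checksums verify.

## Known limitations

* Pocket detection is the PSP-rank grid method only; alpha-sphere or
  surface-based detectors can disagree on absolute volumes.
* The reversible MLE assumes the largest strongly connected set is the
  relevant ergodic component; sparsely connected datasets can silently
  drop states (they are logged and excluded from weights).
* The aggregation treats docking scores as per-conformation binding free
  energies; systematic scoring-function bias propagates directly into
  ΔG_total.
* IC50 conversion assumes the mixed-inhibition mechanism transfers across
  isoforms with the same α.
* mmCIF input, bond perception and protonation are out of scope; PDB,
  XTC and DCD are the supported formats.
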