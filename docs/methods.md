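# Methods

This note documents the models, algorithms, defaults and numerical choices
behind each stage of the pipeline, and what the synthetic test systems do
and do not establish about real molecular systems.

Units throughout: energies kcal/mol, distances Å, temperatures K, masses
amu, times ps; kB = 0.0019872041 kcal/(mol·K).

## Toy systems

Four analytic potentials stand in for an all-atom force field
(`mcdock.systems`):

* **harmonic** — n particles in 0.5·k·|r|²; canonically exactly solvable
  (⟨E⟩ = f/2·kB·T for f degrees of freedom), the reference for reweighting
  checks.
* **double_well** — 1D quartic h·(x²/w² − 1)² + t·x.  Defaults h = 3
  kcal/mol, w = 2 Å.  The tilt t (0.4 kcal/mol/Å where free-energy recovery
  is tested) makes the well populations unequal so quadrature comparisons
  are non-trivial; t = 0 keeps the closed-form barrier (height h at x = 0).
* **mueller_like_2d** — the Müller–Brown surface scaled by 0.05 so its
  basins and saddles land in the low-kcal/mol range.
* **gated_pocket** — a 3D cryptic-site model with 28 beads: a single-bead
  ligand; a receptor shell (8-bead front ring of radius 3.5 Å, 9-bead back
  cap, 8-bead entrance collar, all harmonically tethered with k = 20
  kcal/mol/Å²); and two gate beads at the entrance whose separation follows
  a double well with minima at 3 Å (closed) and 8 Å (open), a 2.5 kcal/mol
  barrier and a 0.3 kcal/mol/Å tilt favouring closed.  The ligand feels
  Gaussian attraction wells — one buried pocket site (8 kcal/mol deep) and
  two surface decoys (3.5 and 3.0 kcal/mol) — soft Gaussian repulsion
  (50·exp(−d²/2σ²), σ = 1 Å) from every bead, and a flat-bottom spherical
  confinement (radius 12 Å).  The geometry is built so the gap between the
  gate beads is the only opening wider than the inter-bead spacing: pocket
  entry *requires* a gate-opening fluctuation (conformational selection),
  and the escape barrier from the pocket greatly exceeds that from the
  surface decoys, which fixes the designed stability ordering that the
  validation stage must recover.

Pairwise harmonic distance restraints 0.5·k·(d − d₀)² are supported on any
system (the toy counterpart of hydrogen-bond restraints that keep a
receptor folded at high effective temperatures) and are excluded on request
in validation runs.

## Sampling

The default sampler is single-particle-move Metropolis Monte Carlo
(Gaussian proposals, default width 0.5 Å; 0.35 Å for the gated pocket,
keeping acceptance near 0.5).  Metropolis is exactly analyzable — detailed
balance against the target density is asserted in the tests via the
Kolmogorov–Smirnov distance to the analytic position marginal.  A BAOAB
Langevin integrator (central-difference forces, default dt = 0.01 ps,
friction 1 ps⁻¹) is provided for the gated-pocket model; under the bias the
force is scaled by 1 + b′(E), the gradient of the effective potential
E + b(E).  Runs abort with an integration error if E exceeds 10⁶ kcal/mol.

Reproducibility: all randomness derives from a root seed; trajectory i uses
seed + i, bias-learning iteration j uses seed + 100003·(j+1), validation
replica j at the i-th temperature uses seed + 7919·i + j (all masked below
2³¹).  Identical seeds give bit-identical trajectories.

## Bias learning

`learn_bias` implements the standard iterative flat-histogram scheme:

1. Short canonical probe runs at 280 K and 750 K bracket the energy-knot
   grid (201 knots, piecewise linear).  The grid's top is the 750 K mean
   plus 3σ — energies above the last knot are handled by the canonical
   tail, so the flattened range only needs to clear the T_high mean.
2. The bias is initialised as the linear ramp b(E) = (T_ref/T_high − 1)·E
   (+ const), which makes sampling at T_ref equivalent to canonical
   sampling at T_high.
3. Each iteration runs a prerun leg with the current bias, histograms the
   visited energies on the knot grid and updates
   b(E) ← b(E) + kB·T_ref·ln ĥ(E), with ĥ normalised to its maximum,
   Gaussian-smoothed over 1 bin, and unvisited bins inheriting their
   nearest visited value.  Given a converged histogram this update is
   exact in one step (b → kB·T_ref·ln n(E) − E + const); iteration handles
   the finite-sample and coverage error.  Every leg restarts from the
   reference configuration: otherwise the walker lingers at high energy
   (overwhelming configurational entropy) and the bias below the visited
   range keeps its initial ramp, trapping production runs started from a
   bound pose.
4. Consecutive iterations whose energy histograms share no occupied bin
   raise a convergence error with diagnostics.

Outside the knot range the bias continues linearly with the canonical-tail
slopes T_ref/T_low − 1 (below) and T_ref/T_high − 1 (above), so sampling
decays like a canonical distribution at the range edges.  The flatness
diagnostic reweights the production ensemble to T_low and T_high to locate
the canonical mean energies, then reports the min/max occupied-bin ratio of
the raw energy histogram between them (default 20 bins); the learning
defaults achieve ratios of 0.7–0.9 on the 1D toys (target ≥ 0.5).

Default schedule: 30 trajectories × (8 prerun iterations × 2×10⁵ steps,
10⁶ production steps), stride 100 — a 30-walker prerun/production protocol
scaled to desk size.  Tests and the acceptance script use 2–10 trajectories.

## Reweighting

`canonical_weights` applies the single-ensemble multicanonical identity
w_i ∝ exp(−E_i/kB·T + [E_i + b(E_i)]/kB·T_ref), computed in log space and
normalised with log-sum-exp.  The Kish effective sample size 1/Σw²
accompanies every reweighting; dropping below 1% of the ensemble size —
the signature of reweighting far outside the flattened range — emits a
warning, and non-finite log-weights raise a degenerate-ensemble error.
Statistical errors of reweighted means are estimated from independent
trajectories (or contiguous blocks when only one trajectory exists), since
Markov-chain samples are autocorrelated.

## FEL and clustering

Snapshots are rigid-body superposed onto a reference via the SVD (Kabsch)
construction — fits on fewer than 3 non-collinear points are rejected —
then projected onto the first two principal components of the ligand
coordinates (weighted PCA: weighted mean and covariance, `eigh`,
deterministic sign convention; the unweighted variant serves the raw
multicanonical ensemble).  The FEL is the weighted 2D histogram mapped
through F = −kB·T·ln(ρ/ρ_max) on a 100×100 grid padded 5% (empty cells are
+∞).

Basins are found by steepest descent over occupied cells (8-neighbourhood;
the descent key is (F, flat index), strictly decreasing, hence
terminating).  Because a histogrammed density is shot-noise-limited near
its peaks, the descent runs on a copy whose density is Gaussian-smoothed by
1 cell — without this, one physical basin fragments into several spurious
ones at realistic sample sizes.  Populations and CFEs are always computed
from the raw snapshot weights, so the smoothing affects only the basin
assignment; `build_fel` itself is exact.  Clusters are ranked by
CFE = −kB·T·ln(p/p_max) and reported up to a cutoff (1 kcal/mol by
convention); the representative of a cluster is the highest-weight snapshot
in the basin's minimum-F cell, ties to the lowest snapshot index.

## Structural metrics

* **Contacts** — (receptor residue, ligand atom) pairs with minimum
  heavy-atom distance ≤ 4.5 Å, boundary inclusive; for bead models each
  bead is its own residue.
* **R-value** — the hard-count fraction |observed ∩ reference|/|reference|
  of a reference contact set conserved in a configuration (Q-value family;
  no soft switching).  Trace statistics pool the final-window frames of all
  replicas and report the mean and *population* SD.
* **Ligand RMSD** — fit on the receptor selection only (applied to all
  particles), RMSD over the ligand selection without refitting.
* **SASA** — Shrake–Rupley with a deterministic golden-angle lattice
  (default 960 points/atom, probe 1.4 Å, generic bead radius 1.7 Å; fewer
  than 32 points is rejected).  Translation invariance is exact; rotation
  invariance holds to lattice resolution (~1/n_points relative), which is
  intrinsic to any fixed-lattice Shrake–Rupley.
* **RASA** — ligand SASA in complex over ligand SASA isolated at the same
  conformation, clamped to [0, 1.02]; low values flag buried poses, and on
  the gated-pocket model RASA cleanly separates the pocket pose from
  surface poses (ordering is asserted, not values).

## Ensemble observables

RMSF is the per-particle root of the weighted positional variance; DCC is
the weighted displacement correlation C_ij = ⟨Δr_i·Δr_j⟩ /
(⟨Δr_i²⟩⟨Δr_j²⟩)^½ with unit diagonal and NaN rows for zero-variance
particles.  Per-cluster subensembles renormalise the weights within the
cluster.  Ligand density grids bin ligand-atom positions with snapshot
weights (1 Å voxels) and carry nested high/medium/low level sets at
0.5/0.1/0.01 of the maximum voxel density.  Ion-contact counts use an
inclusive minimum-distance cutoff (5 Å by convention).

## Validation and refinement

Each representative pose r_k seeds n replicas (default 10) of
restraint-free canonical MC at each temperature in (300, 400) K, default
5×10⁴ steps each.  The reference contact set is taken from r_k itself; the
per-frame R-value over the final 40% of each replica, pooled across
replicas, gives the stability statistics.  The refined pose q_k is the
room-temperature final-window frame with maximal R-value (ties to the
lowest replica, then frame — with frozen dynamics q_k = r_k).  Poses are
ranked by mean R at the highest temperature, then at room temperature;
per-replica integration failures are recorded and tolerated as long as one
replica per temperature survives.

## Path extraction

The dissociation direction is estimated from the bound pose: the base ray
runs from the receptor centroid through the ligand centroid, and a
deterministic full-sphere fan (13 polar × 36 azimuthal rays) is scored by
the Gaussian steric overlap (σ = 1.5 Å) with receptor atoms accumulated
along the ray out to 15 Å; the minimal-overlap ray wins, with ties resolved
toward the base ray.  The fan covers the full sphere because a buried
ligand sits near the receptor centroid and the base ray can point into the
back wall.  λ is the projection of each snapshot's ligand-centroid
displacement (in the superposed frame) onto this unit ray; the bound pose
is λ = 0.

Milestones are chained outward from the bound snapshot: within each λ
window the snapshot minimising all-particle RMSD to the previous milestone
is chosen (exact ties → higher weight, then lower index; a ligand-only RMSD
variant is available via `rmsd_selection`).  Default windows are centred at
14/9/4.5/0 Å with ±1.5 Å half-width; quantile-based windows
(`auto_lambda_windows`) guarantee non-empty windows on arbitrary ensembles,
ignoring snapshots more than 0.5 Å behind the origin.  Empty windows raise
a gap error naming the window.  The gateway metric — the distance between
the two gate particles — reported along the path exposes the
open-then-close mechanism: on the planted trace it rises from the apo
separation to the full opening mid-path and is tightest at λ = 0.

## Synthetic ground truth

* **Planted clusters** — Gaussian binding-configuration clusters with
  chosen populations on the gated-pocket scaffold (defaults 0.5/0.3/0.2 at
  σ = 0.8 Å: two surface poses and one buried pose, the qualitative layout
  of a docking landscape).  Gate state couples to binding: pocket-bound
  snapshots have a closed, low-noise gate, so bound subensembles show
  reduced gate RMSF by construction.  Expected CFEs are
  −kB·T·ln(p/p_max) exactly.
* **Bias-consistent energies** — inverse-CDF samples from
  n(E)·exp(−[E + b(E)]/kB·T_ref) for a power-law density of states
  n(E) ∝ E^α; with the closed-form flattening bias the sample is uniform,
  with b ≡ 0 it is Gamma(α+1) with mean (α+1)·kB·T.
* **Binding trace** — a dumbbell ligand walks λ from 14 Å to 0 in 0.5 Å
  steps with 0.08 Å lateral jitter, completing a 90° reorientation before
  λ = 2; the gate separation follows holo 2.8 Å → apo 3.2 Å with a Gaussian
  opening to 8 Å peaking at λ = 4.5.  Decoys are placed at ≥ 80° polar
  angle and verified exhaustively to lie at least 2× the maximum
  inter-frame RMSD from every trace frame (a spec error if unattainable),
  so milestone recovery is decidable.

Every generator is a pure function of (spec, seed).

**What passing these tests does not show:** the toys have smooth
low-dimensional energy surfaces, isotropic noise, no solvent, no ions, no
force-field error and no conformational entropy beyond a handful of beads.
They establish the *statistical machinery* — bias convergence, reweighting
identities, basin/CFE arithmetic, metric definitions, selection and
tie-break rules, path chaining — not the physics of any real
receptor–ligand system, whose headline numbers depend on all-atom
ensembles this package deliberately does not attempt.

## Problem sizes

Unit tests sample 10⁴–10⁵ steps per check; the shared fixtures and the
acceptance script use the full study conditions of the toy protocol
(8 × 2×10⁵ prerun, 10⁶ production steps per trajectory; 6–10 trajectories;
10 validation replicas × 5×10⁴ steps; 10⁵-snapshot planted ensembles),
chosen so every statistical assertion has a ≥3σ margin under the stated
tolerances.

## Known limitations

* The bias update uses full-strength ln ĥ with restart-based legs; a
  production-grade implementation would anneal the update magnitude
  (Wang–Landau-style) and monitor saturation of the visited range.
* Piecewise-linear bias in the samplers; the cubic interpolation option
  exists for evaluation and files but learning always emits linear knots.
* The watershed runs on the 2D FEL only; clustering in higher-dimensional
  PC spaces is out of scope.
* Rotation invariance of the lattice SASA is bounded by lattice
  resolution, not machine precision.
* The gated-pocket multicanonical histogram is flat to ~0.3 min/max at the
  default learning schedule (the 1D toys reach ≥ 0.5); longer preruns
  improve it, and reweighted averages are unbiased regardless since the
  weights use the same bias that generated the ensemble.
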