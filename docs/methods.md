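# Methods

This note documents the models, estimators and numerical choices behind
`allosnet`, what the synthetic generator does and does not emulate, and
the limitations a user should keep in mind when moving from synthetic
validation to real trajectories.

## Network model

**Topology.** The network has one node per residue, anchored at its Cα
atom (or the designated bead of a coarse system). An edge joins two
residues when their heavy atoms come within a cutoff of each other in at
least a minimum fraction of the frames of the window under analysis.
Defaults: cutoff 6.0 Å, persistence 0.75. The 6 Å value is deliberately
wider than the 4.5 Å common in dynamical-network studies of protein
cores: at interfaces, contacts are sparser and more fluctuating, and the
wider cutoff retains them. A distance exactly at the cutoff counts as a
contact. Contact persistence is evaluated **per window**, not over the
concatenated trajectory, so window-to-window variation in the edge set
is part of the signal (it feeds the persistence statistics below).
Sequence-adjacent residues are retained as edges by default
(`include_adjacent=True`): allosteric paths must be able to run through
covalent linkers, and removing i→i+1 edges would cut every inter-lobe
route that uses them. The flag exists because the opposite convention is
also common.

**Edge weights.** The coupling of an edge is the generalized correlation

  r_MI = (1 − exp(−2·I/d))^(1/2),  d = 3,

where I is the mutual information (nats) between the two nodes'
3-dimensional fluctuation vectors (coordinates minus their window mean,
after rigid-body alignment of all frames to a reference). For per-axis
Gaussian displacements with correlation ρ and three independent axes,
I = −(3/2)·ln(1−ρ²) and r_MI = |ρ| exactly; r_MI is monotone in I and
bounded in [0, 1].

**MI estimator.** Kraskov–Stögbauer–Grassberger algorithm 1 with k = 7
neighbours (configurable), Chebyshev metric, strict-inequality marginal
counts. Estimates can be slightly negative for near-independent data;
they are reported as-is by the estimator and clamped to zero before the
r_MI transform. Known behaviour to be aware of: in the 6-D joint space
the estimator carries a negative finite-sample bias that grows with
dependence strength — at per-axis ρ = 0.8 and n = 5000 it is roughly
0.1 nats for any k. The r_MI transform compresses this strongly (the
recovered coefficient stays within 0.02 of ρ across the whole range
tested, ρ ∈ {0.3, 0.6, 0.9}), which is why the pipeline's thresholds are
set on the r_MI scale. Fewer than 4k frames in a window is treated as an
error rather than returning an unstable estimate.

**Aggregation across windows.** Because an interaction may fail the
contact criterion in some windows, averaging r_MI over *all* windows
(absent → 0) under-represents the coupling present when the contact is
formed. Both statistics are therefore reported: the all-window mean and
the mean over windows with the edge present and r_MI > 0, each with a
standard error (sample SD across windows / √count; undefined below two
windows). An edge is **persistent** when r_MI > 0.3 in at least 15 of 20
windows; the criterion is evaluated window-by-window (not on the window
mean), matching the joint "present in ≥15/20 windows and > 0.3" reading,
with the alternative exposed in config. r_MI is computed only for
contact-graph edges, not all residue pairs — paths only need edge
weights — with an all-pairs mode available for completeness.

## Optimal paths

Edge length is −ln r_MI, the standard dynamical-network convention:
perfectly correlated contacts have zero length, weak ones are long, and
r_MI = 0 edges are **absent** (not infinite). Each window's graph is
weighted by that same window's correlations. All-pairs distances come
from Floyd–Warshall; the path for each (source, target) pair is
reconstructed greedily from the distance matrix, always stepping to the
smallest-index neighbour that preserves optimality (tolerance 1e−9
relative), which yields the lexicographically smallest optimal node
sequence — a deterministic, platform-independent tie-break. Sources are
the receptor-side endpoints of persistent binder-interface edges; targets
are a configured residue set.

Paths from all windows and pairs are pooled; uniqueness is judged on node
sequences. The noise filter keeps a path if it recurs in more than one
window, or if its maximum Jaccard similarity (intersection-over-union of
**edge sets** — "common edges") to another path of the unfiltered
ensemble reaches a threshold. When no threshold is supplied it is derived
as t* = min over paths of (max similarity to another path): the largest
value at which every path still has a neighbour. Note that at exactly
t = t* the similarity clause passes every path by construction; the
filter bites when a stricter explicit threshold (e.g. 0.6) is applied.
Routes are classified by the named regions their nodes traverse; a path
whose interior touches a designated partner region is "via-partner",
otherwise "direct".

## Binding-mode clustering

Features are 2-D per frame: Cα RMSD of the binder's heavy-chain CDR
residues (dimension 1) and light-chain CDR residues (dimension 2), each
measured after superposing the frame on a receptor reference region
(alignment on the receptor, measurement on the binder — so the features
express binder pose relative to the receptor). Clustering is flat-kernel
mean shift, all points as seeds, bandwidth 2.5 Å in feature space
(scikit-learn's implementation; modes closer than the bandwidth merge,
every point is assigned to its nearest surviving mode). Mean shift is
chosen because the number of binding modes is not known in advance. The
reference defaults to the first frame of the first replica and is
configurable.

## Surface area

Shrake–Rupley with a probe of 1.7 Å (the van der Waals radius of water)
and a deterministic golden-section spiral of 960 test points per atom —
seedless and identical across platforms, converged to < 0.5 % under
point doubling on the toy systems. A test point is buried only if
*strictly* inside a neighbour's probe-inflated sphere, so tangent spheres
do not occlude (and coincident equal spheres symmetrically do not
occlude each other — a deterministic, documented edge case). vdW radii
are a Bondi-type table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å),
per-atom overridable. Contact area between groups A and B is
(S_A + S_B − S_complex)/2 with each term computed on the isolated group;
it is reported in nm² and clamped to zero for discretisation-level
negatives (> −0.01 nm²; anything larger raises). Translation invariance
is exact; rotation invariance holds to the discretisation level (~1 %
per atom at 960 points, tighter in total).

## Superposition and windows

Rigid-body alignment is closed-form Kabsch: SVD of the covariance with a
reflection correction guaranteeing a proper rotation. Fewer than three
points, or collinear points, are a degenerate-geometry error. Alignment
uses Cα atoms by default ("backbone" N/CA/C/O selectable). Replicas are
split into contiguous, equal, non-overlapping windows; frame counts that
do not divide evenly lose trailing frames with a logged warning — never
padded. Coordinates are ångström throughout; nm inputs are converted on
read.

## Synthetic generator

The generator emulates the study design the pipeline is built for —
multiple short replicas of a receptor/partner/binder complex — at desk
scale: a 24-bead receptor chain (upper lobe, 4-bead linker, lower lobe),
a 12-bead partner chain bridging both lobes, and an optional 8-bead
binder chain docked against the upper lobe. Default conditions: 10
replicas × 600 frames split into 2 windows each (20 windows of 300
frames), per-axis noise σ = 0.4 Å.

Displacements are i.i.d. per frame from N(0, σ²·C) per Cartesian axis
(axes independent), with C a planted per-axis correlation matrix. This
is a deliberate modelling choice: the statistics under test (contact
frequency, MI, r_MI) are distributional, and i.i.d. sampling makes the
Gaussian closed forms *exact* ground truth. No Langevin integrator, no
force field, no solvent — and therefore no autocorrelation: real MD
frames are time-correlated, which reduces the effective sample size of a
window. Passing tests on synthetic data validate the estimators and the
pipeline logic, not the sufficiency of any particular amount of real
sampling.

Couplings are kept strictly diagonally dominant (every bead's
off-diagonal |ρ| sum ≤ 0.95, softening backbone bonds next to strongly
coupled beads), which guarantees positive-definiteness by construction;
the matrix is verified at build time and a non-PD matrix is rejected
with its offending eigenvalue. Two binder modes reproduce the
qualitative contrast of interest:

- `localized_strong`: three staggered binder↔upper-lobe couplings at
  ρ = 0.65, plus a correlated bridge upper-lobe → partner → lower-lobe
  (ρ = 0.65) and moderate backbone coupling through the linker — a
  tight binder that activates both the direct and the inter-subunit
  route.
- `diffuse_weak`: sixteen binder↔upper-lobe couplings at ρ ≤ 0.25 and
  linker bonds cut to ρ = 0.05 — many weak touches, no lobe-to-lobe
  communication.

Geometry is arranged so contact topology is decided by the equilibrium
layout, not by noise: bonded/aligned pairs expose heavy atoms well
inside the 6 Å cutoff (two of each bead's three satellite atoms point
along the chain axis), while diagonal cross-chain pairs stay ≈ 0.9 Å
outside it even with satellites extended, against ≈ 0.57 Å/axis relative
noise. Beads carry three heavy satellite atoms rigidly attached (≤ 1 Å),
so contact detection, SASA and I/O are exercised with realistic
multi-atom residues.

## Numerical choices and degenerate inputs

- Negative MI estimates clamp to 0 before the r_MI transform.
- Shortest-path ties break to the lexicographically smallest sequence.
- Windows with too few frames for the estimator (< 4k) raise.
- A single-path ensemble has no derived Jaccard threshold; the filter
  degenerates to the window-count rule.
- All generators, the pipeline, and every output file are deterministic
  given spec + seed; output JSON/TSV contain no timestamps, and a
  manifest records parameters and input checksums so a run is
  reproducible bit-for-bit.

## Problem sizes used in validation

Module and acceptance tests run at sizes where brute-force oracles are
exact and fast: superposition against a numerical optimiser on 10-atom
clouds; contact graphs against the all-pairs oracle at 50 residues × 20
frames × 20 seeds; shortest paths against exhaustive simple-path
enumeration on ≤ 7-node graphs × 100 seeds; the Jaccard threshold
against a full scan; SASA against closed forms (isolated sphere,
spherical caps, buried shell); estimator recovery at 5000 frames; the
strong-vs-weak binder contrast at the full default condition (20 windows
× 300 frames) across 3 generator seeds. These sizes are the package's
validation design; the pipeline itself has no intrinsic size limit
beyond memory and the O(n³) Floyd–Warshall on the set of connected
nodes.

## Known limitations

- i.i.d. synthetic frames cannot expose failure modes caused by slow
  conformational drift within a window (e.g. a contact forming halfway
  through and diluting the 75 % criterion) — the aggregation statistics
  handle the cross-window version of this, but not the within-window
  version.
- KSG bias on the nats scale at strong dependence (above); thresholds
  should be set on the r_MI scale.
- The mean-shift feature space is fixed at 2-D (heavy/light CDR RMSD);
  no bandwidth auto-estimation.
- No periodic-boundary handling: input trajectories must already be
  whole molecules.
- Trajectory formats: PDB (multi-model) and XYZ natively; DCD through
  MDAnalysis when that package is present.
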