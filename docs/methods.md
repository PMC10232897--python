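# Methods

This note records the models implemented in allokit, the defaults and the
reasoning behind them, what the synthetic generators do and do not emulate,
and the numerical choices that affect results.

## Contact time series

A residue pair is "in contact" in a frame when any interatomic distance is
below the cutoff (default 3.5 Å).  Hydrogens are excluded by default
(`heavy_only=True`): heavy-atom contacts are stabler under thermal noise
and cheaper; the flag restores all-atom behavior.  Sequence-adjacent pairs
are retained — invariance trimming removes the permanently bonded ones
anyway.  Distances are computed by exact pairwise evaluation at all system
sizes; a single code path keeps results trivially reproducible.

Trimming removes columns that never change over the *entire* series;
contacts present in nearly every frame but flickering occasionally survive
and typically become the constitutive pairs used for normalization.

Smoothing is a centered sliding mean (default window 25 frames) truncated
at segment boundaries, so replica joins never mix: the window shrinks near
edges rather than padding or reflecting.  Per-column long-run means are
preserved to within 1/window.

## Rare-event detection

The smoothed, trimmed series *I* (t × n_pairs) is factorized by NMF
(scikit-learn coordinate descent, Frobenius loss) into temporal weights
*W* (t × c) and spatial components *H* (c × n_pairs).  Defaults: c = 5
components, deterministic non-negative double-SVD initialization
(`nndsvda`); `init="random"` plus a seed gives randomized restarts.
Non-convergence within `max_iter` is a warning carrying the final residual,
not a failure.

**Constitutive pairs.**  The split of scale between *W* and *H* is
arbitrary per component, so spatial rows are rescaled to unit mean before
applying the selection heuristic: a pair is constitutive when the
coefficient of variation of its rescaled values across components is below
`cv_max = 0.15` and its rescaled mean exceeds `mean_min = 0.5` relative to
the largest pair mean.  These two thresholds are exposed in config; the
qualitative target is the "horizontal line" of pairs contributing equally
to every component.

**Normalization.**  Component k's spatial row is divided by the mean value
of the constitutive pairs in that row and its temporal column multiplied by
the same factor — the reconstruction *W·H* is unchanged to float precision,
but components become directly comparable and constitutive contacts sit at
1.  Normalized SDCP values may legitimately exceed 1.

**SDCPs.**  For a transition between components A and B,
δ = H_B − H_A; pairs with |δ| > kσ·std(δ) (default k = 4, plain standard
deviation over all pairs) are reported, positive δ as *formed*, negative as
*broken*.  Motif group labels are user-supplied annotations.

**Component matching** across independent fits uses greedy cosine
similarity of spatial rows; dominance transitions are argmax changes of the
temporal weights, with replica joins excluded.

## Collective variables and binding modes

The cavity coordinate orients the complex from its own geometry: the gate
helix's long axis (first principal axis of its per-residue anchor points,
oriented N→C to fix the sign) becomes x; the component of the protein-COM
offset from the helix COM perpendicular to x becomes +z; the origin is the
COM of the serine-pair selection; the coordinate is the probe displacement
projected on (x̂+ẑ)/√2.  Because every axis is built from the coordinates,
the value is rigid-body invariant.  The orienting "protein" excludes the
probe's own residue by default.  Degenerate inputs (helix anchors
coincident, protein COM on the helix axis) raise errors.

Binding-mode classification is purely distance-based: SER when the
probe-to-serine-site distance is below `d_site` (default 6.0 Å, wide enough
to absorb water-bridged variants of each mode, which are collapsed into
their parent mode) and not larger than the tryptophan-site distance; TRP
symmetrically; OTHER else.  Explicit hydrogen-bond or water-bridge geometry
is out of scope.

Contact probability is the percentage of frames with any interatomic
distance below the cutoff, consistent by construction with the contacts
module's column means.

## tICA

C(0) and C(τ) are pooled over segments after subtracting the pooled mean;
lagged pairs never span segment boundaries.  C(τ) is symmetrized
((C+Cᵀ)/2) for a real spectrum.  C(0) receives a diagonal ridge
proportional to each CV's own variance (ε = 1e-10): a uniform identity
ridge would break the invariance of the generalized eigenproblem under
per-CV rescaling, which this package treats as a contract (CVs mix Å and
dimensionless quantities).  Eigenvector signs are fixed by making the
largest-magnitude loading positive.

"Kinetic content" of the first k modes is Σ_{i≤k} max(λ_i,0) / Σ_i
max(λ_i,0) — a positive-eigenvalue fraction.  Other normalizations exist in
the literature; this one is documented here and used consistently.

## Markov state models

Microstates: k-means (k-means++ seeding, fixed seed) in the projected
space, default k = 200.  Transition counts use a sliding window at lag τ′
within segments (sliding maximizes data use and is the field default).
Symmetrization C ← (C+Cᵀ)/2 enforces detailed balance exactly; states
outside the largest strongly connected component are dropped with a
warning; T is the row-normalized count matrix and π ∝ symmetrized row sums.
Eigenproblems for reversible T go through the symmetric similarity
transform D^{1/2}TD^{−1/2}, guaranteeing a real spectrum in [−1, 1].

Implied timescales use t_i = −τ′/ln λ_i (the sign convention that makes
0 < λ < 1 yield positive times); λ ≤ 0 reports NaN with a warning, λ = 1
beyond the Perron mode reports +inf.  GMRQ is
R = Tr[(VᵀSTV)(VᵀSV)⁻¹] with V the first n right eigenvectors of the
training TPM, T the test TPM over the training state definition, and S the
diagonal of the test stationary distribution (the left Perron eigenvector,
normalized to sum 1); with train = test it equals the sum of the top-n
eigenvalues exactly.

PCCA+ uses the inner-simplex construction: the m most linearly independent
rows of the first m right eigenvectors define simplex vertices, memberships
are barycentric coordinates, small negative entries from sampling noise are
clipped and rows renormalized (rows sum to 1 exactly either way since the
Perron eigenvector is constant).  The crisp map is the argmax; requesting
more macrostates than the spectral gap supports triggers a warning.

## Transition path theory

The forward committor solves the harmonic boundary problem directly.  Flux
follows J_ij = π_i(1−q_i)T_ij q_j with the target-visiting probability
identified as the forward committor — the only reading under which the
formula reduces to standard reversible TPT.  The backward factor is
validated by the reversibility identity q_fwd + q_bwd = 1.  Pathways are
extracted from the **net** flux (gross-flux mode behind a flag) by
iterative maximum-bottleneck (widest-path) search with bottleneck
subtraction; ties between equally wide paths break lexicographically for
determinism.  Decomposition stops at 95 % coverage of the total flux by
default.

## NbIT coordination measures

All measures are functions of covariances of displacement ensembles taken
on a superposed trajectory.  Default displacement mode is **scalar** (one
variable per atom: distance to its reference position); **vector** mode
(Δx, Δy, Δz) is available — the measures are covariance-based either way
and results are labelled with the mode.  Entropies are Gaussian,
H = ½(N ln 2πe + ln det C), in **nats**; outputs carry the unit explicitly.

Covariance eigenvalues are floored at 1e-8 × their mean magnitude before
the log-determinant, guarding near-rigid motifs.  A transmitter or channel
whose maximum variance is below 1e-12 of the receiver's variance scale is
treated as static and short-circuited to zero coordination — the
mathematically degenerate limit that the floor cannot represent
consistently across entropy terms.

A receiver given as a single motif is split into per-residue blocks (TC
needs ≥ 2 blocks); a receiver given as a list of ensembles is used as-is.
Motifs may not overlap in atoms (the joint covariance would double-count).
The coordination matrix puts receiver TC on the diagonal and NCI
(receiver = row, transmitter = column) off-diagonal; it is asymmetric
whenever receiver TCs differ.  The transmitter-contribution analysis is
leave-one-residue-out: contribution(r) = CI(R,T) − CI(R,T∖r); residues
carrying redundant copies of the signal legitimately score near zero.

Motif presets for the StarD4–cholesterol complex (binding site, β-sheet and
loop/gate elements) ship as `STARD4_MOTIFS`; the alignment residue set is a
config choice, not hard-coded, because it is numbering-specific.

## Synthetic generators

All generators are bit-reproducible given spec + seed.

- **Planted-event trajectory**: residue core beads on a circle (~20 Å
  spacing, never in contact); each planted pair gets dedicated beads in a
  pair-specific z-plane, placed at cutoff − 0.5 Å (in contact) or
  cutoff + 1.5 Å (out) about the pair midpoint, so distinct pairs cannot
  interfere; an optional ligand bead parks at a state-dependent site.
  Gaussian positional noise (default σ = 0.2 Å) makes in-contact pairs
  flicker occasionally (the 0.5 Å margin is ~1.8σ of the distance noise),
  which is realistic and exercised by the tests; the 1.5 Å out-margin makes
  false contacts negligible.  What this model does **not** emulate:
  physical bond geometry, correlated backbone motion, solvent, or gradual
  transitions — events are instantaneous.  Passing tests show the
  *algorithms* recover planted structure; they do not certify behavior on
  diffusive, slowly-relaxing real events.
- **Contact-matrix fixture**: 200 pairs by default — 8 switching
  (occupancy 0.95/0.05 flipping at the event, alternating formed/broken),
  32 constitutive (0.95 throughout), the rest flickering i.i.d. around
  per-pair means drawn U(0.2, 0.8), so their smoothed profiles are flat and
  state-independent.  This mirrors a real trimmed contact map, where most
  retained pairs fluctuate around a stable mean and only a few track the
  event.
- **Gaussian network**: acyclic latent chain z_k = c_k z_parent + ε_k;
  blocks load one latent each plus i.i.d. noise.  The implied covariance is
  returned exactly, so every information measure has a closed-form target.
  Real displacement ensembles are only approximately Gaussian; the tests
  validate the estimator under its own model assumptions.
- **Markov emissions**: CV vectors drawn around per-state means (noise per
  CV configurable) from a sampled chain; birth–death chains are used where
  a reversible ground-truth TPM is required, because the symmetrized
  estimator converges to the reversibilized matrix.

## Problem sizes and tolerances in the verification battery

The study-scale inputs (hundreds of microseconds of all-atom MD) are not
reproducible here, so verification is property-based at sizes the package
chooses: 1e5 samples for the Gaussian battery (2 % tolerance ≈ several
sampling standard deviations), 1000 frames × 200 pairs × 20 seeds for event
recovery (precision/recall ≥ 0.9), 1e6 steps for Markov-chain recovery
(max TPM error < 0.01), 1e6 random walks for the committor oracle
(agreement < 0.01), 1e6 frames for the tICA limit (timescale within 10 %).
Exact identities (GMRQ with train = test, normalization invariance,
symmetric-chain committors, flux conservation) are asserted at 1e-9–1e-12.

## Known limitations

- NMF is non-convex: different seeds can find different local minima; the
  deterministic double-SVD initialization makes the default path
  reproducible but not globally optimal.
- PCCA+ memberships come from the inner-simplex construction without the
  subsequent feasibility optimization; for strongly metastable systems the
  crisp assignments coincide, but soft memberships near block boundaries
  are approximate.
- The Gaussian entropy model understates the entropy of multimodal
  displacement distributions; NbIT values on strongly bistable motifs
  should be read comparatively, not absolutely.
- The binding-mode classifier is distance-only; it cannot distinguish
  direct from water-bridged hydrogen bonding.
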