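# Methods

`ringtop` quantifies the instantaneous shape and the time-fluctuation of
shape of path-integral ring polymers. This note records the models, the
numerical choices, and what the synthetic fixtures do and do not establish.

## The ring-polymer representation

In the imaginary-time path-integral formalism an atom at inverse temperature
β is represented by P beads (replicas, Trotter slices) r^(1)..r^(P) joined
cyclically by harmonic springs. The spatial spread of this closed polymer
encodes the quantum uncertainty of the atom's position: light atoms and low
temperatures give wide, floppy rings; heavy atoms give tight ones. Ring
polymer and thermostatted ring polymer molecular dynamics propagate these
beads in real time, so the *time series* of bead clouds carries dynamical
information about how the delocalization itself fluctuates.

## Static shape descriptors

For a bead cloud with centroid r̄ the package computes

- gyration radius R_g = sqrt((1/P) Σ_k |r^(k) − r̄|²),
- the 3×3 gyration tensor S = (1/P) Σ_k (r^(k) − r̄)(r^(k) − r̄)ᵀ with
  ascending eigenvalues λx² ≤ λy² ≤ λz² (so R_g² = λx² + λy² + λz²),
- asphericity b = (3/2)λz² − R_g²/2 (zero for spherical symmetry),
- acylindricity c = λy² − λx²,
- relative shape anisotropy κ² = (3/2)(λx⁴+λy⁴+λz⁴)/(λx²+λy²+λz²)² − 1/2,
  which is 0 for spherically symmetric clouds and 1 for collinear ones,
- centroid–bead and pairwise bead–bead distance distributions, and
- the imaginary-time mean-square displacement
  Δr²(iτ) = ⟨(1/(N_A P)) Σ_j Σ_k |r_j^(k) − r_j^(k+l mod P)|²⟩ with
  τ = lβħ/P, symmetric about l = P/2 by the cyclic topology.

Ensemble R_g is reported either as the pooled RMS centroid–bead distance
(default) or as the mean of per-frame R_g values; the two differ only when
per-frame R_g is broadly distributed, and both are exposed because the
convention used in published tables is often unstated.

Degenerate clouds (all beads coincident) have undefined κ²; we return 0 with
a `degenerate` flag rather than NaN so that tabulated output stays numeric.

The population comparison test is Welch's unequal-variance t-test; the
classic equal-variance variant assumes homoscedasticity that bead-distance
pools from different atom classes do not satisfy.

## Persistent homology of bead clouds

A ball of radius r is grown at every bead; edges enter the Vietoris–Rips
complex when two balls intersect, at r = d(i,j)/2, and triangles at the
maximum of their edge radii. **The filtration parameter is the ball radius
throughout** — most TDA libraries parameterize by diameter, so any external
cross-check must halve its scale. Only simplices up to dimension 2 are
built: β₀ (components) and β₁ (loops) are what a closed polymer can
meaningfully exhibit; β₂ is out of scope.

The β₁ barcode comes from the standard boundary-matrix reduction over GF(2).
A union-find sweep over edges in filtration order separates negative edges
(which kill β₀ bars) from positive edges (which create loops); triangle
columns, processed in (value, lexicographic) order, are reduced against the
current pivots and pair each loop with its filling radius. The ordering by
(value, dimension, lexicographic vertex tuple) makes pairing deterministic.
Zero-length bars (birth = death) are discarded. Loops still open at the
radius cutoff `r_max` are clipped there and flagged truncated; the single
essential β₀ component keeps death = +∞.

Two implementations of the reduction exist: a pure-Python reference using
arbitrary-precision integer bitsets, and a numba kernel over uint64 bitset
words with a branch-free highest-bit computation. The test suite pins them
bit-identical, and both are checked against an independent brute-force
oracle that recovers barcodes purely from ranks of homology inclusion maps
(persistent Betti numbers) on small clouds — a different algorithm sharing
no code with the production path.

### Betti sequences and distributions

The Betti sequence h(r) counts the bars alive at each radius of a uniform
grid on [0, r_max]; a bar [birth, death) counts on the half-open interval,
i.e. a loop is no longer present at the radius where it closes. Defaults:
r_max = 1 native length unit, with 400-step ("coarse") and 1000-step
("fine") grid presets; the sweep warns if any bar outlives r_max, since the
analysis assumes all loops close before the grid ends.

The Betti sequence probability distribution is the normalized histogram of
h values indexed by intersection count 0..B₁, where B₁ is the largest h
observed in *any* ring polymer of the data set (a two-pass computation);
using the data-set-wide bound standardizes all distribution lengths so they
can be transported into one another. Every distribution sums to 1 by
construction (asserted to 1e−12).

## Wasserstein distances and the fluctuation signal

The distance between two Betti distributions K, L is the optimal value of
the transportation problem min Σ d_ij f_ij subject to row sums ≤ K(i),
column sums ≤ L(j), total flow = 1, f ≥ 0, with ground cost d_ij = |i − j|
in bin units. The inequality marginals follow the defining formulation (the
unit-total-flow constraint forces them active at the optimum). For this 1-D
cost the optimum has the closed form Σ_m |CumSum(K − L)(m)|, which is the
production path; the LP (scipy HiGHS) is retained as the reference
definition and is cross-checked against the closed form on hundreds of
random pairs at 1e−9. Optimal *plans* can be degenerate; only the total
cost is contractually deterministic. Distributions are validated to sum to
1 within 1e−9 before computing.

The shape-fluctuation signal of one atom is the WD vector
[wd₁,₂ wd₂,₃ … wd_{N−1,N}]: the N−1 distances between Betti distributions
of time-adjacent snapshots.

## Spectral fingerprints

Each WD series is cut into sliding windows of 2·half_width + 1 snapshots
(default half_width 20; stride 1), mean-subtracted, and discrete-Fourier
transformed; the magnitudes of all nonnegative-frequency coefficients form
one feature vector per window. Mean subtraction removes the baseline so
that fluctuation, not offset, dominates; no taper is applied by default
(Hann optional). The DFT is unnormalized, so Parseval reads
Σ|X_k|² = n·Σ|x_t|² per window. Feeding *all* magnitudes into a joint PCA
(rather than pre-selecting "the two largest frequencies", which is
ambiguous between largest-amplitude and highest-frequency readings) lets
the PCA find the dominant spectral contrasts itself; a `top_k` option
restricts to the k largest-magnitude coefficients for users who want the
narrower reading. PCA is fit jointly over all classes — scores are only
comparable in a common basis — and the component count defaults to the
smallest reaching 90% cumulative explained variance. Class separation is
summarized by per-class centroids, a silhouette score, the overlap
coefficient of the PC1 marginals, and per-class PC1 interquartile ranges.

## Proton-transfer labeling

Shared (zundel-like) protons are flagged when an H centroid lies within
1.3 length units of two distinct O centroids. Bead-level connectivity
assigns each bead its nearest O centroid per snapshot; assigning beads to
the nearest O (rather than a per-bead distance cutoff) is our choice where
the underlying construction is underdetermined, and is configurable in
principle via the partner-trace layer. A window of span 40 time units
(±20 about the center) is labeled PT when every bead's partner at the start
differs from its partner at the end with one common donor→acceptor pair,
non-PT when no bead changes partner anywhere inside, and is otherwise left
unlabeled — partial transfers belong to neither class. PT scanning uses
stride 1 with runs of qualifying centers (same donor/acceptor, centers
within one frame) merged into a single event; non-PT windows tile the
quiescent stretches without overlap.

## Synthetic fixtures: what they emulate and what they don't

**Free-ring sampler.** Bead clouds are exact Gaussian samples of a cyclic
chain of identical harmonic springs, drawn in the normal-mode basis
(eigenvectors of the ring Laplacian, mode k weighted 1/ω_k with
ω_k² = 4 sin²(πk/P)) with the zero (centroid) mode removed. The overall
scale is set so the *mean* R_g equals the requested `spread_scale`; the
mean-to-RMS ratio of R_g is calibrated once per P from 20,000 internal
draws (the RMS is analytic, the mean is not). Parameterizing by target R_g
directly, instead of by (m, T, ħ), keeps physical-constant plumbing out of
the fixtures.

**Two-population (glass-like) trajectories.** Two atom classes with spread
scales in ratio 10 (defaults 0.2 and 0.02 length units, mirroring a system
whose species differ ~10× in thermal wavelength), 50 atoms per class, 500
snapshots, P = 48 beads. Time evolution mixes each cloud with a fresh
sample, new = ((1−α)·prev + α·fresh)/√((1−α)² + α²), re-centered — a
variance-preserving AR(1) scheme whose stationary spread is α-independent,
so mixing rate and amplitude are controlled separately. The delocalized
class decorrelates fully between snapshots (α = 1.0) while the localized
class evolves slowly (α = 0.05): the physical picture is that the floppy
species explores its shape space much faster than the saved-frame interval
while the stiff species barely moves, which is what makes the two WD
histograms separate. P = 48 keeps the loose-class barcode rich (B₁ ≈ 11)
at about 7 ms per barcode; the full fixture is 50,000 barcodes and runs in
roughly six minutes on one core. This scheme is *not* RPMD dynamics: it has
no inertia, no spectrum of mode timescales, and no coupling between atoms.
Passing tests on it show that the pipeline separates populations whose
shape-fluctuation statistics differ as designed — not that it would
separate any particular physical system.

**Toy clouds.** `unit_square` (one loop, born r = 1/2, filled √2/2),
`hexagon_side1` (born 1/2, filled √3/2), `circle_n`, `collinear_n` (no
loops, κ² = 1), `figure_eight` (two tangent octagons sharing a vertex: two
loops). These carry the analytically known barcodes used as oracle anchors.

**Proton-transfer trajectories.** Each H atom sits between its own O pair
(separation 2.4, anchors 1.0 from each O along the axis; H cloud spread
0.12, O spread 0.03 — magnitudes typical of room-temperature water at
these units). A scheduled event spreads the P bead commitment times evenly
over a 36-time-unit transfer (just inside the 40-unit labeling window), so
at every instant inside the transfer some beads have switched and some have
not: exactly the windows bracketing the whole interval qualify as PT, and
each injected event is recovered as exactly one merged window. Inside the
transfer interval the cloud is redrawn independently every frame with 2×
noise amplitude — a stand-in for the rapid rattling of a shared zundel
proton — which is what gives PT windows their larger mean WD. Beads are
clamped to their scheduled side of the O–O midplane by reflection, so
nearest-O partners never flip off-schedule and labels are deterministic.
An earlier fixture design with purely deterministic bead migration produced
*smaller* WD inside transfers than outside (the two static lobes barely
change shape frame to frame); the shuttling design replaced it.

## Numerical choices

- Duplicate points within 1e−12 are deduplicated (with a warning) before
  building the filtration; coincident points would create zero-value edges
  and spurious instant cycles.
- Eigenvalues of the gyration tensor are clipped at 0 to absorb round-off
  on degenerate clouds.
- Periodic unwrapping is chained minimum-image anchored at bead 0 and warns
  when the unwrapped ring is still wider than half the box. It is
  idempotent and unique up to a lattice translation. How (or whether)
  periodic images should be handled for bead clouds is genuinely open; all
  downstream metrics here use unwrapped coordinates.
- Histogram binning for distance distributions is Freedman–Diaconis with a
  single-bin fallback for zero-spread samples.
- WD-histogram class comparison uses 100 equal-width bins over the pooled
  range and the overlap coefficient Σ min(p, q); PC1 marginal overlap uses
  50 bins.
- Trajectory text formats round-trip coordinates at 17 significant digits
  (< 1e−12 error).

## Known limitations

- Homology is computed per frame from scratch; no vineyard/update scheme
  across snapshots.
- The LP transport plan is one optimal vertex among possibly many; tests
  must not assert plan uniqueness.
- The events module assumes O and H atom types by label and one partner per
  bead; Grotthuss-chain topology and rate estimation are out of scope.
- The synthetic generators are statistical emulators, not dynamics; see
  above for what that implies about test coverage.
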