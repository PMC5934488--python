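# Methods

## Scope and data model

The package implements the analysis stages downstream of EEG source
localization: per-subject ROI time series (or precomputed coherence
matrices) → band-limited lagged-coherence adjacency → weighted small-world
and spanning-tree metrics → two-group permutation inference. Scalp
preprocessing, artifact rejection and the inverse solution are out of
scope; ROI time series are taken as given.

Nodes are the 84 Brodmann-area parcels that standard source-localization
software resolves: BA 1–47 minus {12, 14, 15, 16, 26}, each in both
hemispheres. The canonical ordering (left ascending by BA number, then
right) is fixed so that delimited-text matrices are unambiguous.

## Spectral estimation and lagged coherence

Cross-spectra are mean Hann-tapered periodograms across epochs, with the
transform length defaulting to the next power of two at or above the epoch
length (1024 samples at 250 Hz → 0.244 Hz bins). Epochs of 1000–1250
samples (4–5 s) are therefore zero-padded to 1024 or 2048 points. The
taper is a design choice, not part of the coherence definition, and is the
only windowing applied; epochs do not overlap.

Lagged coherence per pair and bin is `Im(S_xy)² / (S_xx S_yy − Re(S_xy)²)`.
The denominator removes the instantaneous (real) cross-spectral component,
so any static linear mixing of a common source — volume-conduction leakage
projected into source space — contributes nothing. Degenerate bins
(denominator ≤ 0, possible with numerically rank-deficient spectra) are
defined as 0 and logged. The band value is the plain mean over bins whose
centers fall in the half-open interval `[f_lo, f_hi)`; half-open edges keep
the shared 8 / 12 / 20 Hz boundaries in exactly one band. Averaging
coherence over bins (rather than computing coherence from band-integrated
spectra) is a documented choice; the alternative weighs bins by power and
is not implemented.

## Weighted graph analysis

All analysis is on weighted graphs; no binary thresholding is performed
anywhere (thresholds are arbitrary and multiply comparisons).

- **Clustering**: Onnela per-node coefficient, geometric mean of triangle
  weights normalized by the network maximum; nodes with degree < 2
  contribute 0; the graph value is the node mean.
- **Characteristic path**: mean all-pairs shortest path with edge length
  d = 1/w (strong coherence = short edge). The observed graph must be
  connected (dense coherence matrices always are); an informative error
  names the smallest isolated component otherwise.
- **Lattice surrogate**: the off-diagonal weight multiset is re-laid so
  the largest weights occupy the shortest ring spans (heaviest in the
  diagonal band), randomized within equal-span groups under the seed.
- **Random surrogate**: uniform permutation of the off-diagonal weight
  multiset. Surrogate path lengths average over reachable pairs only, so
  the ensemble remains defined if a sparse surrogate disconnects; the
  observed graph is still required to be connected.
- **SWP**: ΔC = (C_latt − C_obs)/(C_latt − C_rand),
  ΔL = (L_obs − L_rand)/(L_latt − L_rand), each clamped to [0, 1], with
  C_rand / L_rand the means over `n_null = 50` random surrogates;
  φ = 1 − √((ΔC² + ΔL²)/2). Clamping guarantees φ ∈ [0, 1]. Degenerate
  denominators (|·| < 1e−12, or non-finite surrogate paths) set that
  deviation to 0 with a warning. φ > 0.6 is the small-world
  classification bound used throughout.

A property worth knowing: on a *fully dense* matrix with near-uniform
weights, banded (lattice) placement does not maximize Onnela clustering —
the concave cube root makes spread placements competitive — so the
lattice-vs-random contrast, and hence SWP, is only informative when the
weight distribution has real dynamic range. The synthetic generator is
parameterized to be in that informative regime (below).

## Minimum spanning tree metrics

The MST is computed on d = 1/w (equivalently the maximum-coherence
spanning tree; any strictly monotone distance transform gives the same
tree). Kruskal's algorithm with edges ordered by (distance, i, j) makes
the tree deterministic under ties. Metrics:

- **Betweenness centrality**: ordered-pair convention — BC(v) counts
  ordered pairs (s, u), s ≠ u ≠ v, routed through v; computed from the
  component sizes of the tree with v removed, BC(v) = (n−1)² − Σ s_a².
  Ceiling (n−1)(n−2) = 6806 for n = 84 (star center); exactly twice the
  unordered count. The unnormalized ordered-pair convention is the one
  whose scale matches maximum-BC values in the thousands for n = 84.
- **Leaf fraction**: #(degree = 1)/(n − 1); 1 for a star, minimal for a
  path.
- **Eccentricity / diameter**: BFS edge-distances from every node;
  diameter = max eccentricity, measured in edges (with the node-count
  convention every value would shift by one; edges is the convention
  used here).

## Group inference

The observed statistic is the Welch two-sample t (groups are unbalanced —
19 vs 52 by default — and variances need not match). The null shuffles
pooled group labels; the pool is sorted and the smaller group is always
drawn first, which makes the realized p-value exactly invariant to
exchanging the two samples. p = (1 + #{|t_perm| ≥ |t_obs|})/(n_perm + 1)
(add-one convention; attainable minimum 1/(n_perm+1)). Zero pooled
variance yields p = 1 with a warning; zero within-group variance with
unequal means yields |t| = ∞, handled consistently on both sides of the
comparison.

The global family is all 7 × 4 = 28 index/band cells with joint
Benjamini–Hochberg FDR; significance at q < 0.05. Note the design
consequence: with a single true effect among 28 cells, q < 0.05 requires
the p floor to be below 0.05/28, i.e. n_perm ≥ 560 — the 5000-shuffle
default is comfortably above, but heavily reduced shuffle counts are not.
Nodal BC / eccentricity follow-ups are gated: they run only in bands whose
global max-BC / average-eccentricity cell was significant (an override
flag exists for exploratory use), with FDR across the 84 ROIs within each
metric/band family. The choice of FDR families (28 jointly; 84 per nodal
family) is exposed rather than hidden: both p and q are always reported.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the biophysics of EEG:

- **Base matrix**: 84-node ring lattice, spans ≤ k = 6 carry strong
  coherence ~ truncated-normal(0.85, 0.01) on [0, 1]; each strong weight
  is swapped to a uniformly random background pair with probability
  `p_rewire` (default 0.1), preserving the weight multiset; all other
  pairs carry weak background coherence ~ truncated-normal(0.01, 0.003);
  independent N(0, 0.001) noise is added and the matrix clipped to
  (0, 1]. The two-orders-of-magnitude separation between strong and
  background weights keeps the lattice/random surrogate contrast
  resolvable (see the density caveat above) and makes the construction
  genuinely small-world: φ > 0.6 at 10% rewiring, φ < 0.6 after full
  weight permutation. The background level is low relative to the
  ~1/n_epochs noise floor of real 25-epoch lagged coherence; real
  matrices are flatter, which is one reason passing tests here do not
  certify effect sizes on real data.
- **Cohort**: 19 cases / 52 controls by default, 4 bands per subject;
  between-subject variability is a per-subject jitter on the strong-weight
  mean (SD 0.02). Case-group effects act on the weight matrix in one
  band: `clustering` scales background weights (triangle closure);
  `path` scales all weights (distances scale exactly, normalized
  clustering untouched); `diameter` shifts shortcut weights by multiples
  of the strong-weight spread (only rank displacement on that scale
  changes how many shortcuts the MST keeps — a plain multiplicative
  scaling saturates immediately); `hub_bc`/`nodal_bc:<ROI>` scales one
  ROI's row/column. Direction +1 raises the targeted index in cases.
  Magnitude 0.5 on `clustering` is the "strong deficit" condition used in
  the power checks.
- **Time series**: independent white noise per ROI plus band-limited
  stochastic oscillations shared by coupled pairs at a chosen sample lag;
  an optional zero-lag common source emulates volume conduction. This
  path exercises the spectral pipeline end-to-end; it makes no claim to
  1/f spectra, nonstationarity, or realistic source geometry.

Everything is reproducible from a single seed, fanned out with
`numpy.random.SeedSequence.spawn` into independent per-subject, per-band,
and per-stage substreams, so stages can be re-run in isolation.

## Problem sizes used in the checks

The shipped checks use reduced but sufficient simulation sizes, chosen as
the package's own verification budget: oracle equivalence on 100 random
graphs/trees with n ≤ 8 (spanning-tree enumeration at n ≤ 6, where the
exhaustive search is affordable); SWP classification over 10 generator
seeds with 50 nulls; permutation calibration with 1000 null replicates at
500 shuffles; null-cohort false-positive rate over 15 replicate cohorts;
power checks over 10–20 cohorts with 1000 shuffles and 5–10 SWP nulls.
Properties checked this way (calibration, ordering, classification) are
insensitive to the reduction; estimated powers at these sizes carry
binomial error of roughly ±10%.

## Known limitations

- Reported group statistics from real resting-state cohorts are not
  reproduced numerically — no public recordings exist to consume — so
  real-data values serve only as plausibility anchors for scale and
  convention (e.g. maximum BC in the 4600–5100 range for n = 84 is
  reachable only under the ordered-pair convention).
- The lattice surrogate follows the banded, weight-sorted construction;
  other lattice nulls (degree-sequence-preserving rewiring) would give
  numerically different ΔC.
- Band-averaged coherence treats all bins equally; power-weighted band
  integration is a plausible alternative convention.
- The synthetic generator's effects are applied to weights, not to the
  underlying time series; the coupled-time-series path exists for
  end-to-end connectivity tests but is not used to build cohorts (desk-
  scale runtimes).
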