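# Methods

## Signal model and phase extraction

Epochs are treated as independent, non-contiguous segments; every
operation is applied per epoch. Band-pass filtering uses a fourth-order
Butterworth applied forward and backward (`scipy.signal.sosfiltfilt`),
i.e. an effective eighth-order magnitude response with exactly zero
group delay. Zero-phase filtering is mandatory here: every downstream
quantity is a function of instantaneous phase, and any group delay would
masquerade as phase lag. The six analysis bands are delta 0.5–4, theta
4–8, lower alpha 8–10, upper alpha 10–13, beta 13–30 and gamma
30–48 Hz; a band whose upper edge reaches the Nyquist frequency is
rejected with the band named.

Instantaneous phase is the argument of the analytic signal (Hilbert
transform). The analytic signal is unreliable near segment boundaries,
so a symmetric edge trim is applied after the transform: by default one
cycle of the band's low edge (2 s for the 0.5 Hz delta edge at full
scale), capped at 10% of the epoch so that short desk-scale epochs
retain most of their samples. The trim is configurable and recorded in
the run manifest. An all-zero channel has no defined phase and raises an
error naming the ROI.

## Phase lag index

For two phase series the PLI is |⟨sign sin ΔΦ(t)⟩|. Conventions:

- sign(0) contributes 0, so constructed inputs with ΔΦ ≡ 0 or ΔΦ ≡ π
  score exactly 0. Floating-point sines within 1e-9 of zero are treated
  as exact zeros so that these analytic cases hold under finite
  precision; for stochastic signals the adjustment is inert
  (|sin ΔΦ| < 1e-9 has probability ≈ 0).
- The PLI is invariant under a common phase shift and under 2πk wraps
  of the difference, and symmetric in its arguments (all property-tested).
- Per-epoch PLI matrices are averaged entrywise per subject before any
  group statistic. The subject-level edge summary is therefore the
  epoch-mean PLI, consistent with how the network metrics are averaged.

With N ROIs the matrix has N(N−1)/2 distinct entries (3003 at the
78-ROI full scale), symmetric with zero diagonal, all in [0, 1].

## Weighted small-world metrics and surrogate normalization

Weighted clustering (per node, then averaged):

    Cw_i = Σ_{k≠l} w_ik w_il w_kl / Σ_{k≠l} w_ik w_il

with the node term set to 0 when its denominator vanishes. This ratio
scales linearly under global weight scaling, Cw(cW) = c·Cw(W) — the
scaling law is asserted in the tests rather than assumed away.

Weighted path length uses distances d = 1/w (infinite where w = 0),
Dijkstra shortest paths, and the harmonic-mean form

    Lw = 1 / [ (1/(N(N−1))) Σ_{i≠j} 1/L_ij ],   1/L_ij = 0 if disconnected,

which tolerates disconnected pairs and gives Lw(cW) = Lw(W)/c. A fully
disconnected matrix is invalid input and raises.

Surrogates shuffle the upper-triangle weights uniformly and mirror them
(weight multiset preserved exactly, topology destroyed). Normalized
metrics divide the observed Cw and Lw by their means over 50 surrogates
(default), computed per epoch-matrix and then averaged over epochs per
subject. Surrogate RNG streams are keyed by (master seed, subject,
epoch, band), so runs reproduce bit-identically. Numerical detail: when
every surrogate yields the same value (a shuffle-invariant, i.e.
constant-weight, matrix) the mean is taken as that value directly, so
normalized Cw = normalized Lw = 1 exactly rather than to one ulp.

## Minimum spanning tree

The MST is built with Kruskal's algorithm (own union-find) on edge
costs 1/PLI, keeping the strongest connections that close no cycle.
Candidate edges sort by (1/w, i, j) with i < j, so ties in PLI resolve
deterministically to the lexicographically smallest pair. A graph that
is disconnected at positive weights raises with its components listed —
there is no spanning-forest fallback. Because the tree depends only on
weight ranks, any strictly increasing transform of the PLI leaves the
edge set unchanged (property-tested); optimality is pinned against
exhaustive enumeration of all 7⁵ labeled trees on 7 nodes.

Metric conventions, all recorded in output metadata:

- **Betweenness centrality**: pass-through pair counts divided by
  (N−1)(N−2)/2, so a star center scores exactly 1. Tree paths are
  unique, so the count is exact (delegated to networkx; pinned against
  a brute-force path-enumeration oracle).
- **Degree**: raw counts plus the fraction of the 2(N−1) endpoint slots.
- **Eccentricity / diameter**: hop counts within the tree.
- **Leaf number / leaf fraction**: degree-1 nodes; fraction of the
  maximum possible N−1.
- **Degree correlation R**: Pearson correlation over edge-endpoint
  degree pairs, both orientations per edge; returns NaN (flagged
  undefined) when the endpoint degrees have zero variance.
- **κ (degree divergence)**: ⟨k²⟩/⟨k⟩, reported with the full degree
  histogram P(k).
- **Tree hierarchy**: Th = L/(2 m BC_max) with m = N−1 and BC_max on
  the pair normalization above; Th ∈ (0, 1] on every tree with N ≥ 3
  (verified exhaustively for N = 6).

The verbal definitions these conventions implement leave the exact
normalization constants open; a different bounded convention would
change node values by a constant factor but not group contrasts or
rankings.

## Group statistics

Features are compared with a pooled-variance two-sample t statistic
(zero pooled variance: t = 0 for equal means, signed infinity
otherwise). The permutation null relabels subjects preserving group
sizes; the two-sided p-value uses the add-one estimator
p = (1 + #{|t_perm| ≥ |t_obs|})/(n_perm + 1), bounded below by
1/(n_perm + 1). The test is two-sided because group differences in both
directions are scientifically expected (hyper- and hypo-connectivity
coexist); a Welch variant was not used since the permutation calibrates
the pooled statistic directly. Within a band, all features share one
relabeling sequence, preserving cross-feature dependence under the
null; the sequence is keyed by (master seed, band). The single-feature
`permutation_test` draws its null from the sorted pooled sample so that
swapping the group labels reproduces the identical p-value.

FDR control is Benjamini–Hochberg step-up (statsmodels, pinned against
a literal step-up oracle), applied within each (feature family, band):
families are the 3003 edges, the per-node MST betweenness+degree
vector, and the global metrics. BH was chosen over BY as the standard
choice when no strong negative dependence is suspected; the pooling
scope (per family × band, not pooled across bands) mirrors correcting
each analysis separately.

The pipeline can optionally restrict network-level statistics to bands
whose edge-wise tests yielded uncorrected significance, mirroring a
two-stage exploratory design; the selection is recorded in the run
manifest.

## Synthetic cohorts

Per epoch and band, each ROI receives unit-variance Gaussian noise
brick-wall limited to the band (frequency-domain masking). A coupled
edge (i, j, strength c, offset φ) replaces j's band component with
√(1−c²)·own + c·(i's component with its analytic phase rotated by φ),
so ΔΦ concentrates around φ, tightening as c → 1 (PLI → 1 in the
noise-free limit; at c = 0 the pair is indistinguishable from
independent noise). Offsets must be strictly inside (0, π) mod π:
zero-lag "coupling" would be invisible to PLI by design and the ground
truth unrecoverable, so it is rejected at configuration time.

Field spread is modeled separately as instantaneous mixing of one
shared source with the same per-band spectral makeup:
x ← √(1−m²)·x + m·s, m ∈ [0, 1). This raises naive phase-consistency
measures (e.g. the phase-locking value) while leaving the PLI unchanged
within sampling noise — both verified on 50-seed ensembles. Broadband
sensor noise of standard deviation `noise_sd` (default 1.0, against
unit-variance band components; amplitudes are conventional since no SNR
calibration of real recordings exists) is added last. At the full-scale
sampling rate each requested band carries ≥ 10× the in-band power of
that noise floor; at the desk-scale 250 Hz rate the wide beta/gamma
bands admit relatively more broadband noise, which is a deliberate
trade for speed, not a property of the study-scale conditions.

Presets: full scale is 78 ROIs, 29+29 subjects, 20 epochs × 4096
samples at 1000 Hz; desk scale is 30 ROIs, 10+10 subjects, 10 epochs ×
1024 samples at 250 Hz, chosen so that complete pipeline runs finish in
seconds while group effects of moderate strength remain detectable.
Subjects draw from independent spawned RNG streams of the config seed;
identical configs generate bit-identical cohorts.

What the generator does **not** emulate: realistic head geometry or
sensor forward models, 1/f background spectra, amplitude dynamics and
cross-frequency coupling, inter-subject variability in spectral peaks,
or artifacts. Passing tests therefore demonstrate that the analysis
chain recovers the phase structure it is designed to measure — not that
it is robust to every pathology of real recordings.

## Problem sizes in the test suite

Unit tests run at 2–30 ROIs with 512–4096-sample epochs. The
enumeration oracles use all 16 807 labeled 7-node trees (MST
optimality, 100 random matrices) and 1000 random trees up to N = 12
(metric suite). Permutation calibration uses 1000 null features with
29+29 subjects at 500 permutations; injected-coupling recovery uses 20
desk-scale cohorts with five coupled edges at strength 0.6. These sizes
are the package's own test-design choices and are independent of the
full-scale defaults the presets encode.

## Known limitations

- Betweenness/degree normalization constants are conventions (see
  above); absolute per-node values are comparable only within runs of
  this package.
- The MST errors on disconnected graphs rather than computing a forest;
  PLI matrices of real data are almost surely strictly positive, so
  this arises only with constructed inputs.
- `average_connectivity` and the pipeline average PLI linearly over
  epochs; epochs are assumed exchangeable within a recording.
- Degree correlation is undefined (NaN) on degenerate trees; at
  realistic network sizes this effectively never occurs, but the value
  would propagate as an error if such a tree entered group statistics.
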