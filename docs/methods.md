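# Methods

## Model

A subject's functional connectome is a symmetric weighted graph on the
regions of a parcellation. Edge weights ("proximities") are non-negative
Pearson correlations of wavelet coefficients, so `w_ij ∈ [0, 1]` with
`w_ij = 0` meaning the edge is absent. The isomorphism `d_ij = 1/w_ij − 1`
carries proximities to distances: `w = 1` maps to `d = 0`, `w → 0` to
`d → ∞`. Absent edges are represented by an explicit infinite sentinel,
never a large finite number, so shortest paths cannot leak through them.

The metric closure replaces every pairwise distance with the all-pairs
shortest-path distance `D_ij`, computed with Johnson's algorithm
(`scipy.sparse.csgraph.johnson`). Since `D_ij ≤ d_ij` always, each present
edge is either *metric* (`D_ij = d_ij`) or *semi-metric* (`D_ij < d_ij`, a
transitivity violation), with distortion `s_ij = d_ij / D_ij`. The
semi-metric percentage (SMP) of an edge subset is the fraction of its
present edges labelled semi-metric; subsets with no present edge have an
*undefined* SMP (an error, never 0).

Only the metric (shortest-path) closure is implemented; generalized
closures over other path algebras, and directed or signed graphs, are out
of scope.

## Connectivity estimation

Region-averaged BOLD series are decomposed with the stationary
(maximal-overlap) discrete wavelet transform, Daubechies-4, periodic
boundary handling, in its energy-preserving normalization (`pywt.swt`,
`norm=True`): each dyadic scale keeps the full series length and the
detail scales plus the final approximation partition the input energy.
Scale `j` nominally covers `(f_N/2^j, f_N/2^(j−1))` with Nyquist
`f_N = 1/(2·TR)`; at TR = 2.43 s scale 2 is ≈ 0.051–0.103 Hz, the band
conventionally used for resting-state analysis, and is the default
analysis scale (configurable). Correlations are computed on all retained
coefficients; no boundary coefficients are excluded — a documented
simplification. The transform requires the series length to be divisible
by `2^n_scales` (256 time points at 4 scales qualifies).

Negative correlations are excluded from the proximity graph (set to 0 =
absent); their per-subject count is retained and compared between groups.
Exact zero correlations are likewise treated as absent edges.

## Region hierarchy

Regions carry a hemisphere (left, right, or cerebellum incl. vermis), one
of six cerebral lobes (frontal, parietal, occipital, temporal, limbic,
subcortical) or the cerebellar label, and an MNI centroid. Edge subsets:
whole brain; each cerebral hemisphere; the cerebellum; between-hemisphere
(all left × right cerebral pairs); per hemisphere, one subset per lobe
plus the within-hemisphere between-lobe pairs. Within a hemisphere the
lobe subsets and the between-lobe subset partition that hemisphere's pairs
exactly; cerebellum-to-cerebrum pairs count toward the whole brain only.
The bundled 116-region layout (90 cerebral + 26 cerebellar/vermis) is a
synthetic convention, generated programmatically — users with a real atlas
supply their own table (`id, label, hemisphere, lobe, x, y, z`).

## Group statistics

* **SMP tests.** Welch (unequal-variance) two-sample *t*, two-tailed, with
  the Welch 95 % CI on the difference of group means. Welch is used
  uniformly; edges are classified once on the whole-brain graph and
  subsets merely select which classified pairs are counted (re-running the
  closure inside each subgraph is a possible alternative, not implemented).
* **Hierarchical gating.** The whole brain is always tested; hemispheres,
  cerebellum and between-hemisphere edges gate on the whole-brain test;
  lobes and between-lobe sets gate on their hemisphere. A child is tested
  iff its parent's *p* < α (default 0.05). Gated-off subsets are reported
  descriptively without *p*-values. No multiplicity correction is applied
  beyond the gating itself; `bh_correct_leaves=True` optionally applies
  Benjamini–Hochberg across tested leaf rows.
* **Asymmetry.** Per subject, `(r − l)/(r + l)` of right/left hemisphere
  SMPs (undefined when `r + l = 0`; such subjects are excluded with a
  warning), compared between groups with a two-sided Mann–Whitney U.
* **Backbones.** A pair belongs to a group's consensus backbone when it is
  semi-metric in strictly more than the threshold fraction (default 0.9)
  of the group's subjects — the comparison is strict, so exactly 90 %
  consensus is excluded.
* **Difference maps.** Per subject the closed distances are mapped back to
  proximity space (`w = 1/(D + 1)`), averaged elementwise within group;
  the node score is the row mean (diagonal excluded) of the absolute
  difference of the two group means. This aggregation — closure →
  proximity embedding → group mean → absolute difference → row mean — is
  this package's declared construction; optional max-normalization is for
  display only.
* **Correlation summaries.** Median / mean / SD of all off-diagonal raw
  correlations pooled per group, a Shapiro–Wilk normality *p* (computed on
  a seeded random subsample of 4 000 when the pool is larger, since the
  test's validity degrades at huge n), and a Welch *t* on per-subject
  negative-correlation counts (reported NaN when both groups' counts are
  constant).

## Synthetic generator

The generator emulates the target study conditions: two groups (12
control, 11 case subjects), 116 regions, 256 time points at TR = 2.43 s.
Per subject, background weights are drawn from a normal with
group-specific mean and spread, clipped to [0, 1] — control
μ_R = 0.316, σ_R = 0.036; case μ_R = 0.291, σ_R = 0.034, the groups'
printed correlation summaries. *Triads* are then planted on node-disjoint
triples: a weak direct edge `w_weak = 0.2` bridged through a hub by two
strong edges `w_strong = 0.8`. Because
`2·(1/0.8 − 1) = 0.5 < 1/0.2 − 1 = 4`, the two-hop path undercuts the
direct edge whatever the background (extra edges only shorten shortest
paths), so every planted edge is analytically guaranteed semi-metric —
the ground truth needs no oracle.

The case group's effect is modeled as (i) the narrower correlation spread
above, (ii) twice the planted triads (12 vs 6), and (iii) higher
topological *jitter* (0.5 vs 0.1): per subject, each triad relocates to a
random disjoint site with that probability, so case subjects agree less on
where their semi-metric edges sit. Triad counts and jitter rates are the
generator's own defaults, chosen by a power argument: 12 disjoint triads
fit comfortably in 116 nodes; with jitter 0.1 and 12 subjects the
probability that a canonical edge is semi-metric in ≥ 11 of 12 subjects is
≈ 0.66, so the control backbone keeps a few edges at the strict > 0.9
rule, while jitter 0.5 drives the case consensus toward 0.5 and empties
its backbone — reproducing the "sparser case backbone" phenomenon.

Time-series emulation draws temporally white multivariate Gaussians whose
correlation matches the proximity target after an eigenvalue-clipping
nearest-PSD repair (a modeling convenience); because the noise is white,
band-limited wavelet correlations converge to the same target as the
series lengthens. The generator does **not** model hemodynamics, drift,
motion or physiological noise, scanner artefacts, or spatially structured
connectivity; passing tests demonstrate the pipeline's correctness and the
stated qualitative recoveries under these idealized conditions, not
performance on real fMRI.

## Numerical choices

* Semi-metric tie tolerance: `D_ij < d_ij·(1 − 1e−9)` (relative);
  otherwise metric. A metric edge's closed distance is *snapped* to its
  direct distance, which removes sub-tolerance floating-point undershoot
  from path summation and makes the closure an exact fixed point.
* Johnson's per-source runs can disagree across the diagonal by one ulp;
  the undirected result is symmetrized by an elementwise minimum.
* `w = 1` gives `d = 0`; zero-cost edges are legal on paths and nodes are
  not merged (verified to survive the sparse-graph conversion).
* Self-pairs never enter any count; SMP denominators count only
  positive-weight (finite-distance) pairs.
* A cubic Floyd–Warshall-style closure (`brute_force_closure`) with the
  identical contract serves as the independent oracle in tests.
* Matrix files serialize floats at 17 significant digits and parse with
  the round-trip parser, so write∘read is bit-faithful; infinity is the
  literal token `inf`.

## Problem sizes

The test suite and the acceptance script run closures on graphs of 20–116
nodes; replicate counts are 50 (planted recovery), 200 (direction of
effect) and 400 (null calibration) full 23-subject studies, sizes at which
the whole suite completes in minutes on one CPU while leaving the binomial
bands on the estimated rates comfortably narrow.

## Known limitations

* Subgraph SMPs use globally classified edges (see above); with very
  sparse subsets the SMP may be undefined for some subjects, who are then
  dropped from that subset's test.
* The printed nominal band labels of wavelet scales assume the configured
  TR; at TR = 2.43 s they differ from the conventional round-number labels.
* The synthetic parcellation's lobe assignment is arbitrary; geometric
  (distance-ranked) summaries on it are structurally correct but not
  anatomically meaningful.
* The difference-map aggregation is one reasonable embedding of multilayer
  group comparison, not a canonical one.
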