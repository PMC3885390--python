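# Methods

## Scope and data model

The package analyzes stimulus-response transcription dynamics. Its inputs
are a replicated expression array (genes × time points × replicates, time
stamps in hours) and a static directed regulatory network with node roles
TF/TG and two edge kinds: `regulates` (TF → TG) and `interacts` (TF → TF).
TGs are sinks by construction. Undirected TF–TF interactions, when they
occur in source data, should be encoded as reciprocal directed edges; this
convention matters for the directed clustering coefficient (both
directions count toward `E_n`) and is assumed throughout.

## Synthetic study generator

Because the real inputs of such experiments (microarray accessions,
interaction-database snapshots) are external and version-dependent, the
generator produces a complete, controlled stand-in study:

- **Network**: each of L TFs regulates exactly `targets_per_tf` TGs drawn
  uniformly; target sets are resampled on collision so no two TFs are
  duplicates (duplicate target columns are exactly the degenerate case
  the NCA identifiability criteria reject). Directed TF→TF interaction
  edges are added uniformly without self-loops or duplicates.
- **Activities**: Gaussian bumps `a·exp(−(t−t_peak)²/2w²)` with amplitude
  `a ~ U[1, 3]`. A single-peak impulse is the typical shape of early
  transcriptional responses; the bump gives exactly one unambiguous peak.
  Peaks are dealt round-robin over the four ranges delimited by the
  boundaries (default 1, 3, 8 h), so all ranges are populated when L ≥ 4.
  Bump width is uniform in 0.25–0.6 of the range width.
- **Control strengths**: magnitudes `U[0.5, 2]` with random sign, so both
  activation and repression occur.
- **Expression**: `E_r = C·T + ε_r`, `ε_r` i.i.d. Gaussian per entry and
  replicate. The default noise SD in the analysis drivers is 0.05 (about
  5–10% of the signal SD at these parameter ranges).
- **Sampling grid**: 0, 0.25, 0.5, 1, 1.5, 2, 3, 4, 6, 10, 14 h — eleven
  points over 14 hours, densely sampled early, as stimulus-response
  designs are. The exact grid is a configurable default, not a fixed
  property of the method.

What the generator does **not** emulate: probe-level microarray artifacts,
dye/channel effects, missing values, combinatorial (AND/OR) regulation,
TF–TF activity coupling, autocorrelated noise. Tests passing on this
generator therefore demonstrate correctness of the computations and
recoverability under the stated noise model, not performance on raw
microarray data.

## Preprocessing

- **Quantile normalization** across time points: each column's sorted
  values are replaced by rank-wise means. Idempotent; ranks are taken with
  a stable argsort, so ties are resolved by row order.
- **Loess normalization** is provided for two-channel intensity data: a
  lowess fit of M = log2(R/G) on A = ½·log2(R·G) is subtracted. The
  single-channel synthetic path does not use it; it exists for real
  two-color arrays.
- **Differential expression**: per gene and non-baseline time point, a
  two-sample equal-variance t-test of replicate values against the
  baseline (first) time point; a gene is selected when p < α (default
  0.05) at ≥ 3 time points. The baseline-referenced form was chosen
  because a stimulus-response design measures change from the unstimulated
  state; a paired variant is a config switch away in principle but is not
  the default. Zero pooled variance is resolved by evidence: p = 1 if the
  means agree, p = 0 if they differ. No multiple-testing correction is
  applied — the selection rule ("significant at three or more time
  points") is itself the guard, and calibration of the raw per-test error
  rate is verified by simulation.
- **Fourier smoothing**: least-squares fit of a truncated Fourier series
  with H harmonics (default 3) and period `period_factor × span` (default
  2× the 14 h window, so the fit is not forced periodic on the window).
  With 2H+1 = M the design is square and interpolates.

## NCA fitting

Alternating least squares with the support of C fixed: T-step is one full
`lstsq`; the C-step solves each gene's row restricted to its support.
Initialization draws support entries from ±U[0.5, 1.5], seeded.
Convergence: relative objective change < 1e−6 or 500 iterations; the
objective trace is recorded each full iteration and is non-increasing (a
property of exact alternating minimization; asserted in tests at 1e−10
relative slack). Restarts (default 5) keep the lowest objective — the
objective is non-convex and restarts are the standard cheap remedy.
Identifiability is probed by generic rank: the support is filled with
random values 5 times and rank (singular values > 1e−10 of the largest) is
taken by majority, since a structured pattern can only lose rank, never
gain it. Non-compliant patterns are repaired greedily: remove the TF whose
removal most reduces the violation count, breaking ties by fewest targets
then lexicographic id, dropping orphaned genes as they arise. This repair
is an explicit policy of this package, not a reconstruction of any
particular historical analysis. The scale/sign ambiguity is fixed by the
diagonal matrix S with `S_ll = ‖C_l‖₂ · sign(dominant entry)`: unit-norm C
columns with positive dominant entries make fits comparable across runs,
and `C·T` is invariant (checked to 1e−10). Recovery is scored by per-TF
absolute Pearson correlation, the natural metric under diagonal
indeterminacy.

## Time-range partitioning

Peak time is `argmax_t |x(t) − x(0)|` — absolute deviation, so strong
repression counts as a peak — with ties broken earliest and flat profiles
flagged and excluded. Amplitude is peak deviation divided by the SD of the
deviation profile (scale-free; threshold default 1.0). Each node is
assigned to the **single** range (half-open intervals, default (0,1],
(1,3], (3,8], (8,14] h) containing its peak; multi-range soft membership
is deliberately not supported, which keeps the four active sets a
partition of the above-threshold nodes. Peaks are measured on the
Fourier-smoothed profiles in the default pipeline.

## Topology

Closeness and path metrics are computed over reachable ordered pairs only
(directed); nodes reaching nothing score 0. Betweenness is normalized by
(|V|−1)(|V|−2). The directed clustering coefficient uses the union
neighborhood and counts directed edges: `E_n/(k(k−1))`, with k < 2 → 0.
Centralization is Freeman degree centralization computed on the undirected
collapse of the graph (each connected pair counted once), which keeps it
in [0, 1] with the star at 1. The random null samples TFs and TGs
separately (role-stratified, matching the observed sub-network's
composition — a uniform-node null would systematically change the TF/TG
ratio and with it every metric); 100 replicates, SD with ddof = 1.

## Motifs

The census is an exact ESU enumeration: every weakly-connected induced
k-subset is visited once and classified by the lexicographically minimal
row-major adjacency bit-string over all k! permutations (k ≤ 5, label
cache on raw patterns). The null is the directed double-edge swap
(a→b, c→d) ⇒ (a→d, c→b), rejecting self-loops and duplicates, with
3·|E| attempted switches per replicate; it preserves every in- and
out-degree exactly, which also preserves the TF/TG bipartite structure
(pure targets have out-degree 0 and stay sinks). Z-scores use the sample
SD over replicates (flagged undefined when the null is degenerate);
p-values are add-one empirical, `(r+1)/(n+1)`, so p = 0 cannot occur.
Significance threshold α = 0.05. Five-node census is exact; for graphs
far beyond the scale used here a sampling variant would be required and
is out of scope.

## Sizes and determinism

Default experiment sizes (10 TFs × 150 TGs for recovery; 200-node
scaffolds with 100 randomizations for motif enrichment; 2000 genes × 10
tests for calibration; ≤ 12-node graphs for brute-force oracle
comparisons) were chosen so each validation completes in seconds while
leaving no statistical ambiguity in the pass criteria. All randomness
flows through `numpy.random.default_rng` seeds; the pipeline derives
per-stage seeds as `blake2b(global_seed:stage_name)`, so stages are
independently reproducible and identical configs give byte-identical
numeric outputs (floats are printed with a fixed `%.12g` format).

## Known limitations

- NCA assumes the connectivity prior is correct; edges missing from `Z0`
  bias both C and T, and nothing in the fit can flag them.
- The linear model `E = C·T` ignores saturation, cooperativity and
  mRNA-degradation dynamics.
- Single-range assignment hides genuinely biphasic profiles; the peak
  statistic keeps only the dominant excursion.
- Quantile normalization across time points equalizes column
  distributions by design and will compress genuine global shifts in
  expression magnitude over time.
- The greedy compliance repair is order-dependent by its tie-break rule
  and is not guaranteed to remove a minimum set of TFs.
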