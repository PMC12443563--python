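# Methods

This note documents the models and procedures implemented by `dysfunctome`,
the defaults and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Connectivity estimation

Signals are band-pass filtered with a zero-phase 4th-order Butterworth
(forward–backward, `scipy.signal.sosfiltfilt`); the canonical band set is
delta 1–4, theta 4–8, alpha 8–12, beta 15–30 and low-gamma 31–40 Hz. The
12–15 Hz gap between alpha and beta is reproduced deliberately — it is part of
the analysis convention this package follows, not an oversight. Filtering
precedes epoching so that filter transients do not straddle epoch boundaries.

Epochs are non-overlapping 4-s windows; an epoch is rejected whole if any
sample on any channel exceeds ±50 µV. Instantaneous phase is the angle of the
analytic (Hilbert) signal per epoch. The phase lag index between channels i, j
is

    PLI_ij = | mean_t sign( sin(φ_i(t) − φ_j(t)) ) |,

with `sign(0) = 0`, so exactly zero-lag samples carry no weight — this is the
property that makes PLI insensitive to volume conduction, and it is kept
exact rather than perturbed. PLI is computed per epoch and averaged across
retained epochs (computing it over concatenated epochs is the other defensible
reading; per-epoch averaging is standard practice and composes naturally with
epoch-wise rejection). The estimator is positively biased at finite epoch
length (|mean of signs| of a finite sample), which is why independent channels
show small nonzero PLI; all inference is comparative, so the bias is shared
across conditions.

## Network-based statistic

For n subjects with a severity score s (an aphasia-quotient-like scale,
higher = milder), every edge weight w_e is regressed on s. In simple linear
regression the slope t-statistic equals `t = r √(df / (1 − r²))` with
`df = n − 2`; this identity is used directly (and verified against a per-edge
least-squares loop in the tests). Constant edges get t = 0; numerically
perfect fits are capped at 1e6 and flagged rather than propagating infinities.

Thresholding is one-sided and strict (`t > τ`): the search is for components
whose connectivity increases with the score. A negative-direction search is
available by configuration but off by default. Components are connected
subgraphs of the suprathreshold graph, sized in edges. The null distribution
of the maximal component size is obtained by uniformly re-shuffling the score
labels (duplicates across iterations allowed — with n = 15 the 15! permutation
space cannot be enumerated), recomputing all edge statistics, thresholding and
taking the largest component; the permutation stream is seeded. p-values use
the `(1 + #{null ≥ observed}) / (1 + K)` convention, so the smallest
achievable p at K = 10 000 is ≈ 1e-4. Every component at a threshold is tested
against that threshold's null-max distribution, which preserves family-wise
control for all of them; reporting is not limited to the largest.

Implementation note: inside the permutation loop the threshold on t is mapped
to the equivalent threshold on r (`r_τ = τ/√(df + τ²)`), the per-permutation
edge correlations are obtained with one matrix product, and the suprathreshold
graphs of all permutations are stacked into one block-diagonal sparse graph so
a single connected-components pass labels everything. This makes the
10 000-permutation default and the calibration studies cheap (a 200-cohort
type-I study with 1000 permutations each runs in seconds).

The sweep covers τ ∈ {2.0, 2.2, …, 4.0}. Per condition, the retained component
is the significant one (p < 0.05) at the highest τ whose edge count still
reaches `ceil(min_edge_frac · n(n−1)/2)` — with the default 3% on 61 channels,
55 edges. Across conditions the target dysfunctome is the candidate whose mean
within-component connectivity has the highest Pearson correlation with the
score; ties break toward higher τ, then condition label order, to keep runs
deterministic.

## Targeting

Edge betweenness centrality is computed on the binary component graph shared
by all subjects (raw shortest-path pair counts, equal-length paths split
fractionally), not on subject-weighted graphs: centrality describes the
group-level topology of the dysfunctome, while the individual contributes only
the connectivity ranking. Rankings are normalized as `(rank − 1)/(m − 1)` with
average ranks for ties and the best edge at 1 (a single edge maps to 1.0). The
priority index is the unweighted mean of the centrality ranking and the
connectivity ranking; restoration ranks weak edges high, enhancement ranks
strong edges high, so for any edge
`priority_restoration + priority_enhancement = centrality + 0.5` (up to ties).

Site admissibility: two 3×1 units must not interlock. The default rule rejects
an edge iff either endpoint lies inside the other's return ring or the two
rings share an electrode — the geometric failure mode of a dual-site 3×1
montage. No distance cut-off is implied by the ring rule itself, so a plain
Euclidean minimum-distance rule is exposed as an alternative. Nearest-neighbour
rings break distance ties lexicographically by label, making ring membership
independent of file row order.

The selected target is the highest-priority admissible edge; inadmissible
edges are skipped in priority order and the number skipped is recorded
(`fallback_depth`). Although the two principles reverse only the connectivity
ranking, they *can* select the same edge (an edge dominating the centrality
ranking at the subject's median connectivity wins under both); the package
warns rather than forbids, since the priority formula admits such profiles.

Stimulation montages place ±`intensity` (default 0.5 mA) at the two target
nodes and `intensity/ring_size` of opposite polarity on each of the
`ring_size` (default 3) nearest channels per site; in-phase drives both
centers with the same sign, anti-phase with opposite signs. Currents sum to
zero per site by construction; the per-return current is also reported rounded
to two decimals (0.17 mA at the defaults).

## Outcome metrics

Weighted outcomes are read from the raw PLI matrix: target edge weight, target
node strength (mean row sum of the two target nodes), mean connectivity over
the dysfunctome edges. "Normalized" variants are within-subject z-scores
(sample SD, ddof = 1, configurable): the edge weight against all
n(n−1)/2 edge weights, the node strength against all node strengths, and the
dysfunctome mean as the mean of per-edge z-scores over component edges.

Global metrics are computed on an unweighted graph keeping the
`floor(density·M)` strongest edges (default density 35%; ties at the cutoff
break lexicographically, relevant only for weight-tied synthetic matrices):

- mean clustering coefficient (nodes of degree < 2 contribute 0);
- global efficiency (mean inverse shortest-path length, disconnected pairs
  contribute 0);
- small-worldness σ = (C/C_null)/(L/L_null) with C and the characteristic path
  length L (on the largest connected component) referenced to degree-preserving
  rewired null graphs (10 swap attempts per edge, default 100 seeded nulls) —
  the conventional definition; a graph whose giant component covers < 90% of
  nodes is flagged;
- Newman modularity Q of the best partition over seeded Louvain restarts
  (default 100). Restart semantics make Q monotone in the number of restarts.
  A deterministic greedy agglomerative optimizer was the alternative; seeded
  Louvain with best-of restarts explores more of the partition space at equal
  cost and keeps runs reproducible.

A density sweep (5–50% in 5% steps) reports all four metrics per level;
densities at which σ or Q are undefined (fragmented or too-sparse graphs)
yield NaN rather than aborting.

## Bayesian evaluation

Paired pre/post changes are evaluated with the JZS Bayes factor: a Cauchy
prior (scale 0.707) on the standardized effect δ, so

    BF₁₀ = ∫ f_t(t | ν, δ√n) dCauchy(δ; 0, 0.707) / f_t(t | ν, 0),

with f_t the noncentral-t density, ν = n − 1, evaluated by adaptive quadrature
split at ±10 with explicit tails. The two-sided alternative is used. Posterior
summaries of δ (median, 95% highest-density interval) come from a 4001-point
grid on [−10, 10]. Sequential traces recompute BF₁₀ on the first k
observations (k = 2…n) in input-table order, with the conventional evidence
thresholds 3 and 1/3.

Condition comparisons are implemented as Bayesian *post hoc* paired contrasts
on the within-subject difference of change scores (all pairs). A full Bayesian
repeated-measures ANOVA with model averaging is deliberately not implemented:
the inferential statements of interest are the pairwise comparisons, and the
paired-contrast BF answers exactly those.

Correlations between outcome changes use the exact sampling density of the
Pearson r under bivariate normality (hypergeometric-function form) integrated
against a stretched-beta prior on ρ (width 1 = uniform on [−1, 1]). Both Bayes
factors are validated in the tests against independent fine-grid trapezoid
quadrature (relative error < 1e-6) and against pingouin's closed-form
implementations.

Degenerate inputs are surfaced, not patched: zero-variance difference vectors
raise. One practical caveat: global metrics of densely binarized graphs are
discrete-valued (e.g. global efficiency on a diameter-2 graph), so short
sequential prefixes can be exactly tied; the pipeline omits the sequential
trace in that case and keeps the full-sample BF.

## Synthetic cohorts

The generator emulates the reference study design: 15 subjects, a 61-channel
extended 10–20 cap, severity scores evenly spread over [20, 95] (an
aphasia-quotient-like scale; stored untransformed), theta band with a 7 Hz
carrier, 4-s epochs at 250 Hz, and a planted subnetwork — by default 20 edges
on 8 channels, connected by construction — whose coupling grows linearly with
the severity z-score.

Signal mode: each channel is a unit-RMS narrowband oscillation (band-passed
white noise) plus 1/f-amplitude pink noise. For a planted edge (i, j), channel
j mixes κ × (a copy of channel i's oscillation delayed by a constant analytic
phase, default π/4) with (1 − κ) × its own oscillation,
κ = κ₀ + β·z(severity). The nonzero default lag is essential: PLI is blind to
zero-lag coupling by design, so a planted effect at zero lag would be
invisible. At κ = 1 and zero noise the planted edge's PLI reaches 1 (up to
Hilbert end effects of order 1e-3).

Matrix mode (the fast path for calibration and recovery studies): edge weights
are `μ_e + β_e·z(severity) + ε`, ε ~ N(0, σ), with β_e = 0.08 on planted edges
and 0 elsewhere, σ = 0.06, and per-edge baselines drawn around 0.3; weights
are clipped to [0, 1]. These defaults give each planted edge a population
edge–severity correlation of 0.8 (`β/√(β² + σ²)`). Under β = 0 the per-edge
t-statistics are exactly central-t distributed, which the calibration tests
exploit. No published effect size exists for real severity-predictive EEG
edges; the 0.8 figure is a design choice for the recovery studies, not an
empirical calibration, and recovery results must be read accordingly.

Pre/post mode plants a known node-strength increment: every edge incident to
either target node gains `Δ/(n−1)`, so each target node's strength rises by
exactly Δ at zero noise (these matrices are not re-clipped, to preserve that
exactness; baselines are mid-range so realistic Δ stays in range).

What the generator does **not** emulate: volume conduction and field spread
(channels are spatially independent except planted edges), lesion anatomy,
task-dependent nonstationarity, artifacts beyond amplitude excursions, and
test–retest variability of EEG networks. Passing recovery tests therefore
demonstrate correctness of the statistical machinery under the planted model,
not expected sensitivity on real sensor-space EEG.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline at reduced
Monte-Carlo depth chosen for a single-CPU workstation: 200 null cohorts ×
1000 permutations for type-I calibration, 20 seeds × 500 permutations for
recovery (with the qualifying-size floor set to 16 edges = 80% of the planted
size, the analog of the 3%-of-total retention rule at planted scale),
100-restart/100-null graph metrics reduced to 5–20 where they appear inside
per-subject loops, and 50–100 random graphs/profiles for the brute-force
oracle comparisons. Production defaults (10 000 permutations, 100 nulls,
100 restarts) remain the package defaults.

## Known limitations

- Sensor-space only; no source localization or leakage correction beyond what
  PLI itself provides.
- The admissibility rule operationalizes "sites too close" geometrically; no
  electric-field simulation is performed, and current budgeting is fixed
  rather than optimized.
- The exact small-world normalization and null-model count used by other
  toolboxes vary; σ values are comparable only within a fixed configuration.
- Whether connectivity rankings should use raw PLI or a normalized variant is
  underdetermined; raw PLI is used.
- The Bayesian RM-ANOVA omnibus test is out of scope (see above); only paired
  contrasts are provided.
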