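# Methods

## Networks and metrics

A raw connectome is a pair of co-indexed symmetric matrices per participant:
integer streamline counts `NS` and mean radial diffusivity `RD` (mm²/s),
with `RD` finite and positive exactly where `NS > 0`. An edge is retained
when `NS ≥ NS_thr` ("fewer than `NS_thr` streamlines" excluded, so
thresholds 0 and 1 coincide — count-0 cells are non-edges either way) and
weighted `w = 1/RD` (s/mm²). The retained edge set depends only on the
counts, never on RD; all degree-based results are therefore invariant under
any global rescaling of RD, a property the acceptance suite checks
end-to-end.

"Sparsity" follows the usage of the connectomics literature this pipeline
serves: the fraction of possible edges *retained* (connection density),
averaged over participants. `calibrate_threshold` returns the smallest
integer threshold whose cohort-mean sparsity is at or below a target;
because all participants share one atlas, the cohort mean reduces to a
pooled edge count, and the default sweep calibrates thirteen targets,
0.85 → 0.25 in steps of 0.05. One threshold per target is shared by the
whole cohort. The step of 0.05 is a package choice; the range endpoints are
the analysis convention the pipeline reproduces.

Metrics are computed on induced subgraphs (extraction before metrics), so
degree counts intra-subnetwork edges only. Per node: degree
`k_i = #{j : w_ij > 0}`; strength `s_i = Σ_j w_ij`; weighted clustering in
the Onnela geometric-mean form on max-normalised weights,

    c_i = 2 / (k_i (k_i − 1)) · Σ_{j<h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3},  ŵ = w / max(w),

with `c_i = 0` for `k_i < 2` and all-zero output for an edgeless graph
(whose weight maximum is undefined). This is the convention of the Brain
Connectivity Toolbox for undirected weighted graphs; a `binary` variant is
selectable. Subnetwork means are arithmetic means over member nodes;
isolated nodes remain members and contribute zeros (an exclude-isolated
flag is available). Means equal the means of the reported node vectors to
1e-12 by construction.

The collinearity screen computes, within every (subnetwork, threshold)
cell, Pearson correlations among the three mean metrics across
participants, then walks the fixed retention priority degree > clustering >
strength: a metric is dropped when its |r| against a retained metric
exceeds 0.85 in the majority of cells (zero-variance cells vote to drop and
are flagged). The fixed priority makes the screen deterministic and
reproduces the standard outcome — strength is nearly collinear with degree
(weights per edge vary little relative to edge count) and drops, leaving a
2 metrics × 4 subnetworks = 8-test family.

## Association statistics

For each metric × subnetwork at each sweep point: ordinary least squares of
the metric on [1, schizotypy, age, sex] yields Cook's distances
`D_i = e_i² h_ii / (p s² (1−h_ii)²)`; points with `D > 4 × mean(D)` are
excluded in a single pass (the mean is over finite distances; exact
leverage points are flagged infinite and excluded whenever the cutoff is
finite). On the kept rows, the partial Pearson correlation of score and
metric given [age, sex] is computed by residualising both against
[1, covariates]; the two-sided p value uses the t transform with
`n − 2 − k` degrees of freedom. Benjamini–Hochberg adjustment (via
statsmodels) is applied over the 8-test family at each sweep point
separately, matching per-threshold significance reporting; pooling across
thresholds is deliberately not the default. Sex enters as a 0/1 indicator,
so the demographic screen's sex correlations are point-biserial.

Persistence across the sweep: `robust` if q < 0.05 at ≥ 80% of sweep
points, else `nominal` if p < 0.05 at ≥ 80%, else `none`. The fraction 0.8
is configurable and both fractions are always reported, so the
classification is auditable. Node drivers are computed only for persistent
pairs, at the sweep point closest to sparsity 0.30 (the conventional
scatter-plot operating point), reusing the subnetwork-level exclusion set;
their p values are uncorrected by design and flagged as exploratory.
Zero-variance cells yield explicit NaN records — never silent omission —
and are kept out of the BH family.

Outlier exclusion is re-run independently at every sweep point (each
analysis self-contained); fixing exclusions at one threshold is a
reconstruction choice we did not adopt.

## Synthetic cohorts

The generator stands in for undeposited cohort data and gives every
downstream stage a known ground truth. It emulates:

* **Scores.** Nine SPQ subscales with the published item counts (summing to
  74); each subscale is binomial over its 0/1 items with a shared response
  probability (default 0.168, placing the mean total near 12.4). Totals are
  exact subscale sums and always lie in [0, 74].
* **Demographics.** Age uniform on [18, 55] years, sex Bernoulli(0.657
  female), both independent of the score by construction.
* **Connectomes.** A template fixes per-edge existence probability (uniform
  at the requested density), log-normally heterogeneous expected counts
  (median 40, σ_log = 0.6 — heterogeneity makes count thresholds graded),
  RD mean 0.6e-3 mm²/s and SD 0.05e-3 (physiologically plausible scale),
  and a negative-binomial dispersion of 8 (overdispersed tract counts).
  Given existence, counts are 1 + negative binomial (gamma–Poisson); RD is
  normal truncated strictly positive, defined exactly where the count is
  positive.
* **The planted effect.** Schizotypy is standardised within the cohort to
  z; on every edge incident to a chosen target-node set, `beta_edge` shifts
  the existence logit by `beta_edge·z` and `beta_weight` shifts the RD mean
  by `beta_weight·z` (mm²/s per SD; negative = stronger 1/RD weight).
  `beta_edge = beta_weight = 0` is the exact global null.
  `effect_for_partial_r` converts a desired true partial correlation r of
  the subnetwork mean degree into `beta_edge` by a delta-method
  linearisation of the logistic edge model,
  `β = r √v / (c √(1−r²))` with `c = Σ_affected p(1−p)`,
  `v = Σ_all p(1−p)` over intra-subnetwork pairs — derived from the
  template alone, before any data are drawn. The approximation holds for
  the unthresholded network; count thresholding attenuates it, which is why
  the replicate studies analyse at the loosest sweep point.

One integer seed drives everything through a documented stream split
(`SeedSequence(seed).spawn`: child 0 participants, child 1 connectomes);
identical configs are bit-identical, including written files (floats
serialised with 17 significant digits and re-read with round-trip parsing).

What the generator does **not** emulate: spatial geometry and
distance-dependent connection probabilities, hemispheric symmetry,
subject-level global effects (head motion, scanner drift), trait
overdispersion of SPQ totals (a single response probability gives an SD of
≈ 3.2, tighter than empirical cohorts), or correlated measurement noise
between counts and RD. Passing simulation studies therefore demonstrate
that the pipeline's inferential machinery is correct and well calibrated on
an idealised data-generating process — not that real tractography data meet
these assumptions.

## Atlases and subnetworks

Packaged registries: AAL (90 cerebral areas, left/right interleaved),
Desikan–Killiany (34 cortical areas per hemisphere + 7 subcortical per
hemisphere = 82 cerebral, plus 2 cerebellar hemispheres = 84), and a
20-node toy registry partitioned into four 5-node systems for simulation
work. Registries are immutable; label order is the packaged file order and
subnetwork members are kept in atlas order. The four analysed systems are
fixed by name (default_mode, sensorimotor, visual, auditory). Their default
memberships are reconstructions — assembled so that every node reported as
a driver for a system is a member of that system's default, completed with
conventional resting-state definitions — and are explicitly overridable by
user YAML/JSON, since published node lists for these systems are not
standardised (the defaults include, e.g., middle/superior frontal areas in
the sensorimotor set and thalamus/hippocampus in the default-mode set, as
the driver reports imply).

## Numerical conventions

* Counts must be exactly symmetric integers; RD asymmetry is tolerated to
  1e-12 relative (float noise from upstream writers) and symmetrised by
  averaging; anything larger is rejected. Label permutations between a
  count/RD file pair are an error, never silently reordered.
* The clustering implementation is vectorised over stacked graphs
  (`(..., n, n)` arrays) via an einsum of the cube-rooted normalised
  weights; tests compare it with an explicit triple-enumeration oracle and
  with networkx. Degree and strength agree with brute force bit-exactly on
  the dyadic test grid; clustering agrees to 1e-12 (cube roots of non-dyadic
  rationals cannot match bitwise across summation orders).
* Partial-correlation degenerate cells are detected with a relative
  residual-norm floor (1e-10 of the variable scale) so that exactly
  constant metrics are reported as degenerate rather than producing noise
  correlations from rounding residue.
* CSV outputs are sorted on (subnetwork, metric, threshold, participant)
  with mergesort, making runs byte-stable.

## Known limitations

* **The exclusion rule is anticonservative on clean data.** Deleting points
  with Cook's distance above 4 × mean from the association regression and
  re-testing on the remainder removes the very observations that inflate
  the slope's standard error; on null cohorts with no genuine artifacts the
  per-test false-positive rate roughly doubles, and the family-wise
  any-discovery rate of the 8-test family rises well above the nominal FDR
  level (the acceptance script's `null_any_fdr_rate` quantifies this at the
  chosen seed; disabling the exclusion, `cooks_multiplier=inf`, restores
  nominal behaviour). The rule is retained because it is the procedure this
  pipeline exists to reproduce — in its original use the flagged points
  were data-quality artifacts (isolated nodes, degree outliers), which the
  exclusion records annotate. Users analysing clean data should treat
  exclusion-dependent findings with care or raise the multiplier.
* Persistence across thresholds is not independent evidence: results at
  neighbouring thresholds share almost all their edges, so correlated noise
  can persist (the worked example's `nominal` visual entries show this).
* The generator's independence assumptions (score ⟂ age ⟂ sex; edges
  independent given the template) are idealisations; real cohorts need the
  demographic screen they motivate.
* Node-driver p values are uncorrected; the driver list is descriptive.
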