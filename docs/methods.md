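# Methods

## Morphometry

A muscle's size is summarized by its maximum Feret diameter (maximum
caliper): the largest distance between any two boundary points.  Boundaries
are the outer pixels of 8-connected components above a threshold of
`threshold_fraction` × the image maximum (default 0.14, the conventional
setting for phalloidin-stained tergite preparations), with vertices at
pixel centers, 0-based row/column coordinates.  Because the Feret diameter
depends only on the convex hull, the implementation computes an Andrew
monotone-chain hull and sweeps antipodal pairs with rotating calipers —
exact to floating-point round-off, O(n log n).  Components under `min_area`
pixels (default 50) are discarded as speckle; the default is purely
practical (hot pixels survive any intensity threshold).

Within a hemisegment the *candidate* is the component with the largest
Feret diameter and the *control* the component whose centroid column is
nearest the dorsal midline (user-supplied; defaults to the image center,
since dissection opens the abdomen along the dorsal midline).  The
standardized ratio F_A/F_B is dimensionless, invariant to magnification,
and may legitimately fall below 1.  Left and right hemisegments are
independent data points (the bilateral muscle pair forms independently);
no mixed-effects modeling of within-fly correlation is attempted.
Anatomical segment assignment (A4 vs A5) is input metadata, not inferred.

## Dimorphism statistics

Groups are (sex, segment) cells per species; the two comparisons of
interest are female-A5 vs male-A5 (the dimorphism contrast) and male-A4 vs
male-A5 (segment-specificity control).

* **Gaussian gate.** The original workflow fitted Gaussians to ratio
  histograms by eye, with or without log transformation.  The mechanized
  surrogate is D'Agostino's omnibus skew/kurtosis test per group at
  α = 0.05, first on raw then (if all values are positive) on log values;
  all groups must pass on a common scale.  Groups with n < 8 make
  normality unassessable and route to the nonparametric branch.
* **Parametric branch.** Welch's heteroscedastic F* (Welch–Satterthwaite
  denominator df) plus the Brown–Forsythe F* for the same hypothesis;
  pairwise Games–Howell: t = Δmean / √(s²ᵢ/nᵢ + s²ⱼ/nⱼ), Welch df, adjusted
  p from the studentized-range distribution with k = number of groups and
  q = |t|·√2.  Cross-checked in the test suite against an independent
  implementation (pingouin) and a permutation reference.
* **Nonparametric branch.** Tie-corrected Kruskal–Wallis omnibus; pairwise
  Dunn z tests on pooled ranks with the tie-corrected variance, Bonferroni
  multiplied by the number of comparisons of interest (2).  The published
  tables name only a "multiplicity adjusted P value"; Dunn + restricted
  Bonferroni is this package's documented surrogate, so adjusted p values
  from raw data are not expected to match the published ones digit for
  digit.
* **Call rule.** "+" iff male-A5 mean > female-A5 mean AND adjusted
  p < 0.001, strictly; p = 0.001 yields "−" (the packaged table contains
  exactly this boundary case and the regression test pins it).  Stars: *
  p<0.05, ** p<0.01, *** p<0.001.  The scatter envelope quoted alongside is
  mean ± 3·SD.
* SDs reconstructed from published SEMs use SD = SEM·√n with n the
  hemisegment count.

## Fiber counting

Each fiber's nuclei lie in one longitudinal row, so fibers = rows of
nuclei.  The long axis is the principal direction of the point cloud
(override with `muscle_axis` for bundles wider than they are long).  Row
splitting: project nuclei on the transverse axis, sort, and start a new row
at any gap exceeding `gap_factor` (default 3.0) × a within-row transverse
scale.  That scale is the RMS transverse offset between each nucleus and
its along-fiber nearest neighbour, found under a metric that penalizes
transverse displacement 3× (so the neighbour is the adjacent nucleus of the
same row even when rows sit closer together than nuclei within a row).
For Gaussian jitter the scale is √2 × the jitter SD, giving an effective
split threshold of ≈ 4.2 jitter SDs.

Operating characteristics (measured on the generator): with ~12 nuclei per
row the rule recovers 1–8 rows in ≥ 99% of seeded runs when the row spacing
is ≥ 12× the jitter SD; at spacing ≈ 5× the jitter SD adjacent Gaussian
rows physically overlap and **no** threshold rule is reliable.  Real
nucleus rows are typically much better separated than 5σ, but the rule is
validated only on synthetic layouts — the reference counts in the packaged
table were obtained by eye.

Species comparison: tie-corrected Kruskal–Wallis omnibus (ties are
ubiquitous in small counts), pairwise Tukey HSD on the raw counts, and an
insert-and-absorb compact letter display (groups share a letter iff not
significantly different at α = 0.05).  Tukey HSD downstream of a rank
omnibus is statistically unorthodox; it is retained deliberately because it
is the workflow the reference tables encode, and the caveat stands here.

## Ancestral-state reconstruction

Binary character (0 = absent, 1 = present) on a rooted tree with branch
lengths in expected-change units.  Two-state F81-type kernel

    P_ij(t) = e^(−r t) δ_ij + (1 − e^(−r t)) π_j,   r = μ / (2 π₀ π₁),

normalized so μ is the expected number of changes per unit branch length at
stationarity.  Tip data enter via Felsenstein pruning with per-node
rescaling; unknown tips ("?") carry partials (1, 1); multifurcations are
handled natively; the root is weighted by (π₀, π₁) — the root state is
always one of the two states, never null.  Node marginals come from the
standard up–down pass and equal, at the root, the renormalized
prior-weighted root partials (a test pins this identity, and enumeration
over all internal assignments pins both quantities on small trees).

Inference is Metropolis random-walk on (logit π₁, log μ) with a
Dirichlet(0.5, 0.5) prior on (π₀, π₁).  The reference workflow estimates
only the frequencies; on a fixed tree the overall rate is not identified by
the single binary character unless constrained, so μ carries a weakly
informative log-normal(0, 1) prior, and a fixed-rate mode (`fix_mu = 1`)
provides the closest emulation of the frequency-only analysis.  "Equal
rates among sites" is vacuous for one character and recorded only.
Defaults: 50 000 generations, 4 chains (reduced from 10 for desk-scale
runs; flag-overridable), sampling every 100, 25% burn-in, proposal SD 0.8
(acceptance ≈ 0.5 on the packaged data).  Runs are bit-reproducible given
the seed; chains use independent seed streams.  Node posteriors are the
equal-weight average of marginals over pooled post-burn-in samples.  Across
a tree sample, nodes are matched by tip-set bipartition; a bipartition's
posterior averages over the trees containing it and its support is the
containing fraction (trees all reuse the same settings and seed, so a
degenerate sample of identical trees reduces exactly to the single-tree
analysis).  Whether the published pies averaged over the 10 000 input trees
or used the consensus alone is ambiguous in the source; both modes are
provided.

Calibration, verified by the test suite and the acceptance script: on a
saturated star tree the π₁ posterior matches the conjugate
Beta(k+0.5, n−k+0.5) answer within Monte-Carlo error; on 100-tip Yule
simulations at (π₁ = 0.7, μ = 0.5) the 95% credible interval covers the
truth in ≥ 90% of replicates.  A caution on root-state reconstruction:
unit-rate Yule trees with 100 tips are ≈ 4.2 expected-change units deep, so
even a modest μ = 0.3 implies > 1 expected change per root-to-tip path;
the root posterior is well calibrated (binned reliability matches, and
E[max(p, 1−p)] ≈ 0.69 equals the observed modal accuracy), which means
modal root recovery much above ~70% is unattainable in that regime — a
property of the data, not of the sampler.

## Synthetic data

* **Ratio samples** — Normal(mean, SD) truncated at > 0 (log-normal mode
  with matched moments for the log branch), two hemisegments per fly,
  sides independent by default with an optional within-fly correlation
  knob.  Calibration from a summary table uses SD = SEM·√n.  Gaussian
  ratio noise mirrors the Gaussian histogram fits of the source workflow.
* **Images** — rotated capsules/rectangles with exact Feret ground truth
  (capsule: its length; rectangle: its diagonal), optional Gaussian blur
  and additive noise; overlapping primitives flag a warning.  End-to-end,
  thresholded Feret measurements stay within 3 px of truth at ≤ 1 px blur
  and ≤ 2% noise.  No attempt is made to simulate confocal texture,
  autofluorescent oenocytes or staining artifacts, so segmentation results
  on these images bound only geometric, not photometric, errors.
* **Nuclei** — jittered row grids (see fiber counting above).
* **Trees** — Yule process at unit speciation rate; the hold time at n
  lineages is included, so E[root-to-tip depth] = Σ_{k=2..n} 1/k exactly
  (tested against that closed form).
* **Traits** — forward simulation of the same F81 kernel recording all
  internal node states; transition frequencies on a branch match P_ij(t)
  (chi-square goodness-of-fit in the suite).

All generators are pure functions of (parameters, seed).

## Packaged reference data

The per-species dimorphism table (42 *montium*-group species: summary
statistics, test family, adjusted P values as printed, "+/−" call) and the
fiber-count table (19 dimorphic species + 2 outgroups) are transcribed from
the published tables; load-time validation enforces row counts and
min ≤ mean ≤ max per statistics block.  One printed min/max pair
(watanabei fiber counts, "3 1") is stored corrected to (1, 3).  Printed
inequalities are mapped to numeric surrogates preserving the call rule
("<0.001" → 0.0005, ">0.99" → 0.995).  The 49-taxon fixture topology (42
ingroup + 7 outgroup) is a transcription of the consensus figure plus
standard *montium*-group relationships; its branch lengths are unpublished
and set to 1, so every conclusion drawn on this tree is qualitative
(majority state) only.

Raw per-fly measurements were never deposited, so the published adjusted P
values cannot be recomputed from data.  Re-simulating measurements from the
rounded table moments and re-running the battery reproduces the "+/−" call
for ~36/42 species per run: the discrepancy is concentrated in species
whose printed adjusted P lies in (0.001, 0.01], where SEMs rounded to 0.01
already shift the recomputed p across the 0.001 boundary.  The exact
regression route (printed means + printed P values → calls) reproduces all
42 published calls.

## Numerical notes

* Pruning rescales partials at every internal node and accumulates the log
  scale; zero-likelihood configurations (e.g. μ = 0 with conflicting tips)
  return −∞ rather than raising.
* Welch/Brown–Forsythe with all-constant equal groups return p = 1 by
  convention; Games–Howell with zero pooled SE returns p = 1 for equal
  means and p → 0 otherwise.
* The compact letter display inserts-and-absorbs and then verifies its
  defining invariant (share a letter ⇔ not significantly different) by
  construction; a property test hammers random significance matrices.
* Adjusted p values are clipped to [0, 1] and are never smaller than their
  unadjusted counterparts.
* CSV schemas are versioned in `molmorph.io`; readers name the missing
  column in their error.  Coordinates 0-based; intervals half-open; UTF-8
  with "." decimals.
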