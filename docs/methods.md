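# Methods

This note documents the models implemented in `cagesym`, the parameters
that matter, the design choices made where the design was genuinely open,
and what the synthetic data do and do not establish about real data.

## Study design being modelled

The unit of replication is the **cage**: a mesh enclosure over a branch
into which 12 lab-reared, initially aposymbiotic second-instar nymphs are
released (10 cages per treatment, one per tree). Treatments differ in the
symbiont sources available (a symbiont-fed control plus open treatments).
At harvest, surviving bugs' life stages and per-cage mortality are
recorded; up to 7 survivors per cage are tested for the symbiont by
diagnostic PCR, aiming for at least 2 bugs per juvenile instar present
and 2 adults per sex. Cages from which more than 12 bugs are recovered
(wild intrusion) are excluded outright. Free-roaming wild adults sampled
at the same site serve as the comparison group for symbiont diversity.

## Synthetic data generator

The generator's defaults are the study conditions; they are fixed once
and the tests are run against them.

- **Acquisition.** Each caged bug acquires the symbiont independently
  with its treatment's probability (defaults: 0.75 for the fed control,
  0.30 for the open treatments — the first field season's rates).
- **Development.** Endpoint stage is reduced to a single late-stage
  Bernoulli conditioned on symbiont status (defaults 0.9 symbiotic,
  0.15 aposymbiotic), because the downstream analysis only uses the
  early (instar 3–4) / late (instar 5–adult) coding. A full
  stage-duration model would add parameters the analysis never sees.
- **Mortality.** Deaths per cage are Poisson with the treatment's rate
  (capped at the census), matching the Poisson model fitted downstream.
- **Communities.** Each symbiont-positive bug hosts k ∈ {1..5} lineages
  (default weights 0.35/0.30/0.20/0.10/0.05) drawn uniformly without
  replacement from its origin's pool: 3 lineages for caged bugs, 14 for
  wild bugs — the observed dominant/total pool sizes. The first-drawn
  lineage is dominant and receives at least `dominant_fraction`
  (default 0.85) of the bug's reads; every hosted minor lineage receives
  at least one read so that presence equals hosting. Wild bugs are always
  symbiont-positive, reflecting the near-impossibility of aposymbiotic
  survival to adulthood in the field.
- **Reads.** Per-bug depth is uniform on 12 000–30 000 (the plateau
  depth of 9123 must be comfortably exceeded for most samples; real
  depth distributions are not pinned by the study, so this is a free
  simulation parameter). Lineage reads are split
  uniformly-multinomially over the lineage's ASVs. Row sums equal the
  drawn depth exactly. Aposymbiotic bugs yield all-zero rows, which the
  rarefaction step then drops — emulating samples that fail sequencing.
- **Phylogeny.** A pectinate backbone with inter-lineage stems of at
  least `between_scale`/2 each carries one compact random subtree per
  lineage whose tip-to-tip diameter is rescaled to equal `within_scale`
  exactly. Any two tips of different lineages are therefore at least
  `between_scale` apart while within-lineage distances never exceed
  `within_scale`; with `within_scale < h < between_scale` the true
  partition is recoverable at threshold h *by construction*, which makes
  the agglomeration ground truth exact rather than statistical.
- **Climate.** Sinusoidal daily cycles (temperature peaking at 15:00,
  humidity at 05:00) with per-day peak noise and optional per-reading
  noise; 5-minute cadence for the first year, hourly for the second.
  Humidity is clipped to [0, 100].

What the generator does **not** emulate: sequencing error and chimeras
(no FASTQ level), taxon-specific read biases, uneven lineage frequencies
within a pool, spatial structure among cages, or fecal-transmission
dynamics. Passing tests therefore demonstrate correctness of the
*statistical machinery* under a clean community model, not robustness to
denoising artefacts.

## Rarefaction and agglomeration

Rarefaction is a multivariate-hypergeometric draw (without replacement)
to exactly `depth` reads; samples below depth are dropped and logged.
Agglomeration clusters the cophenetic distance matrix (exact tip-to-tip
path sums) with average linkage by default — the common default of
tip-level agglomeration tools; complete and single linkage are exposed
as options since only the threshold, not the linkage, is conventionally
reported. The dendrogram is cut at height h (default 0.1, the
species-level convention for these bacteria); each cluster's counts are
summed, conserving per-sample totals exactly, and the cluster is named
after its **archetype**: the member ASV with the largest total count
across samples, ties broken by lexicographically smallest id.

Whether rarefaction is applied before or after agglomeration is not
pinned by convention; the pipeline default is rarefy → agglomerate with
a flag to swap. Count conservation under collapse holds either way.

## The cluster-aware permutation test

Statistic: d = S(A) − S(W), where S is group richness (lineages present
in the union) of the one-per-cage selection A and the full wild set W.
Each of B iterations draws a fresh A_i, computes d_obs,i, pools A_i with
W, re-randomizes which |A_i| pool members carry the "caged" label, and
computes the paired d_null,i. One-tailed p-values count iterations with
d_null,i ≤ d_obs,i (caged-lower; mirrored for caged-higher), with the
add-one finite-sample correction (1 + k)/(B + 1) so p is never 0; the
raw proportion is available via `PermConfig(correction=False)`. The
two-tailed p doubles the smaller tail and caps at 1.

Numerical notes: the test is fully vectorized over iterations (boolean
presence matrix, ~10⁴ × 48 index array), so 10 000 iterations on the
study's geometry run in tens of milliseconds. `exact_small_oracle`
enumerates all label assignments for pools of at most 12 bugs with the
identical statistic and tail conventions, and anchors the Monte-Carlo
implementation in tests.

**Calibration caveat.** Group richness is a small integer. When the
pools are small enough that unions saturate (19 bugs from a 14-lineage
pool almost always cover 13–14 lineages), the paired comparison has a
large tie mass, and the standard extremeness count (ties included)
makes the test markedly conservative: in 500 simulated null datasets at
the study's geometry the two-sided rejection rate at α = 0.05 was 0.
Super-uniformity (P(p ≤ α) ≤ α) holds — the type-I error is controlled,
never inflated — but the test is far from exactly calibrated at these
conditions, so small p-values are trustworthy while moderate ones
understate the evidence. Power at the study's effect geometry (caged
pool of 3 vs wild pool of 14) is essentially 1.

## Cage-level GLMs and contrasts

Both GLMs use cell-means coding of the single treatment factor fitted by
IRLS (tolerance 1e-8 on coefficients, ≤ 100 iterations), so coefficients
are per-group means on the link scale.

- **Proportions (quasibinomial).** Cage-level successes/trials
  (positive-of-tested, or late-of-surviving), logit link. Dispersion
  φ = Pearson χ²/(N − k). Treatment term: F = (Δdeviance/(k−1))/φ on
  (k−1, N−k) df — the drop-one quasi-likelihood F test. A level with all
  successes or all failures is a boundary (separated) estimate: the
  linear predictor is capped at ±30, the level is flagged, and its
  contrasts are marked indeterminate rather than reported with
  meaningless standard errors.
- **Mortality (Poisson).** Per-cage death counts, log link; treatment
  assessed by the likelihood-ratio χ² (deviance drop against the
  intercept-only model, k−1 df), as is standard for Poisson counts.
- **Post-hoc contrasts.** All level pairs, Wald z on the link scale with
  dispersion-scaled covariance (dispersion fixed at 1 for the plain
  Poisson model), Holm step-down adjustment, and a compact letter
  display built by insert-and-absorb at α = 0.05. Holm-adjusted Wald
  contrasts stand in for Tukey's HSD: with a single factor and modest k
  they give the same qualitative separation while avoiding
  multivariate-t machinery; the substitution is recorded in every
  report's metadata. Indeterminate (boundary) pairs are treated as
  not-separated in the letter display.

## Mann-Whitney U

U counts pairs with x > y plus half the ties (computed via mid-ranks);
W additionally reports the first sample's rank sum, U + n₁(n₁+1)/2,
because rank-sum conventions differ across ecosystems. The two-sided p
is exact — full enumeration of label assignments, doubling the smaller
tail — when min(n, m) ≤ 8 and the assignment count is at most 5·10⁵;
otherwise a normal approximation with tie-corrected variance and 0.5
continuity correction is used. For continuous data at small-to-moderate
sizes the two agree to well under 0.02; with heavy ties in very small
samples the normal approximation can deviate by several hundredths,
which is why exact mode is preferred whenever feasible. If every pooled
value is identical the variance is zero and p = 1.

## Determinism

All randomness flows from one root seed through named substreams
(phylogeny / experiment / reads / climate / subsample / rarefy /
permtest), so stages are independently reproducible and adding
iterations to one stage does not perturb another. Writers use fixed
column orders and float formats; the run manifest records SHA-256
digests of every artifact, and two runs with the same configuration and
seed are digest-identical.

## Problem sizes used in the test suite

The statistical checks run at the study's own scale: 19 cages of 3
sequenced bugs versus 29 wild bugs for the permutation analyses (500
null replicates, 200 power replicates, 10 000 iterations each); 100
random phylogenies up to 64 tips for partition recovery; 500 replicates
of the 4 × 10 × 12 field design for GLM recovery; 1000 instances for
rarefaction moments and Mann-Whitney accuracy. These sizes make the
whole suite run in about a minute while keeping Monte-Carlo standard
errors well inside the asserted tolerances.

## Known limitations

- Uniform lineage frequencies within pools understate the dominance
  structure of real communities; richness saturation (see the
  calibration caveat) would be milder with uneven frequencies.
- The quasibinomial F test relies on the Pearson dispersion estimate,
  which is noisy with few cages per treatment.
- The compact letter display reflects pairwise decisions only; it is not
  a simultaneous confidence procedure.
- Tree inference, phylogenetic placement, and denoising are out of
  scope: the phylogeny is an input (or simulated), never estimated.
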