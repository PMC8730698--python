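# Methods

## Scope and data model

`comprof` analyses complexome-profiling experiments: a BN-PAGE lane is cut
into S gel slices (slice 1 at the top of the gel, largest apparent mass),
each slice is digested and protein-group ion intensities are quantified per
slice by LC-MS/MS. The data are a dense nonnegative tensor indexed by
(protein, slice, sample), with a design mapping samples to (group,
replicate). S is a property of the dataset, not a constant; the motivating
two-genotype study used S = 36 with three biological replicates per
genotype, and those are the package defaults wherever a ready-made scenario
is offered.

Missing values are stored as exact 0, the convention of protein-group
intensity exports. There is no separate missingness channel: "detected in a
replicate" means the protein's summed intensity over all S slices in that
replicate is nonzero, and zeros enter means, standard deviations and sums
as ordinary measured values. This is the simplest model consistent with the
export format; it slightly biases group means downward where dropout is
frequent, which is visible in the parameter-recovery results below.

## Normalization

Lane loading differs between replicates even when equal protein amounts are
loaded. Each sample's correction factor is its total ion intensity
(summed over all proteins and slices) divided by the arithmetic mean of all
samples' totals; every intensity is divided by its sample's factor. After
normalization every per-sample total equals the pre-normalization grand
mean (asserted to 1e-9 relative in the tests), and normalizing twice leaves
all factors at 1.

Two consequences worth knowing:

* Normalization is computed on the matrix as loaded, *before* the
  proteotypic filter, so dropping non-proteotypic proteins afterwards does
  not change the factors.
* A sample with zero total raises an error rather than passing through with
  factor 1 — an empty lane signals an upstream defect, not biology.

Proteins identified only by shared (non-proteotypic) peptides are then
discarded; their intensities cannot be attributed to a single protein
group.

## Migration profiles and differential statistics

A group profile is the per-slice mean across the group's replicates, with
the n−1 standard deviation (0 when n = 1). For heat maps each profile is
max-scaled — divided by its own maximum so the peak slice is exactly 1; an
all-zero profile is left unchanged. Row order for heat maps comes from
agglomerative clustering (average linkage, Euclidean metric on max-scaled
profiles); scipy's deterministic linkage breaks ties by input order.

Two statistics are computed per protein between a reference group a and a
test group b, wrapped in the `DifferentialAbundanceModel` /
`DifferentialAbundanceResults` pair:

* **Welch test on slice-sum totals.** Each replicate contributes the sum
  of its S normalized slice intensities; the two groups of totals are
  compared with Welch's unequal-variance t-statistic
  t = (x̄_a − x̄_b)/√(s²_a/n_a + s²_b/n_b), Welch–Satterthwaite degrees of
  freedom, and a two-sided p-value. Degenerate inputs: both variances zero
  with equal means gives p = 1; with unequal means, t = ±∞ and p = 0.
  No multiple-testing correction is part of the procedure; the results
  table carries a clearly-labelled Benjamini–Hochberg column (`p_adj_bh`)
  as a convenience extension.
* **Amplitude-adjusted distance.** d = ‖ā − b̄‖₂ / max(max ā, max b̄)
  between the two group-mean profiles. Dividing by the joint maximum makes
  d invariant under common positive rescaling (the point of the
  adjustment: shape difference, not abundance difference), symmetric, zero
  iff the mean profiles are identical, and bounded by √S. The denominator
  is the maximum over *both* group means, which yields a single distance
  per protein and exact scale invariance; a per-group-reference variant
  would produce two numbers and lose the invariance.

### Calibration of the Welch test at n = 3

Two empirical facts, both verified against scipy's independent
implementation (p-values agree to 1e-12):

1. At the study design of 3 vs 3 replicates the Welch–Satterthwaite
   approximation makes the test *conservative* even under a normal null:
   the measured size at α = 0.05 is ≈ 0.034, for this implementation and
   for scipy alike. With n = 30 per group the approximation is accurate
   and the measured size is ≈ 0.05.
2. On skewed (log-normal, CV 0.2) replicate totals at n = 3 the test is
   further conservative (measured size ≈ 0.03).

Neither effect is an implementation artefact, and neither is
anti-conservative: p < 0.05 calls at n = 3 are, if anything,
under-claimed. The acceptance suite therefore checks an upper bound on the
size at 3 vs 3 and two-sided nominal calibration at n = 30.

## Ratio tables

A subunit's abundance in a group is its summed normalized intensity over a
scope's slices — the whole lane or one named band — pooled over all of the
group's replicates (summed, not averaged; a common replicate count cancels
in the ratio). The ratio is test/reference per subunit; a subunit with zero
scoped total in either group yields the sentinel `nd` (not detected) and is
excluded from the complex median. Medians use the even-n convention (mean
of the two central sorted values). Computation keeps full precision;
reported values are rounded half-up to two decimals only in the display
column, mirroring standard report tables (0.985 → 0.99).

The package embeds the published per-subunit mutant/wild-type ratios of the
Chlamydomonas *lpa2* complexome study (ProteomeXchange PXD023443) in
`comprof.datasets`; the test suite and `scripts/acceptance.py` recompute
every published per-complex and per-band median from them exactly,
including the `nd` exclusion rule (the RC47 band median is over the 7
detected subunits).

## Screens

**Co-migration screen.** Candidate proteins for association with a
reference complex must satisfy four criteria: (i) a migration profile
resembling the reference subunits in *both* groups, (ii) detection in at
least `min_replicates` (default 2) replicates of at least one group,
(iii) a predicted chloroplast transit peptide, and (iv) conservation in
photosynthetic organisms. Criteria (iii)/(iv) are consumed as boolean
annotations; the package predicts neither. Criterion (i) needs a numeric
rule: the consensus profile is the mean of the max-scaled group-mean
profiles of the detected reference subunits (max-scaling first gives every
subunit equal weight), and similarity is the Pearson correlation between
the max-scaled candidate and the consensus, thresholded at 0.8 in both
groups by default. Correlation against a constant vector is 0 by
convention. The threshold is a parameter, not a claim: the original screen
was expert visual inspection, and a correlation cut-off of 0.8 in both
groups is a reasonable operationalization whose exact candidate list on
real data will depend on the cut-off.

**Band-enrichment screen.** For one named band (e.g. the RC47 band),
`band_fold` = band total in the test group / band total in the reference
group; a protein absent from the reference band but present in the test
band gets infinite fold. Candidates pass fold ≥ `min_fold` (default 4 —
the motivating enrichment was ~6-fold, so 4 leaves margin) plus criteria
(ii)–(iv). Both screens are deterministic, permutation-invariant up to a
protein-id tie-break, monotone in their thresholds, and report
per-criterion failure reasons for every evaluated protein.

## Synthetic data generator

The generator exists to give every pipeline stage a ground truth. A
protein's expected profile in group g is a Gaussian mixture over slice
index k:

    E[x_k] = amplitude × Σ_states occupancy_g(state) ×
             exp(−(k − center)² / (2·width²))

Observed intensities multiply the expectation by a per-sample scale factor
(emulating unequal lane loading), then by unit-mean multiplicative
log-normal noise with σ_log = √(ln(1 + CV²)) — the standard noise model
for ion intensities; additive Gaussian noise was rejected because it
produces negatives — and finally zero cells independently with the dropout
probability. All randomness flows from the single seed passed to
`simulate_experiment`; the same seed reproduces the matrix bit-identically.

Parameter choices and what they mean:

* **Band width.** The generic default is σ = 0.7 slices (a band narrower
  than one slice). The ready-made study scenarios use σ = 0.25: the
  closest bands of interest sit 2 slices apart (monomer at 15, RC47 at
  17), and with σ = 0.25 the cross-bleed between them is exp(−32) ≈ 1e-14
  of the peak, so a noiseless run recovers planted band ratios to better
  than 1e-9. With σ = 0.7 the ~1.7% bleed between those two bands would
  contaminate the strongly-divergent RC47 ratio by several percent —
  worth remembering when building custom scenarios with adjacent bands.
* **Study scenario.** `default_study_scenario()` has 36 slices, 3 + 3
  replicates, and: a PSII-like complex (8 subunits, amplitudes 0.25–1.2
  × 10⁶) whose four assembly states (slices 4/10/15/17) carry
  mutant/wild-type multipliers 0.07, 0.27, 0.60 and 6.05; an unchanged
  complex; a complex increased 1.29-fold; background singletons; a planted
  co-migrating candidate sharing the PSII ladder with correct annotation
  flags; shifted-peak and flag-failing decoys; three band-17-enriched
  proteins; and two non-proteotypic proteins. Defaults are CV 0.2 and
  dropout 0.05. Per-sample scale factors (0.8–1.2) emulate unequal
  loading.
* **Lane-total balance.** The two genotypes' expected lane totals are
  balanced exactly by a free antenna-pool protein with higher occupancy in
  the mutant (unassembled antenna accumulates when photosystem assembly
  stalls). This mirrors the experimental premise of equal protein loading
  per lane. It is not a cosmetic choice: total-ion normalization equalizes
  lane totals, so any genuine difference in expected totals between
  genotypes would tilt *every* downstream ratio by the totals ratio.
  Simulations that plant unbalanced totals are simulating a violated
  normalization assumption.

What the generator does not emulate: peptide-level sampling, chromatography
or spectral noise, intensity-dependent missingness (dropout here is
uniform, while real dropout concentrates at low intensities), correlated
noise across slices, or band-shape asymmetry. Passing recovery tests on
this generator therefore demonstrates correctness of the pipeline's
arithmetic and decision rules under the stated model, not robustness to
every pathology of real gels.

## Recovery results computed by the test suite

* Noiseless study scenario: per-band PSII medians equal the planted
  multipliers to 1e-9; the whole-lane medians for the unchanged and
  increased complexes equal 1.00 and 1.29.
* CV 0.2, dropout 0.05, 20 seeds: the across-seed median of each band's
  estimate is within ±20% of the planted multiplier. Single seeds can
  stray further on one band (dropout of a band-slice cell removes a third
  of a member's pooled total, making per-seed band medians heavy-tailed);
  the per-seed spread is part of the test output.
* Screens at default thresholds, 20/20 seeds: the planted co-migrating
  candidate is the *only* protein returned by the co-migration screen, and
  the planted trio is exactly the set returned by the band screen on the
  background-plus-planted scenario; decoys fail with the expected
  per-criterion reasons.
* Planting per-sample scale factors drawn from [0.5, 2] changes raw totals
  but leaves all normalized ratio outputs identical to 1e-9.

## Numerical and interface choices

* Slice indices are 1-based from the top of the gel so band numbers match
  gel annotation verbatim; arrays are 0-based internally.
* Intensity TSVs round-trip exactly: written with 17 significant digits,
  read with pandas' round-trip float parser.
* Ratio display rounding is decimal half-up, two decimals; medians are
  computed on unrounded ratios.
* The full pipeline writes a manifest (package versions, parameters, input
  SHA-256 checksums, output list); re-running with the same inputs and
  configuration reproduces all numeric outputs byte-identically.

## Known limitations

* The co-migration similarity threshold is a proxy for expert inspection;
  candidate lists on real data are threshold-sensitive near the cut-off.
* The Welch test at n = 3 is conservative (see above); interpret p-values
  near 0.05 accordingly.
* `nd` conflates "not detected" with "below detection"; a subunit present
  but weak in one group is excluded from band medians rather than
  contributing an extreme ratio.
* No peptide-to-protein inference, FDR control, spectrum processing, or
  transit-peptide/conservation prediction: those enter only as annotations.
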