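# Methods

## Data model and coordinates

Probes are 1-based genomic midpoints on autosomes "1".."22" (sex
chromosomes are excluded throughout: paired male/female dosage on X/Y
is confounded by subject sex, not copy-number state). Event and locus
intervals are 1-based inclusive; a probe belongs to an interval iff
start ≤ position ≤ end. On disk, BED-style files are 0-based half-open;
conversion happens only in `cgh_io`. The central container is the pair
ratio matrix: probes × pairs of log2(dose_case / dose_control), NaN for
missing measurements. Probes missing in more than 20% of pairs are
dropped at read time (the threshold is a pragmatic default; the
remaining NaNs are ignored by the probe-wise tests and treated as null
signal by the interval detector).

## Synthetic-data generator

The generator emulates a direct two-color case/control hybridization:
each of 48 pairs (default) co-hybridizes one case against its matched
control, case always in the numerator (fixed dye orientation; dye swaps
are out of scope).

* **Probe map** — probe midpoints drawn uniformly without replacement
  per chromosome, allocated proportionally to chromosome length by
  largest-remainder apportionment. Default genome: 22 autosomes with
  lengths shrinking linearly 250→47 Mb, a deliberately simple stand-in
  for a human autosome set.
* **Events** — integer copy state *c* in the carrier cells, carrier
  cell fraction *f* ∈ (0, 1]; the effective relative dose is
  (f·c + (1−f)·2)/2. f = 1 gives constitutional events; f < 1 dilutes
  the log2 signal toward zero (somatic mosaicism). Overlapping events
  on one subject multiply their dose effects with a logged warning.
* **Noise** — per-probe i.i.d. Gaussian on the log2 scale with a
  per-pair SD drawn from U(0.10, 0.25) by default, mimicking
  array-to-array quality spread; the segmentation stage must recover it
  blind. An optional slow sinusoidal baseline ("wave") can be added to
  exercise the fuzzy-zero correction. No modeling of GC waves proper,
  probe-specific response, saturation or spatial artifacts — so passing
  tests demonstrate correctness of the statistical machinery under the
  stated noise model, not robustness to every real-array artifact.
* **qPCR plates** — single-efficiency TaqMan model: CT = ct0 −
  log2(dose) + N(0, σ_CT), quadruplicate wells, an internal-control
  assay at fixed dose 1.0 per (sample, region). Amplification-efficiency
  curves are not modeled.

Everything is reproducible bit-for-bit from a single integer seed.

Where simulation studies need a mosaic fraction the defaults use
f ∈ {0.3, 0.5}; fractions in the 0.1–0.5 range are what a
brain-mosaicism study would plausibly encounter, and 0.5 is the
smallest fraction at which a one-copy event remains comfortably above
the detector's fuzzy-zero floor at typical noise (see below).

## Interval detection

A documented, deterministic surrogate for proprietary
maximal-scoring-interval detectors (the ADM-2 family), with the same
contract: quality-weighted interval score, sensitivity threshold 6,
fuzzy-zero suppression, centralization.

* **Noise scale** — DLRS: robust SD (IQR/1.349) of adjacent-probe
  differences divided by √2, per pair per chromosome, floored at 1e-6.
  The IQR basis keeps breakpoints from inflating the estimate.
* **Centralization** — the pair's values are histogrammed with bin
  width σ/4 (bins anchored so zero is a bin center); the mode is
  refined as the median of values within 2σ of the tallest bin, and
  subtracted iff |mode|·√n/σ ≥ 6. The local-median refinement is
  needed because a raw histogram-mode estimate is quantized to σ/4,
  which at n ≥ 1000 exceeds the decision threshold and would re-center
  already-centered data by bin noise.
* **Scores** — S = |weighted mean| · √(Σw) / σ (weights default to 1;
  per-probe quality weights are accepted but no public quality data
  exists to calibrate them). With fuzzy zero on, an interval must also
  clear S′ = |mean| / √(σ²/Σw + σ_g²), where σ_g is estimated once per
  pair as the robust SD of means of consecutive non-overlapping bins of
  10 probes (within chromosomes). On white noise σ_g ≈ σ/√10; its role
  is to cap the score of arbitrarily long, low-amplitude intervals at
  |mean|/σ_g, so an event is detectable regardless of length only if
  its amplitude exceeds ~6·σ_g ≈ 1.9σ. This floor is the binding
  constraint for low-fraction mosaics.
* **Extraction** — greedy: among all intervals with S ≥ τ (and S′ ≥ τ
  if fuzzy zero is on), take the highest S; ties prefer the longer
  interval, then the smaller start index; remove its probes and repeat
  on the remaining contiguous runs. Because runs are independent, the
  recursive per-segment implementation returns the same call set as
  literal global iteration; calls are reported sorted by position and
  never span chromosomes. Equivalence with exhaustive O(n²) enumeration
  is asserted over 100 random instances in the test suite. Ranking uses
  the plain score S, with the fuzzy score acting as an admissibility
  filter; ranking by S′ instead would reorder only near-tied calls.

## Two-stage selection

* **Penetrance summary** — per probe, the count of pairs whose calls
  cover it, split by direction (G gains, L losses).
* **Selection 1** — flag probes with |G − L| ≥ 4 (`diff` rule); merge
  maximal runs (gap tolerance default 0) into candidate loci. The
  alternative `exclusive` rule — at least 4 calls in one direction and
  none in the other — is exposed as an option; it reads the differential
  criterion as requiring fully concordant calls and is the stricter of
  the two.
* **Selection 2** — per member probe, a two-tailed one-sample *t*-test
  of the pairs' log2 ratios against 0, computed in the log domain
  (`t.logsf`) so that probes beyond double-precision p-values still
  cumulate correctly; a KS test against a Gaussian with the sample mean
  and SD is reported descriptively (`frac_gaussian` per locus), never
  used as a filter. Per locus: mean_log2 = unweighted mean of per-probe
  means, cum_neglog10p = Σ −log10 p over non-degenerate probes
  (degenerate = all-identical values; such probes are excluded with a
  warning). A locus passes iff cum_neglog10p ≥ −log10(α / n_loci) with
  n_loci the number of stage-1 loci actually tested in the run.
* **Calibration caveat** — the cumulated product of p-values grows with
  locus size and neighboring probes share segment-level signal, so the
  procedure is anti-conservative for multi-probe loci as a formal
  combined test. It is retained as the primary statistic because it is
  the screen being implemented; Fisher's combined chi-square p
  (`fisher_p`, independence assumed) is emitted alongside as the
  calibrated reference. In fully null simulations stage 1 already
  requires a four-pair call coincidence at one probe, which makes
  stage-2 false positives rare (asserted empirically in the suite).
* **Effect size** — OR = 2^mean_log2, the linear-scale case/control
  fold change (reported to 2 d.p. in tables).

## Annotation

A locus is flagged as overlapping the common-CNV catalog iff some
catalog interval shares ≥ 1 base with it (configurable
`min_overlap_bp`; abutting intervals share zero bases). The any-overlap
default is the weakest defensible criterion; reciprocal-overlap
fractions can be imposed by raising `min_overlap_bp`. No catalog is
shipped — population CNV reference sets are user-supplied BED.

## qPCR quantification and validation

ΔCT = mean CT_target − mean CT_internal-control per (sample, region);
ΔΔCT subtracts the calibrator ΔCT, taken as the **control-group median
ΔCT within each region** — a robust stand-in for a known-diploid
reference when no designated calibrator sample exists (the choice is
exposed as `calibrator_rule`). Copy number cn = 2·2^(−ΔΔCT); replicate-
level copy numbers pair target replicate r with internal-control
replicate r on the same plate position.

* **Paired design** — two-way fixed-effects ANOVA (disease + pair,
  type-II SS) on replicate-level cn; fixed effects because pairs are
  the deliberately sampled units here. A constant response returns
  p = 1 by convention.
* **Group design** — chi-square (Pearson, no continuity correction) on
  integer-rounded copy classes (rounding half away from zero; classes
  with expected count < 1 are pooled into their nearest neighbor until
  all expectations reach 1 or two classes remain) × group, plus a
  two-sided Mann–Whitney U with normal approximation and tie
  correction on the raw values. A single surviving class marks the
  chi-square degenerate.
* **Region comparison** — per pair and region, replicate-level
  case/control cn ratios; two-way ANOVA (region + pair) on the ratios
  asks whether the dosage aberration differs between brain regions
  (a regional difference suggests a later somatic origin; a shared one
  is consistent with germline or early developmental timing).

## Numerical choices and degenerate inputs

σ floors at 1e-6 (zero-noise input stays finite); t-test p-values are
propagated as −log10 p from `logsf`; all-identical probe vectors are
flagged degenerate rather than producing 0/0; empty ANOVA cells raise
with the cell named; non-finite ratios entering the detector are
treated as null signal (log2 = 0) with a warning; BED records with
start ≥ end are rejected with a warning rather than aborting the read.

## Problem sizes used in the automated checks

The test and acceptance suites run desk-scale versions of the study
design: the demonstration fixture uses 1000 probes / 8 pairs; null
calibration uses 1000–10⁴ probes × 48 pairs; the mosaic-recovery study
uses 100 replicates × 48 pairs × 600 probes on two chromosomes with a
14 Mb planted event (~40 probes), at σ = 0.15 and 30/48 case carriers.
These sizes preserve the per-probe statistics of the full-scale design
(probe density only changes how many probes an event covers) while
keeping the whole suite to a few minutes. The demonstration fixture's
mosaic event uses c = 4 at f = 0.5 (effective dose 1.5) so that its
amplitude clears the fuzzy-zero floor across the simulated noise range;
weaker mosaics (e.g. one extra copy in half the cells, dose 1.25,
log2 ≈ 0.32) fall below that floor for pairs with σ ≳ 0.17 — a real
sensitivity limit of the score model, exercised separately in the
recovery study via deletions.

## Known limitations

* The interval detector is a surrogate with the documented contract,
  not a re-implementation of any proprietary binary's internals.
* The cumulated-probability locus statistic is anti-conservative for
  multi-probe loci (see above); `fisher_p` is the calibrated companion.
* The generator's noise is i.i.d. Gaussian per probe; wave artifacts
  are available but GC-correlated structure, outlier probes, and
  spatial effects are not modeled.
* qPCR assumes perfect doubling per cycle; efficiency mis-calibration
  biases cn multiplicatively.
* Stage-2 testing is confined to stage-1 loci; probes outside them are
  never tested.
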