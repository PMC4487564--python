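# cghscreen

Case–control screening for copy-number variants — including somatic,
mosaic ones — from **paired two-color array-CGH**, with ΔΔCT qPCR dosage
validation. The package targets study designs in which each patient's
DNA is co-hybridized directly against a matched control on the same
array (patient in the numerator channel), so every probe reports
log2(dose_case / dose_control) with technical variation largely
cancelled within the pair. Typical use: screening postmortem brain DNA
from psychiatric case–control cohorts for dosage differences too subtle
or too mosaic for conventional integer-copy CNV callers.

## The method

**Dilution model.** A somatic event present at copy number *c* in a
fraction *f* of cells against a diploid background has apparent relative
dose

    d(c, f) = (f·c + (1 − f)·2) / 2,

a non-integer value for 0 < f < 1; the expected per-probe signal in a
carrier's pair is log2 d. The synthetic-data generator plants such
events with known truth, which is how every downstream stage is tested.

**Per-pair interval detection.** For each pair and chromosome, noise is
estimated blind by the derivative log ratio spread (DLRS, robust SD of
adjacent-probe differences / √2), the profile is re-centered on its
modal state (centralization), and contiguous intervals are scored

    S(i, j) = |mean(x[i..j])| · √n / σ,

with a fuzzy-zero correction S′ = |mean| / √(σ²/n + σ_g²) that adds a
global systematic-error term σ_g and suppresses long low-amplitude
calls. Intervals with S (and S′) at or above the sensitivity threshold
(default 6) are extracted greedily from best to worst; the greedy search
is verified against exhaustive enumeration in the tests.

**Two-stage selection.** Stage 1 flags probes where the numbers of
pairs calling gain versus loss differ by ≥ 4 (penetrance differential)
and merges runs of flagged probes into candidate loci. Stage 2 tests
each member probe's per-pair log2 ratios against zero with a two-tailed
one-sample *t*-test, averages the per-probe means per locus, cumulates
the per-probe probabilities as Σ −log10 p, and keeps loci clearing the
Bonferroni threshold −log10(α / n_loci). The locus effect size is
reported as OR = 2^mean_log2; Fisher's combined p is emitted alongside
the raw cumulated product as a calibrated alternative, and a
Kolmogorov–Smirnov normality fraction per locus documents the Gaussian
assumption. Candidate loci can be flagged against a user-supplied
common-CNV BED catalog.

**qPCR validation.** TaqMan CT values with an internal-control assay
give copy numbers cn = 2·2^(−ΔΔCT) (calibrator: control-group median
ΔCT). Three statistics mirror the validation designs: two-way ANOVA
(disease × pair) on replicate-level copy numbers, chi-square on
integer-rounded copy classes plus Mann–Whitney U between groups, and a
between-brain-region comparison of per-pair case/control dosage ratios.

## Worked example

```sh
python examples/02_two_stage_selection.py
```

runs the packaged demonstration study — 1000 probes on two chromosomes,
8 case–control pairs, a constitutional heterozygous deletion planted in
5 cases and a 50%-mosaic amplification (effective dose 1.5) in 6 cases
— and prints:

```
11 per-pair aberration calls across 8 pairs
2 stage-1 loci; Bonferroni threshold -log10 p = 1.60 for alpha = 0.05

chrom    start      end  n_probes  span_kb  mean_log2   OR  cum_neglog10p     fisher_p  frac_gaussian stage
    1 20012779 23540864        17 3528.086  -0.627614 0.65        32.6436 1.425856e-16            1.0  both
    2 60075722 65704892        29 5629.171   0.435626 1.35        68.7430 2.761627e-37            1.0  both
```

Both planted events — and nothing else — survive both stages. The locus
means match the dilution model: 5/8 carriers × log2 0.5 = −0.625 for the
deletion, 6/8 × log2 1.5 = +0.439 for the mosaic amplification (the
mosaic signal is attenuated, not absent). `stage = both` marks loci
passing the penetrance filter *and* Bonferroni-corrected significance;
OR is the linear-scale case/control fold change.

The same screen is available from the shell:

```sh
cghscreen all --out run_dir --seed 20        # simulates, then screens
cghscreen detect --ratios ratios.tsv --out run_dir --tau 6
```

See `examples/` for interval detection on mosaic events
(`01_simulate_and_detect.py`), qPCR group validation
(`03_qpcr_validation.py`) and the full file-level pipeline
(`04_full_pipeline.py`).

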