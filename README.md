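# ervscreen

Case–control screening of insertionally polymorphic endogenous retroviruses
(ERVs), built for the HERV-K(HML-2) presence/absence study design: a short
group of young proviruses segregates in the human population as full
provirus, solo LTR, or empty pre-integration alleles at each insertion
locus, and carrier status at every locus is compared between disease cases
and controls.

The package implements the whole screen as composable, testable stages:

1. **`synthetic_data`** — reference panels (host mini-genome + a proviral
   family with a gradient of nucleotide identity to the youngest element)
   and diploid case–control cohorts drawn under Hardy–Weinberg equilibrium,
   with ground truth retained for every downstream check.
2. **`probe_design`** — ranks proviruses by identity to the reference
   element and scans the alignment for a short window (default 32 nt) that
   is conserved among the most recent integrations, distinct in the older
   background, and just 3′ of the 5′LTR (the *gag*-leader probe); plus an
   ungapped k-mismatch search for probe hits on either strand.
3. **`virtual_digest`** — restriction-enzyme selection (≥1 cut in the
   provirus body, none in the 5′LTR; BsrI `ACTGG` by default) and
   prediction of the probe-containing host/provirus junction fragment per
   locus, i.e. a "virtual unblot": each detectable insertion shows as one
   band whose size is the distance from the nearest upstream host cut to
   the first proviral cut 3′ of the probe.
4. **`band_analysis`** — collates per-individual band patterns across the
   cohort (single-linkage on log size, 2 % tolerance), matches clusters to
   predicted known-locus sizes with PCR concordance as dual evidence, and
   flags unexplained polymorphic bands as putatively novel insertions.
5. **`pcr_genotyping`** — three-primer in silico PCR per locus (set I spans
   the 5′LTR junction and fires only on proviral alleles; set II spans the
   integration site and sizes solo vs pre) and diploid allele calling.
6. **`association_stats`** — uncorrected Pearson χ² (1 df) on 2×2 carrier
   counts, two-proportion sample-size/power analysis, and Monte Carlo
   type-I-error / power estimation.
7. **`pipeline` / `cli`** — a `full-run` orchestration with a single seed
   and a joined per-locus report.

## The statistics at the core

For carrier counts *a*/(a+b) in cases and *c*/(c+d) in controls the
association statistic is the uncorrected Pearson chi-square with one degree
of freedom,

    χ² = N(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)],   N = a+b+c+d,

significant at p < 0.05 (no multiple-testing correction by default; a
Bonferroni flag exists). Sample sizes for replication screens use the
classical two-proportion normal approximation (pooled null, unpooled
alternative), rounded up per group. Under Hardy–Weinberg, a proviral allele
frequency *f* yields an expected carrier frequency 1 − (1 − f)², which the
simulator, PCR caller and unblot stage must all recover consistently.

## Worked example

A 25+25 cohort over four polymorphic loci with proviral allele frequencies
0.8, 0.4, 0.15 and 0.05:

```
$ cat run.yaml
panel: {n_elements: 12, ltr_length: 120, internal_length: 900,
        n_loci: 4, locus_spacing: 6000, flank: 2500,
        guard_protect_k: 6, n_recent_locus_elements: 4}
cohort: {n_cases: 25, n_controls: 25,
         frequencies: {L00: 0.8, L01: 0.4, L02: 0.15, L03: 0.05}}
recent_k: 6
pcr_max_product: 4000

$ ervscreen full-run --config run.yaml --seed 7 --out out
probe TCTCACCATAGTCTATTTCAAAGCACCTTAGG / enzyme BsrI
locus_id  pcr_case_pos  case_n  pcr_control_pos  control_n  case_freq  control_freq  predicted_bp  band_case_pos  band_control_pos  in_window     chi2        p  significant  monomorphic
     L00            24      25               22         25       0.96          0.88           650             24                22       True 1.086957 0.297147        False        False
     L01            16      25               17         25       0.64          0.68           569             16                17       True 0.089127 0.765291        False        False
     L02             8      25                9         25       0.32          0.36          1130              8                 9       True 0.089127 0.765291        False        False
     L03             3      25                2         25       0.12          0.08           688              3                 2       True 0.222222 0.637352        False        False
0 significant locus/loci at alpha=0.05
```

Reading the report: the pipeline designed a 32-nt probe from the conserved
*gag*-leader window, kept BsrI (cuts the provirus body, never the 5′LTR),
predicted one junction-fragment size per locus (`predicted_bp`), and then
*measured* the cohort twice — by in silico PCR (`pcr_*_pos` carriers) and by
virtual unblot band presence (`band_*_pos`). With no simulated SNPs the two
measurements agree exactly at every in-window locus, and the observed
carrier frequencies (e.g. 0.96/0.88 at L00, where 1 − (1 − 0.8)² = 0.96)
are compared between groups with χ²; here no locus reaches significance, as
expected for a null cohort.

The power analysis used for scaling a replication screen:

```
$ ervscreen power --p1 0.04 --p2 0.24 --power 0.9 --empirical --n-reps 10000 --seed 1
n per group: 62 (total 124) for power 0.90 at alpha 0.05
empirical power at n=62/group: 0.930 (10000 replicates)
```

Stage-wise commands (`simulate`, `design-probe`, `predict-fragments`,
`digest`, `unblot`, `pcr`, `assoc`) expose the same steps over TSV/FASTA
files; see `ervscreen --help`.

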