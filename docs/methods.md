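# Methods

## The screen being modeled

Young endogenous retroviruses of the HERV-K(HML-2) group are insertionally
polymorphic: at a given chromosomal locus an individual may carry a full
provirus, a solo LTR left by LTR–LTR recombination, or the empty ancestral
(pre-integration) site, in any diploid combination. A presence/absence
screen compares carrier frequencies between cases and controls, using two
complementary read-outs: locus-specific PCR for annotated insertions, and a
genome-wide hybridization of restriction-digested DNA with a short probe
conserved among recent integrations, in which each detectable provirus
appears as one junction-fragment band and previously undescribed
insertions appear as bands that no prediction or PCR pattern explains.

This package implements that design as code, with a synthetic data
generator standing in for genomic DNA so that every stage can be tested
against known truth.

## Coordinates and conventions

All coordinates are 0-based, half-open; conversion to 1-based happens
nowhere (exports state the convention in a header comment). Restriction
"cut positions" are bond indices: a cut at `c` severs the bond between
bases `c-1` and `c`. Fragment sizes are differences of cut positions.
PCR product sizes follow the UCSC in silico PCR convention (5′ end of the
forward primer to the 5′ end of the reverse primer, inclusive).

## Synthetic reference panels

A panel is a host mini-genome (random uniform DNA, one contig by default)
plus a family of proviral elements and a set of insertion loci.

* **Element geometry.** Each element is 5′LTR + internal region + 3′LTR,
  with both LTRs identical at generation time (as for a new integration).
  Defaults are scaled to desk size — LTR 400 bp, internal 3,200 bp in the
  library default, 120/900 bp in the test geometry — while preserving the
  feature that matters: a probe-sized leader window just 3′ of the 5′LTR.
* **Identity gradient.** Element *i* is derived from the reference by
  substituting exactly `round((1 − identity/100) · length)` random
  positions, so measured Hamming identity reproduces the requested
  gradient to within rounding. Defaults emulate a family of ~60 elements
  spanning 100→88 % identity to the designated youngest element.
* **Conservation contrast.** The top `guard_protect_k` elements by
  identity (default 25, matching the probe-design stage's default "recent"
  subset) never mutate in the 5′LTR + leader region through the guard
  window; all older elements receive a few forced substitutions inside
  the guard window. This reproduces the real situation — a leader region
  conserved among recent integrations and divergent in the older proviral
  background — and is what makes probe selection non-trivial rather than
  degenerate.
* **Enzyme compatibility.** The recognition sequence of the screening
  enzyme (BsrI `ACTGG`, plus reverse complement) is scrubbed from the
  reference 5′LTR and leader, because the real reference provirus is
  chosen/selected for exactly this property (cuts in the body, none in the
  5′LTR, none between LTR and probe). Without this the enzyme filter and
  the junction-fragment contract would fail on almost any random sequence.
* **Loci.** Insertion points are spaced along the contig (default 14 kb
  apart, jittered), strands random, elements drawn from the most recent
  subfamily. Target-site duplication defaults to 0 bp (keeps fragment
  arithmetic transparent) and is configurable per locus; a TSD of length
  *t* adds one extra copy of the *t* host bases at the insertion point, so
  realized lengths are exactly `flank + insert + t`.
* **Alleles.** `pre` leaves the host unchanged; `pro` inserts the full
  element; `solo` inserts the element's 5′LTR (the generator must pick one
  LTR; the 5′ copy is used); `tandem` inserts two element bodies sharing a
  single central LTR. Inserts are reverse-complemented on '−' strand loci.

## Cohorts

Diploid individuals are drawn with independent haplotypes per locus
(Hardy–Weinberg, no linkage — loci are treated independently throughout,
matching how such screens analyze them). The per-haplotype proviral
frequency *f* is given per locus, either shared or as an explicit
`(f_case, f_control)` pair — enrichment is parameterized as frequencies
rather than odds ratios because that is how screen results are reported.
The non-proviral mass is split between solo and pre by `solo_fraction`
(default 0.5) where the repertoire allows. Carrier status means at least
one `pro` or `tandem` allele; the expected carrier frequency is
1 − (1 − f)². Optional SNPs are applied to realized regional sequences at
`snp_rate` per bp, with per-(individual, locus, haplotype) substreams so
realization order never matters. Simulated frequency defaults in the demo
configuration span nearly fixed (0.9) to rare (0.05) loci, the range such
screens actually encounter.

## Probe design

Elements are ranked by percent identity to the reference over shared
non-gap columns (the synthetic family is substitution-only, hence already
aligned; externally supplied alignments are consumed as-is — manual
curation is out of scope). Windows of length L (default 32, the
field-typical probe size) strictly 3′ of the 5′LTR and within
`max_ltr_distance` (default 2,000 bp — the real probe sits ~1 kb into the
element) are scored by:

* recent conservation — mean pairwise identity over the window within the
  `recent_k` most reference-like elements (default 25);
* distinctness — the maximum identity between the window's recent-subset
  consensus and any older element (smaller is better).

Ranking is (conservation desc, distinctness asc, LTR distance asc,
leftmost column). No canonical scoring exists for this step; this one is
declared and checked against exhaustive enumeration in the tests. Probe
hits use an ungapped Hamming scan on both strands (substitutions only — a
~32 nt probe does not tolerate indels in hybridization-like matching);
the default mismatch tolerance is 2, mirroring how near-identical
proviral copies are counted as probe targets.

## Virtual digestion and junction fragments

`find_sites` expands IUPAC degeneracy at match time and resolves every
recognition match (both strands) to a top-strand cut coordinate:
`start + offset` for forward matches, `start + len(site) − offset` for
reverse matches. Fragment boundaries therefore use actual cut positions,
not recognition starts; for a staggered cutter the two strand-resolved
coordinates differ by a few bp, far below gel tolerance. BsrI is modeled
as `ACTGG` with top-strand cut offset 6 (1 nt past the 5-bp site).

An enzyme qualifies for the screen if it cuts at least once in the element
body but never within the 5′LTR — the condition that guarantees every
probe-positive fragment spans the 5′ host/provirus junction.

`predict_junction_fragment` brackets the probe with the nearest cut 5′ of
it (in the host flank) and the first cut 3′ of it (inside the element).
Cut sites are searched on the locally assembled host+TSD+element
composite, so recognition sites straddling the junction are resolved
exactly as in a real digest — this is what lets prediction match the
full-digest oracle exactly on arbitrary random fixtures. When no host cut
exists within the search horizon (default 20 kb, preventing unbounded
scans) the fragment is reported as undetectably large (size `None`), not
an error; a probe lying 3′ of the first internal cut violates the
operation's contract and raises.

`digest_pattern` performs the oracle-side computation for real cohorts: a
full digest of each realized regional haplotype, a band for every internal
fragment that wholly contains a probe hit and whose size falls in the
detectable window (default 500–10,000 bp, bracketing the ~1–>6 kb range
such gels resolve). Identical sizes collapse to one band, as on a gel;
fragments truncated by a region boundary are censored, matching the
prediction horizon.

## Band collation and classification

Bands are clustered across lanes by single linkage on log size with a
relative tolerance (default 0.02 — approximate agarose sizing precision;
scale-relative so a 2 % tolerance means ~40 bp at 2 kb and ~200 bp at
10 kb). Chaining is possible at high band density; clusters spanning more
than twice the tolerance carry a `wide` flag. A cluster is assigned to a
known locus only when exactly one predicted size matches its median within
tolerance *and* (when PCR calls are available) its presence/absence vector
across individuals equals the locus's PCR carrier vector — the
dual-evidence rule; a size match with a discordant vector, or two
candidate predictions, leaves it ambiguous, and everything else is novel.
Rare novel clusters are reported as such with no further locus inference.

Because band identity is size-only, two loci whose predicted fragments
fall within tolerance of each other are inherently confounded on a gel.
The pipeline therefore places synthetic loci so that in-window predicted
sizes are pairwise separated by >2.5× the tolerance (re-jittering
insertion points under a derived subseed), the synthetic analogue of
choosing the screening enzyme for a well-spread fragment-size
distribution. Stage-wise CLI use without this placement can produce
ambiguous clusters, which the classifier reports honestly.

## PCR genotyping

Each locus is typed by three primers stored as two pairs: set I = host
forward primer upstream of the insertion + reverse primer in the proviral
leader (fires only when a provirus is present); set II = the same host
forward + a host reverse downstream of the integration site (sizes the
solo vs pre alleles, which differ by one LTR + TSD). Primer binding is
perfect-match by default (primers in such screens are validated by
sequencing, not thermodynamics); an optional mismatch tolerance keeps the
3′-terminal 3 bases anchored. Products are matched to expected sizes
within ±50 bp; set-II products classify solo vs pre by the nearer expected
size. With phased haplotypes the diploid call is composed per haplotype;
with a merged template a lone proviral signal degrades to `carrier-only`.
`design_primer_set` extracts primers from panel coordinates and measures
expected sizes by running the in silico PCR on clean single-allele
templates — a coordinate lookup standing in for primer design, which is
out of scope.

## Association and power

Uncorrected Pearson χ² (1 df) on the 2×2 carrier table; `p < 0.05`
two-sided is significant, uncorrected for multiple comparisons by default
(a Bonferroni option exists). Loci monomorphic across both groups have no
defined statistic and are reported with blank χ²/p and a `monomorphic`
flag, frequencies still shown. The no-continuity-correction choice is
deliberate: it is the variant that reproduces the published values this
kind of screen reports (e.g. (6,94,11,89) → 1.61/0.20).

Sample size per group is
`⌈(z_{1−α/2}√(2p̄q̄) + z_{1−β}√(p₁q₁+p₂q₂))² / (p₁−p₂)²⌉ `
(pooled null, unpooled alternative, two-sided), which gives 47/group at
80 % power and 62/group at 90 % for the 0.04 vs 0.24 contrast used to
scale a replication screen. `empirical_power` simulates binomial 2×2
tables and counts rejections (zero-margin tables count as non-rejections);
by exact enumeration the χ² test's true size at n=50/group, p=0.2 is
0.0522 and its true power at n=47/group, 0.04 vs 0.24 is 0.861, so the
Monte Carlo estimates sit near (not exactly at) the nominal 0.05 and the
analytic 0.80 — an approximation gap of the normal-theory formula, not an
implementation artifact.

## Reproducibility and problem sizes

All randomness flows from one top-level seed fanned out per stage through
`numpy.random.SeedSequence`; identical config + seed gives byte-identical
report bodies. The test suite and the acceptance script use the compact
panel geometry (12 elements of ~1.1 kb, loci 6 kb apart, 2.5 kb realized
flanks) and cohorts of 24–200 individuals; the oracle-equivalence checks
run on 54+ randomized loci and the calibration checks on 10,000 Monte
Carlo replicates. These sizes were chosen so the full suite runs in
seconds while every statistical assertion retains 3-SE resolution.

## What the synthetic data does and does not show

The generator reproduces the *structure* of the screen — allele
repertoires, Hardy–Weinberg genotypes, identity gradients, junction
fragments, band patterns, primer products — on uniform random host DNA.
It does not emulate: repetitive or low-complexity genomic context (real
probes can cross-hybridize; real enzymes hit repeat-dense regions
unevenly), whole-genome-amplification bias, partial digests or
methylation sensitivity, linkage between loci, population structure or
ethnicity-dependent allele frequencies, or human-chromosome scale.
Passing tests therefore demonstrate the correctness of the pipeline's
logic and statistics under its stated model, not the wet-lab performance
of any particular probe or enzyme on real genomes. Published
junction-fragment sizes for real loci (e.g. the 19p12b/K113 5,287 bp BsrI
fragment) require the corresponding GenBank accessions and are documented
here as context only; the package's fragment engine accepts such real
sequences through the same FASTA/TSV interfaces when users supply them.

## Known limitations

* Band identity is size-only; co-migrating fragments from different loci
  are indistinguishable by design (flagged ambiguous when predictions
  collide).
* The probe scoring is a declared formula, not a learned or
  thermodynamic model; melting temperature and hybridization kinetics are
  out of scope.
* In silico PCR reports every anchored perfect/near-perfect product pair
  within the size cap; it does not model amplification efficiency or
  competition.
* The two-proportion sample-size formula is the classical normal
  approximation; its ceiling-rounded results are reproduced exactly, but
  exact-test power differs by a few points (quantified above).
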