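# Methods

## Scope and model

`telodrip` analyses the distal ends of human chromosomes: for each
chromosome arm, the last ~2 kb of subtelomeric sequence oriented 5'→3' on
the TERRA-sense strand, followed by the telomeric (TTAGGG)n tract. The
package covers the dry-lab side of a subtelomeric R-loop study — sequence
propensity scoring, restriction-fragment logic, qPCR/seq quantification and
group statistics — and deliberately excludes everything upstream of those
inputs (read mapping, peak calling, TSS prediction, wet-lab protocols).
Coordinates are 0-based half-open throughout; FASTA headers carry the
chromosome-arm label.

## Sequence metrics

Per window: GC skew `(G − C)/(G + C)`, GC content `(G + C)/len`, CpG
density = count of CG dinucleotides per bp. N bases are excluded from all
counts and from the GC-content denominator. A window with no G or C has
undefined skew, encoded as NaN and propagated — never coerced to 0. CpG
density is raw count per bp by default; the observed/expected ratio
`n_CG·len/(n_C·n_G)` is available via `cpg_mode="obs_exp"`.

Windows tile a region left to right; the default 200 bp window with 100 bp
step (50% overlap) is a conventional half-overlap choice — the window
length is biologically motivated (promoter-scale features), the step is a
resolution/compute trade-off, both configurable. A trailing partial window
is dropped.

The **cumulative GC skew** of a record is the region-wide skew computed on
raw base counts over `[TSS, telomere-tract start)`. Because it is a raw
count statistic it is independent of any window/step choice. The anchor can
be switched to the promoter start (`anchor="promoter_start"`); the TSS is
the default since hybrid formation is co-transcriptional and begins at the
TSS. A record is classified hybrid-prone when this score strictly exceeds
the threshold (default 0); a record with undefined skew is labelled
unscorable (`None`), never silently negative.

Clustering uses the skew of windows downstream of each record's promoter
end, linearly resampled to a common length (20 points), with NaN windows
linearly interpolated from their defined neighbours; records whose
downstream skew is entirely undefined are excluded with a warning.
Euclidean distance with average linkage (scipy) — the heatmap package
behind the original displays does not document its defaults, so we fix a
standard, fully deterministic choice.

## In-silico digestion and the HinfI linkage assay

Enzymes are IUPAC recognition site + cut offset (bp from the site's 5'
end): XhoI C^TCGAG, SspI AAT^ATT, HindIII A^AGCTT, EcoRI G^AATTC, BsrGI
T^GTACA, HinfI G^ANTC — standard REBASE offsets. Fragment *lengths* never
depend on sub-site resolution for the assay's conclusions, but fixing
offsets makes them exact. Matching uses a regex lookahead so overlapping
matches are all reported; all six sites are palindromic so single-strand
search suffices (a both-strand option exists for user enzymes). Cuts at
position 0 or len(seq) are ignored (they produce no new fragment).

A digest is the partition of `[0, len)` induced by the union of all cut
positions, each boundary annotated with the enzyme that produced it. The
terminal restriction fragment (TRF) is the rightmost fragment.

The linkage assay: `telomere_linked` is true iff amplicon and telomere
tract lie in the same fragment of the (cocktail ± HinfI) digest. The
*category* (+HinfI/−HinfI) is a property of the record's geometry — whether
a HinfI cut falls between the amplicon end and the tract start — and is
reported independently of which digest was run. An amplicon spanning a cut
site is flagged `amplicon_destroyed` (qPCR would fail), and such fragments
are never called linked.

## qPCR quantification

Percent of input is `2^(Ct_1%input − Ct_IP)`, applied literally: a value of
1 means the IP recovered as much template as the reserved 1% input aliquot.
Whether plots divide by 100 for absolute fractions is a convention that
cancels in every reported ratio; a `dilution_correction` toggle provides
the absolute-fraction scale, default off to match the percent-of-input
plotting convention. Replicates are aggregated by arithmetic mean of Ct —
equivalently geometric mean on the linear scale — because qPCR noise is
additive in cycles (log-normal in signal).

Relative enrichment divides each stratum (per sample, per locus) by its
declared baseline row: the −HinfI fraction for the linkage assay, the G1
fraction for cell-cycle comparisons. Baseline rows are set to exactly 1;
strata lacking a usable baseline are dropped with a warning. RNase H
specificity is the treated/untreated ratio per sample×locus with per-locus
mean ± s.e.m. TERRA expression uses ΔΔCt with a reference gene (β-actin)
and a calibrator stratum (e.g. G1 of sample WT1 set to 1).

## DRIP-seq aggregation

The summary per subtelomere is the fold enrichment of called peaks
aggregated over the most distal 2,000 bp of subtelomeric sequence
(immediately proximal to the tract). "Aggregate" is the
overlap-length-weighted mean over covered bases: bases under k overlapping
peaks contribute k terms to numerator and denominator, which makes the
interval formula identical to per-base averaging with multiplicity and
invariant under splitting a peak into abutting equal-FE pieces. Uncovered
bases are excluded (no peak ⇒ 0). `sum` and `max` alternatives are exposed
because "aggregated" admits both a pileup-like and a max-signal reading.
Replicate consistency of a dataset requires ≥ 1 overlapping peak in every
replicate (half-open intervals: a peak ending at the window start does not
overlap).

## Statistics

Two-group comparisons follow a gated decision tree: Shapiro–Wilk on each
group (and on the paired differences when paired) plus Levene's test across
groups, all at the comparison's alpha. Levene is median-centred
(Brown–Forsythe), the robust default; mean-centring is available. All gates
pass ⇒ two-tailed t-test (paired/unpaired); otherwise Wilcoxon signed-rank
(paired) or Mann–Whitney U (unpaired). Constant inputs have no defined
normality, so they force the non-parametric branch with a warning, and
all-zero paired differences return p = 1 directly (no ranks to sign). The
result records the branch and the gate p-values that chose it. Signed-rank
p-values are exact for small samples without ties (scipy's exact method,
equal to full enumeration over sign assignments), normal approximation with
continuity correction otherwise.

The proportions test is the chi-square test of equal proportions with Yates
continuity correction, two-sided — the standard prop-test default. Equal
observed proportions (including 0/n vs 0/n) short-circuit to statistic 0,
p = 1, where the chi-square expected-frequency table degenerates.

Repeated-measures ANOVA is the classic within-subject decomposition
(SS_total = SS_subjects + SS_treatment + SS_error;
F = MS_treatment/MS_error on (k−1, (n−1)(k−1)) df). Missing cells are an
error; no imputation. A zero error mean square yields F = 0, p = 1 when the
treatment effect is also zero, else p = 0 (the noise-free limit).

Raw p-values are reported (no multiple-testing correction), matching common
practice for small targeted panels; Benjamini–Hochberg adjustment is
available but off by default.

## Synthetic data: what it emulates, what it does not

The generator produces (i) subtelomeric sequence as ordered composition
blocks of i.i.d. per-base multinomial draws — the simplest model whose
expected window skew is analytic, `(g − c)/(g + c)` — with recognition
sites spliced in by overwriting sampled bases (coordinates stay stable) and
an exact (TTAGGG)n tract appended; (ii) long-format Ct tables where
`Ct_IP = Ct_input − log2(true level) + N(0, sd)`, with 1%-input rows
anchored at 25.0 cycles (arbitrary; cancels in every ratio), ±RNase H,
±HinfI and per-phase rows; (iii) peak files with a planted peak over the
downstream-of-TSS window for hybrid-prone records.

Default study conditions: 4 WT vs 4 ICF samples (6/group in the recovery
simulations), Ct noise 0.3 cycles, RNase H residual 0.05, HinfI reduction
0.3 at telomere-linked loci, ICF/WT effect sizes around 3× at prone loci,
S-phase multiplier 4 in ICF. Group sizes mirror the cohort sizes typical of
patient-cell panels; the effect sizes are free parameters of the design —
plausible magnitudes for this assay, not estimates of any dataset — chosen
once and used unchanged by tests and the acceptance script. Seeding: one
master seed, one fixed child stream per sample, so a sample's measurements
do not change when the cohort grows.

Deliberately not modelled: sequencing reads, chromatin/methylation state,
telomere-length dynamics, amplification-efficiency curves, partial
digestion/star activity. Passing tests therefore demonstrate that the
pipeline's arithmetic and logic recover planted truth under idealized
noise; they say nothing about mapping artefacts, probe chemistry or
biological variability beyond log-normal qPCR noise.

Test fixtures that need a site-free background use T-free composition
blocks (every recognition site in the enzyme set contains a T), making
planted sites the only cuts — a controlled construction, labelled as such
where used.

## Numerical and design notes

- Undefined skew (NaN) propagates; classification maps it to an explicit
  unscorable label.
- Strict inequality at the classification threshold: a score exactly at
  threshold is not prone.
- Degenerate digests (no sites) return the whole sequence as one fragment.
- Problem sizes in the test and acceptance runs (100 random 2 kb sequences
  for metric oracles, 1,000 short sequences for IUPAC enumeration, 200
  simulated cohorts for ratio recovery, 20-record cohorts for classifier
  and linkage recovery) are the package's verification defaults; they run
  in seconds while holding the Monte-Carlo error of the recovery medians
  near 1%.
- The ±0.05 band on the 1 kb cumulative-skew expectation and the ±0.35
  per-window band were derived from the multinomial sampling distribution
  (≈1.6σ and ≈4σ respectively) by simulation before the tests were frozen.
- Hierarchical clustering and all generators are deterministic given the
  seed; two runs with the same seed produce byte-identical artifacts
  (excluding the wall-clock timings in the run log).

## Known limitations

- The linkage module reports fragment geometry mechanically; subtelomeres
  whose behaviour contradicts their geometry (as biological exceptions do)
  are not special-cased.
- The classifier is a single-threshold rule on one scalar; it does not
  weight skew by distance from the TSS or model G-quadruplex propensity.
- narrowPeak parsing expects well-formed ENCODE 6+4 columns; malformed rows
  raise rather than being skipped.
- The CLI's `run-all` regenerates synthetic inputs; applying the pipeline
  to real data means invoking the per-stage subcommands on your own
  FASTA/BED/CSV/narrowPeak files.
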