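# Methods

This note documents the models, conventions and numerical choices behind
`saber`, in the order the pipeline applies them, together with what the
synthetic-data generator does and does not emulate.

## Read preprocessing

**Merging.** Paired 2×250 bp reads are merged over the highest-scoring
ungapped overlap (score = matches − mismatches) after reverse-complementing
mate 2. An overlap is acceptable when it is at least `min_overlap` (default
10) bases long and its mismatch fraction is at most `max_mismatch_frac`
(default 0.1); ties in score go to the longer overlap. At mismatched
overlap positions the base with the higher Phred quality is kept with its
quality; at agreeing positions the higher quality is kept. `N` never
matches anything (including another `N`) and carries effective quality 0.
This is a deliberate simplification of probabilistic merger tools: merging
is a preprocessing step here, and for fully spanned amplicons with ~200 bp
overlaps the max-score overlap is unambiguous.

**Quality trimming.** A 5′→3′ sliding window (default width 4) truncates
the read at the start of the first window whose mean quality falls below
`min_q` (default 15); reads shorter than `min_len` (default 100) after
truncation are dropped. Trimming runs on merged reads, i.e. merge → trim →
primer filter.

**Primer filtering.** A read must contain exactly one approximate
occurrence of the forward primer near its 5′ end and exactly one of the
reverse-complemented reverse primer near its 3′ end, each within
`max_error_rate` edits per primer base (default 0.1, the conventional
adapter-trimming tolerance; the positional slack is 16 bases so that a
UMI prefix upstream of the primer is permitted). Occurrence search uses
edlib's infix alignment; after the best hit is masked, any secondary hit
within tolerance counts as a duplicate and the read is discarded. Reads
matching only in reverse-complement orientation are flipped first. Both
primers are removed; what remains is aligned against the primer-trimmed
reference window (the *insert*).

## Alignment and variant naming

Reads are aligned globally to the insert with an affine-gap
Needleman–Wunsch (Gotoh) dynamic program: match +5, mismatch −4, gap open
10, gap extension 0.25, a gap of length L costing `open + (L−1)·ext`. End
gaps are penalised like internal gaps, so the CIGAR always spans both
sequences. Tie-breaking prefers match/mismatch over deletion over
insertion, making tracebacks deterministic; the DP kernel is
numba-compiled and identical sequences are aligned once per run.

A variant allele is the set of indels in the alignment; substitutions are
ignored so that base miscalls cannot mint false barcodes (an alignment
without indels is the unedited "no variant" allele). Indels are
left-aligned — shifted maximally 5′ through repeat context — and named
`<pos>:<len><I|D>` with 1-based positions on the insert: for deletions the
first deleted base, for insertions the base immediately after the
insertion point. Multi-indel alleles join components with `","` in
ascending position order. These conventions make the name a pure function
of the edited sequence, which is what cross-sample identity requires.

Reads whose optimal score falls below 0.4 × match × min(len(read),
len(insert)) are counted as unaligned and excluded from all denominators;
this floor rejects inserts from foreign templates while accepting alleles
with deletions spanning several target sites (a 108-bp deletion still
scores ~0.95 of its ceiling).

## UMI module (optional)

When a UMI of configured length prefixes the forward read, it is split off
after merging; reads are grouped by exact UMI match (optional single-edit
absorption of smaller groups into larger ones, off by default) and each
group is reduced to one per-position majority consensus over members of
the modal length, ties broken by summed quality. Consensus precedes
alignment, and singleton groups are retained. Deduplication is idempotent.

## Sharing analysis

Per sample, aligned reads are tabulated into count and proportion vectors
(matrices C and P over the union of variant names). For threshold θ_V, any
variant whose proportion strictly exceeds θ_V in ≥ 2 samples is a *common
variant*; per sample its reads are summed into one `common variant sum`
row and the individual rows dropped, yielding reduced tables C′ with
unedited, common-sum and informative rows. Reads are conserved exactly at
every reduction. Φ = informative reads / aligned reads.

The Sharing Factor of a sample pair is computed over the union of variant
names (absent = 0). The sweep evaluates the θ_V grid {0.0003, 0.001,
0.003, 0.01, 0.03, 0.1, 0.3, 1}; mean S averages all unordered distinct
pairs (self-comparisons excluded) and is taken on informative rows, the
universe that post-selection reporting uses; the all-rows universe
(including unedited and common-sum) is available for the descriptive
"all variants" curves. A pair with no informative reads at all shares
nothing and scores S = 0.

θ_V is selected by maximising z(mean Φ) · z(1 − mean S), with z-scores
standardised across the sweep (sample sd). Two numerical choices matter:

* **Exact ties** in the product are resolved toward the *largest* θ_V.
  On discrete data, adjacent thresholds whose flagged-variant sets
  coincide produce exactly equal products; the least stringent of them
  discards the least data. This rule also gives the dominant-shared-allele
  failure archetype its diagnostic signature (θ_V = 0.3 selected).
* **Zero variance** across the sweep (all values identical) makes the
  z-score undefined; the raw uncentered values are used instead and a
  warning is recorded.

QC warnings fire when (a) the selected θ_V equals the largest non-trivial
sweep value (0.3), (b) post-selection mean S exceeds 0.01, or (c)
post-selection mean Φ falls below 0.6. The S/Φ thresholds bracket the
values observed in interpretable experiments (S ≈ 0.002–0.008,
Φ ≈ 0.7–0.9) against the failure archetypes (S ≥ 0.012, Φ ≤ 0.55).

## Sample selection

For each sample, Φ and B₀.₀₂ (informative barcodes with VAF > 0.02,
against all aligned reads) are computed. A paired bootstrap (default 1000
replicates, seeded; default seed 20200207) resamples the sample set with
replacement, recording each replicate's mean Φ and sd of B₀.₀₂ on the same
index set, plus their Pearson correlation across replicates. The 95% CI of
the mean Φ uses the bias-corrected accelerated construction: bias
correction z₀ from the fraction of replicates below the observed mean,
acceleration from the jackknife skewness of the leave-one-out means.
Samples with Φ ≥ the lower CI bound are classified high-Φ (the boundary is
inclusive). All-identical Φ yields a degenerate, flagged interval. The
B₀.₀₂ distributions of the two classes are compared with a two-sample
Kolmogorov–Smirnov test.

Note on calibration: bootstrap percentile-family intervals of a mean are
intrinsically narrow at a few dozen samples (no t-correction, and the
resampling sd is shrunk by √((n−1)/n)); at n = 28 the realised coverage of
the 95% BCa interval is ≈ 92%, matching scipy's reference implementation
on identical cohorts. Consumers needing strict coverage should increase
the cohort size, not the replicate count.

## Clone enumeration and statistics

An HSC clone is an informative barcode with VAF strictly above the cutoff
(default 0.02). Shannon entropy (natural log; effective clone number
exp H′) and inverse Simpson diversity are computed by default over *all*
informative barcodes of a sample with proportions renormalised over that
set — richness R is then the number of observed informative barcodes — and
optionally over the above-cutoff clones only. Group comparisons check
normality per group (Shapiro–Wilk; a constant group yields p = NA with a
warning) and use the pooled-variance two-tailed Student's t-test (Welch
via flag); two constant groups make the t-test undefined and raise.

## Longitudinal matching

Cross-timepoint pairs are scored by |top-k barcode-name intersection| / k
(k = 5), so a sample with fewer than k clones cannot reach score 1 even
against itself. A greedy pass proposes a 1-to-1 assignment in descending
score order, but the full score matrix is always emitted: barcode overlap
is evidence, not proof, of animal identity, and the assignment is
explicitly advisory. Trajectories keep clones with VAF > 0.02 per
timepoint, renormalise each timepoint to cumulative frequency 1.0, and
report absent clones at frequency 0.

## Synthetic data

The generator emulates: a 300-nt amplicon (20-nt primers, 260-nt insert,
10 evenly spaced 23-nt target sites with cut sites 3 nt from the
PAM-proximal end); per-sample clone structure (clone count ~ N(4, 1),
min 1; Dirichlet(α = 1) allele fractions) with editing outcomes drawn per
clone as 1–10 edited sites carrying geometric-length deletions (≤ 20 nt)
or insertions (≤ 12 nt); an unedited fraction (default 0.10); planted
stereotypical variants shared by every sample (defaults: an 8-nt deletion
at VAF 0.05 and a 2-nt insertion at VAF 0.005); substitution errors at
10⁻³/base and single-base indel errors at 10⁻⁵/base (indel miscalls on
Illumina platforms are orders of magnitude rarer than substitutions);
constant Q35 qualities with optional linear droop; and optional UMI tags,
in which case template molecules are the sampling unit, each sequenced
`umi_duplication` times (default 5) with collision-free UMIs per sample,
so that error-free read proportions equal molecule proportions exactly.
Truth tables account for every emitted read; an allele is informative in
truth iff it is not planted and occurs in exactly one sample. The same
seed reproduces byte-identical FASTQ.

It does **not** emulate: realistic Cas9 repair-outcome spectra (clone
patterns are drawn uniformly, not from a repair model), PCR chimeras or
jackpot amplification bias, quality-dependent error profiles, or
per-target-site editing kinetics. Passing end-to-end tests therefore
demonstrates correct accounting and threshold behaviour under controlled
sharing structure, not robustness to every artefact of real libraries.

Failure presets: *poor_labeling* (12 samples × 2000 reads, 96% unedited)
reproduces an inadequately barcoded experiment and trips the low-Φ
warning; *dominant_shared_allele* (16 samples × 2000 reads, a deletion
spanning five target sites at VAF 0.6 in 14/16 samples, plus trace 0.002
carry-over of each sample's main clone into the next) reproduces the
stereotypical-dominance archetype: the dominant allele is flagged at every
θ_V < 1 while the trace carry-over makes lower thresholds strictly worse,
so the sweep lands on θ_V = 0.3 and warns.

## Problem sizes

The test suite and the acceptance script run the default conditions at 20
samples × 5,000 reads (≈ 20 s end to end after JIT compilation), the
failure presets at 12–16 × 2,000, and the UMI comparison at 4 × 1,500
error-free reads; oracle comparisons use 500–1,000 random instances and
the bootstrap-coverage study 500 cohorts of 28. These sizes were chosen so
the whole suite completes in a few minutes while keeping every statistic
far from its decision boundaries.

## Known limitations

* Variant positions are insert coordinates; alleles from references with
  different primer definitions are not name-compatible.
* The aligner is exact but O(len(read)·len(insert)); it is intended for
  short amplicons, not genome-scale references.
* UMI grouping assumes the UMI is a fixed-length forward-read prefix.
* The θ_V sweep needs ≥ 2 samples and meaningful variation across the
  grid; single-sample experiments cannot define common variants.
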