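# Methods

This note documents the statistical procedures, the synthetic-data model
behind the test suite, the numerical choices, and what the package does and
does not establish about real data.

## Scope and data model

The package operates downstream of basecalling, alignment, transcript
assembly, per-read poly(A) estimation and per-read modification calling:
its inputs are an annotation (GFF3, 1-based inclusive coordinates, used
internally unchanged; BED exports convert to 0-based half-open at the
boundary) and two per-read tables. A read carries a transcript assignment,
a genomic 3′-end position, a poly(A) tail length (PAL, possibly missing),
a full-length flag and a transcript-level alternative-splicing class; a
modification call links a read to a genomic site with a 0/1 modified flag.
Reads naming unknown transcripts are dropped and counted; reads whose 3′
end falls > 1 kb (configurable) outside the gene span are flagged, not
dropped, since unannotated distal sites are biologically plausible.

The stop-codon position is the annotated CDS 3′ terminus (stop codon
inside the CDS, the common GFF3 convention). The final exon is the
rightmost exon on `+`, leftmost on `-`; the 3′ UTR is the part of the
final exon downstream of the stop codon in transcription direction.

## Poly(A)-site clustering and APA statistics

Clustering is single linkage over sorted 3′-end positions: adjacent
positions merge while the gap is ≤ the window (default 24 nt, inclusive).
This is deterministic, O(n log n), and equals the transitive closure of
the "within window" relation (property-tested against a brute-force
union-find oracle). A cluster's representative is its modal endpoint;
modal ties break toward the stop codon in transcription direction, then
by coordinate.

Gene-level APA uses the transcript whose stop codon is most 3′. Among
final-exon clusters with ≥ 5 reads (configurable), the two most abundant
are the PAS pair; count ties break by proximity to the stop codon, and
the nearer of the chosen pair is always the pPAS. A gene enters testing
when both sites have ≥ 5 reads in both conditions (log-ratio stability).

The usage-shift statistic between two conditions is
`D = |log2((DPAS1+c)/(DPAS2+c)) − log2((PPAS1+c)/(PPAS2+c))|` with
pseudocount `c = 1` (the statistic is undefined at zero counts without
it). The "more than 30 %" significance rule is ambiguous between three
readings, all implemented and selectable: `log2` (D > 0.3, the default,
taking the statement at face value on the printed statistic), `fold`
(D > log2 1.3 ≈ 0.378, a 1.3-fold odds change) and `usage` (the distal
usage fraction moves by > 30 percentage points). Per-condition RED scores
are `log2((dPAS+c)/(pPAS+c))`; ΔRED = RED₂ − RED₁, negative exactly when
condition 2 is more proximal — the sign convention under which negative
global values denote 3′ UTR shortening. The exact functional form of a
"relative expression difference" is not uniquely fixed by that sign
convention; the log2 usage-ratio contrast used here is the simplest form
that satisfies it and makes ΔRED antisymmetric under condition swap.
Significant genes classify as `proximal_up` (ΔRED < 0), `distal_up`
(ΔRED > 0) or `unchanged` (a strict sign is required; ΔRED = 0 is
unchanged).

## PAL differential testing

Per transcript, condition replicates are pooled and missing PAL values
excluded (per-read poly(A) estimators fail on some reads; imputing 0
would bias medians). Transcripts with < 10 non-missing reads in either
condition (configurable) are flagged untested. The test is two-sided
Mann–Whitney *U*: for n₁+n₂ ≤ 12, exact enumeration of all C(n₁+n₂, n₁)
group assignments using midranks (valid under ties), with the two-sided p
as twice the smaller tail, capped at 1; otherwise the normal
approximation with tie correction and continuity correction. Fold change
is Control_median/Treatment_median, applied two-sidedly
(max(FC, 1/FC) > 1.5) because both lengthened and shortened transcript
sets are of interest and a one-sided ratio cannot yield both.

## m6A statistics

A site's stoichiometry is modified/(modified+unmodified) covering reads;
zero-coverage sites are untestable, never ratio 0. Differential calls use
a two-sided Fisher exact test (point-probability method: all tables with
the observed margins whose probability does not exceed the observed
table's are summed — stated explicitly because the alternative "double
the one-sided tail" definition differs) on the **pooled** 2×2 table,
while Δ is the difference of **mean per-replicate** ratios. The two
choices coexist deliberately: a Fisher test needs a single table, whereas
the "mean difference in ratio > 0.1" criterion is naturally replicate
wise. Raw p-values are reported (Benjamini–Hochberg is available as an
option but off by default). Region assignment (5′UTR/CDS/3′UTR, CDS
termini inclusive) is strand-aware at genomic coordinates; multi-isoform
genes use the longest-CDS transcript. The metagene profile maps each site
to its fractional position within its region, histograms into
3 × `bins_per_region` bins and normalizes to sum 1. The per-stage "m6A
modification rate" is computed as the per-gene mean of site ratios, then
summarized across genes (median, quartiles); per-site and per-read
definitions would also be defensible — the per-gene mean is used because
the rate is reported gene-wise alongside gene-level Venn comparisons.

## Expression and integration

TPM divides counts by spliced transcript length in kb and rescales each
sample to sum 10⁶ (waived, with a warning, for all-zero samples). The
differential-expression test is a **declared stand-in**: Welch *t* on
log2(TPM+1) across replicates with thresholds *p* < 0.05 and
|log2 FC| > 1, labelled `welch-t-log2tpm-standin` in its output. A
count-model estimator with dispersion shrinkage is out of scope; the
thresholds, not the estimator, are the fixed content here. Group
comparisons (AS class vs expression/PAL, APA shift class vs m6A ratio,
modified vs unmodified transcripts vs PAL) use one-way ANOVA plus all
pairwise Welch *t* tests; with two groups the omnibus is exactly the
unpaired Welch *t*. "Modified transcript" means ≥ 1 site with ratio ≥ 0.1
at ≥ 10 covering reads (both configurable; no standard definition
exists). Correlations are Spearman ranks — robust to the heavy-tailed
PAL and TPM scales. The modified-vs-unmodified PAL comparison reports
its direction; no direction is encoded as an expectation.

## The synthetic generator

The generator is the package's study-condition model, not a test shim.
Defaults: 200 genes on 4 chromosomes (strands alternating), one
3-exon transcript per gene with a 5′ UTR (150–250 nt), CDS (450–1200 nt)
and a 3′ UTR long enough for two PAS 200 nt apart; 4 stages × 3
replicates; per-gene per-sample read counts negative binomial (mean 200,
dispersion 20) scaled by a lognormal per-gene expression factor
(σ = 0.2 log-units).

* **PAL**: gamma with shape 4 (right-skewed, strictly positive), the
  scale solved so the distribution median equals the stage target
  (84.38/79.91/81.6/86.59 nt); values rounded to 0.01 nt; 3 % missing.
  A small per-gene multiplier (σ = 0.03 log-units) is rank-linked
  negatively (ρ = −0.6) to the expression factor, reproducing the
  negative PAL–expression correlation. Because high-expression genes then
  contribute more (slightly shorter-tailed) reads, pooled stage medians
  sit ~0.5–1 % below the per-gene target; the calibration tests therefore
  switch the gene-level multiplier off when checking the gamma median
  calibration (±1 nt at 50 000 reads).
* **APA**: each read picks the proximal PAS with stage weight 0.45 plus
  N(0, 5 nt) rounded positional noise; 10 % of genes have their proximal
  odds multiplied by 3 in the last two stages (the developmental
  distal→proximal shift). These defaults give an expected global mean
  RED of ≈ −0.1 × log2 3 ≈ −0.16 for an early-vs-late comparison, the
  magnitude scale reported for pod development. At ~600 reads per gene
  per condition the binomial noise of D is ~0.17 log2 units, so the
  D > 0.3 rule yields a false-positive rate near 10 % (≈ 7–12 %
  depending on seed) among unplanted genes — an inherent property of
  the statistic at this depth, not an implementation artifact.
* **m6A**: Poisson(2) sites per gene placed 5 %/74 %/21 % in
  5′UTR/CDS/3′UTR, each with a Beta(8, 8) stoichiometry (mean 0.5, the
  reported ~50 % rate); full-length reads always cover a site,
  non-full-length reads with probability 0.5; 15 % of sites gain +0.3
  (clipped at 0.99) in the last two stages.
* **Planted PAL/expression effects**: 10 % of transcripts change PAL
  1.8-fold (direction alternating, so stage medians stay centred), and
  5 % of genes change expression 4-fold (either direction), both in the
  last two stages.

Every planted identity, direction and size is recorded in a ground-truth
object exported as `truth.json`; identical seed and config produce
byte-identical outputs (verified at the byte level for the GFF3 and TSVs).

What the generator does **not** emulate: sequence content (no FASTQ/FAST5
or signal), splice-graph structure (AS classes are sampled labels), more
than two PAS per gene, PAS microheterogeneity beyond Gaussian jitter,
batch effects between replicates, coverage decay along transcripts, or
correlated m6A sites. Passing recovery tests therefore demonstrates that
the statistics detect the planted effect classes at realistic depths —
not that they are robust to every artefact of real nanopore runs.

## Numerical and reproducibility choices

Randomness flows exclusively through `numpy.random.default_rng` seeded
from the user seed (sub-streams `[seed, k]` per generator phase).
Problem sizes used by the test suite and the acceptance script — 200
genes × 12 samples × ~200 reads (~0.5 M reads, ~0.9 M modification
calls) for recovery, 1 000 transcripts at lower depth for type-I error,
50 genes for end-to-end determinism — were chosen so each check carries
real statistical power while the whole suite runs in a couple of minutes
on one CPU. Analysis outputs round floats at 6 significant/decimal
digits in TSV/JSON for byte-stable reruns; `run.log` carries timestamps
and is excluded from the byte-identity guarantee. Degenerate inputs have
explicit behaviour: empty cluster sets are valid absences, empty testable
sets return explicit empty results rather than NaN, zero-variance t tests
report p = 1, constant-input correlations report NaN with a warning.

## Known limitations

* The DE stand-in understates power relative to count models at low
  replicate numbers; its significant sets should be read as
  threshold-compatible, not DESeq2-equivalent.
* The 30 %-rule ambiguity means APA significant-set sizes depend on the
  configured interpretation; only the default is exercised by the
  acceptance checks.
* The asymptotic Mann–Whitney path is approximate near the n₁+n₂ = 12
  boundary (verified within 0.01 of exact at n₁ = n₂ = 12).
* FDR control is optional and off by default, mirroring raw-p reporting;
  genome-scale use should enable it.
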