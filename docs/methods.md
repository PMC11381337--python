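# Methods

## Problem and model

Adenosine deaminases acting on RNA (ADARs) convert adenosine to inosine in
double-stranded RNA. Reverse transcription reads inosine as guanosine, so
editing appears in RNA-seq as A→G mismatches against the genome — or T→C
on the plus strand when the edited adenosine lies on the minus strand. The
package quantifies this signal from per-position text pileups of a
three-strain *C. elegans*-style design: wild type, an *adbp-1* mutant in
which the editing enzyme mislocalizes to the cytoplasm (shifting editing
from intronic to exonic adenosines), and an editing-null ADAR mutant that
serves as the negative control for everything that looks like editing but
is not.

The core quantity is the editing level of a site: the fraction of
quality-passing reads carrying the target change among all quality-passing
base calls covering the position. Counts are integers; all threshold
comparisons are performed on exact rationals (`fractions.Fraction` built
from the decimal literal), never on binary floats, so a site at exactly a
printed boundary is classified the way the wording dictates.

## Known-site analysis

Inputs: a catalogue of previously described editing sites, pileups pooled
over the replicas of each strain and stage, and the pooled ADAR-null
pileups of the same stage.

1. Base calls with Phred quality < 25 are discarded.
2. A catalogued site is blacklisted when its target change exceeds 3%
   (strictly) in the pooled ADAR-null data. A site without ADAR-null
   coverage cannot be assessed; it is retained and flagged.
3. A remaining site is called edited when the A→G (or T→C) fraction is
   ≥ 1% of the quality-passing depth and all other mismatches together
   are ≤ 1%. Zero depth is reported as "not expressed", which is distinct
   from "not edited".
4. Gene-level editing pools target and total counts over the gene's
   catalogued sites: level = Σ n_target / Σ n_total, exactly.
5. The editing matrix reports the unthresholded target fraction per site
   and sample, with an expression flag; an unexpressed cell has an
   undefined level (NaN), never zero. The default expression floor is a
   depth of 1.

The "≤ 1% other changes" condition is applied to the *sum* of non-target
mismatch fractions (an aggregate purity condition); a per-change variant
is available via `EditingConfig(aggregate_other=False)`.

## De-novo analysis

Runs per sample, on every covered position, after two subtraction steps:

* **Genomic variants** — positions (or position/alt pairs) present in the
  DNA-variant and SNP masks lose the corresponding mismatch calls.
* **Mutant changes** — any alt observed in ≥ 1 quality-passing read of
  the pooled ADAR-null data at that position is erased from the test
  column. This is deliberately literal (one read suffices) and
  idempotent.

A position then yields a candidate when the most abundant remaining
mismatch has ≥ 2 reads, reaches ≥ 5% of the quality-passing
post-subtraction depth, and every other mismatch stays ≤ 1%. The 5%
denominator is the depth after quality filtering and subtraction, chosen
for internal consistency. Ties for the most abundant change are broken in
fixed A<C<G<T order and logged; note a tied runner-up necessarily violates
the 1% bound, so ties never actually produce candidates.

Candidates present in ≥ 2 biological replicas of a strain and stage
(same position *and* same change) are consolidated, pooling counts over
the supporting replicas. Candidates of any substitution class survive to
consolidation; only A>G / T>C enter the editing report, the remainder go
to a diagnostics channel. An *adbp-1* site is classified *de novo* when
its position is edited in neither wild-type analysis (known-site or
de-novo).

## Region annotation

Gene models are read from GFF3-like annotation; introns are derived as
gaps between consecutive exons of a transcript, and coordinates are
1-based closed throughout. A position receives exactly one label with
precedence coding exon > UTR > noncoding exon > intron > intergenic; when
genes on both strands overlap, the gene matching the site's inferred
editing strand wins before precedence applies. Isoform conflicts resolved
by precedence are a declared design choice (the upstream material is
silent); it maximizes agreement with exon counts whenever any transcript
is coding at the position. UTR5 and UTR3 are distinguished internally and
merged into "UTR" in three-group summaries.

## Nucleotide context

For each edited adenosine, the nucleotides at offsets −w..+w on the edited
strand are counted (minus-strand sites contribute the reverse complement
of the plus-strand window, so −1 is always the 5′ neighbor). Counts become
probabilities by

    P_ic = (n_ic + λ) / (Σ_c′ n_ic′ + C·λ),  C = 4.

Defaults: w = 3 and λ = 1 (Laplace smoothing, avoiding zero cells on small
strata); λ = 0 reproduces the empirical frequencies. Neither value is
dictated by the source material, so both are configuration flags.
Profiles are computed per region stratum (exon / intron / UTR) and paired
with random-adenosine controls drawn, with matched per-region counts, from
gene-strand adenosines of the same annotation — deterministic given the
seed. Sites within w of a sequence end or with an ambiguous base in the
window are excluded and logged.

## Secondary structure

Each site contributes a window of 50 nt on either side (101 nt total,
center = the edited adenosine), extracted from the genome for the
unspliced form and from the spliced transcript (longest isoform per gene,
oriented 5′→3′ on the gene strand) for the spliced form; minus-strand
windows are reverse-complemented. The minimum free energy (kcal/mol) is
computed with nearest-neighbor thermodynamics (ViennaRNA), T transcribed
to U first; results are deterministic per sequence and backend version,
and downstream checks rely only on sign, determinism and relative order,
never on backend-specific magnitudes.

The printed outlier rule "MFE above 100" is sign-ambiguous for a quantity
that is typically ≤ 0; the default removes |ΔG| > 100 (catching numeric
pathologies of either sign) and `literal_outlier_rule=True` restores the
literal ΔG > 100 reading. Group means are compared with the two-sided
Welch t-test (Welch–Satterthwaite degrees of freedom). Degenerate inputs:
two constant groups with equal means give t = 0, p = 1 by convention;
constant groups with unequal means raise.

## Expression

Genes are kept when they have ≥ 10 reads in total and a coefficient of
variation (sample sd / mean, ddof = 1) < 1 across samples; zero-mean genes
are dropped and logged. The editing-class shift test compares, between a
gene class and its complement (testing against a superset that contains
the class would double-count), a per-gene statistic — by default the log2
ratio of library-size-normalized (CPM) mean expression, mutant over wild
type, with a half-count offset. Differential-expression flags consume
log2FC/Padj from any upstream engine and apply the strict thresholds
|log2FC| > 1 (embryo) or > 2 (L4) with Padj < 0.05. Set overlaps are
scored with the upper-tail hypergeometric p-value including the observed
overlap, the standard enrichment convention.

## Synthetic data

The generator emulates the study design at desk scale, emitting pileups
directly (the analysis starts at pileup level, so read simulation and
alignment are out of scope):

* genome: two chromosomes of random sequence at GC 0.36, 180 genes by
  default (~150 kb total, ~112 k covered A/T positions), 1–4 exons per
  gene, UTRs at the transcriptional ends, 15% lncRNAs, both strands;
* truth: 200 wild-type sites (80% intron / 13% coding exon / 7% UTR) and
  200 *adbp-1* sites (65.5% exon / 20% intron / 14.5% UTR), all on
  gene-strand adenosines, with uniform 0.05–0.5 editing levels; zero true
  sites in the ADAR-null strain. The two stated fractions (0.80, 0.655)
  are the study's; the remaining splits are the package's own choice of a
  plausible complement. Region counts use largest-remainder allocation so
  the planted mix equals the profile exactly and recovery checks measure
  the caller rather than planning noise;
* artifacts: 20 A-to-I-mimicking changes at 5–10%, half present in every
  strain (systematic artifacts the ADAR-null subtraction must remove, and
  deliberately included in the known-site catalogue as realistic false
  catalogue entries), half only in the ADAR-null strain;
* noise: negative-binomial coverage (mean 60, dispersion 10), 0.1%
  per-base error spread uniformly over the three non-reference bases,
  unstranded read orientation, and a two-point quality model (95% Q37,
  5% Q15) drawn i.i.d. so low-quality calls pair with bases at random;
* 100 homozygous SNPs inside gene spans, split between the DNA-variant
  and SNP mask files;
* three replicas per strain at two stages (the stage level multiplier
  defaults to 1.0, making the stages statistically identical);
* a simple per-gene negative-binomial count table with optional planted
  class shifts, for the expression module.

Everything is deterministic given the seed (child seeds are derived per
component and per sample id via CRC32, keeping them below 2³¹).

What the generator does **not** emulate: alignment artifacts with
positional structure, strand-biased libraries, PCR duplicates, coverage
autocorrelation along transcripts, splice-aware read placement, or
realistic transcriptome-wide expression dynamics. Passing recovery tests
therefore demonstrates the correctness of the calling logic under the
declared statistical model, not performance on real libraries.

## Problem sizes and numerical choices

Recovery checks run the full pipeline on the default fixture and analyse
the embryo stage (with a stage multiplier of 1.0 the second stage is a
statistical duplicate, so one stage characterizes the design). At these
sizes the fixture provides ≥ 10⁵ covered non-edited adenosines for the
false-positive denominator. Welch statistics are validated against an
independent reference implementation to 1e-9 relative error; the
hypergeometric tail is validated against exact combinatorial enumeration
for all universes up to N = 20. Probability-matrix rows sum to 1 within
1e-12.

## Known limitations

* The known-site blacklist is a statistical screen: an artifact editing at
  5% true rate escapes the "above 3%" rule in roughly 10% of sites at
  pooled depth ~180, and such escapes then appear in the known-site
  output. This is inherent to the printed rule, not a defect of the
  implementation; the de-novo path is immune because a single ADAR-null
  read of the change erases it.
* De-novo sensitivity at the 5% level boundary is limited by the ≥ 2-reads
  / ≥ 5% / ≥ 2-replica criteria themselves (a site with exactly 3 expected
  edited reads per replica passes per-replica calling only ~60% of the
  time); catalogued sites are rescued by the pooled known-site analysis.
* One transcript (the longest) represents each gene in the spliced
  structure analysis; isoform-specific splicing around editing sites is
  not modelled.
* The expression module consumes externally computed log2FC/Padj; it does
  not fit a negative-binomial DE model itself.
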