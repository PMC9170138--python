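# Methods

## The mapping model

`fhmap` implements pooled-sequencing homozygosity mapping for a fully
penetrant recessive trait in an F2 intercross between two divergent inbred
lines. The assumptions are those of the classical design: both parents are
fully inbred (homozygous everywhere), the causal allele arose on the
mutant-line (LVG) background, F2 offspring are produced by F1×F1 matings,
and phenotypic selection retains exactly the homozygous-mutant F2. Around
the causal locus the selected pool is then fixed for the LVG haplotype,
and the expected frequency of the LVG background decays toward 0.5 with
genetic distance from the locus.

Per-SNP evidence is encoded as a weight in {0, 0.2, 0.5, 0.8, 1}: a pool
SNP homozygous for an allele private to one parent is maximal evidence for
that background (1 for LVG, 0 for BIO); a heterozygous pool call at such a
marker is damped evidence (0.8/0.2); sites that are uninformative
(both parents sharing the same homozygous allele while the pool is also
homozygous) are skipped, and everything ambiguous scores 0.5. The damped
heterozygous weights exist because the two parental marker sets are very
unequal in size (the reference genome derives from the LVG ecotype, so
roughly three times as many private SNPs are called against the BIO
parent); with hard 1/0 weights the denser marker set would dominate every
window.

Windows are rolling runs of 100 *scored* SNPs (skipped SNPs do not occupy
slots), advancing one SNP per step and never spanning contigs. Windows with
mean ≥ 0.9 are LVG-linked and ≤ 0.1 BIO-linked (both thresholds inclusive);
qualifying windows of the same label that share a contributing SNP or are
adjacent in window order are merged. Because window means are averages of
values that are exact multiples of 0.1, window sums are accumulated as
scaled integers and divided once, so the rolling mean is exactly the
brute-force mean with no accumulated rounding drift. Region bounds are the
min/max positions of contributing SNPs — a conservative, reproducible
convention (window centres and midpoint interpolation are alternatives the
merger deliberately avoids). A `min_windows` knob (default 1: a single
qualifying window already forms a region) is exposed because the original
procedure states no minimum.

Marker classification is allele-aware: "unique homozygous" means
homozygous for a non-reference allele in one parent that the other parent
is not homozygous for. Two parents homozygous for *different* alternate
alleles are informative but ambiguous and fall into OTHER (weight 0.5)
rather than SHARED_HOM; a parental call below 5× depth is demoted to
missing before classification, symmetric with the pool coverage rule.
"Total coverage" of a call is the DP field when present, else the sum of
allele depths. Only SNPs that the pool itself carries (non-missing call
including at least one alternate allele) enter the scan; INDELs are
excluded from scoring but retained for candidate filtration.

## Candidate filtration

Five filters applied in a fixed order, each recorded per variant:

1. position inside an LVG-linked region (1-based closed containment);
2. unique to the mutant line: the LVG parent *and* the pool carry an
   alternate allele (any zygosity) that the BIO parent does not carry;
3. most severe consequence across overlapping transcripts is HIGH or
   MODERATE putative impact;
4. cluster screen: more than one other variant within ±50 bp (one combined
   up+downstream count, against the full pre-filter variant list — a proxy
   for alignment-noise pileups; both the radius, the neighbour budget and
   the background list are configurable);
5. reading-frame confidence: a candidate in a transcript whose reference
   CDS is not a complete reading frame (length divisible by 3, ATG start,
   terminal stop, no internal stop) is re-checked in all three forward
   frames and dropped only if every frame contains ≥ 2 stop codons — the
   signature of a spuriously annotated transcript in a low-quality
   assembly region. An incomplete frame that is open in some frame passes
   with a low-confidence warning.

The cluster and frame rules replace an interactive pileup-inspection step
with deterministic criteria plus a complete audit trail (each candidate
keeps pass/fail flags for all five filters; a dropped candidate always has
at least one failing flag recorded).

## Consequence annotation

The annotator re-translates the mutated coding sequence: substitutions
become synonymous / missense / stop_gained / stop_lost / start_lost by
codon comparison; indels with net coding length not divisible by 3 are
frameshifts (with the premature stop located by translating the shifted
sequence), otherwise in-frame indels. Splice region is the 2 intronic
bases flanking internal exon boundaries; exonic-but-noncoding positions
are UTR; positions inside a transcript but outside exons are intronic;
everything else is intergenic. Impact is a pure function of category
(frameshift/stop/start/splice → HIGH; missense/in-frame indel → MODERATE;
synonymous → LOW; intronic/UTR/intergenic → MODIFIER). Protein notation is
simplified HGVS — `p.P193fs`, `p.A12D` — with no 3′-rule repositioning of
indels. Minus-strand transcripts are handled by performing all coordinate
surgery in plus orientation and reverse-complementing last; indels are
supported within a single CDS interval (the scope needed for the toy gene
models used throughout). The standard nuclear codon table is used, via
Biopython's table data; the test-suite oracle uses an independent,
hand-written 64-entry table.

## The cross simulator

The simulator emulates the study design rather than sequencing physics:

- **Parents.** Each contig is a uniform-random sequence carrying private
  marker SNPs of each parent placed by Poisson counts at configurable
  densities (defaults 100/Mb LVG-unique vs 300/Mb BIO-unique, emulating
  the ~1:3 imbalance of the real cross), plus small densities of shared
  and conflicting homozygous sites to exercise the SHARED_HOM/OTHER paths.
  The causal allele is a 1-bp deletion in codon 193 (Pro) of a planted
  1,788-nt single-exon gene, so a successful end-to-end run annotates the
  causal candidate as a `p.P193fs` frameshift.
- **Meiosis.** Haldane model: crossover counts per gamete per contig are
  Poisson (default 0.1 per 10-Mb contig, ~1 cM/Mb, the mammalian
  genome-wide average; the hamster map is unknown) with uniform breakpoint
  placement and no interference. Contigs are independent scaffolds —
  origin at the left end is drawn independently per contig.
- **Selection and pooling.** Phenotype is fully penetrant recessive
  (the two phenotype classes in the real cross were cleanly separable, so
  no misclassification is modelled). A pool of 45 mutants is drawn; at
  each site the pool's true allele frequency follows from the selected
  gametes' local ancestry, total depth is Poisson (default 30×), allele
  depths are multinomial, and the genotype is called heterozygous when the
  minor-allele read fraction reaches 0.1 (a crude stand-in for a diploid
  caller applied to pooled DNA; configurable), homozygous otherwise,
  missing at zero depth. A small genotype-error rate (default 0.001)
  perturbs calls in all three samples.
- **Cohort size.** The default demo cohort is 300 F2 with a pool of 45.
  Under 25% recessive segregation a 197-animal cohort (the historical
  size) fails to supply 45 mutants in roughly one replicate in five, which
  would abort pooling; 300 keeps the pool available in essentially every
  replicate while leaving all other study conditions unchanged. The
  197-animal cohort is retained as-is wherever segregation itself is the
  quantity under test.

What the simulator does **not** model: read-level errors and mapping bias
(the real SNP imbalance is emulated by density parameters, not by
alignment), recombination interference, incomplete penetrance, and
polygenic phenotype variation. Passing tests therefore demonstrate the
correctness of the scoring/windowing/filtration machinery under the
declared design, not robustness to alignment artefacts in real data.

## Circadian phenotyping

Activity onsets of a nocturnal rodent in constant darkness drift by
(τ − 24) h per day, so the free-running period is 24 h plus the
least-squares slope of onset time against day (onset times are kept
unwrapped — free to drift past midnight). A light-pulse phase shift is
estimated by fitting separate regressions to pre-pulse onsets (days up to
and including the pulse day) and post-pulse steady-state onsets (by
default the 10 days following the pulse, with a configurable count of
excluded transient cycles, default 0), extrapolating both lines to the
first post-pulse cycle, and taking pre-predicted minus post-predicted
onset — positive for advances (earlier onsets), negative for delays —
reduced modulo τ into (−τ/2, τ/2]. Circadian time of the pulse uses the
convention CT12 = activity onset, with circadian hours scaled by 24/τ.
Animals with τ ≤ 23.5 h are classed as short-period mutants (the two
phenotype distributions, ~22.7 h vs ~24.0 h, are far from this boundary).
Onset detection from raw wheel-running counts is out of scope; the input
is the onset time series itself.

## Problem sizes and numerical choices

The bundled demo cross is 2 × 10 Mb contigs (~8,400 sites, pool of 45 at
30×); a full simulate–scan–filter cycle takes well under a second of
compute after simulation (~0.7 s per replicate in total), and the
replicated recovery experiments in the test suite and acceptance script
use 100 fresh replicates. Phase-shift recovery experiments use 200 noisy
replicates at 0.25 h onset noise; the annotation oracle sweep uses 1,000
random CDS/variant pairs including both strands and 1–4 bp indels. All
randomness flows from a single integer seed per run; reruns are
byte-identical. Window means are exact (integer accumulation, one
division); regression fits use ordinary least squares via
`numpy.polyfit`; ties at the homozygous-call threshold (minor fraction
exactly 0.1) call heterozygous, and thresholds printed as ≥/≤ are
implemented inclusively.

## Known limitations

- The annotator is deliberately miniature: no 3′-shifting HGVS, no
  multi-interval indels, no UTR-regulatory or splice-branch effects, and
  the most-severe-consequence rule stands in for transcript prioritisation.
- Region calling reports no statistical significance — the thresholds are
  the procedure's fixed 0.9/0.1 rule, not a calibrated test.
- The pooled genotype caller is a threshold rule, not a likelihood model;
  at marginal depth it is noisier than a real caller.
- Marker densities, crossover rates and error rates are order-of-magnitude
  choices for a genome whose true recombination landscape is unknown; they
  are all exposed in `CrossConfig`.
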