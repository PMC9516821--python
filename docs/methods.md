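# Methods

`falseloss` quantifies how much of a genome — and which parts of its
genes — is missing or misrepresented in a lower-quality ("prior")
assembly relative to a high-quality reference of the same individual or
species, and classifies each affected gene into one of eight
false-gene-loss types. This note describes the models and procedures,
the simulator that makes them testable at desk scale, and the numerical
and design choices a maintainer would want to know about.

## Missing-region model

A reference base is called *missing* in the prior assembly only when it
is unaligned under **two** independent whole-genome alignments; the
per-base intersection of the two unaligned sets is the conservative
estimate used everywhere downstream. The rationale is that anchoring
strategies differ in how they treat masked and high-frequency sequence,
so each aligner's unaligned set contains tool-specific artifacts that
the intersection removes. Falsely duplicated regions are excluded after
merging nearby duplication intervals at 25 kbp, so that a haplotype
duplication in the reference cannot masquerade as prior-assembly loss.

Alignments are consumed as PAF (with or without `cg:Z` CIGAR). For
self-contained runs a minimizer anchor aligner (`anchor_align`, default
k=15, w=10, colinear chaining with ≤1 kbp between anchors, minimizer
occurrence cap 8) is provided. It seeds only from unmasked sequence —
repeats are spanned when flanking anchors share a diagonal but cannot
cross-seed between copies — and splits blocks at N runs, since no
aligner reports alignment through assembly gaps. It is a stand-in for
desk-scale, high-identity comparisons, not a general aligner; supplied
PAF always wins over it.

## Content metrics

GC content is G+C over non-N bases; an all-N interval is undefined and
excluded from averages. Repeat content is coverage by the softmask
(FASTA lowercase, or a BED track that takes precedence). CpG islands
follow the classic definition — length ≥ 200 bp, GC > 50%,
observed/expected CpG = (#CpG·len)/(#C·#G) > 0.6, both inequalities
strict — evaluated over 100-bp windows shifted by 1 bp; overlapping
qualifying windows are fused and fused regions are kept only when they
satisfy both criteria themselves. Windows containing N never qualify.

The 10-kbp block comparison of missing versus present sequence is
offered in two modes: `window` tiles each sequence and classes a window
as missing at ≥ 50% missing coverage; `concat` pools missing bases (and
separately present bases) genome-wide and re-tiles each pool into
10-kbp blocks before computing GC and repeat content. The concatenation
mode is the primary read-out for direction-of-bias statements (one-sided
Wilcoxon rank-sum on block GC and repeat content) because it weighs each
missing base once rather than through window composition.

## Gene-level missingness

One representative transcript per gene: the longest by summed exon
length, ties broken by lexicographically smallest transcript id (the tie
rule is this package's choice; common practice states only "longest").
An exon is *completely missing* iff it lies entirely within the missing
regions **and** no local-similarity rescue exists: hits are eligible
when the exon exceeds 15 bp, hit identity ≥ 90% and per-hit coverage
≥ 50%, and rescue requires unique query coverage (each exon base counted
once, the `qcovus` convention) strictly above 90%. A gene is completely
missing iff all its exons are. Per-gene missing percent covers the full
transcript span including introns by default (exon-only available),
feeding an ECDF whose standard read-out is the fraction of genes with
<10% missing.

Metagene profiles use 100-bp blocks across 3 kbp upstream of the TSS
and 3 kbp downstream of the TTS, strand-oriented, with gene bodies of
coding genes with ≥4 coding exons partitioned into 5′UTR / first /
internal / last coding exon / 3′UTR (exons carrying both UTR and CDS are
split at the boundary). A block is missing iff ≥ 90% of its bases are
missing. Genes are stratified by the presence of a CpG island ending
within 3 kbp upstream of the TSS (strand-aware; overlap counts as
distance 0; downstream islands are ignored).

Missing bases are attributed to prior-read support (prior-individual
reads mapped to the reference at ≥1× depth), to prior assembly gaps, or
to neither. Gap support is decided by interpolation: the prior-side span
bracketed by the missing interval's nearest aligned neighbours is
checked for overlap with an N run — a direct lift is impossible because
gaps are by definition unaligned.

## False SNPs and short indels

Candidates are variants carried by the prior assembly but not by the
alternate haplotype, with indels strictly under 10 bp, left-aligned, and
mapping to a single prior locus. Multi-nucleotide substitutions are
split into per-position SNVs. Sites where the *reference-side* pileup
shows more than 10 reads with more than 20% alternate support — real
heterozygosity or reference base error — are excluded together with 2 bp
of flank; both thresholds are strict, and the exclusion commutes with
the carrier filter. Variants in homopolymers (runs of ≥5 identical
bases) are annotated, not removed. When no VCF is supplied, variants are
extracted from alignment chains (mismatches inside blocks; clean
one-sided inter-block gaps as indels).

## Eight-type classification

Each coding gene's representative transcript is projected onto the prior
through the chains. Structural calls come from lift geometry plus hit
rescue:

- **completely_missing** — no lifted exon bases and no eligible hit;
- **missing_exon** — ≥1 exon with no lifted bases and ≤90% unique hit
  coverage (in a gene that is not completely missing);
- **fragmented** — lifted exons on more than one prior scaffold, with
  ≥1 hit intersecting each split locus;
- **translocation** — one scaffold but discordant orientation or order
  of the lifted exons, same hit-overlap requirement.

The projected CDS is assembled strand-aware from lifted CDS pieces.
Prior-side insertions between colinear pieces are spliced in, and an
unlifted reference span whose bracketing lifts are colinear with an
equal-length prior span is filled from the prior (capped at 60 bp) —
this is how a projection reads through an assembly gap and what keeps
prior N runs visible (**cds_Ns**). Sequence-level calls:

- **frameshift** — indels between reference and projected CDS (global
  affine alignment, match 1 / mismatch −2 / open −5 / extend −1) with
  length not a multiple of three and strictly under 10 bp; each
  qualifying indel is one event, including compensating pairs.
- **premature_stop** — the codon scan is alignment-anchored: reference
  codons are read off matched alignment columns, so a frameshifted
  projection cannot spray false stops downstream of its indel. A
  projected stop at a non-stop reference codon is a candidate only when
  the 5-base genomic flanks on both assemblies are identical
  (orientation-aware), which suppresses paralogous lifts.
- **splice_disruption** — donor and acceptor dinucleotides (with the
  canonical set GT-AG, GC-AG, AT-AC) are lifted; an intron is comparable
  only when both sites lift contiguously to one scaffold with consistent
  orientation and a single colinear prior intron between them. Events
  require a canonical reference junction and a non-canonical prior
  junction; prior junctions containing N are skipped and counted
  separately.

Frameshifts, premature stops and splice disruptions are validated
against a prior-assembly read pileup over the event locus ±2 bp: fewer
than 10 reads at any position, or ≥ 80% of reads carrying a mismatch or
indel (frameshifts: ≥ 80% carrying an indel), confirm an assembly error;
otherwise the event is rejected as a plausible real variant; missing
pileup leaves it unvalidated. A completely missing gene emits no other
record type. The summary reports per-type counts, confirmed counts, and
the fraction of annotated genes with at least one false loss.

## The synthetic paired-assembly generator

The simulator produces the statistical structure the analysis assumes,
with a machine-readable truth ledger. Defaults define the standard
conditions: 4 sequences × 1.25 Mbp; 300 coding genes (4–8 coding exons,
GT-AG introns, in-frame CDS without internal stops) plus 40 two-exon
lncRNA genes; 75% of coding genes carry a 1-kbp, 70%-GC, CpG-retaining
promoter and GC-rich first exon that satisfy the CpG-island criteria;
background at 42% GC; ~600 intergenic softmasked repeat copies from 3
families (400–800 bp, 1% copy divergence).

Degradation: every 100-bp tile is lost with probability
`logistic(s·(GC − g0))` (defaults g0 = 0.60, s = 12; s ≤ 0 disables
dropout entirely), half deleted and half replaced by N runs; 25% of
repeat copies are collapsed (deleted with a contig break, modelling
repeat-driven fragmentation); 40 events of each of the eight types are
engineered at randomly chosen eligible genes; 200 heterozygous sites and
200 GC-biased base errors are substituted in neutral sequence. Reads are
summarised as per-position pileups from a Poisson read-start process
(30×, 150 bp, 0.2% error): reads carry the truth, so prior-assembly
error sites show ~100% contradicting reads while het sites show ~50% on
both assemblies; reads do not map onto N runs. A separate prior-read
depth track over the reference is nominal outside missing regions and
sparse (0.5×) inside them. Exact alignment chains are emitted from the
edit script and written as two PAF dialects (CIGAR chains, and
block-resolved CIGAR-free lines) to stand in for two aligners; the toy
aligner is an independent cross-check.

Ground-truth identifiability is a deliberate design constraint: GC
dropout trims at exact exon boundaries and never deletes exon bases or
engineered loci; repeats are intergenic; random substitutions avoid
exons (±10 bp) and splice junctions; at most two compatible
sequence-level events share a gene (never frameshift with premature
stop), in distinct exons/introns. Each gene-level defect therefore has
exactly one recorded cause, which is what makes per-type sensitivity
and precision against the ledger meaningful. Background sequence is
CpG-depleted (≈0.25 of chance CpG retained, as in methylated vertebrate
genomes); without depletion, an i.i.d. 42%-GC background is littered
with chance CpG islands and the CGI+/CGI− stratification collapses.

What the simulator does **not** model — and hence what passing tests do
not establish about real data: real repeat families and their phylogeny,
sequencing-chemistry error profiles, alignment ambiguity in segmental
duplications, annotation errors in the reference, isoform diversity
(one transcript per gene), and biological inter-individual variation
beyond simple het sites. Recovery rates on the bundle are upper bounds:
the chains are exact where a real aligner would be noisy.

## Numerical choices and degenerate inputs

All coordinates are 0-based half-open; GFF3 converts at the boundary.
Interval sets are kept sorted and disjoint, and all operations are
tested against per-base boolean-array oracles. Lift of an interval
through chains keeps only aligned sub-spans, so lift followed by the
reverse lift is always contained in the original. Zero-length targets,
all-N windows, genes without transcripts, chains referencing unknown
sequences, and infeasible simulator packings raise immediately with the
offending object named. The pairwise CDS aligner scores are configurable;
the defaults favour mismatches over spurious indel pairs so substitution
runs (including N fills) do not masquerade as frameshifts.

## Problem sizes

The shipped configurations are desk-scale by design: the standard bundle
is 5 Mbp / 300 genes / 320 engineered events and runs the full pipeline
in well under a minute; unit fixtures are 0.2–0.8 Mbp. All sizes are
configuration, not code, and scale up without modification.

## Known limitations

The fragmented/translocation distinction follows lift geometry rather
than an annotation tool's split-gene labels; genes split by real
structural variation between individuals would be misclassified as
assembly error (the read-validation step exists precisely to flag such
cases at sequence level, but structural calls carry no read check).
The exon-hit rescue route in the self-contained pipeline derives from
the same chains as the lift, so rescue is only exercised independently
when external hits are supplied. The pileup exclusion uses the
reference-side pileup only; a `--both-sides` variant would additionally
require prior-side support and is left to the caller by supplying a
second Pileup.
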