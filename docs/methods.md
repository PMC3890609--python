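# Methods

## Scope and model

`gliascan` quantifies the celiac-disease (CD) epitope content of the
alpha-gliadin fraction expressed in developing wheat grains from deep
amplicon sequencing of the N-terminal first repetitive domain. The
analysis assumes:

* amplicons cover the whole domain in one read (454-scale read lengths;
  the domain is 240–281 nt / 80–94 residues after trimming), so no
  assembly is needed and each read is an independent observation of one
  transcript;
* the dominant sequencing error mode is a ±1-base change of a
  homopolymer run, with a lower uniform substitution rate;
* read counts are proportional to transcript abundance within a sample
  (equimolar pooling, no length bias within the narrow size range);
* epitope activity can be assessed on the non-deamidated (Q-form)
  9-mer cores by exact string matching — deamidation chemistry and
  HLA-binding affinity are out of scope.

## Denoising and clustering

Unique sequences are counted exactly (every gap and mismatch is a
difference), then homopolymer artefacts are merged into their source:
a rare unique joins a dominant one when the dominant has at least
`min_ratio` (default 5) times its raw read support and an optimal
alignment shows only 1–2 single-base indels, each inside a homopolymer
run (length ≥ 2) of the dominant sequence, and no substitutions. The
merge criterion is verified per indel on the edlib alignment path; a
base-composition distance test (indel-only variants change each base
count by ≤ 1) rules out most pairs without aligning. Ratios use
pre-correction read support, making the procedure order-independent in
effect and deterministic.

Uniques with ≥ 20 reads in at least one sequencing run (pooled counts
when no run structure is annotated) enter greedy clustering: scanning
in decreasing abundance, a record joins the first cluster whose
*representative* (founding member) is ≥ 99.5% identical, else founds a
new cluster. Identity is `1 − d/max(|a|,|b|)` with `d` the Levenshtein
distance. This is equivalent to the matched-columns definition for the
equal-length, substitution-dominated comparisons that decide cluster
membership here, and — unlike an alignment-column count — it is free of
tie-breaking ambiguity between optimal alignments, so an independent
dynamic-programming oracle reproduces it exactly. Clusters with ≤ 20
pooled reads are discarded (dropped read mass is reported; read-mass
conservation is asserted at every stage).

Consensus is an abundance-weighted per-column majority over members
aligned to the representative; ties, including insertion decisions,
resolve toward the representative.

A consequence of the 99.5% threshold at these amplicon lengths is that
transcripts differing by a single nucleotide merge into one cluster.
Real paralogous gliadin transcripts differ at silent sites as well, so
the simulator's reference panel guarantees ≥ 2 nt between templates
(see below); users comparing near-identical alleles should raise the
identity threshold.

## Trimming

Both domain boundaries are located by sequence content with IUPAC
degenerate matching (≤ 1 mismatching position, configurable): the
domain starts after the last 15 nt of the signal-peptide coding region
and ends at the reverse-primer-region match; the degenerate forward
primer must additionally be present. Content anchoring matters: with a
fixed-offset cut, an indel between primer and domain shifts the frame
and produces edge variants whose read support scales with template
abundance, biasing recovered abundances upward for dominant templates.
Reads failing any anchor are kept as QC records with a reason, never
silently dropped. Coordinates are 0-based half-open internally. The
240–281 nt window is a QC flag, not a filter.

## Quantification

Normalised transcript abundance is `100·reads(s,u)/total(s)` (per-100
transcripts; rows sum to 100 before filtering). UPFs are kept when some
sample shows abundance ≥ 0.1 *and* more than 5 reads; abundances are
not renormalised after filtering, so filtered rows may sum below 100 —
matching the published convention in which per-profile totals of main
components are below 100. The CD immunogenic potential of a sample is
`Σ_u canonical(u)·a(s,u)/100` (canonical DQ2.5 cores per transcript);
single-epitope abundances are reported per 100 transcripts.

Fragments with internal stop codons are translated through, flagged,
and retained: pseudogene transcripts whose premature stop lies
downstream of the epitope region still encode immunogenic peptides.
Sub-genome assignment uses diagnostic motifs with precedence
D/B > D > B > A, because the A-genome "YS" dipeptide occurs in nearly
every fragment and would otherwise mask B/D signatures; "YS" is matched
anywhere in the fragment, as no fixed position is defined for it.

## Expression profiles

Samples are grouped by average-linkage hierarchical clustering on the
Pearson correlation distance `d = 1 − r` between abundance vectors,
cut at a configurable height (default 0.5). Published analyses of this
assay used a clustering-tool-internal threshold (2.075) that exceeds
this metric's range [0, 2] and cannot be mapped onto it, so the cut
height is a free parameter; the recoverable quantity is the grouping
itself. In simulations, replicate samples of one mixture sit at
d < 0.01 while distinct mixtures sit at d ≈ 0.13–0.7, so any cut in
that gap (the recovery test uses 0.05) separates mixtures exactly.
Zero-variance abundance vectors yield undefined correlations; they are
flagged NaN and treated as maximal distance when clustering.

## The simulator

The simulator emulates the study design: per-sample 10-bp barcodes
(minimum pairwise Hamming distance 3, so the 1-mismatch demultiplexing
rule is unambiguous), a fixed 57-nt signal-peptide flank beginning with
the degenerate-forward-primer site, the in-frame domain, and the
reverse-primer region. Template draws are multinomial on the designed
mixture; errors are per-run homopolymer ±1 events (default 0.01/run)
plus uniform substitutions (default 0.001/base — pyrosequencing error
is indel-dominated, with substitutions roughly an order of magnitude
rarer). All randomness flows from one seed; identical seeds give
byte-identical output.

Reference templates are built by deterministic reverse translation
(fixed, wheat-leaning codon table) of the published epitope-region
fragments, embedded in a fixed domain scaffold free of catalog epitope
cores and sub-genome motifs, padded to a constant 86 residues (258 nt).
Two deliberate departures from naive reverse translation keep the panel
realistic and well-posed:

* fragments whose printed epitope regions are identical (distinct
  gene-family members can share the region) receive one distinguishing
  scaffold substitution each, using residues absent from the epitope
  alphabet with codons ≥ 2 nt from every scaffold codon;
* a parity-coded CAA/CAG synonymous tag on the first eight glutamine
  codons guarantees that any two templates differ by ≥ 2 nt, as real
  paralogues do at silent sites; otherwise two templates one codon
  apart could be 1 nt apart and inseparable at 99.5% identity.

Constant template length keeps the per-read retention probability
(the chance a read survives trimming, denoising and the abundance
gate, ≈ 0.72 under default rates) uniform across templates — verified
empirically to within sampling noise — so recovered abundances are
unbiased estimates of the simulated mixture.

What the simulator does **not** model: PCR amplification bias and
chimeras, flowgram-level 454 noise, quality-score structure,
length-dependent sequencing efficiency, and biological variation
between replicate cDNA preparations. Passing recovery tests therefore
demonstrate correctness of the analysis pipeline under the stated error
model, not robustness to every artefact of real amplicon data.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at the study's
per-sample scale: replicate concordance at depth 4,478 (the study mean)
with Pearson r ≥ 0.99 between independently simulated replicates;
mixture recovery at depth 5,000 with abundances compared to the
realised template draws within three binomial standard errors; profile
recovery over 15 samples (3 mixtures × 5 replicates) at depth 5,000.
Greedy clustering and pairwise identity are checked against brute-force
reimplementations on 200 random instances of up to 50 unique sequences.
Boundary semantics are inclusive as published: a cluster needs *more
than* 20 pooled reads (≥ 21), the gate needs *more than* 19 reads per
run (≥ 20), the UPF filter needs *more than* 5 reads (≥ 6) at abundance
≥ 0.1. Tie-breaks are deterministic everywhere: dereplication orders by
count then sequence; consensus ties go to the representative; profile
group ids are renumbered in sample order.
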