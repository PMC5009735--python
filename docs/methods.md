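# Methods

## Crosslink extraction

The truncation model of iCLIP places the reverse-transcription stop at the
protein-crosslinked nucleotide, so the contact point is one base upstream of
the read start in transcript direction. With 0-based half-open alignment
coordinates the rule is: `+` strand alignment starting at *s* → crosslink at
*s* − 1 on `+`; `−` strand alignment with end *e* → crosslink at *e* on `−`
(the mirror of the `+` rule in transcript direction). Alignments whose
crosslink falls off the chromosome (position −1, or position equal to the
chromosome length) are dropped and counted.

Demultiplexing matches the first three read bases against the known sample
codes exactly; bases 4–7 are the UMI; all seven barcode bases are trimmed.
PCR duplicates are defined by exact identity of (chromosome, crosslink
position, strand, UMI); no edit-distance UMI merging is attempted, because at
4-nt UMI length error-tolerant merging would collapse genuinely distinct
molecules far more often than it would rescue sequencing errors. The duplicate
key uses the crosslink position rather than the alignment start so that the
rule remains stable under soft-clipping in real alignments (for the fixed-
length untrimmed reads of the simulator the two coincide). Unique cDNA counts
of replicate experiments are summed per site by `merge_replicates`.

## Peak calling

The statistic at a crosslink site is its *window score*: the sum of unique
cDNA counts over same-strand sites within ±`half_width` nt (default 15, so a
31-nt window). Sites are grouped by the same-strand gene containing them; a
site outside any gene is analyzed against a pseudo-gene spanning its ±500 nt
neighborhood, because intergenic crosslinks still need a local null. Each of
`n_perm` (default 100) permutations redistributes the group's total cDNA count
as single cDNAs uniformly over the permutation domain — the full genomic gene
span by default, exonic positions with `perm_domain="exonic"` — and records
window scores at the randomized occupied positions. The pooled null gives

    p(site) = (1 + #{null scores ≥ observed}) / (1 + #null scores),

which is strictly positive under finite permutations. BH adjustment is applied
genome-wide over all tested sites and significance is FDR < 0.05. Genes
shorter than one full window are analyzed but flagged. Determinism comes from
a single seeded generator consumed in sorted gene order.

Because the window statistic is shared, every position whose window overlaps a
strong site is individually (and correctly) significant. For positional
reporting, `peak_summits` clusters significant sites closer than the window
half-width and reports each cluster's maximum-count position, breaking ties by
window score and then leftmost position. Note that BH controls the FDR in
expectation: on typical default-scale runs zero or one of ~30 summits is a
false discovery, which is the designed behavior of a 5% FDR procedure rather
than a defect.

Two conventions in the window statistic are deliberately configurable because
the field uses both: `half_width` (±15 vs a 15-nt total window) and whether
permutations redistribute single cDNAs (default) or preserve per-site count
multiplicities.

## Feature assignment and density enrichment

A site in a same-strand protein-coding gene takes a single class with priority
3UTR > 5UTR > ORF > intron across overlapping transcripts; 3'UTR priority
matches the biology of ARE-binding proteins, and the order is configurable in
spirit (the priority list is a module constant). Sites inside genes on the
opposite strand only are "antisense" and are excluded from 3'UTR statistics
and k-mer windows. Class fractions are weighted by unique cDNA count; density
is count per annotated nt of the class (positions unioned across transcripts
within a gene), and enrichment is the class density divided by the genome-wide
mean density. Binding targets are genes whose summed unique cDNA count reaches
`min_unique_cdna` (default 2, i.e. more than one cDNA), optionally restricted
to one region class.

## k-mer analysis

For each sense crosslink in one feature class (3'UTR or ncRNA) a sequence
window over transcript-direction offsets (default −50..+50) is extracted,
reverse-complemented on `−` genes and clipped at the boundaries of the
containing feature interval (clipped windows are kept with their clipped
sequence rather than discarded, so boundary-proximal sites still contribute).
The observed score of a k-mer is the fraction of windows containing it at
least once. Each of `n_random` (default 100) randomizations draws the same
number of positions uniformly (length-weighted) from the class's annotated
intervals and is scored identically; then z = (observed − mean)/sd over the
randomizations. When the randomization sd is zero the z is defined as 0 if the
observed score equals the mean and as ±10 otherwise, keeping the table finite
and sortable. Output k-mers are transliterated T→U. k defaults to 5; k = 8 is
routinely used to resolve the full tandem-zinc-finger octamer. The window
specification is exposed rather than fixed because published descriptions of
this analysis mix two window conventions; the (−50, +50) window is the
default. Ranking is by z with lexicographic tie-break.

Downstream motif analyses should be run on FDR-filtered sites: unfiltered
tables mix one-cDNA background positions into the windows and dilute the
observed scores (the pipeline and acceptance script do this filtering).

## RNA maps

Junctions are collected one per gene from the transcript with the longest
3'UTR (preventing isoform double-counting). Offset 0 is the first 3'UTR
nucleotide (ORF–3'UTR) or the first nucleotide past the transcript end
(3'UTR–intergenic); offsets are transcript-directional. Raw per-offset sums of
unique cDNA counts, split by sense/antisense relative to the junction's gene,
are normalized by (number of crosslinks used) × (number of junctions whose
transcript covers that offset) — the length correction; on the intergenic side
of a 3'UTR–intergenic junction coverage is unconditional. Because the
appropriate crosslink denominator is ambiguous (all crosslinks vs those inside
windows), both normalizations are emitted as separate columns; the
window-restricted one feeds the smoothed profile. Smoothing is a centered
running mean of width 15 (configurable); a moving average was chosen over
kernel alternatives because it preserves mass away from boundaries and has an
obvious window interpretation.

## DE integration

DE tables arrive as (gene_id, log2fc, pvalue, padj) rows per modality
(abundance, translation); fitting the upstream count model is out of scope.
Genes present in only one modality are treated as non-significant in the
missing one. The overlap summary partitions DE genes (padj below threshold,
default 0.05) into RNA-only/both/Ribo-only, overall and restricted to a
binding-target set; percentages are recomputed from counts and rounded
half-up to one decimal, matching how such tables are printed. One caveat is
recorded: in the published table this summary mirrors, the "bound targets in
translation" row percentage is not consistent with any single denominator in
the table (548/1681 = 32.6% vs the printed 34.7% = 548/1577); this package
reports that row against the bound-DE total and treats the count as the
primary quantity.

Target-vs-non-target fold-change comparisons use the two-sided Wilcoxon
rank-sum test with continuity-corrected normal approximation, switching to the
exact null enumeration when both groups have at most 8 untied observations;
with no separation at all (all values identical) p = 1 by definition. Gene-set
response counts genes increased/decreased (padj < threshold, signed log2FC)
per modality, with the binding-target member count of each group.

## Synthetic data: what it emulates and what it does not

The generator produces a single-chromosome genome (simple fixtures, simple
browser tracks) of non-overlapping genes separated by intergenic gaps. Each
protein-coding gene has a 5'UTR (30–100 nt), an ORF (300–900 nt, divisible by
3, ATG...stop, with one intron at a codon boundary in 30% of genes), and a
3'UTR (150–400 nt) carrying an AAUAAA poly(A) signal ending 20–30 nt upstream
of the transcript end. ncRNA genes (5 by default) have a single-class body.
Default scale: 100 protein-coding genes, 20 of them targets (drawn by index
without replacement).

Target 3'UTRs carry 1–2 planted ARE elements of the form WWW(AUUUA)WWW. The W
positions draw U with probability 0.75, so the modal planted element is the
ideal ARE UU(AUUUA)UU in a U-rich context — the element this protein family
actually selects — while still producing A-substituted variants. Motif 3' ends
lie 10–100 nt upstream of the transcript end, emulating the observed
concentration of binding near poly(A) signals (maximal enrichment a few tens
of nt upstream of 3' ends); this is what makes the RNA-map maximum fall in the
final 100 nt of the 3'UTR.

Reads are 50 nt: 3 sample-code bases + 4 uniform-random UMI bases + 43
genomic bases starting one nt downstream (transcript direction) of the
crosslink. Per target gene, 50 signal reads choose a planted site uniformly
with probability equal to the 3'UTR affinity share — 0.6 in `wildtype` mode,
0.95 in `AA` (non-phosphorylatable mutant-like) mode — and otherwise land
uniformly in a random length-weighted gene, modeling diffuse residual binding
rather than artificial per-gene clusters. 500 background reads distribute over
gene spans (90%) and intergenic space (10%). Each read then spawns PCR
duplicates geometrically at rate 0.3, copying position and UMI. Qualities are
constant "I" because nothing downstream consumes them.

DE tables draw per-gene log2FC = planted shift + N(0, 0.3²); targets are
shifted −1.0 in abundance and −0.8 in translation for half of them, matching
the observed pattern that abundance changes are more frequent than translation
changes; p-values come from a two-sided normal test at standard error 0.15 and
are BH-adjusted.

Not emulated: sequencing errors, fragment-length variation, multi-isoform
genes, replicate-level count matrices, non-uniform UMI usage, mappability
artifacts, and transcript-abundance-dependent background. Passing tests
therefore demonstrate correctness of the statistical machinery and
coordinate handling under the truncation model, not robustness to alignment
noise or expression-level confounding in real libraries.

## Problem sizes and numerical choices

Tests and the acceptance script run the default scale (100 genes, ~130 kb
genome, ~2000 reads, 100 permutations, 100 randomizations), which exercises
every code path in seconds per run; the empirical-FDR check pools 10–20
background-only simulations. All randomness flows through seeded
`numpy.random.Generator` instances (stage-separated seed sequences), so every
operation is a pure function of its inputs and seed. Exact-match read
placement is a deliberately simple stand-in for an external aligner and drops
multi-hit reads, emulating unique-mapping filters.
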