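# Methods

## The analysis model

The package operates on four variant call sets for a species pair A/B: reads
of each species mapped to its own assembly (AA, BB) and to the other
species' assembly (AB, BA). All positional comparison happens on the
reference the reads were mapped to, so only AA↔AB and BB↔BA may be paired;
pairing sets from different coordinate systems is a hard error (detected via
disjoint scaffold namespaces). The pipeline makes no attempt to lift
coordinates between the two assemblies.

### Filters

Small variants require a phred-scaled QUAL ≥ `min_qual` (default 30, the
conventional GATK post-filter). Structural variants require
`min_support_pairs` ≥ 5 discordant read pairs for every type and a length of
`min_sv_len` ≥ 300 bp for deletions, inversions and duplications only —
translocations have no length, and insertion lengths from short-read callers
are unreliable, so both are exempt. Records with missing QUAL are dropped
and logged rather than guessed.

### Region model

Per transcript, in transcription orientation:

* promoter: `[TSS − promoter_up, TSS + promoter_down)` with defaults
  2000/200 bp;
* upstream: the remainder of the `gene_flank` (5 kbp) window on the TSS
  side, i.e. promoter takes precedence over upstream where they overlap;
* downstream: `gene_flank` beyond the transcript end;
* UTRs from exon sequence outside the CDS span; introns between exons;
* splice sites: `splice_core` intronic bases at each intron end. The default
  is 2 (the canonical donor/acceptor dinucleotides); the source analyses of
  this kind rarely state their splice window, so it is prominently
  configurable. Introns of ≤ 2·`splice_core` bp are entirely splice.

All windows are clipped at scaffold edges; minus-strand genes mirror every
orientation-dependent window. Labels may overlap freely (promoter reaching
into the transcript, flanks of neighbouring genes); a single fixed severity
order — SPLICE > CODING > UTR5 > UTR3 > INTRON > PROMOTER > UPSTREAM >
DOWNSTREAM > INTERGENIC — flattens a position to one class for coverage and
location tallies, while per-gene label sets keep every class (so a promoter
hit still registers for the gene even when the flattened label is another
gene's CDS). Interfaces use 1-based inclusive coordinates (GFF3/VCF); all
internal arithmetic is 0-based half-open.

Genome coverage (GCOV) is computed by painting intervals onto per-scaffold
severity arrays, which is exact; the test suite checks it against an
independent per-position classifier written directly from the definitions
above.

### Effect annotation

For a coding SNP the affected codon is rebuilt from the spliced CDS in
transcript orientation (reverse-complemented on the minus strand) and
translated with the standard genetic code: new stop → NONSENSE, changed
residue → MISSENSE, same residue → SILENT. Impact follows the SnpEff
convention: NONSENSE or any splice-core hit → HIGH; MISSENSE → MODERATE;
SILENT → LOW; everything else → MODIFIER. Coding InDels are HIGH when
frameshifting (length change not divisible by 3) and MODERATE otherwise;
they are excluded from the nonsense/missense/silent denominator, which is a
SNP-only trichotomy. Structural variants touching coding or splice sequence
are HIGH, otherwise MODIFIER. One effect is emitted per (variant, gene,
alt) — a variant inside several overlapping gene regions fans out into one
effect per gene, which is why "variants with effects" can exceed the number
of VCF records. A variant whose REF disagrees with the genome raises an
integrity error naming the position.

### Summaries

The variant rate is `floor(effective_length / n_records)`, reported as
"1 variant in N bases"; flooring (not rounding) is forced by the published
rate values this reproduces (220 from 220.77, 218 from 218.56). Effective
length is an *input* — the callable-mask length — not derived from the
genome, because the assessed fraction of a reference legitimately differs
between mapping experiments on the same assembly. Percentages are rounded
half-up to two decimals. SNP/INS/DEL counts are per-alt events (an
equal-length multi-base substitution decomposes into per-base SNPs), so type
totals can exceed row counts while multi-allelic rows count once.

### Sharing classification

Positions are indexed per (scaffold, pos) with their alternate alleles.
Allele identity is the bare alt for SNPs and the (REF, ALT) pair for
left-anchored indels — two deletions of different length share the anchor
base as ALT but are different variants. Labels: both sets with intersecting
alleles → IDENTICAL; both sets, disjoint alleles → NONIDENTICAL; otherwise
UNIQUE to the side that has the position. The published description matches
"at the same location" with an allele-aware example (A→T within vs A→G
between), which is what is implemented. SVs have no allele; equivalence is
same type, start within 50 bp and reciprocal overlap ≥ 0.8 (both
configurable); a different-type SV whose start falls within the tolerance
makes the location NONIDENTICAL. Translocation breakend pairs (MATEID)
collapse to one event at the first-sorted breakend.

### Mutation load and candidate selection

A gene's load in a category is the number of distinct filtered variants
intersecting its gene region (gene body ± 5 kbp), small and structural
variants tallied separately; each variant counts once per gene it touches.
Selection takes, per category and variant class, the load quantile at
p = 0.5 (the median) over genes with load > 0 and keeps genes strictly
above it. Strict-greater is the default so that heavy ties at the median do
not select half the genome; `strict=False` gives the ≥ rule. The quantile is
taken over loaded genes rather than all genes — with nearly all genes
carrying variants this barely differs, but it keeps the rule meaningful on
sparse data.

### GO enrichment

Annotations are closed under is_a ancestry (true-path rule) before testing.
The universe is every gene with ≥ 1 propagated term; terms with fewer than 2
annotated genes are untestable and skipped. The base test is the one-sided
hypergeometric (Fisher) over-representation p-value. Because propagation
makes parent and child terms strongly dependent, the default method is the
decorrelating *weight* algorithm: terms are processed children-before-
parents (by longest-path depth); at each term the p-value is compared with
each child's, and

* if some children are more significant, their genes are down-weighted in
  the term and all its ancestors by the p-value ratio and the term is
  retested against the remaining children;
* otherwise each child's genes are down-weighted in the child by the inverse
  ratio and the child's p recomputed.

Weighted tests round the weighted gene counts to integers before the
hypergeometric tail. On a flat ontology this reduces exactly to the classic
test. The simpler *elim* variant (remove genes of significant descendants
from ancestors, cutoff 0.01) and the classic test are also available.
Results are reported at a raw cutoff p ≤ 0.001 with no multiple-testing
correction, matching the procedure this reproduces; a correction flag exists
but defaults off. Note one consequence of *weight* semantics: when two
disjoint gene sets with planted signal sit under a common parent, the parent
(carrying the union signal) can out-compete both children and be reported in
their place — that is the algorithm attributing the signal to the most
significant node, not a defect.

### Assembly statistics

Nx is the length of the sequence at which the cumulative sum of descending
lengths first reaches x% of the total; the boundary is inclusive (a
cumulative sum hitting exactly x% assigns the current sequence). The tool
lineage behind published contiguity tables is usually unstated, so this
convention is documented and fixed. Scaffolds are broken to contigs at runs
of ≥ 10 N; shorter runs stay inside contigs and other IUPAC codes count as
ordinary bases. Genome size from a k-mer spectrum is total k-mer mass above
the error region divided by the coverage-peak depth; a spectrum that is
monotone around the candidate peak (error-dominated) is an error, not an
estimate.

## The synthetic data generator

The generator emulates the study conditions: a multi-scaffold reference
(4 × 300 kbp) with Poisson-planted N-gaps (10–60 bp), ~120 non-overlapping
multi-exon genes on both strands with valid ORFs written into the sequence
(ATG start, stop end, no internal stop, CDS length divisible by 3, phases
set), a single-rooted is_a DAG of 60 terms over 4 levels, and gene→term
annotations for 90% of genes (the rest test universe exclusion).

Variant intensities default to the observed call rates of the comparison
being emulated: ~1 SMV per 220 bp between species, ~1 per 2500 bp (A) and
~1 per 1600 bp (B) within species, with a 75/12.5/12.5 SNP/INS/DEL split;
SV rates per Mbp are dominated by deletions and translocations in the
between-species sets. Gene spacing (4.5–8 kbp between bodies) mirrors the
~1 gene per 20 kbp density of the real assemblies, so the ±5 kbp load
windows rarely overlap. Sharing is planted by re-emitting each
within-species variant into the paired between-species set with probability
0.35 (same allele, IDENTICAL), 0.15 (different allele at the same position,
NONIDENTICAL), else leaving it unique; between-species-only variants are
sampled on top. A 10% decoy fraction fails the filters by construction
(QUAL < 30, or support < 5 / length < 300) to exercise the filter stage
without touching the planted structure.

One GO term is planted with excess load: its 15 member genes receive 10×
variant intensity across their load windows in every category. The member
set is exclusive (background annotation never uses the planted term) so the
planted signal maps onto a well-defined term; with ~50% of genes selected at
the median threshold and all 15 members selected, the planted term's Fisher
p is ~10⁻⁵–10⁻⁷, comfortably below the 0.001 cutoff. Only one term is
planted by default because two planted terms below a common ancestor make
the *weight* method (correctly) report the ancestor instead — see above.

Every emitted record has a ground-truth row (dataset, position, alleles,
type, quality/support, filter fate, planted sharing label, region class);
planted per-gene loads are tallied by a direct interval check independent of
the pipeline's interval trees. A fixed config (including seed) yields a
byte-identical bundle.

What the generator does **not** emulate: read-level errors, diploid
genotypes/phasing, repeat content, mapping artifacts, and a genuinely
distinct second assembly (all four call sets live on one synthetic
reference, which is what makes the AA↔AB comparison exact). Passing tests
therefore demonstrate the correctness of the downstream computations under
clean inputs, not robustness to caller- or mapping-induced noise.

## Problem sizes and numerical choices

The default bundle is ~1.2 Mbp with ~25k small variants and ~1.1k SVs across
the four datasets; a full simulate-plus-pipeline run takes a few seconds, and
the replicate recovery study (20 seeds) a couple of minutes — sizes chosen
so the whole study is routinely re-runnable while keeping per-gene counts in
a realistic regime. Quantiles use numpy's default linear interpolation.
Enrichment p-value ties in reports are broken by term id for determinism.
Degenerate inputs (empty VCFs, gene-less GFF3s, all-zero loads, single-term
ontologies) return empty-but-valid results rather than raising, except where
a value is genuinely undefined (variant rate with zero variants is reported
as absent).

## Known limitations

* The AB/BA sets are only comparable to AA/BB because the simulation shares
  one reference; with real data the pipeline requires the user to supply the
  paired sets on a common coordinate system, and refuses otherwise.
* Stop-loss SNPs are classified as MISSENSE (no stop-retention logic).
* Insertion sequences of SVs are not modelled beyond a length tag.
* The weight implementation follows the published algorithm with the default
  significance-ratio rule; alternative ratio functions are not implemented.
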