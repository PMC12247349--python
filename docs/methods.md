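# Methods

This note records the models and procedures ap2erf implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical conventions that make every run
reproducible. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Family identification

One representative protein per gene is chosen as the longest isoform;
length ties break to the lexicographically smaller protein id so output is
deterministic. A gene enters the family when its representative carries at
least one AP2-profile hit with independent E-value ≤ `ap2_evalue_max`
(default 10⁻⁵, the conventional domain-search cutoff). B3 hits are
consulted only on genes that already qualify by AP2 domain, mirroring the
search-within-selected workflow, with the same default threshold.

Overlapping AP2 hits whose alignment envelopes share at least 50% of the
shorter envelope are merged and counted as one domain. Profile HMM searches
routinely split one biological domain into two reported fragments; counting
hits rather than merged envelopes would misassign such genes to the
two-domain (AP2) subfamily. The 50% reciprocal-overlap rule is the
package's own convention.

Architecture then gives the provisional subfamily: ≥ 2 AP2 domains → AP2;
1 AP2 + B3 → RAV; 1 AP2 → ERF, subject to tree-based revision (below).
Systematic names (`<prefix>AP2.<n>`, `<prefix>ERF<nnn>` zero-padded to
three digits, etc.) number genes within each subfamily in chromosome
natural-sort order then start coordinate, unplaced contigs last. Published
surveys of this family never state their numbering rule, so these names are
reproducible but will not match any particular published table
gene-by-gene.

Coordinates are 1-based fully closed intervals; strand is carried but never
used — every distance and overlap criterion in the pipeline is
strand-agnostic. Intron counts are `exon_count − 1`.

## Alignment

Pairwise global alignment is Needleman–Wunsch with affine gaps via
Bio.Align.PairwiseAligner: BLOSUM62, gap open 10, gap extend 0.5 (the
CLUSTALW-style defaults), a length-L gap costing `open + L·extend`, end
gaps penalized like internal ones. Of co-optimal tracebacks the aligner's
first reported alignment is used, which is deterministic. The test suite
checks optimality against exhaustive enumeration over all gapped alignments
of short sequence pairs.

"Similarity" in the duplicate criterion is percent identity over
residue–residue columns; "coverage" is the fraction of each input sequence
that falls in residue–residue columns. Both definitions are configurable;
a BLASTP-based workflow might instead use positives for similarity, which
would loosen the duplicate screen.

The multiple aligner is deliberately naive — greedy guide order by
decreasing pairwise identity, then sequence-to-profile NW where a profile
column scores as the mean substitution score over its non-gap residues. It
exists so the pipeline is self-contained on synthetic data; it is not a
MUSCLE reimplementation, and any externally produced aligned FASTA is
accepted wherever an MSA is consumed. On real, indel-rich families the
naive aligner will misalign low-complexity linkers; its job is only to keep
the conserved domain block in register, which partial deletion then
isolates.

p-distances apply partial deletion first: alignment columns with non-gap
fraction below `min_site_coverage` (default 0.9) are removed globally;
within each pair, surviving columns where either row is gapped are skipped;
the distance is the mismatch fraction of the compared sites. A pair with
zero comparable sites is an error, not a silent zero.

## Trees and tree-based classification

Neighbor joining follows Saitou–Nei: join the pair minimizing
Q(i,j) = (n−2)·d(i,j) − Σₖd(i,k) − Σₖd(j,k); pendant lengths by the
two-point formulas; negative branch lengths clamped to zero without
redistribution; Q-ties broken by the smallest (i,j) index pair so equal
inputs give identical trees. On additive matrices NJ provably recovers the
generating topology, which the tests verify on random 6–10-leaf trees and
cross-check against scikit-bio's implementation.

The NJ "root" is merely the final join point, so before any clade-based
rule runs the tree is midpoint-rooted (root placed halfway along the
longest leaf-to-leaf path). Without this, genes that happen to join last
hang directly off the arbitrary root and acquire meaningless clade
contexts.

Manual tree curation is replaced by a deterministic clade-context rule:
walk from a query leaf toward the root; at the first ancestor carrying at
least k reference leaves (default k = 3), take the plurality reference
label; ties give no context; the root itself is excluded, since a context
spanning the entire tree carries no grouping signal. Applied twice:

* **Single-domain revision.** References are architecture-certain genes
  (two-domain genes vote "AP2", provisional ERF genes vote "ERF"). A
  provisional-ERF gene with AP2 context becomes AP2 (basis recorded as
  tree override); one with no context at all becomes a Soloist; an ERF
  context keeps it ERF.
* **ERF subgroup refinement.** Each ERF gene first takes the subgroup of
  its closest labeled reference by global-alignment score (the pipeline's
  stand-in for a BLASTP best hit); a differing tree context overrides it
  and marks the gene reclassified (this is how V/VII-labeled genes that
  cluster with VI-L references end up VI-L). Genes with neither evidence
  are reported unassigned rather than raising.

k and the plurality rule are configurable; no bootstrap support is
computed and no maximum-likelihood tree is built — for subfamily/subgroup
assignment the NJ topology is the operative object.

## Duplicate classification

Candidate pairs are all family-gene pairs passing identity ≥ 80% and
bidirectional coverage > 80% (both configurable). Labels:

* **tandem** — same chromosome and start-to-start distance ≤ 1 Mb. The
  anchor point (start-to-start) is a package convention; end-to-start gap
  is available by configuration. The 1 Mb rule applies only within a
  chromosome.
* **homoeolog** — in subgenome mode, chromosomes carry the same leading
  number with differing subgenome suffixes (default 'c'/'e', configurable
  for other polyploids). These pairs are parental homologs of an
  allopolyploid, not duplications within one genome; summaries report both
  accounting conventions (homoeologs inside or outside the "segmental"
  total) because the field's headline counts use the inclusive one before
  splitting.
* **segmental** — every other qualifying pair.

All qualifying pairs are reported with no transitive reduction; tandem
clusters are the connected components of the tandem-pair graph.

## Ka/Ks (NG86)

Site counting assigns each of a codon's nine possible single-nucleotide
changes one third of a site, synonymous when the encoded amino acid is
unchanged; changes into stop codons count as nonsynonymous; every sense
codon therefore has exactly 3 sites. Between two codons, one observed
difference is classified directly; two or three are averaged over all 2 or
6 mutational orderings, excluding orderings that pass through a stop codon
(standard NG86 practice; if every ordering crosses a stop — possible only
for rare codon pairs — the average is taken over all orderings). Site
totals are per-sequence counts averaged over the two sequences and summed
over compared columns; codon columns containing gaps, ambiguous bases, or
stops are skipped with a logged count.

Proportions pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
d = −¾·ln(1 − 4p/3); pS ≥ ¾ leaves Ks undefined and flags the pair
saturated. The ratio ω = Ka/Ks is reported only when Ks > 0; undefined is
reported as such, never as NaN. Significance is a two-sided Fisher's exact
test (scipy) on [[round(Sd), round(S−Sd)], [round(Nd), round(N−Nd)]] —
the rounding is needed because NG86 sites are fractional and follows the
common calculator convention. The test suite checks the p-values against an
exhaustive hypergeometric enumeration written independently.

NG86 + JC is a deliberate simplification relative to model-averaged Ka/Ks
calculators: replicated values will differ in the second decimal on real
data, and the supported claim is qualitative (ratios below 1 ⇒ purifying
selection) plus quantitative recovery of a known generating ω on synthetic
data.

## Expression

CPM = count × 10⁶ / library size per sample; values are log₂(CPM + 1)
(pseudocount 1, configurable). A gene is "expressed" at CPM ≥ 1 in at
least one sample — the field rarely states its threshold, so this default
is explicit, configurable, and echoed into output metadata. Gene and
sample orders for heatmap export come from agglomerative clustering
(Euclidean distance, complete linkage by default) with scipy's
deterministic index-order tie-breaking. Read alignment and counting are
upstream of this package; the count-matrix TSV is the contract.

## Synthetic genomes and ground truth

The generator builds what the pipeline consumes — protein/CDS FASTA,
coordinate TSV, domain-hit TSV — plus a complete truth table, emulating:

* multi-isoform genes (representative strictly longest; extra isoforms are
  truncations);
* domain architectures from fixed canonical blocks (an AP2-like 60-mer, a
  B3-like 100-mer) embedded in random linker sequence, so hits are emitted
  from construction at E = 10⁻³⁰ with true envelope coordinates and no HMM
  scoring is needed;
* subfamily-distinct AP2 variants (ERF carries the base block, AP2 and RAV
  ~25%-diverged variants, Soloist ~45%) with 5% per-gene jitter — enough
  signal that p-distance over the retained domain columns separates the
  clades;
* tandem copies placed 0.1–0.9 Mb from their source on the same
  chromosome, segmental copies on other chromosomes, genes non-overlapping
  with ~2 Mb spacing on 11 chromosomes of 60 Mb (defaults sized to the
  diploid genomes such surveys analyze);
* an allotetraploid built by merging two diploids with 'c'/'e' chromosome
  suffixes; ortholog pairs are matched by shared ancestral gene index, so
  the sister parent is derived from the first (`diverge_bundle`) rather
  than generated independently;
* duplicate divergence by acceptance sampling on the CDS: random
  single-nucleotide proposals, stop-creating proposals discarded,
  synonymous changes accepted, nonsynonymous accepted with probability
  min(1, ω) (synonymous thinned by 1/ω when ω > 1), until the target
  amino-acid divergence is reached. Because proposals hit synonymous and
  nonsynonymous sites in proportion to their availability, the realized
  Ka/Ks tracks ω — approximately, so validation asserts recovery bands,
  not equality;
* negative-binomial expression counts (dispersion 0.1) for an exact
  round(fraction × n) subset of expressed genes, all-zero otherwise. Count
  means are specified on the nominal counts-per-million scale; because the
  matrix holds family genes only, realized CPM values are inflated
  relative to a whole-transcriptome library, which only strengthens the
  expressed/unexpressed separation being tested.

What passing on this data shows — and does not. The generator plants
substitution-only divergence (no indels, no domain loss), clean domain
tables (no marginal E-values), and linkers with no shared ancestry. Perfect
recovery therefore certifies the decision logic and the estimators, not
robustness to alignment ambiguity, fragmented gene models, or noisy domain
calls in real annotations.

The exact-recovery fixture (12 tandem, 11 segmental, 77 homoeolog pairs at
5% divergence) plants tandem and segmental events only on genes whose
homoeolog partner is absent from the sister subgenome. Otherwise a copy of
a gene with a surviving partner induces a third detectable pair
(copy–partner), and "precision against the planted list" would be
ill-posed. The general-purpose generator records such closures in the
truth table instead.

## Numerical and reproducibility conventions

* Every stochastic step takes a seed; identical seeds give byte-identical
  written bundles and reports (JSON keys sorted, fixed float formats).
* NJ Q-ties and traceback ties have documented deterministic resolutions.
* Validation experiment sizes: ω recovery uses 30 pairs × 300 codons per ω
  at 10% amino-acid divergence. At ω = 1 this leaves only ~7 synonymous
  substitutions per pair, so the mean-of-ratios estimator is right-skewed
  and run-to-run spread of the 30-pair mean is roughly ±0.15; the fixed
  acceptance bands account for this.
* Fisher oracle comparison enumerates all 2×2 tables with total N ≤ 24
  exhaustively plus a seeded sample of larger tables with margins up to
  60; full enumeration of all margin-≤60 tables (~3.6 M) would add nothing
  but runtime.
* The all-vs-all alignment pass is computed once and shared by the
  duplicate screen and the MSA guide order; on the 213-gene allotetraploid
  the full characterization takes well under a minute per stage on one
  core.

## Known limitations

* The naive progressive aligner is the weakest stage on real data; use an
  external MSA for publication-grade trees.
* NG86 underestimates rates at high divergence (saturation is flagged, not
  corrected); no maximum-likelihood codon models.
* Homoeolog detection keys on chromosome-name suffixes, not on synteny;
  rearranged or unplaced regions will be labeled segmental.
* Subgroup assignment quality is bounded by the provided reference set;
  with no references the pipeline reports subfamilies only.
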