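# ap2erf

Genome-wide characterization of the AP2/ERF transcription-factor family:
identification from profile-domain hits, subfamily and subgroup
classification with neighbor-joining trees, tandem/segmental/homoeolog
duplicate-pair classification, Nei–Gojobori Ka/Ks estimation with Fisher's
exact significance, and expression summaries — plus a synthetic-genome
generator with planted ground truth so every stage is testable end to end
without downloading genomes.

## The scientific problem

The AP2/ERF superfamily is a large group of plant transcription factors
defined by the ~70-residue AP2 DNA-binding domain (Pfam PF00847). Its
subfamilies are distinguished by domain architecture: **AP2** (two tandem
AP2 domains, development), **ERF** (one AP2 domain, stress response; further
split into functional subgroups I–X, V-L, VI-L — subgroup III contains the
CBF/DREB cold and drought regulators, subgroup IX is defense-associated),
**RAV** (one AP2 plus a B3 domain, Pfam PF02362), and the rare **Soloist**
genes whose single divergent AP2 domain clusters with neither the AP2 nor
the ERF clades. Comparative surveys of this family — typically across a
polyploid crop and its diploid progenitors — ask how many members each
genome carries, how the family expanded (tandem vs segmental duplication,
or simple inheritance of homoeologous copies from an allopolyploid's two
parents), and what selective pressure acts on the duplicates.

This package implements that survey as a reusable, tested pipeline. Given a
protein FASTA, CDS FASTA, gene-coordinate table, and a HMMER-style
per-domain hit table per species, it reproduces each analysis stage:

* **Identification** — one representative protein per gene (the longest
  isoform); a gene is a family member iff it has an AP2 hit with
  E ≤ 10⁻⁵; architecture gives the provisional subfamily.
* **Phylogeny** — pairwise-identity-guided progressive alignment, p-distance
  with partial deletion of columns under 90% data coverage, Saitou–Nei
  neighbor joining (d(ij) joined minimizing the Q-criterion
  Q(i,j) = (n−2)d(ij) − Σₖd(ik) − Σₖd(jk)), midpoint rooting, then
  deterministic clade rules: a single-domain gene nested in the AP2 clade is
  reassigned to AP2; one grouping with neither clade is a Soloist.
* **Duplicates** — all gene pairs with ≥ 80% global-alignment identity and
  > 80% bidirectional coverage; same chromosome within 1 Mb → tandem;
  homoeologous chromosomes ('2c'/'2e') in subgenome mode → homoeolog;
  otherwise segmental.
* **Ka/Ks** — protein alignments back-translated to codon alignments; NG86
  counting (⅓ site per possible mutation, pathway averaging over 2 or 6
  orderings excluding stop-crossing paths), Jukes–Cantor correction
  d = −¾ ln(1 − 4p/3), ω = Ka/Ks; two-sided Fisher's exact test on the
  [[Sd, S−Sd], [Nd, N−Nd]] table.
* **Expression** — CPM normalization, log₂(CPM+1), expressed = CPM ≥ 1 in
  any sample, hierarchical clustering for heatmap ordering.

## Worked example

Generate a small diploid genome with planted structure and characterize it:

```python
from ap2erf import pipeline
from ap2erf.pipeline import SpeciesInputs
from ap2erf.synthetic import SyntheticSpec, generate_diploid, generate_counts

bundle = generate_diploid(SyntheticSpec(
    seed=42, n_two_domain=4, n_single_domain=16, n_rav=2, n_soloist_like=1,
    n_tandem_events=3, n_segmental_events=2))
matrix, _ = generate_counts(bundle, seed=43)
report = pipeline.characterize(SpeciesInputs(
    species="demo", prefix="Dm",
    proteins=bundle.proteins, coordinates=bundle.coordinates,
    domain_hits=bundle.domain_hits, cds=bundle.cds, counts=matrix))
print(report.summary["subfamily_counts"])
print(report.summary["pair_counts"])
print(report.kaks_table.head())
```

This prints (exactly, for these seeds):

```
{'AP2': 4, 'ERF': 21, 'RAV': 2, 'Soloist': 1}
{'n_pairs': 5, 'n_tandem': 3, 'n_segmental': 2, 'n_homoeolog': 0, 'n_segmental_incl_homoeolog': 2}
   gene_a    gene_b       Ka       Ks    ratio  fisher_p  saturated
syn_g0005 syn_g0045 0.020371 0.051127 0.398437  0.151004      False
syn_g0007 syn_g0046 0.020354 0.093288 0.218185  0.001209      False
syn_g0010 syn_g0047 0.019822 0.034423 0.575833  0.424633      False
```

The generator planted 4 two-domain (AP2), 16+5 single-domain (ERF), 2
AP2+B3 (RAV) and 1 Soloist-like gene, with 3 tandem and 2 segmental
duplicate copies diverged at ω = 0.3 — the pipeline recovers every
subfamily label and pair label, and the Ka/Ks ratios scatter around the
generating ω, all below 1 (purifying selection).

The same flow is available from the shell:

```bash
ap2erf simulate --seed 42 --outdir bundle --counts
ap2erf characterize config.yaml     # paths + thresholds in YAML
ap2erf compare out/speciesA out/speciesB --out comparison.tsv
```

Each report directory holds `family.tsv`, `pairs.tsv`, `kaks.tsv`,
`tree.nwk`, `expression.tsv`, and a `summary.json` with every threshold
echoed for provenance.

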