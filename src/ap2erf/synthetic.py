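"""Synthetic genomes with planted AP2/ERF-like families and ground truth.

The generator emulates the statistical structure of the pipeline's real
inputs without any external data:

* proteins are built from fixed canonical domain blocks (an AP2-like
  60-mer, a B3-like 100-mer) embedded in random linker sequence, so the
  domain-hit table can be emitted from construction instead of HMM scoring;
* each subfamily uses its own diverged variant of the AP2 block (ERF the
  base block, AP2 and RAV ~25% diverged variants, Soloist ~45%) plus a
  small per-gene jitter, so trees recover the subfamily clades;
* duplicate copies diverge by codon-level acceptance sampling: random
  single-nucleotide proposals, synonymous changes always accepted,
  nonsynonymous ones with probability min(1, omega) (synonymous changes
  are thinned by 1/omega when omega > 1), until the target amino-acid
  divergence is reached — so the realized Ka/Ks tracks omega;
* an allotetraploid is formed by merging two diploids with chromosome
  labels suffixed (default 'c'/'e'), recording ortholog pairs (matched by
  shared ancestral gene index) as true homoeologs;
* expression counts are negative-binomial (dispersion 0.1) for a chosen
  fraction of expressed genes, all-zero otherwise.

Everything is deterministic under the seed: identical seeds give
byte-identical written bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .expression import CountMatrix
from .io_formats import (
    DomainHit,
    GeneCoordinate,
    SequenceRecord,
    write_coordinates,
    write_domain_table,
    write_fasta,
)
from .kaks import GENETIC_CODE, STOP_CODONS

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "TruthPair",
    "GenomeBundle",
    "generate_diploid",
    "diverge_bundle",
    "generate_allotetraploid",
    "generate_counts",
    "generate_coffee_like_allotetraploid",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# inverse genetic code for reverse translation (sense codons only)
_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in sorted(GENETIC_CODE.items()):
    if _aa != "*":
        _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


# canonical domain blocks: fixed constants drawn once from a pinned stream
_block_rng = np.random.default_rng(720847)
AP2_BLOCK = _random_protein(_block_rng, 60)
B3_BLOCK = _random_protein(_block_rng, 100)
AP2_VARIANTS = {
    "ERF": AP2_BLOCK,
    "AP2": _mutate_protein(_block_rng, AP2_BLOCK, 0.25),
    "RAV": _mutate_protein(_block_rng, AP2_BLOCK, 0.25),
    "Soloist": _mutate_protein(_block_rng, AP2_BLOCK, 0.45),
}
del _block_rng


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _CODONS_FOR_AA[aa][rng.integers(len(_CODONS_FOR_AA[aa]))] for aa in protein
    )


def _translate(cds: str) -> str:
    return "".join(GENETIC_CODE[cds[i : i + 3]] for i in range(0, len(cds), 3))


def _diverge_cds(
    rng: np.random.Generator,
    cds: str,
    target_protein_divergence: float,
    omega: float,
) -> str:
    """Mutate a CDS by omega-weighted acceptance sampling (see module doc)."""
    seq = list(cds)
    protein0 = _translate(cds)
    n_aa = len(protein0)
    accept_nonsyn = min(1.0, omega)
    accept_syn = min(1.0, 1.0 / omega) if omega > 1 else 1.0
    changed: set[int] = set()
    target_changes = int(round(target_protein_divergence * n_aa))
    max_proposals = 200 * len(cds)
    proposals = 0
    while len(changed) < target_changes and proposals < max_proposals:
        proposals += 1
        pos = int(rng.integers(len(seq)))
        base = "ACGT"[rng.integers(4)]
        if base == seq[pos]:
            continue
        ci = pos // 3
        old_codon = "".join(seq[3 * ci : 3 * ci + 3])
        new_codon = old_codon[: pos % 3] + base + old_codon[pos % 3 + 1 :]
        if new_codon in STOP_CODONS:
            continue
        syn = GENETIC_CODE[new_codon] == GENETIC_CODE[old_codon]
        p = accept_syn if syn else accept_nonsyn
        if rng.random() >= p:
            continue
        seq[pos] = base
        aa_now = GENETIC_CODE[new_codon]
        if aa_now != protein0[ci]:
            changed.add(ci)
        else:
            changed.discard(ci)
    return "".join(seq)


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 0
    n_chromosomes: int = 11
    chrom_length_bp: int = 60_000_000
    n_two_domain: int = 5
    n_single_domain: int = 20
    n_rav: int = 2
    n_soloist_like: int = 1
    n_tandem_events: int = 2
    n_segmental_events: int = 2
    duplicate_divergence: float = 0.05
    omega: float = 0.3
    n_isoforms_max: int = 3
    background_genes: int = 20
    species: str = "syn"

    def __post_init__(self) -> None:
        for name in (
            "n_chromosomes", "chrom_length_bp", "n_two_domain", "n_single_domain",
            "n_rav", "n_soloist_like", "n_tandem_events", "n_segmental_events",
            "n_isoforms_max", "background_genes",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.duplicate_divergence < 1):
            raise ValueError("duplicate_divergence must be in [0, 1)")
        if self.omega <= 0:
            raise ValueError("omega must be positive")


@dataclass(frozen=True)
class TruthPair:
    gene_a: str
    gene_b: str
    label: str  # tandem | segmental | homoeolog
    omega: float

    def key(self) -> tuple[str, str]:
        return (min(self.gene_a, self.gene_b), max(self.gene_a, self.gene_b))


@dataclass
class GroundTruth:
    subfamily: dict[str, str] = field(default_factory=dict)
    pairs: list[TruthPair] = field(default_factory=list)
    homoeolog_map: dict[str, str] = field(default_factory=dict)
    ancestral_id: dict[str, int] = field(default_factory=dict)
    deleted_genes: list[str] = field(default_factory=list)
    expressed: dict[str, bool] = field(default_factory=dict)
    ortholog_omega: float | None = None


@dataclass
class _Gene:
    gene_id: str
    ancestral_id: int
    subfamily: str | None  # None for background genes
    chromosome: str
    start: int
    end: int
    strand: str
    exon_count: int
    protein: str
    cds: str
    domains: list[tuple[str, int, int]]
    rep_protein_id: str = ""


@dataclass
class GenomeBundle:
    species: str
    n_chromosomes: int
    proteins: list[SequenceRecord]
    cds: dict[str, str]  # gene_id -> representative CDS
    coordinates: list[GeneCoordinate]
    domain_hits: list[DomainHit]
    truth: GroundTruth
    genes: list[_Gene] = field(default_factory=list)

    @property
    def family_gene_ids(self) -> list[str]:
        return sorted(self.truth.subfamily)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle as the text formats the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins.faa",
            "cds": outdir / "cds.fna",
            "coordinates": outdir / "coordinates.tsv",
            "domain_hits": outdir / "domain_hits.tsv",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.proteins, paths["proteins"])
        write_fasta(
            [SequenceRecord(id=g, residues=c) for g, c in sorted(self.cds.items())],
            paths["cds"],
        )
        write_coordinates(self.coordinates, paths["coordinates"])
        write_domain_table(self.domain_hits, paths["domain_hits"])
        truth = {
            "subfamily": dict(sorted(self.truth.subfamily.items())),
            "pairs": [
                {"gene_a": p.gene_a, "gene_b": p.gene_b, "label": p.label,
                 "omega": p.omega}
                for p in sorted(self.truth.pairs, key=lambda p: p.key())
            ],
            "homoeolog_map": dict(sorted(self.truth.homoeolog_map.items())),
            "deleted_genes": sorted(self.truth.deleted_genes),
            "expressed": dict(sorted(self.truth.expressed.items())),
            "ortholog_omega": self.truth.ortholog_omega,
        }
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
        return paths


def _build_family_protein(
    rng: np.random.Generator, subfamily: str
) -> tuple[str, list[tuple[str, int, int]]]:
    """Protein string plus 1-based domain envelopes for one architecture."""
    jitter = 0.05
    l1 = int(rng.integers(30, 60))
    l2 = int(rng.integers(50, 110))
    variant = AP2_VARIANTS[subfamily]
    if subfamily in ("ERF", "Soloist"):
        dom = _mutate_protein(rng, variant, jitter)
        protein = _random_protein(rng, l1) + dom + _random_protein(rng, l2)
        domains = [("AP2", l1 + 1, l1 + len(dom))]
    elif subfamily == "AP2":
        d1 = _mutate_protein(rng, variant, jitter)
        d2 = _mutate_protein(rng, variant, jitter)
        mid = int(rng.integers(20, 35))
        protein = (
            _random_protein(rng, l1) + d1 + _random_protein(rng, mid) + d2
            + _random_protein(rng, l2)
        )
        domains = [
            ("AP2", l1 + 1, l1 + len(d1)),
            ("AP2", l1 + len(d1) + mid + 1, l1 + len(d1) + mid + len(d2)),
        ]
    elif subfamily == "RAV":
        dom = _mutate_protein(rng, variant, jitter)
        b3 = _mutate_protein(rng, B3_BLOCK, jitter)
        mid = int(rng.integers(15, 30))
        protein = (
            _random_protein(rng, l1) + dom + _random_protein(rng, mid) + b3
            + _random_protein(rng, l2)
        )
        domains = [
            ("AP2", l1 + 1, l1 + len(dom)),
            ("B3", l1 + len(dom) + mid + 1, l1 + len(dom) + mid + len(b3)),
        ]
    else:
        raise ValueError(f"unknown architecture {subfamily!r}")
    return protein, domains


def _exon_count(rng: np.random.Generator, subfamily: str | None) -> int:
    if subfamily in ("AP2", "Soloist"):
        return int(rng.integers(4, 12))
    if subfamily == "RAV":
        return int(rng.integers(2, 8))
    if subfamily == "ERF":
        return 1 if rng.random() < 0.7 else int(rng.integers(2, 6))
    return int(rng.integers(1, 9))


def generate_diploid(spec: SyntheticSpec) -> GenomeBundle:
    """Generate one diploid genome bundle with planted family and duplicates.

    Tandem copies land on the source chromosome within 1 Mb (start-to-start);
    segmental copies land on a different chromosome. Duplicate sources are
    drawn from the single-domain (ERF) pool. Genes never overlap; the
    generator errors if the chromosomes cannot hold them.
    """
    rng = np.random.default_rng(spec.seed)
    sp = spec.species
    n_dup = spec.n_tandem_events + spec.n_segmental_events
    if spec.n_single_domain < n_dup:
        raise ValueError("need at least as many single-domain genes as duplication events")

    genes: list[_Gene] = []
    truth = GroundTruth()
    counter = 0

    def new_gene(subfamily: str | None, ancestral: int | None = None) -> _Gene:
        nonlocal counter
        counter += 1
        gid = f"{sp}_g{counter:04d}"
        if subfamily is None:
            length = int(rng.integers(150, 300))
            protein = _random_protein(rng, length)
            domains: list[tuple[str, int, int]] = []
        else:
            protein, domains = _build_family_protein(rng, subfamily)
        cds = _reverse_translate(rng, protein)
        return _Gene(
            gene_id=gid,
            ancestral_id=ancestral if ancestral is not None else counter,
            subfamily=subfamily,
            chromosome="",
            start=0,
            end=0,
            strand="+" if rng.random() < 0.5 else "-",
            exon_count=_exon_count(rng, subfamily),
            protein=protein,
            cds=cds,
            domains=domains,
        )

    for _ in range(spec.n_two_domain):
        genes.append(new_gene("AP2"))
    for _ in range(spec.n_single_domain):
        genes.append(new_gene("ERF"))
    for _ in range(spec.n_rav):
        genes.append(new_gene("RAV"))
    for _ in range(spec.n_soloist_like):
        genes.append(new_gene("Soloist"))
    for _ in range(spec.background_genes):
        genes.append(new_gene(None))

    # duplication events: sources drawn without replacement from the ERF pool
    erf_pool = [g for g in genes if g.subfamily == "ERF"]
    sources = [erf_pool[i] for i in rng.choice(len(erf_pool), size=n_dup, replace=False)]
    tandem_sources = sources[: spec.n_tandem_events]
    segmental_sources = sources[spec.n_tandem_events :]

    def duplicate(src: _Gene) -> _Gene:
        nonlocal counter
        counter += 1
        cds = _diverge_cds(rng, src.cds, spec.duplicate_divergence, spec.omega)
        protein = _translate(cds)
        return _Gene(
            gene_id=f"{sp}_g{counter:04d}",
            ancestral_id=counter,  # a copy is its own lineage
            subfamily=src.subfamily,
            chromosome="",
            start=0,
            end=0,
            strand=src.strand,
            exon_count=src.exon_count,
            protein=protein,
            cds=cds,
            domains=list(src.domains),
        )

    # placement units: tandem (source, copy) adjacent; everything else single
    tandem_units: list[tuple[_Gene, _Gene]] = []
    for src in tandem_sources:
        copy = duplicate(src)
        tandem_units.append((src, copy))
        truth.pairs.append(
            TruthPair(*sorted((src.gene_id, copy.gene_id)), "tandem", spec.omega)
        )
    segmental_copies: list[tuple[_Gene, _Gene]] = []
    for src in segmental_sources:
        copy = duplicate(src)
        segmental_copies.append((src, copy))
        truth.pairs.append(
            TruthPair(*sorted((src.gene_id, copy.gene_id)), "segmental", spec.omega)
        )

    tandem_members = {g.gene_id for pair in tandem_units for g in pair}
    singles = [g for g in genes if g.gene_id not in tandem_members]

    # round-robin placement with generous spacing so tandem offsets fit
    cursors = [500_000 + int(rng.integers(0, 200_000)) for _ in range(spec.n_chromosomes)]
    placed: list[_Gene] = []

    def genomic_length(g: _Gene) -> int:
        return len(g.cds) * 2 + int(rng.integers(500, 3000))

    def place(g: _Gene, chrom_idx: int, start: int) -> None:
        glen = genomic_length(g)
        g.chromosome = str(chrom_idx + 1)
        g.start = start
        g.end = start + glen - 1
        if g.end > spec.chrom_length_bp:
            raise ValueError(
                f"chromosome {g.chromosome} too short ({spec.chrom_length_bp} bp) "
                f"to place gene {g.gene_id}"
            )
        placed.append(g)

    chrom_iter = 0
    for g in singles:
        ci = chrom_iter % spec.n_chromosomes
        place(g, ci, cursors[ci])
        cursors[ci] = g.end + 1_500_000 + int(rng.integers(0, 500_000))
        chrom_iter += 1
    for src, copy in tandem_units:
        ci = chrom_iter % spec.n_chromosomes
        place(src, ci, cursors[ci])
        offset = 100_000 + int(rng.integers(0, 800_000))
        place(copy, ci, src.start + offset)
        cursors[ci] = max(src.end, copy.end) + 1_500_000 + int(rng.integers(0, 500_000))
        chrom_iter += 1
    for src, copy in segmental_copies:
        src_ci = int(src.chromosome) - 1
        ci = (src_ci + 1 + int(rng.integers(0, max(1, spec.n_chromosomes - 1)))) % spec.n_chromosomes
        if ci == src_ci:
            ci = (ci + 1) % spec.n_chromosomes
        place(copy, ci, cursors[ci])
        cursors[ci] = copy.end + 1_500_000 + int(rng.integers(0, 500_000))

    # emit records
    proteins: list[SequenceRecord] = []
    coords: list[GeneCoordinate] = []
    hits: list[DomainHit] = []
    cds_map: dict[str, str] = {}
    for g in sorted(placed, key=lambda g: g.gene_id):
        rep_pid = f"{g.gene_id}.p1"
        g.rep_protein_id = rep_pid
        n_iso = 1 + int(rng.integers(0, spec.n_isoforms_max))
        for iso in range(1, n_iso + 1):
            pid = f"{g.gene_id}.p{iso}"
            tid = f"{g.gene_id}.t{iso}"
            if iso == 1:
                residues = g.protein
            else:
                cut = int(rng.integers(10, max(11, len(g.protein) // 3)))
                residues = g.protein[: len(g.protein) - cut]
                if not residues:
                    residues = g.protein[:1]
            proteins.append(SequenceRecord(id=pid, residues=residues))
            coords.append(
                GeneCoordinate(
                    gene_id=g.gene_id,
                    chromosome=g.chromosome,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    exon_count=g.exon_count,
                    protein_id=pid,
                    transcript_id=tid,
                )
            )
        cds_map[g.gene_id] = g.cds
        for profile, a, b in g.domains:
            hits.append(
                DomainHit(protein_id=rep_pid, profile=profile, evalue=1e-30,
                          ali_start=a, ali_end=b)
            )
        if g.subfamily is not None:
            truth.subfamily[g.gene_id] = g.subfamily
            truth.ancestral_id[g.gene_id] = g.ancestral_id

    return GenomeBundle(
        species=sp,
        n_chromosomes=spec.n_chromosomes,
        proteins=proteins,
        cds=cds_map,
        coordinates=coords,
        domain_hits=hits,
        truth=truth,
        genes=sorted(placed, key=lambda g: g.gene_id),
    )


def diverge_bundle(
    bundle: GenomeBundle,
    divergence: float,
    omega: float,
    seed: int,
    species: str,
    keep_genes: Sequence[str] | None = None,
) -> GenomeBundle:
    """Derive a sister diploid: same gene layout, sequences diverged.

    Ancestral ids are preserved so :func:`generate_allotetraploid` can match
    orthologs. ``keep_genes`` restricts which family genes survive in the
    sister lineage (background genes are always carried)."""
    rng = np.random.default_rng(seed)
    keep = set(keep_genes) if keep_genes is not None else None
    genes: list[_Gene] = []
    truth = GroundTruth(ortholog_omega=omega)
    for g in bundle.genes:
        if g.subfamily is not None and keep is not None and g.gene_id not in keep:
            continue
        new_id = g.gene_id.replace(f"{bundle.species}_", f"{species}_", 1)
        if g.subfamily is not None and divergence > 0:
            cds = _diverge_cds(rng, g.cds, divergence, omega)
        else:
            cds = g.cds
        ng = _Gene(
            gene_id=new_id,
            ancestral_id=g.ancestral_id,
            subfamily=g.subfamily,
            chromosome=g.chromosome,
            start=g.start,
            end=g.end,
            strand=g.strand,
            exon_count=g.exon_count,
            protein=_translate(cds),
            cds=cds,
            domains=list(g.domains),
        )
        genes.append(ng)
        if ng.subfamily is not None:
            truth.subfamily[ng.gene_id] = ng.subfamily
            truth.ancestral_id[ng.gene_id] = ng.ancestral_id
    # carry over duplicate-pair truth for surviving pairs
    id_map = {
        g.gene_id: g.gene_id.replace(f"{bundle.species}_", f"{species}_", 1)
        for g in bundle.genes
    }
    surviving = {g.gene_id for g in genes}
    for p in bundle.truth.pairs:
        a, b = id_map.get(p.gene_a), id_map.get(p.gene_b)
        if a in surviving and b in surviving:
            truth.pairs.append(TruthPair(*sorted((a, b)), p.label, p.omega))
    return _assemble(bundle.n_chromosomes, species, genes, truth, np.random.default_rng(seed + 1))


def _assemble(
    n_chromosomes: int,
    species: str,
    genes: list[_Gene],
    truth: GroundTruth,
    rng: np.random.Generator,
    max_isoforms: int = 3,
) -> GenomeBundle:
    proteins: list[SequenceRecord] = []
    coords: list[GeneCoordinate] = []
    hits: list[DomainHit] = []
    cds_map: dict[str, str] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        rep_pid = f"{g.gene_id}.p1"
        g.rep_protein_id = rep_pid
        n_iso = 1 + int(rng.integers(0, max_isoforms))
        for iso in range(1, n_iso + 1):
            pid = f"{g.gene_id}.p{iso}"
            tid = f"{g.gene_id}.t{iso}"
            if iso == 1:
                residues = g.protein
            else:
                cut = int(rng.integers(10, max(11, len(g.protein) // 3)))
                residues = g.protein[: len(g.protein) - cut] or g.protein[:1]
            proteins.append(SequenceRecord(id=pid, residues=residues))
            coords.append(
                GeneCoordinate(
                    gene_id=g.gene_id,
                    chromosome=g.chromosome,
                    start=g.start,
                    end=g.end,
                    strand=g.strand,
                    exon_count=g.exon_count,
                    protein_id=pid,
                    transcript_id=tid,
                )
            )
        cds_map[g.gene_id] = g.cds
        for profile, a, b in g.domains:
            hits.append(
                DomainHit(protein_id=rep_pid, profile=profile, evalue=1e-30,
                          ali_start=a, ali_end=b)
            )
    return GenomeBundle(
        species=species,
        n_chromosomes=n_chromosomes,
        proteins=proteins,
        cds=cds_map,
        coordinates=coords,
        domain_hits=hits,
        truth=truth,
        genes=sorted(genes, key=lambda g: g.gene_id),
    )


def generate_allotetraploid(
    parent_a: GenomeBundle,
    parent_b: GenomeBundle,
    loss_fraction: float = 0.0,
    post_hybrid_tandem: int = 0,
    seed: int = 0,
    species: str = "allo",
    suffixes: tuple[str, str] = ("c", "e"),
) -> GenomeBundle:
    """Merge two diploids into an allotetraploid bundle.

    Chromosomes get the subgenome suffixes; family genes sharing an
    ancestral id across the parents are recorded as true homoeolog pairs.
    ``loss_fraction`` of family genes is then deleted at random and
    ``post_hybrid_tandem`` new tandem copies are planted on random
    subgenome chromosomes.
    """
    if parent_a.n_chromosomes != parent_b.n_chromosomes:
        raise ValueError("parents have different chromosome counts")
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    genes: list[_Gene] = []
    for parent, suffix in ((parent_a, suffixes[0]), (parent_b, suffixes[1])):
        for g in parent.genes:
            ng = replace_gene(g, chromosome=f"{g.chromosome}{suffix}")
            genes.append(ng)
            if ng.subfamily is not None:
                truth.subfamily[ng.gene_id] = ng.subfamily
                truth.ancestral_id[ng.gene_id] = ng.ancestral_id
    for p in parent_a.truth.pairs + parent_b.truth.pairs:
        truth.pairs.append(p)
    # ortholog pairs by shared ancestral id
    by_anc_a = {
        g.ancestral_id: g for g in parent_a.genes if g.subfamily is not None
    }
    by_anc_b = {
        g.ancestral_id: g for g in parent_b.genes if g.subfamily is not None
    }
    shared = sorted(set(by_anc_a) & set(by_anc_b))
    if not shared:
        raise ValueError(
            "parents share no ancestral gene ids; derive one parent from the "
            "other (diverge_bundle) so orthologs are identifiable"
        )
    hom_omega = (
        parent_b.truth.ortholog_omega
        or parent_a.truth.ortholog_omega
        or 0.0
    )
    for anc in shared:
        ga, gb = by_anc_a[anc].gene_id, by_anc_b[anc].gene_id
        truth.pairs.append(TruthPair(*sorted((ga, gb)), "homoeolog", hom_omega))
        truth.homoeolog_map[ga] = gb
        truth.homoeolog_map[gb] = ga

    # random gene loss
    family = sorted(truth.subfamily)
    n_del = int(round(loss_fraction * len(family)))
    if n_del:
        deleted = {family[i] for i in rng.choice(len(family), size=n_del, replace=False)}
        truth.deleted_genes = sorted(deleted)
        genes = [g for g in genes if g.gene_id not in deleted]
        truth.subfamily = {
            g: s for g, s in truth.subfamily.items() if g not in deleted
        }
        truth.ancestral_id = {
            g: a for g, a in truth.ancestral_id.items() if g not in deleted
        }
        truth.pairs = [
            p for p in truth.pairs
            if p.gene_a not in deleted and p.gene_b not in deleted
        ]
        truth.homoeolog_map = {
            a: b for a, b in truth.homoeolog_map.items()
            if a not in deleted and b not in deleted
        }

    # post-hybridization tandem duplications
    erf_pool = [g for g in genes if g.subfamily == "ERF"]
    counter = 0
    for _ in range(post_hybrid_tandem):
        src = erf_pool[int(rng.integers(len(erf_pool)))]
        counter += 1
        omega = 0.3
        cds = _diverge_cds(rng, src.cds, 0.03, omega)
        copy = _Gene(
            gene_id=f"{species}_ph{counter:03d}",
            ancestral_id=-counter,
            subfamily=src.subfamily,
            chromosome=src.chromosome,
            start=src.start + 100_000 + int(rng.integers(0, 800_000)),
            end=0,
            strand=src.strand,
            exon_count=src.exon_count,
            protein=_translate(cds),
            cds=cds,
            domains=list(src.domains),
        )
        copy.end = copy.start + len(copy.cds) * 2 + 1000
        genes.append(copy)
        truth.subfamily[copy.gene_id] = copy.subfamily
        truth.ancestral_id[copy.gene_id] = copy.ancestral_id
        truth.pairs.append(
            TruthPair(*sorted((src.gene_id, copy.gene_id)), "tandem", omega)
        )
    truth.ortholog_omega = hom_omega
    return _assemble(
        parent_a.n_chromosomes, species, genes, truth, np.random.default_rng(seed + 7)
    )


def replace_gene(g: _Gene, **kwargs) -> _Gene:
    return replace(g, **kwargs)


def generate_counts(
    bundle: GenomeBundle,
    n_samples: int = 3,
    expressed_fraction: float = 0.5,
    mean_cpm_expressed: float = 50.0,
    seed: int = 0,
    dispersion: float = 0.1,
) -> tuple[CountMatrix, dict[str, bool]]:
    """Negative-binomial counts for family genes plus true expressed flags.

    Exactly round(expressed_fraction * n_family) genes are expressed, drawing
    counts with the stated mean on the nominal per-million scale;
    unexpressed genes are all-zero.
    """
    rng = np.random.default_rng(seed)
    genes = bundle.family_gene_ids
    n = len(genes)
    n_expr = int(round(expressed_fraction * n))
    expressed_idx = set(
        int(i) for i in rng.choice(n, size=n_expr, replace=False)
    )
    counts = np.zeros((n, n_samples), dtype=int)
    shape = 1.0 / dispersion
    for i in range(n):
        if i in expressed_idx:
            lam = rng.gamma(shape, mean_cpm_expressed * dispersion, size=n_samples)
            counts[i] = rng.poisson(lam)
    flags = {g: (i in expressed_idx) for i, g in enumerate(genes)}
    bundle.truth.expressed = dict(flags)
    matrix = CountMatrix(
        gene_ids=list(genes),
        sample_ids=[f"sample{j + 1}" for j in range(n_samples)],
        counts=counts,
    )
    return matrix, flags


def generate_coffee_like_allotetraploid(
    seed: int = 0,
    n_homoeolog: int = 77,
    n_tandem: int = 12,
    n_segmental: int = 11,
    n_two_domain: int = 8,
    n_rav: int = 3,
    n_soloist_like: int = 2,
    divergence: float = 0.05,
    omega: float = 0.3,
    n_chromosomes: int = 11,
) -> GenomeBundle:
    """Allotetraploid with exact planted pair counts (default 12/11/77).

    Tandem and segmental events are planted only on genes whose ortholog is
    absent from the sister subgenome, so the planted pair set is exactly the
    set of detectable related pairs (no induced third pairs), and recovery
    can be scored as precision/recall against it.
    """
    spec = SyntheticSpec(
        seed=seed,
        n_chromosomes=n_chromosomes,
        n_two_domain=n_two_domain,
        n_single_domain=n_homoeolog + n_tandem + n_segmental,
        n_rav=n_rav,
        n_soloist_like=n_soloist_like,
        n_tandem_events=n_tandem,
        n_segmental_events=n_segmental,
        duplicate_divergence=divergence,
        omega=omega,
        background_genes=15,
        species="subc",
    )
    parent_a = generate_diploid(spec)
    # sister subgenome keeps only family genes without duplicates in parent A:
    # the homoeolog partners
    in_pairs = {
        g for p in parent_a.truth.pairs for g in (p.gene_a, p.gene_b)
    }
    keep = [
        g.gene_id
        for g in parent_a.genes
        if g.subfamily == "ERF" and g.gene_id not in in_pairs
    ]
    if len(keep) != n_homoeolog:
        raise AssertionError("internal: homoeolog pool size mismatch")
    parent_b = diverge_bundle(
        parent_a, divergence, omega, seed=seed + 1, species="sube", keep_genes=keep
    )
    return generate_allotetraploid(
        parent_a, parent_b, loss_fraction=0.0, post_hybrid_tandem=0,
        seed=seed + 2, species="allo",
    )
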