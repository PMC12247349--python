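"""AP2/ERF family identification and subfamily classification.

A gene belongs to the family when its representative protein (the longest
isoform) carries at least one AP2-domain hit at E-value <= 1e-5. Domain
architecture then assigns a provisional subfamily:

* two or more AP2 domains        -> AP2
* one AP2 domain plus a B3 domain -> RAV
* one AP2 domain, no B3           -> ERF (provisional; the phylogeny stage
  may override single-domain genes into AP2 or Soloist based on tree
  placement)

B3 hits are only consulted on proteins that already qualify by AP2 domain,
mirroring the search-within-selected workflow. Overlapping AP2 hits whose
envelopes share at least half of the shorter envelope are merged and counted
as one domain, so split HMM matches are not double-counted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

from .io_formats import DomainHit, GeneCoordinate, SequenceRecord

__all__ = [
    "IdentificationThresholds",
    "GeneArchitecture",
    "FamilyCall",
    "select_longest_isoform",
    "identify_family",
    "classify_subfamily",
    "assign_names",
    "count_introns",
    "natural_chromosome_key",
]

AP2_PROFILE = "AP2"
B3_PROFILE = "B3"

SUBFAMILIES = ("AP2", "ERF", "RAV", "Soloist")


@dataclass(frozen=True)
class IdentificationThresholds:
    ap2_evalue_max: float = 1e-5
    b3_evalue_max: float = 1e-5

    def __post_init__(self) -> None:
        if self.ap2_evalue_max <= 0 or self.b3_evalue_max <= 0:
            raise ValueError("E-value thresholds must be positive")


@dataclass(frozen=True)
class GeneArchitecture:
    gene_id: str
    ap2_domain_count: int
    has_b3: bool


@dataclass(frozen=True)
class FamilyCall:
    gene_id: str
    species: str
    subfamily: str
    subfamily_basis: str  # domain_architecture | tree_override | reference_hit
    ap2_domain_count: int
    has_b3: bool
    assigned_name: str = ""
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        if self.subfamily == "RAV" and not self.has_b3:
            raise ValueError(f"{self.gene_id}: RAV call requires a B3 domain")
        if self.ap2_domain_count >= 2 and self.subfamily != "AP2":
            raise ValueError(
                f"{self.gene_id}: two or more AP2 domains force the AP2 subfamily"
            )


def select_longest_isoform(
    proteins: Iterable[SequenceRecord], coords: Iterable[GeneCoordinate]
) -> dict[str, SequenceRecord]:
    """One representative protein per gene: the longest isoform.

    Length ties are broken by lexicographically smaller protein_id so the
    choice is deterministic.
    """
    by_id = {p.id: p for p in proteins}
    reps: dict[str, SequenceRecord] = {}
    for coord in coords:
        prot = by_id.get(coord.protein_id)
        if prot is None:
            raise KeyError(
                f"gene {coord.gene_id!r}: protein {coord.protein_id!r} not found"
            )
        cur = reps.get(coord.gene_id)
        if (
            cur is None
            or len(prot) > len(cur)
            or (len(prot) == len(cur) and prot.id < cur.id)
        ):
            reps[coord.gene_id] = prot
    return reps


def _merge_overlapping(hits: list[DomainHit]) -> int:
    """Count domains after merging hits overlapping >= 50% of the shorter one."""
    if not hits:
        return 0
    spans = sorted((h.ali_start, h.ali_end) for h in hits)
    merged: list[list[int]] = [list(spans[0])]
    for s, e in spans[1:]:
        ms, me = merged[-1]
        overlap = min(e, me) - max(s, ms) + 1
        shorter = min(e - s + 1, me - ms + 1)
        if overlap >= 0.5 * shorter:
            merged[-1][1] = max(me, e)
        else:
            merged.append([s, e])
    return len(merged)


def identify_family(
    hits: Iterable[DomainHit],
    representatives: Mapping[str, SequenceRecord],
    thresholds: IdentificationThresholds | None = None,
) -> dict[str, GeneArchitecture]:
    """Select family genes and summarize each one's domain architecture.

    Only hits on representative proteins count. Genes without a qualifying
    AP2 hit are silently excluded; B3 is only assessed on genes that qualify.
    """
    thresholds = thresholds or IdentificationThresholds()
    protein_to_gene = {rec.id: gene for gene, rec in representatives.items()}
    ap2_hits: dict[str, list[DomainHit]] = {}
    b3_hits: dict[str, list[DomainHit]] = {}
    for hit in hits:
        gene = protein_to_gene.get(hit.protein_id)
        if gene is None:
            continue
        rep_len = len(representatives[gene])
        if hit.ali_end > rep_len:
            raise ValueError(
                f"hit on {hit.protein_id!r} ends at {hit.ali_end}, "
                f"beyond protein length {rep_len}"
            )
        if hit.profile == AP2_PROFILE and hit.evalue <= thresholds.ap2_evalue_max:
            ap2_hits.setdefault(gene, []).append(hit)
        elif hit.profile == B3_PROFILE and hit.evalue <= thresholds.b3_evalue_max:
            b3_hits.setdefault(gene, []).append(hit)
    out: dict[str, GeneArchitecture] = {}
    for gene, ghits in ap2_hits.items():
        out[gene] = GeneArchitecture(
            gene_id=gene,
            ap2_domain_count=_merge_overlapping(ghits),
            has_b3=bool(b3_hits.get(gene)),
        )
    return out


def classify_subfamily(
    architectures: Mapping[str, GeneArchitecture], species: str = ""
) -> list[FamilyCall]:
    """Provisional subfamily from domain architecture alone."""
    calls: list[FamilyCall] = []
    for gene in sorted(architectures):
        arch = architectures[gene]
        if arch.ap2_domain_count < 1:
            raise ValueError(f"{gene}: family gene without an AP2 domain")
        if arch.ap2_domain_count >= 2:
            subfam = "AP2"
        elif arch.has_b3:
            subfam = "RAV"
        else:
            subfam = "ERF"
        calls.append(
            FamilyCall(
                gene_id=gene,
                species=species,
                subfamily=subfam,
                subfamily_basis="domain_architecture",
                ap2_domain_count=arch.ap2_domain_count,
                has_b3=arch.has_b3,
            )
        )
    return calls


_NAT_SPLIT = re.compile(r"(\d+)")


def natural_chromosome_key(chromosome: str, placed_prefixes: tuple[str, ...] = ()) -> tuple:
    """Natural-sort key for chromosome names; unplaced contigs sort last.

    A name is "placed" when it starts with a digit (optionally suffixed,
    e.g. '1c') or matches one of ``placed_prefixes``. Everything else
    (scaffolds/contigs) sorts after all placed chromosomes.
    """
    placed = bool(re.match(r"^\d", chromosome)) or chromosome.startswith(
        tuple(placed_prefixes) or ("chr",)
    )
    parts = _NAT_SPLIT.split(chromosome)
    key = tuple(int(p) if p.isdigit() else p for p in parts if p != "")
    return (0 if placed else 1,) + key


def assign_names(
    calls: list[FamilyCall],
    species_prefix: str,
    coords: Iterable[GeneCoordinate],
) -> list[FamilyCall]:
    """Systematic names per subfamily in genomic order.

    AP2/RAV/Soloist use dotted unpadded numbering (``CaAP2.1``); ERF is
    zero-padded to three digits (``CaERF001``). Numbering runs in
    chromosome natural-sort order then start coordinate, unplaced contigs
    last. This ordering is this package's own reproducible convention; names
    will not match any particular published gene-by-gene table.
    """
    pos: dict[str, tuple] = {}
    for c in coords:
        key = natural_chromosome_key(c.chromosome) + (c.start,)
        if c.gene_id not in pos or key < pos[c.gene_id]:
            pos[c.gene_id] = key
    missing = [c.gene_id for c in calls if c.gene_id not in pos]
    if missing:
        raise KeyError(f"no coordinates for genes: {missing[:5]}")
    named: list[FamilyCall] = []
    for subfam in SUBFAMILIES:
        members = sorted(
            (c for c in calls if c.subfamily == subfam),
            key=lambda c: (pos[c.gene_id], c.gene_id),
        )
        for n, call in enumerate(members, start=1):
            if subfam == "ERF":
                name = f"{species_prefix}ERF{n:03d}"
            else:
                name = f"{species_prefix}{subfam}.{n}"
            named.append(replace(call, assigned_name=name))
    order = {c.gene_id: i for i, c in enumerate(calls)}
    named.sort(key=lambda c: order[c.gene_id])
    return named


def count_introns(coord: GeneCoordinate) -> int:
    """Intron count of one transcript: exon_count - 1."""
    return coord.exon_count - 1
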