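"""Duplicate-pair detection and tandem/segmental/homoeolog classification.

A pair of family genes is a duplicate candidate when their representative
proteins align globally with >= 80% identity and > 80% coverage of both
sequences (thresholds configurable). Candidates are then labeled:

* tandem     — same chromosome, start-to-start distance <= 1 Mb;
* homoeolog  — in subgenome mode, chromosomes are homoeologous partners
  (same leading number, differing subgenome suffix, e.g. '2c' vs '2e');
  such pairs are parental homologs of an allopolyploid, not duplications
  within one genome;
* segmental  — everything else that passes the similarity screen.

The 1 Mb rule only applies within a chromosome; cross-chromosome pairs can
never be tandem. All qualifying pairs are reported (no transitive
reduction), so three mutually similar genes yield three pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .align import AlignmentScoring, alignment_stats, global_align
from .io_formats import GeneCoordinate, SequenceRecord

__all__ = [
    "DuplicationCriteria",
    "DuplicatePair",
    "candidate_pairs",
    "classify_pair",
    "classify_pairs",
    "tandem_clusters",
    "duplication_summary",
    "homoeologous_partners",
]


@dataclass(frozen=True)
class DuplicationCriteria:
    max_tandem_distance_bp: int = 1_000_000
    min_identity_pct: float = 80.0
    min_coverage_pct: float = 80.0
    subgenome_suffixes: tuple[str, str] = ("c", "e")

    def __post_init__(self) -> None:
        if (
            self.max_tandem_distance_bp <= 0
            or self.min_identity_pct <= 0
            or self.min_coverage_pct <= 0
        ):
            raise ValueError("duplication criteria must be positive")


@dataclass(frozen=True)
class DuplicatePair:
    gene_a: str
    gene_b: str
    identity_pct: float
    coverage_a_pct: float
    coverage_b_pct: float
    same_chromosome: bool = False
    chromosome_a: str = ""
    chromosome_b: str = ""
    distance_bp: int | None = None
    label: str | None = None  # tandem | segmental | homoeolog

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("pair must be lexicographically ordered and not a self-pair")


_CHROM_RE = re.compile(r"^(\d+)([A-Za-z]?)$")


def homoeologous_partners(
    chrom_a: str, chrom_b: str, suffixes: tuple[str, str] = ("c", "e")
) -> bool:
    """True when the chromosomes are the two subgenome copies of one number."""
    ma, mb = _CHROM_RE.match(chrom_a), _CHROM_RE.match(chrom_b)
    if not ma or not mb:
        return False
    if ma.group(1) != mb.group(1):
        return False
    return {ma.group(2), mb.group(2)} == set(suffixes)


def candidate_pairs(
    family_genes: Sequence[str],
    representatives: Mapping[str, SequenceRecord],
    criteria: DuplicationCriteria | None = None,
    scoring: AlignmentScoring | None = None,
) -> list[DuplicatePair]:
    """All-vs-all similarity screen; returns unlabeled qualifying pairs."""
    criteria = criteria or DuplicationCriteria()
    scoring = scoring or AlignmentScoring()
    genes = sorted(set(family_genes))
    out: list[DuplicatePair] = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1 :]:
            aln = global_align(representatives[ga], representatives[gb], scoring)
            stats = alignment_stats(aln)
            if (
                stats.identity_pct >= criteria.min_identity_pct
                and stats.coverage_a_pct > criteria.min_coverage_pct
                and stats.coverage_b_pct > criteria.min_coverage_pct
            ):
                out.append(
                    DuplicatePair(
                        gene_a=ga,
                        gene_b=gb,
                        identity_pct=stats.identity_pct,
                        coverage_a_pct=stats.coverage_a_pct,
                        coverage_b_pct=stats.coverage_b_pct,
                    )
                )
    return out


def classify_pair(
    pair: DuplicatePair,
    coords: Mapping[str, GeneCoordinate],
    criteria: DuplicationCriteria | None = None,
    subgenome_mode: bool = False,
) -> DuplicatePair:
    """Attach the tandem/segmental/homoeolog label to one candidate pair."""
    criteria = criteria or DuplicationCriteria()
    try:
        ca, cb = coords[pair.gene_a], coords[pair.gene_b]
    except KeyError as exc:
        raise KeyError(f"no coordinates for gene {exc.args[0]!r}") from None
    same = ca.chromosome == cb.chromosome
    distance = abs(ca.start - cb.start) if same else None
    if same and distance <= criteria.max_tandem_distance_bp:
        label = "tandem"
    elif subgenome_mode and homoeologous_partners(
        ca.chromosome, cb.chromosome, criteria.subgenome_suffixes
    ):
        label = "homoeolog"
    else:
        label = "segmental"
    return replace(
        pair,
        same_chromosome=same,
        chromosome_a=ca.chromosome,
        chromosome_b=cb.chromosome,
        distance_bp=distance,
        label=label,
    )


def classify_pairs(
    pairs: Iterable[DuplicatePair],
    coords: Mapping[str, GeneCoordinate],
    criteria: DuplicationCriteria | None = None,
    subgenome_mode: bool = False,
) -> list[DuplicatePair]:
    return [classify_pair(p, coords, criteria, subgenome_mode) for p in pairs]


def tandem_clusters(tandem_pairs: Sequence[DuplicatePair]) -> list[set[str]]:
    """Connected components of the tandem-pair graph (clusters of size >= 2)."""
    for p in tandem_pairs:
        if p.label != "tandem":
            raise ValueError(f"pair ({p.gene_a}, {p.gene_b}) is not labeled tandem")
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in tandem_pairs:
        for g in (p.gene_a, p.gene_b):
            parent.setdefault(g, g)
        ra, rb = find(p.gene_a), find(p.gene_b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, set[str]] = {}
    for g in parent:
        clusters.setdefault(find(g), set()).add(g)
    return sorted(clusters.values(), key=lambda s: sorted(s)[0])


def duplication_summary(pairs: Sequence[DuplicatePair], species: str = "") -> dict:
    """Headline counts, in both labeling conventions.

    ``n_segmental_incl_homoeolog`` counts homoeologous pairs inside the
    segmental total (the inclusive convention comparative surveys quote
    before splitting off homoeologs); ``n_segmental`` excludes them.
    """
    n_tandem = sum(1 for p in pairs if p.label == "tandem")
    n_seg = sum(1 for p in pairs if p.label == "segmental")
    n_hom = sum(1 for p in pairs if p.label == "homoeolog")
    unlabeled = sum(1 for p in pairs if p.label is None)
    if unlabeled:
        raise ValueError(f"{unlabeled} pairs are unlabeled")
    return {
        "species": species,
        "n_pairs": len(pairs),
        "n_tandem": n_tandem,
        "n_segmental": n_seg,
        "n_homoeolog": n_hom,
        "n_segmental_incl_homoeolog": n_seg + n_hom,
    }
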