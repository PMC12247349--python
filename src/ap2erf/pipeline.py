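"""End-to-end characterization: identification through report tables.

``characterize`` runs, per species: representative-isoform selection,
domain-based family identification, provisional subfamily calls, the
family NJ tree with single-domain overrides (AP2 override / Soloist
designation), systematic naming, duplicate-pair detection and labeling,
NG86 Ka/Ks with Fisher significance, optional ERF subgroup assignment
against a labeled reference set, and optional expression summarization.

All thresholds are echoed into the summary for provenance, and per-stage
counts are logged so every census (selected N, retained M) is
reconstructible. Outputs are plain TSV/JSON/Newick; re-running on the same
inputs rewrites byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import align, duplication, expression, family, io_formats, kaks, phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesInputs",
    "PipelineThresholds",
    "CharacterizationReport",
    "characterize",
    "characterize_paths",
    "run_compare",
    "write_report",
]


@dataclass(frozen=True)
class PipelineThresholds:
    ap2_evalue_max: float = 1e-5
    b3_evalue_max: float = 1e-5
    max_tandem_distance_bp: int = 1_000_000
    min_identity_pct: float = 80.0
    min_coverage_pct: float = 80.0
    min_site_coverage: float = 0.9
    significance_alpha: float = 0.05
    min_cpm: float = 1.0
    pseudocount: float = 1.0
    clade_k: int = 3

    def identification(self) -> family.IdentificationThresholds:
        return family.IdentificationThresholds(
            ap2_evalue_max=self.ap2_evalue_max, b3_evalue_max=self.b3_evalue_max
        )

    def duplication(self) -> duplication.DuplicationCriteria:
        return duplication.DuplicationCriteria(
            max_tandem_distance_bp=self.max_tandem_distance_bp,
            min_identity_pct=self.min_identity_pct,
            min_coverage_pct=self.min_coverage_pct,
        )


@dataclass
class SpeciesInputs:
    species: str
    prefix: str
    proteins: list[io_formats.SequenceRecord]
    coordinates: list[io_formats.GeneCoordinate]
    domain_hits: list[io_formats.DomainHit]
    cds: Mapping[str, str] | None = None  # gene_id -> CDS
    subgenome_mode: bool = False
    counts: expression.CountMatrix | None = None
    reference_proteins: list[io_formats.SequenceRecord] | None = None
    reference_subgroups: Mapping[str, str] | None = None


@dataclass
class CharacterizationReport:
    species: str
    family_table: pd.DataFrame
    pair_table: pd.DataFrame
    kaks_table: pd.DataFrame
    subgroup_table: pd.DataFrame | None
    expression_summary: expression.ExpressionSummary | None
    tree: phylogeny.Tree | None
    summary: dict
    tandem_clusters: list[set[str]] = field(default_factory=list)


def _pairwise_screen(
    gene_ids: list[str],
    representatives: Mapping[str, io_formats.SequenceRecord],
    criteria: duplication.DuplicationCriteria,
    scoring: align.AlignmentScoring,
) -> tuple[list[duplication.DuplicatePair], np.ndarray]:
    """One all-vs-all pass yielding candidate pairs AND the identity matrix."""
    n = len(gene_ids)
    ident = np.zeros((n, n))
    pairs: list[duplication.DuplicatePair] = []
    for i in range(n):
        for j in range(i + 1, n):
            aln = align.global_align(
                representatives[gene_ids[i]], representatives[gene_ids[j]], scoring
            )
            stats = align.alignment_stats(aln)
            ident[i, j] = ident[j, i] = stats.identity_pct
            if (
                stats.identity_pct >= criteria.min_identity_pct
                and stats.coverage_a_pct > criteria.min_coverage_pct
                and stats.coverage_b_pct > criteria.min_coverage_pct
            ):
                ga, gb = sorted((gene_ids[i], gene_ids[j]))
                cov = (
                    (stats.coverage_a_pct, stats.coverage_b_pct)
                    if ga == gene_ids[i]
                    else (stats.coverage_b_pct, stats.coverage_a_pct)
                )
                pairs.append(
                    duplication.DuplicatePair(
                        gene_a=ga,
                        gene_b=gb,
                        identity_pct=stats.identity_pct,
                        coverage_a_pct=cov[0],
                        coverage_b_pct=cov[1],
                    )
                )
    return pairs, ident


def characterize(
    inputs: SpeciesInputs,
    thresholds: PipelineThresholds | None = None,
    scoring: align.AlignmentScoring | None = None,
) -> CharacterizationReport:
    thresholds = thresholds or PipelineThresholds()
    scoring = scoring or align.AlignmentScoring()
    stage_log: dict[str, dict] = {}

    # 1. representatives
    reps = family.select_longest_isoform(inputs.proteins, inputs.coordinates)
    stage_log["representatives"] = {
        "n_genes": len(reps), "n_proteins_in": len(inputs.proteins)
    }

    # 2. identification + provisional subfamilies
    archs = family.identify_family(
        inputs.domain_hits, reps, thresholds.identification()
    )
    calls = family.classify_subfamily(archs, species=inputs.species)
    stage_log["identification"] = {
        "n_hits_in": len(inputs.domain_hits),
        "n_family_genes": len(archs),
        "provisional": _subfamily_counts(calls),
    }

    gene_ids = sorted(archs)
    coords_by_gene = _representative_coords(inputs.coordinates)

    # 3. one all-vs-all alignment pass: duplicate candidates + identity matrix
    pairs, ident = _pairwise_screen(
        gene_ids, reps, thresholds.duplication(), scoring
    )
    stage_log["pair_screen"] = {
        "n_pairs_possible": len(gene_ids) * (len(gene_ids) - 1) // 2,
        "n_candidates": len(pairs),
    }

    # 4. family tree and single-domain overrides
    tree = None
    if len(gene_ids) >= 3:
        fam_records = [reps[g] for g in gene_ids]
        renamed = [
            io_formats.SequenceRecord(id=g, residues=rec.residues)
            for g, rec in zip(gene_ids, fam_records)
        ]
        msa = align.progressive_msa(renamed, scoring, identity=ident)
        dm = align.pdistance_matrix(msa, thresholds.min_site_coverage)
        tree = phylogeny.midpoint_root(phylogeny.nj_tree(dm))
        calls = phylogeny.resolve_single_domain_overrides(
            calls, tree, k=thresholds.clade_k
        )
    stage_log["tree"] = {
        "n_leaves": len(gene_ids) if tree else 0,
        "final": _subfamily_counts(calls),
    }

    # 5. systematic names
    calls = family.assign_names(calls, inputs.prefix, inputs.coordinates)

    # 6. duplicate labeling
    labeled = duplication.classify_pairs(
        pairs, coords_by_gene, thresholds.duplication(), inputs.subgenome_mode
    )
    clusters = duplication.tandem_clusters(
        [p for p in labeled if p.label == "tandem"]
    )
    dup_summary = duplication.duplication_summary(labeled, inputs.species)
    stage_log["duplication"] = dup_summary

    # 7. Ka/Ks
    kaks_results: list[kaks.KaKsResult] = []
    if inputs.cds is not None and labeled:
        kaks_results = kaks.kaks_batch(labeled, inputs.cds, reps_by_gene(reps))
    kaks_sum = kaks.kaks_summary(kaks_results)
    stage_log["kaks"] = kaks_sum

    # 8. ERF subgroups against a labeled reference set
    subgroup_table = None
    if inputs.reference_proteins and inputs.reference_subgroups:
        subgroup_table = _assign_erf_subgroups(
            calls, reps, inputs, thresholds, scoring
        )
        stage_log["subgroups"] = {
            "n_assigned": int(subgroup_table["final_subgroup"].notna().sum()),
            "n_reclassified": int(subgroup_table["reclassified"].sum()),
        }

    # 9. expression
    expr = None
    if inputs.counts is not None:
        expr = expression.summarize_expression(
            inputs.counts,
            pseudocount=thresholds.pseudocount,
            min_cpm=thresholds.min_cpm,
        )
        stage_log["expression"] = {
            "n_genes": len(inputs.counts.gene_ids),
            "n_expressed": int(expr.expressed.sum()),
        }

    family_table = _family_table(calls, coords_by_gene)
    pair_table = _pair_table(labeled)
    kaks_table = _kaks_table(kaks_results)

    summary = {
        "species": inputs.species,
        "n_family_genes": len(gene_ids),
        "subfamily_counts": _subfamily_counts(calls),
        "pair_counts": {
            k: v for k, v in dup_summary.items() if k.startswith("n_")
        },
        "n_tandem_clusters": len(clusters),
        "kaks": kaks_sum,
        "n_expressed": int(expr.expressed.sum()) if expr is not None else None,
        "thresholds": asdict(thresholds),
        "stages": stage_log,
    }
    return CharacterizationReport(
        species=inputs.species,
        family_table=family_table,
        pair_table=pair_table,
        kaks_table=kaks_table,
        subgroup_table=subgroup_table,
        expression_summary=expr,
        tree=tree,
        summary=summary,
        tandem_clusters=clusters,
    )


def reps_by_gene(
    reps: Mapping[str, io_formats.SequenceRecord]
) -> dict[str, io_formats.SequenceRecord]:
    """Representative records re-keyed (and re-labeled) by gene id."""
    return {
        g: io_formats.SequenceRecord(id=g, residues=rec.residues)
        for g, rec in reps.items()
    }


def _representative_coords(
    coordinates: Sequence[io_formats.GeneCoordinate],
) -> dict[str, io_formats.GeneCoordinate]:
    out: dict[str, io_formats.GeneCoordinate] = {}
    for c in coordinates:
        if c.gene_id not in out:
            out[c.gene_id] = c
    return out


def _subfamily_counts(calls: Sequence[family.FamilyCall]) -> dict[str, int]:
    counts = {s: 0 for s in family.SUBFAMILIES}
    for c in calls:
        counts[c.subfamily] += 1
    return counts


def _assign_erf_subgroups(calls, reps, inputs, thresholds, scoring) -> pd.DataFrame:
    erf_genes = sorted(c.gene_id for c in calls if c.subfamily == "ERF")
    refs = inputs.reference_proteins
    ref_groups = dict(inputs.reference_subgroups)
    best = phylogeny.best_reference_hits(
        [io_formats.SequenceRecord(id=g, residues=reps[g].residues) for g in erf_genes],
        refs,
        ref_groups,
        scoring,
    )
    joint = [
        io_formats.SequenceRecord(id=g, residues=reps[g].residues) for g in erf_genes
    ] + list(refs)
    tree = None
    if len(joint) >= 3:
        msa = align.progressive_msa(joint, scoring)
        dm = align.pdistance_matrix(msa, thresholds.min_site_coverage)
        tree = phylogeny.midpoint_root(phylogeny.nj_tree(dm))
    assignments = phylogeny.assign_subgroups(
        erf_genes,
        best,
        tree if tree is not None else phylogeny.Tree(phylogeny.TreeNode("empty")),
        ref_groups,
        k=thresholds.clade_k,
    )
    return pd.DataFrame(
        [
            {
                "gene_id": a.gene_id,
                "blast_subgroup": a.blast_subgroup,
                "tree_subgroup": a.tree_subgroup,
                "final_subgroup": a.final_subgroup,
                "reclassified": a.reclassified,
            }
            for a in assignments
        ]
    )


def _family_table(calls, coords_by_gene) -> pd.DataFrame:
    rows = []
    for c in calls:
        coord = coords_by_gene.get(c.gene_id)
        rows.append(
            {
                "gene_id": c.gene_id,
                "assigned_name": c.assigned_name,
                "subfamily": c.subfamily,
                "subfamily_basis": c.subfamily_basis,
                "ap2_domain_count": c.ap2_domain_count,
                "has_b3": c.has_b3,
                "chromosome": coord.chromosome if coord else "",
                "start": coord.start if coord else -1,
                "end": coord.end if coord else -1,
                "introns": family.count_introns(coord) if coord else -1,
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def _pair_table(labeled) -> pd.DataFrame:
    rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "identity_pct": round(p.identity_pct, 3),
            "coverage_a_pct": round(p.coverage_a_pct, 3),
            "coverage_b_pct": round(p.coverage_b_pct, 3),
            "chromosome_a": p.chromosome_a,
            "chromosome_b": p.chromosome_b,
            "distance_bp": p.distance_bp if p.distance_bp is not None else -1,
            "label": p.label,
        }
        for p in labeled
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "identity_pct", "coverage_a_pct",
            "coverage_b_pct", "chromosome_a", "chromosome_b",
            "distance_bp", "label",
        ],
    )
    return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def _kaks_table(results) -> pd.DataFrame:
    rows = [
        {
            "gene_a": r.gene_a,
            "gene_b": r.gene_b,
            "Ka": round(r.Ka, 6) if r.Ka is not None else None,
            "Ks": round(r.Ks, 6) if r.Ks is not None else None,
            "ratio": round(r.ratio, 6) if r.ratio is not None else None,
            "fisher_p": round(r.fisher_p, 8) if r.fisher_p is not None else None,
            "saturated": r.saturated,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "Ka", "Ks", "ratio", "fisher_p", "saturated"],
    )
    return df.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def characterize_paths(
    species: str,
    prefix: str,
    proteins_path,
    coordinates_path,
    domain_hits_path,
    cds_path=None,
    counts_path=None,
    domain_hits_dialect: str = "tsv",
    subgenome_mode: bool = False,
    reference_proteins_path=None,
    reference_subgroups_path=None,
    thresholds: PipelineThresholds | None = None,
) -> CharacterizationReport:
    """File-based entry point: read inputs, then :func:`characterize`."""
    proteins = io_formats.read_fasta(proteins_path)
    coords = io_formats.read_coordinates(coordinates_path)
    hits = io_formats.read_domain_table(domain_hits_path, domain_hits_dialect)
    cds = None
    if cds_path is not None:
        cds = {r.id: r.residues for r in io_formats.read_fasta(cds_path)}
    counts = None
    if counts_path is not None:
        counts = expression.read_count_matrix(counts_path)
    ref_prot = ref_groups = None
    if reference_proteins_path and reference_subgroups_path:
        ref_prot = io_formats.read_fasta(reference_proteins_path)
        df = pd.read_csv(reference_subgroups_path, sep="\t")
        ref_groups = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    return characterize(
        SpeciesInputs(
            species=species,
            prefix=prefix,
            proteins=proteins,
            coordinates=coords,
            domain_hits=hits,
            cds=cds,
            subgenome_mode=subgenome_mode,
            counts=counts,
            reference_proteins=ref_prot,
            reference_subgroups=ref_groups,
        ),
        thresholds=thresholds,
    )


def write_report(report: CharacterizationReport, outdir) -> dict[str, Path]:
    """Write the report bundle (TSV + JSON + Newick) and a MANIFEST."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, fn) -> None:
        path = outdir / name
        fn(path)
        paths[name] = path

    emit("family.tsv", lambda p: report.family_table.to_csv(p, sep="\t", index=False))
    emit("pairs.tsv", lambda p: report.pair_table.to_csv(p, sep="\t", index=False))
    emit("kaks.tsv", lambda p: report.kaks_table.to_csv(p, sep="\t", index=False))
    if report.subgroup_table is not None:
        emit(
            "subgroups.tsv",
            lambda p: report.subgroup_table.to_csv(p, sep="\t", index=False),
        )
    if report.tree is not None:
        emit("tree.nwk", lambda p: io_formats.write_newick(report.tree, p))
    if report.expression_summary is not None:
        expr = report.expression_summary
        emit(
            "expression.tsv",
            lambda p: pd.DataFrame(
                {
                    "gene_id": expr.log2cpm.index,
                    "expressed": expr.expressed.values,
                    "max_log2cpm": expr.log2cpm.max(axis=1).round(4).values,
                }
            ).to_csv(p, sep="\t", index=False),
        )
    emit(
        "summary.json",
        lambda p: p.write_text(json.dumps(report.summary, indent=1, sort_keys=True)),
    )
    manifest = {"species": report.species, "files": sorted(paths)}
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1))
    return paths


def run_compare(reports: Sequence[CharacterizationReport]) -> pd.DataFrame:
    """Long-format subfamily/subgroup counts across species and subgenomes.

    For subgenome-mode species, counts are additionally split by chromosome
    suffix; subgroups absent from one species appear as zero-filled rows.
    """
    if len(reports) < 2:
        raise ValueError("compare needs at least 2 reports")
    rows = []
    all_subfams = list(family.SUBFAMILIES)
    all_subgroups: set[str] = set()
    for rep in reports:
        if rep.subgroup_table is not None:
            all_subgroups |= set(rep.subgroup_table["final_subgroup"].dropna())
    for rep in reports:
        units = {rep.species: rep.family_table}
        suffixes = {
            c[-1]
            for c in rep.family_table["chromosome"]
            if c and c[-1].isalpha() and c[:-1].isdigit()
        }
        if suffixes:
            for suf in sorted(suffixes):
                mask = rep.family_table["chromosome"].str.match(rf"^\d+{suf}$")
                units[f"{rep.species}.{suf}"] = rep.family_table[mask]
        for unit, table in units.items():
            for subfam in all_subfams:
                rows.append(
                    {
                        "unit": unit,
                        "category": "subfamily",
                        "group": subfam,
                        "count": int((table["subfamily"] == subfam).sum()),
                    }
                )
            if rep.subgroup_table is not None and all_subgroups:
                genes = set(table["gene_id"])
                sg = rep.subgroup_table[
                    rep.subgroup_table["gene_id"].isin(genes)
                ]
                for group in sorted(all_subgroups):
                    rows.append(
                        {
                            "unit": unit,
                            "category": "subgroup",
                            "group": group,
                            "count": int((sg["final_subgroup"] == group).sum()),
                        }
                    )
    return pd.DataFrame(rows, columns=["unit", "category", "group", "count"])
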