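"""Nei–Gojobori (1986) Ka/Ks estimation with Fisher's exact significance.

For each codon, every one of the nine possible single-nucleotide changes
contributes one third of a site, scored synonymous when the encoded amino
acid is unchanged and nonsynonymous otherwise (changes into stop codons are
nonsynonymous), so each sense codon carries exactly three sites. Observed
differences between two codons are classified directly when a single
position differs and by averaging over all mutational pathways (2 or 6
orderings) otherwise; pathways passing through a stop codon are excluded
from the average. Proportions are corrected for multiple hits with the
Jukes–Cantor formula d = -(3/4) ln(1 - (4/3) p), and the Ka/Ks ratio is
reported only when Ks > 0. Significance follows the KaKs_calculator
convention: a two-sided Fisher's exact test on the 2x2 table of rounded
(substitutions, sites - substitutions) rows.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Mapping, Sequence

from scipy.stats import fisher_exact

from .align import AlignmentScoring, CodonAlignment, backtranslate, global_align
from .duplication import DuplicatePair
from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "KaKsResult",
    "count_sites",
    "count_differences",
    "kaks_pair",
    "fisher_significance",
    "kaks_batch",
    "kaks_summary",
    "GENETIC_CODE",
]

_BASES = "ACGT"

# standard genetic code, stops as '*'
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
GENETIC_CODE: dict[str, str] = dict(_CODON_TABLE)

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")


@dataclass(frozen=True)
class KaKsResult:
    gene_a: str
    gene_b: str
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    fisher_p: float | None = None
    codons_compared: int = 0
    codons_skipped: int = 0
    saturated: bool = False


def _check_codon(codon: str) -> str:
    codon = codon.upper()
    if len(codon) != 3 or any(b not in _BASES for b in codon):
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no defined site counts")
    return codon


@lru_cache(maxsize=64)
def count_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (s, n) of one sense codon; s+n=3."""
    codon = _check_codon(codon)
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:  # stop != sense aa, counts nonsyn
                s += 1.0 / 3.0
    return s, 3.0 - s


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (sd, nd) between two sense codons.

    Multi-step differences are averaged over all orderings of the single
    changes; orderings that pass through a stop codon are dropped from the
    average (if every ordering does, the surviving direct classification of
    each step is taken over all orderings regardless — degenerate and rare).
    """
    codon_a, codon_b = _check_codon(codon_a), _check_codon(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals: list[tuple[float, float]] = []
    all_orderings: list[tuple[float, float]] = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                through_stop = True
            aa_cur = GENETIC_CODE[cur]
            aa_nxt = GENETIC_CODE[nxt]
            if aa_cur == aa_nxt:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        all_orderings.append((sd, nd))
        if not through_stop:
            totals.append((sd, nd))
    use = totals if totals else all_orderings
    sd = sum(t[0] for t in use) / len(use)
    nd = sum(t[1] for t in use) / len(use)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def kaks_pair(caln: CodonAlignment, with_fisher: bool = True) -> KaKsResult:
    """NG86 Ka/Ks for one codon alignment.

    Columns containing a gap, an ambiguous base, or a stop codon are skipped
    (counted in ``codons_skipped``). Site counts are per-sequence counts
    averaged over the two sequences. A saturated synonymous proportion
    (pS >= 3/4) leaves Ks undefined and flags the result.
    """
    S = N = Sd = Nd = 0.0
    compared = skipped = 0
    for ca, cb in caln.columns:
        if (
            "-" in ca
            or "-" in cb
            or any(b not in _BASES for b in ca + cb)
            or ca in STOP_CODONS
            or cb in STOP_CODONS
        ):
            skipped += 1
            continue
        sa, na = count_sites(ca)
        sb, nb = count_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = count_differences(ca, cb)
        Sd += sd
        Nd += nd
        compared += 1
    if compared == 0:
        raise ValueError(
            f"no comparable codon columns between {caln.id_a!r} and {caln.id_b!r}"
        )
    if skipped:
        logger.info(
            "kaks %s/%s: skipped %d of %d codon columns",
            caln.id_a, caln.id_b, skipped, compared + skipped,
        )
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    saturated = Ks is None or Ka is None
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    res = KaKsResult(
        gene_a=caln.id_a,
        gene_b=caln.id_b,
        S_sites=S,
        N_sites=N,
        Sd=Sd,
        Nd=Nd,
        Ks=Ks,
        Ka=Ka,
        ratio=ratio,
        codons_compared=compared,
        codons_skipped=skipped,
        saturated=saturated,
    )
    if with_fisher:
        res = replace(res, fisher_p=fisher_significance(res))
    return res


def fisher_significance(res: KaKsResult) -> float:
    """Two-sided Fisher's exact p for the (substituted, unchanged) site table."""
    table = [
        [round(res.Sd), round(res.S_sites - res.Sd)],
        [round(res.Nd), round(res.N_sites - res.Nd)],
    ]
    for row in table:
        for cell in row:
            if cell < 0:
                raise ValueError(f"negative cell in Fisher table: {table}")
    return float(fisher_exact(table, alternative="two-sided")[1])


def kaks_batch(
    pairs: Sequence[DuplicatePair],
    cds: Mapping[str, str],
    proteins: Mapping[str, SequenceRecord],
    scoring: AlignmentScoring | None = None,
) -> list[KaKsResult]:
    """Align, back-translate, and estimate Ka/Ks for every pair.

    Per-pair failures are logged and skipped so one bad gene model does not
    abort the batch.
    """
    scoring = scoring or AlignmentScoring()
    out: list[KaKsResult] = []
    for pair in pairs:
        try:
            aln = global_align(proteins[pair.gene_a], proteins[pair.gene_b], scoring)
            caln = backtranslate(aln, cds[pair.gene_a], cds[pair.gene_b])
            out.append(kaks_pair(caln))
        except (KeyError, ValueError) as exc:
            logger.warning(
                "kaks failed for pair (%s, %s): %s", pair.gene_a, pair.gene_b, exc
            )
    return out


def kaks_summary(results: Sequence[KaKsResult]) -> dict:
    """Min/mean/max over defined Ka/Ks ratios, plus bookkeeping counts."""
    ratios = [r.ratio for r in results if r.ratio is not None]
    return {
        "n_results": len(results),
        "n_defined_ratio": len(ratios),
        "ratio_min": min(ratios) if ratios else None,
        "ratio_mean": sum(ratios) / len(ratios) if ratios else None,
        "ratio_max": max(ratios) if ratios else None,
        "n_significant": sum(
            1 for r in results if r.fisher_p is not None and r.fisher_p <= 0.05
        ),
    }
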