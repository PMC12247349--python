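"""Pairwise and naive progressive alignment, back-translation, distances.

The pairwise engine is global Needleman–Wunsch with affine gaps (BLOSUM62,
gap open 10, gap extend 0.5 by default — CLUSTALW-like). A gap of length L
costs ``open + L * extend``; end gaps are penalized like internal ones.
"Similarity" downstream means percent identity over residue–residue columns,
and "coverage" the fraction of each input sequence falling in such columns.

The progressive multiple aligner here is intentionally naive (greedy guide
order by decreasing pairwise identity, sequence-to-profile NW): it exists so
the pipeline is self-contained on synthetic data and it is NOT a
reimplementation of MUSCLE. Pre-computed aligned FASTA from any external MSA
tool is accepted everywhere an MSA is consumed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .io_formats import SequenceRecord

__all__ = [
    "AlignmentScoring",
    "PairwiseAlignment",
    "AlignmentStats",
    "CodonAlignment",
    "DistanceMatrix",
    "global_align",
    "alignment_stats",
    "backtranslate",
    "pdistance_matrix",
    "progressive_msa",
]

GAP = "-"


@dataclass(frozen=True)
class AlignmentScoring:
    """Substitution matrix name plus affine gap penalties (positive costs)."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def load_matrix(self):
        return _load_matrix(self.matrix)


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=None)
def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _load_matrix(matrix)
    # first gap residue costs open+extend so a length-L gap costs open + L*extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        for i, (x, y) in enumerate(zip(self.aligned_a, self.aligned_b)):
            if x == GAP and y == GAP:
                raise ValueError(f"column {i} is all-gap")


@dataclass(frozen=True)
class AlignmentStats:
    identity_pct: float
    coverage_a_pct: float
    coverage_b_pct: float


def _check_alphabet(seq: str, allowed: frozenset[str], seq_id: str) -> None:
    for i, res in enumerate(seq):
        if res not in allowed:
            raise ValueError(
                f"illegal residue {res!r} at position {i + 1} of sequence {seq_id!r}"
            )


def global_align(
    a: SequenceRecord | str,
    b: SequenceRecord | str,
    scoring: AlignmentScoring | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two protein sequences.

    Deterministic: of the co-optimal tracebacks the aligner's first reported
    alignment is returned.
    """
    scoring = scoring or AlignmentScoring()
    id_a, seq_a = (a.id, a.residues) if isinstance(a, SequenceRecord) else ("a", a)
    id_b, seq_b = (b.id, b.residues) if isinstance(b, SequenceRecord) else ("b", b)
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    allowed = frozenset(str(c) for c in scoring.load_matrix().alphabet)
    _check_alphabet(seq_a, allowed, id_a)
    _check_alphabet(seq_b, allowed, id_b)
    aligner = _make_aligner(scoring.matrix, scoring.gap_open, scoring.gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    return PairwiseAlignment(
        id_a=id_a, id_b=id_b, aligned_a=aln[0], aligned_b=aln[1], score=aln.score
    )


def alignment_stats(aln: PairwiseAlignment) -> AlignmentStats:
    """Percent identity over residue–residue columns and per-sequence coverage."""
    both = ident = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                ident += 1
    if both == 0:
        raise ValueError(
            f"alignment {aln.id_a}/{aln.id_b} has no residue-residue column; "
            "identity undefined"
        )
    len_a = len(aln.aligned_a.replace(GAP, ""))
    len_b = len(aln.aligned_b.replace(GAP, ""))
    return AlignmentStats(
        identity_pct=100.0 * ident / both,
        coverage_a_pct=100.0 * both / len_a,
        coverage_b_pct=100.0 * both / len_b,
    )


# --- back-translation -----------------------------------------------------


@dataclass(frozen=True)
class CodonAlignment:
    """Codon-level alignment: one (codon, codon) column per protein column."""

    id_a: str
    id_b: str
    columns: tuple[tuple[str, str], ...]

    @property
    def row_a(self) -> str:
        return "".join(c[0] for c in self.columns)

    @property
    def row_b(self) -> str:
        return "".join(c[1] for c in self.columns)


def _prepare_cds(cds: str, protein: str, seq_id: str) -> str:
    cds = cds.upper()
    if len(cds) == 3 * (len(protein) + 1):
        tail = cds[-3:]
        if tail in standard_dna_table.stop_codons:
            cds = cds[:-3]
    if len(cds) != 3 * len(protein):
        raise ValueError(
            f"CDS/protein length mismatch for {seq_id!r}: "
            f"{len(cds)} nt vs {len(protein)} aa"
        )
    translated = str(Seq(cds).translate())
    for i, (got, want) in enumerate(zip(translated, protein)):
        if got != want and want != "X":
            raise ValueError(
                f"translation mismatch for {seq_id!r} at codon {i + 1}: "
                f"{cds[3 * i:3 * i + 3]} -> {got}, protein has {want}"
            )
    return cds


def backtranslate(aln: PairwiseAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Thread coding sequences onto a protein alignment, codon by codon.

    A trailing stop codon on either CDS is stripped; the CDS must otherwise
    translate exactly to its protein.
    """
    prot_a = aln.aligned_a.replace(GAP, "")
    prot_b = aln.aligned_b.replace(GAP, "")
    cds_a = _prepare_cds(cds_a, prot_a, aln.id_a)
    cds_b = _prepare_cds(cds_b, prot_b, aln.id_b)
    cols: list[tuple[str, str]] = []
    ia = ib = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == GAP:
            ca = "---"
        else:
            ca = cds_a[3 * ia : 3 * ia + 3]
            ia += 1
        if y == GAP:
            cb = "---"
        else:
            cb = cds_b[3 * ib : 3 * ib + 3]
            ib += 1
        cols.append((ca, cb))
    return CodonAlignment(id_a=aln.id_a, id_b=aln.id_b, columns=tuple(cols))


# --- distance matrices ----------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    sites_used: int = 0

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")


def pdistance_matrix(
    msa: list[SequenceRecord], min_site_coverage: float = 0.9
) -> DistanceMatrix:
    """p-distances with partial deletion.

    Sites whose non-gap fraction across the whole alignment is below
    ``min_site_coverage`` are removed globally; within each pair, remaining
    sites where either row is gapped are skipped; the distance is the
    mismatch fraction over compared sites.
    """
    if len(msa) < 2:
        raise ValueError("p-distance needs at least 2 sequences")
    lengths = {len(r.residues) for r in msa}
    if len(lengths) != 1:
        raise ValueError("MSA rows differ in length")
    mat = np.array([list(r.residues) for r in msa])
    nongap = mat != GAP
    coverage = nongap.mean(axis=0)
    keep = coverage >= min_site_coverage
    mat = mat[:, keep]
    nongap = nongap[:, keep]
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValueError(
                    f"no comparable sites between {msa[i].id!r} and {msa[j].id!r} "
                    "after partial deletion"
                )
            mismatches = int((mat[i][both] != mat[j][both]).sum())
            d[i, j] = d[j, i] = mismatches / comparable
    return DistanceMatrix(labels=[r.id for r in msa], d=d, sites_used=int(keep.sum()))


# --- naive progressive MSA ------------------------------------------------


def _profile_align(
    rows: list[str], seq: str, matrix, gap_open: float, gap_extend: float
) -> tuple[list[str], str]:
    """Align one sequence to an existing alignment (profile NW, affine gaps)."""
    alphabet = [str(c) for c in matrix.alphabet]
    aidx = {c: k for k, c in enumerate(alphabet)}
    ncol = len(rows[0])
    # mean substitution score of each profile column against each residue
    counts = np.zeros((ncol, len(alphabet)))
    for row in rows:
        for c, res in enumerate(row):
            if res != GAP:
                counts[c, aidx[res]] += 1
    tot = counts.sum(axis=1)
    tot[tot == 0] = 1.0
    S = np.asarray(matrix)
    colscore = (counts @ S) / tot[:, None]  # ncol x alphabet

    m, n = ncol, len(seq)
    sidx = np.array([aidx[r] for r in seq])
    sub = colscore[:, sidx]  # m x n
    NEG = -1e30
    go, ge = gap_open + gap_extend, gap_extend
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap in seq (consume profile)
    Y = np.full((m + 1, n + 1), NEG)  # gap in profile (consume seq)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, n + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    ptrM = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrX = np.zeros((m + 1, n + 1), dtype=np.int8)
    ptrY = np.zeros((m + 1, n + 1), dtype=np.int8)
    # boundary rows: the j=0 column stays in X, the i=0 row stays in Y,
    # each opening from M at the origin
    ptrX[1:, 0] = 1
    ptrX[1, 0] = 0
    ptrY[0, 1:] = 2
    ptrY[0, 1] = 0
    for i in range(1, m + 1):
        prevM, prevX, prevY = M[i - 1], X[i - 1], Y[i - 1]
        # M: diagonal from best of three
        diag = np.maximum(np.maximum(prevM[:-1], prevX[:-1]), prevY[:-1])
        Mi = diag + sub[i - 1]
        M[i, 1:] = Mi
        ptrM[i, 1:] = np.where(
            prevM[:-1] >= np.maximum(prevX[:-1], prevY[:-1]),
            0,
            np.where(prevX[:-1] >= prevY[:-1], 1, 2),
        )
        # X: vertical (consume profile row i)
        fromM = M[i - 1] - go
        fromX = X[i - 1] - ge
        X[i] = np.maximum(fromM, fromX)
        ptrX[i, 1:] = np.where(fromM >= fromX, 0, 1)[1:]
        X[i, 0] = -(go + (i - 1) * ge)
        # Y: horizontal (consume seq). The recurrence
        # Y[j] = max(M[j-1] - go, Y[j-1] - ge) is a decayed running max;
        # substituting u[j] = Y[j] + j*ge turns it into a prefix maximum.
        jj = np.arange(1, n + 1)
        cand = M[i, :-1] - go + jj * ge
        u = np.maximum.accumulate(cand)
        Y[i, 1:] = u - jj * ge
        prev_u = np.concatenate(([-np.inf], u[:-1]))
        ptrY[i, 1:] = np.where(cand >= prev_u, 0, 2)
        Y[i, 0] = NEG
    # traceback, preferring M > X > Y
    i, j = m, n
    scores = (M[m, n], X[m, n], Y[m, n])
    state = int(np.argmax(scores))
    cols: list[tuple[bool, bool]] = []  # (consume profile col, consume seq res)
    while i > 0 or j > 0:
        if state == 0:
            prev = ptrM[i, j]
            cols.append((True, True))
            i -= 1
            j -= 1
            state = prev
        elif state == 1:
            prev = ptrX[i, j]
            cols.append((True, False))
            i -= 1
            state = prev
        else:
            prev = ptrY[i, j]
            cols.append((False, True))
            j -= 1
            state = prev
    cols.reverse()
    new_rows = ["" for _ in rows]
    new_seq = []
    pi = si = 0
    for use_p, use_s in cols:
        if use_p:
            for k, row in enumerate(rows):
                new_rows[k] += row[pi]
            pi += 1
        else:
            for k in range(len(rows)):
                new_rows[k] += GAP
        if use_s:
            new_seq.append(seq[si])
            si += 1
        else:
            new_seq.append(GAP)
    return new_rows, "".join(new_seq)


def progressive_msa(
    records: list[SequenceRecord],
    scoring: AlignmentScoring | None = None,
    identity: np.ndarray | None = None,
) -> list[SequenceRecord]:
    """Greedy progressive multiple alignment (see module docstring).

    Output rows are in the input order, all of equal length; removing gaps
    recovers each input sequence exactly. A precomputed pairwise identity
    matrix (percent, symmetric, input order) can be supplied to skip the
    all-vs-all pass.
    """
    scoring = scoring or AlignmentScoring()
    if not records:
        raise ValueError("no sequences to align")
    if len(records) == 1:
        return list(records)
    n = len(records)
    if identity is not None:
        ident = np.asarray(identity, dtype=float)
        if ident.shape != (n, n):
            raise ValueError("identity matrix shape does not match records")
    else:
        ident = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                aln = global_align(records[i], records[j], scoring)
                ident[i, j] = ident[j, i] = alignment_stats(aln).identity_pct
    i0, j0 = np.unravel_index(np.argmax(ident), ident.shape)
    i0, j0 = int(min(i0, j0)), int(max(i0, j0))
    first = global_align(records[i0], records[j0], scoring)
    order = [i0, j0]
    rows = [first.aligned_a, first.aligned_b]
    matrix = scoring.load_matrix()
    remaining = [k for k in range(n) if k not in (i0, j0)]
    while remaining:
        best = max(remaining, key=lambda k: (ident[k, order].max(), -k))
        rows, new_row = _profile_align(
            rows, records[best].residues, matrix, scoring.gap_open, scoring.gap_extend
        )
        order.append(best)
        rows.append(new_row)
        remaining.remove(best)
    by_index = {idx: row for idx, row in zip(order, rows)}
    return [
        SequenceRecord(id=records[k].id, residues=by_index[k], description=records[k].description)
        for k in range(n)
    ]
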