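"""NG86 counting against enumeration oracles; JC correction; Fisher test."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from ap2erf.align import PairwiseAlignment, backtranslate
from ap2erf.duplication import DuplicatePair
from ap2erf.io_formats import SequenceRecord
from ap2erf.kaks import (
    GENETIC_CODE,
    STOP_CODONS,
    count_differences,
    count_sites,
    fisher_significance,
    kaks_batch,
    kaks_pair,
    kaks_summary,
)
from ap2erf.synthetic import _diverge_cds, _reverse_translate

SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOP_CODONS)


def oracle_sites(codon):
    """Brute-force 9-mutation enumeration, written independently."""
    s = n = 0.0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1:]
        if GENETIC_CODE[mutant] == GENETIC_CODE[codon]:
            s += 1 / 3
        else:
            n += 1 / 3
    return s, n


def oracle_differences(ca, cb):
    """Explicit pathway enumeration over orderings of the differing sites."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and nxt != cb:
                ok = False
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


class TestCountSites:
    def test_all_sense_codons_match_enumeration(self):
        for codon in SENSE_CODONS:
            assert count_sites(codon) == pytest.approx(oracle_sites(codon))

    def test_known_values(self):
        assert count_sites("TTT") == pytest.approx((1 / 3, 8 / 3))
        assert count_sites("ATG") == (0.0, 3.0)

    def test_site_conservation(self):
        for codon in SENSE_CODONS:
            s, n = count_sites(codon)
            assert s + n == pytest.approx(3.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            count_sites("TAA")


class TestCountDifferences:
    def test_single_synonymous(self):
        assert count_differences("AAA", "AAG") == (1.0, 0.0)

    def test_single_nonsynonymous(self):
        assert count_differences("AAA", "AAC") == (0.0, 1.0)

    def test_two_difference_pathway_average(self):
        assert count_differences("TTT", "GTA") == pytest.approx(
            oracle_differences("TTT", "GTA")
        )

    def test_200_random_pairs_match_pathway_oracle(self):
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 200:
            ca, cb = rng.choice(SENSE_CODONS, size=2)
            expected = oracle_differences(ca, cb)
            if expected is None:
                continue
            got = count_differences(ca, cb)
            assert got == pytest.approx(expected), (ca, cb)
            sd, nd = got
            ndiff = sum(a != b for a, b in zip(ca, cb))
            assert sd + nd == pytest.approx(ndiff)
            checked += 1


def codon_alignment(cds_a, cds_b):
    prot_a = "".join(GENETIC_CODE[cds_a[i:i + 3]] for i in range(0, len(cds_a), 3))
    prot_b = "".join(GENETIC_CODE[cds_b[i:i + 3]] for i in range(0, len(cds_b), 3))
    aln = PairwiseAlignment("A", "B", prot_a, prot_b, 0.0)
    return backtranslate(aln, cds_a, cds_b)


class TestKaKsPair:
    def test_identical_pair_zero_rates(self):
        rng = np.random.default_rng(1)
        cds = _reverse_translate(rng, "MKVAGAHDLLIV" * 5)
        res = kaks_pair(codon_alignment(cds, cds))
        assert res.Ka == 0.0 and res.Ks == 0.0 and res.ratio is None

    def test_synonymous_only_changes(self):
        # 100 Lys codons; 4 changed AAA->AAG (synonymous single changes)
        cds_a = "AAA" * 100
        cds_b = "AAG" * 4 + "AAA" * 96
        res = kaks_pair(codon_alignment(cds_a, cds_b))
        assert res.Ka == 0.0
        # independent recount: S per AAA codon is 1/3, so S=100/3 sites
        # averaged with AAG (also 1/3): pS = 4 / (100/3)
        pS = 4 / (100 / 3)
        expected_ks = -0.75 * math.log(1 - 4 / 3 * pS)
        assert res.Ks == pytest.approx(expected_ks)
        assert res.Sd == 4.0 and res.Nd == 0.0

    def test_site_conservation_over_columns(self):
        rng = np.random.default_rng(5)
        cds_a = _reverse_translate(rng, "MKVAGAHDLLIVPQRS" * 4)
        cds_b = _diverge_cds(rng, cds_a, 0.1, 0.5)
        res = kaks_pair(codon_alignment(cds_a, cds_b))
        assert res.S_sites + res.N_sites == pytest.approx(3 * res.codons_compared)

    def test_symmetric_in_inputs(self):
        rng = np.random.default_rng(9)
        cds_a = _reverse_translate(rng, "MKVAGAHDLLIV" * 6)
        cds_b = _diverge_cds(rng, cds_a, 0.08, 0.4)
        r1 = kaks_pair(codon_alignment(cds_a, cds_b))
        r2 = kaks_pair(codon_alignment(cds_b, cds_a))
        assert (r1.Ka, r1.Ks, r1.Sd, r1.Nd) == pytest.approx(
            (r2.Ka, r2.Ks, r2.Sd, r2.Nd)
        )

    def test_gap_columns_skipped_and_counted(self):
        aln = PairwiseAlignment("A", "B", "MK-V", "MKAV", 0.0)
        caln = backtranslate(aln, "ATGAAAGTT", "ATGAAAGCAGTC")
        res = kaks_pair(caln)
        assert res.codons_compared == 3 and res.codons_skipped == 1

    def test_jc_correction_small_at_low_divergence(self):
        # pS <= 0.05 regime: |Ks - pS|/pS <= 8%
        cds_a = "AAA" * 200
        cds_b = "AAG" * 3 + "AAA" * 197
        res = kaks_pair(codon_alignment(cds_a, cds_b))
        pS = 3 / (200 / 3)
        assert abs(res.Ks - pS) / pS <= 0.08


class TestFisher:
    @staticmethod
    def oracle(table):
        """Exhaustive two-sided Fisher: sum hypergeometric probabilities of
        all tables with the observed margins whose probability does not
        exceed the observed table's."""
        (a, b), (c, d) = table
        n = a + b + c + d
        if n == 0:
            return 1.0
        row1, col1 = a + b, a + c
        p_obs = hypergeom.pmf(a, n, row1, col1)
        total = 0.0
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
            p = hypergeom.pmf(x, n, row1, col1)
            if p <= p_obs * (1 + 1e-12):
                total += p
        return min(total, 1.0)

    def _fisher_p(self, table):
        from scipy.stats import fisher_exact

        return fisher_exact(table, alternative="two-sided")[1]

    def test_no_substitutions_p_one(self):
        from ap2erf.kaks import KaKsResult

        res = KaKsResult("a", "b", 50.0, 150.0, 0.0, 0.0, 0.0, 0.0, None)
        assert fisher_significance(res) == 1.0

    def test_spec_table_matches_oracle(self):
        table = [[3, 97], [0, 300]]
        assert self._fisher_p(table) == pytest.approx(self.oracle(table), abs=1e-12)

    def test_row_swap_invariance(self):
        from ap2erf.kaks import KaKsResult

        r1 = KaKsResult("a", "b", 100.0, 300.0, 3.0, 0.0, None, None, None)
        r2 = KaKsResult("a", "b", 300.0, 100.0, 0.0, 3.0, None, None, None)
        assert fisher_significance(r1) == pytest.approx(fisher_significance(r2))

    def test_small_tables_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            table = [[a, b], [c, d]]
            assert self._fisher_p(table) == pytest.approx(
                self.oracle(table), abs=1e-12
            ), table


class TestBatch:
    def test_omega_recovery_mean(self):
        rng = np.random.default_rng(31)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=300))
        ratios = []
        for i in range(20):
            cds_a = _reverse_translate(rng, protein)
            cds_b = _diverge_cds(rng, cds_a, 0.10, 0.3)
            res = kaks_pair(codon_alignment(cds_a, cds_b))
            if res.ratio is not None:
                ratios.append(res.ratio)
        assert abs(np.mean(ratios) - 0.3) <= 0.1

    def test_empty_pairs_empty_results(self):
        assert kaks_batch([], {}, {}) == []
        summary = kaks_summary([])
        assert summary["ratio_mean"] is None

    def test_batch_end_to_end_and_p_in_unit_interval(self):
        rng = np.random.default_rng(12)
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
        cds, prots, pairs = {}, {}, []
        for i in range(4):
            a = _reverse_translate(rng, protein)
            b = _diverge_cds(rng, a, 0.06, 0.4)
            ga, gb = f"g{i}a", f"g{i}b"
            cds[ga], cds[gb] = a, b
            prots[ga] = SequenceRecord(ga, protein)
            prots[gb] = SequenceRecord(
                gb, "".join(GENETIC_CODE[b[k:k + 3]] for k in range(0, len(b), 3))
            )
            pairs.append(DuplicatePair(
                gene_a=ga, gene_b=gb, identity_pct=95,
                coverage_a_pct=100, coverage_b_pct=100, label="segmental",
            ))
        results = kaks_batch(pairs, cds, prots)
        assert len(results) == 4
        assert all(0 <= r.fisher_p <= 1 for r in results)

    def test_failed_pair_logged_not_raised(self):
        pairs = [DuplicatePair(gene_a="missing1", gene_b="missing2",
                               identity_pct=90, coverage_a_pct=90,
                               coverage_b_pct=90, label="tandem")]
        assert kaks_batch(pairs, {}, {}) == []
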