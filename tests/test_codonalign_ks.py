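import itertools
import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from paleoks.codonalign_ks import (
    GENETIC_CODE,
    SENSE_CODONS,
    CodonAlignment,
    align_codons,
    count_sites,
    jc_correct,
    ng86,
    pair_divergence,
)
from paleoks.io_formats import SequenceRecord

# ---------------------------------------------------------------- oracles

_BLOSUM = substitution_matrices.load("BLOSUM62")


def brute_force_best_score(a: str, b: str, gap_open=10, gap_extend=1) -> float:
    """Enumerate every global alignment of two short proteins; best score.

    Affine gaps: a run of g gap columns costs open + (g-1) * extend;
    terminal gaps are penalized like internal ones.
    """

    best = -math.inf
    n, m = len(a), len(b)

    def recurse(i, j, cols):
        nonlocal best
        if i == n and j == m:
            score = 0.0
            run = None
            for kind, x, y in cols:
                if kind == "M":
                    score += _BLOSUM[x, y]
                    run = None
                else:
                    score -= gap_open if run != kind else gap_extend
                    run = kind
            best = max(best, score)
            return
        if i < n and j < m:
            recurse(i + 1, j + 1, cols + [("M", a[i], b[j])])
        if i < n:
            recurse(i + 1, j, cols + [("D", a[i], "-")])
        if j < m:
            recurse(i, j + 1, cols + [("I", "-", b[j])])

    recurse(0, 0, [])
    return best


def oracle_ng86_codon_pair(ca: str, cb: str):
    """Independent pathway enumeration using Biopython translation."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    syn_t = nonsyn_t = 0.0
    paths = 0
    for order in itertools.permutations(diffs):
        cur = ca
        s = ns = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if str(Seq(nxt).translate()) == "*":
                ok = False
                break
            if str(Seq(cur).translate()) == str(Seq(nxt).translate()):
                s += 1
            else:
                ns += 1
            cur = nxt
        if ok:
            syn_t += s
            nonsyn_t += ns
            paths += 1
    if paths == 0:
        return None
    return syn_t / paths, nonsyn_t / paths


def oracle_syn_sites(codon: str) -> float:
    aa = str(Seq(codon).translate())
    total = 0.0
    for pos in range(3):
        syn = sense = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if str(Seq(mut).translate()) == "*":
                continue
            sense += 1
            if str(Seq(mut).translate()) == aa:
                syn += 1
        if sense:
            total += syn / sense
    return total


# ------------------------------------------------------------ site counts


class TestCountSites:
    def test_phe_has_one_third_synonymous_site(self):
        # of the nine single-nt mutants of TTT only TTC is synonymous
        assert count_sites("TTT") == pytest.approx(1 / 3)

    def test_trp_has_no_synonymous_site(self):
        assert count_sites("TGG") == 0.0

    def test_complementarity_over_all_sense_codons(self):
        for codon in SENSE_CODONS:
            s = count_sites(codon)
            assert 0.0 <= s <= 3.0
            assert s == pytest.approx(oracle_syn_sites(codon))

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")


# -------------------------------------------------------------- alignment


class TestAlignCodons:
    def test_identical_sequences_align_ungapped(self):
        cds = "".join(SENSE_CODONS[:50])
        aln = align_codons(SequenceRecord("A|x", cds), SequenceRecord("A|y", cds))
        assert aln.row_a == aln.row_b == cds
        assert sum(1 for _ in aln.codon_columns()) == 50

    def test_single_codon_insertion_gives_triplet_gap(self):
        base = "ATGGCTCATAAGGAGTGCGTGATC"
        with_insert = base[:12] + "TGG" + base[12:]
        aln = align_codons(
            SequenceRecord("A|x", base), SequenceRecord("A|y", with_insert)
        )
        assert aln.row_a.count("-") == 3
        assert "---" in aln.row_a
        assert aln.row_b == with_insert

    def test_gap_stripped_rows_recover_inputs(self):
        a = "ATGGCTCATAAGGAGTGC"
        b = "ATGCATAAGGAGTGCGTG"
        aln = align_codons(SequenceRecord("A|x", a), SequenceRecord("A|y", b))
        assert aln.row_a.replace("-", "") == a
        assert aln.row_b.replace("-", "") == b

    @pytest.mark.parametrize("seed", range(6))
    def test_score_matches_exhaustive_enumeration(self, seed):
        from paleoks.codonalign_ks import _aligner, translate

        rng = np.random.default_rng(seed)
        n_codons = int(rng.integers(5, 8))
        pick = lambda: "".join(
            SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)
        )
        pa, pb = translate(pick()), translate(pick())
        ours = _aligner().align(pa, pb).score
        assert ours == pytest.approx(brute_force_best_score(pa, pb))

    def test_internal_stop_rejected(self):
        with pytest.raises(Exception, match="stop"):
            align_codons(
                SequenceRecord("A|x", "ATGTAAGCT"), SequenceRecord("A|y", "ATGGCTGCT")
            )


# ------------------------------------------------------------------- ng86


def _aln(ca: str, cb: str) -> CodonAlignment:
    return CodonAlignment("A|x", "A|y", ca, cb)


class TestNg86:
    def test_identical_rows_have_zero_differences(self):
        cds = "GCT" * 30
        counts = ng86(_aln(cds, cds))
        assert counts.Sd == counts.Nd == 0.0

    def test_single_synonymous_difference(self):
        a = "GCT" * 30
        b = "GCT" * 29 + "GCC"  # Ala -> Ala at the third position
        counts = ng86(_aln(a, b))
        assert counts.Sd == 1.0 and counts.Nd == 0.0

    def test_site_conservation(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            pick = lambda: "".join(
                SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n)
            )
            counts = ng86(_aln(pick(), pick()))
            assert counts.S + counts.N == pytest.approx(3 * counts.codons_used)

    def test_matches_pathway_enumeration_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 6))
            idx = rng.integers(0, len(SENSE_CODONS), size=(2, n))
            a = "".join(SENSE_CODONS[i] for i in idx[0])
            b = "".join(SENSE_CODONS[i] for i in idx[1])
            counts = ng86(_aln(a, b))
            exp_sd = exp_nd = 0.0
            used = 0
            for i in range(n):
                res = oracle_ng86_codon_pair(a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3])
                if res is None:
                    continue
                exp_sd += res[0]
                exp_nd += res[1]
                used += 1
            assert counts.codons_used == used
            assert counts.Sd == pytest.approx(exp_sd, abs=1e-12)
            assert counts.Nd == pytest.approx(exp_nd, abs=1e-12)

    def test_gap_and_ambiguous_columns_skipped(self):
        counts = ng86(_aln("GCT---GCT", "GCTGCAGCC"))
        assert counts.codons_used == 2

    def test_all_gap_alignment_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            ng86(_aln("---", "GCT"))


class TestJcCorrect:
    def test_zero_and_boundary(self):
        assert jc_correct(0.0) == 0.0
        assert jc_correct(0.75) is None
        assert jc_correct(0.9) is None

    def test_closed_form_value(self):
        assert jc_correct(0.3) == pytest.approx(-0.75 * math.log(0.6))

    def test_strictly_increasing(self):
        grid = np.linspace(0, 0.749, 200)
        vals = [jc_correct(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestPairDivergence:
    def test_identical_pair_is_zero(self):
        cds = "GCTAAAGAT" * 10
        p = pair_divergence(_aln(cds, cds))
        assert p.ks == 0.0 and p.ka == 0.0

    def test_symmetric_in_input_order(self, rng):
        pick = lambda: "".join(
            SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), 30)
        )
        a, b = pick(), pick()
        p1 = pair_divergence(_aln(a, b))
        p2 = pair_divergence(CodonAlignment("A|y", "A|x", b, a))
        assert p1.ks == p2.ks and p1.ka == p2.ka

    def test_zero_synonymous_sites_is_an_error(self):
        # TGG (Trp) has no synonymous site at all
        with pytest.raises(ValueError, match="TGG|synonymous"):
            pair_divergence(_aln("TGG" * 10, "TGG" * 10))
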