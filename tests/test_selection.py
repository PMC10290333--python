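"""NG86 and PBL dN/dS machinery against brute-force oracles."""

import math
from itertools import permutations

import numpy as np
import pytest
from Bio.Seq import Seq

from mhcsel.alignment import SENSE_CODONS, CodonAlignment
from mhcsel.selection import (
    bootstrap_se,
    dnds_ng86,
    dnds_pbl,
    ng86_pair_diffs,
    ng86_sites,
    pbl_pair_stats,
    z_test_positive_selection,
)
from conftest import random_sense_codon


def _aa(codon):
    return str(Seq(codon).translate())


# -- independent oracles ----------------------------------------------------

def _oracle_ng86_sites(codon):
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1 :] for b in "ACGT" if b != codon[pos]]
        valid = [a for a in alts if _aa(a) != "*"]
        if valid:
            s += sum(_aa(a) == aa for a in valid) / len(valid)
    return s, 3 - s


def _oracle_ng86_diffs(a, b):
    """Explicit enumeration of the 1/2/6 substitution orderings with the
    same stop rule (exclude stop-traversing paths; fall back to counting
    stop steps as nonsynonymous if every path hits a stop)."""
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur, sd, nd, hit_stop = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                hit_stop = True
            if _aa(cur) == _aa(nxt) and _aa(cur) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, hit_stop))
    ok = [(s, n) for s, n, stop in paths if not stop] or [(s, n) for s, n, _ in paths]
    return sum(s for s, _ in ok) / len(ok), sum(n for _, n in ok) / len(ok)


class TestNg86Sites:
    def test_glycine_family_box(self):
        s, n = ng86_sites("GGG")
        assert s == pytest.approx(1.0) and n == pytest.approx(2.0)

    def test_methionine_has_no_synonymous_sites(self):
        assert ng86_sites("ATG") == (0.0, 3.0)

    def test_all_61_sense_codons_match_oracle_and_sum_to_3(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            os, on = _oracle_ng86_sites(codon)
            assert s == pytest.approx(os, abs=1e-12)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TGA")


class TestNg86PairDiffs:
    def test_identical_codons(self):
        assert ng86_pair_diffs("ATG", "ATG") == (0.0, 0.0)

    def test_single_synonymous_third_position_change(self):
        assert ng86_pair_diffs("TTT", "TTC") == (1.0, 0.0)

    def test_500_random_pairs_match_pathway_enumerator(self, rng):
        for _ in range(500):
            a, b = random_sense_codon(rng), random_sense_codon(rng)
            sd, nd = ng86_pair_diffs(a, b)
            osd, ond = _oracle_ng86_diffs(a, b)
            assert sd == pytest.approx(osd, abs=1e-12), (a, b)
            assert nd == pytest.approx(ond, abs=1e-12), (a, b)

    def test_symmetric_in_argument_order(self, rng):
        for _ in range(100):
            a, b = random_sense_codon(rng), random_sense_codon(rng)
            assert ng86_pair_diffs(a, b) == ng86_pair_diffs(b, a)


class TestDndsNg86:
    def test_identical_sequences_give_zero(self):
        aln = CodonAlignment(("a", "b"), ("ATGGGGTTT", "ATGGGGTTT"))
        est = dnds_ng86(aln)
        assert est.dn == 0.0 and est.ds == 0.0

    def test_dnds_na_when_ds_zero(self):
        # one nonsynonymous difference, no synonymous ones
        aln = CodonAlignment(("a", "b"), ("ATGGGG", "ATGGTG"))
        est = dnds_ng86(aln)
        assert est.ds == 0.0 and math.isnan(est.dnds)

    def test_toy_pair_composes_from_site_and_diff_counts(self):
        # ATG GGG TTT vs ATG GGA TTA: one synonymous (GGG->GGA) and one
        # nonsynonymous (TTT->TTA, Phe->Leu) third-position difference
        a, b = "ATGGGGTTT", "ATGGGATTA"
        aln = CodonAlignment(("x", "y"), (a, b))
        est = dnds_ng86(aln)
        sd = nd = s_sites = n_sites = 0.0
        for i in range(0, 9, 3):
            ca, cb = a[i : i + 3], b[i : i + 3]
            d = ng86_pair_diffs(ca, cb)
            sd += d[0]
            nd += d[1]
            s_sites += (ng86_sites(ca)[0] + ng86_sites(cb)[0]) / 2
            n_sites += (ng86_sites(ca)[1] + ng86_sites(cb)[1]) / 2
        expected_ds = -0.75 * math.log(1 - 4 / 3 * (sd / s_sites))
        expected_dn = -0.75 * math.log(1 - 4 / 3 * (nd / n_sites))
        assert est.ds == pytest.approx(expected_ds, abs=1e-12)
        assert est.dn == pytest.approx(expected_dn, abs=1e-12)

    def test_gap_codons_pairwise_deleted(self):
        aln = CodonAlignment(
            ("a", "b"), ("ATG---TTTGGAGGA", "ATGGGGTTCGGAGGA")
        )
        est = dnds_ng86(aln)
        # the gapped codon is excluded pairwise: one synonymous difference
        # among the four compared codons, no nonsynonymous ones
        assert est.dn == 0.0 and est.ds > 0

    def test_mask_restriction(self):
        a, b = "ATGGGGGGATTT", "ATGGGAGGATTA"
        aln = CodonAlignment(("x", "y"), (a, b))
        # columns 0-2 exclude the nonsynonymous codon (TTT vs TTA)
        est = dnds_ng86(aln, columns=[0, 1, 2])
        assert est.dn == 0.0 and est.ds > 0


def _oracle_pbl_tally(a, b):
    """Independent position-by-position recount of degeneracy classes and
    substitution types for one codon pair."""
    from mhcsel.alignment import classify_degeneracy

    idx = {0: 0, 2: 1, 4: 2}
    L = [0.0] * 3
    ts = [0.0] * 3
    tv = [0.0] * 3
    for p in range(3):
        ca = idx[classify_degeneracy(a)[p]]
        cb = idx[classify_degeneracy(b)[p]]
        for cls, w in ([(ca, 1.0)] if ca == cb else [(ca, 0.5), (cb, 0.5)]):
            L[cls] += w
            if a[p] != b[p]:
                if {a[p], b[p]} in ({"A", "G"}, {"C", "T"}):
                    ts[cls] += w
                else:
                    tv[cls] += w
    return L, ts, tv


class TestDndsPbl:
    def test_identical_sequences_give_zero(self):
        aln = CodonAlignment(("a", "b"), ("ATGGGGCTT", "ATGGGGCTT"))
        est = dnds_pbl(aln)
        assert est.dn == 0.0 and est.ds == 0.0

    def test_random_codon_pairs_match_independent_tally(self, rng):
        for _ in range(200):
            a, b = random_sense_codon(rng), random_sense_codon(rng)
            L, ts, tv = pbl_pair_stats(a, b)
            oL, ots, otv = _oracle_pbl_tally(a, b)
            assert list(L) == pytest.approx(oL, abs=1e-12)
            assert list(ts) == pytest.approx(ots, abs=1e-12)
            assert list(tv) == pytest.approx(otv, abs=1e-12)
            assert sum(L) == pytest.approx(3.0, abs=1e-12)

    def test_single_fourfold_synonymous_transition(self):
        # GGG vs GGA: transition at a fourfold site; dN has no A0 or
        # B-component contribution, dS is positive
        aln = CodonAlignment(
            ("a", "b"), ("ATGGGGAAACTTGGCGTC", "ATGGGAAAACTTGGCGTC")
        )
        est = dnds_pbl(aln)
        assert est.ds > 0
        assert est.dn == pytest.approx(0.0, abs=1e-12)

    def test_pair_order_symmetry(self):
        from mhcsel.simulate import CodonSimConfig, simulate_codon_alignment

        cfg = CodonSimConfig(n_alleles=2, n_codons=40, pairwise_ds=0.2)
        aln, _ = simulate_codon_alignment(cfg, seed=23)
        a, b = aln.seqs
        fwd = dnds_pbl(CodonAlignment(("a", "b"), (a, b)))
        rev = dnds_pbl(CodonAlignment(("b", "a"), (b, a)))
        assert fwd.dn == pytest.approx(rev.dn) and fwd.ds == pytest.approx(rev.ds)


class TestBootstrap:
    def _toy_alignment(self, rng, n=8, codons=30):
        from mhcsel.simulate import CodonSimConfig, simulate_codon_alignment

        cfg = CodonSimConfig(n_alleles=n, n_codons=codons, pairwise_ds=0.15)
        aln, _ = simulate_codon_alignment(cfg, seed=7)
        return aln

    def test_monomorphic_alignment_has_zero_se(self):
        aln = CodonAlignment(("a", "b", "c"), ("ATGGGG",) * 3)
        assert bootstrap_se(aln, reps=50, seed=0) == 0.0

    def test_same_seed_reproduces_se(self, rng):
        aln = self._toy_alignment(rng)
        assert bootstrap_se(aln, reps=200, seed=11) == bootstrap_se(aln, reps=200, seed=11)

    def test_se_stable_across_replicate_counts(self, rng):
        aln = self._toy_alignment(rng)
        se_lo = bootstrap_se(aln, reps=1000, seed=3)
        se_hi = bootstrap_se(aln, reps=10000, seed=4)
        assert se_lo == pytest.approx(se_hi, rel=0.15)

    def test_too_few_reps_rejected(self, rng):
        aln = self._toy_alignment(rng)
        with pytest.raises(ValueError):
            bootstrap_se(aln, reps=1)


class TestZTest:
    def test_equal_dn_ds_gives_z_zero_p_half(self):
        aln = CodonAlignment(("a", "b"), ("ATGGGG",) * 2)
        res = z_test_positive_selection(aln, reps=50, seed=0)
        assert res.z == 0.0 and res.p == 0.5

    def test_result_carries_provenance(self, rng):
        from mhcsel.simulate import CodonSimConfig, simulate_codon_alignment

        cfg = CodonSimConfig(n_alleles=6, n_codons=30, pairwise_ds=0.1)
        aln, _ = simulate_codon_alignment(cfg, seed=5)
        res = z_test_positive_selection(aln, reps=100, seed=9, mask_tag="All sites")
        assert res.n_bootstrap == 100 and res.seed == 9
        assert 0.0 <= res.p <= 1.0
        assert res.diff == pytest.approx(res.dn - res.ds)
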