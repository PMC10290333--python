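"""Genotype filtering, replicate reproducibility, allele validation and
expression cross-checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mhcsel.alignment import ProteinAlignment, SiteMap, build_site_map
from mhcsel.qc import (
    CLASS_I_ANCHORS,
    allele_summary,
    expression_crosscheck,
    filter_genotypes,
    mean_reproducibility,
    replicate_reproducibility,
    reverse_complement,
    validate_allele,
)
from mhcsel.simulate import GenotypeSimConfig, simulate_genotype_dataset


def _table(rows):
    return pd.DataFrame(rows, columns=["individual", "replicate", "amplicon", "allele", "reads"])


class TestFilter:
    def _toy(self):
        rows = []
        for i, total in [("i1", 500), ("i2", 50), ("i3", 120)]:
            rows.append((i, "1", "MHC", "a1", total // 2))
            rows.append((i, "1", "MHC", "a2", total - total // 2))
        return _table(rows)

    def test_low_read_samples_removed(self):
        kept, log = filter_genotypes(self._toy(), min_reads=100)
        assert set(kept["individual"]) == {"i1", "i3"}
        removed = log[log["action"] == "removed"]
        assert list(removed["individual"]) == ["i2"]

    def test_kept_plus_removed_equals_input(self):
        table = self._toy()
        kept, log = filter_genotypes(table, min_reads=100)
        n_removed_rows = len(table) - len(kept)
        assert n_removed_rows == 2  # both alleles of the removed sample

    def test_excess_alleles_flagged_not_removed(self):
        rows = [("i1", "1", "MHC", f"a{k}", 100) for k in range(8)]
        kept, log = filter_genotypes(_table(rows), min_reads=100, max_alleles=6)
        assert len(kept) == 8
        assert list(log["action"]) == ["flagged"]

    def test_zero_threshold_is_identity_on_samples(self):
        table = self._toy()
        kept, _ = filter_genotypes(table, min_reads=0)
        assert len(kept) == len(table)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            filter_genotypes(_table([]))


class TestReproducibility:
    def test_identical_replicates(self):
        assert replicate_reproducibility({"a", "b", "c"}, {"a", "b", "c"}) == 100.0

    def test_two_of_three_shared(self):
        value = replicate_reproducibility({"a", "b", "c"}, {"a", "b", "d"})
        assert value == pytest.approx(66.667, abs=1e-3)

    def test_empty_replicate_rejected(self):
        with pytest.raises(ValueError):
            replicate_reproducibility(set(), {"a"})

    @settings(max_examples=50, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 20), min_size=1, max_size=8),
        b=st.sets(st.integers(0, 20), min_size=1, max_size=8),
    )
    def test_symmetric_and_100_iff_equal(self, a, b):
        fwd = replicate_reproducibility(a, b)
        assert fwd == replicate_reproducibility(b, a)
        assert (fwd == 100.0) == (a == b)

    def test_dataset_mean_tracks_dropout_analytics(self):
        # with per-allele dropout d applied independently to each replicate,
        # the expected reproducibility is ~100*(1-d)
        dropout = 0.02
        cfg = GenotypeSimConfig(
            n_individuals=65,
            replicate_fraction=1.0,
            dropout=dropout,
            cnv_probability=0.0,
        )
        table, _, _, _ = simulate_genotype_dataset(cfg, seed=101)
        mean, pairs = mean_reproducibility(table)
        assert len(pairs) == 65
        assert mean == pytest.approx(100 * (1 - dropout), abs=2.0)


class TestValidateAllele:
    def _site_map(self):
        # 5-codon protein; anchors at reference 143, 146, 147 map to columns
        # 0, 3, 4; positions 159/171 are off-map for this fragment
        return SiteMap({0: 143, 1: 144, 2: 145, 3: 146, 4: 147}, 5, "HLA-A2")

    def test_perfectly_conserved_anchors_match(self):
        # T at 143, K at 146, W at 147: ACT xxx xxx AAA TGG
        seq = "ACT" + "GGG" + "CCC" + "AAA" + "TGG"
        report = validate_allele(seq, 1, CLASS_I_ANCHORS, self._site_map())
        assert not report.has_stop
        assert report.conserved_site_status[143] == "match"
        assert report.conserved_site_status[146] == "match"
        assert report.conserved_site_status[147] == "match"
        assert report.conserved_site_status[159] == "unmapped"

    def test_arginine_for_lysine_tolerated_at_146(self):
        seq = "ACT" + "GGG" + "CCC" + "AGA" + "TGG"  # R at 146
        report = validate_allele(seq, 1, CLASS_I_ANCHORS, self._site_map())
        assert report.conserved_site_status[146] == "tolerated"

    def test_internal_stop_detected(self):
        seq = "ACT" + "TAA" + "CCC" + "AAA" + "TGG"
        report = validate_allele(seq, 1, CLASS_I_ANCHORS, self._site_map())
        assert report.has_stop

    def test_anchor_mismatch_reported(self):
        seq = "GGG" + "GGG" + "CCC" + "AAA" + "TGG"  # G at 143, not T
        report = validate_allele(seq, 1, CLASS_I_ANCHORS, self._site_map())
        assert report.conserved_site_status[143] == "mismatch"
        assert not report.passes


class TestExpression:
    def test_substring_match_is_expressed(self):
        alleles = {"a1": "ACGTACGT"}
        transcripts = {"t1": "TTTTACGTACGTTTTT"}
        assert expression_crosscheck(alleles, transcripts) == {"a1": True}

    def test_single_mismatch_is_not_expressed(self):
        alleles = {"a1": "ACGTACGT"}
        transcripts = {"t1": "TTTTACGAACGTTTTT"}
        assert expression_crosscheck(alleles, transcripts) == {"a1": False}

    def test_reverse_strand_detected(self):
        allele = "ACGTTGCA"
        transcripts = {"t1": "GG" + reverse_complement(allele) + "CC"}
        assert expression_crosscheck({"a1": allele}, transcripts) == {"a1": True}

    def test_planted_expressed_set_recovered_exactly(self):
        cfg = GenotypeSimConfig(n_individuals=20, expressed_fraction=0.35)
        _, alleles, transcripts, truth = simulate_genotype_dataset(cfg, seed=77)
        result = expression_crosscheck(alleles, transcripts)
        recovered = {a for a, expressed in result.items() if expressed}
        assert recovered == set(truth["expressed"])


class TestAlleleSummary:
    def test_single_individual(self):
        table = _table(
            [("i1", "1", "MHC", "a", 100), ("i1", "1", "MHC", "b", 100)]
        )
        summary = allele_summary(table)
        assert summary.mean_alleles["MHC"] == 2.0
        assert summary.carrier_proportion[("MHC", "a")] == 1.0

    def test_replicates_collapse_by_union(self):
        table = _table(
            [
                ("i1", "1", "MHC", "a", 100),
                ("i1", "2", "MHC", "b", 100),
            ]
        )
        summary = allele_summary(table)
        assert summary.alleles_per_individual[("MHC", "i1")] == 2

    def test_carrier_proportions_near_planted_frequencies(self):
        cfg = GenotypeSimConfig(
            n_individuals=200,
            n_loci=1,
            pool_sizes=(6,),
            frequency_skew="uniform",
            cnv_probability=0.0,
            dropout=0.0,
            replicate_fraction=0.0,
        )
        table, _, _, truth = simulate_genotype_dataset(cfg, seed=3)
        summary = allele_summary(table)
        n = cfg.n_individuals
        for allele, f in truth["allele_frequencies"].items():
            expected = 1 - (1 - f) ** 2  # diploid carrier probability
            se = np.sqrt(expected * (1 - expected) / n)
            observed = summary.carrier_proportion.get(("MHC", allele), 0.0)
            assert abs(observed - expected) < 4 * se + 1e-9
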