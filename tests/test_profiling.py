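"""Profiling operations against hand-computed oracles."""

import numpy as np
import pandas as pd
import pytest

from qmpipe import profiling
from qmpipe.profiling import (
    absolute_profile,
    aggregate_rank,
    apply_coverage_cutoff,
    filter_rare_reads,
    relative_abundance,
    subtract_blank_contaminants,
)


def _blanks(rows, taxa, run="run1"):
    df = pd.DataFrame(rows, columns=taxa,
                      index=[f"b{i}" for i in range(len(rows))])
    runs = pd.Series([run] * len(rows), index=df.index)
    return df, runs


class TestBlankSubtraction:
    def test_simple_subtraction_and_floor(self, toy_counts):
        counts, runs = toy_counts
        blanks, brun = _blanks([[30, 20, 0]], counts.columns)
        out = subtract_blank_contaminants(counts, blanks, runs, brun)
        assert out.loc["s1", "TaxA"] == 70  # 100 - 30
        assert out.loc["s1", "TaxB"] == 0  # 10 - 20, floored
        assert out.loc["s2", "TaxB"] == 10  # 30 - 20
        assert out.loc["s2", "TaxA"] == 50

    def test_two_blanks_use_their_mean(self, toy_counts):
        counts, runs = toy_counts
        blanks, brun = _blanks([[20, 0, 0], [40, 0, 0]], counts.columns)
        out = subtract_blank_contaminants(counts, blanks, runs, brun)
        expected = (counts["TaxA"] - 30).clip(lower=0)
        assert (out["TaxA"] == expected).all()

    def test_all_zero_taxa_dropped(self, toy_counts):
        counts, runs = toy_counts
        blanks, brun = _blanks([[0, 100, 0]], counts.columns)
        out = subtract_blank_contaminants(counts, blanks, runs, brun)
        assert "TaxB" not in out.columns

    def test_reapplication_refused(self, toy_counts):
        counts, runs = toy_counts
        blanks, brun = _blanks([[10, 0, 0]], counts.columns)
        once = subtract_blank_contaminants(counts, blanks, runs, brun)
        with pytest.raises(ValueError, match="already applied"):
            subtract_blank_contaminants(once, blanks, runs, brun)

    def test_run_without_blank_passes_through(self, toy_counts, caplog):
        counts, runs = toy_counts
        blanks, brun = _blanks([[30, 0, 0]], counts.columns, run="run2")
        with caplog.at_level("WARNING"):
            out = subtract_blank_contaminants(counts, blanks, runs, brun)
        assert (out == counts).all().all()
        assert "no blank control" in caplog.text


class TestRareReadFilter:
    def test_below_threshold_zeroed(self):
        counts = pd.DataFrame({"T1": [5, 4], "T2": [100, 100]},
                              index=["s1", "s2"])
        out = filter_rare_reads(counts, 10)
        assert (out["T1"] == 0).all()
        assert (out["T2"] == counts["T2"]).all()

    def test_min_count_one_is_identity(self, toy_counts):
        counts, _ = toy_counts
        assert filter_rare_reads(counts, 1).equals(counts)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(0, 40, size=(6, 10)),
                              index=[f"s{i}" for i in range(6)],
                              columns=[f"t{j}" for j in range(10)])
        out = filter_rare_reads(counts, 50)
        survivors = {c for c in counts.columns if counts[c].sum() >= 50}
        assert {c for c in out.columns if out[c].any()} == survivors

    def test_per_run_totals(self):
        counts = pd.DataFrame({"T1": [9, 9, 50]}, index=["a", "b", "c"])
        runs = pd.Series(["r1", "r1", "r2"], index=counts.index)
        out = filter_rare_reads(counts, 10, runs=runs)
        assert out.loc["a", "T1"] == 9  # run total 18 >= 10
        assert out.loc["c", "T1"] == 50


class TestCoverageCutoff:
    def test_inclusive_boundary(self):
        counts = pd.DataFrame({"T1": [1999, 2000, 120, 119]},
                              index=["h1", "h2", "j1", "j2"])
        cohorts = pd.Series(["HELMi", "HELMi", "Jorvi", "Jorvi"],
                            index=counts.index)
        kept, removed = apply_coverage_cutoff(
            counts, {"HELMi": 2000, "Jorvi": 120}, cohorts)
        assert list(kept.index) == ["h2", "j1"]
        assert set(removed.index) == {"h1", "j2"}

    def test_survivors_match_manual_tally(self):
        rng = np.random.default_rng(9)
        counts = pd.DataFrame(rng.integers(0, 300, size=(10, 5)),
                              index=[f"s{i}" for i in range(10)])
        cohorts = pd.Series(["A"] * 10, index=counts.index)
        kept, _ = apply_coverage_cutoff(counts, {"A": 700}, cohorts)
        manual = [s for s in counts.index if counts.loc[s].sum() >= 700]
        assert list(kept.index) == manual

    def test_missing_cohort_cutoff_errors(self):
        counts = pd.DataFrame({"T1": [10]}, index=["s1"])
        with pytest.raises(KeyError, match="B"):
            apply_coverage_cutoff(counts, {"A": 5}, pd.Series(["B"], index=["s1"]))


class TestRelativeAbundance:
    def test_even_split(self):
        counts = pd.DataFrame({"a": [50], "b": [50]}, index=["s"])
        out = relative_abundance(counts)
        assert out.loc["s", "a"] == 0.5

    def test_single_taxon_is_one(self):
        counts = pd.DataFrame({"a": [7]}, index=["s"])
        assert relative_abundance(counts).loc["s", "a"] == 1.0

    def test_zero_total_sample_named_in_error(self):
        counts = pd.DataFrame({"a": [0, 5]}, index=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            relative_abundance(counts)

    def test_rows_sum_to_one(self, small_sim):
        rel = relative_abundance(small_sim.counts)
        np.testing.assert_allclose(rel.sum(axis=1), 1.0, rtol=1e-12)


class TestAbsoluteProfile:
    def _tables(self):
        counts = pd.DataFrame({"Bifidobacterium": [500], "Blautia": [500]},
                              index=["s1"])
        qpcr = pd.DataFrame({"copies_per_g": [1e10]}, index=["s1"])
        cn = pd.DataFrame({"name": ["Bifidobacteriales", "Clostridiales"],
                           "rank": ["order", "order"],
                           "mean16S": [3.5, 5.5]})
        tax = pd.DataFrame(
            {"family": ["Bifidobacteriaceae", "Lachnospiraceae"],
             "order": ["Bifidobacteriales", "Clostridiales"],
             "class": ["Actinobacteria", "Clostridia"]},
            index=pd.Index(["Bifidobacterium", "Blautia"], name="genus"))
        return counts, qpcr, cn, tax

    def test_printed_copy_number_arithmetic(self):
        """relative 0.5 x 1e10 copies/g at copy number 5.5 -> ~9.09e8 cells/g."""
        counts, qpcr, cn, tax = self._tables()
        prof = absolute_profile(counts, qpcr, cn, tax)
        assert prof.copies.loc["s1", "Blautia"] == pytest.approx(5e9)
        assert prof.cells.loc["s1", "Blautia"] == pytest.approx(5e9 / 5.5)
        assert prof.cells.loc["s1", "Blautia"] == pytest.approx(9.09e8, rel=1e-3)

    def test_low_copy_taxon_gains_after_correction(self):
        """Equal reads, copy numbers 3.5 vs 5.5 -> cell ratio 5.5/3.5."""
        counts, qpcr, cn, tax = self._tables()
        prof = absolute_profile(counts, qpcr, cn, tax)
        ratio = (prof.cells.loc["s1", "Bifidobacterium"]
                 / prof.cells.loc["s1", "Blautia"])
        assert ratio == pytest.approx(5.5 / 3.5)

    def test_unit_copy_number_is_identity(self):
        counts, qpcr, _, tax = self._tables()
        cn1 = pd.DataFrame({"name": ["Bifidobacteriales", "Clostridiales"],
                            "rank": ["order", "order"], "mean16S": [1.0, 1.0]})
        prof = absolute_profile(counts, qpcr, cn1, tax)
        pd.testing.assert_frame_equal(prof.copies, prof.cells)

    def test_conservation_against_qpcr(self, small_sim):
        prof = absolute_profile(small_sim.counts, small_sim.qpcr,
                                small_sim.copy_numbers, small_sim.taxonomy)
        load = small_sim.qpcr.loc[prof.copies.index, "copies_per_g"]
        assert float((prof.copies.sum(axis=1) / load - 1).abs().max()) < 1e-9

    def test_missing_qpcr_sample_excluded(self):
        counts, qpcr, cn, tax = self._tables()
        counts.loc["s2"] = [100, 100]
        prof = absolute_profile(counts, qpcr, cn, tax)
        assert prof.excluded_samples == ["s2"]
        assert "s2" not in prof.cells.index

    def test_negative_load_errors(self):
        counts, qpcr, cn, tax = self._tables()
        qpcr.loc["s1"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            absolute_profile(counts, qpcr, cn, tax)

    def test_copy_number_fallback_chain(self):
        counts, qpcr, _, tax = self._tables()
        # exact genus beats order; unknown taxon falls to the global mean
        cn = pd.DataFrame({"name": ["Bifidobacterium", "Clostridiales"],
                           "rank": ["genus", "order"], "mean16S": [2.0, 6.0]})
        prof = absolute_profile(counts, qpcr, cn, tax)
        assert prof.copy_number["Bifidobacterium"] == 2.0
        assert prof.copy_source["Bifidobacterium"] == "Bifidobacterium"
        assert prof.copy_number["Blautia"] == 6.0
        assert prof.copy_source["Blautia"] == "Clostridiales"


class TestAggregateRank:
    def test_family_sum_and_conservation(self, toy_taxonomy):
        mat = pd.DataFrame({"TaxA": [0.2], "TaxB": [0.3], "TaxC": [0.5]},
                           index=["s"])
        fam = aggregate_rank(mat, toy_taxonomy, "family")
        assert fam.loc["s", "FamX"] == pytest.approx(0.5)
        assert fam.sum(axis=1).loc["s"] == pytest.approx(1.0)

    def test_matches_brute_force_group_sum(self, small_sim):
        rel = relative_abundance(small_sim.counts)
        fam = aggregate_rank(rel, small_sim.taxonomy, "class")
        for cls in fam.columns:
            members = [g for g in rel.columns
                       if small_sim.taxonomy.loc[g, "class"] == cls]
            np.testing.assert_allclose(fam[cls], rel[members].sum(axis=1))

    def test_unassigned_pooled(self, toy_taxonomy):
        mat = pd.DataFrame({"TaxA": [1.0], "Mystery": [2.0]}, index=["s"])
        fam = aggregate_rank(mat, toy_taxonomy, "family")
        assert fam.loc["s", "unclassified-family"] == 2.0

    def test_unknown_rank_errors(self, toy_taxonomy):
        with pytest.raises(ValueError, match="rank"):
            aggregate_rank(pd.DataFrame({"TaxA": [1]}), toy_taxonomy, "phylum")


def test_rank_constant_copy_numbers_preserve_order(small_sim):
    """Within an order, copy-number correction cannot reorder taxa."""
    prof = absolute_profile(small_sim.counts, small_sim.qpcr,
                            small_sim.copy_numbers, small_sim.taxonomy)
    tax = small_sim.taxonomy
    clostridia = [g for g in prof.cells.columns
                  if g in tax.index and tax.loc[g, "order"] == "Clostridiales"
                  and prof.copy_source[g] == "Clostridiales"]
    sample = prof.cells.index[0]
    order_before = prof.copies.loc[sample, clostridia].rank()
    order_after = prof.cells.loc[sample, clostridia].rank()
    pd.testing.assert_series_equal(order_before, order_after)
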