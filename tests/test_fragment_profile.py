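import numpy as np
import pandas as pd
import pytest

import ncrf
from ncrf.fragment_profile import (
    BinDistribution,
    bin_distribution,
    call_fragments,
    end_fraction_summary,
    enrichment,
    fragment_label,
    prorate,
)
from ncrf.synthref import realized_end_bias, realized_enrichment
from conftest import make_assignments

ANNOT = pd.DataFrame(
    {
        "precursor_id": ["p1", "p2", "t1"],
        "class": ["miRNA", "miRNA", "tRNA"],
        "family": ["p1", "p2", "GlyGCC"],
    }
).set_index("precursor_id")
LENGTHS = {"p1": 70, "p2": 100, "t1": 80}


def frag_rows(pid, cls, n, length=20, start=0):
    return [(f"{pid}-r{i}-{start}-{length}", pid, cls, start, start + length)
            for i in range(n)]


class TestCallFragments:
    def test_length_partition_boundaries(self):
        # one read of each length 15-36 on a single precursor
        rows = [(f"r{L}", "p2", "miRNA", 0, L) for L in range(15, 37)]
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        row = fs.per_precursor.loc["p2"]
        frag_lengths = fs.fragment_reads["insert_length"]
        assert frag_lengths.max() == 27
        assert row["n_fragment"] == 27 - 15 + 1
        assert row["n_precursor"] == 36 - 29 + 1  # reads of 29-36 nt
        assert row["n_gap28"] == 1
        assert row["n_total"] == 22

    def test_min_reads_filter_boundary(self):
        rows = []
        for n in range(1, 11):
            pid = f"p{n}"
            rows += [(f"{pid}-r{i}", pid, "miRNA", 0, 20) for i in range(n)]
        annot = pd.DataFrame(
            {"precursor_id": [f"p{n}" for n in range(1, 11)],
             "class": ["miRNA"] * 10}
        ).set_index("precursor_id")
        lengths = {f"p{n}": 70 for n in range(1, 11)}
        fs = call_fragments(make_assignments(rows), lengths, annot)
        kept = sorted(fs.per_precursor["n_total"])
        assert kept == [5, 6, 7, 8, 9, 10]

    def test_end_categories_and_tolerance(self):
        rows = [
            ("five", "p1", "miRNA", 0, 20),       # start 0 -> 5'
            ("five_tol", "p1", "miRNA", 2, 22),   # start 2 within tolerance
            ("three", "p1", "miRNA", 50, 70),     # ends at the 3' terminus
            ("three_tol", "p1", "miRNA", 47, 68), # 70-68 = 2 within tolerance
            ("internal", "p1", "miRNA", 20, 40),
        ]
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        cats = fs.fragment_reads.set_index("read_id")["end_category"]
        assert cats["five"] == "5prime"
        assert cats["five_tol"] == "5prime"
        assert cats["three"] == "3prime"
        assert cats["three_tol"] == "3prime"
        assert cats["internal"] == "internal"

    def test_five_prime_wins_when_both_ends_qualify(self):
        annot = pd.DataFrame(
            {"precursor_id": ["s1"], "class": ["miRNA"]}
        ).set_index("precursor_id")
        rows = [(f"r{i}", "s1", "miRNA", 1, 28) for i in range(5)]
        fs = call_fragments(make_assignments(rows), {"s1": 29}, annot)
        assert fs.per_precursor.loc["s1", "n_5prime"] == 5
        assert fs.per_precursor.loc["s1", "n_3prime"] == 0

    def test_partition_invariant(self, sim_classified):
        params, seqs, annot, *_ , assignments, _ = sim_classified
        lengths = {p: len(s) for p, s in seqs.items()}
        fs = call_fragments(assignments, lengths, annot)
        tab = fs.per_precursor
        assert (
            tab["n_5prime"] + tab["n_3prime"] + tab["n_internal"]
            == tab["n_fragment"]
        ).all()

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            call_fragments(make_assignments([]), LENGTHS, ANNOT, end_tolerance=-1)

    def test_fragment_labels(self):
        assert fragment_label("tRNA") == "tRF"
        assert fragment_label("snoRNA") == "snoRF"
        assert fragment_label("lincRNA") == "lincRNA-RF"


class TestBinDistribution:
    def test_all_5prime_reads_land_in_first_bin(self):
        rows = frag_rows("p1", "miRNA", 20, length=20, start=0)
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        dist = bin_distribution(fs.fragment_reads, LENGTHS)["miRNA"]
        assert len(dist.proportions) == 10
        assert dist.proportions[0] == pytest.approx(1.0)
        assert dist.proportions[1:].sum() == pytest.approx(0.0)

    def test_uniform_starts_give_flat_distribution(self):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 80, size=10_000)
        rows = [(f"r{i}-{s}", "p2", "miRNA", int(s), int(s) + 20)
                for i, s in enumerate(starts)]
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        dist = bin_distribution(fs.fragment_reads, LENGTHS)["miRNA"]
        # starts uniform over [0, 80) on a 100-nt precursor: bins 1-8 flat
        assert np.all(np.abs(dist.proportions[:8] - 0.125) < 0.02)

    def test_proportions_sum_to_one(self, sim_classified):
        params, seqs, annot, *_ , assignments, _ = sim_classified
        lengths = {p: len(s) for p, s in seqs.items()}
        fs = call_fragments(assignments, lengths, annot)
        for cls, dist in bin_distribution(fs.fragment_reads, lengths).items():
            assert len(dist.proportions) == 10
            if not dist.empty:
                assert dist.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_class_flagged_not_error(self):
        empty = pd.DataFrame(columns=["read_id", "precursor_id", "class",
                                      "start", "end", "insert_length"])
        assert bin_distribution(empty, LENGTHS) == {}
        d = BinDistribution("snRNA", np.zeros(10), 0)
        assert d.empty

    def test_coverage_method_spreads_reads(self):
        rows = frag_rows("p2", "miRNA", 10, length=20, start=0)
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        dist = bin_distribution(fs.fragment_reads, LENGTHS, method="coverage")["miRNA"]
        # a 20-nt read on a 100-nt precursor covers exactly bins 1 and 2
        assert dist.proportions[0] == pytest.approx(0.5)
        assert dist.proportions[1] == pytest.approx(0.5)


class TestEnrichment:
    def test_equal_counts_give_ratio_one(self):
        rows = frag_rows("p1", "miRNA", 10, length=20)
        rows += frag_rows("p1", "miRNA", 10, length=29)
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        table = enrichment(fs)
        assert table.loc[0, "ratio"] == pytest.approx(1.0)

    def test_zero_fragments_ratio_zero(self):
        rows = frag_rows("p1", "miRNA", 5, length=29)
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        table = enrichment(fs)
        assert table.loc[0, "ratio"] == 0.0

    def test_zero_denominator_flagged_missing(self):
        rows = frag_rows("p1", "miRNA", 7, length=20)
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        table = enrichment(fs)
        assert not table.loc[0, "ratio_defined"]
        assert np.isnan(table.loc[0, "ratio"])
        assert len(table) == 1  # row retained

    def test_family_aggregation_sums_before_dividing(self):
        annot = pd.DataFrame(
            {"precursor_id": ["t1", "t2"], "class": ["tRNA", "tRNA"],
             "family": ["GlyGCC", "GlyGCC"]}
        ).set_index("precursor_id")
        lengths = {"t1": 80, "t2": 80}
        rows = frag_rows("t1", "tRNA", 8, length=20)
        rows += frag_rows("t1", "tRNA", 2, length=29)
        rows += frag_rows("t2", "tRNA", 1, length=20)
        rows += frag_rows("t2", "tRNA", 4, length=29)
        fs = call_fragments(make_assignments(rows), lengths, annot)
        fam = enrichment(fs, by="family")
        assert len(fam) == 1
        assert fam.loc[0, "ratio"] == pytest.approx((8 + 1) / (2 + 4))

    def test_recovery_against_ground_truth(self, sim_classified):
        params, seqs, annot, reads, truth, assignments, _ = sim_classified
        lengths = {p: len(s) for p, s in seqs.items()}
        fs = call_fragments(assignments, lengths, annot)
        measured = enrichment(fs).set_index("precursor_id")
        expected = realized_enrichment(truth)
        joined = measured.join(expected)
        busy = joined[
            (joined["n_fragment"] + joined["n_precursor"] >= 100)
            & joined["ratio_defined"] & joined["ratio_true"].notna()
        ]
        assert len(busy) >= 10
        rel_err = (busy["ratio"] - busy["ratio_true"]) / busy["ratio_true"]
        assert rel_err.abs().max() <= 0.15


class TestProrate:
    def counts(self):
        return {
            "FC_SR_M": pd.Series({"p1": 100.0, "t1": 50.0}),
            "HIP_Ct_F": pd.Series({"p1": 40.0, "t1": 10.0}),
        }

    def test_half_depth_pool_doubled(self):
        scaled = prorate(self.counts(), {"FC_SR_M": 1000, "HIP_Ct_F": 500},
                         "FC_SR_M")
        assert scaled["HIP_Ct_F"]["p1"] == pytest.approx(80.0)

    def test_reference_pool_unchanged(self):
        scaled = prorate(self.counts(), {"FC_SR_M": 1000, "HIP_Ct_F": 500},
                         "FC_SR_M")
        pd.testing.assert_series_equal(scaled["FC_SR_M"], self.counts()["FC_SR_M"])

    def test_scaled_totals_match_reference_depth(self):
        totals = {"FC_SR_M": 1000, "HIP_Ct_F": 400}
        tables = {pool: pd.Series({"p1": float(t)})
                  for pool, t in totals.items()}
        scaled = prorate(tables, totals, "FC_SR_M")
        for pool in totals:
            assert scaled[pool]["p1"] == pytest.approx(1000.0)

    def test_zero_depth_pool_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            prorate(self.counts(), {"FC_SR_M": 1000, "HIP_Ct_F": 0}, "FC_SR_M")

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            prorate(self.counts(), {"HIP_Ct_F": 500}, "FC_SR_M")


class TestEndFractions:
    def test_degenerate_bias_fully_5prime(self):
        rows = frag_rows("t1", "tRNA", 10, length=20, start=0)
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        summary = end_fraction_summary(fs)
        assert summary.per_class.loc["tRNA", "frac_5prime"] == 1.0

    def test_internal_only_class_excluded_with_flag(self):
        rows = frag_rows("p1", "miRNA", 6, length=20, start=25)
        fs = call_fragments(make_assignments(rows), LENGTHS, ANNOT)
        summary = end_fraction_summary(fs)
        assert "miRNA" not in summary.per_class.index
        assert summary.excluded_classes == ["miRNA"]

    def test_recovery_of_simulated_end_bias(self, sim_classified):
        params, seqs, annot, reads, truth, assignments, _ = sim_classified
        lengths = {p: len(s) for p, s in seqs.items()}
        fs = call_fragments(assignments, lengths, annot)
        summary = end_fraction_summary(fs)
        true_bias = realized_end_bias(truth)
        frag_counts = fs.class_totals
        for cls in true_bias.index:
            if frag_counts.get(cls, 0) >= 200:
                assert summary.per_class.loc[cls, "frac_5prime"] == pytest.approx(
                    true_bias[cls], abs=0.05
                )
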