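import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paired16s.activity import (
    collapse_taxonomy,
    dominance_matrix,
    dominance_ratio,
    phantom_adjust,
    ratio_16s,
    spearman_screen,
    to_proportions,
    top_n_zotus,
)
from paired16s.io import CountTable, SamplePair, TaxonomyMap


def table_from(rows, ids, taxa):
    return CountTable(pd.DataFrame(np.atleast_2d(rows), index=ids, columns=taxa))


def make_pair(station="A"):
    date = dt.date(2022, 2, 15)
    return SamplePair(
        dna_sample_id=f"{station}_DNA",
        rna_sample_id=f"{station}_RNA",
        station=station,
        zone="Lagoon",
        date=date,
    )


class TestPhantomAdjust:
    @pytest.mark.parametrize(
        "dna,rna,expected",
        [
            (0, 7, 1),  # phantom: RNA>0, DNA=0 -> DNA becomes 1
            (0, 0, 0),  # absent in both: untouched
            (5, 0, 5),  # DNA-only: untouched
        ],
    )
    def test_single_cell_rule(self, dna, rna, expected):
        pair = make_pair()
        taxa = ["tx", "pad"]
        dna_t = table_from([[dna, 3]], [pair.dna_sample_id], taxa)
        rna_t = table_from([[rna, 4]], [pair.rna_sample_id], taxa)
        adjusted = phantom_adjust(dna_t, rna_t, [pair])
        assert adjusted.data.loc[pair.dna_sample_id, "tx"] == expected

    def test_only_phantom_cells_change(self, rng):
        pairs = [make_pair(s) for s in "ABCD"]
        taxa = [f"t{i}" for i in range(30)]
        dna = rng.integers(0, 3, size=(4, 30))
        rna = rng.integers(0, 3, size=(4, 30))
        dna_t = table_from(dna, [p.dna_sample_id for p in pairs], taxa)
        rna_t = table_from(rna, [p.rna_sample_id for p in pairs], taxa)
        adjusted = phantom_adjust(dna_t, rna_t, pairs)
        diff = adjusted.counts - dna
        n_phantom = int(((rna > 0) & (dna == 0)).sum())
        assert int((diff != 0).sum()) == n_phantom  # exact cell count
        assert set(np.unique(adjusted.counts[(rna > 0) & (dna == 0)])) == (
            {1} if n_phantom else set()
        )

    def test_misaligned_taxa_rejected(self):
        pair = make_pair()
        dna_t = table_from([[1]], [pair.dna_sample_id], ["a"])
        rna_t = table_from([[1]], [pair.rna_sample_id], ["b"])
        with pytest.raises(ValueError, match="taxon"):
            phantom_adjust(dna_t, rna_t, [pair])


class TestProportions:
    def test_example(self):
        t = table_from([[2, 2, 4]], ["s"], ["a", "b", "c"])
        assert to_proportions(t).loc["s"].tolist() == [0.25, 0.25, 0.5]

    def test_single_taxon_row(self):
        t = table_from([[7]], ["s"], ["a"])
        assert to_proportions(t).loc["s", "a"] == 1.0

    def test_rows_sum_to_one(self, rng):
        counts = rng.integers(1, 50, size=(6, 10))
        props = to_proportions(
            table_from(counts, [f"s{i}" for i in range(6)], [f"t{i}" for i in range(10)])
        )
        np.testing.assert_allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_all_zero_row_rejected(self):
        t = table_from([[0, 0]], ["s"], ["a", "b"])
        with pytest.raises(ValueError, match="all-zero"):
            to_proportions(t)


class TestCollapseTaxonomy:
    @pytest.fixture
    def taxonomy(self):
        return TaxonomyMap(
            {
                "z1": ["Archaea", "P1", "C1", "O1", "Nitrosopumilaceae", "Nitrosopumilus"],
                "z2": ["Archaea", "P1", "C1", "O1", "Nitrosopumilaceae", "Nitrosopumilus"],
                "z3": ["Archaea", "P2", "C2", "O2", "Poseidoniaceae", None],
                "z4": ["Archaea", "P2", None, None, None, None],
            }
        )

    def test_same_genus_summed(self, taxonomy):
        t = table_from([[3, 4, 0, 0]], ["s"], ["z1", "z2", "z3", "z4"])
        out = collapse_taxonomy(t, taxonomy, "genus")
        assert out.data.loc["s", "Nitrosopumilus"] == 7

    def test_unclassified_prefix_uses_deepest_rank(self, taxonomy):
        t = table_from([[1, 1, 5, 2]], ["s"], ["z1", "z2", "z3", "z4"])
        out = collapse_taxonomy(t, taxonomy, "genus")
        assert out.data.loc["s", "unclassified Poseidoniaceae"] == 5
        assert out.data.loc["s", "unclassified P2"] == 2

    def test_total_count_conserved(self, taxonomy, rng):
        counts = rng.integers(0, 20, size=(3, 4))
        t = table_from(counts, ["a", "b", "c"], ["z1", "z2", "z3", "z4"])
        out = collapse_taxonomy(t, taxonomy, "phylum")
        assert out.counts.sum() == counts.sum()

    def test_missing_taxon_rejected(self, taxonomy):
        t = table_from([[1]], ["s"], ["zX"])
        with pytest.raises(ValueError, match="zX"):
            collapse_taxonomy(t, taxonomy, "genus")


class TestRatio16s:
    def test_simple_ratios(self):
        pair = make_pair()
        taxa = ["a", "b"]
        rna = pd.DataFrame([[0.2, 0.8]], index=[pair.rna_sample_id], columns=taxa)
        dna = pd.DataFrame([[0.1, 0.9]], index=[pair.dna_sample_id], columns=taxa)
        out = ratio_16s(rna, dna, [pair])
        assert out.loc["a", pair.pair_id] == pytest.approx(2.0)
        assert out.loc["b", pair.pair_id] == pytest.approx(0.8 / 0.9)

    def test_equal_proportions_ratio_one(self):
        pair = make_pair()
        rna = pd.DataFrame([[0.5, 0.5]], index=[pair.rna_sample_id], columns=["a", "b"])
        dna = rna.rename(index={pair.rna_sample_id: pair.dna_sample_id})
        out = ratio_16s(rna, dna, [pair])
        assert (out[pair.pair_id] == 1.0).all()

    def test_phantom_chain_traced_by_hand(self):
        # RNA: 3 of 30 reads on the phantom taxon -> 0.1
        # DNA: 9 reads elsewhere, phantom 0 -> adjusted to 1 of 10 -> 0.1
        pair = make_pair()
        taxa = ["phantom", "other"]
        dna_t = table_from([[0, 9]], [pair.dna_sample_id], taxa)
        rna_t = table_from([[3, 27]], [pair.rna_sample_id], taxa)
        adjusted = phantom_adjust(dna_t, rna_t, [pair])
        out = ratio_16s(
            to_proportions(rna_t), to_proportions(adjusted), [pair]
        )
        assert out.loc["phantom", pair.pair_id] == pytest.approx(1.0, abs=1e-12)

    def test_both_zero_is_undefined(self):
        pair = make_pair()
        taxa = ["gone", "there"]
        rna = pd.DataFrame([[0.0, 1.0]], index=[pair.rna_sample_id], columns=taxa)
        dna = pd.DataFrame([[0.0, 1.0]], index=[pair.dna_sample_id], columns=taxa)
        out = ratio_16s(rna, dna, [pair])
        assert np.isnan(out.loc["gone", pair.pair_id])

    def test_unadjusted_phantom_triggers_assertion(self):
        pair = make_pair()
        taxa = ["ph", "ok"]
        rna = pd.DataFrame([[0.1, 0.9]], index=[pair.rna_sample_id], columns=taxa)
        dna = pd.DataFrame([[0.0, 1.0]], index=[pair.dna_sample_id], columns=taxa)
        with pytest.raises(AssertionError, match="phantom-adjusted"):
            ratio_16s(rna, dna, [pair])

    def test_no_phantoms_adjustment_is_identity(self, rng):
        pair = make_pair()
        taxa = [f"t{i}" for i in range(8)]
        counts = rng.integers(1, 30, size=(1, 8))  # strictly positive: no phantoms
        dna_t = table_from(counts, [pair.dna_sample_id], taxa)
        rna_t = table_from(rng.integers(0, 30, size=(1, 8)), [pair.rna_sample_id], taxa)
        adjusted = phantom_adjust(dna_t, rna_t, [pair])
        r1 = ratio_16s(to_proportions(rna_t), to_proportions(adjusted), [pair])
        r2 = ratio_16s(to_proportions(rna_t), to_proportions(dna_t), [pair])
        pd.testing.assert_frame_equal(r1, r2)


class TestTopN:
    def test_all_taxa_full_coverage(self):
        t = table_from([[5, 5, 5]], ["s"], ["a", "b", "c"])
        taxa, coverage = top_n_zotus(t, n=3)
        assert coverage == 1.0

    def test_coverage_fraction(self):
        t = table_from([[50, 30, 20]], ["s"], ["a", "b", "c"])
        taxa, coverage = top_n_zotus(t, n=2)
        assert taxa == ["a", "b"]
        assert coverage == pytest.approx(0.8)

    def test_tie_broken_lexicographically(self):
        t = table_from([[10, 10, 10]], ["s"], ["zc", "za", "zb"])
        taxa, _ = top_n_zotus(t, n=2)
        assert taxa == ["za", "zb"]

    def test_n_beyond_taxon_count(self):
        t = table_from([[1, 2]], ["s"], ["a", "b"])
        taxa, coverage = top_n_zotus(t, n=10)
        assert len(taxa) == 2 and coverage == 1.0


class TestDominance:
    @pytest.mark.parametrize(
        "l,s,expected",
        [(0.3, 0.3, 0.5), (0.3, 0.0, 1.0), (0.0, 0.4, 0.0)],
    )
    def test_examples(self, l, s, expected):
        assert dominance_ratio(l, s) == pytest.approx(expected)

    def test_both_zero_undefined_never_zero(self):
        assert np.isnan(dominance_ratio(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            dominance_ratio(-0.1, 0.2)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=0, max_value=1e3),
        st.floats(min_value=0, max_value=1e3),
    )
    def test_complementarity(self, l, s):
        if l + s == 0:
            return
        assert dominance_ratio(l, s) + dominance_ratio(s, l) == pytest.approx(1.0)
        assert 0 <= dominance_ratio(l, s) <= 1

    def test_matrix_missing_zone_month_is_nan(self):
        values = pd.DataFrame(
            {"t1": [0.2, 0.4, 0.0], "t2": [0.0, 0.0, 0.0]},
            index=["l1", "s1", "s2"],
        )
        zone = pd.Series({"l1": "Lagoon", "s1": "Seaward", "s2": "Seaward"})
        month = pd.Series({"l1": 2, "s1": 2, "s2": 3})  # month 3 has no lagoon
        mat = dominance_matrix(values, zone, month)
        assert mat.loc["t1", 2] == pytest.approx(0.2 / 0.6)
        assert np.isnan(mat.loc["t1", 3])
        assert np.isnan(mat.loc["t2", 2])  # both zones zero -> blank, not 0


class TestSpearmanScreen:
    def test_monotone_pairs(self):
        x = pd.DataFrame({"v": [1.0, 2, 3, 4, 5]}, index=list("abcde"))
        env = pd.DataFrame(
            {"up": [2.0, 4, 9, 16, 30], "down": [-1.0, -2, -3, -4, -5]},
            index=list("abcde"),
        )
        rho, p = spearman_screen(x, env)
        assert rho.loc["v", "up"] == pytest.approx(1.0)
        assert rho.loc["v", "down"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        n = 20
        x = pd.DataFrame({"v": rng.normal(size=n)}, index=range(n))
        env = pd.DataFrame({"e": rng.normal(size=n)}, index=range(n))
        rho, _ = spearman_screen(x, env)
        # independent oracle: average ranks then Pearson correlation
        rx = pd.Series(x["v"]).rank().to_numpy()
        re = pd.Series(env["e"]).rank().to_numpy()
        oracle = np.corrcoef(rx, re)[0, 1]
        assert rho.loc["v", "e"] == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_flagged_nan(self):
        x = pd.DataFrame({"v": [1.0, 1, 1, 1, 1]}, index=range(5))
        env = pd.DataFrame({"e": [1.0, 2, 3, 4, 5]}, index=range(5))
        rho, p = spearman_screen(x, env)
        assert np.isnan(rho.loc["v", "e"]) and np.isnan(p.loc["v", "e"])

    def test_too_few_observations_nan(self):
        x = pd.DataFrame({"v": [1.0, 2, 3]}, index=range(3))
        env = pd.DataFrame({"e": [3.0, 2, 1]}, index=range(3))
        rho, _ = spearman_screen(x, env)
        assert np.isnan(rho.loc["v", "e"])
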