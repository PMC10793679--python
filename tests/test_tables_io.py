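"""Count-table I/O, the two inclusion filters, aggregation, normalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pouchtrack import (
    CountTable, CountTableError, read_count_table, write_count_table,
    filter_min_reads, filter_min_relative_abundance, aggregate_taxa, to_relative,
)
from pouchtrack.tables_io import parse_lineage, apply_default_filters

from conftest import make_table, random_table


class TestRoundTrip:
    def test_read_write_identity(self, tmp_path):
        t = make_table(
            {"S1": [1, 0, 5], "S2": [2, 3, 4]},
            {"t1": {"phylum": "Firmicutes", "family": "Lachnospiraceae", "genus": "Blautia"},
             "t2": {"phylum": "Bacteroidetes", "family": "unclassified", "genus": "unclassified"},
             "t3": {"phylum": "Proteobacteria", "family": "Enterobacteriaceae", "genus": "Escherichia"}},
        )
        p = tmp_path / "c.tsv"
        write_count_table(t, p)
        r = read_count_table(p)
        assert r.taxa == t.taxa and r.samples == t.samples
        assert (r.counts.to_numpy() == t.counts.to_numpy()).all()
        assert r.lineages == t.lineages

    def test_write_is_byte_stable(self, tmp_path):
        t = make_table({"S1": [1, 2], "S2": [3, 4]})
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_count_table(t, p1)
        write_count_table(t, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_taxa_table(self, tmp_path):
        t = CountTable(pd.DataFrame(np.zeros((0, 2), dtype=np.int64),
                                    index=pd.Index([], name="taxon_id"), columns=["S1", "S2"]))
        p = tmp_path / "e.tsv"
        write_count_table(t, p)
        r = read_count_table(p)
        assert r.shape == (0, 2) and r.samples == ["S1", "S2"]

    def test_large_random_round_trip(self, tmp_path, rng):
        counts = {f"S{j}": rng.integers(0, 1000, size=500) for j in range(8)}
        t = make_table({k: list(v) for k, v in counts.items()},
                       taxa=[f"OTU_{i:04d}" for i in range(500)])
        p = tmp_path / "big.tsv"
        write_count_table(t, p)
        r = read_count_table(p)
        assert (r.counts.to_numpy() == t.counts.to_numpy()).all()
        assert r.taxa == t.taxa

    def test_crlf_tolerated(self, tmp_path):
        p = tmp_path / "crlf.tsv"
        p.write_bytes(b"taxon_id\tlineage\tS1\r\nt1\tp__X\t7\r\n")
        r = read_count_table(p)
        assert r.counts.loc["t1", "S1"] == 7


class TestParsing:
    def test_negative_count_names_cell(self, tmp_path):
        p = tmp_path / "neg.tsv"
        p.write_text("taxon_id\tlineage\tS1\nt1\tp__X\t-1\n")
        with pytest.raises(CountTableError, match=r"t1.*S1"):
            read_count_table(p)

    def test_non_integer_count(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("taxon_id\tlineage\tS1\nt1\tp__X\t1.5\n")
        with pytest.raises(CountTableError, match="non-integer"):
            read_count_table(p)

    def test_duplicate_sample_header(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("taxon_id\tlineage\tS1\tS1\nt1\tp__X\t1\t2\n")
        with pytest.raises(CountTableError, match="duplicate sample"):
            read_count_table(p)

    def test_duplicate_taxon_id(self, tmp_path):
        p = tmp_path / "dupt.tsv"
        p.write_text("taxon_id\tlineage\tS1\nt1\tp__X\t1\nt1\tp__Y\t2\n")
        with pytest.raises(CountTableError, match="duplicate taxon"):
            read_count_table(p)

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("p__Firmicutes;f__Lachnospiraceae;g__Blautia",
             {"phylum": "Firmicutes", "family": "Lachnospiraceae", "genus": "Blautia"}),
            ("p__Firmicutes", {"phylum": "Firmicutes", "family": "unclassified", "genus": "unclassified"}),
            ("garbage", {"phylum": "unclassified", "family": "unclassified", "genus": "unclassified"}),
            ("p__;g__Dialister", {"phylum": "unclassified", "family": "unclassified", "genus": "Dialister"}),
        ],
    )
    def test_lineage_parsing(self, raw, expected):
        assert parse_lineage(raw) == expected


class TestFilters:
    def test_min_reads_boundaries(self):
        sums = {"a": 5000, "b": 10000, "c": 15000, "d": 9999, "e": 1000000}
        t = make_table({k: [v] for k, v in sums.items()})
        kept, dropped = filter_min_reads(t, 10000)
        assert kept.samples == ["b", "c", "e"]
        assert dropped == ["a", "d"]
        assert kept.taxa == t.taxa  # taxa list unchanged

    def test_rare_filter_boundary_is_strict(self):
        # grand total 1e6; taxon at exactly 1e-5 (total 10) is retained
        t = make_table({"S1": [999900, 50, 40, 10]})
        out = filter_min_relative_abundance(t, 1e-5)
        assert out.taxa == ["t1", "t2", "t3", "t4"]
        out2 = filter_min_relative_abundance(t, 1.1e-5)
        assert out2.taxa == ["t1", "t2", "t3", "t4"][:3]

    def test_single_taxon_retained(self):
        t = make_table({"S1": [5]})
        assert filter_min_relative_abundance(t, 1e-5).taxa == ["t1"]

    def test_zero_grand_total_errors(self):
        t = make_table({"S1": [0, 0]})
        with pytest.raises(CountTableError, match="grand total"):
            filter_min_relative_abundance(t)

    def test_counts_of_retained_taxa_unchanged(self, rng):
        t = random_table(rng)
        out = filter_min_relative_abundance(t, 0.01)
        assert (out.counts == t.counts.loc[out.taxa]).all().all()

    def test_filter_order_matters(self):
        # Sample A has 10,100 reads of which 200 belong to a globally rare
        # taxon; rarity-first drops A under the read filter, reads-first
        # keeps it.  Default order is rarity first.
        t = make_table({"A": [9900, 200], "B": [1000000, 0]})
        rare_first, _ = filter_min_reads(filter_min_relative_abundance(t, 1e-3), 10000)
        reads_first = filter_min_relative_abundance(filter_min_reads(t, 10000)[0], 1e-3)
        assert rare_first.samples == ["B"]
        assert reads_first.samples == ["A", "B"]
        default, attrition = apply_default_filters(t, 10000, 1e-3)
        assert default.samples == rare_first.samples
        assert attrition["samples_dropped_low_reads"] == ["A"]


class TestAggregation:
    def test_same_genus_summed(self):
        t = make_table(
            {"S1": [3, 4], "S2": [1, 1]},
            {"t1": {"phylum": "F", "family": "L", "genus": "Blautia"},
             "t2": {"phylum": "F", "family": "L", "genus": "Blautia"}},
        )
        g = aggregate_taxa(t, "genus")
        assert g.taxa == ["Blautia"]
        assert list(g.counts.loc["Blautia"]) == [7, 2]
        assert g.lineages["Blautia"]["phylum"] == "F"

    def test_column_sums_conserved(self, rng):
        t = random_table(rng)
        for rank in ("phylum", "family", "genus"):
            g = aggregate_taxa(t, rank)
            assert (g.counts.sum(axis=0) == t.counts.sum(axis=0)).all()

    def test_all_unclassified_single_bucket(self):
        t = make_table({"S1": [1, 2, 3]})  # default lineages: all unclassified
        g = aggregate_taxa(t, "genus")
        assert g.taxa == ["unclassified"]
        assert g.counts.loc["unclassified", "S1"] == 6

    def test_unknown_rank(self):
        with pytest.raises(CountTableError, match="unknown rank"):
            aggregate_taxa(make_table({"S1": [1]}), "species")


class TestToRelative:
    def test_hand_values(self):
        t = make_table({"S1": [2, 2, 0], "S2": [6, 2, 2]})
        rel = to_relative(t)
        assert np.allclose(rel["S1"], [0.5, 0.5, 0.0])
        assert np.allclose(rel["S2"], [0.6, 0.2, 0.2])

    def test_columns_sum_to_one(self, rng):
        rel = to_relative(random_table(rng))
        assert np.allclose(rel.sum(axis=0), 1.0, atol=1e-12)

    def test_zero_column_names_sample(self):
        t = make_table({"ok": [1], "empty": [0]})
        with pytest.raises(CountTableError, match="empty"):
            to_relative(t)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.lists(st.integers(0, 10_000), min_size=3, max_size=3),
        min_size=1, max_size=8,
    )
)
def test_round_trip_property(tmp_path_factory, data):
    """read(write(t)) is value-identical for arbitrary integer tables."""
    tmp = tmp_path_factory.mktemp("rt")
    t = make_table({f"S{j + 1}": [row[j] for row in data] for j in range(3)},
                   taxa=[f"x{i}" for i in range(len(data))])
    p = tmp / "t.tsv"
    write_count_table(t, p)
    r = read_count_table(p)
    assert (r.counts.to_numpy() == t.counts.to_numpy()).all()
    assert r.taxa == t.taxa and r.samples == t.samples
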