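import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_dataset, uniform_eff
from refstab import (
    CqDataset,
    EfficiencyTable,
    FormatError,
    IntegrityError,
    ParseError,
    PreconditionError,
    average_technical_replicates,
    read_cq_table,
    summarize,
    to_quantities,
    write_table,
)


def _long_csv(tmp_path, text, name="cq.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadWrite:
    def test_long_round_trip(self, tmp_path):
        ds = make_dataset({"A": [20.0, 21.5], "B": [22.0, np.nan]})
        path = tmp_path / "out.csv"
        write_table(ds, path)
        assert read_cq_table(path).equals(ds)

    def test_na_cells_become_missing(self, tmp_path):
        p = _long_csv(
            tmp_path,
            "gene,sample,tissue,condition,bio_rep,cq\n"
            "A,s1,leaf,c1,1,20.0\nA,s2,leaf,c2,1,NA\n"
            "B,s1,leaf,c1,1,22.0\nB,s2,leaf,c2,1,23.0\n",
        )
        ds = read_cq_table(p)
        wide = ds.pivot()
        assert math.isnan(wide.loc["A", "s2"])
        assert wide.loc["B", "s2"] == 23.0

    def test_non_numeric_cq_reports_row(self, tmp_path):
        lines = ["gene,sample,tissue,condition,bio_rep,cq"]
        for i in range(5):
            lines.append(f"A,s{i},leaf,c{i},1,2{i}.0")
        lines.append("B,s0,leaf,c0,1,abc")  # data row 6 -> file row 7
        p = _long_csv(tmp_path, "\n".join(lines) + "\n")
        with pytest.raises(ParseError, match="row 7"):
            read_cq_table(p)

    def test_missing_column_named(self, tmp_path):
        p = _long_csv(tmp_path, "gene,sample,cq\nA,s1,20\nB,s2,21\n")
        with pytest.raises(FormatError, match="tissue"):
            read_cq_table(p)

    def test_duplicate_gene_sample_rejected(self, tmp_path):
        p = _long_csv(
            tmp_path,
            "gene,sample,tissue,condition,bio_rep,cq\n"
            "A,s1,leaf,c1,1,20.0\nA,s1,leaf,c1,1,20.5\n"
            "B,s1,leaf,c1,1,22.0\nB,s2,leaf,c2,1,23.0\n",
        )
        with pytest.raises(IntegrityError, match="duplicate"):
            read_cq_table(p)

    def test_wide_layout_with_annotations(self, tmp_path):
        wide = _long_csv(tmp_path, "gene,s1,s2\nA,20.0,21.0\nB,22.0,NA\n", "wide.csv")
        ann = _long_csv(
            tmp_path,
            "sample,tissue,condition,bio_rep\ns1,leaf,c1,1\ns2,leaf,c2,1\n",
            "ann.csv",
        )
        ds = read_cq_table(wide, layout="wide", annotations=ann)
        assert ds.pivot().loc["A", "s2"] == 21.0
        assert math.isnan(ds.pivot().loc["B", "s2"])

    def test_ranking_written_sorted_by_rank(self, tmp_path):
        table = pd.DataFrame(
            {"gene": ["C", "A", "B"], "msd": [0.3, 0.1, 0.2], "rank": [3, 1, 2]}
        )
        p = tmp_path / "rank.csv"
        write_table(table.sample(frac=1, random_state=0), p)
        back = pd.read_csv(p)
        assert list(back["rank"]) == [1, 2, 3]

    def test_unwritable_path_raises_oserror(self, tmp_path):
        ds = make_dataset({"A": [20.0, 21.0], "B": [22.0, 23.0]})
        with pytest.raises(OSError):
            write_table(ds, tmp_path)  # a directory, not a file

    @given(
        rows=st.lists(
            st.lists(
                st.one_of(st.none(), st.floats(1.0, 44.0, allow_nan=False)),
                min_size=3,
                max_size=5,
            ),
            min_size=2,
            max_size=4,
        ).filter(lambda rows: len({len(r) for r in rows}) == 1)
    )
    def test_round_trip_property(self, rows, tmp_path_shared):
        gene_cq = {f"g{i}": [np.nan if v is None else v for v in r] for i, r in enumerate(rows)}
        if all(all(np.isnan(v) for v in r) for r in gene_cq.values()):
            gene_cq["g0"][0] = 25.0
        ds = make_dataset(gene_cq)
        path = tmp_path_shared / "ds.csv"
        write_table(ds, path)
        assert read_cq_table(path).equals(ds)


class TestDatasetInvariants:
    def test_cq_out_of_range_rejected(self):
        with pytest.raises(IntegrityError):
            make_dataset({"A": [20.0, 46.0], "B": [22.0, 23.0]})

    def test_needs_two_genes(self):
        with pytest.raises(IntegrityError):
            make_dataset({"A": [20.0, 21.0]})

    def test_replicate_indices_positive(self):
        df = make_dataset({"A": [20.0, 21.0], "B": [21.0, 22.0]}).data
        df.loc[0, "bio_rep"] = 0
        with pytest.raises(IntegrityError):
            CqDataset(df)


class TestTechnicalAveraging:
    def _with_tech(self, triplicates):
        rows = []
        for gene, trip in triplicates.items():
            for k, cq in enumerate(trip, start=1):
                rows.append(
                    {
                        "gene": gene,
                        "sample": f"w{k}",
                        "tissue": "leaf",
                        "condition": "c1",
                        "bio_rep": 1,
                        "tech_rep": k,
                        "cq": cq,
                    }
                )
        # second condition so the dataset has >= 2 samples after averaging
        for gene in triplicates:
            rows.append(
                {
                    "gene": gene,
                    "sample": "w4",
                    "tissue": "leaf",
                    "condition": "c2",
                    "bio_rep": 1,
                    "tech_rep": 1,
                    "cq": 25.0,
                }
            )
        return CqDataset(pd.DataFrame(rows))

    @pytest.mark.parametrize(
        "trip,expected",
        [
            ([20.0, 20.2, 20.4], 20.2),
            ([20.0, np.nan, 21.0], 20.5),
            ([np.nan, np.nan, np.nan], np.nan),
        ],
    )
    def test_mean_of_present_replicates(self, trip, expected):
        ds = self._with_tech({"A": trip, "B": [22.0, 22.0, 22.0]})
        avg = average_technical_replicates(ds)
        got = avg.pivot().loc["A", "leaf:c1:b1"]
        if np.isnan(expected):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(expected, abs=1e-12)


class TestQuantities:
    def test_perfect_doubling_halves_per_cycle(self):
        ds = make_dataset({"A": [20.0, 21.0, 22.0], "B": [25.0, 25.0, 25.0]})
        q = to_quantities(ds, uniform_eff("AB"))
        assert list(q.quantities.loc["A"]) == [1.0, 0.5, 0.25]
        assert list(q.quantities.loc["B"]) == [1.0, 1.0, 1.0]

    def test_non_doubling_efficiency(self):
        ds = make_dataset({"A": [20.0, 21.0], "B": [25.0, 25.0]})
        q = to_quantities(ds, uniform_eff("AB", 1.9))
        assert q.quantities.loc["A", "s2"] == pytest.approx(1.0 / 1.9, abs=1e-12)

    def test_max_is_exactly_one(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng, n_genes=5, n_samples=7)
        q = to_quantities(ds, uniform_eff(ds.genes, 1.93))
        assert (q.quantities.max(axis=1) == 1.0).all()
        assert (q.quantities.to_numpy() > 0).all()
        assert (q.quantities.to_numpy() <= 1.0).all()

    def test_lower_cq_means_higher_quantity(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng)
        q = to_quantities(ds, uniform_eff(ds.genes, 1.85))
        wide = ds.pivot()
        for g in ds.genes:
            order = np.argsort(wide.loc[g].to_numpy())
            qs = q.quantities.loc[g].to_numpy()[order]
            assert (np.diff(qs) <= 0).all()

    def test_all_missing_gene_is_an_error(self):
        ds = make_dataset({"A": [np.nan, np.nan], "B": [22.0, 23.0]})
        with pytest.raises(PreconditionError, match="A"):
            to_quantities(ds, uniform_eff("AB"))


class TestSummaries:
    def test_range_over_condition_means(self):
        ds = make_dataset({"A": [24.0, 24.5, 25.0], "B": [20.0, 20.0, 20.0]})
        out = summarize(ds).set_index("gene")
        assert out.loc["A", "range_cq"] == pytest.approx(1.0)
        assert out.loc["B", "range_cq"] == 0.0
        assert out.loc["B", "sd_cq"] == 0.0

    def test_translation_equivariance(self, rng):
        from conftest import random_dataset

        ds = random_dataset(rng)
        shifted_df = ds.data.copy()
        shifted_df.loc[shifted_df["gene"] == "g0", "cq"] += 3.0
        shifted = CqDataset(shifted_df)
        a = summarize(ds).set_index("gene")
        b = summarize(shifted).set_index("gene")
        assert b.loc["g0", "mean_cq"] == pytest.approx(a.loc["g0", "mean_cq"] + 3.0)
        assert b.loc["g0", "range_cq"] == pytest.approx(a.loc["g0", "range_cq"])
        assert b.loc["g0", "sd_cq"] == pytest.approx(a.loc["g0", "sd_cq"])

    def test_unknown_grouping_rejected(self):
        ds = make_dataset({"A": [20.0, 21.0], "B": [22.0, 23.0]})
        with pytest.raises(PreconditionError):
            summarize(ds, group_by="condition")


class TestEfficiencyTable:
    def test_default_with_warning(self):
        eff = EfficiencyTable({"A": 1.9})
        with pytest.warns(UserWarning, match="perfect doubling"):
            assert eff.get("Z") == 2.0

    def test_atypical_value_warns(self):
        with pytest.warns(UserWarning, match="typical range"):
            EfficiencyTable({"A": 2.5})

    def test_sub_unity_rejected(self):
        with pytest.raises(IntegrityError):
            EfficiencyTable({"A": 0.95})
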