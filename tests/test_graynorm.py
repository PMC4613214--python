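import itertools

import numpy as np
import pytest

from conftest import make_replicated_dataset, uniform_eff
from oracles import brute_graynorm
from refstab import (
    PreconditionError,
    graynorm_quantities,
    graynorm_rank_all,
    graynorm_score,
    select_combination,
)


def flat_dataset(genes="ABC", conditions=("0", "1", "2"), cq=25.0):
    return make_replicated_dataset(
        {g: {c: cq for c in conditions} for g in genes}
    )


class TestCalibration:
    def test_one_cycle_induction_doubles_quantity(self):
        ds = make_replicated_dataset(
            {"A": {"0": 25.0, "1": 24.0}, "B": {"0": 22.0, "1": 22.0}}
        )
        cal = graynorm_quantities(ds, uniform_eff("AB"), "0")
        assert cal.quantities.loc["A", "1:b1"] == pytest.approx(2.0, abs=1e-12)

    def test_all_at_control_mean_gives_unit_quantities(self):
        cal = graynorm_quantities(flat_dataset(), uniform_eff("ABC"), "0")
        assert np.allclose(cal.quantities.to_numpy(), 1.0)

    def test_non_doubling_efficiency(self):
        ds = make_replicated_dataset(
            {"A": {"0": 25.0, "1": 26.0}, "B": {"0": 22.0, "1": 22.0}}
        )
        cal = graynorm_quantities(ds, uniform_eff("AB", 1.9), "0")
        assert cal.quantities.loc["A", "1:b1"] == pytest.approx(1 / 1.9, abs=1e-12)

    def test_control_geometric_mean_is_one(self, rng):
        conds = ["0", "1", "2"]
        ds = make_replicated_dataset(
            {
                g: {c: float(rng.uniform(20, 30)) for c in conds}
                for g in "ABCD"
            },
            n_bio=3,
        )
        # perturb control replicates so the control mean is non-trivial
        df = ds.data.copy()
        mask = df["condition"] == "0"
        df.loc[mask, "cq"] += rng.normal(0, 0.4, mask.sum())
        from refstab import CqDataset

        cal = graynorm_quantities(CqDataset(df), uniform_eff("ABCD", 1.93), "0")
        ctrl = cal.sample_info.index[cal.sample_info["condition"] == "0"]
        log_gm = np.log(cal.quantities[list(ctrl)].to_numpy()).mean(axis=1)
        assert np.allclose(log_gm, 0.0, atol=1e-12)


class TestScores:
    def test_perfectly_stable_combination_scores_zero(self):
        score = graynorm_score(flat_dataset(), uniform_eff("ABC"), ["A", "B"], "0")
        assert score.cumulative_deviation == pytest.approx(0.0, abs=1e-12)
        assert score.cv_inter == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(score.condition_means.to_numpy(), 1.0)

    def test_single_gene_repressed_one_condition(self):
        # gene A is +1 cycle (halved expression) in condition "3" only:
        # 1/NF there is 2, so the cumulative deviation is 1.0
        conds = ["0", "1", "2", "3", "4", "5"]
        vals = {c: 25.0 for c in conds}
        vals["3"] = 26.0
        ds = make_replicated_dataset(
            {"A": vals, "B": {c: 22.0 for c in conds}}
        )
        score = graynorm_score(ds, uniform_eff("AB"), ["A"], "0")
        assert score.condition_means["3"] == pytest.approx(2.0, abs=1e-12)
        assert score.cumulative_deviation == pytest.approx(1.0, abs=1e-12)

    def test_opposite_shifts_cancel_in_geometric_mean(self):
        conds = ["0", "1"]
        ds = make_replicated_dataset(
            {
                "A": {"0": 25.0, "1": 26.0},
                "B": {"0": 22.0, "1": 21.0},
                "C": {"0": 23.0, "1": 23.0},
            }
        )
        score = graynorm_score(ds, uniform_eff("ABC"), ["A", "B"], "0")
        assert score.cumulative_deviation == pytest.approx(0.0, abs=1e-12)


class TestRankAll:
    def test_number_of_combinations(self):
        genes = [f"g{i:02d}" for i in range(10)]
        ds = flat_dataset(genes, conditions=("0", "1"))
        ranked = graynorm_rank_all(ds, uniform_eff(genes), "0")
        assert len(ranked) == 1023

    def test_best_combination_excludes_unstable_gene(self, rng):
        conds = ["0", "1", "2", "3"]
        genes = {}
        for g in "ABCD":
            genes[g] = {c: 24.0 + float(rng.normal(0, 0.05)) for c in conds}
        genes["E"] = {c: 24.0 + 1.5 * i for i, c in enumerate(conds)}
        ds = make_replicated_dataset(genes)
        ranked = graynorm_rank_all(ds, uniform_eff("ABCDE"), "0")
        assert "E" not in ranked[0].genes

    def test_matches_bruteforce_enumeration(self, rng):
        conds = ["0", "0", "1", "1", "2", "2"]
        cq = {g: list(rng.uniform(22, 26, 6)) for g in "ABCD"}
        rows = []
        import pandas as pd

        for g, values in cq.items():
            for i, v in enumerate(values):
                rows.append(
                    {
                        "gene": g,
                        "sample": f"s{i}",
                        "tissue": "leaf",
                        "condition": conds[i],
                        "bio_rep": i % 2 + 1,
                        "cq": v,
                    }
                )
        from refstab import CqDataset

        ds = CqDataset(pd.DataFrame(rows))
        eff = {g: 1.95 for g in "ABCD"}
        expected = brute_graynorm(cq, eff, conds, "0")
        ranked = graynorm_rank_all(ds, uniform_eff("ABCD", 1.95), "0")
        assert len(ranked) == len(expected)
        for score in ranked:
            exp_means, exp_cv, exp_cumdev = expected[score.genes]
            assert score.cumulative_deviation == pytest.approx(exp_cumdev, abs=1e-12)
            assert score.cv_inter == pytest.approx(exp_cv, abs=1e-12)
        # the implementation's best equals the enumerated minimum
        best = min(expected, key=lambda c: expected[c][2])
        assert expected[best][2] == pytest.approx(
            ranked[0].cumulative_deviation, abs=1e-12
        )

    def test_adding_responsive_gene_degrades_stable_combination(self):
        conds = ["0", "1", "2"]
        genes = {g: {c: 24.0 for c in conds} for g in "AB"}
        genes["C"] = {"0": 24.0, "1": 25.0, "2": 26.0}
        ds = make_replicated_dataset(genes)
        eff = uniform_eff("ABC")
        stable = graynorm_score(ds, eff, ["A", "B"], "0")
        degraded = graynorm_score(ds, eff, ["A", "B", "C"], "0")
        assert degraded.cumulative_deviation >= stable.cumulative_deviation

    def test_enumeration_guard(self):
        ds = flat_dataset("ABCD", conditions=("0", "1"))
        with pytest.raises(PreconditionError, match="max_genes"):
            graynorm_rank_all(ds, uniform_eff("ABCD"), "0", max_genes=3)


class TestSelection:
    def _ranked(self):
        genes = [f"g{i}" for i in range(4)]
        ds = flat_dataset(genes, conditions=("0", "1"))
        return graynorm_rank_all(ds, uniform_eff(genes), "0")

    def test_first_combination_of_minimum_size(self):
        chosen = select_combination(self._ranked(), min_genes=3)
        assert chosen.size >= 3

    def test_min_genes_one_returns_overall_best(self):
        ranked = self._ranked()
        assert select_combination(ranked, min_genes=1) is ranked[0]

    def test_unreachable_size_is_an_error(self):
        with pytest.raises(PreconditionError):
            select_combination(self._ranked(), min_genes=10)
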