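import numpy as np
import pandas as pd
import pytest

from conftest import make_dataset, uniform_eff
from refstab import (
    CqDataset,
    PreconditionError,
    normfinder_best_pair,
    normfinder_stability,
    pairwise_dct,
    genorm_rank,
    to_quantities,
)


def grouped_dataset(gene_values: dict, groups: list, tissue="leaf") -> CqDataset:
    """Dataset whose samples carry the given bio_rep group labels."""
    rows = []
    for gene, values in gene_values.items():
        for i, cq in enumerate(values):
            rows.append(
                {
                    "gene": gene,
                    "sample": f"s{i + 1}",
                    "tissue": tissue,
                    "condition": f"c{i + 1}",
                    "bio_rep": groups[i],
                    "cq": cq,
                }
            )
    return CqDataset(pd.DataFrame(rows))


class TestSingleGroup:
    def test_constant_genes_have_zero_stability(self):
        ds = make_dataset({"A": [20.0] * 4, "B": [22.0] * 4, "C": [25.0] * 4})
        r = normfinder_stability(ds, uniform_eff("ABC"), groups="none")
        assert np.allclose(r.stability.to_numpy(), 0.0)

    def test_noisy_gene_ranked_last(self):
        ds = make_dataset(
            {"A": [20.0] * 4, "B": [22.0] * 4, "C": [24.0, 26.0, 24.0, 26.0]}
        )
        r = normfinder_stability(ds, uniform_eff("ABC"), groups="none")
        assert r.ordering[-1] == "C"
        assert r.stability["C"] > r.stability["A"]


class TestMultiGroup:
    def test_group_shifted_gene_flagged_in_seeded_simulations(self):
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            rng = np.random.default_rng(1000 + seed)
            genes = {}
            for g in "ABCDE":
                noise = rng.normal(0, 0.05, 8)
                values = 24.0 + noise
                if g == "E":
                    values[4:] += 1.0  # shifted only in group 2
                genes[g] = list(values)
            ds = grouped_dataset(genes, groups=[1] * 4 + [2] * 4)
            r = normfinder_stability(ds, uniform_eff("ABCDE"), groups="bio_rep")
            if r.ordering[-1] == "E":
                hits += 1
        assert hits >= 95

    def test_gene_offset_invariance(self):
        rng = np.random.default_rng(42)
        base = {g: list(24 + rng.normal(0, 0.3, 8)) for g in "ABCD"}
        ds = grouped_dataset(base, groups=[1] * 4 + [2] * 4)
        shifted = {g: v.copy() for g, v in base.items()}
        shifted["B"] = [v - 2.5 for v in shifted["B"]]  # constant fold change
        ds2 = grouped_dataset(shifted, groups=[1] * 4 + [2] * 4)
        r1 = normfinder_stability(ds, uniform_eff("ABCD"))
        r2 = normfinder_stability(ds2, uniform_eff("ABCD"))
        assert np.allclose(r1.stability.to_numpy(), r2.stability.to_numpy(), atol=1e-10)

    def test_sample_relabeling_within_groups_is_irrelevant(self):
        rng = np.random.default_rng(7)
        base = {g: list(24 + rng.normal(0, 0.3, 6)) for g in "ABC"}
        ds = grouped_dataset(base, groups=[1, 1, 1, 2, 2, 2])
        perm = [2, 0, 1, 5, 3, 4]  # permute samples within each group
        permuted = {g: [v[i] for i in perm] for g, v in base.items()}
        ds2 = grouped_dataset(permuted, groups=[1, 1, 1, 2, 2, 2])
        r1 = normfinder_stability(ds, uniform_eff("ABC"))
        r2 = normfinder_stability(ds2, uniform_eff("ABC"))
        assert np.allclose(r1.stability.to_numpy(), r2.stability.to_numpy())

    def test_preconditions(self):
        ds = make_dataset({"A": [20.0] * 4, "B": [21.0] * 4})
        with pytest.raises(PreconditionError, match="3 genes"):
            normfinder_stability(ds, uniform_eff("AB"), groups="none")
        ds3 = grouped_dataset(
            {g: [20.0, 21.0, 22.0] for g in "ABC"}, groups=[1, 1, 2]
        )
        with pytest.raises(PreconditionError, match="fewer than 2"):
            normfinder_stability(ds3, uniform_eff("ABC"), groups="bio_rep")


class TestBestPair:
    def test_opposite_intergroup_shifts_cancel(self):
        rng = np.random.default_rng(3)
        genes = {}
        for g in "ABCD":
            noise = rng.normal(0, 0.08, 8)
            values = 24.0 + noise
            if g == "A":
                values[4:] += 0.5
            if g == "B":
                values[4:] -= 0.5
            genes[g] = list(values)
        ds = grouped_dataset(genes, groups=[1] * 4 + [2] * 4)
        r = normfinder_stability(ds, uniform_eff("ABCD"))
        pair, value = normfinder_best_pair(r)
        assert value < min(r.stability["A"], r.stability["B"])

    def test_all_identical_reports_first_lexicographic_pair(self):
        ds = grouped_dataset(
            {g: [20.0] * 4 for g in ["b", "a", "c"]}, groups=[1, 1, 2, 2]
        )
        r = normfinder_stability(ds, uniform_eff("abc"))
        pair, value = normfinder_best_pair(r)
        assert pair == ("a", "b") and value == 0.0

    def test_unstable_gene_excluded_from_best_pair(self):
        rng = np.random.default_rng(11)
        genes = {g: list(24 + rng.normal(0, 0.05, 8)) for g in "ABC"}
        genes["C"] = list(24 + rng.normal(0, 1.0, 8))  # noisy within groups
        ds = grouped_dataset(genes, groups=[1] * 4 + [2] * 4)
        pair, _ = normfinder_best_pair(
            normfinder_stability(ds, uniform_eff("ABC"))
        )
        assert "C" not in pair

    def test_single_group_is_unsupported(self):
        ds = make_dataset({g: [20.0, 21.0, 20.5, 21.5] for g in "ABC"})
        r = normfinder_stability(ds, uniform_eff("ABC"), groups="none")
        with pytest.raises(PreconditionError, match="single-gene"):
            normfinder_best_pair(r)


def test_condition_responsive_gene_ranked_last_by_all_methods():
    """A strongly salt-responsive gene should land at the bottom of the
    ΔCt, NormFinder and geNorm rankings alike."""
    rng = np.random.default_rng(5)
    n = 12
    genes = {g: list(24 + rng.normal(0, 0.1, n)) for g in "ABC"}
    ramp = np.linspace(0, 3, n)  # 3-cycle drift across the time course
    genes["D"] = list(26 + ramp + rng.normal(0, 0.1, n))
    ds = grouped_dataset(genes, groups=[1, 2, 3] * 4)
    eff = uniform_eff("ABCD")
    assert pairwise_dct(ds).ordering[-1] == "D"
    assert normfinder_stability(ds, eff).ordering[-1] == "D"
    assert genorm_rank(to_quantities(ds, eff)).ordering[-1] == "D"
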