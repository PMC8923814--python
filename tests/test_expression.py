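from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allotx.expression import (
    activation_silencing,
    bh_adjust,
    expressed_genes,
    nb_wald_test,
    size_factors,
    tpm,
)
from allotx.models import CountMatrix, SampleSheet, ValidationError
from allotx.report import (
    expressed_sets_from_regions,
    packaged_expressed_venn_regions,
)

from _oracles import bh_stepup, median_of_ratios_bruteforce


def _matrix(data, groups, lengths=None):
    cols = list(data.keys())
    sheet_rows = []
    seen: dict[str, int] = {}
    for c, g in zip(cols, groups):
        seen[g] = seen.get(g, 0) + 1
        sheet_rows.append({"sample_id": c, "group": g, "replicate": seen[g]})
    df = pd.DataFrame(data)
    df.index = [f"g{i}" for i in range(len(df))]
    lg = None
    if lengths is not None:
        lg = pd.Series(lengths, index=df.index, dtype=float)
    return CountMatrix(df, SampleSheet(pd.DataFrame.from_records(sheet_rows)), lg)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        m = _matrix({"s1": [10, 20, 30], "s2": [10, 20, 30]}, ["A", "A"])
        f = size_factors(m.counts)
        assert np.allclose(f, [1.0, 1.0])

    def test_scale_equivariance(self):
        m = _matrix({"s1": [10, 20, 30], "s2": [20, 40, 60]}, ["A", "A"])
        f = size_factors(m.counts)
        assert np.isclose(f["s2"] / f["s1"], 2.0)

    def test_matches_direct_formula(self, rng):
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.1, size=(200, 4)),
            columns=list("abcd"),
        )
        assert np.allclose(size_factors(counts), median_of_ratios_bruteforce(counts))

    def test_gene_order_invariance(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(100, 3)), columns=list("abc"))
        shuffled = counts.sample(frac=1, random_state=1)
        assert np.allclose(size_factors(counts), size_factors(shuffled))

    def test_pseudo_reference_fallback_warns(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.warns(UserWarning, match="pseudo-reference"):
            size_factors(counts)


class TestTpm:
    def test_single_gene(self):
        m = _matrix({"s1": [7]}, ["A"], lengths=[1000])
        assert np.isclose(tpm(m).iloc[0, 0], 1e6)

    def test_length_normalisation(self):
        m = _matrix({"s1": [10, 10]}, ["A"], lengths=[1000, 2000])
        vals = tpm(m)["s1"].to_numpy()
        assert np.allclose(vals, [2e6 / 3, 1e6 / 3])

    def test_columns_sum_to_million(self, rng):
        counts = {f"s{i}": rng.poisson(30, 50) for i in range(4)}
        m = _matrix(counts, ["A", "A", "C", "C"],
                    lengths=rng.integers(200, 5000, 50))
        sums = tpm(m).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_all_zero_sample_warns(self):
        m = _matrix({"s1": [0, 0], "s2": [1, 2]}, ["A", "A"], lengths=[1000, 1000])
        with pytest.warns(UserWarning, match="zero total"):
            out = tpm(m)
        assert (out["s1"] == 0).all()

    def test_lengths_required(self):
        m = _matrix({"s1": [1]}, ["A"])
        with pytest.raises(ValidationError, match="lengths"):
            tpm(m)


class TestExpressedGenes:
    def test_single_positive_replicate_is_expressed(self):
        m = _matrix(
            {"s1": [0, 0], "s2": [0, 0], "s3": [1, 0]},
            ["A", "A", "A"],
            lengths=[1000, 1000],
        )
        t = tpm(m)
        assert expressed_genes(t, m.sheet, "A") == {"g0"}

    def test_unknown_group_rejected(self):
        m = _matrix({"s1": [1]}, ["A"], lengths=[1000])
        with pytest.raises(ValidationError):
            expressed_genes(tpm(m), m.sheet, "Z")

    def test_silenced_class_not_expressed_in_progeny(self):
        from allotx.simulate import SimConfig, generate_annotation, generate_counts

        cfg = SimConfig(seed=21, n_genes=100)
        genes, truth = generate_annotation(cfg)
        m, truth = generate_counts(genes, cfg, truth)
        t = tpm(m)
        expr_rac = expressed_genes(t, m.sheet, "RAC")
        silenced = {g for g, c in truth.expression_class.items() if c == "silenced"}
        assert silenced and silenced.isdisjoint(expr_rac)
        parents = expressed_genes(t, m.sheet, "A") | expressed_genes(t, m.sheet, "C")
        assert silenced <= parents


class TestActivationSilencing:
    def test_set_arithmetic(self):
        res = activation_silencing({"a", "b"}, {"b", "c"})
        assert res["activated"] == {"a"}
        assert res["silenced"] == {"c"}

    def test_identical_sets(self):
        res = activation_silencing({"a"}, {"a"})
        assert res["activated"] == res["silenced"] == set()

    def test_partition_sums(self):
        res = activation_silencing({"a", "b", "c"}, {"c", "d", "e"},
                                   partition_by={"a", "d"})
        inside, outside = res["silenced_split"]
        assert inside | outside == res["silenced"]
        assert inside.isdisjoint(outside)

    def test_fixture_reproduces_reported_venn_arithmetic(self):
        """The shipped three-way Venn regions reproduce the reported
        activation/silencing sums: silenced 3966+2462=6428 and activated
        3515+3177=6692 for the resynthesized allopolyploid vs the hybrid,
        silenced 3515+3891=7406 for natural vs resynthesized."""
        sets = expressed_sets_from_regions(packaged_expressed_venn_regions())
        assert {len(sets[g]) for g in sets} == {62_268, 62_532, 60_389}
        rac_vs_hyb = activation_silencing(
            sets["RAC"], sets["A_C"], partition_by=sets["NAC"]
        )
        assert len(rac_vs_hyb["silenced"]) == 6428
        assert sorted(map(len, rac_vs_hyb["silenced_split"])) == [2462, 3966]
        assert len(rac_vs_hyb["activated"]) == 6692
        assert sorted(map(len, rac_vs_hyb["activated_split"])) == [3177, 3515]
        nac_vs_rac = activation_silencing(
            sets["NAC"], sets["RAC"], partition_by=sets["A_C"]
        )
        assert len(nac_vs_rac["silenced"]) == 7406
        assert sorted(map(len, nac_vs_rac["silenced_split"])) == [3515, 3891]
        assert len(nac_vs_rac["activated"]) == 5263
        assert sorted(map(len, nac_vs_rac["activated_split"])) == [2462, 2801]


class TestBhAdjust:
    def test_closed_form(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert bh_adjust([0.2]) == [0.2]

    def test_matches_literal_stepup(self, rng):
        for _ in range(20):
            p = rng.random(rng.integers(1, 50))
            assert np.allclose(bh_adjust(p), bh_stepup(p))

    @given(
        st.lists(
            st.floats(0.0, 1.0, allow_nan=False, allow_infinity=False),
            min_size=1,
            max_size=60,
        )
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_stepup_property(self, p):
        """BH output is monotone in rank, >= p, and matches the literal
        step-up for arbitrary p vectors."""
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_stepup(p))
        assert (adj >= np.asarray(p) - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestNbWald:
    def _sim_matrix(self, rng, mu2_scale=None, ngenes=400, phi=0.1):
        mu = 10 ** rng.uniform(1, 3, ngenes)
        mu2 = mu.copy()
        if mu2_scale is not None:
            mu2 = mu * mu2_scale
        r = 1 / phi
        c1 = rng.negative_binomial(r, r / (r + mu[:, None]), (ngenes, 3))
        c2 = rng.negative_binomial(r, r / (r + mu2[:, None]), (ngenes, 3))
        data = np.hstack([c1, c2])
        cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
        return _matrix({c: data[:, i] for i, c in enumerate(cols)},
                       ["G1"] * 3 + ["G2"] * 3)

    def test_identical_groups_null(self):
        m = _matrix(
            {"a1": [10, 50], "a2": [12, 55], "a3": [9, 48],
             "b1": [10, 50], "b2": [12, 55], "b3": [9, 48]},
            ["G1"] * 3 + ["G2"] * 3,
        )
        res = nb_wald_test(m, "G1", "G2")
        assert np.allclose(res["log2FC"], 0.0)
        assert not res["is_DEG"].any()

    def test_padj_at_least_p_and_in_unit_interval(self, rng):
        res = nb_wald_test(self._sim_matrix(rng), "G1", "G2")
        ok = res["p"].notna()
        assert (res.loc[ok, "padj"] >= res.loc[ok, "p"] - 1e-12).all()
        assert res.loc[ok, "padj"].between(0, 1).all()

    def test_group_swap_antisymmetry(self, rng):
        m = self._sim_matrix(rng, mu2_scale=2.0)
        r12 = nb_wald_test(m, "G1", "G2")
        r21 = nb_wald_test(m, "G2", "G1")
        assert np.allclose(r12["log2FC"], -r21["log2FC"], equal_nan=True)
        assert np.allclose(r12["p"], r21["p"], equal_nan=True)
        assert (r12["is_DEG"] == r21["is_DEG"]).all()

    def test_all_zero_genes_excluded(self):
        m = _matrix(
            {"a1": [0, 5], "a2": [0, 6], "b1": [0, 5], "b2": [0, 7]},
            ["G1", "G1", "G2", "G2"],
        )
        res = nb_wald_test(m, "G1", "G2")
        assert np.isnan(res.loc["g0", "p"])
        assert not res.loc["g0", "is_DEG"]

    def test_single_replicate_rejected(self):
        m = _matrix({"a1": [1], "b1": [2], "b2": [3]}, ["G1", "G2", "G2"])
        with pytest.raises(ValidationError, match="replicates"):
            nb_wald_test(m, "G1", "G2")
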