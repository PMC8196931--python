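import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psychromark import composition
from psychromark.types import AMINO_ACIDS


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 0.5), ("GGCC", 1.0), ("ATNN", 0.0), ("AAAA", 0.0)],
    )
    def test_values(self, seq, expected):
        assert composition.gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        assert math.isnan(composition.gc_content("NNNN"))
        assert math.isnan(composition.gc_content(""))

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            composition.gc_content("ATGX")


class TestAaComposition:
    def test_single_residue(self):
        freq = composition.aa_composition([("p", "AAAA")])
        assert freq["A"] == 1.0

    def test_across_proteins(self):
        freq = composition.aa_composition([("p1", "AC"), ("p2", "CA")])
        assert freq["A"] == freq["C"] == 0.5

    def test_x_ignored(self):
        freq = composition.aa_composition([("p", "AXXA")])
        assert freq["A"] == 1.0

    @given(st.lists(st.sampled_from(AMINO_ACIDS), min_size=5, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_frequencies_sum_to_one(self, residues):
        freq = composition.aa_composition([("p", "".join(residues))])
        assert freq.sum() == pytest.approx(1.0, abs=1e-9)


class TestAaGroupTest:
    def _comps(self, rng, n=8, shift=0.0):
        base = np.full(20, 0.05)
        rows = {}
        for i in range(n):
            rows[f"a{i}"] = base + rng.normal(0, 0.001, 20)
        shifted = base.copy()
        shifted[AMINO_ACIDS.index("N")] += shift
        for i in range(n):
            rows[f"c{i}"] = shifted + rng.normal(0, 0.001, 20)
        comps = pd.DataFrame(rows, index=list(AMINO_ACIDS)).T
        groups = pd.Series(
            {**{f"a{i}": "A" for i in range(n)}, **{f"c{i}": "C" for i in range(n)}}
        )
        return comps, groups

    def test_identical_compositions_not_flagged(self):
        comps = pd.DataFrame(
            np.tile(np.full(20, 0.05), (6, 1)),
            index=[f"g{i}" for i in range(6)],
            columns=list(AMINO_ACIDS),
        )
        groups = pd.Series({f"g{i}": "A" if i < 3 else "C" for i in range(6)})
        res = composition.aa_group_test(comps, groups)
        assert not res["significant"].any()
        assert (res["p"] == 1.0).all()

    def test_planted_shift_flagged_with_sign(self, rng):
        comps, groups = self._comps(rng, n=10, shift=0.02)
        res = composition.aa_group_test(comps, groups)
        assert res.loc["N", "significant"]
        assert res.loc["N", "delta"] > 0

    def test_small_group_rejected(self, rng):
        comps, groups = self._comps(rng, n=2)
        groups["a1"] = "B"  # leaves group B with one genome
        with pytest.raises(ValueError):
            composition.aa_group_test(comps, groups)


class TestAaGcRegression:
    def test_exact_linear_relationship(self, rng):
        gc = pd.Series(np.linspace(0.5, 0.7, 8), index=[f"g{i}" for i in range(8)])
        comps = pd.DataFrame(
            {res: 0.05 + (0.1 * gc.values if res == "N" else 0.0) for res in AMINO_ACIDS},
            index=gc.index,
        )
        res = composition.aa_gc_regression(comps, gc)
        assert res.loc["N", "r2"] == pytest.approx(1.0)
        assert res.loc["N", "slope"] == pytest.approx(0.1)

    def test_zero_gc_variance_undefined(self):
        gc = pd.Series([0.6] * 5, index=[f"g{i}" for i in range(5)])
        comps = pd.DataFrame(
            np.random.default_rng(0).uniform(0, 0.1, (5, 20)),
            index=gc.index,
            columns=list(AMINO_ACIDS),
        )
        res = composition.aa_gc_regression(comps, gc)
        assert res["r2"].isna().all()

    def test_too_few_genomes_rejected(self):
        gc = pd.Series([0.5, 0.6], index=["g0", "g1"])
        comps = pd.DataFrame(
            np.full((2, 20), 0.05), index=gc.index, columns=list(AMINO_ACIDS)
        )
        with pytest.raises(ValueError):
            composition.aa_gc_regression(comps, gc)


class TestBrayCurtis:
    def test_toy_value(self):
        assert composition.bray_curtis([0.6, 0.4], [0.4, 0.6]) == pytest.approx(0.2)

    def test_identical_vectors(self):
        assert composition.bray_curtis([0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_disjoint_support(self):
        assert composition.bray_curtis([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x, y = rng.dirichlet(np.ones(20)), rng.dirichlet(np.ones(20))
        assert composition.bray_curtis(x, y) == pytest.approx(
            composition.bray_curtis(y, x)
        )


class TestCategoryBias:
    def test_ranking_and_skip(self):
        vec = pd.Series(np.full(20, 0.05), index=list(AMINO_ACIDS))
        biased = vec.copy()
        biased["N"] += 0.04
        biased["A"] -= 0.04
        comp_a = {"cat1": vec, "cat2": vec, "only_a": vec}
        comp_c = {"cat1": vec, "cat2": biased}
        with pytest.warns(UserWarning, match="only_a"):
            df = composition.category_bias(comp_a, comp_c)
        assert list(df["category"]) == ["cat2", "cat1"]
        assert df.loc[df["category"] == "cat1", "bc_distance"].iloc[0] == 0.0


class TestKoEnrichment:
    def _content(self, rows):
        genomes = [f"a{i}" for i in range(10)] + [f"c{i}" for i in range(10)]
        groups = pd.Series(
            {**{f"a{i}": "A" for i in range(10)}, **{f"c{i}": "C" for i in range(10)}}
        )
        return pd.DataFrame(rows, index=genomes).T, groups

    def test_constant_category_p_one(self):
        content, groups = self._content({"k0": [1] * 20})
        res = composition.ko_enrichment(content, groups)
        assert res["p"].iloc[0] == 1.0

    def test_perfect_separation_flagged_toward_c(self):
        content, groups = self._content({"k0": [0] * 10 + [1] * 10})
        res = composition.ko_enrichment(content, groups)
        assert res["significant"].iloc[0]
        assert res["direction"].iloc[0] == "C"

    def test_permuted_labels_control_false_positives(self, rng):
        genomes = [f"g{i}" for i in range(20)]
        content = pd.DataFrame(
            rng.integers(0, 2, size=(40, 20)), columns=genomes
        )
        flags = []
        for _ in range(30):
            labels = np.array(["A"] * 10 + ["C"] * 10)
            rng.shuffle(labels)
            groups = pd.Series(labels, index=genomes)
            res = composition.ko_enrichment(content, groups)
            flags.append(res["significant"].mean())
        assert np.mean(flags) < 0.12
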