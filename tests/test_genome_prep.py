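import math

import numpy as np
import pytest

from psychromark import genome_prep, simulate
from psychromark.genome_prep import QcThresholds, qc_filter
from psychromark.types import AMINO_ACIDS, GenomeRecord


def _genome(gid="g", completeness=99.0, contamination=1.0, contigs=50, n50=500_000):
    return GenomeRecord(
        genome_id=gid,
        completeness=completeness,
        contamination=contamination,
        n_contigs=contigs,
        n50=n50,
    )


class TestQcFilter:
    @pytest.mark.parametrize(
        "kwargs,removed,reason",
        [
            ({"completeness": 94.9}, True, "completeness"),
            ({"contamination": 5.1}, True, "contamination"),
            ({"contigs": 301}, True, "contigs"),
            ({"n50": 19_999}, True, "n50"),
            ({"completeness": 95.0, "contamination": 5.0, "contigs": 300, "n50": 20_000}, False, None),
            ({}, False, None),
        ],
    )
    def test_boundary_semantics(self, kwargs, removed, reason):
        kept, rem = qc_filter([_genome(**kwargs)])
        if removed:
            assert not kept and rem[0][1] == [reason]
        else:
            assert len(kept) == 1 and not rem

    def test_missing_metric_raises(self):
        g = _genome()
        g.n50 = None
        with pytest.raises(ValueError, match="n50"):
            qc_filter([g])

    def test_matches_brute_force_predicate(self, rng):
        genomes = [
            _genome(
                gid=f"g{i}",
                completeness=float(rng.uniform(90, 100)),
                contamination=float(rng.uniform(0, 8)),
                contigs=int(rng.integers(1, 500)),
                n50=int(rng.integers(5_000, 100_000)),
            )
            for i in range(60)
        ]
        kept, removed = qc_filter(genomes)
        for g in genomes:
            should_remove = (
                g.n_contigs > 300
                or g.n50 < 20_000
                or g.completeness < 95
                or g.contamination > 5
            )
            assert (g in [r for r, _ in removed]) == should_remove


class TestPairwiseAai:
    def test_self_identity(self, rng):
        prot = [
            (f"p{i}", simulate._draw_protein(rng, np.full(20, 0.05), simulate.SimConfig()))
            for i in range(6)
        ]
        assert genome_prep.pairwise_aai(prot, prot) == pytest.approx(100.0)

    def test_symmetry(self, rng):
        cfg = simulate.SimConfig()
        a = [(f"a{i}", simulate._draw_protein(rng, np.full(20, 0.05), cfg)) for i in range(6)]
        b = [(pid, simulate.mutate_protein(rng, s, 90.0)) for pid, s in a]
        assert genome_prep.pairwise_aai(a, b) == pytest.approx(
            genome_prep.pairwise_aai(b, a)
        )

    def test_mutated_proteome_aai_near_target(self, rng):
        """~85 % per-protein mutation should land AAI in [80, 90]."""
        cfg = simulate.SimConfig()
        a = [(f"a{i}", simulate._draw_protein(rng, np.full(20, 0.05), cfg)) for i in range(10)]
        b = [(f"b{i}", simulate.mutate_protein(rng, s, 85.0)) for i, (_, s) in enumerate(a)]
        aai = genome_prep.pairwise_aai(a, b)
        assert 80.0 <= aai <= 90.0

    def test_no_rbh_returns_nan(self):
        aai = genome_prep.pairwise_aai([("a", "MKVLIACGTW" * 6)], [("b", "PPPGGGPPPG" * 6)])
        assert math.isnan(aai)

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            genome_prep.pairwise_aai([], [("b", "MKV")])


class TestDereplicate:
    def _aai_fn(self, table):
        def fn(a, b):
            key = tuple(sorted((a.genome_id, b.genome_id)))
            return table.get(key, 50.0)

        return fn

    def test_duplicate_collapsed(self):
        g1 = _genome("g1", completeness=99)
        g2 = _genome("g2", completeness=97)
        reps = genome_prep.dereplicate(
            [g1, g2], aai_fn=self._aai_fn({("g1", "g2"): 100.0})
        )
        assert [r.genome_id for r in reps] == ["g1"]

    def test_single_linkage_chain(self):
        gs = [_genome(f"g{i}", completeness=95 + i) for i in (1, 2, 3)]
        table = {("g1", "g2"): 99.6, ("g2", "g3"): 99.6, ("g1", "g3"): 99.0}
        reps = genome_prep.dereplicate(gs, aai_fn=self._aai_fn(table))
        assert [r.genome_id for r in reps] == ["g3"]  # highest completeness

    def test_all_distinct_retained(self):
        gs = [_genome(f"g{i}") for i in range(4)]
        reps = genome_prep.dereplicate(gs, aai_fn=self._aai_fn({}))
        assert len(reps) == 4

    def test_order_invariance(self):
        gs = [_genome(f"g{i}", completeness=95 + i) for i in range(5)]
        table = {("g0", "g3"): 99.9, ("g1", "g4"): 99.7}
        fwd = genome_prep.dereplicate(gs, aai_fn=self._aai_fn(table))
        rev = genome_prep.dereplicate(gs[::-1], aai_fn=self._aai_fn(table))
        assert [r.genome_id for r in fwd] == [r.genome_id for r in rev]

    def test_tie_breaks_by_contamination_then_id(self):
        g1 = _genome("g1", completeness=99, contamination=2.0)
        g2 = _genome("g2", completeness=99, contamination=1.0)
        reps = genome_prep.dereplicate(
            [g1, g2], aai_fn=self._aai_fn({("g1", "g2"): 99.9})
        )
        assert [r.genome_id for r in reps] == ["g2"]


class TestClusterGeneFamilies:
    def test_identical_proteins_one_family(self, rng):
        seq = simulate._draw_protein(rng, np.full(20, 0.05), simulate.SimConfig())
        gfm = genome_prep.cluster_gene_families({"g1": [("a", seq)], "g2": [("b", seq)]})
        assert gfm.counts.shape[0] == 1
        assert gfm.counts.iloc[0].tolist() == [1, 1]

    def test_unrelated_proteins_are_singletons(self, rng):
        cfg = simulate.SimConfig()
        s1 = simulate._draw_protein(rng, np.full(20, 0.05), cfg)
        s2 = simulate._draw_protein(rng, np.full(20, 0.05), cfg)
        gfm = genome_prep.cluster_gene_families({"g1": [("a", s1)], "g2": [("b", s2)]})
        assert gfm.counts.shape[0] == 2

    def test_transitive_chain_joins_one_family(self, rng):
        """p1-p2 and p2-p3 pass the cutoffs; p1-p3 alone would not."""
        cfg = simulate.SimConfig()
        p1 = simulate._draw_protein(rng, np.full(20, 0.05), cfg)
        p2 = simulate.mutate_protein(rng, p1, 80.0)
        p3 = simulate.mutate_protein(rng, p2, 80.0)
        gfm = genome_prep.cluster_gene_families(
            {"g1": [("p1", p1)], "g2": [("p2", p2)], "g3": [("p3", p3)]}
        )
        assert gfm.counts.shape[0] == 1
        assert gfm.counts.to_numpy().sum() == 3

    def test_counts_conserve_total_proteins(self, rng):
        cfg = simulate.SimConfig()
        proteomes = {
            f"g{i}": [
                (f"g{i}p{j}", simulate._draw_protein(rng, np.full(20, 0.05), cfg))
                for j in range(3)
            ]
            for i in range(3)
        }
        gfm = genome_prep.cluster_gene_families(proteomes)
        assert gfm.counts.to_numpy().sum() == 9
        for g, prots in proteomes.items():
            assert gfm.counts[g].sum() == len(prots)
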