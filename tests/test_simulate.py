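import dataclasses

import numpy as np
import pandas as pd
import pytest

from psychromark import composition, simulate, stability
from psychromark.simulate import ConfigError, SimConfig


class TestGenomeCollection:
    def test_shapes(self):
        cfg = SimConfig(seed=1, n_genomes_per_group=(5, 3, 4),
                        n_families_core=10, n_families_group_specific=4,
                        n_families_accessory=5)
        records, matrix, tree, truth = simulate.simulate_genome_collection(cfg)
        assert len(records) == 12
        assert matrix.counts.shape[1] == 12
        assert len(tree.tip_names) == 12

    def test_deterministic_under_seed(self, small_cfg):
        a = simulate.simulate_genome_collection(small_cfg)
        b = simulate.simulate_genome_collection(small_cfg)
        assert [r.proteome for r in a[0]] == [r.proteome for r in b[0]]
        pd.testing.assert_frame_equal(a[1].counts, b[1].counts)

    def test_markers_satisfy_rule_by_construction(self, small_collection):
        _, matrix, _, truth = small_collection
        presence = matrix.counts >= 1
        groups = truth.genome_groups
        for grp, fams in truth.marker_families.items():
            inside = groups[groups == grp].index
            for fam in fams:
                assert presence.loc[fam, inside].mean() >= 0.95
                for other in set(groups) - {grp}:
                    out = groups[groups == other].index
                    assert presence.loc[fam, out].mean() <= 0.05

    def test_aa_shift_realized_in_proteomes(self, small_collection):
        records, _, _, truth = small_collection
        comps = composition.composition_table(
            {r.genome_id: r.proteome for r in records}
        )
        groups = truth.genome_groups
        mean_c = comps.loc[groups[groups == "C"].index].mean()
        mean_a = comps.loc[groups[groups == "A"].index].mean()
        assert mean_c["N"] > mean_a["N"]
        assert mean_c["A"] < mean_a["A"]

    def test_group_c_has_lower_gc(self, small_collection):
        records, _, _, truth = small_collection
        gc = pd.Series({r.genome_id: r.genome_seq_gc for r in records})
        groups = truth.genome_groups
        assert gc[groups[groups == "C"].index].mean() < gc[groups[groups == "A"].index].mean()

    def test_empty_group_rejected(self):
        with pytest.raises(ConfigError):
            simulate.simulate_genome_collection(SimConfig(n_genomes_per_group=(5, 0, 4)))


class TestMetagenomeCatalogs:
    def test_bookkeeping(self, small_cfg, small_collection, small_markers):
        _, matrix, _, _ = small_collection
        catalogs, meta, truth = simulate.simulate_metagenome_catalogs(
            small_cfg, matrix, small_markers
        )
        assert len(catalogs) == small_cfg.n_metagenomes
        assert len(truth.enriched_samples) == small_cfg.enriched_sample_count
        flagged = [m.sample_id for m in meta if m.cohort == small_cfg.enriched_cohort]
        assert sorted(flagged) == sorted(truth.enriched_samples)

    def test_identity_100_gives_exact_copies(self, small_cfg, small_collection, small_markers):
        _, matrix, _, _ = small_collection
        cfg = dataclasses.replace(small_cfg, mutation_identity=100.0, n_metagenomes=3)
        catalogs, _, truth = simulate.simulate_metagenome_catalogs(cfg, matrix, small_markers)
        rep_seqs = {s for _, s in matrix.representatives.values()}
        for sid, genes in catalogs.items():
            for _, seq in genes:
                assert seq in rep_seqs

    def test_low_identity_rejected(self, small_cfg, small_collection, small_markers):
        _, matrix, _, _ = small_collection
        cfg = dataclasses.replace(small_cfg, mutation_identity=30.0)
        with pytest.raises(ConfigError):
            simulate.simulate_metagenome_catalogs(cfg, matrix, small_markers)

    def test_hit_counts_match_catalog_contents(self, small_cfg, small_collection, small_markers):
        _, matrix, _, _ = small_collection
        catalogs, _, truth = simulate.simulate_metagenome_catalogs(
            small_cfg, matrix, small_markers
        )
        for sid, genes in catalogs.items():
            assert len(genes) == truth.copy_counts.loc[sid, "hits_pan"]
            c_fams = set(small_markers["C"].families)
            n_c = sum(1 for f in truth.source_families[sid] if f in c_fams)
            assert n_c == truth.copy_counts.loc[sid, "hits_C"]

    def test_counts_only_path_matches_catalog_truth(self, small_cfg, small_collection, small_markers):
        _, matrix, _, _ = small_collection
        ht, meta1, t1 = simulate.simulate_hit_counts(small_cfg, matrix, small_markers)
        _, meta2, t2 = simulate.simulate_metagenome_catalogs(small_cfg, matrix, small_markers)
        pd.testing.assert_frame_equal(t1.copy_counts, t2.copy_counts)

    def test_enrichment_multiplies_cohort_mean(self, small_collection, small_markers):
        _, matrix, _, _ = small_collection
        cfg = SimConfig(seed=5, n_metagenomes=40, enriched_sample_count=8,
                        enrichment_factor=4.0)
        ht, meta, truth = simulate.simulate_hit_counts(cfg, matrix, small_markers)
        enr = ht.loc[truth.enriched_samples, "hits_C"].mean()
        bg = ht.drop(index=truth.enriched_samples)["hits_C"].mean()
        assert 2.0 < enr / bg < 8.0  # ~4x up to sampling noise


class TestStabilityParams:
    def test_offset_recovered_from_emitted_params(self):
        cfg = SimConfig(seed=9, stability_offset=0.7)
        curves, groups, truth = simulate.simulate_stability_params(cfg)
        res = stability.group_stability_compare(curves, groups)
        diff = res["group_means"]["C"] - res["group_means"]["A"]
        assert diff == pytest.approx(0.7, abs=0.15)

    def test_zero_offset_null_case(self):
        cfg = SimConfig(seed=9, stability_offset=0.0)
        curves, groups, _ = simulate.simulate_stability_params(cfg)
        res = stability.group_stability_compare(curves, groups)
        diff = res["group_means"]["C"] - res["group_means"]["A"]
        assert abs(diff) < 0.15

    def test_tm_within_configured_range(self):
        cfg = SimConfig(seed=2)
        curves, _, _ = simulate.simulate_stability_params(cfg)
        assert all(cfg.tm_range[0] <= c.tm <= cfg.tm_range[1] for c in curves)

    def test_curves_satisfy_melting_condition(self):
        curves, _, _ = simulate.simulate_stability_params(SimConfig(seed=3))
        assert all(abs(stability.delta_g(c, c.tm)) < 1e-9 for c in curves)


class TestOtuCounts:
    def test_rows_sum_to_depth(self):
        cfg = SimConfig(seed=4)
        counts, _ = simulate.simulate_otu_counts(cfg)
        assert (counts.sum(axis=1) == cfg.otu_depth).all()

    def test_planted_truth_bookkeeping(self):
        cfg = SimConfig(seed=4, planted_corr=0.8)
        _, truth = simulate.simulate_otu_counts(cfg)
        assert ("otu_000", "otu_001", 0.8) in truth.planted
        assert ("otu_002", "otu_003", -0.8) in truth.planted

    def test_zero_planted_corr_gives_identity_truth(self):
        cfg = SimConfig(seed=4, planted_corr=0.0)
        _, truth = simulate.simulate_otu_counts(cfg)
        off = truth.basis_correlation.to_numpy().copy()
        np.fill_diagonal(off, 0.0)
        assert (off == 0).all()

    def test_too_few_otus_rejected(self):
        with pytest.raises(ConfigError):
            simulate.simulate_otu_counts(SimConfig(n_otus=5))
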