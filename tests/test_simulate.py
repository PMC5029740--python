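"""Ground-truth generators: determinism, planted structure, sampling laws."""

import numpy as np
import pandas as pd
import pytest

from trfkit.biomarker import logrank, mann_whitney, relative_expression
from trfkit.reference import build_mature_reference, splice_introns
from trfkit.simulate import (
    QPCRConfig,
    QPCRGroupConfig,
    SimConfig,
    simulate_fragment_truth,
    simulate_libraries,
    simulate_qpcr_cohort,
    simulate_trna_genes,
)


def small_config(**kw):
    defaults = dict(
        seed=5, n_genes=20, duplicate_fraction=0.1, intron_fraction=0.2,
        shared_prefix_pairs=1, n_trfs=40, n_pre_trfs=4, library_depth=20_000,
        n_de_up=3, n_de_down=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSimulateGenes:
    def test_deterministic_for_fixed_seed(self):
        g1 = simulate_trna_genes(small_config(), np.random.default_rng(5))
        g2 = simulate_trna_genes(small_config(), np.random.default_rng(5))
        assert g1 == g2

    def test_duplicate_pairs_collapse_in_mature_reference(self):
        config = small_config(
            n_genes=10, duplicate_fraction=0.2, intron_fraction=0.0, shared_prefix_pairs=0
        )
        genes = simulate_trna_genes(config, np.random.default_rng(1))
        assert len(genes) == 10
        refs = build_mature_reference(genes)
        assert len(refs) == 8  # exactly 2 duplicate pairs collapse
        # direct distinct-sequence count
        assert len({splice_introns(g) for g in genes}) == 8

    def test_no_introns_means_spliced_equals_genomic(self):
        config = small_config(intron_fraction=0.0)
        genes = simulate_trna_genes(config, np.random.default_rng(2))
        assert all(splice_introns(g) == g.genomic_seq for g in genes)

    def test_intron_fraction_carried(self):
        config = small_config(n_genes=20, duplicate_fraction=0.0, intron_fraction=0.5)
        genes = simulate_trna_genes(config, np.random.default_rng(3))
        with_introns = [g for g in genes if g.intron_intervals]
        assert len(with_introns) == 10
        for g in with_introns:
            (start, end) = g.intron_intervals[0]
            assert start == 38 and 10 <= end - start + 1 <= 20


class TestFragmentTruth:
    def test_all_5e_mix_starts_at_one(self):
        config = small_config(
            class_abundance_mix={"5e": 1.0, "D": 0.0, "A": 0.0, "V": 0.0, "3e": 0.0},
            n_trfs=20, n_pre_trfs=0,
        )
        rng = np.random.default_rng(4)
        genes = simulate_trna_genes(config, rng)
        truth = simulate_fragment_truth(genes, config, rng)
        assert all(f.start == 1 for f in truth.fragments)

    def test_class_mass_matches_mix_exactly(self):
        config = small_config(n_pre_trfs=0)
        rng = np.random.default_rng(6)
        genes = simulate_trna_genes(config, rng)
        truth = simulate_fragment_truth(genes, config, rng)
        by_class = {}
        for f in truth.fragments:
            by_class[f.type_class] = by_class.get(f.type_class, 0.0) + f.abundance
        for cls, w in config.class_abundance_mix.items():
            assert by_class.get(cls, 0.0) == pytest.approx(w, abs=1e-12)

    def test_length_mode_is_19(self):
        config = SimConfig(seed=7)
        rng = np.random.default_rng(7)
        genes = simulate_trna_genes(config, rng)
        truth = simulate_fragment_truth(genes, config, rng)
        lengths = pd.Series([f.end - f.start + 1 for f in truth.fragments if f.kind == "mature"])
        assert lengths.mode()[0] == 19

    def test_starts_consistent_with_class_ranges(self):
        from trfkit.simulate import CLASS_START_RANGES

        config = SimConfig(seed=8)
        rng = np.random.default_rng(8)
        genes = simulate_trna_genes(config, rng)
        truth = simulate_fragment_truth(genes, config, rng)
        for f in truth.fragments:
            if f.kind != "mature":
                continue
            lo, hi = CLASS_START_RANGES[f.type_class]
            assert lo <= f.start <= hi
            assert 15 <= f.end - f.start + 1 <= 35

    def test_effects_are_at_least_fourfold(self):
        config = SimConfig(seed=9)
        rng = np.random.default_rng(9)
        genes = simulate_trna_genes(config, rng)
        truth = simulate_fragment_truth(genes, config, rng)
        assert len(truth.effects) == 20
        for _idx, grp, fold in truth.effects:
            assert grp == "PCa"
            assert fold >= 4.0 or fold <= 0.25


class TestSimulateLibraries:
    def _truth(self, config, seed):
        rng = np.random.default_rng(seed)
        genes = simulate_trna_genes(config, rng)
        truth = simulate_fragment_truth(genes, config, rng)
        return truth, rng

    def test_depth_exact_and_reads_are_fragment_sequences(self):
        config = small_config()
        truth, rng = self._truth(config, 10)
        reads, counts = simulate_libraries(truth, config, rng)
        frag_seqs = {f.sequence for f in truth.fragments}
        for lib, lib_reads in reads.items():
            assert len(lib_reads) == config.library_depth
            assert counts[lib].sum() == config.library_depth
            assert all(r.sequence in frag_seqs for r in lib_reads[:100])

    def test_planted_fold_within_3_sigma(self):
        config = small_config(library_depth=50_000)
        truth, rng = self._truth(config, 11)
        _, counts = simulate_libraries(truth, config, np.random.default_rng(12))
        n = config.library_depth
        for idx, grp, fold in truth.effects:
            p_nap = truth.group_probs["NAP"][idx]
            p_case = truth.group_probs[grp][idx]
            # the effect survives renormalization to within a small factor
            assert p_case / p_nap == pytest.approx(fold, rel=0.2)
            x = counts.loc[f"frag{idx:04d}", grp]
            sigma = np.sqrt(n * p_case * (1 - p_case))
            assert abs(x - n * p_case) <= 3.5 * sigma + 1e-9

    def test_same_seed_identical_reads(self):
        config = small_config()
        truth, _ = self._truth(config, 13)
        r1, c1 = simulate_libraries(truth, config, np.random.default_rng(99))
        r2, c2 = simulate_libraries(truth, config, np.random.default_rng(99))
        assert r1 == r2
        pd.testing.assert_frame_equal(c1, c2)


class TestQPCRCohort:
    def test_zero_noise_unit_fold_gives_exact_unity(self):
        config = QPCRConfig(
            sigma=0.0,
            groups=(QPCRGroupConfig("NAP", 5), QPCRGroupConfig("PCa", 5)),
        )
        cohort = simulate_qpcr_cohort(config, np.random.default_rng(1))
        expr = relative_expression(cohort, ["tRF-315", "tRF-544"], "SNORD38B", "NAP")
        assert np.allclose(expr["rel_tRF-315"], 1.0)
        assert np.allclose(expr["rel_tRF-544"], 1.0)

    def test_fourfold_effect_power(self):
        # planted 4-fold, sigma 0.2, n 40/40: Mann-Whitney p < 0.01 in
        # nearly all replicates
        config = QPCRConfig(
            groups=(
                QPCRGroupConfig("NAP", 40),
                QPCRGroupConfig("PCa", 40, {"tRF-315": 4.0}),
            )
        )
        hits = 0
        master = np.random.default_rng(20)
        for _ in range(20):
            cohort = simulate_qpcr_cohort(config, master)
            expr = relative_expression(cohort, ["tRF-315"], "SNORD38B", "NAP")
            a = expr.loc[expr["group"] == "NAP", "rel_tRF-315"].to_numpy()
            b = expr.loc[expr["group"] == "PCa", "rel_tRF-315"].to_numpy()
            _, p = mann_whitney(a, b)
            hits += p < 0.01
        assert hits >= 19

    def test_hazard_ratio_drives_logrank(self):
        # HR 3 between true strata, n 50/50, uniform censoring
        config = QPCRConfig(
            censor_max=120.0,
            groups=(
                QPCRGroupConfig("low", 50, hazard=1 / 60),
                QPCRGroupConfig("high", 50, hazard=3 / 60),
            ),
        )
        master = np.random.default_rng(21)
        hits = 0
        for _ in range(10):
            cohort = simulate_qpcr_cohort(config, master)
            strata = {
                name: list(zip(sub["pfs_time"], sub["event"].astype(int)))
                for name, sub in cohort.groupby("group")
            }
            _, p = logrank(strata)
            hits += p < 0.05
        assert hits >= 9

    def test_follow_up_only_with_hazard(self):
        cohort = simulate_qpcr_cohort(QPCRConfig(), np.random.default_rng(2))
        assert cohort.loc[cohort["group"] == "NAP", "pfs_time"].isna().all()
        assert cohort.loc[cohort["group"] == "PCa_recurrent", "pfs_time"].notna().all()


def test_abundance_mix_rejected_when_not_normalized():
    with pytest.raises(ValueError):
        SimConfig(class_abundance_mix={"5e": 0.9, "D": 0.3})
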