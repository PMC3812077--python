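"""Drift simulator: mutation load, slippage, selection, read generation."""

import numpy as np
import pytest

from indeldrift.reference import GeneReference, find_homonucleotide_runs
from indeldrift.simulate import (
    BypassModel,
    Edit,
    EmptyPoolError,
    SimulationConfig,
    SlippageModel,
    VariantGenome,
    generate_reads,
    mutate_genome,
    mutate_pool,
    orf_runs,
    pool_truth_table,
    sample_mutation_count,
    selection_round,
    simulate_drift,
)


class TestMutationLoad:
    def test_negative_binomial_matches_stated_moments(self):
        """2.2±1.6 substitutions per gene per round, recovered empirically."""
        cfg = SimulationConfig()
        rng = np.random.default_rng(123)
        draws = np.array([sample_mutation_count(cfg, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(2.2, abs=0.02)
        assert draws.std() == pytest.approx(1.6, abs=0.02)

    def test_poisson_fallback_when_underdispersed(self):
        cfg = SimulationConfig(mutation_load_mean=2.2, mutation_load_sd=1.0)
        rng = np.random.default_rng(5)
        with pytest.warns(UserWarning, match="Poisson"):
            draws = np.array([sample_mutation_count(cfg, rng) for _ in range(20_000)])
        assert draws.var() == pytest.approx(draws.mean(), rel=0.05)

    def test_fixed_seed_reproduces_draws(self):
        cfg = SimulationConfig()
        a = [sample_mutation_count(cfg, np.random.default_rng(7)) for _ in range(50)]
        b = [sample_mutation_count(cfg, np.random.default_rng(7)) for _ in range(50)]
        assert a == b


class TestSlippage:
    def test_zero_rate_gives_indel_free_genomes(self, ref):
        model = SlippageModel(rate_length1=0.0)
        cfg = SimulationConfig()
        rng = np.random.default_rng(0)
        g = mutate_genome(VariantGenome(), ref, orf_runs(ref), model, cfg, rng)
        assert all(e.kind == "sub" for e in g.edits.values())

    def test_rate_ratio_follows_fold_law(self):
        model = SlippageModel(rate_length1=1e-4, fold_per_nt=2.5)
        assert model.run_probability(8) / model.run_probability(4) == pytest.approx(2.5**4)

    def test_event_frequencies_match_model_curve(self, ref):
        """Monte-Carlo per-run event rates agree with the analytic per-length
        probability within 3 binomial SE (pool-level mutagenesis)."""
        model = SlippageModel(rate_length1=1e-3, fold_per_nt=2.5)
        cfg = SimulationConfig(mutation_load_mean=0.01, mutation_load_sd=0.2)
        rng = np.random.default_rng(31)
        runs = orf_runs(ref)
        pool = mutate_pool(
            [VariantGenome() for _ in range(20_000)], ref, runs, model, cfg, rng
        )
        by_start = {}
        for g in pool:
            for e in g.edits.values():
                if e.kind != "sub":
                    by_start[e.position] = by_start.get(e.position, 0) + 1
        for L in (3, 4, 6, 8):
            rs = [r for r in runs if r.length == L]
            n_trials = len(rs) * len(pool)
            p = model.run_probability(L)
            observed = sum(by_start.get(r.start, 0) for r in rs)
            se = np.sqrt(n_trials * p * (1 - p))
            assert abs(observed - n_trials * p) <= 3 * se + 1

    def test_deletion_fraction_reflects_event_probabilities(self):
        assert SlippageModel().deletion_fraction == pytest.approx(0.69, abs=0.01)


class TestSelection:
    def test_full_bypass_keeps_pool_unchanged(self):
        pool = [
            VariantGenome({10: Edit(10, "del", 1, run_length=4)}, i) for i in range(200)
        ]
        bypass = BypassModel(bypass_length1=1.0, fold_per_nt=1.0)
        out = selection_round(pool, bypass, np.random.default_rng(0))
        assert out == pool

    def test_motif_masked_indel_never_survives(self):
        pool = [VariantGenome({204: Edit(204, "del", 1, run_length=6)}, 0)] * 50
        bypass = BypassModel(bypass_length1=1.0, fold_per_nt=1.0, motif_mask=frozenset({204}))
        with pytest.raises(EmptyPoolError):
            selection_round(pool, bypass, np.random.default_rng(0))

    def test_survivor_ratio_follows_bypass_fold(self):
        """Cohorts with frame-shifting InDels at L=4 and L=8 survive one
        selection in the closed-form ratio fold**4."""
        bypass = BypassModel(bypass_length1=1e-4, fold_per_nt=3.4)
        p4, p8 = (bypass.survival(Edit(1, "del", 1, run_length=L)) for L in (4, 8))
        assert p8 / p4 == pytest.approx(3.4**4)
        rng = np.random.default_rng(17)
        cohort4 = [VariantGenome({1: Edit(1, "del", 1, run_length=4)}, i) for i in range(60_000)]
        cohort8 = [VariantGenome({1: Edit(1, "del", 1, run_length=8)}, i) for i in range(1_000)]
        s4 = len(selection_round(cohort4, bypass, rng)) / len(cohort4)
        s8 = len(selection_round(cohort8, bypass, rng)) / len(cohort8)
        se = np.sqrt(p4 * (1 - p4) / len(cohort4)) / p4 + np.sqrt(p8 * (1 - p8) / len(cohort8)) / p8
        assert s8 / s4 == pytest.approx(3.4**4, rel=3 * se)

    def test_bypass_probability_nondecreasing_in_run_length(self):
        bypass = BypassModel()
        probs = [bypass.survival(Edit(1, "del", 1, run_length=L)) for L in range(1, 12)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_lethal_substitution_removes_genome(self):
        pool = [VariantGenome({5: Edit(5, "sub", "A", lethal=True)}, 0),
                VariantGenome({5: Edit(5, "sub", "A", lethal=False)}, 1)]
        out = selection_round(pool, BypassModel(), np.random.default_rng(0))
        assert [g.lineage_id for g in out] == [1]


class TestReads:
    def test_error_free_wildtype_reads_are_reference_substrings(self, ref):
        cfg = SimulationConfig(seq_error_sub=0, seq_error_indel=0, mean_depth=20)
        reads, truth = generate_reads(
            [VariantGenome()], ref, cfg, np.random.default_rng(3)
        )
        assert truth.empty
        assert all(seq in ref.sequence for _, seq, _ in reads)
        assert all(len(seq) == cfg.read_length for _, seq, _ in reads)

    def test_truth_table_equals_exact_pool_fractions(self):
        pool = [VariantGenome({7: Edit(7, "del", 1, run_length=3)}, i) for i in range(3)]
        pool += [VariantGenome() for _ in range(7)]
        truth = pool_truth_table(pool, "G0")
        assert len(truth) == 1
        assert truth.iloc[0]["true_frequency"] == pytest.approx(0.3)

    def test_edge_artifacts_confined_to_read_ends(self, ref):
        """With artifacts injected at full quality and no other error source,
        every indel observation sits within 3 nt of a read end."""
        from indeldrift.caller import call_reads

        cfg = SimulationConfig(
            seq_error_sub=0, seq_error_indel=0, edge_artifact_rate=1.0,
            edge_artifact_quality=30, mean_depth=60,
        )
        reads, _ = generate_reads([VariantGenome()], ref, cfg, np.random.default_rng(9))
        result = call_reads(reads, ref, repertoire="G0")
        offsets = [off for offs in result.counts.offsets.values() for off in offs]
        assert offsets, "artifact injection produced no observations"
        # an end insertion can tie with an interior deletion one base in
        # (lowest-ref-start tie-break), shifting rare calls by one position
        assert all(off <= 3 for off in offsets)
        assert np.mean([off < 3 for off in offsets]) >= 0.99

    def test_read_length_exceeding_genome_rejected(self):
        ref = GeneReference("ACGTACGTAC", (1, 10))
        cfg = SimulationConfig(read_length=40)
        with pytest.raises(ValueError, match="read_length"):
            generate_reads([VariantGenome()], ref, cfg, np.random.default_rng(0))


class TestDrift:
    def test_zero_rounds_selected_pool_is_naive_pool(self):
        cfg = SimulationConfig(pool_size=100, rounds=0, mean_depth=5, seed=2)
        res = simulate_drift(cfg)
        assert res.g17_pool is res.g0_pool
        assert res.g0_truth.drop(columns="repertoire").equals(
            res.g17_truth.drop(columns="repertoire")
        )

    def test_fixed_seed_reproduces_reads_exactly(self):
        cfg = SimulationConfig(pool_size=100, rounds=1, mean_depth=5, seed=4)
        a, b = simulate_drift(cfg), simulate_drift(cfg)
        assert [(i, s, q.tolist()) for i, s, q in a.g0_reads] == [
            (i, s, q.tolist()) for i, s, q in b.g0_reads
        ]
        assert [(i, s, q.tolist()) for i, s, q in a.g17_reads] == [
            (i, s, q.tolist()) for i, s, q in b.g17_reads
        ]

    def test_truth_frequencies_are_valid(self, small_drift):
        for truth in (small_drift.g0_truth, small_drift.g17_truth):
            assert ((truth["true_frequency"] > 0) & (truth["true_frequency"] <= 1)).all()

    def test_selection_steepens_length_dependence(self, small_drift):
        """After selection the per-length frequency slope on truth tables is
        at least as steep as before (bypass fold > 1)."""
        from indeldrift.analysis import fit_loglinear

        runs = [r for r in orf_runs(small_drift.ref) if r.length >= 3]

        def fold(truth):
            t = truth[truth["type"].isin(["ins", "del"])]
            by_start = t.groupby("position")["true_frequency"].sum()
            means = {
                L: np.mean([by_start.get(r.start, 0.0) for r in runs if r.length == L])
                for L in {3, 4, 5, 6, 8}
            }
            return fit_loglinear(means).fold_per_nt

        assert fold(small_drift.g17_truth) > fold(small_drift.g0_truth)
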