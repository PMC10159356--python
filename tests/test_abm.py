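"""Agent-based simulator: strategy space, infection sampling, within-cell
rules, mutation, full runs and outcome classification."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cheatsplit import abm
from cheatsplit.abm import (
    CellContents,
    OutcomeClass,
    SimConfig,
    SimResult,
    allocate_progeny,
    apply_mutation,
    cell_productivity,
    classify_outcome,
    competitive_weight,
    enumerate_strategies,
    generation,
    package_and_infect,
    run,
    run_replicates,
    sample_cell_contents,
    strategy_bits,
    sweep,
)

G2 = SimConfig(n_genes=2)


def idx(bits: str) -> int:
    return int(bits, 2)


class TestStrategySpace:
    @pytest.mark.parametrize("g,expected", [(1, 2), (2, 4), (3, 8), (8, 256)])
    def test_counts(self, g, expected):
        assert len(enumerate_strategies(g)) == expected

    def test_order_and_named_strategies(self):
        bits = [s.bits for s in enumerate_strategies(2)]
        assert bits == ["00", "01", "10", "11"]
        assert enumerate_strategies(2)[-1].gene_count == 2  # cooperator
        assert enumerate_strategies(2)[0].gene_count == 0  # full cheat

    def test_out_of_range(self):
        for g in (0, 9):
            with pytest.raises(ValueError):
                enumerate_strategies(g)

    def test_bit_matrix_matches_enumeration(self):
        bits = strategy_bits(3)
        for i, s in enumerate(enumerate_strategies(3)):
            assert tuple(int(b) for b in bits[i]) == s.gene_presence


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genes=9),
            dict(moi=-1),
            dict(mut_rate=1.0),
            dict(e=-0.5),
            dict(prop_single=0.5, n_genes=3),
            dict(prop_single=1.5),
            dict(coinfection="pairwise"),  # missing beta
            dict(initial_freqs=(0.5, 0.5, 0.5, 0.5)),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**{"n_genes": 2, **kwargs})


class TestInfection:
    def test_zero_moi_all_cells_empty(self, rng):
        contents = sample_cell_contents(np.array([0.5, 0.5]), 100, 0.0, rng)
        assert contents.cells.size == 0

    def test_concentrated_frequencies(self, rng):
        freqs = np.zeros(4)
        freqs[idx("10")] = 1.0
        contents = sample_cell_contents(freqs, 500, 3.0, rng)
        assert np.all(contents.strategies == idx("10"))

    def test_mean_genomes_matches_moi(self, rng):
        lam, n_cells = 2.5, 20_000
        contents = sample_cell_contents(np.full(4, 0.25), n_cells, lam, rng)
        se = np.sqrt(lam / n_cells)
        assert contents.cells.size / n_cells == pytest.approx(lam, abs=3 * se)

    def test_counts_table_shape_and_total(self, rng):
        contents = sample_cell_contents(np.full(4, 0.25), 50, 2.0, rng)
        table = contents.counts()
        assert table.shape == (50, 4)
        assert table.sum() == contents.cells.size


class TestCellRules:
    def test_incomplete_cell_unproductive(self):
        assert cell_productivity([idx("10")], G2) == 0.0
        assert cell_productivity([idx("10"), idx("10")], G2) == 0.0
        assert cell_productivity([idx("00")], G2) == 0.0

    def test_single_cooperator_baseline(self):
        assert cell_productivity([idx("11")], G2) == 1.0

    def test_complementation_and_group_benefit(self):
        cell = [idx("10"), idx("01")]
        assert cell_productivity(cell, G2) == 1.0
        assert cell_productivity(cell, dataclasses.replace(G2, e=2.0)) == 2.0

    def test_multiple_sets_and_gamma(self):
        cell = [idx("11"), idx("11"), idx("11")]
        assert cell_productivity(cell, G2) == 3.0
        assert cell_productivity(cell, dataclasses.replace(G2, gamma=2.0)) == 9.0

    def test_group_benefit_not_applied_with_cooperator_present(self):
        cell = [idx("11"), idx("10"), idx("01")]
        cfg = dataclasses.replace(G2, e=2.0)
        assert cell_productivity(cell, cfg) == cell_productivity(cell, G2)

    def test_competitive_weights(self):
        y9 = dataclasses.replace(G2, y=9.0)
        assert competitive_weight(2, G2) == 1.0  # cooperator, any y/alpha
        assert competitive_weight(0, y9) == 10.0  # full cheat at y = 9
        assert competitive_weight(0, G2) == 1.0 + G2.y
        half_dec = competitive_weight(1, dataclasses.replace(G2, alpha=0.5))
        half_acc = competitive_weight(1, dataclasses.replace(G2, alpha=2.0))
        assert half_dec > half_acc  # decelerating advantage is front-loaded

    def test_allocation_examples(self):
        y9 = dataclasses.replace(G2, y=9.0)
        only = allocate_progeny([idx("11"), idx("11")], y9)
        assert only[idx("11")] == pytest.approx(2.0)
        mixed = allocate_progeny([idx("11"), idx("00")], y9)
        assert mixed[idx("00")] == pytest.approx(10 / 11)
        assert mixed[idx("11")] == pytest.approx(1 / 11)

    def test_allocation_conserves_productivity(self, rng):
        for _ in range(200):
            cell = rng.integers(0, 4, size=rng.integers(1, 7))
            total = allocate_progeny(cell, G2).sum()
            assert total == pytest.approx(cell_productivity(cell, G2), abs=1e-12)


class TestMutation:
    def test_identity_without_mutation(self):
        f = np.array([0.7, 0.1, 0.1, 0.1])
        assert np.array_equal(apply_mutation(f, 0.0), f)

    def test_uniform_fixed_point(self):
        f = np.full(8, 1 / 8)
        assert np.allclose(apply_mutation(f, 0.3), f)

    def test_single_gene_redistribution(self):
        out = apply_mutation(np.array([1.0, 0.0]), 0.1)
        assert np.allclose(out, [0.9, 0.1])

    @given(st.floats(0.0, 0.5), st.integers(1, 4))
    def test_mass_conserved(self, mu, g):
        rng = np.random.default_rng(7)
        f = rng.dirichlet(np.ones(2**g))
        out = apply_mutation(f, mu)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(out >= 0)


class TestGeneration:
    def test_pure_cooperator_stays_dominant(self, rng):
        cfg = dataclasses.replace(G2, moi=5.0, n_cells=4000)
        f = np.array([0.0, 0.0, 0.0, 1.0])
        out, dead = generation(f, cfg, rng)
        assert not dead
        # only mutation outflow; progeny pool is pure cooperator
        assert out[idx("11")] == pytest.approx(1 - cfg.mut_rate, abs=1e-9)

    def test_pure_full_cheat_population_dies(self, rng):
        f = np.array([1.0, 0.0, 0.0, 0.0])
        out, dead = generation(f, G2, rng)
        assert dead

    def test_frequency_conservation(self, rng):
        f = np.full(4, 0.25)
        for _ in range(20):
            f, dead = generation(f, G2, rng)
            assert not dead
            assert f.sum() == pytest.approx(1.0, abs=1e-9)


class TestRun:
    def test_same_seed_bit_identical(self):
        cfg = dataclasses.replace(G2, moi=3.0, n_generations=200, seed=42)
        r1, r2 = run(cfg), run(cfg)
        assert np.array_equal(r1.trajectory, r2.trajectory)
        assert np.array_equal(r1.final_freqs, r2.final_freqs)

    def test_single_gene_cooperator_never_extinct(self):
        """With one gene there is nothing to complement: the cooperator
        persists in every replicate."""
        cfg = SimConfig(n_genes=1, moi=5.0, n_cells=2000, n_generations=600)
        df = run_replicates(cfg, 10, master_seed=3)
        assert not df.cooperator_extinct.any()

    def test_trajectory_on_simplex(self):
        cfg = dataclasses.replace(G2, moi=4.0, n_generations=300, seed=5)
        res = run(cfg)
        assert np.allclose(res.trajectory.sum(axis=1), 1.0, atol=1e-9)


class TestOutcome:
    def _result(self, freqs, cfg, extinct=False):
        f = np.asarray(freqs, dtype=float)
        return SimResult(cfg, np.array([0]), f[None, :], f, extinct)

    def test_two_segment_classification(self):
        cfg = dataclasses.replace(G2, mut_rate=1e-4)
        out = classify_outcome(
            self._result([2e-4, 0.4997, 0.5, 3e-4], cfg), cfg
        )
        assert out.cooperator_extinct
        assert out.n_segments == 2
        assert out.evenness == 1.0
        assert out.label == "multipartite"

    def test_cooperator_persisting_is_monopartite(self):
        cfg = dataclasses.replace(G2, mut_rate=1e-4)
        out = classify_outcome(self._result([0.0, 0.05, 0.05, 0.9], cfg), cfg)
        assert not out.cooperator_extinct
        assert out.n_segments == 1

    def test_uneven_split_evenness(self):
        cfg = SimConfig(n_genes=8, mut_rate=1e-4)
        freqs = np.zeros(256)
        freqs[int("11111110", 2)] = 0.5
        freqs[int("00000001", 2)] = 0.5
        out = classify_outcome(self._result(freqs, cfg), cfg)
        assert out.n_segments == 2
        assert out.evenness == pytest.approx(1 / 7)

    def test_uncovered_persisting_set_unclassifiable(self):
        cfg = dataclasses.replace(G2, mut_rate=1e-4)
        out = classify_outcome(self._result([2e-4, 2e-4, 0.9994, 1e-4], cfg), cfg)
        assert out.cooperator_extinct
        assert out.label == "unclassifiable"
        assert out.n_segments is None

    def test_full_cheat_load_reported(self):
        cfg = dataclasses.replace(G2, mut_rate=1e-4)
        out = classify_outcome(
            self._result([0.02, 0.49, 0.49, 1e-5], cfg), cfg
        )
        assert out.full_cheat_load == pytest.approx(0.02)


class TestPackaging:
    def test_prop_single_one_matches_baseline_distribution(self, rng):
        """With every virion holding one genome the per-cell content
        distribution reduces to the baseline sampler (matched moments)."""
        freqs = np.array([0.1, 0.3, 0.4, 0.2])
        cfg = dataclasses.replace(G2, prop_single=1.0, moi=2.0)
        packaged = package_and_infect(freqs, 20_000, 2.0, cfg, rng)
        baseline = sample_cell_contents(freqs, 20_000, 2.0, rng)
        mean_p = packaged.cells.size / 20_000
        mean_b = baseline.cells.size / 20_000
        assert mean_p == pytest.approx(mean_b, abs=3 * np.sqrt(2.0 / 20_000) * 2)
        comp_p = np.bincount(packaged.strategies, minlength=4) / packaged.cells.size
        assert np.allclose(comp_p, freqs, atol=0.02)

    def test_prop_single_zero_doubles_genome_count(self, rng):
        freqs = np.array([0.0, 0.5, 0.5, 0.0])
        cfg = dataclasses.replace(G2, prop_single=0.0, moi=1.5)
        contents = package_and_infect(freqs, 20_000, 1.5, cfg, rng)
        mean = contents.cells.size / 20_000
        assert mean == pytest.approx(3.0, abs=4 * np.sqrt(1.5 / 20_000) * 2)
        # every cell has an even number of genomes
        per_cell = np.bincount(contents.cells, minlength=20_000)
        assert np.all(per_cell % 2 == 0)

    def test_cooperator_only_pool_falls_back_to_single(self, rng, caplog):
        freqs = np.array([0.0, 0.0, 0.0, 1.0])
        cfg = dataclasses.replace(G2, prop_single=0.0)
        with caplog.at_level("INFO", logger="cheatsplit.abm"):
            contents = package_and_infect(freqs, 200, 2.0, cfg, rng)
        assert np.all(contents.strategies == 3)
        assert any("fell back" in r.message for r in caplog.records)

    def test_copackaging_excludes_cooperator_from_shared_capsids(self, rng):
        # the full-length genome cannot share a capsid: with prop_single = 0
        # no cooperator genome is ever delivered
        freqs = np.array([0.2, 0.3, 0.3, 0.2])
        cfg = dataclasses.replace(G2, prop_single=0.0, moi=2.0)
        contents = package_and_infect(freqs, 5000, 2.0, cfg, rng)
        assert np.all(contents.strategies != idx("11"))

    def test_copackaging_respects_length_classes(self, rng):
        # with mass only on 00 (length 0) and 10 (length 1), same-length
        # copackaging forces both genomes of a virion to be identical, so
        # per-cell per-strategy counts are all even
        freqs = np.array([0.5, 0.0, 0.5, 0.0])
        cfg = dataclasses.replace(G2, prop_single=0.0, moi=2.0)
        contents = package_and_infect(freqs, 5000, 2.0, cfg, rng)
        table = contents.counts()
        assert np.all(table % 2 == 0)


class TestPairwiseReduction:
    """Cross-module consistency: in the pairwise coinfection mode (cells
    hold exactly 1 or 2 genomes, as in the analytic game) the simulator's
    long-run outcome matches the closed-form classification built from its
    own effective payoffs."""

    def _sim_config(self, beta, e, start):
        kwargs = dict(
            n_genes=2, coinfection="pairwise", beta=beta, e=e,
            n_cells=2000, n_generations=600, moi=0.0,
        )
        if start == "multipartite":
            kwargs["initial_freqs"] = (0.0, 0.5, 0.5, 0.0)
        return SimConfig(**kwargs)

    def test_effective_payoffs_validity(self):
        from cheatsplit.game import PayoffParameters

        params = abm.pairwise_effective_payoffs(SimConfig(n_genes=2, e=1.0))
        assert isinstance(params, PayoffParameters)
        assert params.b < params.d  # pairwise cells cannot reward cheats

    def test_cheats_never_invade_from_rare(self):
        """b < d under pairwise infection: from the ancestral cooperator
        start, cheats stay at mutation-selection balance at every beta."""
        from cheatsplit.game import invasion_threshold

        for beta, e in ((0.5, 1.0), (0.9, 1.0), (0.9, 6.0)):
            cfg = self._sim_config(beta, e, "cooperator")
            assert invasion_threshold(abm.pairwise_effective_payoffs(cfg)) is None
            df = run_replicates(cfg, 5, master_seed=21)
            assert not df.cooperator_extinct.any(), (beta, e)

    @pytest.mark.parametrize(
        "beta,e,stays_multipartite",
        [
            (0.9, 1.0, True),   # e/2 well above e*(beta = 0.9)
            (0.9, 0.1, False),  # e/2 below e*: cooperators re-invade
            (0.5, 6.0, True),
            (0.5, 1.0, False),
        ],
    )
    def test_multipartite_state_stability_matches_e_star(
        self, beta, e, stays_multipartite
    ):
        """Started at the two-cheat boundary state, the population stays
        multipartite exactly when the mapped complementation payoff clears
        the analytic extinction threshold e*."""
        from cheatsplit.game import CoinfectionParameters, e_star

        cfg = self._sim_config(beta, e, "multipartite")
        params = abm.pairwise_effective_payoffs(cfg)
        predicted = params.e > e_star(params, CoinfectionParameters(beta=beta))
        assert predicted == stays_multipartite  # grid placed off-boundary
        df = run_replicates(cfg, 10, master_seed=31)
        agreement = (df.cooperator_extinct == stays_multipartite).mean()
        assert agreement >= 0.9


class TestSweep:
    def test_fractions_sum_to_one(self):
        cfg = dataclasses.replace(G2, moi=3.0, n_cells=300, n_generations=200)
        table = sweep([cfg, dataclasses.replace(cfg, moi=1.0)], 10, master_seed=1)
        sums = table.groupby("config_index")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_reproducible_from_master_seed(self):
        cfg = dataclasses.replace(G2, moi=3.0, n_cells=300, n_generations=150)
        t1 = sweep([cfg], 5, master_seed=9)
        t2 = sweep([cfg], 5, master_seed=9)
        pd.testing.assert_frame_equal(t1, t2)
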