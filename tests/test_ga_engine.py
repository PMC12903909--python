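"""Evolutionary loop: determinism, budget, elitism, and optimum recovery."""

import numpy as np
import pytest

from flpga import (
    GAConfig,
    SyntheticBackend,
    assemble,
    chimera_scalarize,
    evolve_step,
    express,
    initialize,
    run,
    scores,
)
from flpga.ga_engine import _Evaluator
from flpga.synthetic_backend import enumerate_space, synth_descriptors


@pytest.fixture(scope="module")
def backend(planted):
    return SyntheticBackend(planted.table)


@pytest.fixture(scope="module")
def enumerated_best_cs(planted):
    """Brute-force enumeration oracle: the global best chemistry score."""
    best = -1.0
    for genes in enumerate_space(planted.library):
        cand = assemble(express(genes, planted.library), planted.library)
        fv = scores(synth_descriptors(cand, planted.table))
        best = max(best, fv.cs)
    return best


class TestInitialize:
    def test_seeded_initialization_is_reproducible(self, minilib):
        cfg = GAConfig(seed=1)
        a = initialize(minilib, cfg)
        b = initialize(minilib, cfg)
        assert [c.genes for c in a] == [c.genes for c in b]

    def test_population_size_honored(self, minilib):
        assert len(initialize(minilib, GAConfig(population_size=20, seed=0))) == 20

    def test_single_backbone_pool_is_forced(self, planted):
        pop = initialize(planted.library, GAConfig(seed=3))
        backbones = {c.genes[4] for c in pop}
        assert backbones <= {"k_ophen", "k_gem"}


class TestEvolveStep:
    def _evaluated(self, lib, backend, pop, cfg):
        ev = _Evaluator(lib, backend, cfg)
        records = [ev.evaluate(c) for c in pop]
        merits = chimera_scalarize(
            np.array([r.objective_row for r in records]), cfg.objectives)
        for r, m in zip(records, merits):
            r.merit = float(m)
        return records

    def test_frozen_evolution_with_full_elitism(self, planted, backend):
        cfg = GAConfig(population_size=6, mutation_rate=0.0, elitism_count=6, seed=4)
        pop = initialize(planted.library, cfg)
        records = self._evaluated(planted.library, backend, pop, cfg)
        nxt = evolve_step(pop, records, planted.library, cfg,
                          np.random.default_rng(0))
        ranked = sorted(records, key=lambda r: r.merit)
        assert [c.genes for c in nxt] == [r.chromosome.genes for r in ranked]

    def test_population_size_preserved(self, planted, backend):
        cfg = GAConfig(population_size=10, seed=5)
        pop = initialize(planted.library, cfg)
        records = self._evaluated(planted.library, backend, pop, cfg)
        nxt = evolve_step(pop, records, planted.library, cfg,
                          np.random.default_rng(1))
        assert len(nxt) == 10

    def test_elitism_monotonicity_of_best_merit(self, planted, backend):
        # with elites carried over and a batch-independent (tolerance-0,
        # i.e. lexicographic) scalarization, the best never worsens
        from flpga import ObjectiveSpec
        lexi = (ObjectiveSpec("CS", "maximize", 0.0),
                ObjectiveSpec("GS", "maximize", 0.0),
                ObjectiveSpec("SCS", "minimize", 0.0))
        for seed in range(5):
            cfg = GAConfig(population_size=12, generations=10, seed=seed,
                           patience=None, objectives=lexi)
            res = run(planted.library, cfg, backend)
            bests = [log.best_merit_objectives for log in res.logs]
            for (cs0, gs0, scs0), (cs1, gs1, scs1) in zip(bests, bests[1:]):
                key0 = (-cs0, -gs0, scs0)
                key1 = (-cs1, -gs1, scs1)
                assert key1 <= key0


class TestRun:
    def test_generation_budget(self, planted, backend):
        cfg = GAConfig(population_size=8, generations=5, seed=2, patience=None)
        res = run(planted.library, cfg, backend)
        assert len(res.logs) == 5
        assert res.n_evaluations <= 8 * 5

    def test_single_generation(self, planted, backend):
        cfg = GAConfig(population_size=8, generations=1, seed=2)
        assert len(run(planted.library, cfg, backend).logs) == 1

    def test_cache_deduplicates_candidates(self, planted, backend):
        cfg = GAConfig(population_size=10, generations=10, seed=2, patience=None)
        res = run(planted.library, cfg, backend)
        assert res.n_cache_hits > 0
        assert res.n_evaluations + res.n_cache_hits == 10 * 10

    def test_run_is_fully_reproducible(self, planted, backend):
        cfg = GAConfig(population_size=10, generations=8, seed=9, patience=None)
        a = run(planted.library, cfg, backend)
        b = run(planted.library, cfg, backend)
        assert [c.genes for c in a.final_population] == \
            [c.genes for c in b.final_population]
        assert a.best.chromosome.genes == b.best.chromosome.genes
        for la, lb in zip(a.logs, b.logs):
            assert la.mean_fepa == lb.mean_fepa
            assert la.best_merit_objectives == lb.best_merit_objectives

    def test_population_means_recomputable_from_records(self, planted, backend):
        cfg = GAConfig(population_size=10, generations=3, seed=6, patience=None)
        res = run(planted.library, cfg, backend)
        log = res.logs[-1]
        fepas = [r.descriptors.fepa for r in log.records if r.descriptors]
        assert log.mean_fepa == pytest.approx(np.mean(fepas))

    def test_pareto_archive_is_nondominated(self, planted, backend):
        cfg = GAConfig(population_size=10, generations=10, seed=2, patience=None)
        res = run(planted.library, cfg, backend)
        rows = np.array([[r.fitness.cs, r.fitness.gs, -r.fitness.scs]
                         for r in res.pareto_archive])
        for i in range(len(rows)):
            for j in range(len(rows)):
                if i != j:
                    assert not (np.all(rows[j] >= rows[i])
                                and np.any(rows[j] > rows[i]))

    def test_single_seed_finds_planted_optimum(self, planted, backend,
                                               enumerated_best_cs):
        cfg = GAConfig(population_size=20, generations=30, seed=1, patience=None)
        res = run(planted.library, cfg, backend)
        assert res.best.fitness.cs == pytest.approx(enumerated_best_cs)

    def test_logs_written_to_disk(self, planted, backend, tmp_path):
        cfg = GAConfig(population_size=6, generations=3, seed=1, patience=None)
        run(planted.library, cfg, backend, out_dir=tmp_path)
        assert (tmp_path / "generations.csv").exists()
        assert (tmp_path / "pareto_archive.csv").exists()
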