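"""The evolutionary loop over the IFLP chromosome space.

Populations of eight-gene chromosomes are evaluated by a descriptor
backend, scored (CS, GS, SCS), scalarized hierarchically, and evolved by
elitism, merit-ranked tournament selection, uniform per-gene crossover
and per-gene mutation. Descriptor evaluation is the cost center, so
results are cached by canonical Int2 SMILES.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
import pandas as pd

from .assembler import AssembledCandidate, AssemblyError, Chromosome, assemble, express
from .fitness import DescriptorSet, FitnessConfig, FitnessVector, scores
from .fragment_library import FragmentLibrary, LibraryError
from .scalarizer import DEFAULT_OBJECTIVES, ObjectiveSpec, chimera_scalarize, pareto_front

_SLOT_ROLES = (
    "acid_substituent", "acid_substituent",
    "base_substituent", "base_substituent",
    "backbone",
    "backbone_substituent", "backbone_substituent", "backbone_substituent",
)


class DescriptorBackend(Protocol):
    """Maps an assembled candidate to its descriptor set."""

    def descriptors(self, candidate: AssembledCandidate) -> DescriptorSet:
        ...


class GAError(RuntimeError):
    pass


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 20
    mutation_rate: float = 0.1      # per-gene probability
    generations: int = 50
    seed: int = 0
    elitism_count: int = 2
    tournament_size: int = 3
    patience: int | None = 15       # generations without improvement; None = off
    objectives: tuple[ObjectiveSpec, ...] = DEFAULT_OBJECTIVES
    fitness: FitnessConfig = field(default_factory=FitnessConfig)
    cache: bool = True
    max_retries: int = 5            # offspring re-assembly attempts

    def __post_init__(self):
        if self.population_size < 2:
            raise GAError("population_size must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise GAError("mutation_rate must lie in [0, 1]")
        if self.generations < 1:
            raise GAError("generations must be >= 1")


@dataclass
class CandidateRecord:
    chromosome: Chromosome
    candidate: AssembledCandidate | None
    descriptors: DescriptorSet | None
    fitness: FitnessVector | None
    merit: float = math.nan

    @property
    def objective_row(self) -> tuple[float, float, float]:
        if self.fitness is None:
            return (math.nan, math.nan, math.nan)
        return (self.fitness.cs, self.fitness.gs, self.fitness.scs)


@dataclass
class GenerationLog:
    generation: int
    records: list[CandidateRecord]
    mean_fepa: float
    mean_feha: float
    mean_d: float
    mean_phi: float
    mean_scs: float
    best_merit_objectives: tuple[float, float, float]
    n_evaluations: int  # cumulative backend calls
    n_cache_hits: int


@dataclass
class RunResult:
    logs: list[GenerationLog]
    final_population: list[Chromosome]
    pareto_archive: list[CandidateRecord]
    n_evaluations: int
    n_cache_hits: int
    best: CandidateRecord


def _sample_genes(lib: FragmentLibrary, rng: np.random.Generator) -> tuple[str, ...]:
    genes = []
    for role in _SLOT_ROLES:
        pool = lib.pools[role]
        genes.append(pool[rng.integers(len(pool))].fragment_id)
    return tuple(genes)


def initialize(lib: FragmentLibrary, config: GAConfig,
               rng: np.random.Generator | None = None) -> list[Chromosome]:
    """Seeded uniform sampling of an assemblable starting population."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    population: list[Chromosome] = []
    budget = 50 * config.population_size
    while len(population) < config.population_size and budget > 0:
        budget -= 1
        try:
            chrom = express(_sample_genes(lib, rng), lib)
            assemble(chrom, lib)
        except (AssemblyError, LibraryError):
            continue
        population.append(chrom)
    if len(population) < config.population_size:
        raise GAError(
            f"could not build a valid population of {config.population_size} "
            f"within the retry budget; library may be too failure-prone")
    return population


class _Evaluator:
    """Caches descriptor evaluations by canonical Int2 SMILES."""

    def __init__(self, lib: FragmentLibrary, backend: DescriptorBackend,
                 config: GAConfig):
        self.lib, self.backend, self.config = lib, backend, config
        self.cache: dict[str, tuple[DescriptorSet, FitnessVector]] = {}
        self.n_evaluations = 0
        self.n_cache_hits = 0

    def evaluate(self, chrom: Chromosome) -> CandidateRecord:
        try:
            cand = assemble(chrom, self.lib)
        except AssemblyError:
            return CandidateRecord(chrom, None, None, None)
        key = cand.smiles_int2
        if self.config.cache and key in self.cache:
            self.n_cache_hits += 1
            ds, fv = self.cache[key]
            return CandidateRecord(chrom, cand, ds, fv)
        try:
            ds = self.backend.descriptors(cand)
        except Exception:
            self.n_evaluations += 1
            return CandidateRecord(chrom, cand, None, None)
        self.n_evaluations += 1
        fv = scores(ds, self.config.fitness)
        if self.config.cache:
            self.cache[key] = (ds, fv)
        return CandidateRecord(chrom, cand, ds, fv)


def _tournament(rng: np.random.Generator, ranked: list[CandidateRecord],
                size: int) -> CandidateRecord:
    picks = rng.integers(len(ranked), size=size)
    return ranked[min(picks)]  # ranked list: smaller index = better merit


def _mutate_gene(slot: int, gene: str, lib: FragmentLibrary,
                 rng: np.random.Generator) -> str:
    pool = lib.pools[_SLOT_ROLES[slot]]
    return pool[rng.integers(len(pool))].fragment_id


def evolve_step(population: Sequence[Chromosome],
                records: Sequence[CandidateRecord],
                lib: FragmentLibrary, config: GAConfig,
                rng: np.random.Generator) -> list[Chromosome]:
    """One generation: elites survive; tournament parents recombine
    (uniform per-gene crossover) and mutate; invalid offspring are
    resampled a few times, then fall back to the first parent."""
    order = np.argsort([r.merit for r in records], kind="stable")
    ranked = [records[i] for i in order]
    nxt: list[Chromosome] = [ranked[i].chromosome
                             for i in range(min(config.elitism_count, len(ranked)))]
    while len(nxt) < config.population_size:
        p1 = _tournament(rng, ranked, config.tournament_size)
        p2 = _tournament(rng, ranked, config.tournament_size)
        child: Chromosome | None = None
        for _ in range(config.max_retries):
            genes = []
            for slot in range(8):
                g = (p1 if rng.random() < 0.5 else p2).chromosome.genes[slot]
                if rng.random() < config.mutation_rate:
                    g = _mutate_gene(slot, g, lib, rng)
                genes.append(g)
            try:
                cand = express(tuple(genes), lib)
                assemble(cand, lib)
                child = cand
                break
            except (AssemblyError, LibraryError):
                continue
        nxt.append(child if child is not None else p1.chromosome)
    return nxt


def _population_means(records: Sequence[CandidateRecord]) -> tuple[float, ...]:
    vals = [(r.descriptors.fepa, r.descriptors.feha, r.descriptors.d,
             r.descriptors.phi, r.descriptors.scs)
            for r in records if r.descriptors is not None]
    if not vals:
        return (math.nan,) * 5
    arr = np.array(vals)
    return tuple(arr.mean(axis=0))


def run(lib: FragmentLibrary, config: GAConfig, backend: DescriptorBackend,
        out_dir: str | Path | None = None) -> RunResult:
    """Full evolutionary run: at most population_size x generations backend
    evaluations (cache hits excluded), per-generation logs, optional early
    stop after ``config.patience`` generations without best-merit
    improvement, and a Pareto archive over everything evaluated.
    """
    rng = np.random.default_rng(config.seed)
    evaluator = _Evaluator(lib, backend, config)
    population = initialize(lib, config, rng)
    logs: list[GenerationLog] = []
    archive: dict[str, CandidateRecord] = {}
    best: CandidateRecord | None = None
    stall = 0
    for gen in range(config.generations):
        records = [evaluator.evaluate(ch) for ch in population]
        merits = chimera_scalarize(
            np.array([r.objective_row for r in records]), config.objectives)
        for r, m in zip(records, merits):
            r.merit = float(m)
        gen_best = records[int(np.argmin(merits))]
        for r in records:
            if r.candidate is not None and r.fitness is not None:
                archive.setdefault(r.candidate.smiles_int2, r)
        means = _population_means(records)
        logs.append(GenerationLog(
            generation=gen, records=records,
            mean_fepa=means[0], mean_feha=means[1], mean_d=means[2],
            mean_phi=means[3], mean_scs=means[4],
            best_merit_objectives=gen_best.objective_row,
            n_evaluations=evaluator.n_evaluations,
            n_cache_hits=evaluator.n_cache_hits))
        improved = best is None or _better(gen_best, best, config)
        if improved:
            best = gen_best
            stall = 0
        else:
            stall += 1
        if config.patience is not None and stall >= config.patience:
            break
        if gen < config.generations - 1:
            population = evolve_step(population, records, lib, config, rng)
    arch_records = list(archive.values())
    if arch_records:
        rows = np.array([r.objective_row for r in arch_records])
        front = pareto_front(rows, directions=[s.direction for s in config.objectives])
        pareto = [arch_records[i] for i in front]
    else:
        pareto = []
    result = RunResult(logs=logs, final_population=population,
                       pareto_archive=pareto,
                       n_evaluations=evaluator.n_evaluations,
                       n_cache_hits=evaluator.n_cache_hits,
                       best=best)  # type: ignore[arg-type]
    if out_dir is not None:
        _write_logs(result, Path(out_dir))
    return result


def _better(a: CandidateRecord, b: CandidateRecord, config: GAConfig) -> bool:
    """Fixed-anchor comparison of two candidates: scalarize just the pair."""
    merits = chimera_scalarize(
        np.array([a.objective_row, b.objective_row]), config.objectives)
    return merits[0] < merits[1]


def _write_logs(result: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for log in result.logs:
        for r in log.records:
            d = r.descriptors
            rows.append({
                "generation": log.generation,
                "genes": "|".join(r.chromosome.genes),
                "smiles_int1": r.candidate.smiles_int1 if r.candidate else "",
                "fepa": d.fepa if d else math.nan,
                "feha": d.feha if d else math.nan,
                "d": d.d if d else math.nan,
                "phi": d.phi if d else math.nan,
                "scs": d.scs if d else math.nan,
                "q": d.q if d else math.nan,
                "cs": r.fitness.cs if r.fitness else math.nan,
                "gs": r.fitness.gs if r.fitness else math.nan,
                "merit": r.merit,
            })
    pd.DataFrame(rows).to_csv(out_dir / "generations.csv", index=False)
    pareto_rows = [{
        "genes": "|".join(r.chromosome.genes),
        "smiles_int1": r.candidate.smiles_int1,
        "cs": r.fitness.cs, "gs": r.fitness.gs, "scs": r.fitness.scs,
    } for r in result.pareto_archive]
    pd.DataFrame(pareto_rows).to_csv(out_dir / "pareto_archive.csv", index=False)
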