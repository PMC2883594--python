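"""Mutation, truncation selection and replication of transcriptional gates.

A population of genotypes (cis-regulatory sequence plus three TF
binding-domain sequences) is subjected to cycles of mutation, scoring and
selection.  Mutations act on the sequences: per cycle each cis region
receives a base substitution with probability ``p_sub`` and a single-base
insertion or deletion with probability ``p_indel`` (the promoter anatomy
stays anchored to the right end, i.e. to the transcription start site),
and each TF receives a point mutation with probability ``p_tf``.  The top
20% of the population by fitness survive each cycle and are duplicated at
random to restore the population size.  No attempt is made to mimic
biological population genetics faithfully; the algorithm is an optimizer.

Fitness is deterministic given the genotype and configuration, so the best
score is monotone non-decreasing over cycles (truncation selection never
discards the incumbent best), and whole runs are reproducible from the
random seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gates_and_fitness import (
    EvaluationGrid,
    FitnessWeights,
    GateSpec,
    fitness_noise,
    fitness_rf,
    fitness_rt,
    fitness_total,
)
from .response_dynamics import ModelSet, response_surface
from .sequence_energetics import (
    AMINO_ACIDS,
    MIN_CIS_LENGTH,
    NUCLEOTIDES,
    CisRegion,
    TranscriptionFactor,
)
from .thermodynamic_model import Genotype

__all__ = [
    "EvolutionConfig",
    "RunLog",
    "GenotypeScore",
    "mutate",
    "select_and_replicate",
    "evolve",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Run parameters of the evolutionary algorithm."""

    gate: GateSpec
    population_size: int = 200
    cycles: int = 1000
    survivor_fraction: float = 0.2
    p_sub: float = 0.5
    p_indel: float = 0.1
    p_tf: float = 0.03
    seed: int = 0
    l_cis: int = 150
    l_tf: int = 9
    max_cis_length: int = 300
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    grid: EvaluationGrid = field(default_factory=EvaluationGrid)
    mutate_tf3: bool = True
    track_feedback: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.survivor_fraction < 1:
            raise ValueError("survivor fraction must be in (0, 1)")
        for p in (self.p_sub, self.p_indel, self.p_tf):
            if not 0 <= p <= 1:
                raise ValueError("mutation probabilities must be in [0, 1]")
        if self.population_size < 2 or self.cycles < 1:
            raise ValueError("population size >= 2 and cycles >= 1 required")


@dataclass
class GenotypeScore:
    """Cached fitness components of one genotype."""

    s: float
    e_rf: float
    e_rt: float = 0.0
    e_n: float = 0.0


@dataclass
class RunLog:
    """Per-cycle summary of an evolutionary run plus the final population."""

    cycle: list[int] = field(default_factory=list)
    best_s: list[float] = field(default_factory=list)
    median_s: list[float] = field(default_factory=list)
    best_e_rf: list[float] = field(default_factory=list)
    best_e_rt: list[float] = field(default_factory=list)
    best_e_n: list[float] = field(default_factory=list)
    best_feedback: list[float] = field(default_factory=list)
    final_population: list[Genotype] = field(default_factory=list)
    final_scores: list[GenotypeScore] = field(default_factory=list)

    @property
    def best_genotype(self) -> Genotype:
        best = int(np.argmax([sc.s for sc in self.final_scores]))
        return self.final_population[best]


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------


def _mutate_cis(sequence: str, config: EvolutionConfig, rng: np.random.Generator) -> str:
    if rng.random() < config.p_sub:
        pos = int(rng.integers(len(sequence)))
        base = NUCLEOTIDES[int(rng.integers(4))]
        sequence = sequence[:pos] + base + sequence[pos + 1 :]
    if rng.random() < config.p_indel:
        if rng.random() < 0.5:  # insertion
            if len(sequence) < config.max_cis_length:
                pos = int(rng.integers(len(sequence) + 1))
                base = NUCLEOTIDES[int(rng.integers(4))]
                sequence = sequence[:pos] + base + sequence[pos:]
        else:  # deletion, skipped at the minimum length
            if len(sequence) > MIN_CIS_LENGTH:
                pos = int(rng.integers(len(sequence)))
                sequence = sequence[:pos] + sequence[pos + 1 :]
    return sequence


def _mutate_tf(tf: TranscriptionFactor, rng: np.random.Generator) -> TranscriptionFactor:
    pos = int(rng.integers(len(tf.sequence)))
    old = tf.sequence[pos]
    alternatives = AMINO_ACIDS.replace(old, "")
    new = alternatives[int(rng.integers(len(alternatives)))]
    return replace(tf, sequence=tf.sequence[:pos] + new + tf.sequence[pos + 1 :])


def mutate(
    genotype: Genotype, config: EvolutionConfig, rng: np.random.Generator
) -> tuple[Genotype, bool]:
    """One mutation round; returns the (possibly new) genotype and whether
    any sequence changed."""
    cis_seq = _mutate_cis(genotype.cis.sequence, config, rng)
    tfs = list(genotype.tfs)
    for i in range(3):
        if i == 2 and not config.mutate_tf3:
            continue
        if rng.random() < config.p_tf:
            tfs[i] = _mutate_tf(tfs[i], rng)
    changed = cis_seq != genotype.cis.sequence or any(
        t is not o for t, o in zip(tfs, genotype.tfs)
    )
    if not changed:
        return genotype, False
    cis = CisRegion(cis_seq, max_length=config.max_cis_length)
    return Genotype(cis=cis, tf1=tfs[0], tf2=tfs[1], tf3=tfs[2]), True


# ---------------------------------------------------------------------------
# Selection and replication
# ---------------------------------------------------------------------------


def select_and_replicate(
    population: list[Genotype],
    scores: list[float],
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> tuple[list[int], list[int]]:
    """Indices of the survivors and of the refilled population.

    Keeps the ceil(survivor_fraction * N) highest-scoring genotypes (ties
    broken by stable input order) and refills to N by uniform random
    duplication of survivors.  Returned as indices so callers can carry
    cached scores along.
    """
    n = len(population)
    if n == 0:
        raise ValueError("population is empty")
    if len(scores) != n:
        raise ValueError("scores must match the population size")
    k = int(np.ceil(config.survivor_fraction * n))
    order = np.argsort(-np.asarray(scores), kind="stable")
    survivors = [int(i) for i in order[:k]]
    refill = [survivors[int(j)] for j in rng.integers(k, size=n - k)]
    return survivors, survivors + refill


# ---------------------------------------------------------------------------
# Scoring and the main loop
# ---------------------------------------------------------------------------


def random_population(config: EvolutionConfig, rng: np.random.Generator) -> list[Genotype]:
    pop = []
    for _ in range(config.population_size):
        cis = CisRegion(
            "".join(NUCLEOTIDES[i] for i in rng.integers(4, size=config.l_cis)),
            max_length=config.max_cis_length,
        )
        tfs = [
            TranscriptionFactor(
                f"TF{k + 1}",
                "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=config.l_tf)),
                role="output" if k == 2 else "input",
            )
            for k in range(3)
        ]
        pop.append(Genotype(cis=cis, tf1=tfs[0], tf2=tfs[1], tf3=tfs[2]))
    return pop


def score_genotype(
    genotype: Genotype, models: ModelSet, config: EvolutionConfig, t: int
) -> GenotypeScore:
    """All fitness components of one genotype at cycle ``t``.

    Dynamical terms are only computed when their (ramped) weight is
    nonzero; any error flag maps to the worst score instead of aborting.
    """
    c1, c2 = config.grid.points(config.gate)
    surface = response_surface(genotype, models, c1, c2)
    e_rf = fitness_rf(surface, config.gate, config.weights.c0)
    e_rt = 0.0
    e_n = 0.0
    if config.weights.lambda_rt_max > 0:
        e_rt = fitness_rt(genotype, models, config.gate, config.grid)
    if config.weights.lambda_noise_max > 0:
        e_n = fitness_noise(genotype, models, config.gate, config.grid)
    try:
        s = fitness_total(e_rf, e_rt, e_n, config.weights, t)
    except ValueError:
        s = float("-inf")
    if not np.isfinite(s):
        s = float("-inf")
    return GenotypeScore(s=s, e_rf=e_rf, e_rt=e_rt, e_n=e_n)


def evolve(config: EvolutionConfig, models: ModelSet) -> RunLog:
    """Run the full mutation/selection/replication loop; reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    population = random_population(config, rng)
    scores: list[GenotypeScore | None] = [None] * config.population_size
    ramped = config.weights.lambda_rt_max > 0 or config.weights.lambda_noise_max > 0
    log = RunLog()

    for t in range(config.cycles):
        # mutation precedes scoring and survivors carry fresh mutations,
        # except that the single incumbent best (index 0 after selection)
        # is copied through unchanged: with deterministic fitness this
        # elitism makes the best score exactly monotone non-decreasing
        mutated = [
            (g, False) if (i == 0 and t > 0) else mutate(g, config, rng)
            for i, g in enumerate(population)
        ]
        population = [g for g, _ in mutated]
        for i, (g, changed) in enumerate(mutated):
            if changed or scores[i] is None or ramped:
                scores[i] = score_genotype(g, models, config, t)
        s_values = [sc.s for sc in scores]
        best = int(np.argmax(s_values))
        log.cycle.append(t)
        log.best_s.append(s_values[best])
        log.median_s.append(float(np.median(s_values)))
        log.best_e_rf.append(scores[best].e_rf)
        log.best_e_rt.append(scores[best].e_rt)
        log.best_e_n.append(scores[best].e_n)
        if config.track_feedback:
            from .promoter_analysis import feedback_measure

            try:
                f_val = feedback_measure(population[best], models, config.grid, config.gate)
            except Exception:
                f_val = float("nan")
            log.best_feedback.append(f_val)
        else:
            log.best_feedback.append(float("nan"))

        _, refill = select_and_replicate(population, s_values, config, rng)
        population = [population[i] for i in refill]
        scores = [scores[i] for i in refill]

    log.final_population = population
    log.final_scores = list(scores)
    return log
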