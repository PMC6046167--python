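"""NSGA-II search over the TWSVM hyperparameters (c1, c2, lambda).

The three objectives are the cross-validated per-class correct rates
(CRF, CRE, CRA), maximised jointly; the scalar CR (pooled total rate) is
tracked for model selection but is not an objective.  The algorithm is
the standard elitist loop: fast non-dominated sorting, crowding distance,
binary tournament selection under the crowded comparison, simulated
binary crossover (SBX) and polynomial mutation, and (mu + lambda)
truncation of parents plus offspring.

Genes are encoded in log2 space — the search bounds are powers of two
spanning up to 23 octaves (lambda in [2^-20, 2^3]), which a linear
encoding would squash against the lower bound.  Decoded values are
2**gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from afcsp.pipeline import CVFeatureCache
from afcsp.twsvm import KernelSpec


@dataclass(frozen=True)
class ParamBounds:
    """Search box in log2 units: c1, c2 in [2^-3, 2^3]; lambda in [2^-20, 2^3]."""

    c1: tuple[float, float] = (-3.0, 3.0)
    c2: tuple[float, float] = (-3.0, 3.0)
    lam: tuple[float, float] = (-20.0, 3.0)

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "lam"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.c1[0], self.c2[0], self.lam[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.c1[1], self.c2[1], self.lam[1]])

    def decode(self, genes: np.ndarray) -> np.ndarray:
        return 2.0 ** np.asarray(genes, dtype=float)


@dataclass
class GAConfig:
    pop_size: int = 100
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    generations: int = 200
    eta_c: float = 20.0
    eta_m: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.pop_size < 2 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 2")


@dataclass
class Individual:
    genes: np.ndarray                          # log2-space genome
    objectives: tuple[float, ...] | None = None
    cr: float = float("nan")
    rank: int = -1
    crowding: float = 0.0

    def params(self, bounds: ParamBounds) -> tuple[float, float, float]:
        c1, c2, lam = bounds.decode(self.genes)
        return float(c1), float(c2), float(lam)


@dataclass
class ParetoFront:
    members: list[Individual]
    generation: int = -1


def dominates(a: Individual, b: Individual) -> bool:
    """Strict Pareto dominance under maximisation of all objectives."""
    if a.objectives is None or b.objectives is None:
        raise ValueError("both individuals must be evaluated")
    oa, ob = np.asarray(a.objectives), np.asarray(b.objectives)
    return bool(np.all(oa >= ob) and np.any(oa > ob))


def fast_nondominated_sort(pop: Sequence[Individual]) -> list[list[int]]:
    """Deb's O(M N^2) sort; returns index fronts and sets each rank."""
    n = len(pop)
    S: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    fronts: list[list[int]] = [[]]
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            if dominates(pop[p], pop[q]):
                S[p].append(q)
            elif dominates(pop[q], pop[p]):
                dom_count[p] += 1
        if dom_count[p] == 0:
            pop[p].rank = 0
            fronts[0].append(p)
    k = 0
    while fronts[k]:
        nxt = []
        for p in fronts[k]:
            for q in S[p]:
                dom_count[q] -= 1
                if dom_count[q] == 0:
                    pop[q].rank = k + 1
                    nxt.append(q)
        k += 1
        fronts.append(nxt)
    return fronts[:-1]


def crowding_distance(pop: Sequence[Individual], front: Sequence[int],
                      ) -> np.ndarray:
    """Normalised cuboid-perimeter crowding; boundary members get inf."""
    dist = np.zeros(len(front))
    if len(front) <= 2:
        dist[:] = np.inf
    else:
        objs = np.array([pop[i].objectives for i in front])
        for m in range(objs.shape[1]):
            order = np.argsort(objs[:, m], kind="stable")
            rng = objs[order[-1], m] - objs[order[0], m]
            dist[order[0]] = dist[order[-1]] = np.inf
            if rng > 0:
                gaps = (objs[order[2:], m] - objs[order[:-2], m]) / rng
                dist[order[1:-1]] += gaps
    for d, i in zip(dist, front):
        pop[i].crowding = float(d)
    return dist


def _crowded_better(a: Individual, b: Individual) -> bool:
    if a.rank != b.rank:
        return a.rank < b.rank
    return a.crowding > b.crowding


def _sbx(p1: np.ndarray, p2: np.ndarray, eta: float, lower, upper,
         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulated binary crossover, per-gene, bounds-clipped."""
    c1, c2 = p1.copy(), p2.copy()
    for k in range(len(p1)):
        if rng.random() > 0.5 or abs(p1[k] - p2[k]) < 1e-14:
            continue
        u = rng.random()
        beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else \
            (1 / (2 * (1 - u))) ** (1 / (eta + 1))
        c1[k] = 0.5 * ((1 + beta) * p1[k] + (1 - beta) * p2[k])
        c2[k] = 0.5 * ((1 - beta) * p1[k] + (1 + beta) * p2[k])
    return (np.clip(c1, lower, upper), np.clip(c2, lower, upper))


def _poly_mutate(x: np.ndarray, eta: float, rate: float, lower, upper,
                 rng: np.random.Generator) -> np.ndarray:
    y = x.copy()
    for k in range(len(x)):
        if rng.random() >= rate:
            continue
        u = rng.random()
        span = upper[k] - lower[k]
        if u < 0.5:
            delta = (2 * u) ** (1 / (eta + 1)) - 1
        else:
            delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
        y[k] = x[k] + delta * span
    return np.clip(y, lower, upper)


EvalFn = Callable[[np.ndarray], tuple[tuple[float, ...], float]]
"""Maps a log2 genome to ((objectives...), scalar CR)."""


def make_cv_evaluator(cache: CVFeatureCache, bounds: ParamBounds,
                      kernel_kind: str = "rbf") -> EvalFn:
    """Objective function: pooled 5-fold (CRF, CRE, CRA) with CR attached.

    Folds are fixed inside `cache`, so objective differences between
    genomes reflect the hyperparameters, not fold resampling noise.
    """
    def evaluate(genes: np.ndarray) -> tuple[tuple[float, ...], float]:
        c1, c2, lam = bounds.decode(genes)
        kernel = (KernelSpec("linear") if kernel_kind == "linear"
                  else KernelSpec("rbf", float(lam)))
        crf, cre, cra, cr, _ = cache.score(float(c1), float(c2), kernel)
        return (crf, cre, cra), cr
    return evaluate


@dataclass
class EvolveResult:
    front: ParetoFront
    history: list[float]               # best archived CR per generation
    best: Individual                   # best-CR individual ever evaluated
    n_evaluations: int = 0
    n_clipped: int = 0                 # offspring genes clipped to bounds


def _evaluate_pop(pop: list[Individual], fn: EvalFn) -> None:
    for ind in pop:
        if ind.objectives is None:
            ind.objectives, ind.cr = fn(ind.genes)


def evolve(eval_fn: EvalFn, config: GAConfig,
           bounds: ParamBounds = ParamBounds()) -> EvolveResult:
    """Run the elitist NSGA-II loop and return the final front.

    The returned history is the best *archived* CR after each generation,
    non-decreasing by construction; the archive guarantees the best
    individual ever evaluated is never lost even if truncation drops it.
    """
    rng = np.random.default_rng(config.seed)
    lower, upper = bounds.lower, bounds.upper
    pop = [Individual(genes=rng.uniform(lower, upper))
           for _ in range(config.pop_size)]
    _evaluate_pop(pop, eval_fn)
    n_eval = len(pop)
    best = max(pop, key=lambda i: i.cr)
    history: list[float] = []
    fronts = fast_nondominated_sort(pop)
    for fr in fronts:
        crowding_distance(pop, fr)

    n_clipped = 0
    for gen in range(config.generations):
        offspring: list[Individual] = []
        while len(offspring) < config.pop_size:
            parents = []
            for _ in range(2):
                i, j = rng.integers(len(pop)), rng.integers(len(pop))
                parents.append(pop[i] if _crowded_better(pop[i], pop[j])
                               else pop[j])
            g1, g2 = parents[0].genes, parents[1].genes
            if rng.random() < config.crossover_rate:
                raw1, raw2 = _sbx(g1, g2, config.eta_c, -np.inf, np.inf, rng)
                n_clipped += int(np.sum((raw1 < lower) | (raw1 > upper)))
                n_clipped += int(np.sum((raw2 < lower) | (raw2 > upper)))
                g1, g2 = np.clip(raw1, lower, upper), np.clip(raw2, lower, upper)
            g1 = _poly_mutate(g1, config.eta_m, config.mutation_rate,
                              lower, upper, rng)
            g2 = _poly_mutate(g2, config.eta_m, config.mutation_rate,
                              lower, upper, rng)
            offspring.append(Individual(genes=g1))
            offspring.append(Individual(genes=g2))
        offspring = offspring[:config.pop_size]
        _evaluate_pop(offspring, eval_fn)
        n_eval += len(offspring)
        cand = max(offspring, key=lambda i: i.cr)
        if cand.cr > best.cr:
            best = cand

        union = pop + offspring
        fronts = fast_nondominated_sort(union)
        new_pop: list[Individual] = []
        for fr in fronts:
            dist = crowding_distance(union, fr)
            members = [union[i] for i in fr]
            if len(new_pop) + len(members) <= config.pop_size:
                new_pop.extend(members)
            else:
                order = np.argsort(-dist, kind="stable")
                need = config.pop_size - len(new_pop)
                new_pop.extend(members[i] for i in order[:need])
                break
        pop = new_pop
        history.append(best.cr)

    fronts = fast_nondominated_sort(pop)
    for fr in fronts:
        crowding_distance(pop, fr)
    front = ParetoFront(members=[pop[i] for i in fronts[0]] if fronts else [],
                        generation=config.generations)
    if not history:
        history = [best.cr]
    return EvolveResult(front=front, history=history, best=best,
                        n_evaluations=n_eval, n_clipped=n_clipped)


def select_best(front: ParetoFront | Sequence[Individual]) -> Individual:
    """Max-CR member; ties by the larger minimum per-class rate, then order."""
    members = front.members if isinstance(front, ParetoFront) else list(front)
    if not members:
        raise ValueError("cannot select from an empty Pareto front")
    best = members[0]
    for ind in members[1:]:
        if ind.cr > best.cr + 1e-12:
            best = ind
        elif abs(ind.cr - best.cr) <= 1e-12 and \
                min(ind.objectives) > min(best.objectives) + 1e-12:
            best = ind
    return best


def random_search(eval_fn: EvalFn, n_draws: int,
                  bounds: ParamBounds = ParamBounds(),
                  seed: int = 0) -> Individual:
    """Best-CR individual among uniform random draws (baseline control)."""
    rng = np.random.default_rng(seed)
    best: Individual | None = None
    for _ in range(n_draws):
        ind = Individual(genes=rng.uniform(bounds.lower, bounds.upper))
        ind.objectives, ind.cr = eval_fn(ind.genes)
        if best is None or ind.cr > best.cr:
            best = ind
    return best
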