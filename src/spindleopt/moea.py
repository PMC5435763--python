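"""Pareto dominance over (FN, FP) and the SPEA2 optimizer.

A spindle detector's performance on a dataset is the two-objective vector
``(FN, FP)`` — missed spindles vs. false detections — and both are to be
minimized. The optimal trade-offs form the Pareto front, which SPEA2
(Strength Pareto Evolutionary Algorithm 2) approximates with an external
archive, strength/raw fitness plus a nearest-neighbor density term, and
real-coded variation (simulated-binary crossover, polynomial mutation).

Objective evaluations are memoized by parameter vector, since detector
evaluation dominates the run time and the evolutionary bookkeeping is cheap
by comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .scoring import fbeta

logger = logging.getLogger(__name__)

#: objective sentinel for parameter vectors whose evaluation raised
EVAL_ERROR_SENTINEL = 2 ** 30

#: published per-detector (population size, max generations) settings
DEFAULT_RUN_SETTINGS: dict[str, tuple[int, int]] = {
    "d1": (100, 100), "d2": (100, 100), "d3": (100, 100),
    "d4": (150, 250), "d5": (120, 200), "d6": (120, 200),
    "d7": (170, 250), "d8": (170, 250), "d9": (270, 320),
}


@dataclass(frozen=True, order=True)
class ObjectivePoint:
    """A (false negatives, false positives) pair; both to be minimized."""

    fn: int
    fp: int

    def __post_init__(self) -> None:
        if self.fn < 0 or self.fp < 0:
            raise ValueError("objective counts must be non-negative")


def dominates(a: ObjectivePoint, b: ObjectivePoint) -> bool:
    """Pareto dominance: no worse in both objectives, better in at least one."""
    return (a.fn <= b.fn and a.fp <= b.fp
            and (a.fn < b.fn or a.fp < b.fp))


@dataclass
class Individual:
    """A parameter vector with its objectives and SPEA2 fitness internals."""

    x: np.ndarray
    obj: ObjectivePoint
    strength: int = 0
    raw: int = 0
    density: float = 0.0
    fitness: float = 0.0


@dataclass(frozen=True)
class ParetoFront:
    """Mutually nondominated individuals with pairwise-distinct objectives."""

    members: tuple[Individual, ...]

    def __post_init__(self) -> None:
        objs = [m.obj for m in self.members]
        if len(set(objs)) != len(objs):
            raise ValueError("front objectives must be pairwise distinct")
        for i, a in enumerate(objs):
            for b in objs[i + 1:]:
                if dominates(a, b) or dominates(b, a):
                    raise ValueError("front members must be nondominated")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def objectives(self) -> list[ObjectivePoint]:
        return [m.obj for m in self.members]


@dataclass(frozen=True)
class MOEAConfig:
    """SPEA2 run settings."""

    pop_size: int = 100
    max_gen: int = 100
    archive_size: int | None = None  # defaults to pop_size
    seed: int = 0
    crossover: tuple[float, float] = (0.9, 15.0)  # (probability, eta)
    mutation: tuple[float | None, float] = (None, 20.0)  # (per-gene p, eta)

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.max_gen < 1:
            raise ValueError("max_gen must be >= 1")

    @property
    def n_archive(self) -> int:
        return self.archive_size or self.pop_size


def pareto_filter(points: Iterable[ObjectivePoint],
                  xs: Sequence[np.ndarray] | None = None) -> ParetoFront:
    """Nondominated subset of a set of objective points.

    Duplicate objectives collapse to their first occurrence. When *xs* is
    given, the surviving members carry the corresponding parameter vectors.
    """
    points = list(points)
    if not points:
        return ParetoFront(())
    obj = np.array([[p.fn, p.fp] for p in points])
    members: list[Individual] = []
    seen: set[ObjectivePoint] = set()
    for i, p in enumerate(points):
        if p in seen:
            continue
        dominated = np.any((obj[:, 0] <= p.fn) & (obj[:, 1] <= p.fp)
                           & ((obj[:, 0] < p.fn) | (obj[:, 1] < p.fp)))
        if dominated:
            continue
        seen.add(p)
        x = np.asarray(xs[i], float) if xs is not None else np.empty(0)
        members.append(Individual(x=x, obj=p))
    return ParetoFront(tuple(members))


# ---------------------------------------------------------------------------
# SPEA2 internals

def _normalized_objectives(pool: Sequence[Individual]) -> np.ndarray:
    """Objective matrix scaled by pool ranges (zero-range dims dropped)."""
    obj = np.array([[ind.obj.fn, ind.obj.fp] for ind in pool], dtype=float)
    rng = obj.max(axis=0) - obj.min(axis=0)
    keep = rng > 0
    if not keep.any():
        return np.zeros((len(pool), 1))
    return (obj[:, keep] - obj[:, keep].min(axis=0)) / rng[keep]


def spea2_fitness_assign(pool: list[Individual]) -> list[Individual]:
    """Assign strength, raw fitness, density and fitness in place.

    ``S(i)`` counts the members *i* dominates; ``R(i)`` sums the strengths of
    the members dominating *i* (0 for nondominated members); ``D(i) =
    1 / (sigma_k + 2)`` with ``sigma_k`` the normalized objective-space
    distance to the k-th nearest neighbor, ``k = round(sqrt(|pool|))``.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    n = len(pool)
    fn = np.array([ind.obj.fn for ind in pool])
    fp = np.array([ind.obj.fp for ind in pool])
    dom = ((fn[:, None] <= fn[None, :]) & (fp[:, None] <= fp[None, :])
           & ((fn[:, None] < fn[None, :]) | (fp[:, None] < fp[None, :])))
    strength = dom.sum(axis=1)
    raw = np.array([strength[dom[:, j]].sum() for j in range(n)])
    z = _normalized_objectives(pool)
    dist = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=2)
    np.fill_diagonal(dist, np.inf)
    k = max(1, int(round(np.sqrt(n))))
    k = min(k, n - 1) if n > 1 else 1
    if n > 1:
        sigma_k = np.sort(dist, axis=1)[:, k - 1]
    else:
        sigma_k = np.zeros(1)
    density = 1.0 / (sigma_k + 2.0)
    for i, ind in enumerate(pool):
        ind.strength = int(strength[i])
        ind.raw = int(raw[i])
        ind.density = float(density[i])
        ind.fitness = float(raw[i] + density[i])
    return pool


def _truncate(cands: list[Individual], size: int) -> list[Individual]:
    """SPEA2 archive truncation: iteratively drop the individual with the
    lexicographically smallest sorted distance vector to the others."""
    alive = list(range(len(cands)))
    z = _normalized_objectives(cands)
    dist = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=2)
    while len(alive) > size:
        sub = dist[np.ix_(alive, alive)]
        np.fill_diagonal(sub, np.inf)
        rows = np.sort(sub, axis=1)
        # lexicographic comparison of the sorted distance rows
        order = np.lexsort(rows.T[::-1])
        alive.pop(order[0])
    return [cands[i] for i in alive]


def _environmental_select(pool: list[Individual],
                          size: int) -> list[Individual]:
    nondom = [ind for ind in pool if ind.raw == 0]
    if len(nondom) > size:
        return _truncate(nondom, size)
    filled = list(nondom)
    if len(filled) < size:
        rest = sorted((ind for ind in pool if ind.raw > 0),
                      key=lambda ind: ind.fitness)
        filled.extend(rest[: size - len(filled)])
    return filled


def _sbx_crossover(p1: np.ndarray, p2: np.ndarray, lower: np.ndarray,
                   upper: np.ndarray, prob: float, eta: float,
                   rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = p1.copy(), p2.copy()
    if rng.random() >= prob:
        return c1, c2
    do = rng.random(p1.size) < 0.5
    u = rng.random(p1.size)
    beta = np.where(u <= 0.5, (2 * u) ** (1 / (eta + 1)),
                    (1 / (2 * (1 - u))) ** (1 / (eta + 1)))
    a = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    b = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    c1[do], c2[do] = a[do], b[do]
    return np.clip(c1, lower, upper), np.clip(c2, lower, upper)


def _poly_mutation(x: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                   prob: float, eta: float,
                   rng: np.random.Generator) -> np.ndarray:
    y = x.copy()
    do = rng.random(x.size) < prob
    if do.any():
        u = rng.random(x.size)
        delta = np.where(u < 0.5, (2 * u) ** (1 / (eta + 1)) - 1,
                         1 - (2 * (1 - u)) ** (1 / (eta + 1)))
        y[do] = y[do] + delta[do] * (upper[do] - lower[do])
    return np.clip(y, lower, upper)


def _memo_key(x: np.ndarray) -> tuple[float, ...]:
    # round to 12 significant digits so float jitter does not defeat the memo
    return tuple(float(f"{v:.12g}") for v in x)


def spea2_optimize(evaluate: Callable[[np.ndarray], ObjectivePoint],
                   bounds: tuple[np.ndarray, np.ndarray],
                   cfg: MOEAConfig,
                   history: list | None = None) -> ParetoFront:
    """Minimize ``(FN, FP)`` over a box-bounded parameter space with SPEA2.

    *evaluate* must be deterministic for a fixed input; evaluations are
    memoized. If *history* is a list, the archive objectives of every
    generation are appended to it. Returns the nondominated set of the final
    archive.
    """
    lower = np.asarray(bounds[0], float)
    upper = np.asarray(bounds[1], float)
    if lower.shape != upper.shape or np.any(~np.isfinite(lower)) \
            or np.any(~np.isfinite(upper)):
        raise ValueError("bounds must be finite vectors of equal length")
    n_genes = lower.size
    rng = np.random.default_rng(cfg.seed)
    memo: dict[tuple[float, ...], ObjectivePoint] = {}

    def eval_memo(x: np.ndarray) -> ObjectivePoint:
        key = _memo_key(x)
        if key not in memo:
            try:
                memo[key] = evaluate(x)
            except Exception:
                logger.exception("objective evaluation failed for %s", key)
                memo[key] = ObjectivePoint(EVAL_ERROR_SENTINEL,
                                           EVAL_ERROR_SENTINEL)
        return memo[key]

    pc, eta_c = cfg.crossover
    pm, eta_m = cfg.mutation
    pm = 1.0 / n_genes if pm is None else pm

    pop = [Individual(x=x, obj=eval_memo(x))
           for x in lower + rng.random((cfg.pop_size, n_genes))
           * (upper - lower)]
    archive: list[Individual] = []
    for _ in range(cfg.max_gen):
        pool = spea2_fitness_assign(pop + archive)
        archive = _environmental_select(pool, cfg.n_archive)
        if history is not None:
            history.append([(ind.obj.fn, ind.obj.fp) for ind in archive])

        def tournament() -> Individual:
            i, j = rng.integers(len(archive), size=2)
            a, b = archive[i], archive[j]
            return a if a.fitness <= b.fitness else b

        offspring: list[Individual] = []
        while len(offspring) < cfg.pop_size:
            x1, x2 = tournament().x, tournament().x
            c1, c2 = _sbx_crossover(x1, x2, lower, upper, pc, eta_c, rng)
            for c in (c1, c2):
                if len(offspring) >= cfg.pop_size:
                    break
                c = _poly_mutation(c, lower, upper, pm, eta_m, rng)
                offspring.append(Individual(x=c, obj=eval_memo(c)))
        pop = offspring
    return pareto_filter([ind.obj for ind in archive],
                         [ind.x for ind in archive])


# ---------------------------------------------------------------------------
# Pareto-front-derived performance metrics

@dataclass(frozen=True)
class FrontMetrics:
    """PR- and F1-curves derived from a Pareto front, plus the best point."""

    pr_points: tuple[tuple[float, float], ...]  # (recall, precision)
    f1_points: tuple[float, ...]                # aligned with pr_points
    best: Individual
    best_precision: float
    best_recall: float
    best_f1: float


def front_metrics(front: ParetoFront, n_gold: int,
                  beta: float = 1.0) -> FrontMetrics:
    """Precision/recall/F-beta along a front of (FN, FP) objectives.

    ``TP = n_gold - FN`` per member. Returns the PR pairs sorted by recall
    and the maximal-F member (ties broken by lower FP).
    """
    if len(front) == 0:
        raise ValueError("empty Pareto front")
    rows = []
    for m in front:
        if m.obj.fn > n_gold:
            raise ValueError(f"member fn={m.obj.fn} exceeds n_gold={n_gold}")
        tp = n_gold - m.obj.fn
        p = tp / (tp + m.obj.fp) if tp + m.obj.fp > 0 else 0.0
        r = tp / n_gold if n_gold > 0 else 0.0
        rows.append((r, p, fbeta(p, r, beta), m))
    rows.sort(key=lambda t: (t[0], t[1]))
    best = max(rows, key=lambda t: (t[2], -t[3].obj.fp))
    return FrontMetrics(
        pr_points=tuple((r, p) for r, p, _, _ in rows),
        f1_points=tuple(f for _, _, f, _ in rows),
        best=best[3], best_precision=best[1], best_recall=best[0],
        best_f1=best[2])


def hypervolume_2d(points: Iterable[ObjectivePoint],
                   reference: tuple[float, float]) -> float:
    """Dominated hypervolume of a 2-D minimization front w.r.t. *reference*."""
    front = sorted({(p.fn, p.fp) for p in points})
    ref_fn, ref_fp = reference
    # keep the staircase: strictly decreasing fp with increasing fn
    stairs: list[tuple[float, float]] = []
    for fn, fp in front:
        if not stairs or fp < stairs[-1][1]:
            stairs.append((fn, fp))
    area = 0.0
    for i, (fn, fp) in enumerate(stairs):
        next_fn = stairs[i + 1][0] if i + 1 < len(stairs) else ref_fn
        if fn >= ref_fn or fp >= ref_fp:
            continue
        area += (min(next_fn, ref_fn) - fn) * (ref_fp - fp)
    return area
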