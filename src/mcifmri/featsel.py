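"""Wrapper feature selection over binary masks.

Five search strategies operate on boolean feature masks whose fitness is a
classifier's cross-validated performance on the masked columns:

* **GA** — generational genetic algorithm, maximizes CV accuracy.
* **NSGA-II** — elitist multi-objective GA (non-dominated sorting + crowding
  distance), jointly minimizes the number of selected features and the
  combined objective below; reports a Pareto front.
* **PSO** — binary particle swarm (continuous positions, sigmoid transfer,
  threshold 0.5), minimizes the combined objective.
* **SA** — simulated annealing with Metropolis acceptance on CV accuracy;
  the default proposal draws a fresh random subset each iteration (a
  one-bit-flip neighbourhood is selectable, but on accuracy plateaus it
  random-walks toward very large masks).
* **SFFS** — sequential floating forward selection: greedy add steps with
  conditional (floating) removal, maximizes CV accuracy.

The combined objective trades classification error against parsimony::

    f(x) = alpha * (1 - P) + (1 - alpha) * N_selected / N_total

with P the mean CV accuracy and alpha (default 0.9) the trade-off weight;
lower is better. An exhaustive oracle over all nonempty masks is provided
for small problems so the metaheuristics can be validated against the true
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evalkit import cross_validate
from .parcellate import FeatureTable

METHODS = ("GA", "NSGA2", "PSO", "SA", "SFFS")
CRITERIA = ("accuracy", "combined", "multi_objective")

__all__ = [
    "METHODS",
    "ObjectiveSpec",
    "FitnessValue",
    "SelectionResult",
    "SearchBudget",
    "combined_objective",
    "evaluate_mask",
    "run_feature_selection",
    "exhaustive_best_subset",
]


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def combined_objective(p: float, n_selected: int, n_total: int, alpha: float = 0.9) -> float:
    """f = alpha * (1 - P) + (1 - alpha) * N_selected / N_total (minimize)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"accuracy P must be in [0, 1], got {p}")
    if n_total < 1 or not 0 <= n_selected <= n_total:
        raise ValueError(f"need 0 <= n_selected <= n_total, got {n_selected}/{n_total}")
    return alpha * (1.0 - p) + (1.0 - alpha) * n_selected / n_total


@dataclass(frozen=True)
class ObjectiveSpec:
    """How a candidate mask is scored."""

    criterion: str = "accuracy"
    alpha: float = 0.9
    classifier: str = "SVM"
    cv_folds: int = 10
    seed: int = 42
    clf_params: dict | None = None

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"criterion must be one of {CRITERIA}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")


@dataclass(frozen=True)
class FitnessValue:
    """CV accuracy P, combined objective f and mask size for one mask."""

    p: float
    f: float
    n_selected: int


@dataclass
class SelectionResult:
    method: str
    mask: np.ndarray
    fitness: FitnessValue
    trace: list[float]  # best-so-far value of the method's own criterion
    seed: int
    n_evaluations: int
    front: list[tuple[np.ndarray, tuple[int, float]]] | None = None  # NSGA-II only

    def selected_features(self, feature_names: list[str]) -> list[str]:
        return [feature_names[i] for i in np.nonzero(self.mask)[0]]

    def to_dict(self, feature_names: list[str] | None = None) -> dict:
        out = {
            "method": self.method,
            "mask": [int(b) for b in self.mask],
            "P": self.fitness.p,
            "f": self.fitness.f,
            "n_selected": self.fitness.n_selected,
            "trace": list(self.trace),
            "seed": self.seed,
            "n_evaluations": self.n_evaluations,
        }
        if feature_names is not None:
            out["selected_features"] = self.selected_features(feature_names)
        if self.front is not None:
            out["front"] = [
                {"mask": [int(b) for b in m], "n_selected": int(o[0]), "f": float(o[1])}
                for m, o in self.front
            ]
        return out


@dataclass(frozen=True)
class SearchBudget:
    """Iteration/population sizing shared by the metaheuristics."""

    population_size: int = 20
    n_iterations: int = 24
    sa_steps: int = 300
    sffs_max_features: int | None = None  # None: no cap beyond N_total
    init_density: float = 0.08  # expected fraction of bits set at initialisation

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.n_iterations < 1 or self.sa_steps < 1:
            raise ValueError("budget parameters must be positive")
        if not 0.0 < self.init_density <= 1.0:
            raise ValueError("init_density must be in (0, 1]")


# ---------------------------------------------------------------------------
# fitness evaluation (with caching: metaheuristics revisit masks constantly)
# ---------------------------------------------------------------------------

class _Evaluator:
    """Caching fitness evaluator.

    Computes the same quantity as :func:`evaluate_mask` (mean fold accuracy
    under the spec's stratified CV on the masked columns) but precomputes the
    fold assignment and the fold-wise training standardization of the full
    matrix once, so that scoring a mask only slices columns and fits the
    classifier — metaheuristics evaluate thousands of masks.
    """

    def __init__(self, table: FeatureTable, spec: ObjectiveSpec):
        from .evalkit import make_classifier, stratified_folds

        self.spec = spec
        self.n_total = table.n_features
        self.n_evaluations = 0
        self._cache: dict[bytes, FitnessValue] = {}
        self._make_classifier = make_classifier
        x, y = table.x, table.y
        folds = stratified_folds(y, k=spec.cv_folds, seed=spec.seed)
        self._splits = []
        for fold in range(folds.k):
            tr, te = folds.train_indices(fold), folds.test_indices(fold)
            if len(np.unique(y[tr])) < 2:
                raise ValueError(f"training split for fold {fold} lacks a class; use fewer folds")
            mu = x[tr].mean(axis=0)
            sd = x[tr].std(axis=0)
            sd = np.where(sd <= 0, 1.0, sd)
            self._splits.append(((x[tr] - mu) / sd, y[tr], (x[te] - mu) / sd, y[te]))

    def __call__(self, mask: np.ndarray) -> FitnessValue:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty feature mask")
        key = np.packbits(mask).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        accs = []
        for xtr, ytr, xte, yte in self._splits:
            clf = self._make_classifier(
                self.spec.classifier, seed=self.spec.seed, params=self.spec.clf_params
            )
            clf.fit(xtr[:, mask], ytr)
            accs.append(float(np.mean(clf.predict(xte[:, mask]) == yte)))
        p = float(np.mean(accs))
        n_sel = int(mask.sum())
        value = FitnessValue(
            p=p, f=combined_objective(p, n_sel, self.n_total, self.spec.alpha), n_selected=n_sel
        )
        self.n_evaluations += 1
        self._cache[key] = value
        return value


def evaluate_mask(
    mask: np.ndarray,
    x: np.ndarray | FeatureTable,
    y: np.ndarray | None = None,
    spec: ObjectiveSpec = ObjectiveSpec(),
    n_total: int | None = None,
) -> FitnessValue:
    """Score one mask: P = mean fold accuracy of the spec's classifier under
    stratified CV on the masked columns; f from the combined objective."""
    if isinstance(x, FeatureTable):
        n_total = x.n_features
        y = x.y
        x = x.x
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty feature mask")
    if n_total is None:
        n_total = mask.size
    cv = cross_validate(
        x,
        y,
        mask=mask,
        classifier=spec.classifier,
        k=spec.cv_folds,
        seed=spec.seed,
        clf_params=spec.clf_params,
    )
    p = cv.mean_fold_accuracy
    n_sel = int(mask.sum())
    return FitnessValue(p=p, f=combined_objective(p, n_sel, n_total, spec.alpha), n_selected=n_sel)


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Masks submitted to a classifier need >= 1 bit; set one at random."""
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def _init_population(n: int, size: int, density: float, rng: np.random.Generator) -> np.ndarray:
    pop = rng.random((size, n)) < density
    for i in range(size):
        pop[i] = _repair(pop[i], rng)
    return pop


# ---------------------------------------------------------------------------
# GA (maximizes accuracy)
# ---------------------------------------------------------------------------

def _ga_variation(
    pop: np.ndarray,
    keys: np.ndarray,
    rng: np.random.Generator,
    crossover_rate: float = 0.9,
    tournament: int = 3,
) -> np.ndarray:
    """Tournament selection + uniform crossover + per-bit mutation.

    ``keys`` are minimized (pass negated accuracy for maximization)."""
    size, n = pop.shape
    mut_rate = 1.0 / n
    children = np.empty_like(pop)
    for i in range(size):
        picks_a = rng.integers(size, size=tournament)
        picks_b = rng.integers(size, size=tournament)
        pa = pop[picks_a[np.argmin(keys[picks_a])]]
        pb = pop[picks_b[np.argmin(keys[picks_b])]]
        if rng.random() < crossover_rate:
            take = rng.random(n) < 0.5
            child = np.where(take, pa, pb)
        else:
            child = pa.copy()
        flip = rng.random(n) < mut_rate
        child = np.logical_xor(child, flip)
        children[i] = _repair(child, rng)
    return children


def _run_ga(ev: _Evaluator, budget: SearchBudget, rng: np.random.Generator) -> SelectionResult:
    n = ev.n_total
    pop = _init_population(n, budget.population_size, budget.init_density, rng)
    fits = [ev(m) for m in pop]
    best_i = int(np.argmax([fv.p for fv in fits]))
    best_mask, best_fit = pop[best_i].copy(), fits[best_i]
    trace = [best_fit.p]
    for _gen in range(budget.n_iterations):
        keys = np.array([-fv.p for fv in fits])
        children = _ga_variation(pop, keys, rng)
        children[0] = best_mask  # elitism
        pop = children
        fits = [ev(m) for m in pop]
        gen_best = int(np.argmax([fv.p for fv in fits]))
        if fits[gen_best].p > best_fit.p:
            best_mask, best_fit = pop[gen_best].copy(), fits[gen_best]
        trace.append(best_fit.p)
    return SelectionResult(
        method="GA", mask=best_mask, fitness=best_fit, trace=trace, seed=ev.spec.seed,
        n_evaluations=ev.n_evaluations,
    )


# ---------------------------------------------------------------------------
# NSGA-II (minimizes (n_selected, f)); reports the Pareto front
# ---------------------------------------------------------------------------

def _dominates(a: tuple, b: tuple) -> bool:
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))

def _nondominated_sort(objs: list[tuple]) -> list[list[int]]:
    n = len(objs)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = [0] * n
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if _dominates(objs[i], objs[j]):
                dominated_by[i].append(j)
            elif _dominates(objs[j], objs[i]):
                dom_count[i] += 1
        if dom_count[i] == 0:
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt = []
        for i in fronts[k]:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
        k += 1
    return [f for f in fronts if f]

def _crowding(objs: list[tuple], front: list[int]) -> dict[int, float]:
    dist = {i: 0.0 for i in front}
    m = len(objs[0])
    for d in range(m):
        ordered = sorted(front, key=lambda i: objs[i][d])
        lo, hi = objs[ordered[0]][d], objs[ordered[-1]][d]
        dist[ordered[0]] = dist[ordered[-1]] = float("inf")
        if hi == lo:
            continue
        for pos in range(1, len(ordered) - 1):
            dist[ordered[pos]] += (objs[ordered[pos + 1]][d] - objs[ordered[pos - 1]][d]) / (hi - lo)
    return dist


def _run_nsga2(ev: _Evaluator, budget: SearchBudget, rng: np.random.Generator) -> SelectionResult:
    n = ev.n_total

    def objectives(fv: FitnessValue) -> tuple[int, float]:
        return (fv.n_selected, fv.f)

    pop = _init_population(n, budget.population_size, budget.init_density, rng)
    fits = [ev(m) for m in pop]
    trace = [min(fv.f for fv in fits)]
    for _gen in range(budget.n_iterations):
        objs = [objectives(fv) for fv in fits]
        fronts = _nondominated_sort(objs)
        rank = np.empty(len(pop), dtype=int)
        crowd = np.empty(len(pop))
        for r, fr in enumerate(fronts):
            cd = _crowding(objs, fr)
            for i in fr:
                rank[i] = r
                crowd[i] = cd[i]
        # binary-tournament keys: lower rank, then higher crowding
        keys = np.array([rank[i] - 1e-9 * min(crowd[i], 1e6) for i in range(len(pop))])
        children = _ga_variation(pop, keys, rng)
        union = np.vstack([pop, children])
        union_fits = fits + [ev(m) for m in children]
        union_objs = [objectives(fv) for fv in union_fits]
        u_fronts = _nondominated_sort(union_objs)
        new_idx: list[int] = []
        for fr in u_fronts:
            if len(new_idx) + len(fr) <= budget.population_size:
                new_idx.extend(fr)
            else:
                cd = _crowding(union_objs, fr)
                room = budget.population_size - len(new_idx)
                new_idx.extend(sorted(fr, key=lambda i: -cd[i])[:room])
                break
        pop = union[new_idx]
        fits = [union_fits[i] for i in new_idx]
        trace.append(min(trace[-1], min(fv.f for fv in fits)))

    objs = [objectives(fv) for fv in fits]
    front_idx = _nondominated_sort(objs)[0]
    seen: set[bytes] = set()
    front = []
    for i in sorted(front_idx, key=lambda i: objs[i]):
        key = np.packbits(pop[i]).tobytes()
        if key not in seen:
            seen.add(key)
            front.append((pop[i].copy(), objs[i]))
    # designated solution: minimal combined objective, ties -> fewer features
    best_i = min(front_idx, key=lambda i: (fits[i].f, fits[i].n_selected))
    return SelectionResult(
        method="NSGA2", mask=pop[best_i].copy(), fitness=fits[best_i], trace=trace,
        seed=ev.spec.seed, n_evaluations=ev.n_evaluations, front=front,
    )


# ---------------------------------------------------------------------------
# binary PSO (minimizes f)
# ---------------------------------------------------------------------------

_PSO_W = 0.729
_PSO_C = 1.49445
_PSO_VCLAMP = 4.0


def _run_pso(ev: _Evaluator, budget: SearchBudget, rng: np.random.Generator) -> SelectionResult:
    n = ev.n_total
    swarm = budget.population_size
    bits = _init_population(n, swarm, budget.init_density, rng)
    # continuous positions consistent with the initial bits (sigmoid(x) > 0.5 <=> x > 0);
    # positions start well away from the threshold and velocities small, so the
    # sparse initialisation is not scrambled on the first update
    x = np.where(bits, rng.uniform(0.5, 1.5, (swarm, n)), rng.uniform(-1.5, -0.5, (swarm, n)))
    v = rng.uniform(-0.25, 0.25, (swarm, n))
    masks = [(_repair(row > 0, rng)) for row in x]
    fits = [ev(m) for m in masks]
    pbest_x = x.copy()
    pbest_f = np.array([fv.f for fv in fits])
    pbest_fit = list(fits)
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_fit = x[g].copy(), fits[g]
    gbest_mask = masks[g].copy()
    trace = [gbest_fit.f]
    for _it in range(budget.n_iterations):
        r1 = rng.random((swarm, n))
        r2 = rng.random((swarm, n))
        v = _PSO_W * v + _PSO_C * r1 * (pbest_x - x) + _PSO_C * r2 * (gbest_x - x)
        np.clip(v, -_PSO_VCLAMP, _PSO_VCLAMP, out=v)
        x = x + v
        for i in range(swarm):
            mask = _repair(x[i] > 0, rng)
            fv = ev(mask)
            if fv.f < pbest_f[i]:
                pbest_f[i] = fv.f
                pbest_x[i] = x[i]
                pbest_fit[i] = fv
            if fv.f < gbest_fit.f:
                gbest_fit = fv
                gbest_x = x[i].copy()
                gbest_mask = mask.copy()
        trace.append(gbest_fit.f)
    return SelectionResult(
        method="PSO", mask=gbest_mask, fitness=gbest_fit, trace=trace, seed=ev.spec.seed,
        n_evaluations=ev.n_evaluations,
    )


# ---------------------------------------------------------------------------
# simulated annealing (maximizes accuracy)
# ---------------------------------------------------------------------------

def _run_sa(
    ev: _Evaluator,
    budget: SearchBudget,
    rng: np.random.Generator,
    t0: float = 1.0,
    cooling: float = 0.95,
    proposal: str = "random_subset",
) -> SelectionResult:
    n = ev.n_total
    current = _repair(rng.random(n) < budget.init_density, rng)
    cur_fit = ev(current)
    best_mask, best_fit = current.copy(), cur_fit
    trace = [best_fit.p]
    temp = t0
    for _step in range(budget.sa_steps):
        if proposal == "flip":
            cand = current.copy()
            j = rng.integers(n)
            cand[j] = ~cand[j]
        elif proposal == "random_subset":
            cand = rng.random(n) < budget.init_density
        else:
            raise ValueError(f"unknown SA proposal {proposal!r}")
        cand = _repair(cand, rng)
        fv = ev(cand)
        delta = fv.p - cur_fit.p
        if delta >= 0 or rng.random() < np.exp(delta / max(temp, 1e-300)):
            current, cur_fit = cand, fv
            if cur_fit.p > best_fit.p:
                best_mask, best_fit = current.copy(), cur_fit
        trace.append(best_fit.p)
        temp *= cooling
    return SelectionResult(
        method="SA", mask=best_mask, fitness=best_fit, trace=trace, seed=ev.spec.seed,
        n_evaluations=ev.n_evaluations,
    )


# ---------------------------------------------------------------------------
# SFFS (maximizes accuracy; floating = conditional exclusion)
# ---------------------------------------------------------------------------

def _run_sffs(ev: _Evaluator, budget: SearchBudget) -> SelectionResult:
    n = ev.n_total
    cap = budget.sffs_max_features or n
    cap = min(cap, n)
    mask = np.zeros(n, dtype=bool)
    best_at_size: dict[int, float] = {0: -np.inf}
    best_mask_at_size: dict[int, np.ndarray] = {}
    cur_p = -np.inf
    best_mask, best_fit = None, None
    trace: list[float] = []
    while int(mask.sum()) < cap:
        # forward: best single addition (ties -> lowest column index)
        cand_best, cand_idx = -np.inf, -1
        for j in range(n):
            if mask[j]:
                continue
            trial = mask.copy()
            trial[j] = True
            p = ev(trial).p
            if p > cand_best:
                cand_best, cand_idx = p, j
        if cand_idx < 0 or cand_best <= cur_p:
            break  # no addition improves the criterion
        mask[cand_idx] = True
        cur_p = cand_best
        size = int(mask.sum())
        if cur_p > best_at_size.get(size, -np.inf):
            best_at_size[size] = cur_p
            best_mask_at_size[size] = mask.copy()
        if best_fit is None or cur_p > best_fit.p:
            best_mask, best_fit = mask.copy(), ev(mask)
        trace.append(best_fit.p)
        # floating: conditionally exclude while it beats the best of the smaller size
        while int(mask.sum()) > 2:
            size = int(mask.sum())
            drop_best, drop_idx = -np.inf, -1
            for j in np.nonzero(mask)[0]:
                trial = mask.copy()
                trial[j] = False
                p = ev(trial).p
                if p > drop_best:
                    drop_best, drop_idx = p, int(j)
            if drop_best > best_at_size.get(size - 1, -np.inf):
                mask[drop_idx] = False
                cur_p = drop_best
                best_at_size[size - 1] = cur_p
                best_mask_at_size[size - 1] = mask.copy()
                if cur_p > best_fit.p:
                    best_mask, best_fit = mask.copy(), ev(mask)
                trace.append(best_fit.p)
            else:
                break
    if best_fit is None:  # cap == 0 cannot happen (cap >= 1); defensive
        raise RuntimeError("SFFS made no step")
    return SelectionResult(
        method="SFFS", mask=best_mask, fitness=best_fit, trace=trace, seed=ev.spec.seed,
        n_evaluations=ev.n_evaluations,
    )


# ---------------------------------------------------------------------------
# dispatcher and exhaustive oracle
# ---------------------------------------------------------------------------

def run_feature_selection(
    method: str,
    table: FeatureTable,
    spec: ObjectiveSpec = ObjectiveSpec(),
    budget: SearchBudget = SearchBudget(),
) -> SelectionResult:
    """Run one wrapper selector; reproducible from ``spec.seed``.

    Criterion per method: GA, SA and SFFS maximize CV accuracy; PSO minimizes
    the combined objective; NSGA-II minimizes (n_selected, f) and designates
    the front member with minimal f (ties: fewer features).
    """
    if table.n_features < 2:
        raise ValueError("need at least 2 features to select from")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    ev = _Evaluator(table, spec)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(METHODS.index(method),)))
    if method == "GA":
        return _run_ga(ev, budget, rng)
    if method == "NSGA2":
        return _run_nsga2(ev, budget, rng)
    if method == "PSO":
        return _run_pso(ev, budget, rng)
    if method == "SA":
        return _run_sa(ev, budget, rng)
    return _run_sffs(ev, budget)


def exhaustive_best_subset(
    table: FeatureTable,
    spec: ObjectiveSpec = ObjectiveSpec(),
    max_features: int = 20,
) -> SelectionResult:
    """Evaluate every nonempty mask; the brute-force optimum for small tables.

    Deterministic tie-breaking: fewest selected features, then the smallest
    integer encoding of the mask (feature 0 = least-significant bit).
    """
    n = table.n_features
    if n > max_features:
        raise ValueError(
            f"{n} features means {2**n - 1} masks; refusing above max_features={max_features}"
        )
    ev = _Evaluator(table, spec)
    minimize_f = spec.criterion in ("combined", "multi_objective")
    best_key, best_mask, best_fit = None, None, None
    trace: list[float] = []
    for code in range(1, 2**n):
        mask = np.array([(code >> b) & 1 for b in range(n)], dtype=bool)
        fv = ev(mask)
        key = (fv.f if minimize_f else -fv.p, fv.n_selected, code)
        if best_key is None or key < best_key:
            best_key, best_mask, best_fit = key, mask, fv
        trace.append(best_fit.f if minimize_f else best_fit.p)
    return SelectionResult(
        method="EXHAUSTIVE", mask=best_mask, fitness=best_fit, trace=trace, seed=spec.seed,
        n_evaluations=ev.n_evaluations,
    )
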