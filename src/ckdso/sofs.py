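"""Binary snake-optimization wrapper feature selection.

The snake optimizer (SO) is a population metaheuristic: the swarm is split
into male and female halves, and each iteration is dispatched into one of
three behaviours by two scalar schedules — the food quantity
Q(n) = C exp((n - N)/N) and the temperature T(n) = exp(-n/N):

* Q < q_threshold          : exploration — each snake moves relative to a
  random same-sex snake, scaled by its food-finding ability
  Bs = exp(-f_rand / f_i) and the constant c2 = 0.05;
* Q >= q_threshold, T hot  : approach the best position found so far,
  scaled by c3 = 2 and T;
* Q >= q_threshold, T cold : fight — males move toward the best female and
  vice versa, scaled by the opponent-best fighting ability exp(-f_best/f_i).

Positions live in a continuous box [y_min, y_max]^d and are thresholded at
the midpoint into a binary feature mask; the wrapper objective is
omega * (1 - stratified-CV accuracy) + (1 - omega) * |mask| / d, minimised.
An elitist incumbent ("OptimalCKD") is kept across iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataio import DataMatrix

__all__ = [
    "SnakeParams",
    "SwarmState",
    "FeatureMask",
    "FitnessSpec",
    "RunHistory",
    "food_quantity",
    "temperature",
    "split_sexes",
    "food_ability",
    "init_swarm",
    "explore_step",
    "approach_food_step",
    "fight_step",
    "binarize",
    "subset_fitness",
    "make_cv_fitness",
    "optimize",
    "run_selection",
    "exhaustive_search",
]

_EPS = 1e-12  # fitness positivity floor for ability ratios


@dataclass
class SnakeParams:
    pop_size: int = 30
    iterations: int = 50
    c1: float = 0.5      # food-quantity constant C
    c2: float = 0.05     # exploration constant
    c3: float = 2.0      # approach/fight constant
    q_threshold: float = 0.25
    t_threshold: float = 0.6
    y_min: float = 0.0
    y_max: float = 1.0
    mate: bool = False   # optional mate step during the fight phase
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("pop_size must be an even integer >= 4")
        if not 0 < self.q_threshold < 1 or not 0 < self.t_threshold < 1:
            raise ValueError("thresholds must lie in (0, 1)")
        if self.y_min > self.y_max:
            raise ValueError("y_min must not exceed y_max")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")


@dataclass
class FeatureMask:
    bits: np.ndarray
    selected_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.sum() < 1:
            raise ValueError("a feature mask must select at least one feature")

    @property
    def size(self) -> int:
        return int(self.bits.sum())

    def key(self) -> tuple[int, ...]:
        return tuple(int(b) for b in self.bits)


@dataclass
class FitnessSpec:
    base_classifier: str = "extra_trees"
    cv_folds: int = 5
    cv_repeats: int = 1  # repeated CV damps fold-assignment noise
    omega: float = 0.99
    cache: bool = True
    cv_seed: int = 0
    n_estimators: int = 50  # for tree ensembles

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if not 0 < self.omega <= 1:
            raise ValueError("omega must be in (0, 1]")


@dataclass
class RunHistory:
    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    temperature: list[float] = field(default_factory=list)
    food_quantity: list[float] = field(default_factory=list)
    phase: list[str] = field(default_factory=list)
    mate_active: bool = False

    def record(self, best: float, mean: float, t: float, q: float, phase: str) -> None:
        self.best_fitness.append(best)
        self.mean_fitness.append(mean)
        self.temperature.append(t)
        self.food_quantity.append(q)
        self.phase.append(phase)


@dataclass
class SwarmState:
    positions: np.ndarray
    fitness: np.ndarray
    male_idx: np.ndarray
    female_idx: np.ndarray
    best_male: tuple[np.ndarray, float]
    best_female: tuple[np.ndarray, float]
    best_overall: tuple[np.ndarray, float]
    iteration: int
    rng: np.random.Generator


def food_quantity(n: int, N: int, c1: float = 0.5) -> float:
    """Q = C exp((n - N) / N); rises toward C as the run matures."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return c1 * math.exp((n - N) / N)


def temperature(n: int, N: int) -> float:
    """T = exp(-n / N); cools from 1 toward 1/e."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return math.exp(-n / N)


def split_sexes(num: int) -> tuple[np.ndarray, np.ndarray]:
    """First floor(Num/2) snakes are male, the rest female."""
    if num < 2:
        raise ValueError("population must have at least 2 snakes")
    half = num // 2
    return np.arange(half), np.arange(half, num)


def food_ability(f_rand: float, f_i: float) -> float:
    """Ability coefficient exp(-f_rand / f_i).

    Fitness values are shifted to be positive (by the more negative of the
    pair, plus an eps floor) before the ratio, and the exponent is clamped,
    so arbitrary objective scales cannot overflow.
    """
    shift = min(f_rand, f_i, 0.0)
    fr = f_rand - shift
    fi = max(f_i - shift, _EPS)
    return math.exp(max(-700.0, min(700.0, -fr / fi)))


def init_swarm(params: SnakeParams, d: int) -> SwarmState:
    """Uniform positions y_min + rand (y_max - y_min) from the seeded RNG."""
    if d < 1:
        raise ValueError("dimension must be >= 1")
    rng = np.random.default_rng(params.seed)
    span = params.y_max - params.y_min
    Y = params.y_min + rng.random((params.pop_size, d)) * span
    male, female = split_sexes(params.pop_size)
    nanv = np.full(d, np.nan)
    return SwarmState(
        positions=Y,
        fitness=np.full(params.pop_size, np.inf),
        male_idx=male,
        female_idx=female,
        best_male=(nanv.copy(), np.inf),
        best_female=(nanv.copy(), np.inf),
        best_overall=(nanv.copy(), np.inf),
        iteration=0,
        rng=rng,
    )


def _signs(rng: np.random.Generator, shape) -> np.ndarray:
    return np.where(rng.random(shape) < 0.5, 1.0, -1.0)


def _clip(Y: np.ndarray, params: SnakeParams) -> np.ndarray:
    return np.clip(Y, params.y_min, params.y_max)


def explore_step(state: SwarmState, params: SnakeParams) -> SwarmState:
    """Food-searching move relative to a random same-sex snake."""
    Y = state.positions
    n, d = Y.shape
    span = params.y_max - params.y_min
    new = Y.copy()
    for group in (state.male_idx, state.female_idx):
        for i in group:
            j = group[state.rng.integers(0, len(group))]
            bs = food_ability(state.fitness[j], state.fitness[i])
            rand = state.rng.random(d)
            sign = _signs(state.rng, d)
            new[i] = Y[j] + sign * params.c2 * bs * (span * rand + params.y_min)
    state.positions = _clip(new, params)
    return state


def approach_food_step(
    state: SwarmState, params: SnakeParams, t: float
) -> SwarmState:
    """Hot exploitation: move around the incumbent best position."""
    Y = state.positions
    food = state.best_overall[0]
    rand = state.rng.random(Y.shape)
    sign = _signs(state.rng, Y.shape)
    new = food + sign * params.c3 * t * rand * (food - Y)
    state.positions = _clip(new, params)
    return state


def fight_step(state: SwarmState, params: SnakeParams) -> SwarmState:
    """Cold exploitation: each sex fights toward the other sex's best."""
    Y = state.positions
    new = Y.copy()
    best_f_pos, best_f_fit = state.best_female
    best_m_pos, best_m_fit = state.best_male
    for i in state.male_idx:
        mf = food_ability(best_f_fit, state.fitness[i])
        rand = state.rng.random(Y.shape[1])
        sign = _signs(state.rng, Y.shape[1])
        new[i] = Y[i] + sign * params.c3 * mf * rand * (best_f_pos - Y[i])
    for i in state.female_idx:
        ff = food_ability(best_m_fit, state.fitness[i])
        rand = state.rng.random(Y.shape[1])
        sign = _signs(state.rng, Y.shape[1])
        new[i] = Y[i] + sign * params.c3 * ff * rand * (best_m_pos - Y[i])
    state.positions = _clip(new, params)
    if params.mate:
        _mate_step(state, params)
    return state


def _mate_step(state: SwarmState, params: SnakeParams) -> None:
    """Optional egg-laying: the worst same-sex snake is resampled uniformly."""
    if state.rng.random() >= 0.5:
        return
    span = params.y_max - params.y_min
    for group in (state.male_idx, state.female_idx):
        worst = group[np.argmax(state.fitness[group])]
        state.positions[worst] = (
            params.y_min + state.rng.random(state.positions.shape[1]) * span
        )
        state.fitness[worst] = np.inf


def binarize(
    position: np.ndarray,
    y_min: float = 0.0,
    y_max: float = 1.0,
    feature_names: Sequence[str] | None = None,
) -> FeatureMask:
    """Threshold a continuous position at the box midpoint into a mask.

    Components strictly above the midpoint are selected (a sigmoid centred
    on the midpoint crosses 0.5 exactly there); an all-empty mask falls
    back to selecting the maximal component.
    """
    position = np.asarray(position, dtype=float)
    mid = 0.5 * (y_min + y_max)
    bits = (position > mid).astype(int)
    if bits.sum() == 0:
        bits[int(np.argmax(position))] = 1
    names = (
        [feature_names[j] for j in np.flatnonzero(bits)]
        if feature_names is not None
        else []
    )
    return FeatureMask(bits=bits, selected_names=names)


# ----------------------------------------------------------------- fitness

def make_cv_fitness(
    data: DataMatrix, spec: FitnessSpec
) -> Callable[[FeatureMask], float]:
    """Wrapper objective: omega * CV error + (1 - omega) * subset ratio.

    Stratified k-fold accuracy of the base classifier on the selected
    columns; folds shrink automatically if a class is smaller than the fold
    count.  Results are memoised by mask bits when the spec enables caching.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    from .modeleval import build_classifier

    d = data.n_features
    cache: dict[tuple[int, ...], float] = {}
    neg, pos = data.class_counts()
    max_folds = min(spec.cv_folds, neg, pos)
    if max_folds < 2:
        raise ValueError("both classes need >= 2 members for CV fitness")

    def fitness(mask: FeatureMask) -> float:
        key = mask.key()
        if spec.cache and key in cache:
            return cache[key]
        Xs = data.X[:, mask.bits.astype(bool)]
        accs = []
        for rep in range(spec.cv_repeats):
            clf = build_classifier(
                spec.base_classifier, seed=spec.cv_seed,
                n_estimators=spec.n_estimators,
            )
            cv = StratifiedKFold(
                n_splits=max_folds, shuffle=True, random_state=spec.cv_seed + rep
            )
            accs.append(
                cross_val_score(clf, Xs, data.y, cv=cv, scoring="accuracy").mean()
            )
        acc = float(np.mean(accs))
        value = spec.omega * (1.0 - acc) + (1.0 - spec.omega) * mask.size / d
        if spec.cache:
            cache[key] = value
        return value

    fitness.cache = cache  # type: ignore[attr-defined]
    return fitness


def subset_fitness(
    mask: FeatureMask, data: DataMatrix, spec: FitnessSpec
) -> float:
    """One-off evaluation of the wrapper objective for a mask."""
    return make_cv_fitness(data, spec)(mask)


# ---------------------------------------------------------------- optimizer

def _evaluate(
    state: SwarmState,
    fitness_fn: Callable[[FeatureMask], float],
    params: SnakeParams,
    names: Sequence[str] | None,
) -> None:
    for i in range(state.positions.shape[0]):
        mask = binarize(state.positions[i], params.y_min, params.y_max, names)
        f = float(fitness_fn(mask))
        if not math.isfinite(f):
            raise RuntimeError(
                f"non-finite fitness {f!r} for mask {mask.bits.tolist()}"
            )
        state.fitness[i] = f
    for group, attr in (
        (state.male_idx, "best_male"),
        (state.female_idx, "best_female"),
    ):
        i = group[np.argmin(state.fitness[group])]
        if state.fitness[i] < getattr(state, attr)[1]:  # strict: ties keep old
            setattr(state, attr, (state.positions[i].copy(), float(state.fitness[i])))
    i = int(np.argmin(state.fitness))
    if state.fitness[i] < state.best_overall[1]:
        state.best_overall = (state.positions[i].copy(), float(state.fitness[i]))


def optimize(
    fitness_fn: Callable[[FeatureMask], float],
    d: int,
    params: SnakeParams,
    feature_names: Sequence[str] | None = None,
) -> tuple[FeatureMask, RunHistory, SwarmState]:
    """Run the snake dynamics against an arbitrary mask objective."""
    state = init_swarm(params, d)
    history = RunHistory(mate_active=params.mate)
    _evaluate(state, fitness_fn, params, feature_names)
    N = max(params.iterations, 1)
    for n in range(1, params.iterations + 1):
        state.iteration = n
        q = food_quantity(n, N, params.c1)
        t = temperature(n, N)
        if q < params.q_threshold:
            phase = "explore"
            explore_step(state, params)
        elif t > params.t_threshold:
            phase = "approach_food"
            approach_food_step(state, params, t)
        else:
            phase = "fight"
            fight_step(state, params)
        _evaluate(state, fitness_fn, params, feature_names)
        history.record(
            best=state.best_overall[1],
            mean=float(state.fitness.mean()),
            t=t,
            q=q,
            phase=phase,
        )
    best_mask = binarize(
        state.best_overall[0], params.y_min, params.y_max, feature_names
    )
    return best_mask, history, state


def run_selection(
    data: DataMatrix,
    params: SnakeParams | None = None,
    spec: FitnessSpec | None = None,
) -> tuple[FeatureMask, RunHistory]:
    """Select the best feature subset ("OptimalCKD") for a prepared matrix.

    The returned history carries the (minimised) objective trace; its
    quality complement 1 - objective is the convenient "higher is better"
    reading of the same incumbent.
    """
    params = params or SnakeParams()
    spec = spec or FitnessSpec()
    if data.n_features < 2:
        raise ValueError("feature selection needs at least 2 features")
    fitness_fn = make_cv_fitness(data, spec)
    mask, history, _ = optimize(
        fitness_fn, data.n_features, params, data.feature_names
    )
    return mask, history


def exhaustive_search(
    fitness_fn: Callable[[FeatureMask], float], d: int
) -> tuple[FeatureMask, float]:
    """Brute-force optimum over all 2^d - 1 non-empty masks (d <= 20)."""
    if d > 20:
        raise ValueError("exhaustive search is limited to d <= 20")
    best_mask, best_f = None, math.inf
    for code in range(1, 2**d):
        bits = np.array([(code >> j) & 1 for j in range(d)], dtype=int)
        f = float(fitness_fn(FeatureMask(bits=bits)))
        if f < best_f:
            best_mask, best_f = FeatureMask(bits=bits), f
    assert best_mask is not None
    return best_mask, best_f
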