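"""Improved grey wolf optimizer (IGWO): continuous minimisation core.

Grey wolf optimisation is a population metaheuristic in which the three
best solutions found so far — alpha, beta, delta — guide the movement of
every other search agent.  For a wolf at position Z and leader l at Z_l the
textbook update draws random coefficient vectors r1, r2 ~ U[0,1]^d and sets

    B = 2*a*r1 - a,   E = 2*r2,
    D_l = | E * Z_l - Z |,   cand_l = Z_l - B * D_l,

with the candidate position the arithmetic mean of the three per-leader
candidates; the exploration parameter a decays linearly from 2 to 0 over
the iteration budget.

Two improvements over plain GWO are implemented here:

* chaotic-map initialisation — initial positions come from ergodic chaotic
  sequences (logistic map by default) rather than uniform draws, spreading
  the initial pack over the search space;
* dual-candidate greedy updates — each non-leader wolf draws TWO
  independent candidate positions per iteration and moves only if the
  better of them improves its fitness, which combined with elitist
  global-best retention makes the best-fitness trace non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CHAOTIC_MAPS",
    "Wolf",
    "PackState",
    "chaotic_sequence",
    "init_pack",
    "candidate_position",
    "igwo_step",
    "igwo_minimize",
]


def _logistic(x):
    return 4.0 * x * (1.0 - x)


def _tent(x):
    return 2.0 * x if x < 0.5 else 2.0 * (1.0 - x)


def _singer(x):
    mu = 1.07
    return mu * (7.86 * x - 23.31 * x**2 + 28.75 * x**3 - 13.302875 * x**4)


def _pwlcm(x, p=0.4):
    if x < p:
        return x / p
    if x <= 0.5:  # inclusive: f(0.5) = 1, clipped by the caller's guard
        return (x - p) / (0.5 - p)
    return _pwlcm(1.0 - x, p)


CHAOTIC_MAPS = {
    "logistic": _logistic,
    "tent": _tent,
    "singer": _singer,
    "pwlcm": _pwlcm,
}

# Starting points the iteration never leaves (or leaves (0,1) from).
_FIXED_POINTS = {
    "logistic": (0.0, 0.25, 0.5, 0.75, 1.0),
    "tent": (0.0, 0.5, 1.0),
    "singer": (0.0, 1.0),
    "pwlcm": (0.0, 1.0),
}


def chaotic_sequence(map_name: str, x0: float, length: int) -> np.ndarray:
    """Iterate the named chaotic map from ``x0``, returning ``length`` values."""
    if map_name not in CHAOTIC_MAPS:
        raise ValueError(f"unknown chaotic map {map_name!r}")
    if not 0.0 < x0 < 1.0:
        raise ValueError("x0 must lie strictly in (0, 1)")
    if any(abs(x0 - fp) < 1e-12 for fp in _FIXED_POINTS[map_name]):
        raise ValueError(f"x0={x0} is a fixed point of the {map_name} map")
    f = CHAOTIC_MAPS[map_name]
    out = np.empty(max(length, 0))
    x = x0
    for k in range(length):
        x = f(x)
        x = min(max(x, 1e-12), 1.0 - 1e-12)  # numerical guard
        out[k] = x
    return out


@dataclass
class Wolf:
    """One search agent: a position and its (minimised) objective value."""

    position: np.ndarray
    fitness: float


@dataclass
class PackState:
    """The wolf pack plus bookkeeping for the linear a-schedule and elitism.

    Leaders (``alpha``/``beta``/``delta``) are views of the three best
    wolves by fitness; ``global_best`` is the best solution ever evaluated
    (elitist — its fitness never increases across iterations).
    """

    positions: np.ndarray          # (n_wolves, dim)
    fitnesses: np.ndarray          # (n_wolves,)
    bounds: np.ndarray             # (dim, 2)
    iteration: int
    max_iter: int
    best_position: np.ndarray = None
    best_fitness: float = np.inf
    leader_idx: np.ndarray = field(default=None)  # indices of alpha, beta, delta

    def __post_init__(self):
        self.rank()

    @property
    def a(self) -> float:
        return 2.0 * (1.0 - self.iteration / self.max_iter)

    @property
    def n_wolves(self) -> int:
        return self.positions.shape[0]

    def rank(self) -> None:
        order = np.argsort(self.fitnesses, kind="stable")
        self.leader_idx = order[:3]
        if self.fitnesses[order[0]] < self.best_fitness:
            self.best_fitness = float(self.fitnesses[order[0]])
            self.best_position = self.positions[order[0]].copy()

    def _wolf(self, i: int) -> Wolf:
        return Wolf(self.positions[i].copy(), float(self.fitnesses[i]))

    @property
    def alpha(self) -> Wolf:
        return self._wolf(self.leader_idx[0])

    @property
    def beta(self) -> Wolf:
        return self._wolf(self.leader_idx[1])

    @property
    def delta(self) -> Wolf:
        return self._wolf(self.leader_idx[2])

    @property
    def global_best(self) -> Wolf:
        return Wolf(self.best_position.copy(), self.best_fitness)


def _as_bounds(bounds, dim: int) -> np.ndarray:
    b = np.asarray(bounds, dtype=float)
    if b.ndim == 1:
        b = np.tile(b, (dim, 1))
    if b.shape != (dim, 2) or np.any(b[:, 0] >= b[:, 1]):
        raise ValueError("bounds must be (lo, hi) per dimension with lo < hi")
    return b


def _evaluate(fitness_fn, pos: np.ndarray) -> float:
    v = float(fitness_fn(pos))
    if not np.isfinite(v):
        raise ValueError(f"fitness function returned non-finite value at {pos}")
    return v


def init_pack(n_wolves: int, dim: int, bounds, fitness_fn,
              map_name: str = "logistic", seed: int = 0,
              max_iter: int = 100) -> PackState:
    """Chaotically initialise a pack and evaluate it.

    Each wolf gets an independent chaotic stream: its x0 is drawn from a
    seeded uniform (re-drawn if it lands on a fixed point), the stream is
    iterated ``dim`` times, and the values are scaled into the bounds.
    """
    if n_wolves < 4:
        raise ValueError("need at least 4 wolves (three leaders + followers)")
    if dim < 1:
        raise ValueError("dim must be >= 1")
    b = _as_bounds(bounds, dim)
    rng = np.random.default_rng(seed)
    fixed = _FIXED_POINTS[map_name] if map_name in _FIXED_POINTS else ()
    positions = np.empty((n_wolves, dim))
    for w in range(n_wolves):
        x0 = rng.uniform(1e-6, 1 - 1e-6)
        while any(abs(x0 - fp) < 1e-9 for fp in fixed):
            x0 = rng.uniform(1e-6, 1 - 1e-6)
        u = chaotic_sequence(map_name, x0, dim)
        positions[w] = b[:, 0] + u * (b[:, 1] - b[:, 0])
    fitnesses = np.array([_evaluate(fitness_fn, p) for p in positions])
    return PackState(positions=positions, fitnesses=fitnesses, bounds=b,
                     iteration=0, max_iter=max_iter)


def candidate_position(position: np.ndarray, leaders, a: float, rng,
                       bounds=None) -> np.ndarray:
    """One leader-guided candidate move for the wolf at ``position``.

    ``leaders`` is the (alpha, beta, delta) triple, best first; fresh
    r1/r2 coefficient vectors are drawn per leader.  The candidate is the
    mean of the three per-leader moves, clamped to ``bounds`` if given.
    """
    z = np.asarray(position, dtype=float)
    cands = np.empty((3, z.size))
    for i, leader in enumerate(leaders):
        zl = np.asarray(leader.position if isinstance(leader, Wolf) else leader,
                        dtype=float)
        if zl.shape != z.shape:
            raise ValueError("leader/wolf dimension mismatch")
        r1 = rng.random(z.size)
        r2 = rng.random(z.size)
        B = 2.0 * a * r1 - a
        E = 2.0 * r2
        D = np.abs(E * zl - z)
        cands[i] = zl - B * D
    out = cands.mean(axis=0)
    if bounds is not None:
        b = _as_bounds(bounds, z.size)
        out = np.clip(out, b[:, 0], b[:, 1])
    return out


def igwo_step(pack: PackState, fitness_fn, rng) -> PackState:
    """Advance the pack one iteration (in place) and return it.

    Each non-leader wolf draws two independent candidates (fresh coefficient
    vectors for each) and moves to the fitter of {current, first candidate,
    second candidate}; leaders are then re-ranked, the elitist global best
    updated and the exploration parameter a decayed.
    """
    a = pack.a
    leaders = (pack.alpha, pack.beta, pack.delta)  # snapshot at step start
    leader_set = set(pack.leader_idx.tolist())
    for w in range(pack.n_wolves):
        if w in leader_set:
            continue
        cand1 = candidate_position(pack.positions[w], leaders, a, rng,
                                   pack.bounds)
        cand2 = candidate_position(pack.positions[w], leaders, a, rng,
                                   pack.bounds)
        f1 = _evaluate(fitness_fn, cand1)
        f2 = _evaluate(fitness_fn, cand2)
        if f1 <= f2 and f1 < pack.fitnesses[w]:
            pack.positions[w], pack.fitnesses[w] = cand1, f1
        elif f2 < f1 and f2 < pack.fitnesses[w]:
            pack.positions[w], pack.fitnesses[w] = cand2, f2
    pack.iteration += 1
    pack.rank()
    return pack


def igwo_minimize(fitness_fn, dim: int, bounds, n_wolves: int = 30,
                  max_iter: int = 100, map_name: str = "logistic",
                  seed: int = 0):
    """Minimise ``fitness_fn`` over a box; returns (position, fitness, trace).

    ``trace`` holds the global-best fitness after each iteration and is
    non-increasing by elitism.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x16F0]))
    pack = init_pack(n_wolves, dim, bounds, fitness_fn, map_name=map_name,
                     seed=seed, max_iter=max_iter)
    trace = np.empty(max_iter)
    for t in range(max_iter):
        igwo_step(pack, fitness_fn, rng)
        trace[t] = pack.best_fitness
    return pack.best_position, pack.best_fitness, trace
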