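"""Chimp Optimization Algorithm (ChOA).

A population metaheuristic modelled on the cooperative hunt of a chimp
troop.  The four best solutions found so far play the roles attacker,
barrier, chaser and driver; every other candidate moves toward a
coefficient-weighted blend of the four.  For each leader k the update is

    d_k = | c_k * x_leader_k  -  m_k * x |
    X_k = x_leader_k - a_k * d_k,            x(t+1) = mean_k X_k

with per-dimension coefficients a = 2 f r1 - f (r1 ~ U[0,1]),
c = 2 r2 (r2 ~ U[0,1]) and m drawn from a chaotic map.  The control
scalar f decays linearly from 2.5 to 0 over the run, moving the swarm
from exploration (|a| can exceed 1) to exploitation (|a| < 1, chimps
converge on the leaders).  With probability 1/2 a chimp instead jumps to
a chaotic remap of the search box — the "social motivation" branch that
keeps the population from collapsing early.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import CoaT2FcmError, InvalidArgumentError

__all__ = [
    "ChaoticMap",
    "ChaosStream",
    "ChoaParams",
    "ChimpPopulation",
    "CoefficientSet",
    "chaotic_step",
    "f_schedule",
    "draw_coefficients",
    "leader_guided_position",
    "update_chimp",
    "choa_optimize",
]


class ChaoticMap(enum.Enum):
    LOGISTIC = "logistic"
    TENT = "tent"
    SINE = "sine"


def chaotic_step(map_id: ChaoticMap, state: float) -> float:
    """One step of the chosen chaotic map on [0, 1]."""
    if not 0.0 <= state <= 1.0:
        raise InvalidArgumentError("chaotic state must lie in [0, 1]")
    if map_id is ChaoticMap.LOGISTIC:
        return 4.0 * state * (1.0 - state)
    if map_id is ChaoticMap.TENT:
        return 2.0 * state if state < 0.5 else 2.0 * (1.0 - state)
    return float(np.sin(np.pi * state))


class ChaosStream:
    """A mutable chaotic sequence: holds the map and the current state.

    Default initial state 0.7 avoids the logistic map's fixed points
    (0 and 0.75).
    """

    def __init__(self, map_id: ChaoticMap = ChaoticMap.LOGISTIC, state: float = 0.7):
        if not 0.0 <= state <= 1.0:
            raise InvalidArgumentError("chaotic state must lie in [0, 1]")
        self.map_id = map_id
        self.state = float(state)

    def next(self, n: int = 1) -> np.ndarray:
        out = np.empty(n)
        for i in range(n):
            self.state = chaotic_step(self.map_id, self.state)
            out[i] = self.state
        return out


@dataclass(frozen=True)
class ChoaParams:
    """Run parameters for :func:`choa_optimize`.

    ``bounds`` is a sequence of (low, high) pairs, one per dimension.
    ``f_start``/``f_end`` give the linear exploration schedule (2.5 -> 0
    by default); ``mu_threshold`` splits leader-guided vs chaotic moves.
    ``opposition_init`` additionally evaluates the box-mirrored image of
    every initial chimp and keeps the better half of the joint pool.
    """

    bounds: Sequence[tuple[float, float]]
    pop_size: int = 30
    iterations: int = 100
    f_start: float = 2.5
    f_end: float = 0.0
    mu_threshold: float = 0.5
    chaotic_map: ChaoticMap = ChaoticMap.LOGISTIC
    chaos_init: float = 0.7
    seed: int = 0
    opposition_init: bool = False

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise InvalidArgumentError("pop_size must be >= 4 (four leader roles)")
        if self.iterations < 1:
            raise InvalidArgumentError("iterations must be >= 1")
        if self.f_start < self.f_end:
            raise InvalidArgumentError("f_start must be >= f_end")
        if not 0.0 <= self.mu_threshold <= 1.0:
            raise InvalidArgumentError("mu_threshold must lie in [0, 1]")
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2 or (b[:, 0] >= b[:, 1]).any():
            raise InvalidArgumentError("bounds must be (low < high) pairs")

    @property
    def bounds_array(self) -> np.ndarray:
        return np.asarray(self.bounds, dtype=float)


@dataclass
class ChimpPopulation:
    """Positions, fitnesses and the four ranked leaders."""

    positions: np.ndarray  # (P, D)
    fitnesses: np.ndarray  # (P,)
    leader_positions: np.ndarray = field(default=None)  # (4, D)
    leader_fitnesses: np.ndarray = field(default=None)  # (4,)

    ROLES = ("attacker", "barrier", "chaser", "driver")

    def update_leaders(self) -> None:
        """Merge current members into the all-time four best."""
        pos = self.positions
        fit = self.fitnesses
        if self.leader_positions is not None:
            pos = np.vstack([self.leader_positions, pos])
            fit = np.concatenate([self.leader_fitnesses, fit])
        best = np.argsort(fit, kind="stable")[:4]
        self.leader_positions = pos[best].copy()
        self.leader_fitnesses = fit[best].copy()

    @property
    def best_ever(self) -> tuple[np.ndarray, float]:
        return self.leader_positions[0], float(self.leader_fitnesses[0])


@dataclass(frozen=True)
class CoefficientSet:
    """One leader's per-dimension coefficient vectors (a, c, m)."""

    a_vec: np.ndarray
    c_vec: np.ndarray
    m_vec: np.ndarray


def f_schedule(t: int, t_max: int, f_start: float = 2.5, f_end: float = 0.0) -> float:
    """Linear decay of the exploration coefficient from f_start to f_end."""
    if t_max < 1 or not 0 <= t <= t_max:
        raise InvalidArgumentError("need 0 <= t <= t_max, t_max >= 1")
    return f_start + (f_end - f_start) * t / t_max


def draw_coefficients(
    f: float, chaos: ChaosStream, rng: np.random.Generator, dim: int
) -> CoefficientSet:
    """Draw a = 2 f r1 - f, c = 2 r2 and chaotic m, per dimension."""
    if f < 0:
        raise InvalidArgumentError("f must be >= 0")
    r1 = rng.uniform(0.0, 1.0, size=dim)
    r2 = rng.uniform(0.0, 1.0, size=dim)
    return CoefficientSet(
        a_vec=2.0 * f * r1 - f,
        c_vec=2.0 * r2,
        m_vec=chaos.next(dim),
    )


def leader_guided_position(
    x: np.ndarray,
    leader_positions: np.ndarray,
    f: float,
    rng: np.random.Generator,
    chaos: ChaosStream,
) -> np.ndarray:
    """Move toward the mean of the four leader-attracted targets.

    Coefficients are drawn independently per leader; at f = 0 every
    a-vector vanishes and the result is exactly the leader mean.
    """
    x = np.asarray(x, dtype=float)
    targets = np.empty((4, x.shape[0]))
    for k in range(4):
        cs = draw_coefficients(f, chaos, rng, x.shape[0])
        d_k = np.abs(cs.c_vec * leader_positions[k] - cs.m_vec * x)
        targets[k] = leader_positions[k] - cs.a_vec * d_k
    return targets.mean(axis=0)


def update_chimp(
    x: np.ndarray,
    leader_positions: np.ndarray,
    f: float,
    mu: float,
    bounds: np.ndarray,
    rng: np.random.Generator,
    chaos: ChaosStream,
    mu_threshold: float = 0.5,
) -> np.ndarray:
    """One position update: leader-guided if mu < threshold, else a
    chaotic remap of the box; always clipped to bounds."""
    low, high = bounds[:, 0], bounds[:, 1]
    # mu exactly at the threshold takes the leader-guided branch
    if mu <= mu_threshold:
        new = leader_guided_position(x, leader_positions, f, rng, chaos)
    else:
        new = low + chaos.next(low.shape[0]) * (high - low)
    return np.clip(new, low, high)


def _evaluate(fitness: Callable[[np.ndarray], float], pos: np.ndarray) -> np.ndarray:
    out = np.empty(pos.shape[0])
    for i, p in enumerate(pos):
        val = float(fitness(p))
        if not np.isfinite(val):
            raise CoaT2FcmError(f"non-finite fitness {val!r} at position {p.tolist()}")
        out[i] = val
    return out


def choa_optimize(
    fitness: Callable[[np.ndarray], float],
    params: ChoaParams,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Minimize ``fitness`` over the bounded box.

    Returns ``(best position, best fitness, trace)`` where ``trace`` has
    one best-so-far value per iteration (including the initial
    population as entry 0) and is non-increasing by construction: the
    four leaders are the four best solutions *ever* evaluated.
    """
    rng = np.random.default_rng(params.seed)
    chaos = ChaosStream(params.chaotic_map, params.chaos_init)
    b = params.bounds_array
    low, high = b[:, 0], b[:, 1]
    dim = b.shape[0]

    pos = rng.uniform(low, high, size=(params.pop_size, dim))
    if params.opposition_init:
        mirrored = low + high - pos
        both = np.vstack([pos, mirrored])
        fit_both = _evaluate(fitness, both)
        keep = np.argsort(fit_both, kind="stable")[: params.pop_size]
        pos = both[keep]
        fit = fit_both[keep]
    else:
        fit = _evaluate(fitness, pos)

    popn = ChimpPopulation(positions=pos, fitnesses=fit)
    popn.update_leaders()
    trace = [popn.best_ever[1]]

    for t in range(1, params.iterations + 1):
        f = f_schedule(t, params.iterations, params.f_start, params.f_end)
        new_pos = np.empty_like(popn.positions)
        for i in range(params.pop_size):
            mu = rng.uniform(0.0, 1.0)
            new_pos[i] = update_chimp(
                popn.positions[i],
                popn.leader_positions,
                f,
                mu,
                b,
                rng,
                chaos,
                params.mu_threshold,
            )
        popn.positions = new_pos
        popn.fitnesses = _evaluate(fitness, new_pos)
        popn.update_leaders()
        trace.append(popn.best_ever[1])

    best_pos, best_fit = popn.best_ever
    return best_pos.copy(), best_fit, np.asarray(trace)
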