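"""Goal functions, evaluation grids and the composite fitness score.

A transcriptional gate maps one or two input TF concentrations to a
steady-state output concentration.  Gates are scored against predefined
goal functions on fixed evaluation grids:

* logic gates (AND, OR, NOR, NAND with two inputs; ACT, IN with one) take
  goal value 0 or 1000 nM according to their truth table, with inputs
  above the 500 nM threshold counting as "high";
* linear gates respond gradually: LACT -> c1, LIN -> 1000 - c1,
  MEAN -> (c1 + c2)/2, NMEAN -> 1000 - (c1 + c2)/2.

The response-function deviation E_RF is the sum over the grid of the
squared differences between the realized steady states and the goal (in
units of c0^2 with c0 = 1 nM), plus the bistability penalty.  Optional
terms score the total response time E_RT (sum over grid points and the two
extreme initial conditions) and the total intrinsic-noise magnitude E_N.
The total fitness is S = S0 - E_RF - lambda_RT(t) * E_RT - lambda_N(t) * E_N
with the lambda weights ramped in slowly over the evolutionary cycles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .response_dynamics import (
    MarginalStabilityError,
    ModelSet,
    NonConvergenceError,
    ResponsePolynomial,
    ResponseSurface,
    intrinsic_noise_sd_rp,
    response_polynomial,
    response_time_rp,
)

__all__ = [
    "GateSpec",
    "GATES",
    "EvaluationGrid",
    "FitnessWeights",
    "goal_function",
    "fitness_rf",
    "fitness_rt",
    "fitness_noise",
    "lambda_ramp",
    "fitness_total",
]

INPUT_DOMAIN = (0.0, 1000.0)
LOGIC_THRESHOLD = 500.0  # nM; >= threshold counts as "high"
GOAL_LOW = 0.0
GOAL_HIGH = 1000.0

#: truth tables over (tf1_high, tf2_high) -> output high?
_TRUTH = {
    "AND": lambda a, b: a & b,
    "OR": lambda a, b: a | b,
    "NOR": lambda a, b: ~(a | b),
    "NAND": lambda a, b: ~(a & b),
    "ACT": lambda a, b: a,
    "IN": lambda a, b: ~a,
}


@dataclass(frozen=True)
class GateSpec:
    """One of the ten gate types with its goal function metadata."""

    name: str

    _ARITY = {
        "AND": 2, "OR": 2, "NOR": 2, "NAND": 2, "MEAN": 2, "NMEAN": 2,
        "ACT": 1, "IN": 1, "LACT": 1, "LIN": 1,
    }

    def __post_init__(self) -> None:
        if self.name not in self._ARITY:
            raise ValueError(f"unknown gate {self.name!r}")

    @property
    def arity(self) -> int:
        return self._ARITY[self.name]

    @property
    def is_logic(self) -> bool:
        return self.name in _TRUTH


GATES = tuple(GateSpec(name) for name in GateSpec._ARITY)


@dataclass(frozen=True)
class EvaluationGrid:
    """Input concentrations at which gates are scored.

    Two-input gates use the 4x4 Cartesian product of {125, 375, 625, 875}
    nM (two concentrations per logic class, symmetric about the 500 nM
    threshold); one-input gates use seven equally spaced values on
    [0, 1000] nM.  The four footprint corner conditions are the extreme
    combinations {0, 1000}^2.
    """

    two_input_values: tuple[float, ...] = (125.0, 375.0, 625.0, 875.0)
    one_input_points: int = 7

    def points(self, gate: GateSpec) -> tuple[np.ndarray, np.ndarray]:
        """(c1, c2) arrays for the gate's grid; c2 = 0 for one-input gates."""
        if gate.arity == 2:
            v = np.asarray(self.two_input_values)
            c1, c2 = np.meshgrid(v, v, indexing="ij")
            return c1.ravel(), c2.ravel()
        c1 = np.linspace(*INPUT_DOMAIN, self.one_input_points)
        return c1, np.zeros_like(c1)

    def corners(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = INPUT_DOMAIN
        v = np.array([lo, lo, hi, hi]), np.array([lo, hi, lo, hi])
        return v


def goal_function(gate: GateSpec, c1, c2=0.0):
    """Goal output (nM) of a gate at input concentrations in [0, 1000]."""
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    lo, hi = INPUT_DOMAIN
    if np.any((c1 < lo) | (c1 > hi)) or np.any((c2 < lo) | (c2 > hi)):
        raise ValueError(f"inputs must lie in [{lo}, {hi}] nM")
    if gate.is_logic:
        a = c1 >= LOGIC_THRESHOLD
        b = c2 >= LOGIC_THRESHOLD
        return np.where(_TRUTH[gate.name](a, b), GOAL_HIGH, GOAL_LOW)
    if gate.name == "LACT":
        return c1.copy()
    if gate.name == "LIN":
        return GOAL_HIGH - c1
    if gate.name == "MEAN":
        return 0.5 * (c1 + c2)
    if gate.name == "NMEAN":
        return GOAL_HIGH - 0.5 * (c1 + c2)
    raise AssertionError(gate.name)  # unreachable


@dataclass(frozen=True)
class FitnessWeights:
    """Weights of the composite fitness S = S0 - E_RF - l_RT*E_RT - l_N*E_N.

    ``s0`` is an arbitrary offset large enough to keep all realized scores
    positive; ``c0`` (nM) makes E_RF dimensionless; the lambda weights ramp
    linearly from 0 to their maxima over ``t_ramp`` evolutionary cycles.
    """

    s0: float = 1e8
    c0: float = 1.0
    lambda_rt_max: float = 0.0
    lambda_noise_max: float = 0.0
    t_ramp: int = 200

    def __post_init__(self) -> None:
        if self.s0 <= 0 or self.c0 <= 0:
            raise ValueError("s0 and c0 must be positive")
        if self.lambda_rt_max < 0 or self.lambda_noise_max < 0:
            raise ValueError("lambda weights must be >= 0")
        if self.t_ramp < 1:
            raise ValueError("t_ramp must be >= 1")


def fitness_rf(surface: ResponseSurface, gate: GateSpec, c0: float = 1.0) -> float:
    """Response-function deviation E_RF (dimensionless).

    Sum over the grid of (c3* - goal)^2 / c0^2, plus the bistability
    penalty accumulated on the surface.  Non-finite surface points (failed
    dynamics) yield inf, i.e. the worst possible score.
    """
    goal = goal_function(gate, surface.c1, surface.c2)
    dev = (surface.output - goal) / c0
    total = float(np.sum(dev**2) + np.sum(surface.penalty) / c0**2)
    return total if np.isfinite(total) else float("inf")


def _grid_polynomials(system, models: ModelSet, gate: GateSpec, grid: EvaluationGrid):
    c1, c2 = grid.points(gate)
    return [(response_polynomial(system, a, b, models)) for a, b in zip(c1, c2)]


def fitness_rt(system, models: ModelSet, gate: GateSpec, grid: EvaluationGrid) -> float:
    """Total response time E_RT (tau0): all grid points x both initial states."""
    total = 0.0
    for rp in _grid_polynomials(system, models, gate, grid):
        for c3_init in (0.0, models.dynamics.c_max):
            try:
                total += response_time_rp(rp, c3_init)
            except NonConvergenceError:
                return float("inf")
    return total


def fitness_noise(system, models: ModelSet, gate: GateSpec, grid: EvaluationGrid) -> float:
    """Total intrinsic-noise magnitude E_N (nM) over the evaluation grid."""
    total = 0.0
    for rp in _grid_polynomials(system, models, gate, grid):
        try:
            total += intrinsic_noise_sd_rp(rp)
        except (NonConvergenceError, MarginalStabilityError):
            return float("inf")
    return total


def lambda_ramp(t: int, lambda_max: float, t_ramp: int) -> float:
    """Selection-pressure ramp: linear from 0 to lambda_max over t_ramp cycles.

    Starting the dynamical selection pressures at zero keeps early
    populations from being trapped in the dysfunctional all-off optimum.
    """
    if t < 0:
        raise ValueError("cycle index must be >= 0")
    return lambda_max * min(t / t_ramp, 1.0)


def fitness_total(
    e_rf: float, e_rt: float, e_n: float, weights: FitnessWeights, t: int
) -> float:
    """Composite fitness S = S0 - E_RF - l_RT(t)*E_RT - l_N(t)*E_N.

    Error-flagged components (inf) give S = -inf, the worst possible score,
    rather than aborting.  A finite non-positive S means S0 was chosen too
    small and raises.
    """
    if min(e_rf, e_rt, e_n) < 0:
        raise ValueError("fitness components must be >= 0")
    l_rt = lambda_ramp(t, weights.lambda_rt_max, weights.t_ramp)
    l_n = lambda_ramp(t, weights.lambda_noise_max, weights.t_ramp)
    s = weights.s0 - e_rf - l_rt * e_rt - l_n * e_n
    if s == float("-inf"):
        return s
    if s <= 0:
        raise ValueError(
            f"fitness S = {s:.3g} <= 0: S0 = {weights.s0:.3g} is too small"
        )
    return s
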