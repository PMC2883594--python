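"""Dynamics of the auto-regulated output gene.

The output concentration follows the birth-death equation

    dc3/dt = beta * P_on(c1, c2, c3) - mu * c3,

where ``P_on`` is the equilibrium promoter occupancy.  With the partition
sums represented as polynomials in ``c3`` (see ``thermodynamic_model``),
the steady-state condition becomes a polynomial root problem:

    h(c) = beta * Z_on(c) - mu * c * (Z_on + Z_off)(c) = 0,

and because both partition sums are positive, ``sign(dc3/dt) = sign(h)``.
Trajectories of the one-dimensional ODE are monotone, so the limit point
reached from any initial condition is the nearest stable root in the flow
direction; roots are located by a dense sign-change scan refined by
bisection, which satisfies the steady-state residual contract exactly.
Time courses (for response times) are integrated explicitly.

Intrinsic noise is treated in the small-noise (linear-noise) approximation
of the birth-death process: with production ``f(c3) = beta * P_on`` and
first derivative ``f'`` at the stable fixed point, the stationary standard
deviation of ``c3`` is ``sigma = sqrt(mu * c3* / (V * (mu - f')))``, which
reduces to the Poisson copy-number result ``sqrt(c3*/V)`` for a
constitutive gene and diverges as the restoring force ``mu - f'``
vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .thermodynamic_model import SiteTable, partition_polynomials, polyval_batch

__all__ = [
    "DynamicsParams",
    "ResponsePolynomial",
    "ResponseSurface",
    "NonConvergenceError",
    "MarginalStabilityError",
    "steady_state",
    "detect_bistability",
    "bistability_scan",
    "response_time",
    "intrinsic_noise_sd",
    "response_surface",
]


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the output-gene dynamics.

    beta : maximal production rate, nM per time unit tau0.
    mu : degradation rate constant, 1/tau0 (time is measured in units of
        the TF3 lifetime, so mu = 1 by default; absolute time scales are
        irrelevant to the fitness measures).
    c_max = beta/mu bounds the output to [0, c_max] (default 1000 nM, the
        upper edge of the input domain).
    eps_ss : steady-state tolerance, nM.
    eps_rt : response-time proximity threshold, nM.
    t_max : integration-time limit, tau0.
    volume : conversion from concentration to copy number, molecules/nM.
    """

    beta: float = 1000.0
    mu: float = 1.0
    eps_ss: float = 0.1
    eps_rt: float = 1.0
    t_max: float = 200.0
    rtol: float = 1e-6
    volume: float = 1.0
    n_grid: int = 256

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.mu <= 0:
            raise ValueError("beta and mu must be positive")
        if self.eps_ss <= 0 or self.eps_rt <= 0 or self.t_max <= 0:
            raise ValueError("tolerances and time limits must be positive")
        if self.volume <= 0:
            raise ValueError("volume factor must be positive")

    @property
    def c_max(self) -> float:
        return self.beta / self.mu


class NonConvergenceError(RuntimeError):
    """The dynamics did not reach a steady state within the time limit."""


class MarginalStabilityError(RuntimeError):
    """The restoring force mu - f' is not positive at the fixed point."""


class ResponsePolynomial:
    """P_on as a function of c3 at one fixed input point (c1, c2).

    Wraps the polynomial coefficients of Z_on and Z_off and exposes the
    occupancy, the production rate and the steady-state root structure.
    """

    def __init__(self, zon: np.ndarray, zoff: np.ndarray, dyn: DynamicsParams):
        self.zon = np.asarray(zon, dtype=float)
        self.zoff = np.asarray(zoff, dtype=float)
        self.dyn = dyn
        # h(c) = beta*zon(c) - mu*c*(zon+zoff)(c); deg(h) = deg(z) + 1
        ztot = self.zon + self.zoff
        h = np.zeros(ztot.shape[0] + 1)
        h[: self.zon.shape[0]] += dyn.beta * self.zon
        h[1:] -= dyn.mu * ztot
        self.h_coeffs = h
        self._finite = bool(np.all(np.isfinite(h)))

    @classmethod
    def from_table(
        cls, table: SiteTable, c1: float, c2: float, dyn: DynamicsParams
    ) -> "ResponsePolynomial":
        zon, zoff = partition_polynomials(table, c1, c2)
        return cls(zon[0], zoff[0], dyn)

    def p_on(self, c3):
        zon = polyval_batch(self.zon, c3)
        zoff = polyval_batch(self.zoff, c3)
        return zon / (zon + zoff)

    def production(self, c3):
        """f(c3) = beta * P_on(c3), nM/tau0."""
        return self.dyn.beta * self.p_on(c3)

    def velocity(self, c3):
        """dc3/dt = f(c3) - mu*c3."""
        return self.production(c3) - self.dyn.mu * np.asarray(c3, dtype=float)

    def h(self, c3):
        return polyval_batch(self.h_coeffs, c3)

    # -- root structure ---------------------------------------------------

    def _scan_grid(self, n: int | None = None) -> np.ndarray:
        n = n or self.dyn.n_grid
        c_max = self.dyn.c_max
        # geometric spacing resolves low fixed points (nM scale), a linear
        # tail guards against uneven coverage near c_max
        lo = np.geomspace(c_max * 1e-5, c_max, n)
        lin = np.linspace(0.0, c_max, n // 2)
        return np.unique(np.concatenate([[0.0], lo, lin]))

    def stable_roots(self, n_grid: int | None = None) -> list[float]:
        """All stable fixed points in [0, c_max] (sign scan + bisection)."""
        if not self._finite:
            raise NonConvergenceError("partition sums overflowed")
        grid = self._scan_grid(n_grid)
        hv = self.h(grid)
        roots: list[float] = []
        # stable roots are + -> - crossings of h (and exact-zero plateaus)
        for i in range(len(grid) - 1):
            if hv[i] > 0 >= hv[i + 1]:
                roots.append(self._bisect(grid[i], grid[i + 1]))
        if hv[0] == 0.0 and (len(hv) < 2 or hv[1] < 0):
            roots.insert(0, float(grid[0]))
        if not roots:
            # h(0) >= 0 and h(c_max) <= 0 guarantee at least one crossing;
            # a fully flat h (q_r == 0 with empty region) roots at 0
            roots.append(0.0 if hv[0] <= 0 else float(self.dyn.c_max))
        return roots

    def _bisect(self, lo: float, hi: float) -> float:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if self.h(mid) > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def settle(self, c3_init: float) -> float:
        """Limit point of the ODE started from ``c3_init``."""
        if not self._finite:
            raise NonConvergenceError("partition sums overflowed")
        c_max = self.dyn.c_max
        if not 0 <= c3_init <= c_max:
            raise ValueError(f"c3_init must lie in [0, {c_max}]")
        h0 = float(self.h(c3_init))
        grid = self._scan_grid()
        hv = self.h(grid)
        if h0 > 0:  # flow upward: first + -> - crossing above c3_init
            for i in range(len(grid) - 1):
                if grid[i + 1] <= c3_init:
                    continue
                lo = max(grid[i], c3_init)
                if self.h(lo) > 0 >= hv[i + 1]:
                    return self._bisect(lo, grid[i + 1])
            return c_max
        if h0 < 0:  # flow downward: nearest crossing below c3_init
            for i in range(len(grid) - 2, -1, -1):
                if grid[i] >= c3_init:
                    continue
                hi = min(grid[i + 1], c3_init)
                if hv[i] > 0 >= self.h(hi):
                    return self._bisect(grid[i], hi)
            return 0.0
        return float(c3_init)


def response_polynomial(system, c1: float, c2: float, models) -> ResponsePolynomial:
    """Helper used by the higher-level modules; accepts Genotype or SiteTable."""
    table = models.site_table(system) if not isinstance(system, SiteTable) else system
    return ResponsePolynomial.from_table(table, c1, c2, models.dynamics)


def steady_state_rp(rp: ResponsePolynomial, c3_init: float) -> float:
    """Steady state reached from ``c3_init``; satisfies |f - mu*c| < mu*eps_ss."""
    c_star = rp.settle(c3_init)
    residual = abs(float(rp.velocity(c_star)))
    if residual >= rp.dyn.mu * rp.dyn.eps_ss:
        raise NonConvergenceError(
            f"steady-state residual {residual:.3g} exceeds tolerance"
        )
    return c_star


def detect_bistability_rp(rp: ResponsePolynomial) -> tuple[float, float, float]:
    """Steady states from c3 = 0 and c3 = c_max, plus the bistability penalty.

    The penalty is ``(ss_high - ss_low)^2 / c0^2`` (c0 = 1 nM) whenever the
    two limits differ by more than the steady-state tolerance, else 0.
    """
    ss_low = steady_state_rp(rp, 0.0)
    ss_high = steady_state_rp(rp, rp.dyn.c_max)
    if abs(ss_high - ss_low) > rp.dyn.eps_ss:
        penalty = (ss_high - ss_low) ** 2  # / c0^2 with c0 = 1 nM
    else:
        penalty = 0.0
    return ss_low, ss_high, penalty


def bistability_scan_rp(rp: ResponsePolynomial, n_grid: int = 256) -> list[float]:
    """All stable fixed points on a dense grid (refined by bisection)."""
    if n_grid < 100:
        raise ValueError("n_grid must be >= 100")
    return rp.stable_roots(n_grid)


def response_time_rp(rp: ResponsePolynomial, c3_init: float) -> float:
    """First time (tau0) at which |c3(t) - c3*| < eps_rt, integrating the ODE."""
    c_star = steady_state_rp(rp, c3_init)
    eps = rp.dyn.eps_rt
    if abs(c3_init - c_star) < eps:
        return 0.0

    def rhs(_t, y):
        return [float(rp.velocity(y[0]))]

    def event(_t, y):
        return abs(y[0] - c_star) - eps

    event.terminal = True
    event.direction = -1
    sol = solve_ivp(
        rhs,
        (0.0, rp.dyn.t_max),
        [c3_init],
        events=event,
        rtol=min(rp.dyn.rtol, 1e-8),
        atol=1e-9,
        max_step=rp.dyn.t_max / 50,
    )
    if sol.t_events[0].size == 0:
        raise NonConvergenceError("response time exceeded the integration limit")
    return float(sol.t_events[0][0])


def production_derivatives(rp: ResponsePolynomial, c_star: float, step: float = 0.1):
    """(f', f'') of the production rate at c_star by central differences."""
    lo = max(c_star - step, 0.0)
    hi = c_star + step
    f_lo, f_mid, f_hi = (float(rp.production(c)) for c in (lo, c_star, hi))
    span = hi - lo
    f1 = (f_hi - f_lo) / span
    f2 = (f_hi - 2.0 * f_mid + f_lo) / (0.5 * span) ** 2
    return f1, f2


def intrinsic_noise_sd_rp(rp: ResponsePolynomial, c3_init: float = 0.0) -> float:
    """Stationary standard deviation of c3 (nM), small-noise approximation.

    sigma = sqrt(mu * c3* / (V * (mu - f'))) with f = beta * P_on.  The
    curvature f'' (also estimated by central differences) only enters as a
    validity diagnostic of the linearization.  Raises
    :class:`MarginalStabilityError` when the restoring force vanishes.
    """
    c_star = steady_state_rp(rp, c3_init)
    f1, _f2 = production_derivatives(rp, c_star)
    restoring = rp.dyn.mu - f1
    if restoring <= 0:
        raise MarginalStabilityError(
            f"mu - f' = {restoring:.3g} <= 0 at the fixed point"
        )
    var = rp.dyn.mu * c_star / (rp.dyn.volume * restoring)
    return float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Batched steady states (hot path of the evolutionary engine)
# ---------------------------------------------------------------------------

try:  # pragma: no cover
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=False)(func)

except Exception:  # pragma: no cover

    def _jit(func):
        return func


def _extreme_roots_kernel(h, grid):
    """First and last stable root of each polynomial h[g] on [0, grid[-1]].

    Stable roots are + -> - sign crossings of h; they are the limit points
    of the output ODE started from 0 and from c_max.  Bisection refines
    each bracket to ~1e-12 relative.
    """
    n_g, n_k = h.shape
    n_c = grid.shape[0]
    out = np.empty((n_g, 2))
    for g in range(n_g):
        # Horner evaluation over the scan grid
        first_lo = -1.0
        first_hi = -1.0
        last_lo = -1.0
        last_hi = -1.0
        prev_v = 0.0
        for i in range(n_c):
            c = grid[i]
            v = h[g, n_k - 1]
            for k in range(n_k - 2, -1, -1):
                v = v * c + h[g, k]
            if i > 0 and prev_v > 0 >= v:
                if first_lo < 0:
                    first_lo = grid[i - 1]
                    first_hi = c
                last_lo = grid[i - 1]
                last_hi = c
            prev_v = v
        if first_lo < 0:
            # no crossing: h(0) <= 0 means decay to 0, else saturate at c_max
            v0 = h[g, 0]
            root = 0.0 if v0 <= 0 else grid[n_c - 1]
            out[g, 0] = root
            out[g, 1] = root
            continue
        for j in range(2):
            lo = first_lo if j == 0 else last_lo
            hi = first_hi if j == 0 else last_hi
            for _ in range(70):
                mid = 0.5 * (lo + hi)
                v = h[g, n_k - 1]
                for k in range(n_k - 2, -1, -1):
                    v = v * mid + h[g, k]
                if v > 0:
                    lo = mid
                else:
                    hi = mid
            out[g, j] = 0.5 * (lo + hi)
    return out


_extreme_roots = _jit(_extreme_roots_kernel)


def _scan_grid_for(dyn: DynamicsParams) -> np.ndarray:
    c_max = dyn.c_max
    lo = np.geomspace(c_max * 1e-5, c_max, dyn.n_grid)
    lin = np.linspace(0.0, c_max, dyn.n_grid // 2)
    return np.unique(np.concatenate([[0.0], lo, lin]))


def steady_states_batch(
    zon: np.ndarray, zoff: np.ndarray, dyn: DynamicsParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ss_low, ss_high, penalty) for a batch of partition polynomials.

    Equivalent to running :func:`detect_bistability_rp` at every input
    point; non-finite coefficient rows yield NaN outputs.
    """
    ztot = zon + zoff
    h = np.zeros((zon.shape[0], zon.shape[1] + 1))
    h[:, : zon.shape[1]] += dyn.beta * zon
    h[:, 1:] -= dyn.mu * ztot
    bad = ~np.all(np.isfinite(h), axis=1)
    h[bad] = 0.0
    roots = _extreme_roots(h, _scan_grid_for(dyn))
    low, high = roots[:, 0].copy(), roots[:, 1].copy()
    # residual contract: |beta P_on - mu c| < mu eps_ss at both limits
    for arr in (low, high):
        z_on_v = polyval_batch(zon, arr)
        z_tot_v = polyval_batch(ztot, arr)
        resid = np.abs(dyn.beta * z_on_v / z_tot_v - dyn.mu * arr)
        bad |= ~(resid < dyn.mu * dyn.eps_ss)
    penalty = np.where(np.abs(high - low) > dyn.eps_ss, (high - low) ** 2, 0.0)
    low[bad] = np.nan
    high[bad] = np.nan
    penalty[bad] = np.nan
    return low, high, penalty


# ---------------------------------------------------------------------------
# Response surfaces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseSurface:
    """Steady-state outputs over an input grid, with bistability flags."""

    c1: np.ndarray          # (n,) input concentrations
    c2: np.ndarray          # (n,)
    output: np.ndarray      # (n,) c3* from the low initial condition, nM
    output_high: np.ndarray  # (n,) c3* from the high initial condition, nM
    penalty: np.ndarray     # (n,) bistability penalties (dimensionless, c0=1)

    def __post_init__(self) -> None:
        n = self.c1.shape[0]
        for name in ("c2", "output", "output_high", "penalty"):
            if getattr(self, name).shape != (n,):
                raise ValueError("surface arrays must share one shape")

    @property
    def bistable(self) -> np.ndarray:
        return self.penalty > 0


class ModelSet:
    """Everything needed to evaluate a genotype: energetics plus dynamics."""

    def __init__(self, matrix, promoter_model, thermo, dynamics: DynamicsParams):
        from .thermodynamic_model import RegulatoryModel

        self.regulatory = RegulatoryModel(matrix, promoter_model, thermo)
        self.dynamics = dynamics

    @property
    def matrix(self):
        return self.regulatory.matrix

    @property
    def promoter_model(self):
        return self.regulatory.promoter_model

    @property
    def thermo(self):
        return self.regulatory.params

    def site_table(self, system) -> SiteTable:
        if isinstance(system, SiteTable):
            return system
        return self.regulatory.site_table(system)


def response_surface(system, models: ModelSet, c1, c2) -> ResponseSurface:
    """Steady state and bistability at every input point of a grid.

    ``c1``/``c2`` are equal-length arrays of input concentrations (nM);
    a non-finite entry in the outputs marks a point whose partition sums
    overflowed or whose dynamics did not settle.
    """
    c1 = np.atleast_1d(np.asarray(c1, dtype=float))
    c2 = np.atleast_1d(np.asarray(c2, dtype=float))
    if c1.size == 0:
        raise ValueError("evaluation grid must be nonempty")
    table = models.site_table(system)
    zon, zoff = partition_polynomials(table, c1, c2)
    low, high, pen = steady_states_batch(zon, zoff, models.dynamics)
    return ResponseSurface(c1=c1, c2=c2, output=low, output_high=high, penalty=pen)


# ---------------------------------------------------------------------------
# Public operations on genotypes / explicit site layouts
# ---------------------------------------------------------------------------


def steady_state(system, models: ModelSet, c1: float, c2: float, c3_init: float) -> float:
    """Steady-state output c3* (nM) reached from ``c3_init`` at fixed inputs."""
    return steady_state_rp(response_polynomial(system, c1, c2, models), c3_init)


def detect_bistability(system, models: ModelSet, c1: float, c2: float):
    """(ss_low, ss_high, penalty) from the two extreme initial conditions."""
    return detect_bistability_rp(response_polynomial(system, c1, c2, models))


def bistability_scan(system, models: ModelSet, c1: float, c2: float, n_grid: int = 256):
    """All stable fixed points of the output dynamics at fixed inputs."""
    return bistability_scan_rp(response_polynomial(system, c1, c2, models), n_grid)


def response_time(system, models: ModelSet, c1: float, c2: float, c3_init: float) -> float:
    """Time (tau0) to come within eps_rt of the steady state from ``c3_init``."""
    return response_time_rp(response_polynomial(system, c1, c2, models), c3_init)


def intrinsic_noise_sd(system, models: ModelSet, c1: float, c2: float) -> float:
    """Stationary standard deviation of the output concentration (nM)."""
    return intrinsic_noise_sd_rp(response_polynomial(system, c1, c2, models))
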