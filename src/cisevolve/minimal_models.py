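"""Stylized minimal models of (auto-)regulated promoters, in closed form.

Each layout is a small arrangement of binding sites with explicit
dissociation constants, chosen to isolate one design principle observed in
the evolved sequences:

``act_1site``
    conventional activation: one input-TF site recruiting RNAP.
``act_2site_coop``
    homo-cooperative activation: a recruiting proximal site plus a distal
    site for the same TF, bound cooperatively.
``cond_auto_act``
    conditional auto-activation: the distal site binds the *output* TF, so
    positive feedback engages only when the input TF is present.
``rep_2site_coop``
    cooperative repression: two input-TF operator sites overlapping the
    promoter, excluding RNAP.
``rep_2site_coop_plus_autoact``
    the same repression module plus an auto-activation site, which permits
    repression curves steeper than the two-site Hill limit.
``lin_rep_unequal_sites``
    the repression-plus-auto-activation layout with deliberately unequal
    operator affinities, the design that yields approximately linear
    repression.

The partition sums of these few-site systems are written out explicitly
(statistical weights ``w = c/K``; a shared factor ``omega`` acts as both
TF-TF cooperativity and TF-RNAP recruitment strength; ``p`` is the
normalized RNAP weight).  Each layout also maps onto an explicit site
table of the full sequence-level engine, which serves as the independent
check that the closed forms and the general machinery agree.

The logarithmic sensitivity S = |d ln c3*/d ln c1| quantifies response
steepness.  Without auto-regulation the sensitivity of the cooperative
repression layout cannot exceed 2 (the number of operator sites), while
adding auto-activation lifts it above that bound; conditional
auto-activation has no theoretical sensitivity limit at all as the RNAP
weight is decreased.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize

from .gates_and_fitness import GateSpec, goal_function
from .thermodynamic_model import SiteTable, ThermoParams

__all__ = [
    "LAYOUTS",
    "MinimalModelSpec",
    "SensitivityCurve",
    "minimal_response",
    "minimal_response_all",
    "minimal_site_table",
    "sensitivity",
    "sensitivity_curve",
    "max_sensitivity",
    "optimize_affinities",
    "linear_repression_derivative_check",
]

LAYOUTS = (
    "act_1site",
    "act_2site_coop",
    "cond_auto_act",
    "rep_2site_coop",
    "rep_2site_coop_plus_autoact",
    "lin_rep_unequal_sites",
)

_FEEDBACK_LAYOUTS = {
    "cond_auto_act",
    "rep_2site_coop_plus_autoact",
    "lin_rep_unequal_sites",
}


@dataclass(frozen=True)
class MinimalModelSpec:
    """Parameters of one stylized layout.

    k1, k1b : dissociation constants (nM) of the first/second input-TF
        site (k1b unused by single-site layouts).
    k3 : dissociation constant (nM) of the output-TF (auto-regulatory)
        site, where the layout has one.
    p : normalized RNAP weight (dimensionless), [RNAP]/Kd_promoter.
    omega : cooperativity/recruitment factor (>= 1).
    beta, mu : production and degradation constants of the output gene.
    """

    layout: str
    k1: float = 1000.0
    k1b: float = 1000.0
    k3: float = 1000.0
    p: float = 1.0
    omega: float = 50.0
    beta: float = 1000.0
    mu: float = 1.0

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if min(self.k1, self.k1b, self.k3) <= 0:
            raise ValueError("dissociation constants must be positive")
        if self.p <= 0:
            raise ValueError("RNAP weight p must be positive")
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if self.beta <= 0 or self.mu <= 0:
            raise ValueError("beta and mu must be positive")

    @property
    def c_max(self) -> float:
        return self.beta / self.mu

    @property
    def has_feedback(self) -> bool:
        return self.layout in _FEEDBACK_LAYOUTS


def occupancy(spec: MinimalModelSpec, c1, c3=0.0):
    """Promoter occupancy P_on of the layout's explicit partition sums."""
    w1 = np.asarray(c1) / spec.k1
    w1b = np.asarray(c1) / spec.k1b
    w3 = np.asarray(c3) / spec.k3
    p, om = spec.p, spec.omega
    if spec.layout == "act_1site":
        z_off = 1 + w1
        z_on = p * (1 + om * w1)
    elif spec.layout == "act_2site_coop":
        z_off = 1 + w1 + w1b + om * w1 * w1b
        z_on = p * (1 + om * w1 + w1b + om * om * w1 * w1b)
    elif spec.layout == "cond_auto_act":
        z_off = 1 + w1 + w3 + om * w1 * w3
        z_on = p * (1 + om * w1 + w3 + om * om * w1 * w3)
    elif spec.layout == "rep_2site_coop":
        z_off = 1 + w1 + w1b + om * w1 * w1b
        z_on = p * np.ones_like(z_off)
    else:  # repression module plus auto-activation (equal or unequal sites)
        z_off = (1 + w3) * (1 + w1 + w1b + om * w1 * w1b)
        z_on = p * (1 + om * w3)
    return z_on / (z_on + z_off)


def minimal_site_table(
    spec: MinimalModelSpec, l_cis: int = 120, l_tf: int = 9
) -> SiteTable:
    """The layout as an explicit site table of the full engine.

    Site coordinates realize exactly the interactions of the closed forms
    under the default distance cutoffs: recruiting sites sit within
    ``d_act`` of the RNAP footprint, cooperative partners within
    ``d_coop`` of each other, operators overlap the footprint, and the
    auto-activation site of the repression layouts recruits without
    cooperating with the operators.
    """
    params = ThermoParams(omega_coop=spec.omega, omega_act=spec.omega)
    fp_start = l_cis - 35
    proximal = fp_start - l_tf - 2       # recruiting activator (gap 2)
    distal = proximal - l_tf - 10        # cooperative partner (gap 10; > d_act from RNAP)
    op1 = fp_start                       # operator inside the footprint
    op2 = fp_start + l_tf + 2            # cooperative operator (gap 2)
    auto = fp_start - l_tf - 19          # recruits (gap 19) without operator contact
    sites = {
        "act_1site": [("TF1", proximal, spec.k1)],
        "act_2site_coop": [("TF1", proximal, spec.k1), ("TF1", distal, spec.k1b)],
        "cond_auto_act": [("TF1", proximal, spec.k1), ("TF3", distal, spec.k3)],
        "rep_2site_coop": [("TF1", op1, spec.k1), ("TF1", op2, spec.k1b)],
        "rep_2site_coop_plus_autoact": [
            ("TF1", op1, spec.k1), ("TF1", op2, spec.k1b), ("TF3", auto, spec.k3)
        ],
        "lin_rep_unequal_sites": [
            ("TF1", op1, spec.k1), ("TF1", op2, spec.k1b), ("TF3", auto, spec.k3)
        ],
    }[spec.layout]
    return SiteTable.explicit(l_cis, l_tf, sites, q_r=spec.p, params=params)


# ---------------------------------------------------------------------------
# Steady states of the minimal models
# ---------------------------------------------------------------------------


def _velocity(spec: MinimalModelSpec, c1: float, c3):
    return spec.beta * occupancy(spec, c1, c3) - spec.mu * np.asarray(c3)


def minimal_response_all(spec: MinimalModelSpec, c1: float, n_grid: int = 512):
    """All stable fixed points of the layout's output dynamics at input c1."""
    if c1 < 0:
        raise ValueError("c1 must be >= 0")
    if not spec.has_feedback:
        return [float(spec.c_max * occupancy(spec, c1, 0.0))]
    c_max = spec.c_max
    grid = np.unique(
        np.concatenate(
            [[0.0], np.geomspace(c_max * 1e-6, c_max, n_grid),
             np.linspace(0.0, c_max, n_grid // 2)]
        )
    )
    h = _velocity(spec, c1, grid)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        if h[i] > 0 >= h[i + 1]:
            lo, hi = grid[i], grid[i + 1]
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if _velocity(spec, c1, mid) > 0:
                    lo = mid
                else:
                    hi = mid
            roots.append(0.5 * (lo + hi))
    if not roots:
        roots.append(0.0 if h[0] <= 0 else c_max)
    return roots


def minimal_response(spec: MinimalModelSpec, c1: float) -> float:
    """Stable steady-state output (nM) reached from c3 = 0.

    For bistable parameter regimes this is the lower branch; use
    :func:`minimal_response_all` to inspect all branches.
    """
    return minimal_response_all(spec, c1)[0]


def is_bistable(spec: MinimalModelSpec, c1: float) -> bool:
    return len(minimal_response_all(spec, c1)) > 1


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityCurve:
    """S(c1) = |d ln c3*/d ln c1| tabulated over an input range."""

    c1: np.ndarray
    s: np.ndarray

    @property
    def s_max(self) -> float:
        return float(np.max(self.s))

    @property
    def argmax(self) -> float:
        return float(self.c1[int(np.argmax(self.s))])


def sensitivity(responder, c1: float, factor: float = 1.01) -> float:
    """Logarithmic sensitivity of a response at one input (central log-log
    finite difference with multiplicative step ``factor``)."""
    if c1 <= 0:
        raise ValueError("sensitivity needs c1 > 0")
    hi = responder(c1 * factor)
    lo = responder(c1 / factor)
    if hi <= 0 or lo <= 0:
        raise ValueError("sensitivity undefined for non-positive response")
    return abs(np.log(hi) - np.log(lo)) / (2.0 * np.log(factor))


def sensitivity_curve(
    spec: MinimalModelSpec, c1_range=(1.0, 1e4), n: int = 201
) -> SensitivityCurve:
    c1 = np.geomspace(*c1_range, n)
    resp = lambda c: minimal_response(spec, c)  # noqa: E731
    s = np.array([sensitivity(resp, c) for c in c1])
    return SensitivityCurve(c1=c1, s=s)


def _response_no_feedback(spec: MinimalModelSpec, c1: np.ndarray) -> np.ndarray:
    return spec.c_max * occupancy(spec, c1, 0.0)


def max_sensitivity(
    layout: str,
    c1_range=(1.0, 1e4),
    k_range=(1.0, 1e4),
    omega_range=(1.0, 100.0),
    p_range=(0.1, 100.0),
    k3: float | None = None,
    points_per_decade: int = 20,
    c1_points: int = 201,
) -> dict:
    """Maximal logarithmic sensitivity of a layout over a parameter sweep.

    Sweeps the operator dissociation constant (applied to both input-TF
    sites), the cooperativity/recruitment factor and the RNAP weight on
    log grids, and the input concentration on a log grid refined around the
    optimum.  Feedback layouts additionally need ``k3`` for the
    auto-regulatory site.  Returns the maximum, its location, and the
    site-count bound (the analytic sensitivity limit of the pure
    cooperative-repression layout).
    """

    def log_grid(lo, hi):
        n = max(2, int(round(np.log10(hi / lo) * points_per_decade)) + 1)
        return np.geomspace(lo, hi, n)

    c1 = np.geomspace(*c1_range, c1_points)
    log_c1 = np.log(c1)
    best = {"s_max": -np.inf}
    for k, om, p in itertools.product(
        log_grid(*k_range), log_grid(*omega_range), log_grid(*p_range)
    ):
        spec = MinimalModelSpec(
            layout=layout, k1=k, k1b=k, k3=k3 if k3 is not None else 1e9,
            p=p, omega=om,
        )
        if spec.has_feedback:
            resp = np.array([minimal_response(spec, c) for c in c1])
        else:
            resp = _response_no_feedback(spec, c1)
        with np.errstate(divide="ignore"):
            log_r = np.log(resp)
        slope = np.abs(np.diff(log_r) / np.diff(log_c1))
        finite = np.isfinite(slope)
        if not finite.any():
            continue
        s_here = float(np.max(slope[finite]))
        if s_here > best["s_max"]:
            i = int(np.argmax(np.where(finite, slope, -np.inf)))
            best = {
                "s_max": s_here,
                "c1": float(np.sqrt(c1[i] * c1[i + 1])),
                "k": float(k), "omega": float(om), "p": float(p),
                "spec": spec,
            }
    # refine around the best parameter point with a point-wise central
    # log-log difference on a finer input grid
    spec = best["spec"]
    fine = np.geomspace(
        max(best["c1"] / 10, c1_range[0]), min(best["c1"] * 10, c1_range[1]), 200
    )
    if spec.has_feedback:
        resp_fn = lambda c: minimal_response(spec, c)  # noqa: E731
    else:
        resp_fn = lambda c: float(_response_no_feedback(spec, np.asarray(c)))  # noqa: E731
    refined = -np.inf
    refined_c1 = best["c1"]
    for c in fine:
        try:
            s = sensitivity(resp_fn, float(c))
        except ValueError:
            continue
        if s > refined:
            refined, refined_c1 = s, float(c)
    best["s_max"] = max(best["s_max"], refined)
    best["c1"] = refined_c1
    best["site_count_bound"] = 2.0
    best.pop("spec")
    return best


# ---------------------------------------------------------------------------
# Affinity optimization against a gate goal
# ---------------------------------------------------------------------------

_FREE_KS = {
    "act_1site": ("k1",),
    "act_2site_coop": ("k1", "k1b"),
    "cond_auto_act": ("k1", "k3"),
    "rep_2site_coop": ("k1", "k1b"),
    "rep_2site_coop_plus_autoact": ("k1", "k1b", "k3"),
    "lin_rep_unequal_sites": ("k1", "k1b", "k3"),
}

K_BOUNDS = (1.0, 1e6)  # nM; the upper bound models effective site removal


def minimal_e_rf(spec: MinimalModelSpec, gate: GateSpec, c1_grid: np.ndarray) -> float:
    """E_RF of a one-input minimal model, including bistability penalties."""
    total = 0.0
    for c1 in c1_grid:
        roots = minimal_response_all(spec, float(c1))
        goal = float(goal_function(gate, c1))
        total += (roots[0] - goal) ** 2
        if len(roots) > 1:
            total += (roots[-1] - roots[0]) ** 2
    return total


def optimize_affinities(
    spec: MinimalModelSpec,
    gate: GateSpec,
    c1_grid: np.ndarray | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> tuple[MinimalModelSpec, float]:
    """Nelder-Mead optimization of the layout's site affinities for a gate.

    Optimizes the log10 dissociation constants of the layout's free sites
    within [1, 1e6] nM from ``n_restarts`` seeded random starting points
    (plus the spec's own values); returns the best spec and its E_RF,
    never worse than the best starting point.
    """
    if gate.arity != 1:
        raise ValueError("the shipped layouts are one-input models")
    if c1_grid is None:
        c1_grid = np.linspace(0.0, 1000.0, 7)
    names = _FREE_KS[spec.layout]
    lo, hi = np.log10(K_BOUNDS)
    rng = np.random.default_rng(seed)

    def build(log_ks: np.ndarray) -> MinimalModelSpec:
        ks = 10.0 ** np.clip(log_ks, lo, hi)
        return replace(spec, **dict(zip(names, ks)))

    def objective(log_ks: np.ndarray) -> float:
        return minimal_e_rf(build(log_ks), gate, c1_grid)

    starts = [np.array([np.log10(getattr(spec, n)) for n in names])]
    starts += [rng.uniform(lo, hi, size=len(names)) for _ in range(n_restarts)]
    best_x, best_val = None, np.inf
    for x0 in starts:
        val0 = objective(x0)
        if val0 < best_val:
            best_x, best_val = x0, val0
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400},
        )
        if res.fun < best_val:
            best_x, best_val = res.x, float(res.fun)
    return build(best_x), best_val


# ---------------------------------------------------------------------------
# Linear-repression total-derivative identity
# ---------------------------------------------------------------------------


def linear_repression_derivative_check(
    spec: MinimalModelSpec, c1_range=(1.0, 1000.0), n: int = 25
) -> float:
    """Verify d c3*/d c1 = G_c1 / (1 - G_c3) along the fixed-point branch.

    ``G(c1, c3) = (beta/mu) P_on`` is the normalized production; without
    auto-regulation G_c3 = 0 and the denominator is 1.  The left side is a
    central difference of the solved branch; the partial derivatives are
    evaluated by complex-step differentiation (machine precision for these
    rational occupancy functions).  Returns the maximal absolute residual
    over the input range; bistable points raise.
    """
    if spec.layout not in ("lin_rep_unequal_sites", "rep_2site_coop_plus_autoact",
                           "rep_2site_coop"):
        raise ValueError("identity check targets the repression layouts")
    h_im = 1e-30
    worst = 0.0
    for c1 in np.linspace(*c1_range, n):
        c1 = float(c1)
        if is_bistable(spec, c1):
            raise ValueError(f"bistable at c1 = {c1}; identity check flagged")
        c3 = minimal_response(spec, c1)
        dc1 = max(1e-3, 1e-4 * c1)
        lhs = (minimal_response(spec, c1 + dc1) - minimal_response(spec, max(c1 - dc1, 0.0))) / (
            dc1 + min(dc1, c1)
        )
        g = lambda a, b: spec.c_max * occupancy(spec, a, b)  # noqa: E731
        g_c1 = float(np.imag(g(c1 + 1j * h_im, c3)) / h_im)
        g_c3 = float(np.imag(g(c1, c3 + 1j * h_im)) / h_im)
        rhs = g_c1 / (1.0 - g_c3)
        worst = max(worst, abs(lhs - rhs))
    return worst
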