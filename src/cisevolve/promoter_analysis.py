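"""Post-hoc analysis of evolved cis-regulatory regions.

Because binding constants are continuous, there is no sharp distinction
between binding sites and background; functional sites are recognized the
way an experimentalist would, by computational DNA footprinting.  For each
TF and each candidate site the equilibrium occupancy is evaluated at the
four extreme input conditions (with the output TF at its self-consistent
steady state), and the maximum over conditions, O_max, is thresholded to
call sites.  The degree of auto-regulation of a design is quantified by
the feedback measure F: the mean squared difference (nM^2) between the
response surface of the intact system and the surface recomputed with the
output TF's DNA affinity set to zero everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gates_and_fitness import EvaluationGrid, GateSpec
from .response_dynamics import ModelSet, response_surface, steady_state
from .thermodynamic_model import TF_IDS, SiteTable, occupancy_profile

__all__ = [
    "FootprintProfile",
    "SiteCall",
    "feedback_measure",
    "feedback_from_surfaces",
    "footprint",
    "call_binding_sites",
    "simplify_and_verify",
    "degree_stats",
]


# ---------------------------------------------------------------------------
# Feedback measure
# ---------------------------------------------------------------------------


def feedback_from_surfaces(n: np.ndarray, n0: np.ndarray, mask=None) -> float:
    """F = mean over grid points of (n - n0)^2, in nM^2.

    ``n`` is the response surface of the intact system, ``n0`` the surface
    with all output-TF binding removed; ``mask`` optionally excludes
    flagged (e.g. bistable) points.
    """
    n = np.asarray(n, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    if n.shape != n0.shape:
        raise ValueError("surfaces must have the same shape")
    keep = np.ones(n.shape, dtype=bool) if mask is None else ~np.asarray(mask)
    if not keep.any():
        raise ValueError("no monostable grid points left for the feedback measure")
    return float(np.mean((n[keep] - n0[keep]) ** 2))


def feedback_measure(
    system,
    models: ModelSet,
    grid: EvaluationGrid | None = None,
    gate: GateSpec | None = None,
) -> float:
    """Degree of auto-regulation F (nM^2) of a genotype or site table.

    Computes the response surface, zeroes the TF3 affinity of every site,
    recomputes, and averages the squared differences over the grid.
    Bistable points are excluded with a warning.
    """
    grid = grid or EvaluationGrid()
    gate = gate or GateSpec("NAND")
    c1, c2 = grid.points(gate)
    table = models.site_table(system)
    full = response_surface(table, models, c1, c2)
    reduced = response_surface(table.without_tf3(), models, c1, c2)
    flagged = full.bistable | reduced.bistable | ~np.isfinite(full.output) \
        | ~np.isfinite(reduced.output)
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} bistable/failed grid point(s) excluded "
            "from the feedback measure"
        )
    return feedback_from_surfaces(full.output, reduced.output, mask=flagged)


# ---------------------------------------------------------------------------
# Footprints and binding-site calls
# ---------------------------------------------------------------------------

CORNER_CONCENTRATIONS = (0.0, 1000.0)


@dataclass(frozen=True)
class FootprintProfile:
    """Maximal equilibrium occupancy per (TF, start) over the corner
    conditions, each evaluated at the self-consistent output steady state."""

    l_tf: int
    o_max: np.ndarray  # (3, n_pos)

    def __post_init__(self) -> None:
        if np.any((self.o_max < -1e-12) | (self.o_max > 1 + 1e-12)):
            raise ValueError("occupancies must lie in [0, 1]")


@dataclass(frozen=True)
class SiteCall:
    """One called binding site with its role annotation."""

    tf_id: str
    start: int
    end: int  # half-open, start + L_TF
    o_max: float
    role: str  # e.g. "repressor", "activator", "distal", "auto-activator"


def footprint(system, models: ModelSet) -> FootprintProfile:
    """Computational DNA footprint: O_max per (TF, start) over 4 corners."""
    table = models.site_table(system)
    o_max = np.zeros((3, table.n_pos))
    for c1 in CORNER_CONCENTRATIONS:
        for c2 in CORNER_CONCENTRATIONS:
            c3_star = steady_state(table, models, c1, c2, 0.0)
            occ, _ = occupancy_profile(table, c1, c2, c3_star)
            o_max = np.maximum(o_max, occ)
    return FootprintProfile(l_tf=table.l_tf, o_max=o_max)


def _role(table: SiteTable, start: int, l_tf: int, tf_id: str) -> str:
    fp_start, fp_end = table.footprint
    d_act = table.params.d_act
    end = start + l_tf
    if end > fp_start and start < fp_end:
        base = "repressor"
    else:
        gap = fp_start - end if end <= fp_start else start - fp_end
        base = "activator" if gap <= d_act else "distal"
    return f"auto-{base}" if tf_id == "TF3" else base


def call_binding_sites(
    profile: FootprintProfile,
    table: SiteTable,
    threshold: float = 0.5,
) -> list[SiteCall]:
    """Sites with O_max >= threshold, overlap-merged per TF (argmax kept).

    The threshold is deliberately stringent; O_max histograms over evolved
    populations are bimodal, so calls are insensitive to its exact value.
    """
    calls: list[SiteCall] = []
    for t, tf_id in enumerate(TF_IDS):
        candidates = [
            (int(s), float(profile.o_max[t, s]))
            for s in np.flatnonzero(profile.o_max[t] >= threshold)
        ]
        # merge overlapping same-TF candidates, keeping the strongest start
        candidates.sort(key=lambda c: -c[1])
        kept: list[tuple[int, float]] = []
        for s, o in candidates:
            if all(abs(s - s2) >= profile.l_tf for s2, _ in kept):
                kept.append((s, o))
        for s, o in sorted(kept):
            calls.append(
                SiteCall(
                    tf_id=tf_id,
                    start=s,
                    end=s + profile.l_tf,
                    o_max=o,
                    role=_role(table, s, profile.l_tf, tf_id),
                )
            )
    return calls


def simplify_and_verify(
    system,
    calls: list[SiteCall],
    models: ModelSet,
    grid: EvaluationGrid | None = None,
    gate: GateSpec | None = None,
    tol: float = 50.0,
) -> tuple[SiteTable, float, bool]:
    """Reduced model keeping only the called sites; verifies the surface.

    Returns (reduced site table, max |delta c3*| over the grid, success).
    The reduced system keeps each called site's computed Kd and sets every
    other affinity to zero; if the maximal deviation exceeds ``tol`` the
    threshold should be lowered to recover missed weak sites.
    """
    if not calls:
        raise ValueError("no called sites; lower the footprint threshold")
    grid = grid or EvaluationGrid()
    gate = gate or GateSpec("NAND")
    table = models.site_table(system)
    inv_kd = np.zeros_like(table.inv_kd)
    for call in calls:
        t = TF_IDS.index(call.tf_id)
        inv_kd[t, call.start] = table.inv_kd[t, call.start]
    reduced = SiteTable(
        l_cis=table.l_cis, l_tf=table.l_tf, inv_kd=inv_kd,
        q_r=table.q_r, params=table.params,
    )
    c1, c2 = grid.points(gate)
    full = response_surface(table, models, c1, c2)
    red = response_surface(reduced, models, c1, c2)
    deviation = float(np.nanmax(np.abs(full.output - red.output)))
    return reduced, deviation, deviation <= tol


# ---------------------------------------------------------------------------
# Regulator in-degree statistics
# ---------------------------------------------------------------------------


def degree_stats(records: list[tuple[str, int]]) -> dict:
    """In-degree summary per auto-regulator class.

    ``records`` holds (class, number of non-auto inputs) pairs with class
    in {"auto-activator", "auto-repressor"}; the auto-regulatory edge is
    excluded by construction.  Returns per class the count, total inputs,
    fraction of regulators with at least one input, and the mean in-degree.
    """
    if not records:
        raise ValueError("no records")
    out: dict[str, dict[str, float]] = {}
    for cls in ("auto-activator", "auto-repressor"):
        degrees = [d for c, d in records if c == cls]
        if any(d < 0 for d in degrees):
            raise ValueError("in-degrees must be >= 0")
        if not degrees:
            continue
        n = len(degrees)
        total = sum(degrees)
        out[cls] = {
            "n": n,
            "total_inputs": total,
            "fraction_with_input": sum(d >= 1 for d in degrees) / n,
            "mean_in_degree": total / n,
        }
    if not out:
        raise ValueError("no records in a known regulator class")
    return out
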