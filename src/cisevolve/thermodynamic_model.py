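"""Equilibrium statistical mechanics of the cis-regulatory region.

The transcription rate of the output gene is proportional to the
equilibrium occupancy of the core promoter by RNA polymerase.  Following
the Shea-Ackers formalism, the occupancy is

    P_on = Z_on / (Z_on + Z_off),

where ``Z_on`` sums the Boltzmann weights of every binding configuration
that contains RNAP and ``Z_off`` those that do not (including the empty
configuration, weight 1).  A configuration is a set of non-overlapping TF
placements, optionally plus RNAP on its fixed footprint.  Its weight is the
product of the statistical weights ``c/Kd`` of the bound TFs, a
cooperativity factor ``omega_coop`` for every pair of nearest-neighbour
bound TFs whose edge-to-edge gap is at most ``d_coop`` bp, a recruitment
factor ``omega_act`` for every bound TF within ``d_act`` bp of the RNAP
footprint when RNAP is present, and the basal RNAP weight ``q_R`` when
RNAP is present.  TFs whose site overlaps the footprint are mutually
exclusive with RNAP.

The configuration sum is evaluated with a linear-scan dynamic program over
start positions.  Because every configuration weight is a monomial in the
output-TF concentration ``c3`` (one factor per bound TF3 molecule), the DP
is run once per input point ``(c1, c2)`` and returns the *coefficients* of
``Z_on`` and ``Z_off`` as polynomials in ``c3``.  All downstream steady-state
and bistability computations then reduce to cheap polynomial evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .sequence_energetics import (
    RNAP_FOOTPRINT_BP,
    CisRegion,
    EnergyMatrix,
    PromoterModel,
    TranscriptionFactor,
    rnap_weight,
    scan_energies,
)

__all__ = [
    "ThermoParams",
    "Genotype",
    "SiteTable",
    "RegulatoryModel",
    "partition_polynomials",
    "partition_sums",
    "promoter_occupancy",
    "site_occupancy",
    "occupancy_profile",
]

TF_IDS = ("TF1", "TF2", "TF3")


@dataclass(frozen=True)
class ThermoParams:
    """Interaction parameters of the thermodynamic model.

    omega_coop : TF-TF cooperativity factor per nearest-neighbour pair of
        bound TFs with edge gap <= ``d_coop`` bp (dimensionless, >= 1).
        The biologically validated range is about 10-100.
    omega_act : TF-RNAP recruitment factor per bound TF with edge gap to
        the RNAP footprint <= ``d_act`` bp (dimensionless, >= 1).
    d_coop, d_act : interaction distance cutoffs, bp (edge-to-edge).
    rnap_nM : free RNAP concentration, nM.
    k0, k0r : Kd calibration constants (nM) for TF sites and for the core
        promoter: ``Kd = K0 exp(dG/kT)``.
    """

    omega_coop: float = 50.0
    omega_act: float = 50.0
    d_coop: int = 18
    d_act: int = 20
    rnap_nM: float = 30.0
    k0: float = math.exp(27.0)          # perfect 9-mer site ~ 1 nM
    k0r: float = 30.0 * math.exp(12.357)  # consensus promoter ~ q_R = 1

    def __post_init__(self) -> None:
        if self.omega_coop < 1 or self.omega_act < 1:
            raise ValueError("cooperativity/recruitment factors must be >= 1")
        if self.d_coop < 0 or self.d_act < 0:
            raise ValueError("interaction distances must be >= 0")
        if self.d_coop >= RNAP_FOOTPRINT_BP:
            # the DP chains TF-TF cooperativity straight across the RNAP
            # footprint; gaps across the bound footprint are >= 29 bp, so
            # d_coop must stay below the footprint width
            raise ValueError(
                f"d_coop must be < {RNAP_FOOTPRINT_BP} bp (RNAP footprint width)"
            )
        if self.rnap_nM < 0:
            raise ValueError("RNAP concentration must be >= 0")
        if self.k0 <= 0 or self.k0r <= 0:
            raise ValueError("calibration constants must be positive")


@dataclass(frozen=True)
class Genotype:
    """One cis-regulatory region plus the three TF binding domains.

    The genotype completely specifies a transcriptional gate: every
    interaction in the model is derived from these four sequences.
    """

    cis: CisRegion
    tf1: TranscriptionFactor
    tf2: TranscriptionFactor
    tf3: TranscriptionFactor

    def __post_init__(self) -> None:
        lengths = {len(self.tf1), len(self.tf2), len(self.tf3)}
        if len(lengths) != 1:
            raise ValueError("all three TFs must have the same domain length")
        for tf, want in zip(self.tfs, TF_IDS):
            if tf.id != want:
                raise ValueError(f"expected {want}, got {tf.id}")

    @property
    def tfs(self) -> tuple[TranscriptionFactor, ...]:
        return (self.tf1, self.tf2, self.tf3)

    @property
    def l_tf(self) -> int:
        return len(self.tf1)


# ---------------------------------------------------------------------------
# Site table: per-position affinities plus promoter geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteTable:
    """Positioned affinities of the three TF species on one cis region.

    ``inv_kd[t, s]`` is ``1/Kd`` (1/nM) of species ``t`` (0 = TF1, 1 = TF2,
    2 = TF3) for the site ``[s, s + l_tf)``; ``q_r`` is the basal RNAP
    weight.  This is the complete input of the partition-sum machinery;
    genotypes and explicit minimal-model layouts both reduce to it.
    """

    l_cis: int
    l_tf: int
    inv_kd: np.ndarray  # (3, n_pos)
    q_r: float
    params: ThermoParams

    def __post_init__(self) -> None:
        inv_kd = np.ascontiguousarray(self.inv_kd, dtype=float)
        if inv_kd.shape != (3, self.n_pos):
            raise ValueError(
                f"inv_kd must have shape (3, {self.n_pos}), got {inv_kd.shape}"
            )
        if np.any(inv_kd < 0) or not np.all(np.isfinite(inv_kd)):
            raise ValueError("1/Kd values must be finite and >= 0")
        if self.q_r < 0:
            raise ValueError("q_R must be >= 0")
        object.__setattr__(self, "inv_kd", inv_kd)

    @property
    def n_pos(self) -> int:
        return self.l_cis - self.l_tf + 1

    @property
    def footprint(self) -> tuple[int, int]:
        return self.l_cis - 35, self.l_cis - 6

    @property
    def max_tf3_sites(self) -> int:
        """Upper bound on simultaneously bound TF3 molecules (poly degree)."""
        return self.l_cis // self.l_tf

    def overlap_mask(self) -> np.ndarray:
        """True where a placement overlaps the RNAP footprint."""
        s = np.arange(self.n_pos)
        fp_start, fp_end = self.footprint
        return (s < fp_end) & (s + self.l_tf > fp_start)

    def act_factor(self) -> np.ndarray:
        """Recruitment factor per position in the RNAP-bound ensemble."""
        s = np.arange(self.n_pos)
        fp_start, fp_end = self.footprint
        gap_left = fp_start - (s + self.l_tf)
        gap_right = s - fp_end
        gap = np.where(s + self.l_tf <= fp_start, gap_left, gap_right)
        eligible = ~self.overlap_mask() & (gap >= 0) & (gap <= self.params.d_act)
        return np.where(eligible, self.params.omega_act, 1.0)

    def without_tf3(self) -> "SiteTable":
        """Copy with the TF3 affinity of every site set to zero."""
        inv_kd = self.inv_kd.copy()
        inv_kd[2] = 0.0
        return replace(self, inv_kd=inv_kd)

    @staticmethod
    def explicit(
        l_cis: int,
        l_tf: int,
        sites: list[tuple[str, int, float]],
        q_r: float,
        params: ThermoParams,
    ) -> "SiteTable":
        """Build a table from explicit (tf_id, start, Kd_nM) site placements.

        Every unlisted position has zero affinity.  This is the pathway the
        minimal stylized models use to drive the full machinery.
        """
        n_pos = l_cis - l_tf + 1
        inv_kd = np.zeros((3, n_pos))
        for tf_id, start, kd in sites:
            if not 0 <= start < n_pos:
                raise ValueError(f"site start {start} outside [0, {n_pos})")
            if kd <= 0:
                raise ValueError("explicit site Kd must be positive")
            inv_kd[TF_IDS.index(tf_id), start] = 1.0 / kd
        return SiteTable(l_cis=l_cis, l_tf=l_tf, inv_kd=inv_kd, q_r=q_r, params=params)


@dataclass(frozen=True)
class RegulatoryModel:
    """Bundle of energy matrix, promoter model and thermodynamic parameters."""

    matrix: EnergyMatrix
    promoter_model: PromoterModel
    params: ThermoParams

    def site_table(self, genotype: Genotype) -> SiteTable:
        kds = np.empty((3, len(genotype.cis) - genotype.l_tf + 1))
        for t, tf in enumerate(genotype.tfs):
            dg = scan_energies(tf, genotype.cis, self.matrix)
            kds[t] = self.params.k0 * np.exp(dg)
        q_r = rnap_weight(
            genotype.cis, self.promoter_model, self.params.rnap_nM, self.params.k0r
        )
        return SiteTable(
            l_cis=len(genotype.cis),
            l_tf=genotype.l_tf,
            inv_kd=1.0 / kds,
            q_r=q_r,
            params=self.params,
        )


# ---------------------------------------------------------------------------
# Dynamic program over binding configurations
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=False)(func)

except Exception:  # pragma: no cover - numba always present in practice

    def _jit(func):
        return func


def _dp_kernel_py(
    n_pos, l_tf, l_cis, deg, w12, a3, omega, d_coop, blocked, factor
):
    """Sum of configuration weights as polynomial coefficients in c3.

    ``w12[g, s]`` is the combined concentration-weighted statistical weight
    of TF1/TF2 at start ``s`` for input point ``g`` (already multiplied by
    the recruitment factor where applicable), ``a3[s]`` the per-molecule
    polynomial coefficient of a TF3 placement (1/Kd3, times recruitment
    factor).  Returns ``Z[g, k]`` such that ``Z(c3) = sum_k Z[g, k] c3**k``;
    the empty configuration contributes 1 to ``Z[g, 0]``.

    The scan keeps, per end position ``e``, the summed weight of all
    configurations whose rightmost molecule ends exactly at ``e``.  A new
    molecule starting at ``s`` extends the empty context (weight 1), any
    configuration ending more than ``d_coop`` bp before ``s`` (factor 1),
    or any configuration ending within ``d_coop`` bp (factor omega:
    nearest-neighbour cooperativity; chains gain factors transitively).
    """
    n_grid = w12.shape[0]
    out = np.zeros((n_grid, deg + 1))
    for g in range(n_grid):
        z_end = np.zeros((l_cis + 1, deg + 1))
        s_old = np.zeros(deg + 1)
        s_rec = np.zeros(deg + 1)
        for s in range(n_pos):
            s_rec += z_end[s]
            r = s - d_coop - 1
            if r >= 0:
                s_rec -= z_end[r]
                s_old += z_end[r]
            if blocked[s]:
                continue
            e = s + l_tf
            w = w12[g, s]
            a = a3[s] * factor[s]
            if w == 0.0 and a == 0.0:
                continue
            # context polynomial C = 1 + S_old + omega * S_rec
            for k in range(deg + 1):
                c_k = s_old[k] + omega * s_rec[k]
                if k == 0:
                    c_k += 1.0
                if w != 0.0:
                    z_end[e, k] += w * c_k
                if a != 0.0 and k < deg:
                    z_end[e, k + 1] += a * c_k  # one more bound TF3 molecule
        total = np.zeros(deg + 1)
        total[0] = 1.0
        for e in range(l_tf, l_cis + 1):
            total += z_end[e]
        out[g] = total
    return out


_dp_kernel = _jit(_dp_kernel_py)


def partition_polynomials(
    table: SiteTable, c1: np.ndarray | float, c2: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients of Z_on(c3) and Z_off(c3) for a batch of input points.

    Returns ``(zon, zoff)``, each of shape ``(n_points, deg + 1)`` with
    ``Z(c3) = sum_k coeffs[g, k] * c3**k``.  ``zon`` includes the basal
    RNAP weight ``q_r`` and all recruitment factors.
    """
    c1 = np.atleast_1d(np.asarray(c1, dtype=float))
    c2 = np.atleast_1d(np.asarray(c2, dtype=float))
    if c1.shape != c2.shape:
        raise ValueError("c1 and c2 must have the same shape")
    if np.any(c1 < 0) or np.any(c2 < 0):
        raise ValueError("concentrations must be non-negative")
    deg = table.max_tf3_sites
    omega = table.params.omega_coop
    d_coop = table.params.d_coop
    n_pos = table.n_pos

    w12_off = c1[:, None] * table.inv_kd[0][None, :] + c2[:, None] * table.inv_kd[1][None, :]
    a3 = np.ascontiguousarray(table.inv_kd[2])
    no_block = np.zeros(n_pos, dtype=np.bool_)
    ones = np.ones(n_pos)
    zoff = _dp_kernel(
        n_pos, table.l_tf, table.l_cis, deg,
        np.ascontiguousarray(w12_off), a3, omega, d_coop, no_block, ones,
    )

    factor = table.act_factor()
    blocked = table.overlap_mask()
    w12_on = w12_off * factor[None, :]
    zon = _dp_kernel(
        n_pos, table.l_tf, table.l_cis, deg,
        np.ascontiguousarray(w12_on), a3, omega, d_coop,
        np.ascontiguousarray(blocked), np.ascontiguousarray(factor),
    )
    return table.q_r * zon, zoff


def polyval_batch(coeffs: np.ndarray, c3: np.ndarray | float) -> np.ndarray:
    """Evaluate batched polynomial coefficients at c3 (Horner)."""
    c3 = np.asarray(c3, dtype=float)
    out = np.zeros(np.broadcast_shapes(coeffs.shape[:-1], c3.shape))
    for k in range(coeffs.shape[-1] - 1, -1, -1):
        out = out * c3 + coeffs[..., k]
    return out


# ---------------------------------------------------------------------------
# Spec-level scalar queries
# ---------------------------------------------------------------------------


def _resolve_table(system, matrix=None, pm=None, params=None) -> SiteTable:
    if isinstance(system, SiteTable):
        return system
    if isinstance(system, Genotype):
        if matrix is None or pm is None or params is None:
            raise ValueError("genotype queries need matrix, promoter model and params")
        return RegulatoryModel(matrix, pm, params).site_table(system)
    raise TypeError(f"cannot build a site table from {type(system)!r}")


def partition_sums(
    system, c1: float, c2: float, c3: float, *, matrix=None, pm=None, params=None
) -> tuple[float, float]:
    """(Z_on, Z_off) at scalar TF concentrations (nM).

    ``system`` is a :class:`Genotype` (with ``matrix``/``pm``/``params``)
    or a prebuilt :class:`SiteTable`.
    """
    if min(c1, c2, c3) < 0:
        raise ValueError("concentrations must be non-negative")
    table = _resolve_table(system, matrix, pm, params)
    zon, zoff = partition_polynomials(table, c1, c2)
    return float(polyval_batch(zon, c3)[0]), float(polyval_batch(zoff, c3)[0])


def promoter_occupancy(
    system, c1: float, c2: float, c3: float, *, matrix=None, pm=None, params=None
) -> float:
    """Fractional RNAP occupancy of the promoter, P_on in [0, 1]."""
    z_on, z_off = partition_sums(system, c1, c2, c3, matrix=matrix, pm=pm, params=params)
    return z_on / (z_on + z_off)


# ---------------------------------------------------------------------------
# Per-site occupancies (forward/backward scan at fixed concentrations)
# ---------------------------------------------------------------------------


def _forward_context(w_tot: np.ndarray, l_tf: int, l_cis: int, omega: float, d_coop: int):
    """Context weights C[s] and total Z for one ensemble at fixed scalars.

    ``C[s]`` sums the weights of all configurations strictly left of ``s``
    with the adjacency factor to a molecule starting at ``s`` applied.
    """
    n_pos = w_tot.shape[0]
    z_end = np.zeros(l_cis + 1)
    context = np.zeros(n_pos)
    s_old = 0.0
    s_rec = 0.0
    for s in range(n_pos):
        s_rec += z_end[s]
        r = s - d_coop - 1
        if r >= 0:
            s_rec -= z_end[r]
            s_old += z_end[r]
        context[s] = 1.0 + s_old + omega * s_rec
        if w_tot[s] != 0.0:
            z_end[s + l_tf] += w_tot[s] * context[s]
    z_total = 1.0 + z_end[l_tf:].sum()
    return context, z_total


def _backward_context(w_tot: np.ndarray, l_tf: int, l_cis: int, omega: float, d_coop: int):
    """Mirror of :func:`_forward_context`: R[e] for a molecule ending at e."""
    n_pos = w_tot.shape[0]
    b_start = np.zeros(n_pos)
    r_ctx = np.zeros(l_cis + 1)
    t_old = 0.0
    t_rec = 0.0
    for e in range(l_cis, -1, -1):
        leaving = e + d_coop + 1
        if leaving < n_pos:
            t_rec -= b_start[leaving]
            t_old += b_start[leaving]
        if e < n_pos and w_tot[e] != 0.0:
            b_start[e] = w_tot[e] * r_ctx[e + l_tf]
            t_rec += b_start[e]
        r_ctx[e] = 1.0 + t_old + omega * t_rec
    z_total = 1.0 + b_start.sum()
    return r_ctx, z_total


def occupancy_profile(
    table: SiteTable, c1: float, c2: float, c3: float
) -> tuple[np.ndarray, float]:
    """Equilibrium occupancy of every (species, start) placement.

    Returns ``(occ, p_on)`` where ``occ[t, s]`` is the probability that a
    molecule of species ``t`` occupies ``[s, s + l_tf)`` and ``p_on`` the
    RNAP occupancy of the promoter.  Summed over everything that covers a
    base (including RNAP on its footprint) the total occupancy of any base
    is at most 1.
    """
    if min(c1, c2, c3) < 0:
        raise ValueError("concentrations must be non-negative")
    conc = np.array([c1, c2, c3])
    omega = table.params.omega_coop
    d_coop = table.params.d_coop
    w_species = conc[:, None] * table.inv_kd  # (3, n_pos)

    w_off = w_species.sum(axis=0)
    c_off, z_off = _forward_context(w_off, table.l_tf, table.l_cis, omega, d_coop)
    r_off, z_off_b = _backward_context(w_off, table.l_tf, table.l_cis, omega, d_coop)

    factor = table.act_factor()
    blocked = table.overlap_mask()
    w_on = np.where(blocked, 0.0, w_off * factor)
    c_on, z_on = _forward_context(w_on, table.l_tf, table.l_cis, omega, d_coop)
    r_on, _ = _backward_context(w_on, table.l_tf, table.l_cis, omega, d_coop)
    z_on *= table.q_r

    z_tot = z_off + z_on
    ends = np.arange(table.n_pos) + table.l_tf
    occ = np.empty_like(w_species)
    for t in range(3):
        num_off = w_species[t] * c_off * r_off[ends]
        w_on_t = np.where(blocked, 0.0, w_species[t] * factor)
        num_on = table.q_r * w_on_t * c_on * r_on[ends]
        occ[t] = (num_off + num_on) / z_tot
    return occ, z_on / z_tot


def site_occupancy(
    system,
    c1: float,
    c2: float,
    c3: float,
    tf_id: str,
    start: int,
    *,
    matrix=None,
    pm=None,
    params=None,
) -> float:
    """Probability that ``tf_id`` occupies the site starting at ``start``."""
    table = _resolve_table(system, matrix, pm, params)
    if not 0 <= start < table.n_pos:
        raise ValueError(f"start {start} outside the valid range [0, {table.n_pos})")
    occ, _ = occupancy_profile(table, c1, c2, c3)
    return float(occ[TF_IDS.index(tf_id), start])
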