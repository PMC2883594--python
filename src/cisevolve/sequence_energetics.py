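"""Sequence-level binding energetics.

Maps nucleotide and amino-acid sequences to binding free energies and
dissociation constants.  A transcription factor (TF) is represented by the
amino-acid sequence of its DNA-binding domain; each residue contacts exactly
one base pair, and the total binding free energy of a TF for a site is the
sum of the per-contact free energies taken from a 20x4 contact-energy matrix
(in units of kT).  Dissociation constants follow from the energies through a
single calibration constant, ``Kd = K0 * exp(dG)``.

RNA polymerase (RNAP) binds only the core promoter, whose -35 and -10
hexamers are scored against a position-frequency promoter model; the RNAP
binding energy is the negative log-score summed over the twelve hexamer
positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "NUCLEOTIDES",
    "EnergyMatrix",
    "TranscriptionFactor",
    "CisRegion",
    "PromoterModel",
    "SiteAffinity",
    "tf_site_energy",
    "scan_sites",
    "scan_energies",
    "rnap_promoter_energy",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter code
NUCLEOTIDES = "ACGT"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NT_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: width of the RNAP footprint on the cis-regulatory region, in bp
RNAP_FOOTPRINT_BP = 29
#: hexamer offsets relative to the transcription start site (TSS at the
#: right end of the region; the rightmost base is position -1)
MINUS35_OFFSETS = (-35, -30)  # inclusive interval [-35, -30]
MINUS10_OFFSETS = (-12, -7)   # inclusive interval [-12, -7]


def aa_to_indices(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[a] for a in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid amino-acid character {exc.args[0]!r}") from exc


def nt_to_indices(seq: str) -> np.ndarray:
    try:
        return np.array([_NT_INDEX[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide character {exc.args[0]!r}") from exc


@dataclass(frozen=True)
class EnergyMatrix:
    """20x4 amino-acid x nucleotide contact free energies, in kT.

    Rows follow the alphabetical one-letter amino-acid code, columns the
    nucleotides A, C, G, T.
    """

    entries: np.ndarray
    provenance: str = "unspecified"
    value_range: tuple[float, float] = (-3.0, 3.0)

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        if entries.shape != (20, 4):
            raise ValueError(f"energy matrix must be 20x4, got {entries.shape}")
        if not np.all(np.isfinite(entries)):
            raise ValueError("energy matrix entries must be finite")
        lo, hi = self.value_range
        if entries.min() < lo or entries.max() > hi:
            raise ValueError(
                f"energy matrix entries outside configured range [{lo}, {hi}] kT"
            )
        object.__setattr__(self, "entries", entries)

    def energy(self, amino_acid: str, nucleotide: str) -> float:
        return float(self.entries[_AA_INDEX[amino_acid], _NT_INDEX[nucleotide]])

    def min_energy(self, tf_sequence: str) -> float:
        """Lowest (most favorable) achievable site energy for a TF."""
        idx = aa_to_indices(tf_sequence)
        return float(self.entries[idx].min(axis=1).sum())


@dataclass(frozen=True)
class TranscriptionFactor:
    """A TF DNA-binding domain: one amino acid per contacted base pair."""

    id: str
    sequence: str
    role: str = "input"  # "input" (TF1, TF2) or "output" (TF3)

    def __post_init__(self) -> None:
        if self.id not in ("TF1", "TF2", "TF3"):
            raise ValueError(f"TF id must be TF1/TF2/TF3, got {self.id!r}")
        if not self.sequence or any(a not in _AA_INDEX for a in self.sequence):
            raise ValueError("TF sequence must be non-empty over the 20-letter code")
        if self.role not in ("input", "output"):
            raise ValueError(f"role must be 'input' or 'output', got {self.role!r}")

    def __len__(self) -> int:
        return len(self.sequence)


MIN_CIS_LENGTH = 40
DEFAULT_MAX_CIS_LENGTH = 300


@dataclass(frozen=True)
class CisRegion:
    """A cis-regulatory nucleotide sequence directly upstream of the TSS.

    The rightmost base is position -1 relative to the transcription start
    site.  The promoter anatomy is anchored to the right end: the -10
    hexamer occupies [-12, -7], the spacer [-29, -13] and the -35 hexamer
    [-35, -30]; RNAP covers the whole footprint [-35, -7] (29 bp).
    """

    sequence: str
    max_length: int = DEFAULT_MAX_CIS_LENGTH

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n < MIN_CIS_LENGTH:
            raise ValueError(f"cis region must be >= {MIN_CIS_LENGTH} bp, got {n}")
        if n > self.max_length:
            raise ValueError(f"cis region must be <= {self.max_length} bp, got {n}")
        if any(b not in _NT_INDEX for b in self.sequence):
            raise ValueError("cis region must be over the alphabet ACGT")

    def __len__(self) -> int:
        return len(self.sequence)

    # -- left-anchored (0-based string) coordinates of the promoter anatomy --

    @property
    def footprint(self) -> tuple[int, int]:
        """RNAP footprint as a half-open [start, end) string interval."""
        n = len(self.sequence)
        return n + MINUS35_OFFSETS[0], n + MINUS10_OFFSETS[1] + 1

    @property
    def minus35(self) -> str:
        n = len(self.sequence)
        return self.sequence[n + MINUS35_OFFSETS[0] : n + MINUS35_OFFSETS[1] + 1]

    @property
    def minus10(self) -> str:
        n = len(self.sequence)
        return self.sequence[n + MINUS10_OFFSETS[0] : n + MINUS10_OFFSETS[1] + 1]


@dataclass(frozen=True)
class PromoterModel:
    """Per-position nucleotide scores for the two promoter hexamers.

    ``scores[i, b]`` is the observed frequency of base ``b`` at hexamer
    position ``i`` normalized by the random fraction 1/4, so for every
    position the four scores average to 1.  Rows 0-5 are the -35 hexamer
    positions (-35 ... -30), rows 6-11 the -10 hexamer (-12 ... -7).
    """

    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.shape != (12, 4):
            raise ValueError(f"promoter model must be 12x4, got {scores.shape}")
        if np.any(scores <= 0):
            raise ValueError("promoter-model scores must be positive")
        means = scores.mean(axis=1)
        if not np.allclose(means, 1.0, atol=1e-6):
            raise ValueError(
                "promoter-model scores must correspond to frequencies summing "
                "to 1 (mean score per position must be 1)"
            )
        object.__setattr__(self, "scores", scores)

    @property
    def consensus(self) -> str:
        """Highest-scoring base at each of the 12 hexamer positions."""
        return "".join(NUCLEOTIDES[j] for j in self.scores.argmax(axis=1))


@dataclass(frozen=True)
class SiteAffinity:
    """Affinity of one TF for one candidate site on the cis region."""

    tf_id: str
    start: int  # 0-based, half-open [start, start + L_TF)
    dg: float   # binding free energy, kT
    kd: float   # dissociation constant, nM

    def __post_init__(self) -> None:
        if not (math.isfinite(self.kd) and self.kd > 0):
            raise ValueError("Kd must be finite and positive")


def tf_site_energy(tf: TranscriptionFactor, site: str, matrix: EnergyMatrix) -> float:
    """Binding free energy (kT) of ``tf`` for a site of matching length.

    The energy is the sum over positions of the contact energy between the
    i-th amino acid and the i-th base.
    """
    if len(site) != len(tf):
        raise ValueError(
            f"site length {len(site)} does not match TF length {len(tf)}"
        )
    aa = aa_to_indices(tf.sequence)
    nt = nt_to_indices(site)
    return float(matrix.entries[aa, nt].sum())


def scan_energies(
    tf: TranscriptionFactor, cis: CisRegion, matrix: EnergyMatrix
) -> np.ndarray:
    """Vector of binding energies (kT) for every start position on ``cis``."""
    l_tf = len(tf)
    if len(cis) < l_tf:
        raise ValueError("cis region shorter than the TF binding-site length")
    nt = nt_to_indices(cis.sequence)
    windows = np.lib.stride_tricks.sliding_window_view(nt, l_tf)
    aa = aa_to_indices(tf.sequence)
    return matrix.entries[aa[None, :], windows].sum(axis=1)


def scan_sites(
    tf: TranscriptionFactor,
    cis: CisRegion,
    matrix: EnergyMatrix,
    k0: float,
) -> list[SiteAffinity]:
    """All candidate sites of ``tf`` on ``cis`` with energies and Kds.

    Returns exactly ``len(cis) - L_TF + 1`` entries, one per start position,
    with ``Kd = K0 * exp(dG)`` in nM.
    """
    if k0 <= 0:
        raise ValueError("K0 calibration constant must be positive")
    dgs = scan_energies(tf, cis, matrix)
    return [
        SiteAffinity(tf_id=tf.id, start=int(s), dg=float(dg), kd=float(k0 * math.exp(dg)))
        for s, dg in enumerate(dgs)
    ]


def rnap_promoter_energy(cis: CisRegion, pm: PromoterModel) -> float:
    """RNAP binding energy (kT) of the core promoter of ``cis``.

    The -35 and -10 hexamers are scored against the promoter model; the
    energy is the log-score form ``-sum_i ln s(b_i, i)`` over the twelve
    hexamer positions, so sequences closer to the consensus of real
    promoters bind more strongly (lower energy).
    """
    hexamers = cis.minus35 + cis.minus10
    if len(hexamers) != 12:  # pragma: no cover - guarded by CisRegion length
        raise ValueError("cis region too short to contain the promoter anatomy")
    nt = nt_to_indices(hexamers)
    return float(-np.log(pm.scores[np.arange(12), nt]).sum())


def rnap_weight(
    cis: CisRegion, pm: PromoterModel, rnap_nM: float, k0r: float
) -> float:
    """Basal RNAP statistical weight q_R = [RNAP] / Kd_prom.

    ``Kd_prom = K0R * exp(E_prom)`` with the promoter energy from
    :func:`rnap_promoter_energy`.
    """
    if rnap_nM < 0:
        raise ValueError("RNAP concentration must be non-negative")
    if k0r <= 0:
        raise ValueError("K0R calibration constant must be positive")
    energy = rnap_promoter_energy(cis, pm)
    return rnap_nM / (k0r * math.exp(energy))


def calibrate_k0(matrix: EnergyMatrix, tf_sequence: str, kd_best_nM: float = 1.0) -> float:
    """K0 such that the best possible site for ``tf_sequence`` has Kd ``kd_best_nM``.

    With the shipped synthetic matrices this places optimal sites at ~1 nM and
    random sites far above 10^4 nM, so evolution can tune Kds over the
    biologically required 1-10000 nM range.
    """
    return kd_best_nM * math.exp(-matrix.min_energy(tf_sequence))


def calibrate_k0_matrix(matrix: EnergyMatrix, l_tf: int, kd_best_nM: float = 1.0) -> float:
    """K0 such that an average TF's perfect site has Kd ``kd_best_nM``.

    Uses the mean over amino acids of the most favorable contact energy, so
    the calibration depends only on the matrix and the binding-site length,
    not on a particular TF sequence.
    """
    mean_best = float(matrix.entries.min(axis=1).mean())
    return kd_best_nM * math.exp(-l_tf * mean_best)


def calibrate_k0r(pm: PromoterModel, rnap_nM: float = 30.0, q_consensus: float = 1.0) -> float:
    """K0R such that the consensus promoter has weight ``q_consensus``."""
    e_cons = float(-np.log(pm.scores.max(axis=1)).sum())
    return rnap_nM / (q_consensus * math.exp(e_cons))
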