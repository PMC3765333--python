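"""Two-locus transmission model for half-sib families.

A sire that is heterozygous at two linked biallelic SNPs (``T/t`` and
``M/m``) transmits one of four gametes per meiosis: the two parental
haplotypes each with probability ``(1-c)/2`` and the two recombinant
haplotypes each with probability ``c/2``, where ``c`` is the
recombination fraction.  The maternal gamete of each half-sib is an
independent draw from the dam-population haplotype frequencies
``(f_TM, f_Tm, f_tM, f_tm)``, whose deviation from linkage equilibrium
is measured by ``delta = f_TM*f_tm - f_Tm*f_tM``.

Offspring genotypes fall into nine unordered two-locus classes
(``TTMM`` .. ``ttmm``); their probabilities are sums over the 4x4
(sire gamete x dam gamete) table.  Everything downstream -- the EM
estimators, the simulators and the phasing pipeline -- is built on this
complete-data table.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "GAMETE_NAMES",
    "SirePhase",
    "HaplotypeFrequencies",
    "PairGenotypeCounts",
    "delta_bounds",
    "hapfreqs_from",
    "genotype_class_probs",
    "class_probs_from_config",
    "log_likelihood",
]

#: The nine unordered two-locus offspring genotype classes, in the fixed
#: order used for every 9-vector of counts or probabilities.
CLASS_NAMES = (
    "TTMM", "TTMm", "TTmm", "TtMM", "TtMm", "Ttmm", "ttMM", "ttMm", "ttmm",
)

#: Gamete order used for every 4-vector of haplotype frequencies.
GAMETE_NAMES = ("TM", "Tm", "tM", "tm")

# Allele content of each gamete: number of lowercase alleles at locus 1 / 2.
_G1 = np.array([0, 0, 1, 1])
_G2 = np.array([0, 1, 0, 1])

# (sire gamete, dam gamete) -> genotype class index; class index is
# (#t alleles)*3 + (#m alleles).
_CELL_CLASS = (_G1[:, None] + _G1[None, :]) * 3 + (_G2[:, None] + _G2[None, :])

#: Membership tensor M[j, g, d] = 1 iff sire gamete g + dam gamete d
#: produce genotype class j.
CLASS_MEMBERSHIP = np.zeros((9, 4, 4))
for _g in range(4):
    for _d in range(4):
        CLASS_MEMBERSHIP[_CELL_CLASS[_g, _d], _g, _d] = 1.0
del _g, _d


class SirePhase(enum.Enum):
    """Linkage phase of a double-heterozygous sire."""

    COUPLING = "TM/tm"
    REPULSION = "Tm/tM"

    @property
    def parental_gametes(self) -> np.ndarray:
        """Indicator over the 4 gametes of the two parental haplotypes."""
        if self is SirePhase.COUPLING:
            return np.array([1.0, 0.0, 0.0, 1.0])
        return np.array([0.0, 1.0, 1.0, 0.0])

    @property
    def recombinant_gametes(self) -> np.ndarray:
        return 1.0 - self.parental_gametes


def delta_bounds(f_T: float, f_M: float) -> tuple[float, float]:
    """Admissible range of the disequilibrium coefficient.

    All four haplotype frequencies must be nonnegative, which constrains
    ``delta`` to ``[max(-f_T f_M, -f_t f_m), min(f_T f_m, f_t f_M)]``.
    Boundary allele frequencies (0 or 1) collapse the interval to ``(0, 0)``.
    """
    if not (0.0 <= f_T <= 1.0 and 0.0 <= f_M <= 1.0):
        raise ValueError(f"allele frequencies must lie in [0,1]; got {f_T}, {f_M}")
    f_t, f_m = 1.0 - f_T, 1.0 - f_M
    return max(-f_T * f_M, -f_t * f_m), min(f_T * f_m, f_t * f_M)


@dataclass(frozen=True)
class HaplotypeFrequencies:
    """Maternal (dam-population) gamete frequencies for one SNP pair."""

    f_TM: float
    f_Tm: float
    f_tM: float
    f_tm: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError(f"haplotype frequencies outside [0,1]: {arr}")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies must sum to 1; got {arr.sum()!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_TM, self.f_Tm, self.f_tM, self.f_tm], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "HaplotypeFrequencies":
        a = np.asarray(arr, dtype=float)
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))

    @property
    def f_T(self) -> float:
        return self.f_TM + self.f_Tm

    @property
    def f_M(self) -> float:
        return self.f_TM + self.f_tM

    @property
    def f_t(self) -> float:
        return 1.0 - self.f_T

    @property
    def f_m(self) -> float:
        return 1.0 - self.f_M

    @property
    def delta(self) -> float:
        return self.f_TM * self.f_tm - self.f_Tm * self.f_tM


def hapfreqs_from(f_T: float, f_M: float, delta: float) -> HaplotypeFrequencies:
    """Build haplotype frequencies from allele frequencies and ``delta``.

    ``f_TM = delta + f_T f_M``, ``f_Tm = -delta + f_T f_m``,
    ``f_tM = -delta + f_t f_M``, ``f_tm = delta + f_t f_m``.
    """
    lo, hi = delta_bounds(f_T, f_M)
    if delta < lo - 1e-12 or delta > hi + 1e-12:
        raise ValueError(
            f"delta={delta} outside admissible bounds [{lo}, {hi}] "
            f"for f_T={f_T}, f_M={f_M}"
        )
    f_t, f_m = 1.0 - f_T, 1.0 - f_M
    return HaplotypeFrequencies(
        delta + f_T * f_M,
        -delta + f_T * f_m,
        -delta + f_t * f_M,
        delta + f_t * f_m,
    )


@dataclass(frozen=True)
class PairGenotypeCounts:
    """Counts of the nine offspring genotype classes for one family."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (9,):
            raise ValueError(f"counts must be a 9-vector, got shape {arr.shape}")
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be nonnegative integers")
        object.__setattr__(self, "counts", arr.astype(np.int64))

    @property
    def N(self) -> int:
        return int(self.counts.sum())


def class_probs_from_config(
    parental: np.ndarray,
    recombinant: np.ndarray,
    c: float | np.ndarray,
    h: np.ndarray,
) -> np.ndarray:
    """Genotype-class probabilities for an arbitrary sire gamete mix.

    ``parental`` and ``recombinant`` are 4-vectors of multiplicities (each
    summing to 2) such that the sire-gamete distribution is
    ``parental*(1-c)/2 + recombinant*c/2``.  Works for any sire genotype:
    a double heterozygote in either phase, a sire homozygous at one or
    both loci (where the two vectors coincide and ``c`` cancels).
    Broadcasts over leading axes of ``c``/``h``.
    """
    c = np.asarray(c, dtype=float)
    h = np.asarray(h, dtype=float)
    s = (parental * (1.0 - c[..., None]) + recombinant * c[..., None]) / 2.0
    cells = s[..., :, None] * h[..., None, :]
    return np.einsum("jgd,...gd->...j", CLASS_MEMBERSHIP, cells)


def genotype_class_probs(
    phase: SirePhase, c: float, h: HaplotypeFrequencies
) -> np.ndarray:
    """Probabilities of the nine offspring classes for a double-het sire.

    Coupling at ``c`` and repulsion at ``1-c`` give identical vectors.
    """
    if not 0.0 <= c <= 0.5:
        raise ValueError(f"recombination fraction must lie in [0, 0.5]; got {c}")
    return class_probs_from_config(
        phase.parental_gametes, phase.recombinant_gametes, c, h.as_array()
    )


def log_likelihood(
    counts: PairGenotypeCounts | np.ndarray,
    phase: SirePhase,
    c: float,
    h: HaplotypeFrequencies,
) -> float:
    """Multinomial log-likelihood ``sum_j n_j log(phi_j)``.

    The multinomial coefficient is omitted: it is constant in the
    parameters and cancels both in maximisation and in the phase
    posterior.  Uses the convention ``0*log(0) = 0``; a positive count on
    a zero-probability class yields ``-inf``.
    """
    n = counts.counts if isinstance(counts, PairGenotypeCounts) else np.asarray(counts)
    p = genotype_class_probs(phase, c, h)
    mask = n > 0
    if np.any(p[mask] <= 0.0):
        return -math.inf
    return float(np.sum(n[mask] * np.log(p[mask])))
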