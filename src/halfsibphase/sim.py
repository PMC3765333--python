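"""Monte-Carlo generators for half-sib SNP transmission.

Three generators mirror the validation designs used for the estimators
and the phasing pipeline:

* a single half-sib family from a double-heterozygous sire, with
  offspring genotype classes drawn by cumulative-probability inversion
  of uniform deviates;
* a set of families whose sires are themselves drawn from a population
  with the given haplotype frequencies (so sires may be double
  homozygotes, homo-heterozygotes or double heterozygotes);
* a phased chromosome: the paternal gamete carries 0-3 crossovers with
  given probabilities at uniformly placed positions, and the maternal
  haplotype follows a first-order Markov chain driven by per-adjacent-
  pair haplotype frequencies (local LD structure).

Every generator is deterministic under a fixed seed; replicate harnesses
derive per-replicate seeds from the master seed via ``SeedSequence`` so
replicates are order-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .model import (
    HaplotypeFrequencies,
    PairGenotypeCounts,
    SirePhase,
    class_probs_from_config,
    genotype_class_probs,
    hapfreqs_from,
)
from .em import (
    EMConfig,
    FamilyObservation,
    joint_estimate_batch,
    le_estimate_batch,
    multi_family_batch,
    sire_configs,
)

__all__ = [
    "FamilySimSpec",
    "ChromSimSpec",
    "ChromSimResult",
    "ReplicateSummary",
    "simulate_family",
    "simulate_family_counts_batch",
    "simulate_sire",
    "simulate_multi_family",
    "simulate_multi_family_batch",
    "simulate_phased_chromosome",
    "replicate_experiment",
    "replicate_multi_family",
    "table_experiment",
]


@dataclass(frozen=True)
class FamilySimSpec:
    """Design of one simulated half-sib family (double-het sire)."""

    phase: SirePhase = SirePhase.COUPLING
    c: float = 0.0
    delta: float = 0.0
    f_T: float = 0.5
    f_M: float = 0.5
    N: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("family size must be >= 1")
        hapfreqs_from(self.f_T, self.f_M, self.delta)  # validates admissibility

    @property
    def hapfreqs(self) -> HaplotypeFrequencies:
        return hapfreqs_from(self.f_T, self.f_M, self.delta)


def _inversion_draws(u: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Categorical draws by cumulative-probability inversion.

    ``u`` uniforms with any shape; ``probs`` broadcastable against
    ``u[..., None]`` over the last (category) axis.
    """
    cum = np.cumsum(probs, axis=-1)
    return (u[..., None] > cum[..., None, :]).sum(axis=-1).clip(max=probs.shape[-1] - 1)


def simulate_family(spec: FamilySimSpec, rng: np.random.Generator | None = None) -> PairGenotypeCounts:
    """Draw the nine genotype-class counts for one half-sib family."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    p = genotype_class_probs(spec.phase, spec.c, spec.hapfreqs)
    cls = _inversion_draws(rng.uniform(size=spec.N), p)
    return PairGenotypeCounts(np.bincount(cls, minlength=9))


def simulate_family_counts_batch(spec: FamilySimSpec, n_reps: int, seed: int) -> np.ndarray:
    """Counts for ``n_reps`` independent families, one row per replicate.

    Replicate ``r`` uses the ``r``-th child of ``SeedSequence(seed)``, so
    the draw for any replicate does not depend on how many others run.
    """
    p = genotype_class_probs(spec.phase, spec.c, spec.hapfreqs)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    u = np.stack([np.random.default_rng(s).uniform(size=spec.N) for s in children])
    cls = _inversion_draws(u, p)
    flat = np.arange(n_reps)[:, None] * 9 + cls
    return np.bincount(flat.ravel(), minlength=n_reps * 9).reshape(n_reps, 9)


def simulate_sire(
    h: HaplotypeFrequencies, rng: np.random.Generator | int | None = None
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int], SirePhase | None]:
    """Draw a sire as two independent haplotypes from the population.

    Returns ``(hap1, hap2, genotype, phase)`` where each haplotype is a
    pair of allele codes (0 = T/M, 1 = t/m), ``genotype`` counts
    lowercase alleles per locus, and ``phase`` is the realised linkage
    phase if the sire is a double heterozygote (None otherwise).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    g = _inversion_draws(rng.uniform(size=2), h.as_array())
    hap1 = (int(g[0]) // 2, int(g[0]) % 2)
    hap2 = (int(g[1]) // 2, int(g[1]) % 2)
    genotype = (hap1[0] + hap2[0], hap1[1] + hap2[1])
    phase = None
    if genotype == (1, 1):
        phase = SirePhase.COUPLING if hap1[0] == hap1[1] else SirePhase.REPULSION
    return hap1, hap2, genotype, phase


def _progeny_counts_for_sire(
    hap1: tuple[int, int],
    hap2: tuple[int, int],
    c: float,
    h: np.ndarray,
    N: int,
    rng: np.random.Generator,
) -> np.ndarray:
    u = np.zeros(4)
    v = np.zeros(4)
    u[hap1[0] * 2 + hap1[1]] += 1
    u[hap2[0] * 2 + hap2[1]] += 1
    v[hap1[0] * 2 + hap2[1]] += 1
    v[hap2[0] * 2 + hap1[1]] += 1
    p = class_probs_from_config(u, v, c, h)
    cls = _inversion_draws(rng.uniform(size=N), p)
    return np.bincount(cls, minlength=9)


def simulate_multi_family(
    sizes: Sequence[int],
    c: float,
    delta: float,
    f_T: float = 0.5,
    f_M: float = 0.5,
    seed: int = 0,
) -> list[FamilyObservation]:
    """Simulate several families with population-drawn sires.

    Each sire's two haplotypes are drawn from the dam-population
    frequencies; progeny are generated conditional on the realised sire
    genotype and phase.  The estimation-side observations do not record
    the realised phase (it is latent for a double heterozygote).
    """
    h = hapfreqs_from(f_T, f_M, delta)
    ss = np.random.SeedSequence(seed).spawn(len(sizes))
    out = []
    for N, child in zip(sizes, ss):
        rng = np.random.default_rng(child)
        hap1, hap2, genotype, _phase = simulate_sire(h, rng)
        counts = _progeny_counts_for_sire(hap1, hap2, c, h.as_array(), N, rng)
        out.append(FamilyObservation(PairGenotypeCounts(counts), genotype))
    return out


def simulate_multi_family_batch(
    sizes: Sequence[int],
    c: float,
    delta: float,
    f_T: float,
    f_M: float,
    n_reps: int,
    seed: int,
):
    """Vectorised multi-family simulation for the replication harness.

    Returns ``(counts (R,F,9), u (R,F,2,4), v, kmask (R,F,2))`` where the
    config tensors describe each realised sire for the estimation-side
    EM (double-het sires expose both phase configurations; the realised
    phase stays latent).
    """
    h = hapfreqs_from(f_T, f_M, delta)
    F = len(sizes)
    counts = np.zeros((n_reps, F, 9))
    u = np.zeros((n_reps, F, 2, 4))
    v = np.zeros((n_reps, F, 2, 4))
    kmask = np.zeros((n_reps, F, 2), dtype=bool)
    children = np.random.SeedSequence(seed).spawn(n_reps)
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        for i, N in enumerate(sizes):
            hap1, hap2, genotype, _ = simulate_sire(h, rng)
            counts[r, i] = _progeny_counts_for_sire(hap1, hap2, c, h.as_array(), N, rng)
            for k, (uu, vv) in enumerate(sire_configs(genotype, None)):
                u[r, i, k], v[r, i, k] = uu, vv
                kmask[r, i, k] = True
    return counts, u, v, kmask


# ---------------------------------------------------------------------------
# phased chromosome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromSimSpec:
    """Design of a simulated phased chromosome for one half-sib family.

    positions
        Base-pair positions of the (sire-heterozygous) SNPs, strictly
        increasing.
    sire_haplotypes
        (2, S) allele codes of the sire's two phased haplotypes.
    pair_hapfreqs
        (S-1, 4) maternal haplotype frequencies for each consecutive SNP
        pair, ordered (00, 01, 10, 11) over (allele at left, allele at
        right); drives the maternal Markov chain.
    recomb_count_probs
        Probabilities of 0, 1, 2 and 3 crossovers in the sire meiosis.
    """

    positions: np.ndarray
    sire_haplotypes: np.ndarray
    pair_hapfreqs: np.ndarray
    recomb_count_probs: np.ndarray = field(
        default_factory=lambda: np.array([0.511494, 0.398467, 0.081418, 0.00862])
    )
    n_progeny: int = 36
    seed: int = 0
    chromosome: str = "1"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions)
        S = pos.size
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "sire_haplotypes", np.asarray(self.sire_haplotypes))
        object.__setattr__(self, "pair_hapfreqs", np.asarray(self.pair_hapfreqs, float))
        object.__setattr__(
            self, "recomb_count_probs", np.asarray(self.recomb_count_probs, float)
        )
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.sire_haplotypes.shape != (2, S):
            raise ValueError("sire_haplotypes must have shape (2, n_snps)")
        if self.pair_hapfreqs.shape != (S - 1, 4):
            raise ValueError("pair_hapfreqs must have shape (n_snps-1, 4)")
        if abs(self.recomb_count_probs.sum() - 1.0) > 1e-5:
            raise ValueError("recomb_count_probs must sum to 1")
        object.__setattr__(
            self,
            "recomb_count_probs",
            self.recomb_count_probs / self.recomb_count_probs.sum(),
        )


@dataclass
class ChromSimResult:
    """Genotypes plus the generating truth, for scoring phasing output."""

    genotypes: np.ndarray          # (S, P, 2) sorted allele codes
    paternal_origin: np.ndarray    # (S, P) which sire haplotype (0/1)
    paternal_alleles: np.ndarray   # (S, P)
    maternal_alleles: np.ndarray   # (S, P)
    crossovers: list               # per progeny: array of bp positions
    spec: ChromSimSpec

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for p, xs in enumerate(self.crossovers):
            rows.append(
                {
                    "individual": f"calf{p:03d}",
                    "chromosome": self.spec.chromosome,
                    "crossover_bp": ",".join(str(int(x)) for x in xs),
                    "maternal_haplotype": "".join(
                        map(str, self.maternal_alleles[:, p])
                    ),
                }
            )
        return pd.DataFrame(rows)


def simulate_phased_chromosome(spec: ChromSimSpec) -> ChromSimResult:
    """Simulate genotypes of a half-sib family along a phased chromosome.

    Paternal gamete: the crossover count is drawn from
    ``recomb_count_probs``, crossover positions uniformly on the physical
    span; both meiotic products switch haplotype at every crossover and
    one of the two is transmitted with probability 1/2.  Maternal
    gamete: the first SNP allele follows the marginal frequency of the
    first pair, each later SNP the conditional distribution given the
    previous allele implied by that pair's haplotype frequencies.
    """
    rng = np.random.default_rng(spec.seed)
    pos = spec.positions.astype(float)
    S = pos.size
    P = spec.n_progeny
    haps = spec.sire_haplotypes

    # marginal/conditional tables of the maternal chain; a conditioning
    # allele with zero haplotype mass is only tolerable if the chain can
    # never produce it upstream
    pf = spec.pair_hapfreqs
    left_marg = pf[:, :2].sum(axis=1)  # P(left allele = 0) per pair
    m0 = left_marg[0]  # chain marginal of allele 0, propagated left to right
    for i in range(S - 1):
        for a, marg_prev in ((0, m0), (1, 1.0 - m0)):
            if pf[i, 2 * a] + pf[i, 2 * a + 1] <= 0 and marg_prev > 0:
                raise ValueError(
                    f"pair {i}: conditioning allele {a} at SNP {i} has "
                    "zero haplotype mass (inconsistent chain)"
                )
        p00 = pf[i, 0] / max(pf[i, 0] + pf[i, 1], 1e-300)
        p10 = pf[i, 2] / max(pf[i, 2] + pf[i, 3], 1e-300)
        m0 = m0 * p00 + (1.0 - m0) * p10

    pat_origin = np.zeros((S, P), dtype=np.int8)
    crossovers: list[np.ndarray] = []
    k_draws = _inversion_draws(rng.uniform(size=P), spec.recomb_count_probs)
    for p in range(P):
        k = int(k_draws[p])
        xs = np.sort(rng.uniform(pos[0], pos[-1], size=k))
        start = int(rng.integers(0, 2))
        origin = (start + np.searchsorted(xs, pos, side="left")) % 2
        pat_origin[:, p] = origin
        crossovers.append(xs)

    pat_alleles = haps[pat_origin, np.arange(S)[:, None]]

    mat = np.zeros((S, P), dtype=np.int8)
    u = rng.uniform(size=(S, P))
    mat[0] = (u[0] >= left_marg[0]).astype(np.int8)
    for i in range(1, S):
        f = pf[i - 1]
        prev = mat[i - 1]
        denom = np.where(prev == 0, f[0] + f[1], f[2] + f[3])
        p0 = np.where(prev == 0, f[0], f[2]) / np.maximum(denom, 1e-300)
        mat[i] = (u[i] >= p0).astype(np.int8)

    geno = np.stack([pat_alleles, mat], axis=2).astype(np.int8)
    geno.sort(axis=2)  # unordered allele pairs
    return ChromSimResult(
        genotypes=geno,
        paternal_origin=pat_origin,
        paternal_alleles=pat_alleles.astype(np.int8),
        maternal_alleles=mat,
        crossovers=crossovers,
        spec=spec,
    )


def markov_pair_freqs(
    S: int,
    rng: np.random.Generator,
    delta_scale: float = 0.6,
    f_range: tuple[float, float] = (0.15, 0.85),
) -> np.ndarray:
    """Random per-pair maternal haplotype frequencies with positive LD.

    Allele frequencies are drawn uniformly within ``f_range`` (array
    markers are pre-filtered for extreme MAF) and each pair's
    disequilibrium is a random positive fraction ``delta_scale * U`` of
    its admissible maximum, emulating the strong short-range LD of dense
    array data.  Adjacent pairs share the middle SNP's allele frequency
    so the chain is marginally consistent.
    """
    f = rng.uniform(*f_range, size=S)
    out = np.zeros((S - 1, 4))
    for i in range(S - 1):
        fa, fb = f[i], f[i + 1]
        hi = min(fa * (1 - fb), (1 - fa) * fb)
        d = delta_scale * rng.uniform(0.5, 1.0) * hi
        out[i] = [d + fa * fb, -d + fa * (1 - fb), -d + (1 - fa) * fb, d + (1 - fa) * (1 - fb)]
    return out


# ---------------------------------------------------------------------------
# replication harness
# ---------------------------------------------------------------------------

@dataclass
class ReplicateSummary:
    """Mean/SD of estimates across replicates, plus failure accounting."""

    stats: dict                     # parameter -> (mean, sd)
    n_reps: int
    n_failed: int

    def cell(self, param: str, digits: int = 4) -> str:
        m, s = self.stats[param]
        return f"{m:.{digits}f} ({s:.{digits}f})"


_BATCH_ESTIMATORS: dict[str, Callable] = {}


def _summarise(values: dict, n_reps: int) -> ReplicateSummary:
    stats = {}
    n_failed = 0
    for k, arr in values.items():
        arr = np.asarray(arr, dtype=float)
        ok = np.isfinite(arr)
        n_failed = max(n_failed, int((~ok).sum()))
        if ok.sum() == 0:
            stats[k] = (float("nan"), float("nan"))
        else:
            stats[k] = (float(arr[ok].mean()), float(arr[ok].std(ddof=0)))
    return ReplicateSummary(stats=stats, n_reps=n_reps, n_failed=n_failed)


def replicate_experiment(
    spec: FamilySimSpec,
    estimator: str | Callable[[np.ndarray], dict] = "joint",
    n_reps: int = 10_000,
    seed: int = 0,
    cfg: EMConfig = EMConfig(n_starts=0),
) -> ReplicateSummary:
    """Simulate-and-estimate over replicated single families.

    ``estimator`` is ``"joint"`` (joint EM under the sire's known,
    simulated phase), ``"joint_phase"`` (phase-selected joint EM),
    ``"le"`` (linkage-equilibrium-constrained baseline, known phase) or
    a callable mapping a (R, 9) count matrix to a dict of per-replicate
    estimate arrays.  The single-family reference designs fix the sire
    as a known-phase double heterozygote, so the tabulated estimators
    condition on that phase; the default configuration uses the single
    deterministic start (LE frequencies, c = 0.25) because on the
    confounded c/delta likelihood ridge the surface is flat to within
    Monte-Carlo noise and best-of-random-restarts would report an
    arbitrary ridge point rather than a reproducible estimator.
    Replicates whose estimator output is not finite are counted as
    failures and excluded from the summary.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    counts = simulate_family_counts_batch(spec, n_reps, seed)
    if estimator == "joint":
        from .em import _em_multistart

        c, h, ll, n_iter, conv = _em_multistart(
            counts.astype(float),
            spec.phase.parental_gametes,
            spec.phase.recombinant_gametes,
            cfg,
        )
        delta = h[:, 0] * h[:, 3] - h[:, 1] * h[:, 2]
        values = {"c_hat": c, "delta_hat": delta}
    elif estimator == "joint_phase":
        out = joint_estimate_batch(counts, cfg)
        values = {"c_hat": out["c_hat"], "delta_hat": out["delta_hat"]}
    elif estimator == "le":
        out = le_estimate_batch(counts, spec.phase, cfg)
        values = {"c_hat": out["c_hat"]}
    elif callable(estimator):
        values = estimator(counts)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return _summarise(values, n_reps)


def replicate_multi_family(
    sizes: Sequence[int],
    c: float,
    delta: float,
    n_reps: int,
    seed: int = 0,
    f_T: float = 0.5,
    f_M: float = 0.5,
    cfg: EMConfig = EMConfig(n_starts=0),
) -> ReplicateSummary:
    """Replicated multi-family experiment with population-drawn sires."""
    counts, u, v, kmask = simulate_multi_family_batch(
        sizes, c, delta, f_T, f_M, n_reps, seed
    )
    out = multi_family_batch(counts, u, v, kmask, cfg)
    return _summarise({"c_hat": out["c_hat"], "delta_hat": out["delta_hat"]}, n_reps)


#: Family sizes of the standard six-family multi-sire design.
MULTI_FAMILY_SIZES = (94, 77, 106, 81, 79, 100)

_TABLE_C = (0.0, 0.10, 0.20)
_TABLE_DELTA = (-0.10, 0.0, 0.05, 0.10, 0.20)
_TABLE_N = (36, 100, 300, 500, 1000, 2000)
_TABLE4_DELTA = (0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.075, 0.10, 0.125, 0.15, 0.175, 0.20, 0.25)
_TABLE4_C = (0.0, 0.25, 0.50)


def table_experiment(
    table: int,
    n_reps: int,
    seed: int = 0,
    cfg: EMConfig = EMConfig(n_starts=0),
    subset: dict | None = None,
) -> pd.DataFrame:
    """Monte-Carlo summary grids for the four standard designs.

    Tables 1/2: mean (SD) of the joint-EM delta / c estimate over a
    (c, delta, N) lattice with a coupling-phase double-het sire.
    Table 3: the LE-constrained c estimate on the same lattice.
    Table 4: the six-family multi-sire design over (delta, c).
    ``subset`` may restrict the lattice, e.g. ``{"N": [36]}``.
    """
    subset = subset or {}
    ss = np.random.SeedSequence(seed)
    if table in (1, 2, 3):
        cs = subset.get("c", _TABLE_C)
        ds = subset.get("delta", _TABLE_DELTA)
        ns = subset.get("N", _TABLE_N)
        param = "delta_hat" if table == 1 else "c_hat"
        est = "joint" if table in (1, 2) else "le"
        rows = []
        children = iter(ss.spawn(len(cs) * len(ds) * len(ns)))
        for c in cs:
            for d in ds:
                row = {"c": c, "delta": d}
                for N in ns:
                    child = next(children)
                    summ = replicate_experiment(
                        FamilySimSpec(c=c, delta=d, N=N),
                        est, n_reps, seed=child.generate_state(1)[0] % (2**31), cfg=cfg,
                    )
                    row[str(N)] = summ.cell(param)
                rows.append(row)
        return pd.DataFrame(rows)
    if table == 4:
        ds = subset.get("delta", _TABLE4_DELTA)
        cs = subset.get("c", _TABLE4_C)
        rows = []
        children = iter(ss.spawn(len(ds) * len(cs)))
        for d in ds:
            row = {"delta": d}
            for c in cs:
                child = next(children)
                summ = replicate_multi_family(
                    MULTI_FAMILY_SIZES, c, d, n_reps,
                    seed=child.generate_state(1)[0] % (2**31), cfg=cfg,
                )
                row[f"delta_hat@c={c}"] = summ.cell("delta_hat")
                row[f"c_hat@c={c}"] = summ.cell("c_hat")
            rows.append(row)
        return pd.DataFrame(rows)
    raise ValueError("table must be 1, 2, 3 or 4")
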