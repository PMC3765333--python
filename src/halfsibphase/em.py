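"""EM estimators for recombination fraction and linkage disequilibrium.

The observed data for one SNP pair in one half-sib family are the nine
genotype-class counts.  The complete data add, for every offspring, the
identity of the sire gamete (parental or recombinant) and of the dam
gamete.  The E-step distributes each class count over the compatible
cells of the 4x4 gamete table in proportion to their current
probabilities; the M-step re-estimates the dam haplotype frequencies as
normalised expected gamete counts and the recombination fraction as the
expected fraction of recombinant sire gametes.  The observed-data
log-likelihood is nondecreasing across iterations.

All estimators are implemented on a batched core (leading axis =
independent problems) so that Monte-Carlo replication and genome scans
over thousands of SNP pairs run as single vectorised EM sweeps.

A brute-force grid maximiser (:func:`grid_oracle`) built directly on the
likelihood, with the disequilibrium coefficient profiled out by golden
section (the likelihood is concave in ``delta`` for fixed ``c, f_T,
f_M``), serves as the independent check that the EM finds the global
maximum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .model import (
    CLASS_MEMBERSHIP,
    HaplotypeFrequencies,
    PairGenotypeCounts,
    SirePhase,
    class_probs_from_config,
    delta_bounds,
)

__all__ = [
    "EMConfig",
    "JointEstimate",
    "FamilyObservation",
    "DegenerateCountsError",
    "em_single_family",
    "phase_probability",
    "em_le_constrained",
    "em_multi_family",
    "grid_oracle",
    "OracleResult",
    "expected_loglik_surface",
    "SurfaceResult",
    "joint_estimate_batch",
    "le_estimate_batch",
    "multi_family_batch",
]


class DegenerateCountsError(ValueError):
    """Raised when counts carry no information about a parameter
    (e.g. a marker monomorphic in the progeny)."""


@dataclass(frozen=True)
class EMConfig:
    """Convergence and restart policy for the EM estimators.

    tol
        Convergence threshold on the maximum absolute change of
        ``(f_TM, f_Tm, f_tM, f_tm, c)`` between iterations.
    max_iter
        Iteration cap; hitting it flags ``converged=False``.
    n_starts
        Number of random restarts in addition to the default start
        (linkage-equilibrium frequencies from observed allele counts,
        c = 0.25).  The restart with the best final likelihood wins;
        the likelihood surface can be multimodal when recombination and
        disequilibrium are confounded.
    seed
        Seed for the restart RNG (results are deterministic given it).
    """

    tol: float = 1e-8
    max_iter: int = 10_000
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0 or self.max_iter < 1 or self.n_starts < 0:
            raise ValueError("invalid EMConfig")


@dataclass(frozen=True)
class JointEstimate:
    """Joint estimate of recombination fraction and LD for one SNP pair."""

    c_hat: float
    h_hat: HaplotypeFrequencies | None
    delta_hat: float
    loglik_coupling: float
    loglik_repulsion: float
    phase_posterior: float  # probability of phase TM/tm (coupling)
    phase: SirePhase | None
    n_iter: int
    converged: bool
    family_phase_posteriors: tuple[float, ...] | None = None


# ---------------------------------------------------------------------------
# batched EM core
# ---------------------------------------------------------------------------

def _locus_allele_totals(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus counts of the lowercase allele among progeny genotypes."""
    j = np.arange(9)
    t1 = counts @ (j // 3)
    t2 = counts @ (j % 3)
    return t1, t2


def _monomorphic_mask(counts: np.ndarray) -> np.ndarray:
    n = counts.sum(axis=-1)
    t1, t2 = _locus_allele_totals(counts)
    return (t1 == 0) | (t1 == 2 * n) | (t2 == 0) | (t2 == 2 * n)


def _batch_loglik(counts: np.ndarray, pj: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(pj), 0.0)
    ll = terms.sum(axis=-1)
    ll[np.any((pj <= 0) & (counts > 0), axis=-1)] = -np.inf
    return ll


def _em_core(
    counts: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    c0: np.ndarray,
    h0: np.ndarray,
    tol: float,
    max_iter: int,
    le: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run EM on a batch of count vectors.

    ``u``/``v`` are parental/recombinant gamete multiplicity 4-vectors
    (broadcastable against the batch).  With ``le=True`` the dam
    haplotype frequencies are constrained to allele-frequency products
    (delta fixed at 0).  Returns (c, h, loglik, n_iter, converged).
    """
    counts = np.asarray(counts, dtype=float)
    B = counts.shape[0]
    N = counts.sum(axis=1)
    c = np.array(c0, dtype=float).copy()
    h = np.array(h0, dtype=float).copy()
    u = np.broadcast_to(np.asarray(u, float), (B, 4))
    v = np.broadcast_to(np.asarray(v, float), (B, 4))

    n_iter = np.zeros(B, dtype=np.int64)
    converged = np.zeros(B, dtype=bool)
    active = N > 0
    converged[~active] = True

    idx = np.where(active)[0]
    ca, ha = c[idx], h[idx]
    cnts, Na, ua, va = counts[idx], N[idx], u[idx], v[idx]

    for it in range(max_iter):
        s = (ua * (1.0 - ca[:, None]) + va * ca[:, None]) / 2.0
        cells = s[:, :, None] * ha[:, None, :]
        pj = np.einsum("jgd,bgd->bj", CLASS_MEMBERSHIP, cells)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = cnts / pj
        w[~np.isfinite(w)] = 0.0
        cellw = np.einsum("bj,jgd->bgd", w, CLASS_MEMBERSHIP) * cells
        e_dam = cellw.sum(axis=1)  # expected dam-gamete counts, (b, 4)
        # recombinant fraction of each sire-gamete slot
        denom = ua * (1.0 - ca[:, None]) + va * ca[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = va * ca[:, None] / denom
        r[~np.isfinite(r)] = 0.0
        e_rec = (cellw.sum(axis=2) * r).sum(axis=1)

        if le:
            fT = (e_dam[:, 0] + e_dam[:, 1]) / Na
            fM = (e_dam[:, 0] + e_dam[:, 2]) / Na
            fT = np.clip(fT, 0.0, 1.0)
            fM = np.clip(fM, 0.0, 1.0)
            h_new = np.stack(
                [fT * fM, fT * (1 - fM), (1 - fT) * fM, (1 - fT) * (1 - fM)], axis=1
            )
        else:
            h_new = e_dam / Na[:, None]
            h_new /= h_new.sum(axis=1, keepdims=True)
        c_new = np.clip(e_rec / Na, 0.0, 0.5)

        change = np.maximum(np.abs(h_new - ha).max(axis=1), np.abs(c_new - ca))
        ca, ha = c_new, h_new
        done = change < tol
        if done.any():
            gi = idx[done]
            c[gi], h[gi] = ca[done], ha[done]
            n_iter[gi] = it + 1
            converged[gi] = True
            keep = ~done
            idx = idx[keep]
            ca, ha = ca[keep], ha[keep]
            cnts, Na, ua, va = cnts[keep], Na[keep], ua[keep], va[keep]
            if idx.size == 0:
                break
    if idx.size:
        c[idx], h[idx] = ca, ha
        n_iter[idx] = max_iter

    s = (u * (1.0 - c[:, None]) + v * c[:, None]) / 2.0
    cells = s[:, :, None] * h[:, None, :]
    pj = np.einsum("jgd,bgd->bj", CLASS_MEMBERSHIP, cells)
    ll = _batch_loglik(counts, pj)
    ll[N == 0] = 0.0
    return c, h, ll, n_iter, converged


def _default_start(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LE start from observed allele counts (dam share) and c = 0.25."""
    counts = np.asarray(counts, dtype=float)
    N = np.maximum(counts.sum(axis=1), 1.0)
    t1, t2 = _locus_allele_totals(counts)
    # each offspring carries one sire allele (lowercase with prob 1/2 for a
    # het sire) and one dam allele
    fT = np.clip(1.0 - (t1 / N - 0.5), 0.05, 0.95)
    fM = np.clip(1.0 - (t2 / N - 0.5), 0.05, 0.95)
    h0 = np.stack([fT * fM, fT * (1 - fM), (1 - fT) * fM, (1 - fT) * (1 - fM)], axis=1)
    return np.full(counts.shape[0], 0.25), h0


def _random_starts(
    B: int, n_starts: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    c = rng.uniform(0.0, 0.5, size=(n_starts, B))
    h = rng.dirichlet(np.ones(4), size=(n_starts, B))
    return c, h


def _em_multistart(
    counts: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    cfg: EMConfig,
    le: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Best-of-restarts batched EM for a fixed sire-gamete configuration."""
    counts = np.asarray(counts, dtype=float)
    B = counts.shape[0]
    S = cfg.n_starts + 1
    c0 = np.empty((S, B))
    h0 = np.empty((S, B, 4))
    c0[0], h0[0] = _default_start(counts)
    if cfg.n_starts:
        c0[1:], h0[1:] = _random_starts(B, cfg.n_starts, cfg.seed)

    big_counts = np.tile(counts, (S, 1))
    big_u = np.tile(np.broadcast_to(u, (B, 4)), (S, 1))
    big_v = np.tile(np.broadcast_to(v, (B, 4)), (S, 1))
    c, h, ll, n_iter, conv = _em_core(
        big_counts, big_u, big_v, c0.reshape(-1), h0.reshape(-1, 4),
        cfg.tol, cfg.max_iter, le=le,
    )
    c = c.reshape(S, B)
    h = h.reshape(S, B, 4)
    ll = ll.reshape(S, B)
    n_iter = n_iter.reshape(S, B)
    conv = conv.reshape(S, B)
    best = np.argmax(ll, axis=0)
    ar = np.arange(B)
    return c[best, ar], h[best, ar], ll[best, ar], n_iter[best, ar], conv[best, ar]


# ---------------------------------------------------------------------------
# public single-family estimators
# ---------------------------------------------------------------------------

def _check_counts(counts: PairGenotypeCounts | np.ndarray) -> np.ndarray:
    n = counts.counts if isinstance(counts, PairGenotypeCounts) else np.asarray(counts)
    n = PairGenotypeCounts(n).counts  # validates
    return n


def em_single_family(
    counts: PairGenotypeCounts | np.ndarray,
    phase: SirePhase,
    cfg: EMConfig = EMConfig(),
) -> tuple[float, HaplotypeFrequencies, float]:
    """Maximum-likelihood ``(c, h)`` for a double-het sire of known phase.

    Returns ``(c_hat, h_hat, loglik)``.  Refuses markers monomorphic in
    the progeny (no information on that locus) with
    :class:`DegenerateCountsError`.
    """
    n = _check_counts(counts)
    if n.sum() == 0:
        raise DegenerateCountsError("no offspring observations (N = 0)")
    if _monomorphic_mask(n[None, :])[0]:
        raise DegenerateCountsError("marker monomorphic in progeny; estimate refused")
    c, h, ll, n_iter, conv = _em_multistart(
        n[None, :], phase.parental_gametes, phase.recombinant_gametes, cfg
    )
    if not conv[0]:
        warnings.warn("EM did not converge within max_iter", RuntimeWarning)
    return float(c[0]), HaplotypeFrequencies.from_array(h[0]), float(ll[0])


def phase_probability(
    counts: PairGenotypeCounts | np.ndarray,
    cfg: EMConfig = EMConfig(),
) -> tuple[float, JointEstimate]:
    """Posterior probability of coupling phase, with the joint estimate.

    Each phase's likelihood is maximised separately (profile likelihoods)
    and combined with equal priors; the reported ``(c_hat, delta_hat)``
    come from the higher-likelihood phase.  ``N = 0`` returns posterior
    0.5 with an empty estimate.
    """
    n = _check_counts(counts)
    if n.sum() == 0:
        est = JointEstimate(
            math.nan, None, math.nan, 0.0, 0.0, 0.5, None, 0, True
        )
        return 0.5, est
    if _monomorphic_mask(n[None, :])[0]:
        raise DegenerateCountsError("marker monomorphic in progeny; estimate refused")
    out = joint_estimate_batch(n[None, :], cfg)
    if math.isinf(out["loglik_coupling"][0]) and math.isinf(out["loglik_repulsion"][0]):
        raise ValueError("counts impossible under both phases")
    post = float(out["phase_posterior"][0])
    h = HaplotypeFrequencies.from_array(out["h_hat"][0])
    est = JointEstimate(
        c_hat=float(out["c_hat"][0]),
        h_hat=h,
        delta_hat=float(out["delta_hat"][0]),
        loglik_coupling=float(out["loglik_coupling"][0]),
        loglik_repulsion=float(out["loglik_repulsion"][0]),
        phase_posterior=post,
        phase=SirePhase.COUPLING if post >= 0.5 else SirePhase.REPULSION,
        n_iter=int(out["n_iter"][0]),
        converged=bool(out["converged"][0]),
    )
    return post, est


def em_le_constrained(
    counts: PairGenotypeCounts | np.ndarray,
    phase: SirePhase,
    cfg: EMConfig = EMConfig(),
) -> tuple[float, float, float, float]:
    """Recombination fraction under forced linkage equilibrium.

    Maximises the same likelihood with the dam haplotype frequencies
    constrained to allele-frequency products (``delta = 0``).  This is
    the classical single-parent linkage estimator; it is biased whenever
    the dam population is in disequilibrium and serves only as the
    comparison baseline.  Returns ``(c_hat, f_T_hat, f_M_hat, loglik)``.
    """
    n = _check_counts(counts)
    if n.sum() == 0:
        raise DegenerateCountsError("no offspring observations (N = 0)")
    c, h, ll, n_iter, conv = _em_multistart(
        n[None, :], phase.parental_gametes, phase.recombinant_gametes, cfg, le=True
    )
    fT = float(h[0, 0] + h[0, 1])
    fM = float(h[0, 0] + h[0, 2])
    return float(c[0]), fT, fM, float(ll[0])


# ---------------------------------------------------------------------------
# batch APIs (used by the replication harness and the genome scan)
# ---------------------------------------------------------------------------

def joint_estimate_batch(counts: np.ndarray, cfg: EMConfig = EMConfig()) -> dict:
    """Phase-selected joint EM on a batch of 9-class count vectors.

    Returns a dict of per-row arrays: ``c_hat``, ``h_hat`` (B, 4),
    ``delta_hat``, ``phase_posterior``, ``loglik_coupling``,
    ``loglik_repulsion``, ``n_iter``, ``converged``, ``degenerate``.
    Degenerate rows (monomorphic / empty) yield NaN estimates.
    """
    counts = np.asarray(counts, dtype=float)
    deg = _monomorphic_mask(counts) | (counts.sum(axis=1) == 0)
    cc, hc, llc, itc, cvc = _em_multistart(
        counts, SirePhase.COUPLING.parental_gametes,
        SirePhase.COUPLING.recombinant_gametes, cfg,
    )
    cr, hr, llr, itr, cvr = _em_multistart(
        counts, SirePhase.REPULSION.parental_gametes,
        SirePhase.REPULSION.recombinant_gametes, cfg,
    )
    use_c = llc >= llr
    c_hat = np.where(use_c, cc, cr)
    h_hat = np.where(use_c[:, None], hc, hr)
    delta_hat = h_hat[:, 0] * h_hat[:, 3] - h_hat[:, 1] * h_hat[:, 2]
    with np.errstate(over="ignore"):
        post = 1.0 / (1.0 + np.exp(np.clip(llr - llc, -745, 745)))
    both_inf = np.isinf(llc) & np.isinf(llr)
    post[both_inf] = 0.5
    for arr in (c_hat, delta_hat, post):
        arr[deg] = np.nan
    h_hat[deg] = np.nan
    return {
        "c_hat": c_hat,
        "h_hat": h_hat,
        "delta_hat": delta_hat,
        "phase_posterior": post,
        "loglik_coupling": llc,
        "loglik_repulsion": llr,
        "n_iter": np.maximum(itc, itr),
        "converged": cvc & cvr,
        "degenerate": deg,
    }


def le_estimate_batch(
    counts: np.ndarray,
    phase: SirePhase = SirePhase.COUPLING,
    cfg: EMConfig = EMConfig(),
) -> dict:
    """LE-constrained EM on a batch of count vectors (known phase)."""
    counts = np.asarray(counts, dtype=float)
    c, h, ll, n_iter, conv = _em_multistart(
        counts, phase.parental_gametes, phase.recombinant_gametes, cfg, le=True
    )
    return {
        "c_hat": c,
        "f_T_hat": h[:, 0] + h[:, 1],
        "f_M_hat": h[:, 0] + h[:, 2],
        "loglik": ll,
        "n_iter": n_iter,
        "converged": conv,
    }


# ---------------------------------------------------------------------------
# multi-family EM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FamilyObservation:
    """One half-sib family: class counts plus the sire's two-locus genotype.

    ``sire_genotype`` is ``(g1, g2)`` with ``g`` the number of lowercase
    alleles (0, 1 or 2) at each locus.  ``known_phase`` applies only to
    double heterozygotes; when absent the phase is treated as a latent
    two-component mixture.
    """

    counts: PairGenotypeCounts
    sire_genotype: tuple[int, int]
    known_phase: SirePhase | None = None

    def __post_init__(self) -> None:
        g1, g2 = self.sire_genotype
        if g1 not in (0, 1, 2) or g2 not in (0, 1, 2):
            raise ValueError(f"invalid sire genotype {self.sire_genotype}")
        n = self.counts.counts
        j = np.arange(9)
        nt1, nt2 = j // 3, j % 3
        ok = np.ones(9, dtype=bool)
        if g1 == 0:
            ok &= nt1 <= 1
        elif g1 == 2:
            ok &= nt1 >= 1
        if g2 == 0:
            ok &= nt2 <= 1
        elif g2 == 2:
            ok &= nt2 >= 1
        if np.any(n[~ok] > 0):
            raise ValueError(
                "offspring classes inconsistent with sire genotype "
                f"{self.sire_genotype}: counts {n.tolist()}"
            )
        if self.known_phase is not None and (g1, g2) != (1, 1):
            raise ValueError("known_phase only applies to double-het sires")

    @property
    def category(self) -> str:
        g1, g2 = self.sire_genotype
        if (g1, g2) == (1, 1):
            return "double_het"
        if g1 == 1 or g2 == 1:
            return "hom_het"
        return "double_hom"


def _gamete_index(a1: int, a2: int) -> int:
    return a1 * 2 + a2


def sire_configs(genotype: tuple[int, int], known_phase: SirePhase | None):
    """Parental/recombinant gamete multiplicity vectors for a sire genotype.

    Returns a list of ``(u, v)`` pairs -- two entries for a double
    heterozygote of unknown phase (coupling first), one otherwise.
    """
    g1, g2 = genotype
    if (g1, g2) == (1, 1):
        phases = (
            [known_phase]
            if known_phase is not None
            else [SirePhase.COUPLING, SirePhase.REPULSION]
        )
        return [(p.parental_gametes, p.recombinant_gametes) for p in phases]
    a = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g1]
    b = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g2]
    h1, h2 = (a[0], b[0]), (a[1], b[1])
    u = np.zeros(4)
    v = np.zeros(4)
    u[_gamete_index(*h1)] += 1
    u[_gamete_index(*h2)] += 1
    v[_gamete_index(h1[0], h2[1])] += 1
    v[_gamete_index(h2[0], h1[1])] += 1
    return [(u, v)]


def _pack_families(families: Sequence[FamilyObservation]):
    F = len(families)
    counts = np.zeros((F, 9))
    u = np.zeros((F, 2, 4))
    v = np.zeros((F, 2, 4))
    kmask = np.zeros((F, 2), dtype=bool)
    for i, fam in enumerate(families):
        counts[i] = fam.counts.counts
        cfgs = sire_configs(fam.sire_genotype, fam.known_phase)
        for k, (uu, vv) in enumerate(cfgs):
            u[i, k], v[i, k] = uu, vv
            kmask[i, k] = True
    return counts, u, v, kmask


def _multi_em_core(
    counts: np.ndarray,   # (R, F, 9)
    u: np.ndarray,        # (R, F, K, 4)
    v: np.ndarray,
    kmask: np.ndarray,    # (R, F, K)
    c0: np.ndarray,       # (R,)
    h0: np.ndarray,       # (R, 4)
    tol: float,
    max_iter: int,
):
    """Pooled EM across families, batched over replicates.

    Families enter the pooled M-step with N-weighted expected gamete and
    recombination counts; a double-het family of unknown phase
    contributes through its per-iteration phase posterior.  Families
    whose sire is homozygous at a locus carry no information on ``c``
    (their expected recombinant fraction equals the current ``c``), so
    pooling over all families leaves the fixed point determined by the
    double-het families alone.
    """
    R, F, _ = counts.shape
    N = counts.sum(axis=2)           # (R, F)
    Ntot = N.sum(axis=1)             # (R,)
    c = c0.astype(float).copy()
    h = h0.astype(float).copy()
    informative = ((u != v).any(axis=3) & kmask).any(axis=2)  # (R, F)
    c_estimable = informative.any(axis=1)

    n_iter = np.zeros(R, dtype=np.int64)
    converged = np.zeros(R, dtype=bool)
    active = np.ones(R, dtype=bool)
    idx = np.arange(R)
    ca, ha = c.copy(), h.copy()
    cnts, ua, va, km, Na, Nta = counts, u, v, kmask, N, Ntot

    def estep(ca, ha, cnts, ua, va, km, Na):
        s = (ua * (1.0 - ca[:, None, None, None]) + va * ca[:, None, None, None]) / 2.0
        cells = s[..., :, None] * ha[:, None, None, None, :]
        pj = np.einsum("jgd,rfkgd->rfkj", CLASS_MEMBERSHIP, cells)
        with np.errstate(divide="ignore", invalid="ignore"):
            lterms = np.where(cnts[:, :, None, :] > 0, cnts[:, :, None, :] * np.log(pj), 0.0)
        llk = lterms.sum(axis=3)
        llk[np.any((pj <= 0) & (cnts[:, :, None, :] > 0), axis=3)] = -np.inf
        llk = np.where(km, llk, -np.inf)
        mx = llk.max(axis=2, keepdims=True)
        safe_mx = np.where(np.isfinite(mx), mx, 0.0)
        with np.errstate(invalid="ignore"):
            wk = np.where(km & np.isfinite(llk), np.exp(llk - safe_mx), 0.0)
        wk /= np.maximum(wk.sum(axis=2, keepdims=True), 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            w = cnts[:, :, None, :] / pj
        w[~np.isfinite(w)] = 0.0
        cellw = np.einsum("rfkj,jgd->rfkgd", w, CLASS_MEMBERSHIP) * cells
        cellw *= wk[..., None, None]
        e_dam = cellw.sum(axis=(2, 3))   # (R, F, 4)
        denom = ua * (1.0 - ca[:, None, None, None]) + va * ca[:, None, None, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = va * ca[:, None, None, None] / denom
        r[~np.isfinite(r)] = 0.0
        e_rec = (cellw.sum(axis=4) * r).sum(axis=(2, 3))  # (R, F)
        # observed-data loglik per family = logsumexp over configs, equal prior
        nk = km.sum(axis=2)
        sumexp = np.where(km & np.isfinite(llk), np.exp(llk - safe_mx), 0.0).sum(axis=2)
        fam_ll = (
            np.where(np.isfinite(mx[..., 0]), mx[..., 0], -np.inf)
            + np.log(np.maximum(sumexp, 1e-300))
            - np.log(np.maximum(nk, 1))
        )
        return e_dam, e_rec, fam_ll, wk

    for it in range(max_iter):
        e_dam, e_rec, fam_ll, wk = estep(ca, ha, cnts, ua, va, km, Na)
        h_new = e_dam.sum(axis=1) / Nta[:, None]
        h_new /= h_new.sum(axis=1, keepdims=True)
        c_new = np.clip(e_rec.sum(axis=1) / Nta, 0.0, 0.5)
        change = np.maximum(np.abs(h_new - ha).max(axis=1), np.abs(c_new - ca))
        ca, ha = c_new, h_new
        done = change < tol
        if done.any():
            gi = idx[done]
            c[gi], h[gi] = ca[done], ha[done]
            n_iter[gi] = it + 1
            converged[gi] = True
            keep = ~done
            idx = idx[keep]
            ca, ha = ca[keep], ha[keep]
            cnts, ua, va, km, Na, Nta = (
                cnts[keep], ua[keep], va[keep], km[keep], Na[keep], Nta[keep]
            )
            if idx.size == 0:
                break
    if idx.size:
        c[idx], h[idx] = ca, ha
        n_iter[idx] = max_iter

    _, _, fam_ll, wk = estep(
        c, h, counts, u, v, kmask, N
    )
    total_ll = fam_ll.sum(axis=1)
    c = np.where(c_estimable, c, np.nan)
    return c, h, total_ll, n_iter, converged, wk


def multi_family_batch(
    counts: np.ndarray,   # (R, F, 9)
    u: np.ndarray,
    v: np.ndarray,
    kmask: np.ndarray,
    cfg: EMConfig = EMConfig(),
):
    """Best-of-restarts pooled EM, batched over replicates."""
    R = counts.shape[0]
    S = cfg.n_starts + 1
    c0 = np.empty((S, R))
    h0 = np.empty((S, R, 4))
    c0[0], h0[0] = _default_start(counts.sum(axis=1))
    if cfg.n_starts:
        c0[1:], h0[1:] = _random_starts(R, cfg.n_starts, cfg.seed)
    rep = lambda a: np.repeat(a[None], S, axis=0).reshape((S * R,) + a.shape[1:])
    c, h, ll, n_iter, conv, wk = _multi_em_core(
        rep(counts), rep(u), rep(v), rep(kmask),
        c0.reshape(-1), h0.reshape(-1, 4), cfg.tol, cfg.max_iter,
    )
    c = c.reshape(S, R)
    h = h.reshape(S, R, 4)
    ll = ll.reshape(S, R)
    n_iter = n_iter.reshape(S, R)
    conv = conv.reshape(S, R)
    wk = wk.reshape((S, R) + wk.shape[1:])
    best = np.argmax(ll, axis=0)
    ar = np.arange(R)
    return {
        "c_hat": c[best, ar],
        "h_hat": h[best, ar],
        "delta_hat": h[best, ar, 0] * h[best, ar, 3] - h[best, ar, 1] * h[best, ar, 2],
        "loglik": ll[best, ar],
        "n_iter": n_iter[best, ar],
        "converged": conv[best, ar],
        "phase_weights": wk[best, ar],
    }


def em_multi_family(
    families: Sequence[FamilyObservation],
    cfg: EMConfig = EMConfig(),
) -> JointEstimate:
    """Pooled EM over several half-sib families sharing one dam population.

    Dam haplotype frequencies are pooled as family-size-weighted expected
    gamete counts; the recombination fraction likewise, with only
    double-heterozygous sires contributing information.  If no family has
    a double-het sire, ``c_hat`` is NaN and a warning is issued.
    """
    if not families:
        raise ValueError("at least one family required")
    counts, u, v, kmask = _pack_families(families)
    out = multi_family_batch(counts[None], u[None], v[None], kmask[None], cfg)
    c_hat = float(out["c_hat"][0])
    if math.isnan(c_hat):
        warnings.warn(
            "no double-heterozygous sire family: recombination fraction "
            "is not estimable (reported as NaN)",
            RuntimeWarning,
        )
    h = HaplotypeFrequencies.from_array(out["h_hat"][0])
    posts = []
    for i, fam in enumerate(families):
        if fam.category == "double_het" and fam.known_phase is None:
            posts.append(float(out["phase_weights"][0, i, 0]))
        else:
            posts.append(math.nan)
    return JointEstimate(
        c_hat=c_hat,
        h_hat=h,
        delta_hat=float(out["delta_hat"][0]),
        loglik_coupling=float(out["loglik"][0]),
        loglik_repulsion=math.nan,
        phase_posterior=math.nan,
        phase=None,
        n_iter=int(out["n_iter"][0]),
        converged=bool(out["converged"][0]),
        family_phase_posteriors=tuple(posts),
    )


# ---------------------------------------------------------------------------
# brute-force grid oracle
# ---------------------------------------------------------------------------

class OracleResult(NamedTuple):
    c: float
    f_T: float
    f_M: float
    delta: float
    loglik: float


_INVGOLD = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_profile(nn, base, slope, lo, hi, iters: int = 26):
    """Maximise ``sum(nn * log(base + d*slope))`` over ``d`` in [lo, hi].

    The objective is concave in ``d`` (probabilities are affine in the
    disequilibrium coefficient), so golden-section search is exact up to
    the interval-shrinkage tolerance.  Vectorised over the leading axis
    of ``base``/``lo``/``hi``.
    """

    def ll_at(d):
        p = base + d[:, None] * slope
        with np.errstate(divide="ignore", invalid="ignore"):
            return (nn * np.log(np.maximum(p, 1e-300))).sum(axis=1)

    a, b = lo.copy(), hi.copy()
    for _ in range(iters):
        x1 = b - _INVGOLD * (b - a)
        x2 = a + _INVGOLD * (b - a)
        m = ll_at(x1) < ll_at(x2)
        a = np.where(m, x1, a)
        b = np.where(m, b, x2)
    d_opt = (a + b) / 2.0
    return ll_at(d_opt), d_opt


def _profile_delta_ll(
    n: np.ndarray, phase: SirePhase, c_vals: np.ndarray,
    fT: np.ndarray, fM: np.ndarray, top: int = 160,
):
    """Per c-slice, find the best (f_T, f_M, delta) with delta profiled.

    A coarse 17-point delta screen ranks the (f_T, f_M) lattice points;
    the ``top`` candidates per slice are then profiled exactly over
    delta by golden section.  Returns the per-slice best
    (loglik, f_T, f_M, delta).
    """
    nz = np.where(n > 0)[0]
    nn = n[nz].astype(float)
    u, vv = phase.parental_gametes, phase.recombinant_gametes
    fT = fT.ravel()
    fM = fM.ravel()
    lo = np.maximum(-fT * fM, -(1 - fT) * (1 - fM))
    hi = np.minimum(fT * (1 - fM), (1 - fT) * fM)
    h_le = np.stack(
        [fT * fM, fT * (1 - fM), (1 - fT) * fM, (1 - fT) * (1 - fM)], axis=1
    )
    dvec = np.array([1.0, -1.0, -1.0, 1.0])
    tgrid = np.linspace(0.0, 1.0, 17)
    dcoarse = lo[:, None] + tgrid[None, :] * (hi - lo)[:, None]  # (P, 9)
    top = min(top, fT.size)
    out = []
    for c in c_vals:
        s = (u * (1 - c) + vv * c) / 2.0
        A = np.einsum("jgd,g->jd", CLASS_MEMBERSHIP, s)[nz]  # (k, 4)
        base = h_le @ A.T        # (P, k): probs at delta = 0
        slope = A @ dvec         # (k,)
        if fT.size <= 2500:
            # small grid (refinement windows): profile every point exactly;
            # the coarse screen is only worthwhile on the large base lattice
            cand = np.arange(fT.size)
        else:
            p = base[:, None, :] + dcoarse[:, :, None] * slope
            with np.errstate(divide="ignore", invalid="ignore"):
                coarse = (nn * np.log(np.maximum(p, 1e-300))).sum(axis=2).max(axis=1)
            cand = np.argpartition(coarse, -top)[-top:]
        ll, d = _golden_profile(nn, base[cand], slope, lo[cand], hi[cand])
        j = int(np.argmax(ll))
        pi = cand[j]
        out.append((float(ll[j]), float(c), float(fT[pi]), float(fM[pi]), float(d[j])))
    return out


def grid_oracle(
    counts: PairGenotypeCounts | np.ndarray,
    phase: SirePhase,
    grid_step: float = 0.01,
) -> OracleResult:
    """Brute-force likelihood maximiser, independent of the EM.

    Exhaustive lattice over ``c`` in [0, 0.5] and ``f_T, f_M`` in (0, 1)
    at ``grid_step``, with ``delta`` profiled out within its admissible
    bounds (coarse screen plus exact concave golden-section search),
    followed by one local refinement of the ``(c, f_T, f_M)`` lattice
    around the incumbent.
    """
    if grid_step > 0.01 + 1e-12:
        raise ValueError("grid_step must be <= 0.01")
    n = _check_counts(counts)

    def scan(c_vals, fT_vals, fM_vals):
        FT, FM = np.meshgrid(fT_vals, fM_vals, indexing="ij")
        per_slice = _profile_delta_ll(n, phase, c_vals, FT, FM)
        best = max(per_slice, key=lambda t: t[0])
        return best

    c_vals = np.arange(0.0, 0.5 + 1e-12, grid_step)
    f_vals = np.arange(grid_step, 1.0 - grid_step / 2, grid_step)
    best = scan(c_vals, f_vals, f_vals)

    # local lattice refinement around the incumbent, shrinking 10x per
    # round; the extra rounds let boundary maxima (allele frequency or
    # recombination fraction at the edge) be approached closely enough
    window, step = grid_step, grid_step / 10.0
    for _ in range(6):
        _, c0, fT0, fM0, _ = best
        c_ref = np.unique(
            np.clip(np.arange(c0 - window, c0 + window + 1e-15, step), 0.0, 0.5)
        )
        fT_ref = np.unique(
            np.clip(np.arange(fT0 - window, fT0 + window + 1e-15, step), 1e-9, 1 - 1e-9)
        )
        fM_ref = np.unique(
            np.clip(np.arange(fM0 - window, fM0 + window + 1e-15, step), 1e-9, 1 - 1e-9)
        )
        ref = scan(c_ref, fT_ref, fM_ref)
        if ref[0] > best[0]:
            best = ref
        window, step = step, step / 10.0
    ll, c, fT, fM, d = best
    return OracleResult(c=c, f_T=fT, f_M=fM, delta=d, loglik=ll)


# ---------------------------------------------------------------------------
# expected-count likelihood surfaces
# ---------------------------------------------------------------------------

class SurfaceResult(NamedTuple):
    c_values: np.ndarray
    delta_values: np.ndarray
    loglik: np.ndarray        # (len(c), len(delta)); -inf where impossible
    argmax: tuple[float, float]


def expected_loglik_surface(
    true_c: float,
    true_delta: float,
    f_T: float = 0.5,
    f_M: float = 0.5,
    grid_step: float = 0.05,
) -> SurfaceResult:
    """Infinite-sample likelihood surface over ``(c, delta)``.

    Observed counts are replaced by their expectations under the true
    parameters (the surface shape is invariant to the family size, which
    only scales it), and the log-likelihood is evaluated on a
    ``(c, delta)`` lattice with the allele frequencies held at their true
    values.  The lattice argmax shows whether recombination and
    disequilibrium are separable: they are when either true value is 0,
    and confounded otherwise.
    """
    from .model import genotype_class_probs, hapfreqs_from

    h_true = hapfreqs_from(f_T, f_M, true_delta)
    en = genotype_class_probs(SirePhase.COUPLING, true_c, h_true)
    lo, hi = delta_bounds(f_T, f_M)
    c_vals = np.arange(0.0, 0.5 + 1e-12, grid_step)
    d_vals = np.arange(
        math.ceil(lo / grid_step - 1e-9) * grid_step, hi + 1e-12, grid_step
    )
    d_vals = np.round(d_vals / grid_step) * grid_step + 0.0  # kill -0.0
    ll = np.empty((c_vals.size, d_vals.size))
    for i, c in enumerate(c_vals):
        for j, d in enumerate(d_vals):
            h = hapfreqs_from(f_T, f_M, d)
            p = genotype_class_probs(SirePhase.COUPLING, c, h)
            mask = en > 0
            if np.any(p[mask] <= 0):
                ll[i, j] = -np.inf
            else:
                ll[i, j] = float(np.sum(en[mask] * np.log(p[mask])))
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return SurfaceResult(
        c_values=c_vals,
        delta_values=d_vals,
        loglik=ll,
        argmax=(float(c_vals[i]), float(d_vals[j])),
    )
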