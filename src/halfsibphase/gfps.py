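"""Genome Fragmentation Phasing Strategy (GFPS).

Phases a sire and its half-sib progeny from SNP-array genotypes when
only one parent is genotyped.  The strategy:

A.  For every pair of consecutive sire-heterozygous SNPs (overlapping
    pairs: the right SNP of one pair is the left SNP of the next),
    jointly estimate recombination fraction and maternal LD with the EM
    estimator and call the more probable sire phase.  A positive
    recombination estimate terminates the current *fragment* (haplotype
    block) and starts the next: within a fragment no recombination is
    detected between any adjacent pair, so the pairwise phase calls can
    be chained into two complete sire haplotypes.
A3. Progeny are phased by Mendelian rules: a progeny homozygous at a
    sire-het SNP reveals which sire haplotype the whole fragment came
    from; sire-homozygous SNPs reveal the maternal allele directly.
B.  Whole fragments act as highly informative "super-alleles": origin
    switches between adjacent fragments reveal recombination events
    (and, scanned genome-wide, array assembly errors).
C.  Regions of identity (ROIs) — long shared same-origin haplotype
    stretches between two individuals — generalise runs of
    homozygosity and quantify molecular relatedness.

Genotypes are held as integer allele codes (0/1, -1 = missing) in
unordered pairs; readers for PLINK PED/MAP and a transposed TSV dialect
are provided, along with TSV/VCF writers for every output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .em import DegenerateCountsError, EMConfig, joint_estimate_batch

__all__ = [
    "FamilyDataset",
    "Fragment",
    "ScanPair",
    "RecombinationEvent",
    "ROIRecord",
    "PhasedFamily",
    "qc_filter",
    "mendelian_check",
    "pairwise_scan",
    "fragmentize",
    "phase_sire_fragment",
    "phase_progeny",
    "interfragment_linkage",
    "genome_wide_fragment_scan",
    "match_events",
    "informativity_report",
    "compute_rois",
    "run_gfps",
    "read_plink",
    "read_transposed_tsv",
    "dataset_from_chromsim",
]

MISSING = -1

_MAP_COLUMNS = ["snp_id", "chromosome", "position", "allele1", "allele2"]


# ---------------------------------------------------------------------------
# dataset container and IO
# ---------------------------------------------------------------------------

@dataclass
class FamilyDataset:
    """Genotypes of one sire and its half-sib progeny on a SNP map.

    ``snp_map`` has columns snp_id / chromosome / position / allele1 /
    allele2 with positions strictly increasing within chromosome.
    ``sire`` is (S, 2) and ``progeny`` (S, P, 2) of allele codes
    (0 = allele1, 1 = allele2, -1 = missing); allele pairs are unordered
    and stored sorted.
    """

    snp_map: pd.DataFrame
    sire: np.ndarray
    progeny: np.ndarray
    progeny_ids: list[str]
    sire_id: str = "sire"

    def __post_init__(self) -> None:
        self.snp_map = self.snp_map.reset_index(drop=True)
        S = len(self.snp_map)
        if self.sire.shape != (S, 2):
            raise ValueError("sire genotype shape mismatch")
        if self.progeny.shape[0] != S or self.progeny.shape[2] != 2:
            raise ValueError("progeny genotype shape mismatch")
        if len(self.progeny_ids) != self.progeny.shape[1]:
            raise ValueError("progeny_ids length mismatch")
        for chrom, grp in self.snp_map.groupby("chromosome", sort=False):
            if np.any(np.diff(grp["position"].to_numpy()) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing on chromosome {chrom}"
                )

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    @property
    def n_progeny(self) -> int:
        return self.progeny.shape[1]

    def subset(self, keep: np.ndarray) -> "FamilyDataset":
        return FamilyDataset(
            self.snp_map.loc[keep].reset_index(drop=True),
            self.sire[keep],
            self.progeny[keep],
            list(self.progeny_ids),
            self.sire_id,
        )

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.snp_map["chromosome"]))


def _encode_pairs(a1: np.ndarray, a2: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Map two allele-symbol arrays to sorted code pairs; '0' = missing."""
    out = np.full(a1.shape + (2,), MISSING, dtype=np.int8)

    def enc(col):
        c = np.full(col.shape, MISSING, dtype=np.int8)
        for code in (0, 1):
            sym = alleles[:, code]
            c = np.where(col == (sym[:, None] if col.ndim == 2 else sym), code, c)
        return c

    out[..., 0] = enc(a1)
    out[..., 1] = enc(a2)
    miss = (out[..., 0] == MISSING) | (out[..., 1] == MISSING)
    out[miss] = MISSING
    out.sort(axis=-1)
    return out


def read_plink(
    ped_path: str | Path, map_path: str | Path, sire_id: str | None = None
) -> FamilyDataset:
    """Read a PLINK PED/MAP pair into a :class:`FamilyDataset`.

    The sire is the individual named ``sire_id``, or, if omitted, the
    one listed as father (PAT column) of the other samples.  '0' marks a
    missing allele.
    """
    mp = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chromosome", "snp_id", "cm", "position"],
        dtype={"chromosome": str},
    )
    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    S = len(mp)
    if ped.shape[1] != 6 + 2 * S:
        raise ValueError(
            f"PED has {ped.shape[1]} columns; expected {6 + 2 * S} for {S} SNPs"
        )
    iids = ped[1].tolist()
    if sire_id is None:
        fathers = set(ped[2]) - {"0"}
        cand = [i for i in iids if i in fathers]
        if len(cand) != 1:
            raise ValueError("cannot identify the sire; pass sire_id explicitly")
        sire_id = cand[0]
    geno = ped.iloc[:, 6:].to_numpy()
    a1 = geno[:, 0::2].T  # (S, n_ind)
    a2 = geno[:, 1::2].T
    # observed alleles per SNP (lexicographic => allele1)
    alleles = np.empty((S, 2), dtype=object)
    for i in range(S):
        obs = sorted((set(a1[i]) | set(a2[i])) - {"0"})
        if len(obs) > 2:
            raise ValueError(f"SNP {mp['snp_id'][i]} has >2 alleles: {obs}")
        obs = (obs + ["?", "?"])[:2]
        alleles[i] = obs
    a1 = np.where(a1 == "0", "0", a1)
    codes = _encode_pairs(a1, a2, alleles)
    si = iids.index(sire_id)
    keep = [k for k in range(len(iids)) if k != si]
    snp_map = pd.DataFrame(
        {
            "snp_id": mp["snp_id"],
            "chromosome": mp["chromosome"],
            "position": mp["position"].astype(np.int64),
            "allele1": alleles[:, 0],
            "allele2": alleles[:, 1],
        }
    )
    return FamilyDataset(
        snp_map,
        codes[:, si],
        codes[:, keep],
        [iids[k] for k in keep],
        sire_id,
    )


def read_transposed_tsv(
    geno_path: str | Path, map_path: str | Path, sire_id: str
) -> FamilyDataset:
    """Read the transposed dialect: rows = SNPs, columns = individuals.

    Genotypes are ``A/B`` strings ('0/0' or './.' = missing); the first
    column is the SNP id.  The map TSV has columns chromosome, snp_id,
    position (and optionally allele1, allele2).
    """
    g = pd.read_csv(geno_path, sep="\t", dtype=str)
    g = g.set_index(g.columns[0])
    mp = pd.read_csv(map_path, sep="\t", dtype={"chromosome": str})
    mp = mp.set_index("snp_id").loc[g.index].reset_index()
    inds = list(g.columns)
    if sire_id not in inds:
        raise ValueError(f"sire {sire_id!r} not among individuals")
    S = len(g)
    a1 = np.stack([g[i].str.split("/").str[0].to_numpy() for i in inds], axis=1)
    a2 = np.stack([g[i].str.split("/").str[1].to_numpy() for i in inds], axis=1)
    a1 = np.where(np.isin(a1, ["0", "."]), "0", a1)
    a2 = np.where(np.isin(a2, ["0", "."]), "0", a2)
    if {"allele1", "allele2"}.issubset(mp.columns):
        alleles = mp[["allele1", "allele2"]].to_numpy(dtype=object)
    else:
        alleles = np.empty((S, 2), dtype=object)
        for i in range(S):
            obs = sorted((set(a1[i]) | set(a2[i])) - {"0"})
            if len(obs) > 2:
                raise ValueError(f"SNP {mp['snp_id'][i]} has >2 alleles")
            alleles[i] = (obs + ["?", "?"])[:2]
    codes = _encode_pairs(a1, a2, alleles)
    si = inds.index(sire_id)
    keep = [k for k in range(len(inds)) if k != si]
    snp_map = pd.DataFrame(
        {
            "snp_id": mp["snp_id"],
            "chromosome": mp["chromosome"],
            "position": mp["position"].astype(np.int64),
            "allele1": alleles[:, 0],
            "allele2": alleles[:, 1],
        }
    )
    return FamilyDataset(snp_map, codes[:, si], codes[:, keep], [inds[k] for k in keep], sire_id)


def dataset_from_chromsim(result, snp_ids=None) -> FamilyDataset:
    """Wrap a :class:`~halfsibphase.sim.ChromSimResult` as a dataset."""
    spec = result.spec
    S = spec.positions.size
    if snp_ids is None:
        snp_ids = [f"snp{i:05d}" for i in range(S)]
    snp_map = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chromosome": str(spec.chromosome),
            "position": spec.positions.astype(np.int64),
            "allele1": "A",
            "allele2": "B",
        }
    )
    sire = spec.sire_haplotypes.T.astype(np.int8).copy()
    sire.sort(axis=1)
    prog = result.genotypes.astype(np.int8)
    ids = [f"calf{p:03d}" for p in range(spec.n_progeny)]
    return FamilyDataset(snp_map, sire, prog, ids, "sire")


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def qc_filter(
    data: FamilyDataset,
    maf_min: float = 0.10,
    call_rate_min: float = 0.80,
    min_callrate_fraction: float = 2.0 / 3.0,
) -> tuple[FamilyDataset, pd.DataFrame]:
    """Remove SNPs failing call-rate or minor-allele-frequency filters.

    A SNP is kept when it is called in at least
    ``ceil(min_callrate_fraction * n_progeny)`` progeny (with hard
    genotype calls the per-call confidence threshold ``call_rate_min``
    acts upstream of this count) and its MAF over the called sire +
    progeny alleles is at least ``maf_min``.  SNPs with a missing sire
    genotype are also removed: the family-based machinery has no use for
    them.  Returns the filtered dataset and a per-SNP exclusion report.
    """
    if data.n_snps == 0:
        raise ValueError("empty dataset")
    P = data.n_progeny
    called = np.all(data.progeny >= 0, axis=2)  # (S, P)
    n_called = called.sum(axis=1)
    need = int(np.ceil(min_callrate_fraction * P))
    ok_call = n_called >= need

    sire_called = np.all(data.sire >= 0, axis=1)

    prog_alt = np.where(data.progeny >= 0, data.progeny, 0).sum(axis=(1, 2))
    prog_n = 2 * n_called
    sire_alt = np.where(sire_called, data.sire.sum(axis=1), 0)
    total_alt = prog_alt + sire_alt
    total_n = prog_n + 2 * sire_called.astype(int)
    with np.errstate(invalid="ignore"):
        f_alt = np.where(total_n > 0, total_alt / np.maximum(total_n, 1), 0.0)
    maf = np.minimum(f_alt, 1.0 - f_alt)
    ok_maf = maf >= maf_min

    keep = ok_call & ok_maf & sire_called
    reasons = []
    for i in np.where(~keep)[0]:
        why = []
        if not sire_called[i]:
            why.append("sire_missing")
        if not ok_call[i]:
            why.append(f"call_rate({n_called[i]}/{P}<{need})")
        if not ok_maf[i]:
            why.append(f"maf({maf[i]:.3f})")
        reasons.append({"snp_id": data.snp_map["snp_id"][i], "reason": ";".join(why)})
    report = pd.DataFrame(reasons, columns=["snp_id", "reason"])
    if not keep.any():
        raise ValueError(
            "all SNPs removed by QC: "
            f"call_rate={int((~ok_call).sum())}, maf={int((~ok_maf).sum())}, "
            f"sire_missing={int((~sire_called).sum())}"
        )
    return data.subset(keep), report


def mendelian_check(data: FamilyDataset) -> tuple[FamilyDataset, pd.DataFrame]:
    """Drop SNPs with any sire-progeny inheritance inconsistency.

    A called progeny must share at least one allele with the sire.  A
    single violating progeny discards the SNP for the whole family; the
    report lists every (snp, progeny) violation — this is also the
    genotyping-error detection surface.
    """
    called = np.all(data.progeny >= 0, axis=2)
    share = np.zeros_like(called)
    for s in range(2):
        for p in range(2):
            share |= data.progeny[:, :, p] == data.sire[:, None, s]
    viol = called & ~share
    bad = viol.any(axis=1)
    rows = [
        {
            "snp_id": data.snp_map["snp_id"][i],
            "progeny_id": data.progeny_ids[j],
        }
        for i, j in zip(*np.where(viol))
    ]
    report = pd.DataFrame(rows, columns=["snp_id", "progeny_id"])
    return data.subset(~bad), report


# ---------------------------------------------------------------------------
# pairwise scan and fragmentation
# ---------------------------------------------------------------------------

@dataclass
class ScanPair:
    """Joint estimate for one pair of consecutive sire-het SNPs."""

    left: int                 # global row index of the left SNP
    right: int
    left_bp: int
    right_bp: int
    N: int
    status: str               # ok | skipped | degenerate
    c_hat: float = np.nan
    delta_hat: float = np.nan
    phase_posterior: float = np.nan
    loglik_coupling: float = np.nan
    loglik_repulsion: float = np.nan


def _pair_counts(data: FamilyDataset, i: int, j: int) -> tuple[np.ndarray, int]:
    gi = data.progeny[i]
    gj = data.progeny[j]
    ok = np.all(gi >= 0, axis=1) & np.all(gj >= 0, axis=1)
    n1 = gi[ok].sum(axis=1)
    n2 = gj[ok].sum(axis=1)
    cls = n1 * 3 + n2
    return np.bincount(cls, minlength=9), int(ok.sum())


def pairwise_scan(
    data: FamilyDataset,
    chromosome,
    max_pair_bp: int = 50_000_000,
    cfg: EMConfig = EMConfig(),
) -> list[ScanPair]:
    """Joint (c, delta) estimates for consecutive sire-het SNP pairs.

    Sire-homozygous SNPs are phase-trivial (both homologues carry the
    same allele) and are not scanned; pairs spanning more than
    ``max_pair_bp`` are skipped and force a fragment boundary.  Pairs
    whose progeny counts are degenerate (monomorphic or no overlapping
    calls) carry no estimate.
    """
    rows = np.where((data.snp_map["chromosome"] == chromosome).to_numpy())[0]
    sire = data.sire
    het = rows[(sire[rows, 0] != sire[rows, 1]) & np.all(sire[rows] >= 0, axis=1)]
    if het.size < 2:
        warnings.warn(
            f"chromosome {chromosome}: fewer than 2 sire-heterozygous SNPs",
            RuntimeWarning,
        )
        return []
    pos = data.snp_map["position"].to_numpy()
    pairs: list[ScanPair] = []
    counts = []
    live = []
    from .em import _monomorphic_mask  # shared degeneracy rule

    for a, b in zip(het[:-1], het[1:]):
        sp = ScanPair(
            left=int(a), right=int(b),
            left_bp=int(pos[a]), right_bp=int(pos[b]),
            N=0, status="ok",
        )
        if pos[b] - pos[a] > max_pair_bp:
            sp.status = "skipped"
            pairs.append(sp)
            continue
        n, N = _pair_counts(data, a, b)
        sp.N = N
        if N == 0 or _monomorphic_mask(n[None, :].astype(float))[0]:
            sp.status = "degenerate"
            pairs.append(sp)
            continue
        counts.append(n)
        live.append(len(pairs))
        pairs.append(sp)
    if counts:
        out = joint_estimate_batch(np.asarray(counts, dtype=float), cfg)
        for k, idx in enumerate(live):
            sp = pairs[idx]
            sp.c_hat = float(out["c_hat"][k])
            sp.delta_hat = float(out["delta_hat"][k])
            sp.phase_posterior = float(out["phase_posterior"][k])
            sp.loglik_coupling = float(out["loglik_coupling"][k])
            sp.loglik_repulsion = float(out["loglik_repulsion"][k])
    return pairs


def scan_frame(pairs: list[ScanPair], data: FamilyDataset) -> pd.DataFrame:
    ids = data.snp_map["snp_id"]
    return pd.DataFrame(
        [
            {
                "snp1": ids[p.left],
                "snp2": ids[p.right],
                "bp1": p.left_bp,
                "bp2": p.right_bp,
                "N": p.N,
                "c_hat": p.c_hat,
                "delta_hat": p.delta_hat,
                "phase_posterior": p.phase_posterior,
                "loglik_coupling": p.loglik_coupling,
                "loglik_repulsion": p.loglik_repulsion,
                "status": p.status,
            }
            for p in pairs
        ]
    )


@dataclass
class Fragment:
    """Maximal run of consecutive SNPs with no detected recombination."""

    id: int
    chromosome: object
    het_rows: np.ndarray          # global row indices of sire-het SNPs
    start_row: int                # inclusive global span incl. hom SNPs
    end_row: int
    start_bp: int
    end_bp: int
    terminating_c: float | None   # estimate that closed the fragment
    hap1: np.ndarray | None = None  # allele codes over [start_row, end_row]
    hap2: np.ndarray | None = None

    @property
    def n_snps(self) -> int:
        return self.end_row - self.start_row + 1

    def rows(self) -> np.ndarray:
        return np.arange(self.start_row, self.end_row + 1)


def fragmentize(
    pairs: list[ScanPair],
    data: FamilyDataset,
    chromosome,
    c_threshold: float = 1e-4,
    first_id: int = 0,
) -> list[Fragment]:
    """Cut the scanned chromosome into haplotype blocks.

    A pair with ``c_hat > c_threshold`` closes the current fragment at
    its left SNP and opens the next at its right SNP.  Distance-skipped
    pairs, degenerate pairs (no estimate to chain across) and pairs with
    an exactly ambiguous phase posterior also act as boundaries, the
    last with a warning.  Sire-homozygous SNPs between two het SNPs are
    carried by the fragment of the preceding het SNP; leading/trailing
    hom SNPs attach to the first/last fragment.
    """
    rows = np.where((data.snp_map["chromosome"] == chromosome).to_numpy())[0]
    pos = data.snp_map["position"].to_numpy()
    if not pairs:
        return []
    het = [pairs[0].left] + [p.right for p in pairs]
    groups: list[list[int]] = [[het[0]]]
    term: list[float | None] = []
    for p in pairs:
        boundary = False
        if p.status in ("skipped", "degenerate"):
            boundary = True
        elif p.c_hat > c_threshold:
            boundary = True
        elif p.phase_posterior == 0.5:
            warnings.warn(
                "exactly ambiguous phase posterior; fragment split at "
                f"rows {p.left}-{p.right}",
                RuntimeWarning,
            )
            boundary = True
        if boundary:
            term.append(p.c_hat if np.isfinite(p.c_hat) else None)
            groups.append([p.right])
        else:
            groups[-1].append(p.right)
    term.append(None)  # chromosome-final fragment

    frags = []
    chrom_start, chrom_end = rows[0], rows[-1]
    for k, g in enumerate(groups):
        start = chrom_start if k == 0 else g[0]
        if k + 1 < len(groups):
            end = groups[k + 1][0] - 1  # hom SNPs trail the previous fragment
        else:
            end = chrom_end
        frags.append(
            Fragment(
                id=first_id + k,
                chromosome=chromosome,
                het_rows=np.asarray(g),
                start_row=int(start),
                end_row=int(end),
                start_bp=int(pos[start]),
                end_bp=int(pos[end]),
                terminating_c=term[k],
            )
        )
    return frags


def phase_sire_fragment(
    fragment: Fragment, pairs: list[ScanPair], data: FamilyDataset
) -> tuple[np.ndarray, np.ndarray]:
    """Chain pairwise phase calls into the sire's two haplotypes.

    Within the fragment the consecutive-pair phase posteriors are all
    decisive (ambiguous pairs split fragments upstream); a posterior
    above 0.5 aligns allele1-with-allele1 (coupling), below 0.5 crosses
    them.  Sire-homozygous SNPs carry the same allele on both strings.
    The overall labelling of the two haplotypes is arbitrary (hap1
    carries allele1 at the first het SNP).
    """
    rows = fragment.rows()
    S = rows.size
    hap1 = np.full(S, MISSING, dtype=np.int8)
    hap2 = np.full(S, MISSING, dtype=np.int8)
    sire = data.sire
    hom = sire[rows, 0] == sire[rows, 1]
    hap1[hom] = sire[rows[hom], 0]
    hap2[hom] = sire[rows[hom], 0]

    pair_by_left = {p.left: p for p in pairs}
    orient = 0  # 0: hap1 carries allele1 at this het SNP
    for k, r in enumerate(fragment.het_rows):
        if k > 0:
            p = pair_by_left.get(int(fragment.het_rows[k - 1]))
            if p is None or not np.isfinite(p.phase_posterior):
                raise ValueError(
                    f"no usable phase call for pair starting at row "
                    f"{fragment.het_rows[k - 1]}"
                )
            if p.phase_posterior == 0.5:
                raise ValueError("ambiguous phase posterior inside a fragment")
            if p.phase_posterior < 0.5:  # repulsion: strands cross
                orient ^= 1
        i = int(r - fragment.start_row)
        hap1[i] = orient
        hap2[i] = 1 - orient
    fragment.hap1, fragment.hap2 = hap1, hap2
    return hap1, hap2


# ---------------------------------------------------------------------------
# progeny phasing
# ---------------------------------------------------------------------------

@dataclass
class PhasedFamily:
    """Phasing result for one family across all chromosomes."""

    data: FamilyDataset
    fragments: list[Fragment]
    paternal: np.ndarray          # (S, P) allele codes, -1 unknown
    maternal: np.ndarray
    fragment_of_row: np.ndarray   # (S,) fragment id, -1 if unassigned
    fragment_origin: np.ndarray   # (F, P): 0/1 hap label, -1 unknown, -2 conflict
    scan: dict                    # chromosome -> list[ScanPair]
    boundary: pd.DataFrame | None = None
    events: list = field(default_factory=list)
    mismatches: list = field(default_factory=list)

    def fragment_by_id(self, fid: int) -> Fragment:
        return self.fragments[fid]


def phase_progeny(
    fragment: Fragment, data: FamilyDataset
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, list]:
    """Phase all progeny over one sire-phased fragment.

    The paternal origin (which sire haplotype the fragment copy came
    from) is voted by every SNP where the sire is heterozygous and the
    progeny homozygous; all votes must agree, otherwise the span is
    flagged as a conflict (within-fragment recombination or genotyping
    error), left origin-unphased, and every switch in the ordered vote
    sequence is reported as a candidate within-fragment recombination
    (the change-of-inherited-configuration surface of the strategy).
    Given the origin, the paternal allele is the sire-haplotype allele
    at every SNP of the span — including sire-het/progeny-het SNPs,
    which is where phasing creates information — and the maternal
    allele is the genotype minus the paternal one.  Sire-homozygous
    SNPs and progeny-homozygous sire-het SNPs are resolved
    unconditionally.  Returns
    (origin (P,), paternal (S, P), maternal (S, P), mismatches,
    vote_switches) where each vote switch is a global-row interval
    ``(progeny_index, left_row, right_row)``.
    """
    if fragment.hap1 is None:
        raise ValueError("fragment must be sire-phased first")
    rows = fragment.rows()
    S, P = rows.size, data.n_progeny
    g = data.progeny[rows]                   # (S, P, 2)
    called = np.all(g >= 0, axis=2)
    hom = g[:, :, 0] == g[:, :, 1]
    sire_het = fragment.hap1 != fragment.hap2

    origin = np.full(P, MISSING, dtype=np.int8)
    votes1 = sire_het[:, None] & called & hom & (g[:, :, 0] == fragment.hap1[:, None])
    votes2 = sire_het[:, None] & called & hom & (g[:, :, 0] == fragment.hap2[:, None])
    n1 = votes1.sum(axis=0)
    n2 = votes2.sum(axis=0)
    origin[(n1 > 0) & (n2 == 0)] = 0
    origin[(n2 > 0) & (n1 == 0)] = 1
    origin[(n1 > 0) & (n2 > 0)] = -2  # conflict

    # conflicted calves: every label change along the ordered vote
    # sequence is a candidate within-fragment recombination
    vote_switches = []
    for p in np.where(origin == -2)[0]:
        vr = np.where(votes1[:, p] | votes2[:, p])[0]
        lab = votes2[vr, p].astype(np.int8)
        chg = np.where(lab[1:] != lab[:-1])[0]
        for k in chg:
            vote_switches.append(
                (int(p), int(rows[vr[k]]), int(rows[vr[k + 1]]))
            )

    paternal = np.full((S, P), MISSING, dtype=np.int8)
    maternal = np.full((S, P), MISSING, dtype=np.int8)
    mismatches = []

    # sire-homozygous rows: resolved for every called progeny
    sh = ~sire_het
    pat_allele = fragment.hap1  # == hap2 on hom rows
    paternal[sh] = pat_allele[sh, None]
    # maternal = genotype minus the sire allele (Mendelian-checked data
    # always contains it)
    other = np.where(
        g[:, :, 0] == pat_allele[:, None], g[:, :, 1], g[:, :, 0]
    )
    maternal[sh] = np.where(called[sh], other[sh], MISSING)

    # sire-het rows, progeny homozygous: both alleles equal the genotype
    hh = sire_het[:, None] & called & hom
    paternal[hh] = g[:, :, 0][hh]
    maternal[hh] = g[:, :, 0][hh]

    # sire-het rows with known fragment origin: impute the paternal allele
    for p in range(P):
        if origin[p] < 0:
            continue
        hap = fragment.hap1 if origin[p] == 0 else fragment.hap2
        het_rows = np.where(sire_het)[0]
        for i in het_rows:
            a = hap[i]
            if not called[i, p]:
                paternal[i, p] = a  # imputed; maternal stays unknown
            elif g[i, p, 0] == a or g[i, p, 1] == a:
                paternal[i, p] = a
                maternal[i, p] = g[i, p, 1] if g[i, p, 0] == a else g[i, p, 0]
            else:
                # genotype lacks the expected paternal allele
                mismatches.append((int(rows[i]), p))
                paternal[i, p] = MISSING
                maternal[i, p] = MISSING
    return origin, paternal, maternal, mismatches, vote_switches


# ---------------------------------------------------------------------------
# inter-fragment linkage, events, genome-wide scan
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecombinationEvent:
    """A paternal-origin switch between adjacent fragments in one calf."""

    progeny_id: str
    chromosome: object
    left_bp: int      # last origin-informative bp before the switch
    right_bp: int     # first origin-informative bp after it
    position: float   # midpoint assignment

    def __post_init__(self) -> None:
        if self.left_bp >= self.right_bp:
            raise ValueError("event interval must satisfy left < right")


def _vote_rows(fragment: Fragment, data: FamilyDataset) -> np.ndarray:
    """(S, P) mask of origin-informative sites within the fragment."""
    rows = fragment.rows()
    g = data.progeny[rows]
    called = np.all(g >= 0, axis=2)
    hom = g[:, :, 0] == g[:, :, 1]
    sire_het = fragment.hap1 != fragment.hap2
    return sire_het[:, None] & called & hom


def interfragment_linkage(
    result: PhasedFamily, min_informative: int = 1
) -> tuple[pd.DataFrame, list[RecombinationEvent]]:
    """Super-allele linkage between fragments and recombination events.

    Adjacent fragments' haplotype labels are first chained left to right,
    each boundary aligned to minimise the number of origin switches (so
    the boundary recombination estimate is at most 0.5); exact ties are
    flagged unresolved and break the chain.  With labels aligned, each
    calf's genome-ordered sequence of origin-informative votes (sites
    where the sire is heterozygous and the calf homozygous) is walked
    and every label change — whether across a fragment boundary or
    inside a conflicted fragment — emits a
    :class:`RecombinationEvent` bounded by the two flanking vote sites.
    Alignment flips relabel haplotypes and origins in place; allele
    calls are label-free and unaffected.
    """
    data = result.data
    pos = data.snp_map["position"].to_numpy()
    records = []
    events: list[RecombinationEvent] = []
    by_chrom: dict = {}
    for f in result.fragments:
        by_chrom.setdefault(f.chromosome, []).append(f)
    for chrom, frs in by_chrom.items():
        frs = sorted(frs, key=lambda f: f.start_row)
        break_rows: list[int] = []  # chain breaks at unresolved alignments
        for fl, fr in zip(frs[:-1], frs[1:]):
            ol = result.fragment_origin[fl.id]
            orr = result.fragment_origin[fr.id]
            info = (ol >= 0) & (orr >= 0)
            n = int(info.sum())
            unresolved = False
            if n >= max(min_informative, 1):
                s = int((ol[info] != orr[info]).sum())
                if s * 2 > n:
                    _flip_fragment(result, fr)
                    orr = result.fragment_origin[fr.id]
                    s = n - s
                elif s * 2 == n and s > 0:
                    unresolved = True
                c_b = s / n
            else:
                s, c_b = 0, np.nan
                unresolved = n == 0
            if unresolved:
                break_rows.append(fr.start_row)
            records.append(
                {
                    "chromosome": chrom,
                    "left_fragment": fl.id,
                    "right_fragment": fr.id,
                    "n_informative": n,
                    "n_switches": s if n else 0,
                    "c_boundary": c_b,
                    "unresolved_tie": unresolved,
                }
            )
        # unified per-calf vote walk with the aligned labels
        vote_rows = []
        vote_lab = []
        for f in frs:
            rows = f.rows()
            g = data.progeny[rows]
            called = np.all(g >= 0, axis=2)
            hom = g[:, :, 0] == g[:, :, 1]
            sire_het = f.hap1 != f.hap2
            m1 = sire_het[:, None] & called & hom & (g[:, :, 0] == f.hap1[:, None])
            m2 = sire_het[:, None] & called & hom & (g[:, :, 0] == f.hap2[:, None])
            lab = np.full(m1.shape, MISSING, dtype=np.int8)
            lab[m1] = 0
            lab[m2] = 1
            vote_rows.append(rows)
            vote_lab.append(lab)
        all_rows = np.concatenate(vote_rows)
        all_lab = np.concatenate(vote_lab, axis=0)
        order = np.argsort(all_rows, kind="stable")
        all_rows = all_rows[order]
        all_lab = all_lab[order]
        breaks = np.asarray(sorted(break_rows))
        for p in range(data.n_progeny):
            have = all_lab[:, p] >= 0
            r = all_rows[have]
            lab = all_lab[have, p]
            if r.size < 2:
                continue
            chg = np.where(lab[1:] != lab[:-1])[0]
            for k in chg:
                lrow, rrow = int(r[k]), int(r[k + 1])
                if breaks.size and np.any((breaks > lrow) & (breaks <= rrow)):
                    continue  # label comparison invalid across a chain break
                events.append(
                    RecombinationEvent(
                        progeny_id=data.progeny_ids[p],
                        chromosome=chrom,
                        left_bp=int(pos[lrow]),
                        right_bp=int(pos[rrow]),
                        position=(pos[lrow] + pos[rrow]) / 2.0,
                    )
                )
    return pd.DataFrame(
        records,
        columns=[
            "chromosome", "left_fragment", "right_fragment", "n_informative",
            "n_switches", "c_boundary", "unresolved_tie",
        ],
    ), events


def _flip_fragment(result: PhasedFamily, fragment: Fragment) -> None:
    fragment.hap1, fragment.hap2 = fragment.hap2, fragment.hap1
    o = result.fragment_origin[fragment.id]
    flip = o >= 0
    o[flip] = 1 - o[flip]


def genome_wide_fragment_scan(
    result: PhasedFamily, query_id: int
) -> pd.DataFrame:
    """Super-allele recombination estimate of one fragment vs all others.

    Used to flag array mis-assembly: a fragment unlinked to its physical
    neighbours but tightly linked to a distant fragment suggests its
    markers belong elsewhere.  Label alignment is free, so the estimate
    is ``min(s, n-s)/n``; the ranking is ascending.
    """
    oq = result.fragment_origin[query_id]
    rows = []
    for f in result.fragments:
        of = result.fragment_origin[f.id]
        info = (oq >= 0) & (of >= 0)
        n = int(info.sum())
        if n == 0:
            c = np.nan
        else:
            s = int((oq[info] != of[info]).sum())
            c = min(s, n - s) / n
        rows.append(
            {
                "fragment": f.id,
                "chromosome": f.chromosome,
                "start_bp": f.start_bp,
                "end_bp": f.end_bp,
                "n_informative": n,
                "c_hat": c,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("c_hat", na_position="last").reset_index(drop=True)


def match_events(
    true_events: pd.DataFrame,
    detected_events: pd.DataFrame,
    max_distance: float = 3_000_000,
) -> tuple[float, float, pd.DataFrame]:
    """Greedy one-to-one nearest matching of detected to true events.

    Both frames need columns individual / chromosome / position.  Events
    match only within the same calf and chromosome and closer than
    ``max_distance``.  Returns (matched fraction of true events, mean
    absolute distance of matches, match table).
    """
    if len(true_events) == 0:
        return (1.0 if len(detected_events) == 0 else 0.0), 0.0, pd.DataFrame()
    matches = []
    used_d: set = set()
    used_t: set = set()
    cand = []
    for ti, t in true_events.iterrows():
        for di, d in detected_events.iterrows():
            if t["individual"] != d["individual"] or t["chromosome"] != d["chromosome"]:
                continue
            dist = abs(float(t["position"]) - float(d["position"]))
            if dist <= max_distance:
                cand.append((dist, ti, di))
    for dist, ti, di in sorted(cand):
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        matches.append({"true_index": ti, "detected_index": di, "distance": dist})
    frac = len(matches) / len(true_events)
    mean_d = float(np.mean([m["distance"] for m in matches])) if matches else 0.0
    return frac, mean_d, pd.DataFrame(matches)


def informativity_report(result: PhasedFamily) -> pd.DataFrame:
    """Fraction of sire-het/progeny-het sites resolved by fragment phase.

    Such sites are uninformative in isolation (either sire haplotype
    explains the genotype); they become informative exactly when the
    progeny's fragment origin is known.
    """
    data = result.data
    sire_het = data.sire[:, 0] != data.sire[:, 1]
    called = np.all(data.progeny >= 0, axis=2)
    het = called & (data.progeny[:, :, 0] != data.progeny[:, :, 1])
    target = sire_het[:, None] & het
    resolved = target & (result.paternal >= 0)
    rows = []
    for chrom in result.data.chromosomes():
        m = (data.snp_map["chromosome"] == chrom).to_numpy()
        tot = int(target[m].sum())
        res = int(resolved[m].sum())
        rows.append(
            {
                "chromosome": chrom,
                "n_uninformative_sites": tot,
                "n_resolved": res,
                "fraction_resolved": res / tot if tot else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# regions of identity
# ---------------------------------------------------------------------------

@dataclass
class ROIRecord:
    """Shared same-origin haplotype segments between two individuals."""

    individual_a: str
    individual_b: str
    origin: str                       # paternal | maternal
    segments: pd.DataFrame            # chromosome, start_bp, end_bp, n_snps
    n_joint: int                      # jointly phased SNP count
    proportion: float                 # shared / jointly phased (NaN if n_joint=0)


def compute_rois(
    result: PhasedFamily,
    individual_a: str,
    individual_b: str,
    origin: str = "maternal",
    min_snps: int = 20,
    basis: str = "snp",
) -> ROIRecord:
    """Regions of identity between two phased individuals.

    Maximal runs of consecutive SNPs (within a chromosome) where both
    individuals' same-origin alleles are known and identical; runs of at
    least ``min_snps`` SNPs count.  The proportion is the shared SNP
    count over the jointly phased SNP count (``basis="bp"`` uses base
    pairs of the kept segments over the jointly phased span instead).
    """
    if origin not in ("paternal", "maternal"):
        raise ValueError("origin must be 'paternal' or 'maternal'")
    mat = result.paternal if origin == "paternal" else result.maternal
    ia = result.data.progeny_ids.index(individual_a)
    ib = result.data.progeny_ids.index(individual_b)
    a, b = mat[:, ia], mat[:, ib]
    joint = (a >= 0) & (b >= 0)
    same = joint & (a == b)
    pos = result.data.snp_map["position"].to_numpy()
    chroms = result.data.snp_map["chromosome"].to_numpy()
    segs = []
    shared_snps = 0
    i = 0
    S = a.size
    while i < S:
        if not same[i]:
            i += 1
            continue
        j = i
        while j + 1 < S and same[j + 1] and chroms[j + 1] == chroms[i]:
            j += 1
        length = j - i + 1
        if length >= min_snps:
            segs.append(
                {
                    "chromosome": chroms[i],
                    "start_bp": int(pos[i]),
                    "end_bp": int(pos[j]),
                    "n_snps": length,
                }
            )
            shared_snps += length
        i = j + 1
    n_joint = int(joint.sum())
    if n_joint == 0:
        prop = float("nan")
    elif basis == "snp":
        prop = shared_snps / n_joint
    else:
        span = 0
        for chrom in np.unique(chroms):
            m = joint & (chroms == chrom)
            if m.any():
                span += int(pos[m].max() - pos[m].min())
        kept = sum(s["end_bp"] - s["start_bp"] for s in segs)
        prop = kept / span if span else float("nan")
    return ROIRecord(
        individual_a=individual_a,
        individual_b=individual_b,
        origin=origin,
        segments=pd.DataFrame(segs, columns=["chromosome", "start_bp", "end_bp", "n_snps"]),
        n_joint=n_joint,
        proportion=prop,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_gfps(
    data: FamilyDataset,
    cfg: EMConfig = EMConfig(),
    c_threshold: float = 1e-4,
    max_pair_bp: int = 50_000_000,
    apply_qc: bool = True,
    maf_min: float = 0.10,
    min_callrate_fraction: float = 2.0 / 3.0,
) -> PhasedFamily:
    """Full pipeline: QC, scan, fragmentation, phasing, linkage, events."""
    reports = {}
    if apply_qc:
        data, reports["qc"] = qc_filter(
            data, maf_min=maf_min, min_callrate_fraction=min_callrate_fraction
        )
        data, reports["mendel"] = mendelian_check(data)
    S, P = data.n_snps, data.n_progeny
    paternal = np.full((S, P), MISSING, dtype=np.int8)
    maternal = np.full((S, P), MISSING, dtype=np.int8)
    frag_of_row = np.full(S, -1, dtype=np.int32)
    fragments: list[Fragment] = []
    scans: dict = {}
    all_mismatch: list = []
    origins = []
    for chrom in data.chromosomes():
        pairs = pairwise_scan(data, chrom, max_pair_bp=max_pair_bp, cfg=cfg)
        scans[chrom] = pairs
        if not pairs:
            continue
        frags = fragmentize(
            pairs, data, chrom, c_threshold=c_threshold, first_id=len(fragments)
        )
        for f in frags:
            phase_sire_fragment(f, pairs, data)
            o, pat, mat, mism, switches = phase_progeny(f, data)
            rows = f.rows()
            paternal[rows] = pat
            maternal[rows] = mat
            frag_of_row[rows] = f.id
            origins.append(o)
            all_mismatch.extend(mism)
        fragments.extend(frags)
    fragment_origin = (
        np.stack(origins) if origins else np.zeros((0, P), dtype=np.int8)
    )
    result = PhasedFamily(
        data=data,
        fragments=fragments,
        paternal=paternal,
        maternal=maternal,
        fragment_of_row=frag_of_row,
        fragment_origin=fragment_origin,
        scan=scans,
        mismatches=all_mismatch,
    )
    result.boundary, events = interfragment_linkage(result)
    result.events = sorted(
        events, key=lambda e: (str(e.chromosome), e.position, e.progeny_id)
    )
    return result


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _header(comment: str) -> str:
    from . import __version__

    return f"# halfsibphase {__version__}: {comment}\n"


def write_fragments_tsv(result: PhasedFamily, path: str | Path, comment: str = "") -> None:
    df = pd.DataFrame(
        [
            {
                "chromosome": f.chromosome,
                "start_bp": f.start_bp,
                "end_bp": f.end_bp,
                "fragment": f.id,
                "n_snps": f.n_snps,
                "terminating_c": "" if f.terminating_c is None else f.terminating_c,
            }
            for f in result.fragments
        ]
    )
    with open(path, "w") as fh:
        fh.write(_header(f"fragments {comment}"))
        df.to_csv(fh, sep="\t", index=False)


def write_phased_tsv(result: PhasedFamily, path: str | Path, comment: str = "") -> None:
    data = result.data
    sym = data.snp_map[["allele1", "allele2"]].to_numpy(dtype=object)

    def code2sym(i, c):
        return "." if c < 0 else sym[i, c]

    rows = []
    for p, pid in enumerate(data.progeny_ids):
        for i in range(data.n_snps):
            fid = int(result.fragment_of_row[i])
            orig = (
                int(result.fragment_origin[fid, p]) if fid >= 0 else MISSING
            )
            status = (
                "conflict"
                if orig == -2
                else ("resolved" if result.paternal[i, p] >= 0 else "unknown")
            )
            rows.append(
                {
                    "individual": pid,
                    "snp_id": data.snp_map["snp_id"][i],
                    "paternal": code2sym(i, result.paternal[i, p]),
                    "maternal": code2sym(i, result.maternal[i, p]),
                    "fragment": fid,
                    "status": status,
                }
            )
    with open(path, "w") as fh:
        fh.write(_header(f"phased haplotypes {comment}"))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_events_tsv(events, path: str | Path, comment: str = "") -> None:
    df = pd.DataFrame(
        [
            {
                "individual": e.progeny_id,
                "chromosome": e.chromosome,
                "left_bp": e.left_bp,
                "right_bp": e.right_bp,
                "position": e.position,
            }
            for e in events
        ],
        columns=["individual", "chromosome", "left_bp", "right_bp", "position"],
    )
    with open(path, "w") as fh:
        fh.write(_header(f"recombination events {comment}"))
        df.to_csv(fh, sep="\t", index=False)


def write_scan_tsv(result: PhasedFamily, path: str | Path, comment: str = "") -> None:
    frames = [scan_frame(pairs, result.data) for pairs in result.scan.values()]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    with open(path, "w") as fh:
        fh.write(_header(f"pairwise scan {comment}"))
        df.to_csv(fh, sep="\t", index=False)


def write_roi_tsv(rois: list[ROIRecord], path: str | Path, comment: str = "") -> None:
    rows = []
    for r in rois:
        rows.append(
            {
                "individual_a": r.individual_a,
                "individual_b": r.individual_b,
                "origin": r.origin,
                "n_segments": len(r.segments),
                "n_joint_snps": r.n_joint,
                "proportion": r.proportion,
            }
        )
    with open(path, "w") as fh:
        fh.write(_header(f"regions of identity {comment}"))
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def write_phased_vcf(result: PhasedFamily, path: str | Path) -> None:
    """Minimal VCF 4.2 export of progeny haplotypes.

    Resolved sites use the phased separator (paternal|maternal);
    unresolved called genotypes are written unphased.
    """
    data = result.data
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(data.progeny_ids)
            + "\n"
        )
        for i in range(data.n_snps):
            row = data.snp_map.iloc[i]
            gts = []
            for p in range(data.n_progeny):
                pat, mat = result.paternal[i, p], result.maternal[i, p]
                if pat >= 0 and mat >= 0:
                    gts.append(f"{pat}|{mat}")
                else:
                    g = data.progeny[i, p]
                    gts.append("./." if g[0] < 0 else f"{g[0]}/{g[1]}")
            fh.write(
                f"{row['chromosome']}\t{row['position']}\t{row['snp_id']}\t"
                f"{row['allele1']}\t{row['allele2']}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
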