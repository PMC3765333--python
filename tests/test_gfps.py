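"""Phasing-pipeline tests: QC rules, fragmentation, Mendelian phasing,
event detection, ROIs, IO round-trips and simulator-truth comparison."""

import numpy as np
import pandas as pd
import pytest

from halfsibphase import gfps
from halfsibphase.em import EMConfig
from halfsibphase.gfps import (
    Fragment,
    PhasedFamily,
    ScanPair,
    compute_rois,
    fragmentize,
    genome_wide_fragment_scan,
    informativity_report,
    interfragment_linkage,
    match_events,
    mendelian_check,
    pairwise_scan,
    phase_progeny,
    phase_sire_fragment,
    qc_filter,
)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

class TestQC:
    def test_maf_filter(self):
        rng = np.random.default_rng(0)
        S, P = 5, 20
        prog = rng.integers(0, 2, size=(S, P, 2)).astype(np.int8)
        sire = rng.integers(0, 2, size=(S, 2)).astype(np.int8)
        # SNP 2: one copy of allele B in the whole family -> MAF ~ 0.024
        prog[2] = 0
        prog[2, 0, 1] = 1
        sire[2] = 0
        ds = make_dataset(sire, prog)
        out, report = qc_filter(ds)
        assert out.n_snps == 4
        assert "maf" in report["reason"].iloc[0]

    def test_call_rate_rule_generalises_24_of_36(self):
        rng = np.random.default_rng(1)
        S, P = 3, 36
        prog = rng.integers(0, 2, size=(S, P, 2)).astype(np.int8)
        sire = np.tile([0, 1], (S, 1)).astype(np.int8)
        prog[1, :13] = -1  # called in only 23 of 36
        ds = make_dataset(sire, prog)
        out, report = qc_filter(ds)
        assert out.n_snps == 2
        assert "call_rate" in report["reason"].iloc[0]
        # called in exactly 24 progeny passes
        prog2 = prog.copy()
        prog2[1] = rng.integers(0, 2, size=(P, 2))
        prog2[1, :12] = -1
        out2, _ = qc_filter(make_dataset(sire, prog2))
        assert out2.n_snps == 3

    def test_zero_thresholds_identity(self):
        rng = np.random.default_rng(2)
        prog = rng.integers(0, 2, size=(4, 10, 2)).astype(np.int8)
        sire = rng.integers(0, 2, size=(4, 2)).astype(np.int8)
        ds = make_dataset(sire, prog)
        out, report = qc_filter(ds, maf_min=0.0, min_callrate_fraction=0.0)
        assert out.n_snps == 4 and len(report) == 0

    def test_everything_removed_raises(self):
        prog = np.zeros((2, 10, 2), dtype=np.int8)  # monomorphic
        sire = np.zeros((2, 2), dtype=np.int8)
        with pytest.raises(ValueError, match="all SNPs removed"):
            qc_filter(make_dataset(sire, prog))


class TestMendelian:
    def test_opposite_homozygotes_discard_snp(self):
        prog = np.zeros((2, 5, 2), dtype=np.int8)
        prog[0, 3] = [1, 1]  # calf BB under sire AA
        sire = np.zeros((2, 2), dtype=np.int8)
        ds = make_dataset(sire, prog)
        out, report = mendelian_check(ds)
        assert out.n_snps == 1
        assert report.iloc[0]["progeny_id"] == "calf003"

    def test_het_sire_cannot_be_violated(self):
        rng = np.random.default_rng(3)
        prog = rng.integers(0, 2, size=(3, 8, 2)).astype(np.int8)
        sire = np.tile([0, 1], (3, 1)).astype(np.int8)
        out, report = mendelian_check(make_dataset(sire, prog))
        assert out.n_snps == 3 and len(report) == 0


# ---------------------------------------------------------------------------
# fragmentation rules (synthetic scan inputs)
# ---------------------------------------------------------------------------

def _toy_pairs(c_values, statuses=None, posteriors=None):
    pairs = []
    for k, c in enumerate(c_values):
        pairs.append(
            ScanPair(
                left=k, right=k + 1,
                left_bp=(k + 1) * 10**6, right_bp=(k + 2) * 10**6,
                N=36,
                status=(statuses or ["ok"] * len(c_values))[k],
                c_hat=c,
                phase_posterior=(posteriors or [0.999] * len(c_values))[k],
            )
        )
    return pairs


def _toy_het_dataset(S, P=6, seed=0):
    rng = np.random.default_rng(seed)
    sire = np.tile([0, 1], (S, 1)).astype(np.int8)
    prog = rng.integers(0, 2, size=(S, P, 2)).astype(np.int8)
    return make_dataset(sire, prog)


class TestFragmentize:
    def test_positive_estimate_splits(self):
        ds = _toy_het_dataset(6)
        frags = fragmentize(_toy_pairs([0, 0, 0.07, 0, 0]), ds, "1")
        assert [list(f.het_rows) for f in frags] == [[0, 1, 2], [3, 4, 5]]
        assert frags[0].terminating_c == pytest.approx(0.07)
        assert frags[1].terminating_c is None

    def test_all_linked_single_fragment(self):
        ds = _toy_het_dataset(6)
        frags = fragmentize(_toy_pairs([0] * 5), ds, "1")
        assert len(frags) == 1
        assert frags[0].start_row == 0 and frags[0].end_row == 5

    def test_all_recombinant_singleton_fragments(self):
        ds = _toy_het_dataset(4)
        frags = fragmentize(_toy_pairs([0.1, 0.2, 0.3]), ds, "1")
        assert len(frags) == 4
        assert all(len(f.het_rows) == 1 for f in frags)

    def test_skipped_pair_forces_boundary(self):
        ds = _toy_het_dataset(4)
        frags = fragmentize(
            _toy_pairs([0, np.nan, 0], statuses=["ok", "skipped", "ok"]), ds, "1"
        )
        assert [list(f.het_rows) for f in frags] == [[0, 1], [2, 3]]

    def test_ambiguous_posterior_splits_with_warning(self):
        ds = _toy_het_dataset(3)
        with pytest.warns(RuntimeWarning, match="ambiguous"):
            frags = fragmentize(
                _toy_pairs([0, 0], posteriors=[0.999, 0.5]), ds, "1"
            )
        assert len(frags) == 2


class TestSirePhasing:
    def test_coupling_chain(self):
        ds = _toy_het_dataset(3)
        frags = fragmentize(_toy_pairs([0, 0]), ds, "1")
        h1, h2 = phase_sire_fragment(frags[0], _toy_pairs([0, 0]), ds)
        assert list(h1) == [0, 0, 0] and list(h2) == [1, 1, 1]

    def test_repulsion_call_crosses_strands(self):
        ds = _toy_het_dataset(3)
        pairs = _toy_pairs([0, 0], posteriors=[0.999, 0.001])
        frags = fragmentize(pairs, ds, "1")
        h1, h2 = phase_sire_fragment(frags[0], pairs, ds)
        assert list(h1) == [0, 0, 1] and list(h2) == [1, 1, 0]

    def test_homozygous_snps_on_both_strands(self):
        sire = np.array([[0, 1], [1, 1], [0, 1]], dtype=np.int8)
        prog = np.zeros((3, 4, 2), dtype=np.int8)
        ds = make_dataset(sire, prog)
        pairs = [
            ScanPair(left=0, right=2, left_bp=10**6, right_bp=3 * 10**6,
                     N=4, status="ok", c_hat=0.0, phase_posterior=0.999)
        ]
        frags = fragmentize(pairs, ds, "1")
        h1, h2 = phase_sire_fragment(frags[0], pairs, ds)
        assert h1[1] == h2[1] == 1


class TestProgenyPhasing:
    def test_worked_rule_example(self):
        """Sire TMT/tmt; calf (TT, Mm, Tt) -> paternal TMT, maternal Tmt."""
        sire = np.tile([0, 1], (3, 1)).astype(np.int8)
        prog = np.array(
            [[[0, 0]], [[0, 1]], [[0, 1]]], dtype=np.int8
        )  # one calf: TT, Mm, Tt
        ds = make_dataset(sire, prog)
        pairs = _toy_pairs([0, 0])
        frags = fragmentize(pairs, ds, "1")
        phase_sire_fragment(frags[0], pairs, ds)
        origin, pat, mat, mism, switches = phase_progeny(frags[0], ds)
        assert origin[0] == 0
        assert list(pat[:, 0]) == [0, 0, 0]   # T M T
        assert list(mat[:, 0]) == [0, 1, 1]   # T m t
        assert not mism and not switches

    def test_fully_heterozygous_calf_unknown(self):
        sire = np.tile([0, 1], (3, 1)).astype(np.int8)
        prog = np.tile([0, 1], (3, 1, 1)).astype(np.int8)
        ds = make_dataset(sire, prog)
        pairs = _toy_pairs([0, 0])
        frags = fragmentize(pairs, ds, "1")
        phase_sire_fragment(frags[0], pairs, ds)
        origin, pat, mat, mism, _ = phase_progeny(frags[0], ds)
        assert origin[0] == -1
        assert np.all(pat[:, 0] == -1)

    def test_conflicting_votes_flagged_and_reported(self):
        sire = np.tile([0, 1], (4, 1)).astype(np.int8)
        # calf homozygous A at rows 0-1 then homozygous B at rows 2-3:
        # a within-fragment recombination
        prog = np.array(
            [[[0, 0]], [[0, 0]], [[1, 1]], [[1, 1]]], dtype=np.int8
        )
        ds = make_dataset(sire, prog)
        pairs = _toy_pairs([0, 0, 0])
        frags = fragmentize(pairs, ds, "1")
        phase_sire_fragment(frags[0], pairs, ds)
        origin, pat, mat, mism, switches = phase_progeny(frags[0], ds)
        assert origin[0] == -2
        assert switches == [(0, 1, 2)]
        # homozygous sites still resolved unconditionally
        assert list(pat[:, 0]) == [0, 0, 1, 1]

    def test_sire_homozygous_snp_resolves_maternal(self):
        sire = np.array([[0, 0]], dtype=np.int8)
        prog = np.array([[[0, 1]]], dtype=np.int8)
        ds = make_dataset(sire, prog)
        frag = Fragment(
            id=0, chromosome="1", het_rows=np.array([], dtype=int),
            start_row=0, end_row=0, start_bp=10**6, end_bp=10**6,
            terminating_c=None,
            hap1=np.array([0], dtype=np.int8), hap2=np.array([0], dtype=np.int8),
        )
        origin, pat, mat, mism, _ = phase_progeny(frag, ds)
        assert pat[0, 0] == 0 and mat[0, 0] == 1


# ---------------------------------------------------------------------------
# inter-fragment linkage and events
# ---------------------------------------------------------------------------

def _two_fragment_family(origins_left, origins_right, seed=0):
    """Build a phased family with two 3-SNP fragments and prescribed origins.

    Progeny are made homozygous at every sire-het SNP for the prescribed
    haplotype so votes reproduce the requested origins exactly.
    """
    P = len(origins_left)
    S = 6
    sire = np.tile([0, 1], (S, 1)).astype(np.int8)
    prog = np.zeros((S, P, 2), dtype=np.int8)
    for p in range(P):
        for i in range(3):
            a = origins_left[p]
            prog[i, p] = [a, a]
        for i in range(3, 6):
            a = origins_right[p]
            prog[i, p] = [a, a]
    ds = make_dataset(sire, prog)
    pairs = _toy_pairs([0, 0, 0.2, 0, 0])
    frags = fragmentize(pairs, ds, "1")
    paternal = np.full((S, P), -1, dtype=np.int8)
    maternal = np.full((S, P), -1, dtype=np.int8)
    origins = []
    for f in frags:
        phase_sire_fragment(f, pairs, ds)
        o, pat, mat, _, _ = phase_progeny(f, ds)
        paternal[f.rows()] = pat
        maternal[f.rows()] = mat
        origins.append(o)
    return PhasedFamily(
        data=ds,
        fragments=frags,
        paternal=paternal,
        maternal=maternal,
        fragment_of_row=np.repeat([0, 1], 3),
        fragment_origin=np.stack(origins),
        scan={"1": pairs},
    )


class TestInterfragment:
    def test_switch_ratio(self):
        """3 switches among 36 informative calves give c = 0.0833."""
        left = [0] * 36
        right = [0] * 33 + [1] * 3
        fam = _two_fragment_family(left, right)
        boundary, events = interfragment_linkage(fam)
        assert boundary.iloc[0]["n_informative"] == 36
        assert boundary.iloc[0]["c_boundary"] == pytest.approx(3 / 36)
        assert len(events) == 3
        ev = events[0]
        assert ev.left_bp < ev.position < ev.right_bp

    def test_no_switches_no_events(self):
        fam = _two_fragment_family([0, 1] * 6, [0, 1] * 6)
        boundary, events = interfragment_linkage(fam)
        assert boundary.iloc[0]["n_switches"] == 0
        assert events == []

    def test_label_alignment_minimises_switches(self):
        """If most calves 'switch', the labels are flipped instead."""
        left = [0] * 10
        right = [1] * 9 + [0]
        fam = _two_fragment_family(left, right)
        boundary, events = interfragment_linkage(fam)
        assert boundary.iloc[0]["n_switches"] == 1
        assert len(events) == 1
        assert events[0].progeny_id == "calf009"

    def test_exact_tie_flagged_unresolved(self):
        left = [0] * 4
        right = [0, 0, 1, 1]
        fam = _two_fragment_family(left, right)
        boundary, events = interfragment_linkage(fam)
        assert bool(boundary.iloc[0]["unresolved_tie"])
        assert events == []


class TestGenomeWideScan:
    def test_query_against_itself_zero(self):
        fam = _two_fragment_family([0, 1] * 6, [0, 1] * 6)
        df = genome_wide_fragment_scan(fam, 0)
        self_row = df[df["fragment"] == 0].iloc[0]
        assert self_row["c_hat"] == 0.0

    def test_translocated_fragment_found(self):
        """A fragment whose origins copy a distant fragment ranks it first."""
        rng = np.random.default_rng(5)
        shared = rng.integers(0, 2, size=24)
        other = rng.integers(0, 2, size=24)
        fam = _two_fragment_family(list(shared), list(shared))
        df = genome_wide_fragment_scan(fam, 0)
        assert df.iloc[0]["c_hat"] == 0.0
        # unrelated origins sit near 1/2 (alignment-free estimate <= 0.5)
        fam2 = _two_fragment_family(list(shared), list(other))
        df2 = genome_wide_fragment_scan(fam2, 0)
        far = df2[df2["fragment"] == 1].iloc[0]["c_hat"]
        assert 0.2 < far <= 0.5


class TestMatchEvents:
    def _ev(self, rows):
        return pd.DataFrame(rows, columns=["individual", "chromosome", "position"])

    def test_identical_lists(self):
        t = self._ev([("a", "1", 5e6), ("b", "1", 9e6)])
        frac, md, _ = match_events(t, t.copy())
        assert frac == 1.0 and md == 0.0

    def test_empty_detected(self):
        t = self._ev([("a", "1", 5e6)])
        frac, md, _ = match_events(t, self._ev([]))
        assert frac == 0.0

    def test_shifted_detection(self):
        t = self._ev([("a", "1", 5e6), ("a", "1", 20e6)])
        d = self._ev([("a", "1", 6e6), ("a", "1", 21e6)])
        frac, md, _ = match_events(t, d)
        assert frac == 1.0 and md == pytest.approx(1e6)

    def test_distance_cap_and_identity_matching(self):
        t = self._ev([("a", "1", 5e6)])
        d = self._ev([("a", "1", 9e6), ("b", "1", 5e6), ("a", "2", 5e6)])
        frac, md, _ = match_events(t, d, max_distance=3e6)
        assert frac == 0.0


class TestROIs:
    def _fam_with_maternal(self, mat_a, mat_b):
        S = len(mat_a)
        P = 2
        sire = np.tile([0, 1], (S, 1)).astype(np.int8)
        prog = np.zeros((S, P, 2), dtype=np.int8)
        ds = make_dataset(sire, prog)
        maternal = np.stack([mat_a, mat_b], axis=1).astype(np.int8)
        return PhasedFamily(
            data=ds,
            fragments=[],
            paternal=np.zeros((S, P), dtype=np.int8),
            maternal=maternal,
            fragment_of_row=np.zeros(S, dtype=np.int32),
            fragment_origin=np.zeros((0, P), dtype=np.int8),
            scan={},
        )

    def test_identical_haplotypes_full_proportion(self):
        a = np.zeros(100)
        fam = self._fam_with_maternal(a, a)
        roi = compute_rois(fam, "calf000", "calf001", "maternal")
        assert roi.proportion == 1.0
        assert len(roi.segments) == 1

    def test_single_25_snp_run(self):
        a = np.zeros(100)
        b = 1 - a
        b[10:35] = 0  # one shared run of 25
        fam = self._fam_with_maternal(a, b)
        roi = compute_rois(fam, "calf000", "calf001", "maternal")
        assert roi.proportion == pytest.approx(0.25)
        assert roi.segments.iloc[0]["n_snps"] == 25

    def test_runs_below_minimum_excluded(self):
        a = np.zeros(100)
        b = 1 - a
        for start in (0, 30, 60):
            b[start : start + 19] = 0
        fam = self._fam_with_maternal(a, b)
        roi = compute_rois(fam, "calf000", "calf001", "maternal")
        assert roi.proportion == 0.0

    def test_unknown_breaks_runs(self):
        a = np.zeros(50)
        b = np.zeros(50)
        b[25] = -1  # unknown in the middle
        fam = self._fam_with_maternal(a, b)
        roi = compute_rois(fam, "calf000", "calf001", "maternal")
        assert roi.n_joint == 49
        assert len(roi.segments) == 2

    def test_no_joint_snps_undefined(self):
        a = np.full(30, -1)
        fam = self._fam_with_maternal(a, np.zeros(30))
        roi = compute_rois(fam, "calf000", "calf001", "maternal")
        assert np.isnan(roi.proportion)


# ---------------------------------------------------------------------------
# end-to-end against simulator truth
# ---------------------------------------------------------------------------

class TestEndToEnd:
    def test_sire_haplotypes_match_truth_up_to_fragment_swap(
        self, phased_chrom_family
    ):
        sim_res, out = phased_chrom_family
        id2orig = {
            sid: i
            for i, sid in enumerate(
                gfps.dataset_from_chromsim(sim_res).snp_map["snp_id"]
            )
        }
        row_orig = np.array([id2orig[s] for s in out.data.snp_map["snp_id"]])
        t1 = sim_res.spec.sire_haplotypes[0][row_orig]
        t2 = sim_res.spec.sire_haplotypes[1][row_orig]
        for f in out.fragments:
            r = f.rows()
            direct = np.array_equal(f.hap1, t1[r]) and np.array_equal(f.hap2, t2[r])
            swapped = np.array_equal(f.hap1, t2[r]) and np.array_equal(f.hap2, t1[r])
            assert direct or swapped

    def test_progeny_paternal_alleles_match_truth(self, phased_chrom_family):
        sim_res, out = phased_chrom_family
        id2orig = {
            sid: i
            for i, sid in enumerate(
                gfps.dataset_from_chromsim(sim_res).snp_map["snp_id"]
            )
        }
        row_orig = np.array([id2orig[s] for s in out.data.snp_map["snp_id"]])
        truth = sim_res.paternal_alleles[row_orig]
        mask = out.paternal >= 0
        acc = (out.paternal[mask] == truth[mask]).mean()
        assert acc > 0.99

    def test_phased_calls_are_genotype_consistent(self, phased_chrom_family):
        _, out = phased_chrom_family
        both = (out.paternal >= 0) & (out.maternal >= 0)
        called = np.all(out.data.progeny >= 0, axis=2)
        check = both & called
        lo = np.minimum(out.paternal, out.maternal)
        hi = np.maximum(out.paternal, out.maternal)
        assert np.all(lo[check] == out.data.progeny[..., 0][check])
        assert np.all(hi[check] == out.data.progeny[..., 1][check])

    def test_informativity_high_on_dense_map(self, phased_chrom_family):
        _, out = phased_chrom_family
        rep = informativity_report(out)
        assert rep.iloc[0]["fraction_resolved"] > 0.85

    def test_chromosome_order_invariance(self):
        """Two chromosomes analysed together equal their separate analyses."""
        rng = np.random.default_rng(55)
        parts = []
        for chrom in ("1", "2"):
            S = 40
            pos = np.sort(rng.choice(np.arange(1, 10**7), size=S, replace=False))
            from halfsibphase import sim as hsim

            spec = hsim.ChromSimSpec(
                positions=pos,
                sire_haplotypes=np.stack(
                    [np.zeros(S, dtype=np.int8), np.ones(S, dtype=np.int8)]
                ),
                pair_hapfreqs=hsim.markov_pair_freqs(S, rng),
                n_progeny=12,
                seed=int(rng.integers(2**31)),
                chromosome=chrom,
            )
            res = hsim.simulate_phased_chromosome(spec)
            parts.append(gfps.dataset_from_chromsim(res))
        merged = gfps.FamilyDataset(
            pd.concat([p.snp_map for p in parts], ignore_index=True).assign(
                snp_id=lambda d: [f"s{i}" for i in range(len(d))]
            ),
            np.concatenate([p.sire for p in parts]),
            np.concatenate([p.progeny for p in parts]),
            parts[0].progeny_ids,
        )
        out = gfps.run_gfps(merged, cfg=EMConfig(), apply_qc=False)
        for chrom, part in zip(("1", "2"), parts):
            part.snp_map["snp_id"] = [
                f"s{i + (0 if chrom == '1' else 40)}" for i in range(len(part.snp_map))
            ]
            single = gfps.run_gfps(part, cfg=EMConfig(), apply_qc=False)
            m = (merged.snp_map["chromosome"] == chrom).to_numpy()
            assert np.array_equal(out.paternal[m], single.paternal)
            assert np.array_equal(out.maternal[m], single.maternal)


class TestIO:
    def test_plink_round_trip(self, tmp_path):
        map_text = "1 snpA 0 1000\n1 snpB 0 2000\n"
        ped_lines = [
            "FAM sire 0 0 1 0 A B A A",
            "FAM c1 sire 0 2 0 A A A B",
            "FAM c2 sire 0 2 0 B B 0 0",
        ]
        (tmp_path / "f.map").write_text(map_text)
        (tmp_path / "f.ped").write_text("\n".join(ped_lines) + "\n")
        ds = gfps.read_plink(tmp_path / "f.ped", tmp_path / "f.map")
        assert ds.sire_id == "sire"
        assert ds.progeny_ids == ["c1", "c2"]
        assert list(ds.sire[0]) == [0, 1]  # A/B
        assert list(ds.progeny[0, 1]) == [1, 1]  # B/B
        assert list(ds.progeny[1, 1]) == [-1, -1]  # missing

    def test_transposed_tsv_reader(self, tmp_path):
        (tmp_path / "g.tsv").write_text(
            "snp_id\tsire\tc1\nsnpA\tA/B\tA/A\nsnpB\tB/B\t./.\n"
        )
        (tmp_path / "m.tsv").write_text(
            "snp_id\tchromosome\tposition\nsnpA\t1\t100\nsnpB\t1\t200\n"
        )
        ds = gfps.read_transposed_tsv(
            tmp_path / "g.tsv", tmp_path / "m.tsv", "sire"
        )
        assert ds.n_snps == 2 and ds.n_progeny == 1
        assert list(ds.sire[0]) == [0, 1]
        assert list(ds.progeny[1, 0]) == [-1, -1]

    def test_writers_produce_headers(self, tmp_path, phased_chrom_family):
        _, out = phased_chrom_family
        gfps.write_fragments_tsv(out, tmp_path / "f.tsv")
        gfps.write_events_tsv(out.events, tmp_path / "e.tsv")
        gfps.write_scan_tsv(out, tmp_path / "s.tsv")
        for name in ("f.tsv", "e.tsv", "s.tsv"):
            head = (tmp_path / name).read_text().splitlines()[0]
            assert head.startswith("# halfsibphase")

    def test_vcf_export_phased_separator(self, tmp_path, phased_chrom_family):
        _, out = phased_chrom_family
        gfps.write_phased_vcf(out, tmp_path / "p.vcf")
        body = [
            l for l in (tmp_path / "p.vcf").read_text().splitlines()
            if not l.startswith("#")
        ]
        assert any("|" in l for l in body)
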