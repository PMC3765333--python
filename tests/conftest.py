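import numpy as np
import pandas as pd
import pytest

from halfsibphase import gfps, sim
from halfsibphase.em import EMConfig


def make_dataset(sire, progeny, positions=None, chromosome="1"):
    """Toy FamilyDataset from allele-code arrays.

    ``sire``: (S, 2); ``progeny``: (S, P, 2); codes 0/1, -1 missing.
    """
    sire = np.asarray(sire, dtype=np.int8)
    progeny = np.asarray(progeny, dtype=np.int8)
    S, P = progeny.shape[:2]
    if positions is None:
        positions = 1_000_000 * (np.arange(S) + 1)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(S)],
            "chromosome": chromosome,
            "position": np.asarray(positions, dtype=np.int64),
            "allele1": "A",
            "allele2": "B",
        }
    )
    prog = progeny.copy()
    prog.sort(axis=2)
    sr = sire.copy()
    sr.sort(axis=1)
    return gfps.FamilyDataset(
        snp_map, sr, prog, [f"calf{p:03d}" for p in range(P)], "sire"
    )


@pytest.fixture(scope="session")
def chrom_family():
    """A simulated 160-SNP chromosome family with full truth records."""
    rng = np.random.default_rng(2024)
    S = 160
    positions = np.sort(rng.choice(np.arange(1, 50_000_000), size=S, replace=False))
    haps = np.stack([np.zeros(S, dtype=np.int8), np.ones(S, dtype=np.int8)])
    pf = sim.markov_pair_freqs(S, rng)
    spec = sim.ChromSimSpec(
        positions=positions,
        sire_haplotypes=haps,
        pair_hapfreqs=pf,
        n_progeny=36,
        seed=777,
    )
    res = sim.simulate_phased_chromosome(spec)
    return res


@pytest.fixture(scope="session")
def phased_chrom_family(chrom_family):
    ds = gfps.dataset_from_chromsim(chrom_family)
    return chrom_family, gfps.run_gfps(ds, cfg=EMConfig(), apply_qc=True)
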