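import numpy as np
import pandas as pd
import pytest

from mixstock.io import MISSING, GenotypeMatrix, LocusInfo, PanelClass, make_locus_id


def make_matrix(calls, units=None, loci=None, **meta_cols):
    """Build a small GenotypeMatrix from a call array and unit labels."""
    calls = np.asarray(calls, dtype=np.int8)
    n, L = calls.shape
    if loci is None:
        loci = [LocusInfo.from_locus_id(make_locus_id((j % 20) + 1, 10_000_000 + j * 1_000_000,
                                                      PanelClass.DIAGNOSTIC))
                for j in range(L)]
    individuals = [f"ind_{i:03d}" for i in range(n)]
    meta = pd.DataFrame(index=pd.Index(individuals, name="individual"))
    if units is not None:
        meta["sampling_unit"] = list(units)
    for k, v in meta_cols.items():
        meta[k] = list(v)
    return GenotypeMatrix(individuals, loci, calls, meta)


@pytest.fixture(scope="session")
def qc48():
    """48-locus chip with engineered QC failures: 2 sex loci, 1 monomorphic,
    4 loci with >50% missing data and 3 poorly clustering loci supplied as a
    drop list; 38 clean loci should survive."""
    rng = np.random.default_rng(42)
    n = 40
    loci, cols = [], []
    # 20 diagnostic + 21 clean candidate loci
    for j in range(41):
        cls = PanelClass.DIAGNOSTIC if j < 20 else PanelClass.CANDIDATE
        loci.append(LocusInfo.from_locus_id(
            make_locus_id((j % 20) + 1, 5_000_000 + j * 2_000_000, cls)))
        cols.append(rng.binomial(2, 0.5, size=n))
    # 4 candidates exceeding 50% missing (21 of 40 missing)
    for j in range(4):
        loci.append(LocusInfo.from_locus_id(
            make_locus_id(21, 1_000_000 + j * 1_000_000, PanelClass.CANDIDATE)))
        col = rng.binomial(2, 0.5, size=n)
        col[:21] = MISSING
        cols.append(col)
    # 1 monomorphic
    loci.append(LocusInfo.from_locus_id(make_locus_id(22, 1_000_000, PanelClass.CANDIDATE)))
    cols.append(np.zeros(n, dtype=int))
    # 2 sex loci (not literally removed for genotype reasons)
    for j in range(2):
        loci.append(LocusInfo.from_locus_id(
            make_locus_id(23, 1_000_000 + j * 1_000_000, PanelClass.SEX)))
        cols.append(rng.binomial(2, 0.5, size=n))
    calls = np.stack(cols, axis=1)
    units = ["U1"] * (n // 2) + ["U2"] * (n - n // 2)
    g = make_matrix(calls, units=units, loci=loci)
    # the poorly clustering loci are ordinary-looking candidates
    drop_ids = [loci[20].locus_id, loci[21].locus_id, loci[22].locus_id]
    return g, drop_ids


@pytest.fixture(scope="session")
def two_pop_small():
    """Two diverged populations (p = 0.9 vs 0.1 at 20 loci), 30 each, plus a
    mechanically mixed unit of 40 at 40% western origin."""
    from mixstock.simulate import SimulationConfig, simulate

    cfg = SimulationConfig(seed=7, n_diagnostic=20,
                           units={"W": (30, 1.0), "E": (30, 0.0), "MIX": (40, 0.4)})
    return simulate(cfg)
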