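import numpy as np
import pytest

from foxscape.genodata import GenotypeTable, packaged_table1
from foxscape.simulate import SimConfig, simulate_metapopulation


def build_gt(rows, loci, repeat=False, dates=None, sexes=None):
    """rows: list of (individual, site, [call, ...]) with call a pair of
    allele strings or None for missing."""
    inds = [r[0] for r in rows]
    site_of = {r[0]: r[1] for r in rows}
    calls = np.empty((len(rows), len(loci), 2), dtype=object)
    for i, (_, _, cs) in enumerate(rows):
        for j, c in enumerate(cs):
            calls[i, j] = (None, None) if c is None else c
    return GenotypeTable(inds, list(loci), calls, site_of,
                         date_of=dates or {}, sex_of=sexes or {},
                         repeat_loci=set(loci) if repeat else set())


@pytest.fixture(scope="session")
def table1():
    return packaged_table1()


@pytest.fixture(scope="session")
def synth6():
    """The 6-site synthetic fixture used across the suite (fixed seed)."""
    cfg = SimConfig(n_sites=6, generations=30, census=80, sample_size=25,
                    seed=11)
    return simulate_metapopulation(cfg)


@pytest.fixture(scope="session")
def two_pop_gt():
    """Two strongly diverged sites: fixed for different alleles at 13 loci."""
    rows = []
    for s, allele in (("A", "101"), ("B", "115")):
        for i in range(12):
            rows.append((f"{s}{i}", s, [(allele, allele)] * 13))
    return build_gt(rows, [f"L{j}" for j in range(13)], repeat=True)
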