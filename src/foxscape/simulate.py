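"""Forward metapopulation simulator for landscape-genetic analyses.

Emulates the study design the analysis modules assume: several sites founded
independently by small numbers of pairs drawn from a shared source pool
(fur-farm-like stock), founder bottlenecks, drift over tens of generations
with non-overlapping generations and an even sex ratio, sex-biased migration
between sites weighted by the inverse of a resistance-landscape distance,
and maternally inherited haplotypes that move only with females.

Reproduction is random union of gametes within a site (a monogamous-pair
option exists for mating-system sensitivity checks). Microsatellite mutation
is stepwise (SMM) at a low default rate and can be switched off for
calibration runs. Everything is driven by a single seeded generator, so a
fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genodata import (DataError, DistanceMatrix, GenotypeTable,
                       HaplotypeCounts, RasterGrid, SiteMap)
from .landscape import resistance_distance

__all__ = ["SimConfig", "SimTruth", "simulate_metapopulation",
           "simulate_hierarchical_genotypes"]


@dataclass
class SimConfig:
    n_sites: int = 6
    site_coords: SiteMap | None = None        # default: circle, 50 km radius
    raster: RasterGrid | None = None          # optional resistance landscape
    founder_pairs: int = 2                    # breeding pairs per founding
    n_loci: int = 13
    n_source_alleles: int = 8                 # per locus in the source pool
    n_haplotypes: int = 10
    source_freqs: np.ndarray | None = None    # (L, A) or None -> Dirichlet(1)
    haplotype_freqs: np.ndarray | None = None
    generations: int = 30
    census: int = 100                         # per-site N (even sex ratio)
    m_male: float = 0.04
    m_female: float = 0.01
    monogamy: bool = False
    mutation_rate: float = 5e-4               # SMM, per allele copy per gen
    sample_size: int = 30
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.m_male <= 1 and 0 <= self.m_female <= 1):
            raise DataError("migration rates must be in [0, 1]")
        if self.census < 2 or self.generations < 0:
            raise DataError("census >= 2 and generations >= 0 required")


@dataclass
class SimTruth:
    seed: int
    founder_haplotypes: dict[str, list[int]]
    migrants_per_generation: np.ndarray   # (G, n_sites, 2) counts, [m, f]
    migrants_pairwise: np.ndarray         # (n_sites, n_sites) dest x source
    expected_island_fst: float | None
    site_distances: DistanceMatrix | None


@dataclass
class _Deme:
    geno: np.ndarray      # (n, L, 2) integer repeat scores
    sex: np.ndarray       # (n,) 0 male, 1 female
    hap: np.ndarray       # (n,) maternal haplotype id


def _default_sites(n: int) -> SiteMap:
    ang = 2 * np.pi * np.arange(n) / n
    return SiteMap({f"site{i+1}": (50 * float(np.cos(a)), 50 * float(np.sin(a)))
                    for i, a in enumerate(ang)})


def simulate_metapopulation(cfg: SimConfig):
    """Run the simulator.

    Returns ``(GenotypeTable, HaplotypeCounts, SiteMap, SimTruth)``. Each
    site starts from ``founder_pairs`` pairs drawn from the source pool
    (haplotypes ride with the females); each generation is random gamete
    union to the census size followed by replacement of a Binomial(N_sex, m)
    set by immigrants drawn from other sites with probability proportional
    to 1/resistance-distance.
    """
    rng = np.random.default_rng(cfg.seed)
    sites = cfg.site_coords or _default_sites(cfg.n_sites)
    names = sites.sites[: cfg.n_sites]
    if len(names) < cfg.n_sites:
        raise DataError("site_coords has fewer sites than n_sites")
    d = len(names)
    L, A = cfg.n_loci, cfg.n_source_alleles

    if cfg.source_freqs is not None:
        pool = np.asarray(cfg.source_freqs, dtype=float)
    else:
        pool = rng.dirichlet(np.ones(A), size=L)
    if cfg.haplotype_freqs is not None:
        hpool = np.asarray(cfg.haplotype_freqs, dtype=float)
    else:
        hpool = rng.dirichlet(np.ones(cfg.n_haplotypes))

    # migration weights from the landscape
    truth_dist = None
    if d > 1:
        if cfg.raster is not None:
            truth_dist = resistance_distance(cfg.raster,
                                             SiteMap({s: sites[s] for s in names}))
        else:
            truth_dist = SiteMap({s: sites[s] for s in names}).euclidean_distances()
        dv = truth_dist.values
        if np.isinf(dv).any() and (cfg.m_male > 0 or cfg.m_female > 0):
            raise DataError("disconnected landscape with nonzero migration")
        with np.errstate(divide="ignore"):
            w = 1.0 / np.maximum(dv, 1e-9)
        np.fill_diagonal(w, 0.0)
        mig_w = w / w.sum(1, keepdims=True)
    else:
        mig_w = np.zeros((1, 1))

    # founding: draw founder pairs from the source pool
    base_allele = 20  # repeat-score offset so SMM never walks negative
    demes: list[_Deme] = []
    founder_haps: dict[str, list[int]] = {}
    for s in names:
        nf = 2 * cfg.founder_pairs
        geno = np.empty((nf, L, 2), dtype=np.int64)
        for l in range(L):
            geno[:, l, :] = base_allele + rng.choice(A, size=(nf, 2), p=pool[l])
        sex = np.tile([0, 1], cfg.founder_pairs)
        hap = rng.choice(cfg.n_haplotypes, size=nf, p=hpool)
        demes.append(_Deme(geno, sex, hap))
        founder_haps[s] = sorted(set(int(h) for h in hap[sex == 1]))

    migrants = np.zeros((cfg.generations, d, 2), dtype=int)
    pair_mig = np.zeros((d, d), dtype=int)

    for g in range(cfg.generations):
        # reproduction within each deme up to the census size
        offspring: list[_Deme] = []
        for dem in demes:
            males = np.flatnonzero(dem.sex == 0)
            females = np.flatnonzero(dem.sex == 1)
            if len(males) == 0 or len(females) == 0:
                raise DataError("a deme lost one sex entirely; increase census")
            N = cfg.census
            if cfg.monogamy:
                k = min(len(males), len(females))
                pairm = rng.permutation(males)[:k]
                pairf = rng.permutation(females)[:k]
                pick = rng.integers(0, k, size=N)
                moms, dads = pairf[pick], pairm[pick]
            else:
                moms = females[rng.integers(0, len(females), size=N)]
                dads = males[rng.integers(0, len(males), size=N)]
            geno = np.empty((N, L, 2), dtype=np.int64)
            for par, slot in ((moms, 0), (dads, 1)):
                choice = rng.integers(0, 2, size=(N, L))
                geno[:, :, slot] = np.take_along_axis(
                    dem.geno[par], choice[:, :, None], 2)[:, :, 0]
            if cfg.mutation_rate > 0:
                mut = rng.random((N, L, 2)) < cfg.mutation_rate
                steps = rng.choice([-1, 1], size=int(mut.sum()))
                geno[mut] += steps
            sex = (rng.random(N) < 0.5).astype(np.int8)
            hap = dem.hap[moms]
            offspring.append(_Deme(geno, sex, hap))

        # sex-specific migration among demes
        if d > 1:
            sources = []
            for i in range(d):
                row = []
                for sx, rate in ((0, cfg.m_male), (1, cfg.m_female)):
                    pool_idx = np.flatnonzero(offspring[i].sex == sx)
                    n_mig = rng.binomial(len(pool_idx), rate)
                    row.append((sx, pool_idx, n_mig))
                    migrants[g, i, sx] = n_mig
                sources.append(row)
            # copy immigrants from the source demes' current offspring
            snapshot = [(dem.geno.copy(), dem.sex.copy(), dem.hap.copy())
                        for dem in offspring]
            for i in range(d):
                for sx, pool_idx, n_mig in sources[i]:
                    if n_mig == 0:
                        continue
                    repl = rng.choice(pool_idx, size=n_mig, replace=False)
                    src_sites = rng.choice(d, size=n_mig, p=mig_w[i])
                    for slot, j in zip(repl, src_sites):
                        sg, ss, sh = snapshot[j]
                        cand = np.flatnonzero(ss == sx)
                        if len(cand) == 0:
                            continue
                        pickj = rng.choice(cand)
                        offspring[i].geno[slot] = sg[pickj]
                        # mtDNA moves only with females: an immigrant male
                        # carries a foreign maternal lineage he cannot
                        # transmit; tally it as unknown rather than letting
                        # it enter the site's haplotype pool
                        offspring[i].hap[slot] = sh[pickj] if sx == 1 else -1
                        pair_mig[i, j] += 1
        demes = offspring

    # final sampling
    individuals, calls, site_of, sex_of = [], [], {}, {}
    hap_counts = np.zeros((d, cfg.n_haplotypes), dtype=int)
    for i, s in enumerate(names):
        dem = demes[i]
        n = len(dem.sex)
        take = rng.permutation(n)[: min(cfg.sample_size, n)]
        for t in take:
            ind = f"{s}_{len(individuals)}"
            individuals.append(ind)
            site_of[ind] = s
            sex_of[ind] = "M" if dem.sex[t] == 0 else "F"
            row = []
            for l in range(L):
                if cfg.missing_rate > 0 and rng.random() < cfg.missing_rate:
                    row.append((None, None))
                else:
                    row.append((str(int(dem.geno[t, l, 0])),
                                str(int(dem.geno[t, l, 1]))))
            calls.append(row)
            if dem.hap[t] >= 0:
                hap_counts[i, dem.hap[t]] += 1

    loci = [f"L{j+1:02d}" for j in range(L)]
    gt = GenotypeTable(individuals, loci, np.array(calls, dtype=object),
                       site_of, sex_of=sex_of, repeat_loci=set(loci))
    keep_h = hap_counts.sum(0) > 0
    hc = HaplotypeCounts(names, [f"H{j+1}" for j in np.flatnonzero(keep_h)],
                         hap_counts[:, keep_h])
    m_bar = (cfg.m_male + cfg.m_female) / 2.0
    exp_fst = None
    if d > 1 and m_bar > 0:
        corr = (d / (d - 1.0)) ** 2
        exp_fst = 1.0 / (1.0 + 4 * cfg.census * m_bar * corr)
    truth = SimTruth(cfg.seed, founder_haps, migrants, pair_mig, exp_fst,
                     truth_dist)
    return gt, hc, SiteMap({s: sites[s] for s in names}), truth


def simulate_hierarchical_genotypes(
    seed: int, n_per_deme: int = 20, n_loci: int = 13, n_alleles: int = 6,
    region_concentration: float = 3.0,
    deme_concentrations: tuple[float, float] = (2.5, 6.0),
):
    """Two-region, two-demes-per-region genotype dataset with known truth.

    Region allele frequencies are Dirichlet draws about a shared base
    (smaller concentration = stronger regional divergence); deme frequencies
    are Dirichlet draws about their region (one concentration per region, so
    the two regional splits differ in strength, as real hierarchies do).
    Individuals are drawn in Hardy-Weinberg proportions from their deme.
    Returns ``(GenotypeTable, deme_of_region)`` where the truth maps each
    deme to its region; true K is 4 (regions nested at K = 2).
    """
    rng = np.random.default_rng(seed)
    L, A = n_loci, n_alleles
    base = rng.dirichlet(np.ones(A) * 2, size=L)
    region_f = {r: np.array([rng.dirichlet(base[l] * region_concentration)
                             for l in range(L)])
                for r in ("r1", "r2")}
    spec = [("r1", "d1", deme_concentrations[0]),
            ("r1", "d2", deme_concentrations[0]),
            ("r2", "d3", deme_concentrations[1]),
            ("r2", "d4", deme_concentrations[1])]
    calls, inds, site_of = [], [], {}
    for r, dname, conc in spec:
        pf = np.array([rng.dirichlet(region_f[r][l] * conc)
                       for l in range(L)])
        for i in range(n_per_deme):
            ind = f"{dname}_{i}"
            inds.append(ind)
            site_of[ind] = dname
            calls.append([tuple(str(x)
                                for x in rng.choice(A, size=2, p=pf[l]))
                          for l in range(L)])
    gt = GenotypeTable(inds, [f"L{l+1:02d}" for l in range(L)],
                       np.array(calls, dtype=object), site_of)
    return gt, {"d1": "r1", "d2": "r1", "d3": "r2", "d4": "r2"}
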