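"""Linkage-disequilibrium effective population size and heterozygote-excess
bottleneck tests.

The LD method estimates contemporary Ne from the composite (Burrows)
disequilibrium among physically unlinked loci: drift in a small population
generates inter-locus associations with expectation E[r2] ~ 1/(3Ne) under
random mating, on top of a sampling component that is subtracted with the
small-sample bias corrections of the LD-Ne literature.

The bottleneck test compares each locus's unbiased expected heterozygosity
with its distribution under mutation-drift equilibrium conditional on the
observed allele count (coalescent simulation under IAM, SMM, or a two-phase
model), then combines loci with a two-tailed Wilcoxon signed-rank test. A
recently founded population retains heterozygosity better than allele count,
so He exceeds the equilibrium expectation Heq.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .genodata import DataError, GenotypeTable

__all__ = [
    "NeEstimate",
    "ld_ne",
    "burrows_r2",
    "BottleneckResult",
    "bottleneck_heterozygosity_test",
    "simulate_heq",
]


# ---------------------------------------------------------------------------
# Composite Burrows disequilibrium and LD-Ne
# ---------------------------------------------------------------------------

def burrows_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Composite-LD r^2 for one allele pair from diploid dose vectors.

    ``x``, ``y`` are per-individual allele doses (0/1/2) at two loci for the
    same individuals. Delta = (n/(n-1)) [mean(XY)/2 - 2 p q]; r^2 divides by
    (p(1-p) + D_A)(q(1-q) + D_B) with D_A the within-locus Hardy-Weinberg
    departure, which keeps the measure bounded without assuming equilibrium.
    """
    n = len(x)
    if n < 2:
        raise DataError("need >= 2 individuals")
    p = x.mean() / 2.0
    q = y.mean() / 2.0
    delta = (n / (n - 1.0)) * ((x * y).mean() / 2.0 - 2.0 * p * q)
    da = (x == 2).mean() - p * p
    db = (y == 2).mean() - q * q
    denom = (p * (1 - p) + da) * (q * (1 - q) + db)
    if denom <= 0:
        return np.nan
    return float(delta * delta / denom)


@dataclass
class NeEstimate:
    site: str
    ne: float                      # may be +inf
    ci95: tuple[float, float]
    s_harmonic: float
    r2_mean: float                 # raw mean composite r^2
    r2_drift: float                # after subtracting the sampling expectation
    maf_cutoff: float
    n_locus_pairs: int


def _sample_component(S: float) -> float:
    """Expected sampling contribution to r^2 (random mating)."""
    if S >= 30:
        return 1.0 / S + 3.19 / S ** 2
    return 0.0018 + 0.907 / S + 4.44 / S ** 2


def _ne_from_r2drift(r2d: float, S: float) -> float:
    """Drift r^2 -> Ne, second-order-in-1/Ne inversion (random mating)."""
    if r2d <= 0:
        return math.inf
    if S >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2d
        if disc < 0:
            return max((1.0 / 3.0) / (2.0 * r2d), 0.0)
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2d)
    disc = 0.308 ** 2 - 2.08 * r2d
    if disc < 0:
        return max(0.308 / (2.0 * r2d), 0.0)
    return (0.308 + math.sqrt(disc)) / (2.0 * r2d)


def ld_ne(gt: GenotypeTable, site: str, maf_cutoff: float = 0.05,
          seed: int = 0) -> NeEstimate:
    """Bias-corrected LD effective size for one site.

    Alleles below ``maf_cutoff`` are excluded; r^2 is averaged over all
    allele cross-pairs of every locus pair; the 95% CI is a delete-one
    jackknife over locus pairs. When the corrected drift r^2 is at or below
    zero the point estimate is +inf.
    """
    inds = gt.individuals_of(site)
    if len(inds) < 8:
        raise DataError(f"site {site}: need >= 8 individuals for LD-Ne")
    idx = gt.index_of(inds)
    doses: list[tuple[str, np.ndarray, np.ndarray]] = []
    for locus in gt.loci:
        codes, alleles = gt.locus_codes(locus)
        codes = codes[idx]
        typed = codes[:, 0] >= 0
        if typed.sum() < 8 or len(alleles) < 2:
            continue
        counts = np.bincount(codes[typed].ravel(), minlength=len(alleles))
        freqs = counts / counts.sum()
        keep = np.flatnonzero(freqs >= maf_cutoff)
        if len(keep) < 2:
            continue
        dose = np.zeros((len(inds), len(keep)))
        for j, a in enumerate(keep):
            dose[:, j] = (codes == a).sum(axis=1)
        doses.append((locus, dose[:, :], typed))
    if len(doses) < 2:
        raise DataError(f"site {site}: fewer than 2 usable polymorphic loci")

    pair_r2: list[float] = []
    pair_n: list[float] = []
    for i in range(len(doses)):
        for j in range(i + 1, len(doses)):
            _, dx, tx = doses[i]
            _, dy, ty = doses[j]
            both = tx & ty
            n = int(both.sum())
            if n < 8:
                continue
            vals = []
            for a in range(dx.shape[1]):
                for b in range(dy.shape[1]):
                    r2 = burrows_r2(dx[both, a], dy[both, b])
                    if np.isfinite(r2):
                        vals.append(r2)
            if vals:
                pair_r2.append(float(np.mean(vals)))
                pair_n.append(n)
    if not pair_r2:
        raise DataError(f"site {site}: no informative locus pairs")
    pair_r2 = np.asarray(pair_r2)
    pair_n = np.asarray(pair_n, dtype=float)
    S = len(pair_n) / (1.0 / pair_n).sum()
    r2_mean = float(pair_r2.mean())
    r2_drift = r2_mean - _sample_component(S)
    ne = _ne_from_r2drift(r2_drift, S)

    # delete-one jackknife over locus pairs on mean r^2
    m = len(pair_r2)
    if m >= 2:
        tot = pair_r2.sum()
        jk = (tot - pair_r2) / (m - 1)
        se = math.sqrt((m - 1) / m * ((jk - jk.mean()) ** 2).sum())
        lo_r2, hi_r2 = r2_mean - 1.96 * se, r2_mean + 1.96 * se
        hi_ne = _ne_from_r2drift(lo_r2 - _sample_component(S), S)
        lo_ne = _ne_from_r2drift(hi_r2 - _sample_component(S), S)
        ci = (min(lo_ne, ne), max(hi_ne, ne))
    else:
        ci = (0.0, math.inf)
    return NeEstimate(site, ne, ci, float(S), r2_mean, float(r2_drift),
                      maf_cutoff, int(m))


# ---------------------------------------------------------------------------
# Coalescent simulation of equilibrium heterozygosity (Heq)
# ---------------------------------------------------------------------------

_IAM, _SMM, _TPM = 0, 1, 2
_GEOM_P = 1.0 / 6.0  # multi-step size ~ Geometric(1/6): variance ~ 30


@njit(cache=True)
def _sim_batch(n: int, theta: float, model: int, p_smm: float,
               n_reps: int, seed: int):
    """Simulate n_reps coalescent samples of n genes; return (k, He) arrays.

    He is the unbiased (n/(n-1)) gene diversity of each simulated sample.
    """
    np.random.seed(seed)
    ks = np.empty(n_reps, dtype=np.int64)
    hets = np.empty(n_reps, dtype=np.float64)
    parent = np.empty(2 * n - 1, dtype=np.int64)
    blen = np.empty(2 * n - 1, dtype=np.float64)
    state = np.empty(2 * n - 1, dtype=np.int64)
    active = np.empty(n, dtype=np.int64)
    node_time = np.empty(2 * n - 1, dtype=np.float64)
    for rep in range(n_reps):
        for i in range(n):
            active[i] = i
            node_time[i] = 0.0
        k = n
        t = 0.0
        nxt = n
        while k > 1:
            rate = k * (k - 1) / 2.0
            t += np.random.exponential(1.0 / rate)
            i = np.random.randint(k)
            j = np.random.randint(k - 1)
            if j >= i:
                j += 1
            a, b = active[i], active[j]
            parent[a] = nxt
            parent[b] = nxt
            blen[a] = t - node_time[a]
            blen[b] = t - node_time[b]
            node_time[nxt] = t
            # remove a, b; add nxt
            if i > j:
                i, j = j, i
            active[i] = nxt
            active[j] = active[k - 1]
            k -= 1
            nxt += 1
        root = 2 * n - 2
        state[root] = 0
        new_label = 1
        for node in range(root - 1, -1, -1):
            s = state[parent[node]]
            m = np.random.poisson(theta / 2.0 * blen[node])
            if model == _IAM:
                if m > 0:
                    s = new_label
                    new_label += 1
            else:
                for _ in range(m):
                    if model == _SMM or np.random.random() < p_smm:
                        step = 1
                    else:
                        step = np.random.geometric(_GEOM_P)
                    if np.random.random() < 0.5:
                        step = -step
                    s += step
            state[node] = s
        # tally leaf states
        leaf = np.sort(state[:n].copy())
        kk = 1
        sumsq = 0.0
        run = 1
        for i in range(1, n):
            if leaf[i] == leaf[i - 1]:
                run += 1
            else:
                sumsq += run * run
                run = 1
                kk += 1
        sumsq += run * run
        ks[rep] = kk
        hets[rep] = (n / (n - 1.0)) * (1.0 - sumsq / (n * n))
    return ks, hets


@njit(cache=True)
def _sim_states(n: int, theta: float, model: int, p_smm: float, seed: int):
    """One coalescent sample of n genes; returns the leaf allele states."""
    np.random.seed(seed)
    parent = np.empty(2 * n - 1, dtype=np.int64)
    blen = np.empty(2 * n - 1, dtype=np.float64)
    state = np.empty(2 * n - 1, dtype=np.int64)
    active = np.empty(n, dtype=np.int64)
    node_time = np.empty(2 * n - 1, dtype=np.float64)
    for i in range(n):
        active[i] = i
        node_time[i] = 0.0
    k = n
    t = 0.0
    nxt = n
    while k > 1:
        rate = k * (k - 1) / 2.0
        t += np.random.exponential(1.0 / rate)
        i = np.random.randint(k)
        j = np.random.randint(k - 1)
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        parent[a] = nxt
        parent[b] = nxt
        blen[a] = t - node_time[a]
        blen[b] = t - node_time[b]
        node_time[nxt] = t
        if i > j:
            i, j = j, i
        active[i] = nxt
        active[j] = active[k - 1]
        k -= 1
        nxt += 1
    root = 2 * n - 2
    state[root] = 0
    new_label = 1
    for node in range(root - 1, -1, -1):
        s = state[parent[node]]
        m = np.random.poisson(theta / 2.0 * blen[node])
        if model == _IAM:
            if m > 0:
                s = new_label
                new_label += 1
        else:
            for _ in range(m):
                if model == _SMM or np.random.random() < p_smm:
                    step = 1
                else:
                    step = np.random.geometric(_GEOM_P)
                if np.random.random() < 0.5:
                    step = -step
                s += step
        state[node] = s
    return state[:n].copy()


def sample_equilibrium_alleles(n_genes: int, theta: float, model: str = "SMM",
                               p_smm: float = 0.7, seed: int = 0) -> np.ndarray:
    """Allele states of one mutation-drift-equilibrium coalescent sample.

    Useful for calibration: data generated here are at equilibrium by
    construction. States are integers (repeat scores for SMM/TPM, arbitrary
    labels for IAM) offset to be nonnegative.
    """
    model_id = {"IAM": _IAM, "SMM": _SMM, "TPM": _TPM}[model.upper()]
    s = _sim_states(n_genes, theta, model_id, p_smm, seed)
    return s - s.min() + 100


def simulate_heq(n_genes: int, k_alleles: int, model: str = "TPM",
                 p_smm: float = 0.7, n_sim: int = 1000, seed: int = 0,
                 tune_iters: int = 200, tune_batch: int = 100):
    """Equilibrium-He distribution conditional on the observed allele count.

    The scaled mutation rate is tuned by bisection so the mean simulated
    allele count matches ``k_alleles``, then replicates with exactly
    ``k_alleles`` alleles are retained (rejection conditioning). Returns an
    array of Heq values (may be shorter than n_sim if acceptance is poor) or
    an empty array if no replicate attains k within the budget.
    """
    model_id = {"IAM": _IAM, "SMM": _SMM, "TPM": _TPM}[model.upper()]
    if k_alleles < 2:
        raise DataError("Heq is degenerate for a monomorphic locus")
    rng = np.random.default_rng(seed)

    def mean_k(theta, s):
        ks, _ = _sim_batch(n_genes, theta, model_id, p_smm, tune_batch, s)
        return ks.mean()

    lo, hi = 1e-3, 1.0
    it = 0
    while mean_k(hi, int(rng.integers(1 << 30))) < k_alleles and it < 40:
        hi *= 2.0
        it += 1
    while mean_k(lo, int(rng.integers(1 << 30))) > k_alleles and it < 80:
        lo /= 2.0
        it += 1
    theta = math.sqrt(lo * hi)
    for _ in range(max(tune_iters - it, 8)):
        if hi / lo < 1.05:
            break
        mid = math.sqrt(lo * hi)
        if mean_k(mid, int(rng.integers(1 << 30))) < k_alleles:
            lo = mid
        else:
            hi = mid
        theta = math.sqrt(lo * hi)

    out: list[float] = []
    budget = 60
    while len(out) < n_sim and budget > 0:
        ks, hets = _sim_batch(n_genes, theta, model_id, p_smm,
                              max(2 * n_sim, 200), int(rng.integers(1 << 30)))
        out.extend(hets[ks == k_alleles][: n_sim - len(out)].tolist())
        budget -= 1
    return np.asarray(out)


@dataclass
class BottleneckResult:
    site: str
    model: str
    p_smm: float
    table: pd.DataFrame       # locus, k, he_obs, heq_mean, heq_sd, dh
    wilcoxon_p: float
    n_loci_used: int
    dropped: list[str] = field(default_factory=list)


def bottleneck_heterozygosity_test(
    gt: GenotypeTable, site: str, model: str = "TPM", p_smm: float = 0.7,
    n_sim: int = 1000, seed: int = 0,
) -> BottleneckResult:
    """Heterozygote-excess test against mutation-drift equilibrium.

    For each polymorphic locus the unbiased He of the site sample is
    compared with the simulated Heq distribution conditional on the observed
    allele count; significance across loci is a two-tailed Wilcoxon
    signed-rank on He - mean(Heq) (exact null distribution up to 25 loci).
    SMM/TPM require integer repeat-score alleles (``gt.repeat_loci``).
    """
    model = model.upper()
    if model not in ("IAM", "SMM", "TPM"):
        raise DataError(f"unknown mutation model {model!r}")
    inds = gt.individuals_of(site)
    if not inds:
        raise DataError(f"no individuals at site {site}")
    idx = gt.index_of(inds)
    rng = np.random.default_rng(seed)
    rows = []
    dropped: list[str] = []
    for l, locus in enumerate(gt.loci):
        col = gt.calls[idx, l, :]
        ok = col[:, 0] != None  # noqa: E711
        col = col[ok].astype(str)
        if len(col) < 2:
            dropped.append(locus)
            continue
        alleles, counts = np.unique(col.ravel(), return_counts=True)
        k = len(alleles)
        if k < 2:
            dropped.append(locus)  # monomorphic: Heq degenerate at 0
            continue
        if model != "IAM" and locus not in gt.repeat_loci:
            try:
                [int(a) for a in alleles]
            except ValueError:
                raise DataError(
                    f"{locus}: stepwise models need integer repeat scores")
        n_genes = int(counts.sum())
        p = counts / n_genes
        he_obs = (n_genes / (n_genes - 1.0)) * (1.0 - float((p ** 2).sum()))
        heq = simulate_heq(n_genes, k, model, p_smm, n_sim,
                           seed=int(rng.integers(1 << 30)))
        if len(heq) < max(20, n_sim // 10):
            dropped.append(locus)
            continue
        mu, sd = float(heq.mean()), float(heq.std(ddof=1))
        dh = (he_obs - mu) / sd if sd > 0 else np.nan
        rows.append((locus, k, n_genes, he_obs, mu, sd, dh))
    if len(rows) < 4:
        raise DataError(f"site {site}: fewer than 4 usable polymorphic loci")
    table = pd.DataFrame(rows, columns=["locus", "k", "n_genes", "he_obs",
                                        "heq_mean", "heq_sd", "dh"])
    diffs = (table.he_obs - table.heq_mean).to_numpy()
    method = "exact" if len(diffs) <= 25 else "approx"
    p = float(stats.wilcoxon(diffs, alternative="two-sided", method=method).pvalue)
    return BottleneckResult(site, model, p_smm, table, p, len(rows), dropped)
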