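"""Diversity, differentiation, and disequilibrium statistics.

Covers haplotype (maternal, haploid) and diploid microsatellite markers:

* gene diversity h = 1 - sum p_i^2 (uncorrected by default, which is what
  count-level reproduction of published haplotype tables requires; the
  n/(n-1) unbiased variant is an option),
* the diversity-partition F_ST = 1 - mean within-site h / pooled h,
* Weir-Cockerham variance-components estimators (haploid ANOVA for
  haplotype counts, the diploid multi-allelic theta for microsatellites),
* Nei's D_A allele-sharing distance,
* per-site summaries (Ho, He, rarefied allelic richness, F_IS),
* permutation tests for Hardy-Weinberg and gametic equilibrium, and
* the island-model ratio of male to female gene flow from paired nuclear
  and mitochondrial F_ST estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genodata import DataError, DistanceMatrix, GenotypeTable, HaplotypeCounts

__all__ = [
    "gene_diversity",
    "DiversityPartition",
    "global_fst_from_diversity",
    "pairwise_haplotype_fst",
    "SiteSummary",
    "site_summary_stats",
    "DisequilibriumResult",
    "disequilibrium_tests",
    "sequential_bonferroni",
    "DifferentiationResult",
    "weir_cockerham_theta",
    "nei_da_distance",
    "linearize_fst",
    "SexBiasResult",
    "sex_biased_gene_flow_ratio",
]

LINEARIZE_CAP = 0.999  # F_ST at or above this maps to +inf when linearized


# ---------------------------------------------------------------------------
# Gene diversity and its among-site partition
# ---------------------------------------------------------------------------

def gene_diversity(counts, unbiased: bool = False) -> float:
    """Gene diversity h = 1 - sum p_i^2 from haplotype/allele counts.

    ``unbiased=True`` applies the n/(n-1) small-sample correction.
    """
    c = np.asarray(list(counts.values()) if isinstance(counts, dict) else counts,
                   dtype=float)
    n = c.sum()
    if n <= 0:
        raise DataError("gene diversity of all-zero counts is undefined")
    h = 1.0 - float(((c / n) ** 2).sum())
    if unbiased:
        if n < 2:
            raise DataError("unbiased gene diversity needs n >= 2")
        h *= n / (n - 1.0)
    return h


@dataclass
class DiversityPartition:
    """Total/within decomposition of haplotype gene diversity."""

    h_total: float
    h_within_mean: float
    h_within_sd: float
    fst: float
    included_sites: list[str]
    per_site_h: dict[str, float]
    substituted_sites: list[str] = field(default_factory=list)


def global_fst_from_diversity(
    hc: HaplotypeCounts,
    min_n: int = 5,
    use_declared_for_inconsistent: bool = True,
) -> DiversityPartition:
    """Diversity-partition F_ST = 1 - mean(h_within)/h_total.

    The within mean is unweighted over included sites. Inclusion follows
    ``hc.included_sites`` when set; otherwise all sites with n >= ``min_n``.
    For a row flagged internally inconsistent (declared n != count sum) the
    declared per-site diversity, when present, replaces the count-derived
    value; such substitutions are reported in ``substituted_sites``.
    """
    if hc.included_sites is not None:
        included = list(hc.included_sites)
    else:
        included = [s for s, n in zip(hc.sites, hc.n) if n >= min_n]
    if len(included) < 2:
        raise DataError("diversity partition needs >= 2 included sites")
    h_total = gene_diversity(hc.total_counts)
    if h_total == 0:
        raise DataError("pooled diversity is zero; F_ST undefined")
    consistent = dict(zip(hc.sites, hc.consistent))
    per_site: dict[str, float] = {}
    substituted: list[str] = []
    for s in included:
        i = hc.sites.index(s)
        h = gene_diversity(hc.counts[i])
        if (use_declared_for_inconsistent and not consistent[s]
                and hc.declared_diversity is not None
                and not np.isnan(hc.declared_diversity[i])):
            h = float(hc.declared_diversity[i])
            substituted.append(s)
        per_site[s] = h
    vals = np.array([per_site[s] for s in included])
    mean, sd = float(vals.mean()), float(vals.std(ddof=1))
    return DiversityPartition(h_total, mean, sd, 1.0 - mean / h_total,
                              included, per_site, substituted)


# ---------------------------------------------------------------------------
# Differentiation containers
# ---------------------------------------------------------------------------

@dataclass
class DifferentiationResult:
    """Global and pairwise differentiation for one estimator."""

    method: str
    global_estimate: float | None
    pairwise: DistanceMatrix
    linearized: DistanceMatrix | None = None
    ci95: tuple[float, float] | None = None
    per_locus: dict[str, np.ndarray] | None = None
    n_capped: int = 0


def linearize_fst(values: np.ndarray, cap: float = LINEARIZE_CAP):
    """x/(1-x) with negatives clamped to 0 and x >= cap mapped to +inf.

    Returns ``(linearized, n_capped)``.
    """
    v = np.clip(np.asarray(values, dtype=float), 0.0, None)
    out = np.where(v >= cap, np.inf, v / (1.0 - np.minimum(v, cap - 1e-12)))
    np.fill_diagonal(out, 0.0) if out.ndim == 2 else None
    return out, int((np.asarray(values) >= cap).sum() // (2 if out.ndim == 2 else 1))


# ---------------------------------------------------------------------------
# Haploid (haplotype-count) Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _haploid_theta(counts: np.ndarray) -> float:
    """Weir-Cockerham haploid theta from a (r sites x k haplotypes) table.

    ANOVA on haplotype indicator variables: theta = (MSP - MSG) /
    (MSP + (n_c - 1) MSG). Both-monomorphic-and-identical tables return 0.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1)
    keep = n > 0
    counts, n = counts[keep], n[keep]
    r = len(n)
    if r < 2:
        raise DataError("haploid theta needs >= 2 sites with data")
    N = n.sum()
    p = counts / n[:, None]
    pbar = counts.sum(axis=0) / N
    ssp = (n[:, None] * (p - pbar) ** 2).sum()
    ssg = (n[:, None] * p * (1.0 - p)).sum()
    msp = ssp / (r - 1)
    msg = ssg / (N - r) if N > r else 0.0
    nc = (N - (n ** 2).sum() / N) / (r - 1)
    denom = msp + (nc - 1.0) * msg
    if denom == 0.0:
        return 0.0
    return float((msp - msg) / denom)


def pairwise_haplotype_fst(hc: HaplotypeCounts, min_n: int = 2) -> DifferentiationResult:
    """Pairwise haploid Weir-Cockerham F_ST between sites.

    Sites with n < ``min_n`` are excluded. Negative estimates are kept in the
    pairwise matrix and clamped only in the linearized matrix.
    """
    keep = [s for s, n in zip(hc.sites, hc.n) if n >= min_n]
    if len(keep) < 2:
        raise DataError("need >= 2 sites with sufficient samples")
    sub = hc.subset(keep)
    k = len(keep)
    vals = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            vals[i, j] = vals[j, i] = _haploid_theta(sub.counts[[i, j]])
    glob = _haploid_theta(sub.counts)
    lin, ncap = linearize_fst(vals)
    return DifferentiationResult(
        method="weir-cockerham-haploid",
        global_estimate=glob,
        pairwise=_raw_symmetric(keep, vals),
        linearized=DistanceMatrix(keep, lin),
        n_capped=ncap,
    )


class _RawMatrix(DistanceMatrix):
    """Symmetric labeled matrix allowing negative (estimator) entries."""

    def __post_init__(self) -> None:  # relax the nonnegativity invariant
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise DataError("matrix not square")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise DataError("matrix not symmetric")


def _raw_symmetric(labels, values) -> _RawMatrix:
    return _RawMatrix(labels, values)


# ---------------------------------------------------------------------------
# Per-site summaries (Ho, He, AR, F_IS)
# ---------------------------------------------------------------------------

@dataclass
class SiteSummary:
    site: str
    n: int
    ho: dict[str, float]
    he: dict[str, float]
    ar: dict[str, float]
    ho_mean: float
    he_mean: float
    ar_mean: float
    f_is: float | None
    flags: list[str] = field(default_factory=list)


def _rarefied_richness(counts: np.ndarray, g: int) -> float:
    """Expected allele count in a hypergeometric subsample of g genes."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < g:
        return np.nan
    # 1 - C(n - N_a, g)/C(n, g) per allele, in log space
    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    terms = np.zeros(len(counts))
    for i, c in enumerate(counts):
        if n - c < g:
            terms[i] = 1.0
        else:
            terms[i] = 1.0 - np.exp(logC(n - c, g) - logC(n, g))
    return float(terms.sum())


def _locus_site_stats(gt: GenotypeTable):
    """Yield (site, locus, codes) for genotyped individuals (pairwise deletion)."""
    for site in gt.sites:
        idx = gt.index_of(gt.individuals_of(site))
        for l, locus in enumerate(gt.loci):
            col = gt.calls[idx, l, :]
            ok = col[:, 0] != None  # noqa: E711
            yield site, locus, col[ok]


def site_summary_stats(gt: GenotypeTable, rarefaction_g: int | None = None,
                       unbiased_he: bool = False) -> dict[str, SiteSummary]:
    """Observed/expected heterozygosity, rarefied allelic richness, F_IS.

    He is uncorrected 1 - sum p^2 by default. F_IS is the multi-locus
    ratio-of-sums 1 - sum(Ho)/sum(He_unbiased); undefined (None) where every
    locus is monomorphic.
    """
    # choose the rarefaction gene count: min over sites x loci of 2 * n_typed
    min_genes = None
    per = {}
    for site, locus, col in _locus_site_stats(gt):
        per.setdefault(site, {})[locus] = col
        if len(col) and (min_genes is None or 2 * len(col) < min_genes):
            min_genes = 2 * len(col)
    if rarefaction_g is None:
        rarefaction_g = min_genes or 2
    elif min_genes is not None and rarefaction_g > min_genes:
        warnings.warn(f"rarefaction g={rarefaction_g} exceeds the smallest "
                      f"sample ({min_genes} genes); lowered", stacklevel=2)
        rarefaction_g = min_genes
    out: dict[str, SiteSummary] = {}
    for site in gt.sites:
        ho, he, ar = {}, {}, {}
        ho_sum = he_unb_sum = 0.0
        any_poly = False
        flags: list[str] = []
        for locus in gt.loci:
            col = per[site].get(locus, np.empty((0, 2), dtype=object))
            n = len(col)
            if n == 0:
                flags.append(f"{locus}: no data")
                continue
            labels, counts = np.unique(col.astype(str), return_counts=True)
            p = counts / counts.sum()
            ho_l = float(np.mean(col[:, 0] != col[:, 1]))
            he_l = 1.0 - float((p ** 2).sum())
            if unbiased_he:
                he_l *= 2 * n / (2 * n - 1.0) if n > 0 else 1.0
            ho[locus], he[locus] = ho_l, he_l
            ar[locus] = _rarefied_richness(counts, rarefaction_g)
            if len(labels) > 1:
                any_poly = True
                ho_sum += ho_l
                he_unb_sum += (2 * n / (2 * n - 1.0)) * (1.0 - float((p ** 2).sum()))
        if not any_poly:
            flags.append("all loci monomorphic; F_IS undefined")
            fis = None
        else:
            fis = 1.0 - ho_sum / he_unb_sum if he_unb_sum > 0 else None
        nsite = len(gt.individuals_of(site))
        if all(len(per[site].get(l, ())) < 2 for l in gt.loci):
            flags.append("fewer than 2 genotyped individuals at every locus")
        out[site] = SiteSummary(
            site=site, n=nsite, ho=ho, he=he, ar=ar,
            ho_mean=float(np.mean(list(ho.values()))) if ho else np.nan,
            he_mean=float(np.mean(list(he.values()))) if he else np.nan,
            ar_mean=float(np.nanmean(list(ar.values()))) if ar else np.nan,
            f_is=fis, flags=flags)
    return out


# ---------------------------------------------------------------------------
# Permutation tests: Hardy-Weinberg and gametic equilibrium
# ---------------------------------------------------------------------------

@dataclass
class DisequilibriumResult:
    hwe_p: pd.DataFrame           # site x locus two-sided permutation p
    gametic_p: pd.DataFrame       # rows (site, locus_a, locus_b, p)
    n_perm: int
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _fis_statistic(codes: np.ndarray) -> float:
    """Per-locus F_IS = 1 - Ho/He_unbiased from integer-coded (n, 2) calls."""
    n = len(codes)
    _, counts = np.unique(codes.ravel(), return_counts=True)
    p = counts / counts.sum()
    he = (2 * n / (2 * n - 1.0)) * (1.0 - (p ** 2).sum())
    if he <= 0:
        return 0.0
    ho = np.mean(codes[:, 0] != codes[:, 1])
    return float(1.0 - ho / he)


def _g_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Log-likelihood-ratio association between two genotype vectors."""
    tab = pd.crosstab(a, b).to_numpy(dtype=float)
    tot = tab.sum()
    exp = np.outer(tab.sum(1), tab.sum(0)) / tot
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(tab > 0, tab * np.log(tab / exp), 0.0)
    return float(2.0 * terms.sum())


def disequilibrium_tests(gt: GenotypeTable, n_perm: int = 999,
                         seed: int = 0) -> DisequilibriumResult:
    """Within-site permutation tests.

    Hardy-Weinberg: alleles are permuted among individuals within a site;
    the statistic is per-locus F_IS, two-sided. Gametic equilibrium:
    single-locus genotypes are permuted among individuals; the statistic is
    the log-likelihood-ratio (G) association. p = (1 + #{extreme}) /
    (n_perm + 1). Monomorphic loci are skipped and flagged.
    """
    if n_perm < 99:
        raise DataError("use n_perm >= 99")
    rng = np.random.default_rng(seed)
    sites = gt.sites
    hwe = pd.DataFrame(np.nan, index=sites, columns=gt.loci)
    skipped: list[tuple[str, str]] = []
    gametic_rows = []
    for site in sites:
        idx = gt.index_of(gt.individuals_of(site))
        geno_labels: dict[str, np.ndarray] = {}
        for l, locus in enumerate(gt.loci):
            col = gt.calls[idx, l, :]
            ok = col[:, 0] != None  # noqa: E711
            col = col[ok]
            n = len(col)
            if n < 2 or len(np.unique(col.astype(str))) < 2:
                skipped.append((site, locus))
                continue
            labels = sorted(set(col.astype(str).ravel()))
            lut = {a: k for k, a in enumerate(labels)}
            codes = np.array([[lut[a] for a in row] for row in col.astype(str)])
            obs = abs(_fis_statistic(codes))
            pool = codes.ravel()
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pool).reshape(n, 2)
                if abs(_fis_statistic(perm)) >= obs - 1e-12:
                    count += 1
            hwe.loc[site, locus] = (1 + count) / (n_perm + 1)
            # unordered genotype label per individual for the gametic test
            g = np.sort(codes, axis=1)
            geno_labels[locus] = g[:, 0] * 1000 + g[:, 1], ok
        loci_ok = list(geno_labels)
        for i in range(len(loci_ok)):
            for j in range(i + 1, len(loci_ok)):
                la, lb = loci_ok[i], loci_ok[j]
                ga, oka = geno_labels[la]
                gb, okb = geno_labels[lb]
                both = oka & okb
                a = ga[both[oka]]
                b = gb[both[okb]]
                if len(a) < 2:
                    skipped.append((site, f"{la}x{lb}"))
                    continue
                obs = _g_statistic(a, b)
                count = 0
                for _ in range(n_perm):
                    if _g_statistic(a, rng.permutation(b)) >= obs - 1e-12:
                        count += 1
                gametic_rows.append((site, la, lb, (1 + count) / (n_perm + 1)))
    gametic = pd.DataFrame(gametic_rows,
                           columns=["site", "locus_a", "locus_b", "p"])
    return DisequilibriumResult(hwe, gametic, n_perm, skipped)


def sequential_bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm's sequential Bonferroni: True where the null is rejected."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    k = len(p)
    reject = np.zeros(k, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (k - rank):
            reject[i] = True
        else:
            break
    return reject


# ---------------------------------------------------------------------------
# Diploid multi-allelic Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _wc_components(gt: GenotypeTable, sites: list[str]):
    """Per-locus (a, a+b+c) variance-component sums over alleles."""
    site_idx = {s: gt.index_of(gt.individuals_of(s)) for s in sites}
    a_by_locus = np.zeros(len(gt.loci))
    abc_by_locus = np.zeros(len(gt.loci))
    for l, locus in enumerate(gt.loci):
        ni, pmat, hmat = [], [], []
        alleles: list[str] = []
        cols = {}
        for s in sites:
            col = gt.calls[site_idx[s], l, :]
            ok = col[:, 0] != None  # noqa: E711
            col = col[ok].astype(str)
            if len(col) == 0:
                continue
            cols[s] = col
            for al in np.unique(col):
                if al not in alleles:
                    alleles.append(al)
        if len(cols) < 2 or len(alleles) < 2:
            continue
        alleles.sort()
        for s, col in cols.items():
            n = len(col)
            ni.append(n)
            p = np.array([(col == al).sum() for al in alleles], dtype=float) / (2 * n)
            het = np.array([((col[:, 0] == al) ^ (col[:, 1] == al)).mean()
                            for al in alleles])
            pmat.append(p)
            hmat.append(het)
        ni = np.asarray(ni, dtype=float)
        pmat = np.asarray(pmat)     # (r, alleles)
        hmat = np.asarray(hmat)
        r = len(ni)
        nbar = ni.mean()
        nc = (r * nbar - (ni ** 2).sum() / (r * nbar)) / (r - 1)
        pbar = (ni[:, None] * pmat).sum(0) / (r * nbar)
        s2 = (ni[:, None] * (pmat - pbar) ** 2).sum(0) / ((r - 1) * nbar)
        hbar = (ni[:, None] * hmat).sum(0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        a_by_locus[l] = a.sum()
        abc_by_locus[l] = (a + b + c).sum()
    return a_by_locus, abc_by_locus


def weir_cockerham_theta(gt: GenotypeTable, n_boot: int = 1000,
                         seed: int = 0, min_n: int = 2) -> DifferentiationResult:
    """Multi-locus, multi-allelic Weir-Cockerham theta with a bootstrap CI.

    theta is the ratio of summed variance components sum(a)/sum(a+b+c) over
    alleles and loci; the 95% CI comes from bootstrap over loci. Pairwise
    estimates may be negative and are preserved; they are clamped at 0 only
    in the linearized matrix.
    """
    sites = [s for s in gt.sites
             if sum((~gt.missing_mask()[gt.index_of(gt.individuals_of(s))]).any(1))
             >= min_n]
    if len(sites) < 2:
        raise DataError("theta needs >= 2 sites with >= 2 genotyped individuals")
    a_l, abc_l = _wc_components(gt, sites)
    used = abc_l != 0
    if used.sum() == 0:
        raise DataError("no polymorphic loci shared across sites")
    theta = float(a_l[used].sum() / abc_l[used].sum())
    ci = None
    if used.sum() >= 2 and n_boot > 0:
        rng = np.random.default_rng(seed)
        li = np.flatnonzero(used)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            pick = rng.choice(li, size=len(li), replace=True)
            denom = abc_l[pick].sum()
            reps[b] = a_l[pick].sum() / denom if denom != 0 else np.nan
        reps = reps[np.isfinite(reps)]
        ci = (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
    k = len(sites)
    pw = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            ai, abci = _wc_components(gt, [sites[i], sites[j]])
            u = abci != 0
            pw[i, j] = pw[j, i] = (ai[u].sum() / abci[u].sum()) if u.any() else np.nan
    lin, ncap = linearize_fst(pw)
    return DifferentiationResult(
        method="weir-cockerham-diploid", global_estimate=theta,
        pairwise=_raw_symmetric(sites, pw),
        linearized=DistanceMatrix(sites, lin), ci95=ci, n_capped=ncap,
        per_locus={"a": a_l, "abc": abc_l})


# ---------------------------------------------------------------------------
# Nei's D_A allele-sharing distance
# ---------------------------------------------------------------------------

def _site_freqs(gt: GenotypeTable):
    """Per locus: (allele labels, {site: frequency vector or None})."""
    out = []
    for l, locus in enumerate(gt.loci):
        alleles: list[str] = []
        cols = {}
        for s in gt.sites:
            col = gt.calls[gt.index_of(gt.individuals_of(s)), l, :]
            ok = col[:, 0] != None  # noqa: E711
            col = col[ok].astype(str)
            cols[s] = col if len(col) else None
            if len(col):
                for al in np.unique(col):
                    if al not in alleles:
                        alleles.append(al)
        alleles.sort()
        freqs = {}
        for s, col in cols.items():
            if col is None:
                freqs[s] = None
            else:
                freqs[s] = np.array([(col == al).sum() for al in alleles],
                                    dtype=float) / col.size
        out.append((locus, alleles, freqs))
    return out


def nei_da_distance(gt: GenotypeTable) -> DifferentiationResult:
    """Nei's D_A = 1 - (1/L) sum_loci sum_alleles sqrt(x_a y_a).

    Loci untyped in either member of a pair are dropped for that pair (the
    dropped count is recorded per pair in ``per_locus['n_dropped']``).
    """
    sites = gt.sites
    k = len(sites)
    freq_tables = _site_freqs(gt)
    per_locus_mats = {}
    vals = np.zeros((k, k))
    dropped = np.zeros((k, k), dtype=int)
    for locus, alleles, freqs in freq_tables:
        m = np.full((k, k), np.nan)
        for i in range(k):
            for j in range(i + 1, k):
                x, y = freqs[sites[i]], freqs[sites[j]]
                if x is None or y is None:
                    continue
                m[i, j] = m[j, i] = 1.0 - float(np.sqrt(x * y).sum())
        np.fill_diagonal(m, 0.0)
        per_locus_mats[locus] = m
    stack = np.array([per_locus_mats[l] for l, _, _ in freq_tables])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmean(stack, axis=0)
    dropped = np.isnan(stack).sum(axis=0)
    vals = np.where(np.isnan(vals), np.nan, vals)
    vals = np.clip(vals, 0.0, 1.0)
    np.fill_diagonal(vals, 0.0)
    return DifferentiationResult(
        method="nei-DA", global_estimate=None,
        pairwise=DistanceMatrix(sites, vals),
        per_locus={**per_locus_mats, "n_dropped": dropped})


# ---------------------------------------------------------------------------
# Sex-biased gene flow
# ---------------------------------------------------------------------------

@dataclass
class SexBiasResult:
    fst_nuclear: float
    fst_mt: float
    mm_over_mf: float
    flag: str | None = None


def sex_biased_gene_flow_ratio(fst_nuclear: float, fst_mt: float) -> SexBiasResult:
    """Island-model ratio of male to female gene flow from paired F_ST.

    Under nuclear F_ST = 1/(1 + 4N m_bar) with m_bar = (m_m + m_f)/2 and
    mitochondrial F_ST = 1/(1 + N m_f) (maternal haploid marker carried by
    the N/2 females), the male/female migration ratio is

        m_m/m_f = [(1/F_nuc - 1)/2 - (1/F_mt - 1)] / (1/F_mt - 1).

    A negative implied male rate (mtDNA structure too weak relative to
    nuclear) is reported as ratio 0 with a flag.
    """
    for name, v in (("fst_nuclear", fst_nuclear), ("fst_mt", fst_mt)):
        if not (0.0 < v < 1.0):
            raise DataError(f"{name}={v} outside (0, 1)")
    nm_total = (1.0 / fst_nuclear - 1.0) / 2.0   # N (m_m + m_f)
    nm_f = 1.0 / fst_mt - 1.0                    # N m_f
    ratio = (nm_total - nm_f) / nm_f
    flag = None
    if ratio < 0:
        ratio, flag = 0.0, "implied male gene flow negative; clamped to 0"
    return SexBiasResult(fst_nuclear, fst_mt, float(ratio), flag)
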