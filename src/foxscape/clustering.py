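"""Admixture inference across K with cluster profiles, migrant
classification, and temporal composition tracking.

The sampler is the standard admixture model: each allele copy of individual
i originates in cluster k with probability q_ik, cluster allele frequencies
get a Dirichlet prior (optionally the correlated-frequency F-model), and the
common Dirichlet parameter alpha of the ancestry vectors is updated by
Metropolis steps. ln P(D) is summarised as mean minus half the variance of
the data log-likelihood over post-burn-in cycles and is used for comparison
across K only, never as a hard model-choice criterion.

Rather than picking a single "best" K, the cluster-profile hierarchy records
each individual's modal cluster at every K and chooses the highest K whose
assignments nest within those at lower K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genodata import DataError, GenotypeTable

__all__ = [
    "ClusterRun",
    "admixture_mcmc",
    "ProfileHierarchy",
    "align_runs_build_profiles",
    "align_q",
    "MigrantCall",
    "classify_migrants",
    "temporal_composition",
]


@dataclass
class ClusterRun:
    K: int
    Q: np.ndarray                 # (I, K) posterior-mean ancestry fractions
    lnPD: float
    alpha_trace: np.ndarray
    cycles: int
    burn_in: int
    seed: int
    freq_model: str = "correlated"
    individuals: list[str] | None = None
    alpha_warning: bool = False


def _encode(gt: GenotypeTable):
    """Integer-coded calls (I, L, 2) with -1 missing, plus allele counts."""
    I, L = gt.n_individuals, len(gt.loci)
    X = np.full((I, L, 2), -1, dtype=int)
    n_alleles = np.zeros(L, dtype=int)
    for l, locus in enumerate(gt.loci):
        codes, alleles = gt.locus_codes(locus)
        X[:, l, :] = codes
        n_alleles[l] = max(len(alleles), 1)
    return X, n_alleles


def admixture_mcmc(gt: GenotypeTable, K: int, cycles: int = 20000,
                   burn_in: int = 10000, seed: int = 0,
                   freq_model: str = "correlated") -> ClusterRun:
    """Gibbs sampler for the admixture model at a fixed K.

    ``freq_model='correlated'`` uses the F-model prior Dir(p_anc (1-F_k)/F_k)
    with the ancestral frequencies fixed at the pooled empirical frequencies
    and per-cluster F_k updated by Metropolis; ``'independent'`` uses a flat
    Dirichlet(1) prior. Returns the posterior-mean Q and the usual
    mean-minus-half-variance summary of the data log-likelihood.
    """
    if K < 1:
        raise DataError("K must be >= 1")
    if cycles <= burn_in:
        raise DataError("cycles must exceed burn_in")
    rng = np.random.default_rng(seed)
    X, n_alleles = _encode(gt)
    I, L, _ = X.shape
    typed = X >= 0
    if K == 1:
        Q = np.ones((I, 1))
        # data log-likelihood at the pooled frequencies (for lnPD comparison)
        pool = [np.bincount(X[:, l, :][typed[:, l, :]], minlength=n_alleles[l])
                for l in range(L)]
        # posterior-predictive-ish plug-in with add-one smoothing
        logp = 0.0
        for l in range(L):
            f = (pool[l] + 1.0) / (pool[l] + 1.0).sum()
            obs = X[:, l, :][typed[:, l, :]]
            logp += np.log(f[obs]).sum()
        return ClusterRun(1, Q, float(logp), np.array([]), cycles, burn_in,
                          seed, freq_model, list(gt.individuals))

    A = int(n_alleles.max())
    # pooled empirical frequencies (ancestral frequencies of the F-model)
    p_anc = np.zeros((L, A))
    for l in range(L):
        c = np.bincount(X[:, l, :][typed[:, l, :]], minlength=A).astype(float)
        c[n_alleles[l]:] = 0.0
        c[: n_alleles[l]] += 0.5
        p_anc[l] = c / c.sum()

    P = np.tile(p_anc, (K, 1, 1))                    # (K, L, A)
    Q = rng.dirichlet(np.ones(K), size=I)            # (I, K)
    Fk = np.full(K, 0.1)
    alpha = 1.0
    alpha_trace = []
    ll_trace = []
    Qsum = np.zeros_like(Q)
    n_kept = 0
    flat_t = typed.reshape(I, -1)                    # (I, 2L)
    Xf = X.reshape(I, -1)
    lvec = np.repeat(np.arange(L), 2)                # locus index per column
    Xc = np.clip(Xf, 0, A - 1)
    valid_mask = np.arange(A)[None, :] < n_alleles[:, None]   # (L, A)
    correlated = freq_model == "correlated"

    def gather_p():
        # P[k, l(c), x(i,c)] -> (I, 2L, K)
        return np.transpose(P[:, lvec[None, :], Xc], (1, 2, 0))

    for cycle in range(cycles):
        # --- Z | Q, P ------------------------------------------------------
        probs = gather_p() * Q[:, None, :]           # (I, 2L, K)
        tot = probs.sum(-1, keepdims=True)
        tot[tot == 0] = 1.0
        probs = probs / tot
        u = rng.random((I, 2 * L, 1))
        Z = (probs.cumsum(-1) > u).argmax(-1)        # (I, 2L)
        Z = np.where(flat_t, Z, -1)

        # --- P | Z ---------------------------------------------------------
        flat_idx = lvec[None, :] * A + Xc                 # (I, 2L)
        for k in range(K):
            sel = (Z == k) & flat_t
            cnt = np.bincount(flat_idx[sel], minlength=L * A) \
                .reshape(L, A).astype(float)
            if correlated:
                lam = p_anc * (1 - Fk[k]) / Fk[k]
            else:
                lam = valid_mask.astype(float)
            draw = rng.gamma(np.maximum(lam + cnt, 0.0) * valid_mask)
            draw[~valid_mask] = 0.0
            rowsum = draw.sum(1, keepdims=True)
            rowsum[rowsum == 0] = 1.0
            P[k] = draw / rowsum

        # --- F_k | P (correlated model) ------------------------------------
        if correlated:
            logP = np.log(np.maximum(P, 1e-12))

            def f_logpost(k, f):
                lam = p_anc * (1 - f) / f
                return float(
                    gammaln(lam.sum(1)).sum()
                    - gammaln(lam[valid_mask]).sum()
                    + ((lam - 1) * logP[k])[valid_mask].sum())

            for k in range(K):
                prop = Fk[k] * np.exp(rng.normal(0, 0.2))
                if not (1e-4 < prop < 0.999):
                    continue
                if np.log(rng.random()) < (f_logpost(k, prop)
                                           - f_logpost(k, Fk[k])
                                           + np.log(prop) - np.log(Fk[k])):
                    Fk[k] = prop

        # --- Q | Z, alpha ---------------------------------------------------
        nik = np.zeros((I, K))
        for k in range(K):
            nik[:, k] = (Z == k).sum(axis=1)
        gam = rng.gamma(alpha + nik)
        gam[gam.sum(1) == 0] = 1.0
        Q = gam / gam.sum(1, keepdims=True)

        # --- alpha | Q ------------------------------------------------------
        prop = alpha + rng.normal(0, 0.05)
        if 0 < prop <= 10:
            def alpha_ll(a):
                return I * (gammaln(K * a) - K * gammaln(a)) \
                    + (a - 1) * np.log(np.maximum(Q, 1e-12)).sum()
            if np.log(rng.random()) < alpha_ll(prop) - alpha_ll(alpha):
                alpha = prop
        alpha_trace.append(alpha)

        if cycle >= burn_in:
            Qsum += Q
            # data log-likelihood ln P(X | P, Q)
            pr = gather_p() * Q[:, None, :]
            ll = np.log(np.maximum(pr.sum(-1)[flat_t], 1e-300)).sum()
            ll_trace.append(ll)
            n_kept += 1

    Qbar = Qsum / n_kept
    ll = np.asarray(ll_trace)
    lnPD = float(ll.mean() - 0.5 * ll.var())
    alpha_trace = np.asarray(alpha_trace)
    alpha_warn = bool(alpha_trace[burn_in:].std() > 2.0) if cycles > burn_in else False
    return ClusterRun(K, Qbar, lnPD, alpha_trace, cycles, burn_in, seed,
                      freq_model, list(gt.individuals), alpha_warn)


# ---------------------------------------------------------------------------
# Label alignment and cluster profiles
# ---------------------------------------------------------------------------

def align_q(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Permute columns of ``other`` to best match ``reference``.

    Greedy maximum-correlation bipartite matching (approximate label-
    switching resolution). Returns the permuted copy of ``other``.
    """
    K = reference.shape[1]
    corr = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            x, y = reference[:, a], other[:, b]
            sx, sy = x.std(), y.std()
            corr[a, b] = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy) \
                if sx > 0 and sy > 0 else -np.inf
    perm = np.full(K, -1)
    used_a, used_b = set(), set()
    order = np.dstack(np.unravel_index(np.argsort(corr, axis=None)[::-1],
                                       corr.shape))[0]
    for a, b in order:
        if a not in used_a and b not in used_b:
            perm[a] = b
            used_a.add(int(a))
            used_b.add(int(b))
    return other[:, perm]


@dataclass
class ProfileHierarchy:
    individuals: list[str]
    k_values: list[int]
    profiles: np.ndarray            # (I, len(k_values)) modal cluster per K
    profile_counts: pd.Series       # tally of profile tuples
    consensus_q: dict[int, np.ndarray]
    nested: dict[int, bool]         # K -> transition (K-1 -> K) nested?
    valid: dict[int, bool]          # K -> replicates aligned & clusters occupied
    multimodal: list[int]
    chosen_K: int


def align_runs_build_profiles(
    runs: Sequence[ClusterRun], tolerance: float = 0.05,
    agreement: float = 0.95,
) -> ProfileHierarchy:
    """Align replicate runs, build per-individual cluster profiles, and pick
    the highest K whose assignments nest within lower-K assignments.

    A K -> K+1 transition is *nested* when, for every K+1 cluster, at least
    ``1 - tolerance`` of its modal members share a single modal cluster at K.
    A K level is *valid* when its replicates align (mean column correlation
    >= ``agreement``) and every cluster is modal for at least one individual;
    invalid levels break the nesting chain. chosen_K is the highest K with
    all levels 2..K valid and all transitions nested.
    """
    by_k: dict[int, list[ClusterRun]] = {}
    for r in runs:
        by_k.setdefault(r.K, []).append(r)
    k_values = sorted(by_k)
    if len(k_values) < 2:
        raise DataError("need runs at >= 2 values of K")
    I = by_k[k_values[0]][0].Q.shape[0]
    individuals = by_k[k_values[0]][0].individuals or [str(i) for i in range(I)]

    consensus: dict[int, np.ndarray] = {}
    valid: dict[int, bool] = {}
    multimodal: list[int] = []
    for K in k_values:
        reps = by_k[K]
        ref = reps[0].Q
        aligned = [ref]
        ok = True
        for r in reps[1:]:
            q = align_q(ref, r.Q)
            cors = []
            for c in range(K):
                x, y = ref[:, c], q[:, c]
                if x.std() > 0 and y.std() > 0:
                    cors.append(np.corrcoef(x, y)[0, 1])
            if cors and np.mean(cors) < agreement:
                ok = False
            aligned.append(q)
        cq = np.mean(aligned, axis=0)
        cq = cq / cq.sum(1, keepdims=True)
        consensus[K] = cq
        occupied = len(np.unique(cq.argmax(1))) == K
        valid[K] = ok and occupied
        if not ok:
            multimodal.append(K)

    profiles = np.zeros((I, len(k_values)), dtype=int)
    for j, K in enumerate(k_values):
        profiles[:, j] = consensus[K].argmax(1)
    tuples = [tuple(row) for row in profiles]
    counts = pd.Series(tuples).value_counts()

    # nesting chain over the valid K levels only: a multimodal (invalid) K
    # is excluded from the chain, so nesting is checked between consecutive
    # valid levels
    col_of = {K: j for j, K in enumerate(k_values)}
    valid_levels = [K for K in k_values if valid.get(K, False)]
    nested: dict[int, bool] = {}
    for a_, b_ in zip(valid_levels, valid_levels[1:]):
        lo, hi = profiles[:, col_of[a_]], profiles[:, col_of[b_]]
        ok = True
        for c in np.unique(hi):
            members = lo[hi == c]
            top = np.bincount(members).max()
            if top < (1.0 - tolerance) * len(members):
                ok = False
        nested[b_] = ok

    chosen = valid_levels[0] if valid_levels else k_values[0]
    for b_ in valid_levels[1:]:
        if nested.get(b_, False):
            chosen = b_
        else:
            break
    return ProfileHierarchy(individuals, k_values, profiles, counts,
                            consensus, nested, valid, multimodal, chosen)


# ---------------------------------------------------------------------------
# Migrant classification and temporal composition
# ---------------------------------------------------------------------------

@dataclass
class MigrantCall:
    individual: str
    home_site: str
    modal_cluster: int
    q_max: float
    klass: str                     # resident | migrant | admixed
    source_cluster: int | None = None
    source_site: str | None = None


def classify_migrants(run: ClusterRun, site_of: Mapping[str, str],
                      q_threshold: float = 0.75) -> list[MigrantCall]:
    """Classify individuals as residents, first-generation migrants, or
    admixed, from the chosen-K ancestry matrix.

    The home cluster of a site is the modal cluster among its members (ties
    broken by higher mean q). An individual is admixed iff q_max < threshold;
    a strongly assigned individual whose modal cluster differs from its home
    site's cluster is called a first-generation migrant from the site (if
    any) whose home cluster matches.
    """
    inds = run.individuals or [str(i) for i in range(run.Q.shape[0])]
    modal = run.Q.argmax(1)
    qmax = run.Q.max(1)
    sites: dict[str, list[int]] = {}
    for i, ind in enumerate(inds):
        sites.setdefault(site_of[ind], []).append(i)
    home_cluster: dict[str, int] = {}
    for s, members in sites.items():
        cnt = np.bincount(modal[members], minlength=run.K)
        best = np.flatnonzero(cnt == cnt.max())
        if len(best) > 1:
            means = run.Q[members].mean(0)
            best = [best[np.argmax(means[best])]]
        home_cluster[s] = int(best[0])
    cluster_home_site = {}
    for s, c in home_cluster.items():
        cluster_home_site.setdefault(c, s)
    calls = []
    for i, ind in enumerate(inds):
        s = site_of[ind]
        if qmax[i] < q_threshold:
            calls.append(MigrantCall(ind, s, int(modal[i]), float(qmax[i]),
                                     "admixed"))
        elif modal[i] == home_cluster[s]:
            calls.append(MigrantCall(ind, s, int(modal[i]), float(qmax[i]),
                                     "resident"))
        else:
            calls.append(MigrantCall(
                ind, s, int(modal[i]), float(qmax[i]), "migrant",
                int(modal[i]), cluster_home_site.get(int(modal[i]))))
    return calls


def temporal_composition(run: ClusterRun, date_of: Mapping[str, float],
                         periods: Sequence[tuple[float, float]],
                         site_of: Mapping[str, str] | None = None,
                         q_threshold: float = 0.75):
    """Per-period mean ancestry and migrant fraction, with an L1 change
    statistic between consecutive periods.

    ``periods`` are (start, end] date intervals. Raises on a single period
    or an empty one.
    """
    if len(periods) < 2:
        raise DataError("need >= 2 periods")
    inds = run.individuals or [str(i) for i in range(run.Q.shape[0])]
    calls = classify_migrants(run, site_of, q_threshold) if site_of else None
    klass = {c.individual: c.klass for c in calls} if calls else {}
    rows = []
    comps = []
    for lo, hi in periods:
        members = [i for i, ind in enumerate(inds)
                   if date_of.get(ind) is not None
                   and lo < date_of[ind] <= hi]
        if not members:
            raise DataError(f"empty period ({lo}, {hi}]")
        comp = run.Q[members].mean(0)
        comps.append(comp)
        mig = (np.mean([klass[inds[i]] == "migrant" for i in members])
               if klass else np.nan)
        rows.append({"period": (lo, hi), "n": len(members),
                     "mean_q": comp, "migrant_fraction": float(mig)})
    change = [float(np.abs(comps[i + 1] - comps[i]).sum())
              for i in range(len(comps) - 1)]
    return pd.DataFrame(rows), change
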