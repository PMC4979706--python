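"""Neighbor-joining trees with locus-bootstrap support, and principal
coordinates of individual genotypic distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genodata import DataError, DistanceMatrix, GenotypeTable
from .popgen import nei_da_distance

__all__ = [
    "TreeResult",
    "neighbor_joining",
    "bootstrap_support",
    "OrdinationResult",
    "pcoa_individuals",
    "genotypic_distance_matrix",
]


@dataclass
class _Node:
    name: str | None = None                 # leaf name, None for internal
    children: list = field(default_factory=list)  # (child, branch_length)

    @property
    def is_leaf(self) -> bool:
        return self.name is not None

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])
        out: set[str] = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)


@dataclass
class TreeResult:
    """Unrooted tree (represented rooted at the final join) with optional
    per-bipartition bootstrap support in percent."""

    root: _Node
    labels: list[str]
    support: dict[frozenset, float] | None = None
    n_boot: int = 0

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each canonicalized as the side that does
        not contain the lexicographically smallest leaf."""
        ref = min(self.labels)
        full = frozenset(self.labels)
        out: set[frozenset] = set()

        def walk(node: _Node) -> None:
            for child, _ in node.children:
                side = child.leaves()
                if 1 < len(side) < len(full) - 1:
                    out.add(side if ref not in side else full - side)
                walk(child)

        walk(self.root)
        return out

    def branch_lengths(self) -> dict[frozenset, float]:
        """Map from each edge's leaf-side set (uncanonicalized) to length."""
        out: dict[frozenset, float] = {}

        def walk(node: _Node) -> None:
            for child, bl in node.children:
                out[child.leaves()] = bl
                walk(child)

        walk(self.root)
        return out

    def leaf_distances(self) -> DistanceMatrix:
        """Patristic (path-length) distances between leaves."""
        leaves = sorted(self.labels)
        k = len(leaves)
        idx = {l: i for i, l in enumerate(leaves)}
        vals = np.zeros((k, k))

        def collect(node: _Node) -> dict[str, float]:
            """Distances from node to each leaf below it; fills cross terms."""
            if node.is_leaf:
                return {node.name: 0.0}
            groups = []
            for child, bl in node.children:
                sub = collect(child)
                groups.append({l: d + bl for l, d in sub.items()})
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi].items():
                        for lb, db in groups[gj].items():
                            vals[idx[la], idx[lb]] = vals[idx[lb], idx[la]] = da + db
            merged: dict[str, float] = {}
            for g in groups:
                merged.update(g)
            return merged

        collect(self.root)
        return DistanceMatrix(leaves, vals)

    def newick(self, with_support: bool = True) -> str:
        sup = self.support or {}
        ref = min(self.labels)
        full = frozenset(self.labels)

        def fmt(node: _Node, bl: float | None) -> str:
            if node.is_leaf:
                s = node.name
            else:
                inner = ",".join(fmt(c, b) for c, b in node.children)
                label = ""
                side = node.leaves()
                if with_support and 1 < len(side) < len(full) - 1:
                    key = side if ref not in side else full - side
                    if key in sup:
                        label = f"{sup[key]:.0f}"
                s = f"({inner}){label}"
            return s if bl is None else f"{s}:{bl:.6g}"

        return fmt(self.root, None) + ";"


def neighbor_joining(d: DistanceMatrix) -> TreeResult:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Ties in Q are broken by the lexicographically smallest pair of node
    labels (an internal node carries the smallest leaf name of its subtree).
    A negative branch length is set to zero and its magnitude transferred to
    the sibling branch of the same join.
    """
    labels = list(d.labels)
    if len(labels) < 3:
        raise DataError("neighbor joining needs >= 3 taxa")
    if not np.isfinite(d.values).all():
        raise DataError("infinite distances; cap or exclude them upstream")
    nodes = [_Node(name=l) for l in labels]
    names = list(labels)  # sort key per active node
    D = d.values.astype(float).copy()

    while len(nodes) > 2:
        r = len(nodes)
        sums = D.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                key = (q, *sorted((names[i], names[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = D[i, j] / 2.0 + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = max(li + lj, 0.0), 0.0
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        newd = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = newd[keep]
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
        D = D2

    bl = max(D[0, 1], 0.0)
    a, b = nodes
    # graft to make the final edge explicit (root on it with half lengths
    # folded into one side, keeping the unrooted interpretation)
    root = _Node(children=[(a, bl / 2.0), (b, bl / 2.0)])
    return TreeResult(root=root, labels=labels)


def bootstrap_support(gt: GenotypeTable, n_boot: int = 999,
                      seed: int = 0) -> TreeResult:
    """Locus-bootstrap support for the Nei-D_A neighbor-joining site tree.

    Loci are resampled with replacement; D_A and the NJ tree are recomputed
    per replicate; support for each original-tree bipartition is the percent
    of replicates containing it.
    """
    if len(gt.loci) < 2:
        warnings.warn("single locus: all bootstrap replicates are identical",
                      stacklevel=2)
    res = nei_da_distance(gt)
    original = neighbor_joining(res.pairwise)
    per_locus = np.array([res.per_locus[l] for l in gt.loci])  # (L, k, k)
    rng = np.random.default_rng(seed)
    target = original.bipartitions()
    hits = {bp: 0 for bp in target}
    L = len(gt.loci)
    for _ in range(n_boot):
        pick = rng.integers(0, L, size=L)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(per_locus[pick], axis=0)
        m = np.clip(np.nan_to_num(m, nan=1.0), 0.0, 1.0)
        np.fill_diagonal(m, 0.0)
        rep = neighbor_joining(DistanceMatrix(res.pairwise.labels, m))
        got = rep.bipartitions()
        for bp in target:
            if bp in got:
                hits[bp] += 1
    support = {bp: 100.0 * h / n_boot for bp, h in hits.items()}
    original.support = support
    original.n_boot = n_boot
    return original


# ---------------------------------------------------------------------------
# PCoA of individual genotypic distances
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    individuals: list[str]
    coordinates: np.ndarray     # (n, n_positive_axes), eigenvalue-sorted
    eigenvalues: np.ndarray     # all eigenvalues, descending
    percent_variance: np.ndarray
    n_imputed_pairs: int = 0


def genotypic_distance_matrix(gt: GenotypeTable) -> tuple[np.ndarray, int]:
    """Squared inter-individual genotypic distance (allele-mismatch metric).

    Per locus the squared distance between two diploid genotypes is half the
    squared difference of their allele-count vectors (0 same genotype, 1 one
    shared allele of a heterozygote pair, 2 disjoint heterozygotes, 3
    homozygote vs disjoint heterozygote, 4 opposite homozygotes), summed over
    loci with pairwise deletion and rescaled to the full locus count. Pairs
    sharing no typed locus get the mean of defined distances (count returned).
    """
    n, L = gt.n_individuals, len(gt.loci)
    d2 = np.zeros((n, n))
    shared = np.zeros((n, n))
    for l, locus in enumerate(gt.loci):
        codes, alleles = gt.locus_codes(locus)
        k = len(alleles)
        if k == 0:
            continue
        typed = codes[:, 0] >= 0
        x = np.zeros((n, k))
        for c in range(2):
            idx = codes[:, c]
            x[typed, :] += np.eye(k)[idx[typed]]
        diff = x[:, None, :] - x[None, :, :]
        contrib = 0.5 * (diff ** 2).sum(-1)
        both = typed[:, None] & typed[None, :]
        d2 += np.where(both, contrib, 0.0)
        shared += both
    np.fill_diagonal(shared, L if L else 1)
    defined = shared > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = d2 * (L / shared)
    n_imputed = int((~defined).sum() // 2)
    if n_imputed:
        mean_d = scaled[defined & ~np.eye(n, dtype=bool)].mean()
        scaled = np.where(defined, scaled, mean_d)
    np.fill_diagonal(scaled, 0.0)
    return scaled, n_imputed


def pcoa_individuals(gt: GenotypeTable) -> OrdinationResult:
    """Principal coordinates of the squared genotypic distance matrix.

    Gower double-centering of -D^2/2 followed by eigendecomposition; axes
    with positive eigenvalues are returned (negative eigenvalues are kept in
    ``eigenvalues`` for inspection). Coordinates are centered by construction.
    """
    if gt.n_individuals < 3:
        raise DataError("PCoA needs >= 3 individuals")
    d2, n_imputed = genotypic_distance_matrix(gt)
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10 * max(abs(evals[0]), 1.0)
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total = evals[pos].sum()
    pct = np.where(pos, evals / total, 0.0)[pos] * 100.0
    return OrdinationResult(list(gt.individuals), coords, evals, pct, n_imputed)
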