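"""Data model and I/O for genotypes, haplotype counts, site coordinates,
rasters, and distance matrices.

All geometry is planar, in km. Longitude/latitude input is projected with a
local equirectangular projection about the centroid of the sites, which is
adequate at the ~1000 km extent this package targets (worst-case scale error
below ~1% at that extent).

Missing genotype data are preserved as missing and handled downstream by
pairwise deletion per locus: an individual missing a locus is excluded from
that locus's statistics only, never imputed.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "GenotypeTable",
    "HaplotypeCounts",
    "SiteMap",
    "DistanceMatrix",
    "RasterGrid",
    "read_genotype_table",
    "write_genotype_table",
    "read_haplotype_counts",
    "write_haplotype_counts",
    "read_raster_grid",
    "write_raster_grid",
    "read_distance_matrix",
    "write_distance_matrix",
    "load_dryad_genotypes",
]

MISSING = None  # sentinel for a missing allele call

_EARTH_RADIUS_KM = 6371.0


class DataError(ValueError):
    """Invalid or inconsistent input data."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DataError(msg)


@dataclass
class GenotypeTable:
    """Diploid multi-allelic genotypes for individuals at microsatellite loci.

    ``calls`` is an object array of shape (n_individuals, n_loci, 2) holding
    allele labels (strings) or ``None`` for missing. A call is either fully
    present (two labels) or fully missing. Allele labels are opaque strings;
    loci listed in ``repeat_loci`` additionally promise integer repeat scores,
    which stepwise-mutation-model analyses require.
    """

    individuals: list[str]
    loci: list[str]
    calls: np.ndarray
    site_of: dict[str, str]
    date_of: dict[str, float | None] = field(default_factory=dict)
    sex_of: dict[str, str | None] = field(default_factory=dict)
    repeat_loci: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        n, L = len(self.individuals), len(self.loci)
        _require(len(set(self.individuals)) == n, "duplicated individual id")
        _require(len(set(self.loci)) == L, "duplicated locus id")
        self.calls = np.asarray(self.calls, dtype=object)
        _require(self.calls.shape == (n, L, 2),
                 f"calls shape {self.calls.shape} != {(n, L, 2)}")
        missing_site = [i for i in self.individuals if i not in self.site_of]
        _require(not missing_site, f"individuals without site: {missing_site[:5]}")
        # diploid invariant: both alleles present or both missing
        a, b = self.calls[..., 0], self.calls[..., 1]
        bad = (a == None) ^ (b == None)  # noqa: E711 (elementwise)
        if bad.any():
            i, l = np.argwhere(bad)[0]
            raise DataError(
                f"half-missing call for {self.individuals[i]} at {self.loci[l]}")

    # ---- convenience views -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def sites(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.site_of[ind], None)
        return list(seen)

    def individuals_of(self, site: str) -> list[str]:
        return [i for i in self.individuals if self.site_of[i] == site]

    def index_of(self, individuals: Iterable[str]) -> np.ndarray:
        pos = {ind: k for k, ind in enumerate(self.individuals)}
        return np.array([pos[i] for i in individuals], dtype=int)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci) mask, True where the call is missing."""
        return self.calls[..., 0] == None  # noqa: E711

    def locus_codes(self, locus: str) -> tuple[np.ndarray, list[str]]:
        """Integer-coded alleles for one locus.

        Returns ``(codes, alleles)`` with codes of shape (n_individuals, 2),
        missing coded as -1, and ``alleles`` the sorted label list.
        """
        l = self.loci.index(locus)
        col = self.calls[:, l, :]
        labels = sorted({a for a in col.ravel() if a is not None})
        lut = {a: k for k, a in enumerate(labels)}
        codes = np.array(
            [[lut.get(a, -1) if a is not None else -1 for a in row] for row in col],
            dtype=int,
        )
        return codes, labels

    def subset(self, individuals: Sequence[str]) -> "GenotypeTable":
        idx = self.index_of(individuals)
        return GenotypeTable(
            individuals=list(individuals),
            loci=list(self.loci),
            calls=self.calls[idx].copy(),
            site_of={i: self.site_of[i] for i in individuals},
            date_of={i: self.date_of.get(i) for i in individuals},
            sex_of={i: self.sex_of.get(i) for i in individuals},
            repeat_loci=set(self.repeat_loci),
        )

    def allele_counts(self, site: str, locus: str) -> dict[str, int]:
        """Allele count dictionary at one locus in one site (pairwise deletion)."""
        idx = self.index_of(self.individuals_of(site))
        l = self.loci.index(locus)
        out: dict[str, int] = {}
        for a in self.calls[idx, l, :].ravel():
            if a is not None:
                out[a] = out.get(a, 0) + 1
        return out

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.site_of == other.site_of
            and bool(np.all(self.calls == other.calls))
        )


@dataclass
class HaplotypeCounts:
    """Site-by-haplotype count matrix for a maternally inherited marker.

    ``declared_n`` and ``declared_diversity`` mirror printed summary columns of
    a source table when one is being reproduced; counts remain authoritative,
    the declared n is a checksum. Rows whose count sum disagrees with the
    declared n are flagged inconsistent (see ``consistent``).
    ``included_sites`` lists the sites admitted to within-site means; by
    default, sites with n >= 5 and a single known location.
    """

    sites: list[str]
    haplotypes: list[str]
    counts: np.ndarray
    declared_n: np.ndarray | None = None
    declared_diversity: np.ndarray | None = None
    included_sites: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        _require(self.counts.shape == (len(self.sites), len(self.haplotypes)),
                 "counts shape mismatch")
        _require(np.issubdtype(self.counts.dtype, np.integer)
                 or np.all(self.counts == np.round(self.counts)),
                 "haplotype counts must be integers")
        self.counts = self.counts.astype(int)
        _require((self.counts >= 0).all(), "negative haplotype count")
        if self.declared_n is not None:
            self.declared_n = np.asarray(self.declared_n, dtype=float)
            mism = ~self.consistent
            if mism.any():
                bad = [self.sites[i] for i in np.flatnonzero(mism)]
                warnings.warn(
                    f"declared n disagrees with count sums for sites {bad}; "
                    "counts remain authoritative", stacklevel=2)

    @property
    def n(self) -> np.ndarray:
        """Per-site sample size recomputed from counts."""
        return self.counts.sum(axis=1)

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def consistent(self) -> np.ndarray:
        """True where the declared n (if any) matches the count sum."""
        if self.declared_n is None:
            return np.ones(len(self.sites), dtype=bool)
        ok = np.isnan(self.declared_n) | (self.declared_n == self.n)
        return ok

    def frequencies(self) -> np.ndarray:
        n = self.n.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / n[:, None]

    def row(self, site: str) -> np.ndarray:
        return self.counts[self.sites.index(site)]

    def subset(self, sites: Sequence[str]) -> "HaplotypeCounts":
        idx = [self.sites.index(s) for s in sites]
        return HaplotypeCounts(
            sites=list(sites),
            haplotypes=list(self.haplotypes),
            counts=self.counts[idx].copy(),
            declared_n=None if self.declared_n is None else self.declared_n[idx],
            declared_diversity=(None if self.declared_diversity is None
                                else self.declared_diversity[idx]),
            included_sites=(None if self.included_sites is None
                            else [s for s in self.included_sites if s in sites]),
        )


@dataclass
class SiteMap:
    """Planar site coordinates in km."""

    coords: dict[str, tuple[float, float]]
    crs_note: str = "planar-km"

    def __post_init__(self) -> None:
        for s, (x, y) in self.coords.items():
            _require(np.isfinite(x) and np.isfinite(y),
                     f"non-finite coordinate for site {s}")

    @classmethod
    def from_lonlat(cls, lonlat: Mapping[str, tuple[float, float]]) -> "SiteMap":
        """Project lon/lat (degrees) to local planar km (equirectangular)."""
        lons = np.array([v[0] for v in lonlat.values()])
        lats = np.array([v[1] for v in lonlat.values()])
        lon0, lat0 = lons.mean(), lats.mean()
        k = np.pi / 180.0 * _EARTH_RADIUS_KM
        coords = {
            s: ((lon - lon0) * np.cos(np.deg2rad(lat0)) * k, (lat - lat0) * k)
            for s, (lon, lat) in lonlat.items()
        }
        return cls(coords, crs_note=f"equirectangular about ({lon0:.4f},{lat0:.4f})")

    def __getitem__(self, site: str) -> tuple[float, float]:
        return self.coords[site]

    @property
    def sites(self) -> list[str]:
        return list(self.coords)

    def array(self, order: Sequence[str] | None = None) -> np.ndarray:
        order = list(self.coords) if order is None else list(order)
        missing = [s for s in order if s not in self.coords]
        _require(not missing, f"sites without coordinates: {missing}")
        return np.array([self.coords[s] for s in order], dtype=float)

    def euclidean_distances(self, order: Sequence[str] | None = None) -> "DistanceMatrix":
        order = list(self.coords) if order is None else list(order)
        xy = self.array(order)
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        return DistanceMatrix(order, d)


@dataclass
class DistanceMatrix:
    """Labeled symmetric nonnegative matrix with a zero diagonal.

    Infinities are permitted (e.g. capped linearized F_ST, disconnected
    resistance pairs) and flagged through ``has_infinite``.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.labels)
        _require(self.values.shape == (k, k), "distance matrix not square")
        _require(np.array_equal(self.values, self.values.T),
                 "distance matrix not symmetric")
        _require(np.all(np.diag(self.values) == 0.0), "nonzero diagonal")
        finite = self.values[np.isfinite(self.values)]
        _require((finite >= 0).all() or np.allclose(finite[finite < 0], 0),
                 "negative distances")

    @property
    def has_infinite(self) -> bool:
        return bool(np.isinf(self.values).any())

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) entries in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        missing = [l for l in labels if l not in self.labels]
        _require(not missing, f"labels absent from matrix: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def require_matching_labels(*mats: DistanceMatrix) -> None:
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            extra = sorted(set(m.labels) ^ set(ref))
            raise DataError(f"distance-matrix labels do not match: {extra or 'order differs'}")


@dataclass
class RasterGrid:
    """Rectangular grid of per-cell resistance (or suitability) values.

    ``values[0, 0]`` is the top-left cell (ESRI ASCII row order); ``origin``
    is the (x, y) of the lower-left corner in km. ``nodata_mask`` is True
    where the cell carries no value.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = None
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        _require(self.values.ndim == 2, "raster must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        _require(self.nodata_mask.shape == self.values.shape, "nodata mask shape")
        _require(self.cell_size > 0, "cell size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, each of shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 + (self.n_rows - np.arange(self.n_rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((y - y0) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise DataError(f"point ({x}, {y}) falls outside the raster")
        return row, col


def invert_suitability(r: RasterGrid, floor: float = 1e-3) -> RasterGrid:
    """Turn a habitat-suitability raster (values in [0,1]) into resistance 1/s.

    Suitability is floored at ``floor`` so resistance stays finite.
    """
    vals = 1.0 / np.maximum(r.values, floor)
    vals[r.nodata_mask] = r.nodata_value
    return RasterGrid(vals, r.cell_size, r.origin, r.nodata_mask.copy(),
                      r.nodata_value)


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------

_TWOCOL_META = ("id", "site", "date", "sex")


def read_genotype_table(path, dialect: str = "two-column") -> GenotypeTable:
    """Read a genotype table.

    dialect:
      ``two-column``      CSV with columns id, site, [date], [sex], then two
                          columns per locus named ``LOCUS.1``/``LOCUS.2``;
                          empty or ``NA`` cells are missing.
      ``genepop``         GenePop text: title, locus names, ``Pop`` blocks,
                          2- or 3-digit diploid codes; ``0`` codes missing.
      ``structure-rows``  whitespace table, header of locus names, then one
                          row per individual: id site a1 a2 a1 a2 ...;
                          ``-9`` codes missing.
    """
    if dialect == "two-column":
        return _read_twocol(path)
    if dialect == "genepop":
        return _read_genepop(path)
    if dialect == "structure-rows":
        return _read_structure_rows(path)
    raise DataError(f"unknown genotype dialect {dialect!r}")


def _read_twocol(path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    _require(cols[:2] == ["id", "site"], "two-column dialect needs id,site first")
    meta = [c for c in cols if c in _TWOCOL_META]
    allele_cols = [c for c in cols if c not in _TWOCOL_META]
    loci: list[str] = []
    for c in allele_cols:
        base, _, suf = c.rpartition(".")
        _require(suf in ("1", "2") and base, f"bad allele column name {c!r}")
        if base not in loci:
            loci.append(base)
    for loc in loci:
        _require(f"{loc}.1" in cols and f"{loc}.2" in cols,
                 f"odd allele count: locus {loc} lacks a paired column")
    individuals = df["id"].tolist()
    if len(set(individuals)) != len(individuals):
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise DataError(f"duplicated individual id {dup!r}")
    n, L = len(individuals), len(loci)
    calls = np.empty((n, L, 2), dtype=object)
    for j, loc in enumerate(loci):
        for k in (0, 1):
            col = df[f"{loc}.{k + 1}"].to_numpy()
            calls[:, j, k] = [None if v in ("", "NA") else v for v in col]
    date_of = {}
    if "date" in meta:
        for ind, v in zip(individuals, df["date"]):
            date_of[ind] = float(v) if v not in ("", "NA") else None
    sex_of = {}
    if "sex" in meta:
        for ind, v in zip(individuals, df["sex"]):
            sex_of[ind] = v if v not in ("", "NA") else None
    return GenotypeTable(individuals, loci, calls,
                         dict(zip(individuals, df["site"])), date_of, sex_of)


def write_genotype_table(gt: GenotypeTable, path) -> None:
    """Write the two-column CSV dialect (round-trips with the reader)."""
    data: dict[str, list] = {"id": gt.individuals,
                             "site": [gt.site_of[i] for i in gt.individuals]}
    if any(gt.date_of.get(i) is not None for i in gt.individuals):
        data["date"] = ["" if gt.date_of.get(i) is None else repr(gt.date_of[i])
                        for i in gt.individuals]
    if any(gt.sex_of.get(i) is not None for i in gt.individuals):
        data["sex"] = [gt.sex_of.get(i) or "" for i in gt.individuals]
    for j, loc in enumerate(gt.loci):
        for k in (0, 1):
            data[f"{loc}.{k + 1}"] = ["" if a is None else a
                                      for a in gt.calls[:, j, k]]
    pd.DataFrame(data).to_csv(path, index=False)


def _read_genepop(path) -> GenotypeTable:
    lines = Path(path).read_text().splitlines()
    _require(len(lines) >= 3, "truncated GenePop file")
    body = lines[1:]
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().lower() != "pop":
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    _require(i < len(body), "GenePop file has no Pop line")
    individuals, calls_rows, site_of = [], [], {}
    pop_idx = 0
    for line in body[i:]:
        s = line.strip()
        if not s:
            continue
        if s.lower() == "pop":
            pop_idx += 1
            continue
        _require("," in s, f"malformed GenePop individual line {s!r}")
        name, genos = s.split(",", 1)
        name = name.strip()
        fields = genos.split()
        _require(len(fields) == len(loci),
                 f"{name}: {len(fields)} genotypes for {len(loci)} loci")
        row = []
        for loc, g in zip(loci, fields):
            _require(len(g) in (4, 6) and g.isdigit(),
                     f"parse error at {name}/{loc}: bad code {g!r}")
            w = len(g) // 2
            a, b = g[:w], g[w:]
            row.append((None, None) if (int(a) == 0 or int(b) == 0)
                       else (str(int(a)), str(int(b))))
        if name in site_of:
            raise DataError(f"duplicated individual id {name!r}")
        individuals.append(name)
        site_of[name] = f"pop{pop_idx}"
        calls_rows.append(row)
    calls = np.array(calls_rows, dtype=object)
    return GenotypeTable(individuals, loci, calls, site_of,
                         repeat_loci=set(loci))


def _read_structure_rows(path) -> GenotypeTable:
    lines = [l for l in Path(path).read_text().splitlines() if l.strip()]
    loci = lines[0].split()
    individuals, calls_rows, site_of = [], [], {}
    for line in lines[1:]:
        parts = line.split()
        _require(len(parts) == 2 + 2 * len(loci),
                 f"row for {parts[0]!r}: expected {2 + 2 * len(loci)} fields, "
                 f"got {len(parts)} (odd allele count?)")
        name, site = parts[0], parts[1]
        if name in site_of:
            raise DataError(f"duplicated individual id {name!r}")
        row = []
        for j in range(len(loci)):
            a, b = parts[2 + 2 * j], parts[3 + 2 * j]
            row.append((None, None) if "-9" in (a, b) else (a, b))
        individuals.append(name)
        site_of[name] = site
        calls_rows.append(row)
    return GenotypeTable(individuals, loci, np.array(calls_rows, dtype=object),
                         site_of, repeat_loci=set(loci))


def write_structure_rows(gt: GenotypeTable, path) -> None:
    """Structure one-row-per-individual writer (for external cross-checks)."""
    with open(path, "w") as fh:
        fh.write(" ".join(gt.loci) + "\n")
        for i, ind in enumerate(gt.individuals):
            row = [ind, gt.site_of[ind]]
            for j in range(len(gt.loci)):
                a, b = gt.calls[i, j]
                row.extend(["-9", "-9"] if a is None else [a, b])
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# Haplotype counts I/O
# ---------------------------------------------------------------------------

def read_haplotype_counts(path) -> HaplotypeCounts:
    """Read a site-by-haplotype count CSV.

    Columns: ``site``, optional ``n``, optional ``diversity``, optional
    ``included`` (0/1), then one column per haplotype. Dashes ("-", "–") and
    blanks count as zero. The declared n column is a checksum only; a mismatch
    with the count sum is a warning, not an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require(len(df) > 0 and df.shape[1] > 1, "empty haplotype table")
    cols = list(df.columns)
    _require(cols[0] == "site", "first column must be 'site'")
    meta = {c for c in ("n", "diversity", "included") if c in cols}
    hap_cols = [c for c in cols[1:] if c not in meta]
    counts = np.zeros((len(df), len(hap_cols)), dtype=int)
    for j, h in enumerate(hap_cols):
        for i, v in enumerate(df[h]):
            v = v.strip()
            if v in ("", "-", "–"):
                counts[i, j] = 0
            else:
                x = float(v)
                if x < 0 or x != int(x):
                    raise DataError(f"bad count {v!r} for {df['site'][i]}/{h}")
                counts[i, j] = int(x)
    if not counts.sum(axis=1).all():
        empty = df["site"][counts.sum(axis=1) == 0].iloc[0]
        raise DataError(f"empty haplotype row for site {empty!r}")
    declared_n = None
    if "n" in meta:
        declared_n = np.array([float(v) if v.strip() not in ("", "-", "–")
                               else np.nan for v in df["n"]])
    declared_div = None
    if "diversity" in meta:
        declared_div = np.array([float(v) if v.strip() not in ("", "-", "–")
                                 else np.nan for v in df["diversity"]])
    included = None
    if "included" in meta:
        included = [s for s, v in zip(df["site"], df["included"])
                    if v.strip() == "1"]
    return HaplotypeCounts(df["site"].tolist(), hap_cols, counts,
                           declared_n, declared_div, included)


def write_haplotype_counts(hc: HaplotypeCounts, path) -> None:
    data: dict[str, list] = {"site": hc.sites}
    if hc.declared_n is not None:
        data["n"] = ["" if np.isnan(v) else str(int(v)) for v in hc.declared_n]
    if hc.declared_diversity is not None:
        data["diversity"] = ["" if np.isnan(v) else f"{v:.3f}"
                             for v in hc.declared_diversity]
    if hc.included_sites is not None:
        data["included"] = ["1" if s in hc.included_sites else "0"
                            for s in hc.sites]
    for j, h in enumerate(hc.haplotypes):
        data[h] = hc.counts[:, j].tolist()
    pd.DataFrame(data).to_csv(path, index=False)


def packaged_table1() -> HaplotypeCounts:
    """The packaged mtDNA haplotype count fixture (study Table-1 layout)."""
    here = Path(__file__).parent / "data" / "table1_haplotypes.csv"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the contact-zone checksum mismatch
        return read_haplotype_counts(here)


# ---------------------------------------------------------------------------
# Raster I/O (ESRI ASCII grid)
# ---------------------------------------------------------------------------

def read_raster_grid(path) -> RasterGrid:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize)."""
    text = Path(path).read_text().split("\n")
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(text):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        _require(key in header, f"ASCII grid header missing {key}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    tokens = " ".join(text[body_start:]).split()
    vals = np.array(tokens, dtype=float)
    _require(vals.size == nrows * ncols,
             f"grid body has {vals.size} values, header says {nrows * ncols}")
    vals = vals.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    mask = vals == nodata
    return RasterGrid(vals, header["cellsize"],
                      (header["xllcorner"], header["yllcorner"]), mask, nodata)


def write_raster_grid(r: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {r.n_cols}\nnrows {r.n_rows}\n")
        fh.write(f"xllcorner {r.origin[0]!r}\nyllcorner {r.origin[1]!r}\n")
        fh.write(f"cellsize {r.cell_size!r}\nNODATA_value {r.nodata_value!r}\n")
        vals = np.where(r.nodata_mask, r.nodata_value, r.values)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Distance matrix I/O
# ---------------------------------------------------------------------------

def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    _require(list(df.index) == list(df.columns), "row/column labels differ")
    return DistanceMatrix([str(l) for l in df.index], df.to_numpy(dtype=float))


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_dataframe().to_csv(path)


def load_dryad_genotypes(path=None) -> GenotypeTable:
    """Load the archived source genotypes (Dryad doi:10.5061/dryad.hj722).

    The deposit is optional and never downloaded by this package; pass the
    path to a local copy converted to the two-column CSV dialect. Per-site
    Ne values, the global theta of the source study, and its K=8 clustering
    are only reproducible with this input.
    """
    if path is None or not Path(path).exists():
        raise FileNotFoundError(
            "Dryad deposit doi:10.5061/dryad.hj722 not available locally; "
            "accession-gated checks are skipped without it")
    return read_genotype_table(path, dialect="two-column")
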