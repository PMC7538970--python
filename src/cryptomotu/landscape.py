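"""Genetic landscape surfaces: divergence between neighbouring sites.

Sites are joined into a Delaunay neighbour network (planar treatment of
lon/lat), the mean between-site K2P divergence is placed at each edge
midpoint, and the midpoint values are interpolated onto a lon/lat raster by
inverse-distance weighting.  High "elevation" marks abrupt genetic
transitions between neighbouring localities; a variant excluding chosen
divergent lineages shows the residual structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .distances import DistanceMatrix
from .errors import CoverageError, GeometryError
from .partition import Partition
from .seqio import HaplotypeTable, SequenceRecord, SiteTable

#: minimum unambiguous sequence length for the landscape analysis (gap-free
#: alignment rule: sequences longer than 496 bp).
DEFAULT_MIN_LEN = 497


@dataclass
class EdgeValue:
    """A Delaunay edge with its midpoint and divergence value."""

    site_a: str
    site_b: str
    midpoint: tuple[float, float]  # (lon, lat)
    value: float


@dataclass
class LandscapeGrid:
    """Interpolated divergence raster over a lon/lat lattice."""

    lons: np.ndarray  # (n_x,)
    lats: np.ndarray  # (n_y,)
    values: np.ndarray  # (n_y, n_x)
    mask: np.ndarray  # True where outside the site convex hull
    power: float = 2.0

    def to_long_form(self):
        import pandas as pd

        rows = []
        for iy, lat in enumerate(self.lats):
            for ix, lon in enumerate(self.lons):
                rows.append(
                    (lon, lat, self.values[iy, ix], bool(self.mask[iy, ix]))
                )
        return pd.DataFrame(rows, columns=["lon", "lat", "value", "masked"])

    def write_asc(self, path) -> None:
        """ESRI ASCII grid; masked cells as nodata."""
        cell = float(self.lons[1] - self.lons[0]) if len(self.lons) > 1 else 1.0
        vals = np.where(self.mask, -9999.0, self.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {len(self.lons)}\n")
            fh.write(f"nrows {len(self.lats)}\n")
            fh.write(f"xllcorner {self.lons[0] - cell / 2:.6f}\n")
            fh.write(f"yllcorner {self.lats[0] - cell / 2:.6f}\n")
            fh.write(f"cellsize {cell:.6f}\n")
            fh.write("NODATA_value -9999\n")
            for row in vals[::-1]:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def delaunay_network(sites: SiteTable) -> list[tuple[str, str]]:
    """Unique undirected edges of the Delaunay triangulation of the sites
    (planar on lon/lat)."""
    ids = sites.site_ids
    if len(ids) < 3:
        raise GeometryError("Delaunay network needs at least 3 sites")
    pts = np.array([[sites.coords(s)[1], sites.coords(s)[0]] for s in ids])
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise GeometryError(f"degenerate site geometry: {exc}") from exc
    edges: set[tuple[str, str]] = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = sorted((ids[simplex[i]], ids[simplex[(i + 1) % 3]]))
            edges.add((a, b))
    return sorted(edges)


def site_haplotype_counts(
    records: Iterable[SequenceRecord],
    haps: HaplotypeTable,
    min_length: int = DEFAULT_MIN_LEN,
) -> dict[str, dict[str, int]]:
    """Per-site haplotype counts, keeping only sequences whose haplotype
    has at least ``min_length`` unambiguous bases."""
    out: dict[str, dict[str, int]] = {}
    for rec in records:
        hid = haps.record_to_haplotype.get(rec.record_id)
        if hid is None or haps.effective_length(hid) < min_length:
            continue
        out.setdefault(rec.site_id, {})
        out[rec.site_id][hid] = out[rec.site_id].get(hid, 0) + 1
    return out


def intersite_divergence(
    a: str,
    b: str,
    counts: dict[str, dict[str, int]],
    m: DistanceMatrix,
    weighting: str = "individual",
) -> float:
    """Mean pairwise K2P over cross-site sequence pairs.

    ``individual`` weighting multiplies each haplotype-pair distance by the
    product of member counts; ``haplotype`` weighting averages over
    distinct haplotype pairs.  Undefined distances are excluded.
    """
    if a not in counts or not counts[a] or b not in counts or not counts[b]:
        raise CoverageError(f"site without usable sequences: {a if a not in counts else b}")
    num = 0.0
    den = 0.0
    for ha, ca in counts[a].items():
        for hb, cb in counts[b].items():
            d = 0.0 if ha == hb else m.get(ha, hb)
            if np.isnan(d):
                continue
            w = float(ca * cb) if weighting == "individual" else 1.0
            num += w * d
            den += w
    return num / den if den > 0 else float("nan")


def edge_values(
    edges: Sequence[tuple[str, str]],
    sites: SiteTable,
    counts: dict[str, dict[str, int]],
    m: DistanceMatrix,
    weighting: str = "individual",
) -> list[EdgeValue]:
    """Divergence at the arithmetic midpoint of every usable network edge."""
    out = []
    for a, b in edges:
        if a not in counts or b not in counts:
            continue
        lat_a, lon_a = sites.coords(a)
        lat_b, lon_b = sites.coords(b)
        v = intersite_divergence(a, b, counts, m, weighting)
        if np.isnan(v):
            continue
        out.append(EdgeValue(a, b, ((lon_a + lon_b) / 2, (lat_a + lat_b) / 2), v))
    return out


def interpolate_surface(
    edges: Sequence[EdgeValue],
    grid: tuple[int, int] = (200, 200),
    power: float = 2.0,
    sites: SiteTable | None = None,
    pad_frac: float = 0.02,
) -> LandscapeGrid:
    """Inverse-distance-weighted surface over the edge midpoints.

    Every unmasked cell is the IDW mean (exponent ``power``) of all
    midpoint values; a cell coinciding with a midpoint takes its value
    exactly.  Cells outside the convex hull of the sites (or, lacking a
    site table, of the midpoints) are masked.  The grid spans the site
    bounding box padded by ``pad_frac``.
    """
    if not edges:
        raise GeometryError("no edge values to interpolate")
    # fixed summation order makes the surface invariant to edge order
    edges = sorted(edges, key=lambda e: (e.midpoint, e.value, e.site_a, e.site_b))
    mids = np.array([e.midpoint for e in edges])  # (n, 2) lon/lat
    vals = np.array([e.value for e in edges])
    if sites is not None:
        hull_pts = np.array(
            [[sites.coords(s)[1], sites.coords(s)[0]] for s in sites.site_ids]
        )
    else:
        hull_pts = mids
    lo = hull_pts.min(axis=0)
    hi = hull_pts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo = lo - pad_frac * span
    hi = hi + pad_frac * span
    nx, ny = grid
    lons = np.linspace(lo[0], hi[0], nx)
    lats = np.linspace(lo[1], hi[1], ny)

    glon, glat = np.meshgrid(lons, lats)
    cells = np.column_stack([glon.ravel(), glat.ravel()])
    # squared distances midpoints x cells
    d2 = ((cells[:, None, :] - mids[None, :, :]) ** 2).sum(axis=2)
    exact = d2 < 1e-18
    with np.errstate(divide="ignore"):
        w = 1.0 / np.power(d2, power / 2.0)
    w[exact.any(axis=1)] = 0.0
    values = (w * vals).sum(axis=1) / np.where(w.sum(axis=1) > 0, w.sum(axis=1), 1.0)
    hit_i, hit_j = np.nonzero(exact)
    values[hit_i] = vals[hit_j]

    if hull_pts.shape[0] >= 3:
        try:
            hull = Delaunay(hull_pts)
            outside = hull.find_simplex(cells) < 0
        except QhullError:
            outside = np.zeros(len(cells), dtype=bool)
    else:
        outside = np.zeros(len(cells), dtype=bool)
    return LandscapeGrid(
        lons, lats, values.reshape(ny, nx), outside.reshape(ny, nx), power
    )


@dataclass
class ExclusionReport:
    records: list[SequenceRecord]
    n_sites: int
    n_haplotypes: int
    empty: bool = field(default=False)


def exclude_lineages(
    records: Iterable[SequenceRecord],
    partition: Partition,
    excluded_motus: Sequence[str],
    haps: HaplotypeTable,
) -> ExclusionReport:
    """Drop records belonging to excluded MOTUs (e.g. divergent endemic
    lineages) and report the remaining site and haplotype counts."""
    known = set(partition.labels.values())
    unknown = set(excluded_motus) - known
    if unknown:
        raise CoverageError(f"unknown MOTU labels: {sorted(unknown)}")
    excluded = set(excluded_motus)
    kept = []
    for rec in records:
        hid = haps.record_to_haplotype.get(rec.record_id)
        label = partition.labels.get(hid if hid in partition.labels else rec.record_id)
        if label is None:
            raise CoverageError(f"record {rec.record_id} has no MOTU label")
        if label not in excluded:
            kept.append(rec)
    sites_left = {r.site_id for r in kept}
    haps_left = {haps.record_to_haplotype[r.record_id] for r in kept}
    return ExclusionReport(kept, len(sites_left), len(haps_left), empty=not kept)
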