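"""MOTU-level summary statistics joining genetics to geography.

Builds the site x MOTU incidence table and derives from it: within-site
syntopy rates (co-occurrence of >= 2 MOTUs), rare-MOTU frequency profiles,
partition concordance and nestedness, geographic range-size classes
(great-circle distances), latitudinal diversity bands and altitudinal
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, EmptyInputError
from .partition import Partition
from .seqio import HaplotypeTable, SequenceRecord, SiteTable

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two WGS84 points."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def incidence(
    records: Iterable[SequenceRecord],
    partition: Partition,
    sites: SiteTable,
    haplotypes: HaplotypeTable | None = None,
) -> pd.DataFrame:
    """Site x MOTU table of individual counts.

    ``partition`` may label record ids directly or haplotype ids (then
    ``haplotypes`` supplies the record -> haplotype mapping).  Counts are
    individuals, not haplotypes.
    """
    rows = []
    unlabelled, unknown_sites = [], []
    for rec in records:
        key = rec.record_id
        if key not in partition.labels and haplotypes is not None:
            key = haplotypes.record_to_haplotype.get(rec.record_id)
        if key not in partition.labels:
            unlabelled.append(rec.record_id)
            continue
        if rec.site_id not in sites:
            unknown_sites.append(rec.record_id)
            continue
        rows.append((rec.site_id, partition.labels[key]))
    if unlabelled:
        raise CoverageError(f"records without MOTU label: {unlabelled[:5]}")
    if unknown_sites:
        raise CoverageError(f"records at unknown sites: {unknown_sites[:5]}")
    if not rows:
        raise EmptyInputError("no records to tabulate")
    df = pd.DataFrame(rows, columns=["site_id", "motu"])
    return df.pivot_table(
        index="site_id", columns="motu", aggfunc="size", fill_value=0
    )


@dataclass
class SyntopyResult:
    n_eligible: int
    pct_multi: float  # % of eligible sites hosting >= 2 MOTUs
    n_sites_3plus: int  # eligible sites hosting >= 3 MOTUs


def syntopy_rates(table: pd.DataFrame, min_individuals: int = 2) -> SyntopyResult:
    """Within-site co-occurrence among sites with enough individuals.

    Eligible sites have >= ``min_individuals`` sampled individuals; the
    headline rate is the percentage of them hosting >= 2 MOTUs.
    """
    totals = table.sum(axis=1)
    eligible = table.loc[totals >= min_individuals]
    if eligible.empty:
        raise EmptyInputError("no site reaches min_individuals; rate undefined")
    n_motus = (eligible > 0).sum(axis=1)
    return SyntopyResult(
        n_eligible=len(eligible),
        pct_multi=float(100.0 * (n_motus >= 2).mean()),
        n_sites_3plus=int((n_motus >= 3).sum()),
    )


def rare_motu_profile(
    table: pd.DataFrame,
    min_individuals: int = 10,
    cutoffs: Sequence[float] = (0.2, 0.1),
) -> dict[float, float]:
    """Percentage of well-sampled multi-MOTU sites whose least-frequent
    MOTU has relative frequency <= cutoff.

    Eligible sites have more than ``min_individuals`` individuals and at
    least two MOTUs (a monomorphic site has no rare MOTU).
    """
    totals = table.sum(axis=1)
    eligible = table.loc[(totals > min_individuals) & ((table > 0).sum(axis=1) >= 2)]
    out: dict[float, float] = {}
    if eligible.empty:
        return {c: float("nan") for c in cutoffs}
    min_freq = eligible.where(eligible > 0).min(axis=1) / eligible.sum(axis=1)
    for c in cutoffs:
        out[c] = float(100.0 * (min_freq <= c).mean())
    return out


@dataclass
class NestednessResult:
    fine_per_coarse: dict[str, int]  # coarse label -> distinct fine MOTUs
    violations: list[str] = field(default_factory=list)  # straddling fine MOTUs

    @property
    def max_count(self) -> int:
        return max(self.fine_per_coarse.values(), default=0)

    @property
    def min_count(self) -> int:
        return min(self.fine_per_coarse.values(), default=0)


def nestedness(fine: Partition, coarse: Partition) -> NestednessResult:
    """How many fine MOTUs each coarse MOTU contains, plus violations
    (fine MOTUs straddling two coarse MOTUs)."""
    if set(fine.labels) != set(coarse.labels):
        raise CoverageError("partitions cover different id universes")
    counts: dict[str, set[str]] = {}
    for hid, lab in coarse.labels.items():
        counts.setdefault(lab, set()).add(fine.labels[hid])
    violations = []
    for fset in fine.as_sets():
        coarse_labels = {coarse.labels[h] for h in fset}
        if len(coarse_labels) > 1:
            violations.append(fine.labels[next(iter(fset))])
    return NestednessResult({k: len(v) for k, v in counts.items()}, sorted(violations))


def concordance_count(partitions: Sequence[Partition]) -> int:
    """Number of MOTUs identical (as id sets) across all partitions."""
    if len(partitions) < 2:
        raise ValueError("need at least two partitions")
    common = set(partitions[0].as_sets())
    for p in partitions[1:]:
        common &= set(p.as_sets())
    return len(common)


@dataclass
class RangeClass:
    motu: str
    max_km: float
    category: str  # narrow (<100 km), broad (100-1000 km), widespread (>1000 km)


def range_classes(table: pd.DataFrame, sites: SiteTable) -> dict[str, RangeClass]:
    """Classify each MOTU by the maximum great-circle distance among its
    occupied sites: narrow < 100 km, broad 100-1000 km, widespread > 1000 km."""
    out: dict[str, RangeClass] = {}
    for motu in table.columns:
        occupied = table.index[table[motu] > 0]
        missing = [s for s in occupied if s not in sites]
        if missing:
            raise CoverageError(f"sites without coordinates: {missing[:5]}")
        coords = [sites.coords(s) for s in occupied]
        dmax = 0.0
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                dmax = max(dmax, haversine_km(*coords[i], *coords[j]))
        if dmax < 100:
            cat = "narrow"
        elif dmax <= 1000:
            cat = "broad"
        else:
            cat = "widespread"
        out[motu] = RangeClass(motu, dmax, cat)
    return out


def latitudinal_bins(
    table: pd.DataFrame, sites: SiteTable, band_width: float = 0.5
) -> pd.Series:
    """MOTU count per half-open latitude band [k*w, (k+1)*w).

    A MOTU counts once per band in which it occupies at least one site.
    """
    pairs: set[tuple[float, str]] = set()
    for motu in table.columns:
        for s in table.index[table[motu] > 0]:
            lat, _ = sites.coords(s)
            band = np.floor(lat / band_width) * band_width
            pairs.add((round(float(band), 6), motu))
    counts: dict[float, int] = {}
    for band, _ in pairs:
        counts[band] = counts.get(band, 0) + 1
    return pd.Series(counts, name="n_motus").sort_index()


def altitudinal_summary(
    table: pd.DataFrame, sites: SiteTable, min_sites: int = 3, bin_m: float = 100.0
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-MOTU altitude box stats and a pooled occurrence histogram.

    Box stats (min, Q1, mean, Q3, max over occupied-site altitudes) are
    reported for MOTUs present at >= ``min_sites`` sites; the pooled
    histogram counts MOTU x site occurrences per 100 m altitude band.
    """
    stats_rows = []
    band_counts: dict[float, int] = {}
    for motu in table.columns:
        occupied = list(table.index[table[motu] > 0])
        alts = np.array([sites.altitude(s) for s in occupied])
        for a in alts:
            band = float(np.floor(a / bin_m) * bin_m)
            band_counts[band] = band_counts.get(band, 0) + 1
        if len(occupied) >= min_sites:
            stats_rows.append(
                {
                    "motu": motu,
                    "n_sites": len(occupied),
                    "alt_min": float(alts.min()),
                    "alt_q1": float(np.percentile(alts, 25)),
                    "alt_mean": float(alts.mean()),
                    "alt_q3": float(np.percentile(alts, 75)),
                    "alt_max": float(alts.max()),
                }
            )
    stats = pd.DataFrame(
        stats_rows,
        columns=["motu", "n_sites", "alt_min", "alt_q1", "alt_mean", "alt_q3", "alt_max"],
    )
    hist = pd.Series(band_counts, name="n_occurrences").sort_index()
    return stats, hist
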