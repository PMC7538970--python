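"""BIN-style MOTU clustering (RESL-like single linkage with refinement).

The procedure mirrors how barcode index clusters are formed: (1) initial
single-linkage clustering of full-length sequences at a 2.2% distance
ceiling, with clusters closer than the 4.4% isolation floor merged back
when the merged set shows no internal discontinuity; (2) refinement, where
a cluster whose internal variation shows a clear partition is split into
two or more MOTUs even below 2.2%; (3) short sequences (300–500 bp) are
ascribed to the nearest existing cluster, or — when too divergent — kept
as flagged "BIN-equivalent" singleton MOTUs.

Discontinuity is measured by the mean silhouette of a candidate
bipartition, candidates being the subtree-vs-rest cuts of the cluster's
single-linkage dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage

from .distances import DistanceMatrix, k2p
from .errors import ConfigError, DelimitationError
from .partition import Partition, relabel_canonical
from .delimit_abgd import _components
from .seqio import HaplotypeTable, SequenceRecord


@dataclass
class ReslConfig:
    """Thresholds for BIN-style clustering.

    ``t_intra`` is the initial linkage ceiling (0.022), ``t_isolation`` the
    isolation floor (0.044 — twice the ceiling); clusters closer than it are
    merge candidates.  Sequences need >= ``len_full`` unambiguous bases to
    found a cluster and >= ``len_assign`` to be ascribed to one.
    ``silhouette_min`` is the mean-silhouette level at which an internal
    discontinuity counts as real.
    """

    t_intra: float = 0.022
    t_isolation: float = 0.044
    len_full: int = 500
    len_assign: int = 300
    silhouette_min: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.t_intra < self.t_isolation):
            raise ConfigError("need 0 < t_intra < t_isolation")
        if not (self.len_assign < self.len_full):
            raise ConfigError("need len_assign < len_full")


def mean_silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width for a 2-group labeling on a distance matrix.

    NaN (undefined) distances are ignored via nan-aware means; singleton
    groups contribute silhouette 0 for their lone member.
    """
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = (labels == labels[i]) & (np.arange(n) != i)
        other = labels != labels[i]
        if not own.any():
            s[i] = 0.0
            continue
        with np.errstate(invalid="ignore"):
            a = np.nanmean(d[i, own])
            b = np.nanmean(d[i, other])
        if np.isnan(a) or np.isnan(b):
            s[i] = 0.0
            continue
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(np.mean(s))


def _dendrogram_bipartitions(d: np.ndarray) -> list[np.ndarray]:
    """Candidate bipartitions of a cluster: each subtree of its
    single-linkage dendrogram against the rest (boolean masks)."""
    n = d.shape[0]
    if n < 2:
        return []
    if n == 2:
        return [np.array([True, False])]
    iu, ju = np.triu_indices(n, k=1)
    condensed = d[iu, ju].copy()
    fill = np.nanmax(condensed) if np.isfinite(condensed).any() else 1.0
    condensed[np.isnan(condensed)] = fill * 2 + 1.0
    Z = linkage(condensed, method="single")
    members: list[set[int]] = [{i} for i in range(n)]
    for a, b, _, _ in Z:
        members.append(members[int(a)] | members[int(b)])
    cuts: list[np.ndarray] = []
    seen: set[frozenset[int]] = set()
    for mset in members[:-1]:  # exclude the root (trivial bipartition)
        key = frozenset(mset)
        comp = frozenset(range(n)) - key
        if key in seen or comp in seen or not comp:
            continue
        seen.add(key)
        mask = np.zeros(n, dtype=bool)
        mask[list(mset)] = True
        cuts.append(mask)
    return cuts


def _best_split(d: np.ndarray, silhouette_min: float) -> np.ndarray | None:
    """The dendrogram cut maximizing mean silhouette, if it reaches the
    threshold; ties break toward the first (deterministic) candidate."""
    best_mask, best_s = None, -np.inf
    for mask in _dendrogram_bipartitions(d):
        s = mean_silhouette(d, mask.astype(int))
        if s > best_s:
            best_mask, best_s = mask, s
    if best_mask is not None and best_s >= silhouette_min:
        return best_mask
    return None


def initial_clusters(m: DistanceMatrix, cfg: ReslConfig | None = None) -> Partition:
    """Single-linkage components at ``t_intra``, then isolation-rule merging.

    Cluster pairs whose minimum between-cluster distance is <= ``t_isolation``
    are merged iff the merged set shows no internal discontinuity (no
    dendrogram bipartition reaching ``silhouette_min``).  Merging repeats to
    a fixed point, closest pairs first.
    """
    cfg = cfg or ReslConfig()
    if len(m) == 0:
        raise DelimitationError("no full-length haplotypes to cluster")
    labels = _components(m.d, cfg.t_intra)
    clusters: list[list[int]] = [
        list(np.flatnonzero(labels == g)) for g in np.unique(labels)
    ]
    merged = True
    while merged and len(clusters) > 1:
        merged = False
        # candidate pairs by ascending min between-cluster distance
        cand: list[tuple[float, int, int]] = []
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                block = m.d[np.ix_(clusters[i], clusters[j])]
                if np.isnan(block).all():
                    continue
                dmin = float(np.nanmin(block))
                if dmin <= cfg.t_isolation:
                    cand.append((dmin, i, j))
        for dmin, i, j in sorted(cand):
            union = sorted(clusters[i] + clusters[j])
            sub = m.d[np.ix_(union, union)]
            if _best_split(sub, cfg.silhouette_min) is None:
                clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
                clusters.append(union)
                merged = True
                break
    out = {}
    for g, members in enumerate(sorted(clusters)):
        for i in members:
            out[m.ids[i]] = f"C{g}"
    return Partition("RESL", relabel_canonical(out, "BIN"), {"stage": "initial"})


def refine_clusters(
    p: Partition, m: DistanceMatrix, cfg: ReslConfig | None = None
) -> Partition:
    """Split clusters showing a clear internal partition, recursively.

    Within each cluster the dendrogram cut maximizing mean silhouette is
    applied whenever it reaches ``silhouette_min`` — even if the two parts
    are separated by less than ``t_intra``.
    """
    cfg = cfg or ReslConfig()
    idx = {h: i for i, h in enumerate(m.ids)}
    final: list[list[str]] = []

    def recurse(ids: list[str]) -> None:
        if len(ids) < 2:
            final.append(ids)
            return
        sub = m.d[np.ix_([idx[h] for h in ids], [idx[h] for h in ids])]
        mask = _best_split(sub, cfg.silhouette_min)
        if mask is None:
            final.append(ids)
            return
        part_a = [h for h, keep in zip(ids, mask) if keep]
        part_b = [h for h, keep in zip(ids, mask) if not keep]
        recurse(part_a)
        recurse(part_b)

    for group in sorted(p.as_sets(), key=lambda s: sorted(s)[0]):
        recurse(sorted(group))
    labels = {h: f"R{g}" for g, ids in enumerate(final) for h in ids}
    return Partition(
        "RESL", relabel_canonical(labels, "BIN"), {"stage": "refined"}
    )


@dataclass
class ShortAssignment:
    """Outcome of placing short sequences against final clusters."""

    partition: Partition
    bin_equivalent: list[str] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)


def assign_short_sequences(
    short: list[SequenceRecord],
    p: Partition,
    haps: HaplotypeTable,
    cfg: ReslConfig | None = None,
) -> ShortAssignment:
    """Ascribe 300–500 bp sequences to their nearest cluster.

    A short sequence joins the cluster of its nearest full-length haplotype
    when that K2P distance is <= ``t_intra``; otherwise it becomes a flagged
    BIN-equivalent singleton MOTU.  Sequences with fewer than ``len_assign``
    unambiguous bases are rejected.
    """
    cfg = cfg or ReslConfig()
    labels = dict(p.labels)
    bin_equiv: list[str] = []
    rejected: list[str] = []
    full_ids = list(p.labels)
    n_extra = 0
    for rec in short:
        if rec.effective_length < cfg.len_assign:
            rejected.append(rec.record_id)
            continue
        best_hap, best_d = None, np.inf
        for h in full_ids:
            d = k2p(rec.sequence, haps.sequence(h), min_overlap=cfg.len_assign)
            if not np.isnan(d) and d < best_d:
                best_hap, best_d = h, d
        if best_hap is not None and best_d <= cfg.t_intra:
            labels[rec.record_id] = p.labels[best_hap]
        else:
            n_extra += 1
            lab = f"BINEQ{n_extra:03d}"
            labels[rec.record_id] = lab
            bin_equiv.append(rec.record_id)
    out = Partition(
        "RESL",
        labels,
        {"stage": "with_short", "bin_equivalent": list(bin_equiv)},
    )
    return ShortAssignment(out, bin_equiv, rejected)


def resl_delimit(
    haps: HaplotypeTable,
    m: DistanceMatrix,
    cfg: ReslConfig | None = None,
    short_records: list[SequenceRecord] | None = None,
) -> ShortAssignment:
    """Full BIN-style pipeline over a haplotype table.

    Haplotypes with >= ``len_full`` unambiguous bases found clusters; the
    caller may pass additional short records for the assignment stage.
    """
    cfg = cfg or ReslConfig()
    full = [h for h in haps.ids() if haps.effective_length(h) >= cfg.len_full]
    if not full:
        raise DelimitationError("no haplotype reaches len_full")
    sub = m.submatrix(full)
    refined = refine_clusters(initial_clusters(sub, cfg), sub, cfg)
    return assign_short_sequences(short_records or [], refined, haps, cfg)
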