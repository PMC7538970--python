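"""Barcode-gap discovery and recursive partitioning (ABGD-style MOTUs).

Distance-based delimitation splits a group wherever the sorted pairwise
distances show a *barcode gap*: a discontinuity separating putative
intraspecific from interspecific divergence.  Starting from a prior maximum
intraspecific distance ``p``, the widest qualifying gap above ``p`` sets a
clustering threshold, groups are cut into single-linkage components at that
threshold, and the procedure recurses inside each component until no group
shows a gap.  Running this over a ladder of priors and keeping the partition
stable over the longest run of priors yields the *primary* partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .errors import ConfigError, DelimitationError
from .partition import Partition, relabel_canonical


@dataclass
class AbgdConfig:
    """Prior ladder and gap-width rule for barcode-gap discovery.

    ``p_min``/``p_max`` bound the prior maximum intraspecific distance
    (defaults 0.001 and 0.1); ``n_steps`` priors are log-spaced between
    them.  ``gap_factor`` (X) sets how much wider than the local baseline
    increment a distance interval must be to count as a gap.
    """

    p_min: float = 0.001
    p_max: float = 0.1
    n_steps: int = 10
    gap_factor: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.p_min < self.p_max < 1):
            raise ConfigError(f"need 0 < p_min < p_max < 1, got {self.p_min}, {self.p_max}")
        if self.n_steps < 1:
            raise ConfigError("n_steps must be >= 1")
        if self.gap_factor <= 0:
            raise ConfigError("gap_factor must be > 0")

    def priors(self) -> np.ndarray:
        return np.geomspace(self.p_min, self.p_max, self.n_steps)


def find_barcode_gap(
    distances: np.ndarray | list[float], prior_p: float, X: float = 1.5
) -> float | None:
    """Find the threshold below the widest significant gap above ``prior_p``.

    The defined pairwise distances are sorted ascending.  The baseline
    increment ``b`` is the 95th percentile of consecutive differences among
    distances <= ``prior_p`` (0 if there are none).  A candidate gap is an
    interval ``(d_i, d_{i+1})`` ending above the prior (``d_{i+1} >
    prior_p``) with at least two distances below it (a gap needs a
    populated intraspecific cluster underneath).  It qualifies when its
    width exceeds ``X * max(b, prior_p / 10, d_i)`` — the *relative* gap
    criterion: a barcode gap must dwarf both the spacing noise below the
    prior and the whole intraspecific distance level ``d_i`` under the gap.
    The widest qualifying interval wins; ties break toward the smaller
    threshold.  Returns ``d_i``, or None when no interval qualifies.
    """
    d = np.sort(np.asarray([v for v in np.ravel(distances) if np.isfinite(v)]))
    if d.size < 2:
        return None
    diffs = np.diff(d)
    below = d[d <= prior_p]
    b = float(np.percentile(np.diff(below), 95)) if below.size >= 2 else 0.0
    best: tuple[float, float] | None = None  # (width, threshold)
    for i in range(1, d.size - 1):  # i >= 1: two distances below the gap
        if d[i + 1] <= prior_p:
            continue
        w = diffs[i]
        if w <= X * max(b, prior_p / 10.0, d[i]):
            continue
        if best is None or w > best[0]:
            best = (float(w), float(d[i]))
    return None if best is None else best[1]


def partition_at_threshold(m: DistanceMatrix, t: float) -> Partition:
    """Single-linkage clustering: MOTUs are connected components of the
    graph with an edge wherever ``d <= t``; undefined pairs contribute no
    edge."""
    if t < 0:
        raise ValueError("threshold must be >= 0")
    labels = _components(m.d, t)
    named = {m.ids[i]: f"C{labels[i]}" for i in range(len(m.ids))}
    return Partition("ABGD", relabel_canonical(named, "MOTU"), {"threshold": t})


def _components(d: np.ndarray, t: float) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        adj = (d <= t) & ~np.isnan(d)
    np.fill_diagonal(adj, True)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    return labels


def _recursive_partition(
    m: DistanceMatrix, idx: np.ndarray, prior: float, X: float, out: list[np.ndarray]
) -> None:
    """Split the group ``idx`` at its barcode gap, recursing into parts."""
    sub = m.d[np.ix_(idx, idx)]
    iu, ju = np.triu_indices(len(idx), k=1)
    vals = sub[iu, ju]
    vals = vals[~np.isnan(vals)]
    t = find_barcode_gap(vals, prior, X) if vals.size else None
    if t is None:
        out.append(idx)
        return
    labels = _components(sub, t)
    groups = [idx[labels == g] for g in np.unique(labels)]
    if len(groups) == 1:
        out.append(idx)
        return
    for g in groups:
        _recursive_partition(m, g, prior, X, out)


def abgd_at_prior(m: DistanceMatrix, prior: float, X: float = 1.5) -> Partition:
    """One full recursive ABGD partition at a single prior."""
    groups: list[np.ndarray] = []
    _recursive_partition(m, np.arange(len(m.ids)), prior, X, groups)
    labels = {}
    for g_num, g in enumerate(groups):
        for i in g:
            labels[m.ids[i]] = f"G{g_num}"
    return Partition(
        "ABGD", relabel_canonical(labels, "MOTU"), {"prior": prior, "gap_factor": X}
    )


@dataclass
class AbgdResult:
    """Per-prior partitions plus the primary (most stable) partition."""

    priors: list[float]
    partitions: list[Partition]
    primary: Partition
    primary_run: tuple[int, int] = field(default=(0, 0))  # half-open index range


def abgd_primary(m: DistanceMatrix, cfg: AbgdConfig | None = None) -> AbgdResult:
    """Run the prior ladder and report the primary partition.

    The primary partition is the grouping observed over the longest
    contiguous run of priors; ties break toward the run with larger priors.
    """
    cfg = cfg or AbgdConfig()
    if m.upper_values().size == 0:
        raise DelimitationError("all pairwise distances are undefined")
    priors = list(cfg.priors())
    parts = [abgd_at_prior(m, p, cfg.gap_factor) for p in priors]
    groupings = [frozenset(p.as_sets()) for p in parts]
    # longest contiguous run of identical groupings; ties -> larger priors
    best_start, best_len = 0, 1
    start = 0
    for i in range(1, len(parts) + 1):
        if i == len(parts) or groupings[i] != groupings[start]:
            run = i - start
            if run >= best_len:  # >= keeps the later (larger-prior) run on ties
                best_start, best_len = start, run
            start = i
    primary = parts[best_start]
    primary.provenance["primary_run_priors"] = (
        priors[best_start],
        priors[best_start + best_len - 1],
    )
    return AbgdResult(priors, parts, primary, (best_start, best_start + best_len))
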