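"""Chronogram utilities and the Lagrue sister-clade MOTU rule.

A strict molecular clock converts an ultrametric tree in
substitutions/site into a chronogram in My (COI default rate: 0.0115
substitutions/site/My).  Lineage-through-time (LTT) curves summarize the
tempo of diversification.  The Lagrue rule delimits MOTUs by reproductive
isolation calibration: sister clades diverging by more than a K2P cutoff
(default 0.20) are distinct MOTUs, those below it merge.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .errors import ClockError, ConfigError, CoverageError
from .partition import Partition, relabel_canonical


@dataclass
class ClockConfig:
    """Strict-clock rate in substitutions/site/My (arthropod COI default)."""

    rate: float = 0.0115

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ConfigError("clock rate must be > 0")


@dataclass
class LagrueConfig:
    """Sister-clade divergence cutoff and between-clade linkage.

    The cutoff (default 0.20 K2P) is calibrated against mate-choice
    experiments: pairs around 0.04 mate randomly, pairs around 0.16
    discriminate.  ``linkage`` chooses how the between-clade distance is
    summarized over defined haplotype pairs ("mean" or "min").
    """

    cutoff: float = 0.20
    linkage: str = "mean"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be > 0")
        if self.linkage not in ("mean", "min"):
            raise ConfigError("linkage must be 'mean' or 'min'")


@dataclass
class Chronogram:
    """Rooted ultrametric tree with branch lengths in My."""

    tree: dendropy.Tree
    root_age: float


def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[str, float] = {}
    stack = [(tree.seed_node, 0.0)]
    while stack:
        nd, depth = stack.pop()
        if nd.is_leaf():
            depths[nd.taxon.label] = depth
        for child in nd.child_nodes():
            stack.append((child, depth + (child.edge.length or 0.0)))
    return depths


def rescale_to_time(
    tree: dendropy.Tree, cfg: ClockConfig | None = None, tolerance: float = 1e-6
) -> Chronogram:
    """Divide every branch length by the clock rate, giving ages in My.

    The input must be ultrametric: root-to-tip path lengths equal within
    ``tolerance`` (relative to the maximum depth).
    """
    cfg = cfg or ClockConfig()
    depths = _tip_depths(tree)
    dmax = max(depths.values())
    if dmax > 0 and (dmax - min(depths.values())) > tolerance * dmax:
        raise ClockError(
            f"tree is not ultrametric (tip depth spread "
            f"{dmax - min(depths.values()):.3g}); increase `tolerance` if the "
            "spread is numerical noise"
        )
    out = copy.deepcopy(tree)
    for nd in out.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length = nd.edge.length / cfg.rate
    return Chronogram(out, root_age=dmax / cfg.rate)


def ltt(chron: Chronogram) -> list[tuple[float, int]]:
    """Lineage-through-time series: (time before present in My, count).

    One event per internal node; the count starts at 2 just after the root
    and reaches the tip count at the most recent internal node.  The series
    is non-decreasing toward the present.
    """
    ages: list[float] = []
    stack = [(chron.tree.seed_node, 0.0)]
    while stack:
        nd, depth = stack.pop()
        if not nd.is_leaf():
            ages.append(chron.root_age - depth)
        for child in nd.child_nodes():
            stack.append((child, depth + (child.edge.length or 0.0)))
    series: list[tuple[float, int]] = []
    count = 1
    for age in sorted(ages, reverse=True):
        count += 1
        series.append((float(age), count))
    return series


def sister_pairs(tree: dendropy.Tree) -> list[tuple[frozenset[str], frozenset[str]]]:
    """For every internal node, the tip sets of its two child clades."""
    pairs = []
    for nd in tree.preorder_node_iter():
        children = nd.child_nodes()
        if len(children) < 2:
            continue
        tip_sets = [
            frozenset(leaf.taxon.label for leaf in c.leaf_iter()) for c in children
        ]
        # a polytomy contributes the pairs of its first two children only if
        # binary; report all unordered pairs to stay total
        for i in range(len(tip_sets)):
            for j in range(i + 1, len(tip_sets)):
                pairs.append((tip_sets[i], tip_sets[j]))
    return pairs


def _between(m: DistanceMatrix, a: frozenset[str], b: frozenset[str], linkage: str) -> float:
    vals = m.between(sorted(a), sorted(b))
    if vals.size == 0:
        return float("nan")
    return float(np.mean(vals)) if linkage == "mean" else float(np.min(vals))


def count_divergent_sisters(
    tree: dendropy.Tree, m: DistanceMatrix, cfg: LagrueConfig | None = None
) -> int:
    """Number of sister-clade pairs whose between-clade distance exceeds
    the cutoff."""
    cfg = cfg or LagrueConfig()
    n = 0
    for a, b in sister_pairs(tree):
        d = _between(m, a, b, cfg.linkage)
        if not np.isnan(d) and d > cfg.cutoff:
            n += 1
    return n


def lagrue_motus(
    tree: dendropy.Tree | Chronogram,
    m: DistanceMatrix,
    cfg: LagrueConfig | None = None,
) -> Partition:
    """Delimit MOTUs by post-order sister-clade agglomeration.

    Each tip starts as its own group.  At an internal node whose two child
    clades are each currently a single group, the groups merge iff their
    between-group K2P distance is <= cutoff.  Once a child is multi-group,
    no merge happens above it, so every MOTU is a clade of the input tree.
    """
    cfg = cfg or LagrueConfig()
    if isinstance(tree, Chronogram):
        tree = tree.tree
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = set(tips) - set(m.ids)
    if missing:
        raise CoverageError(f"tree tips absent from matrix: {sorted(missing)[:5]}")
    group_of: dict[str, int] = {t: i for i, t in enumerate(tips)}
    group_size: dict[int, int] = {i: 1 for i in range(len(tips))}

    def clade_group(tip_set: frozenset[str]) -> int | None:
        gids = {group_of[t] for t in tip_set}
        if len(gids) != 1:
            return None
        g = gids.pop()
        return g if group_size[g] == len(tip_set) else None

    for nd in tree.postorder_node_iter():
        children = nd.child_nodes()
        if len(children) != 2:
            continue
        a = frozenset(leaf.taxon.label for leaf in children[0].leaf_iter())
        b = frozenset(leaf.taxon.label for leaf in children[1].leaf_iter())
        ga, gb = clade_group(a), clade_group(b)
        if ga is None or gb is None or ga == gb:
            continue
        d = _between(m, a, b, cfg.linkage)
        if np.isnan(d) or d > cfg.cutoff:
            continue
        for t in b:
            group_of[t] = ga
        group_size[ga] += group_size.pop(gb)
    labels = {t: f"L{group_of[t]}" for t in tips}
    return Partition(
        "LAGRUE",
        relabel_canonical(labels, "MOTU"),
        {"cutoff": cfg.cutoff, "linkage": cfg.linkage},
    )


def write_ltt(series: list[tuple[float, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("time_my\tn_lineages\n")
        for t, n in series:
            fh.write(f"{t:.6f}\t{n}\n")
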