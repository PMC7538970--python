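"""Poisson tree processes (PTP) delimitation on a non-ultrametric tree.

Branch lengths of the input tree (in substitutions/site) are modeled as
draws from two independent exponential classes: *speciation* branches
(between species) and *coalescent* branches (within species).  A
delimitation is an antichain of *crown nodes* covering all tips; edges
strictly inside a crown subtree belong to the within-species class, all
other edges (including the crown nodes' own edges and the root edge) to
the speciation class.  With ``n`` edges of total length ``L`` in a class,
the plugged-in MLE rate is ``lambda = n / L`` and the class log-likelihood
is ``n ln(lambda) - lambda L = n ln(n/L) - n``.

The ML search is greedy from the one-species delimitation; an optional
Metropolis-Hastings sampler provides posterior support per crown subtree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .errors import ConfigError, DegenerateBranchError, TreeShapeError
from .partition import Partition, relabel_canonical


@dataclass
class McmcConfig:
    """Sampler settings: iteration count, burn-in fraction, seed, runs."""

    iterations: int = 500_000
    burn_in: float = 0.10
    seed: int = 0
    n_runs: int = 3

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ConfigError("iterations must be > 0")
        if not (0 <= self.burn_in < 1):
            raise ConfigError("burn_in must be in [0, 1)")


@dataclass
class PtpDelimitation:
    """A delimitation: crown nodes, fitted rates and log-likelihood."""

    crown_nodes: list[dendropy.Node]
    lambda_spec: float
    lambda_coal: float
    loglik: float
    support: dict[frozenset[str], float] | None = None

    def tip_sets(self) -> list[frozenset[str]]:
        return [crown_tip_set(nd) for nd in self.crown_nodes]

    def to_partition(self) -> Partition:
        labels = {}
        for k, tips in enumerate(self.tip_sets()):
            for t in sorted(tips):
                labels[t] = f"P{k}"
        return Partition(
            "PTP", relabel_canonical(labels, "MOTU"), {"loglik": self.loglik}
        )

    @property
    def n_motus(self) -> int:
        return len(self.crown_nodes)


def crown_tip_set(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def _edges(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Nodes carrying an edge: all non-root nodes, plus the root when its
    edge has a positive length (root edge -> speciation class)."""
    out = [nd for nd in tree.preorder_node_iter() if nd.parent_node is not None]
    root = tree.seed_node
    if root.edge.length:
        out.append(root)
    return out


def _check_crown(tree: dendropy.Tree, crown_nodes) -> None:
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    covered: set[str] = set()
    for nd in crown_nodes:
        sub = crown_tip_set(nd)
        if covered & sub:
            raise ValueError("crown nodes are nested or overlapping")
        covered |= sub
    if covered != tips:
        raise ValueError("crown nodes do not cover all tips")


#: branches shorter than this (substitutions/site) are below the
#: resolution of trees estimated from barcode-length alignments and are
#: excluded from the likelihood, preventing a degenerate rate class of
#: near-zero branches from dominating the fit.
DEFAULT_MIN_BRANCH = 1e-4


def ptp_loglik(
    tree: dendropy.Tree, crown_nodes, validate: bool = True,
    min_branch: float = DEFAULT_MIN_BRANCH,
) -> tuple[float, float, float]:
    """Log-likelihood and MLE rates for a delimitation.

    Returns ``(loglik, lambda_spec, lambda_coal)``; an empty class
    contributes 0 to the likelihood and rate 0.  Branches shorter than
    ``min_branch`` are excluded from both classes.
    """
    if validate:
        _check_crown(tree, crown_nodes)
    crown = set(id(nd) for nd in crown_nodes)
    within_ids: set[int] = set()
    for nd in crown_nodes:
        for desc in nd.preorder_iter():
            if desc is not nd:
                within_ids.add(id(desc))
    n_w = n_s = 0
    L_w = L_s = 0.0
    for nd in _edges(tree):
        length = nd.edge.length or 0.0
        if length < 0:
            raise TreeShapeError("negative branch length")
        if length < min_branch:
            continue
        if id(nd) in within_ids:
            n_w += 1
            L_w += length
        else:
            n_s += 1
            L_s += length
    del crown

    def class_ll(n: int, L: float) -> tuple[float, float]:
        if n == 0:
            return 0.0, 0.0
        if L <= 0:
            raise DegenerateBranchError(f"class with {n} edges has zero total length")
        lam = n / L
        return n * np.log(lam) - lam * L, lam

    ll_s, lam_s = class_ll(n_s, L_s)
    ll_w, lam_w = class_ll(n_w, L_w)
    return float(ll_s + ll_w), lam_s, lam_w


def _require_binary(tree: dendropy.Tree, auto_resolve: bool) -> dendropy.Tree:
    for nd in tree.preorder_node_iter():
        if len(nd.child_nodes()) > 2:
            if auto_resolve:
                tree.resolve_polytomies(limit=2, update_bipartitions=False)
                for n2 in tree.preorder_node_iter():
                    if n2.parent_node is not None and n2.edge.length is None:
                        n2.edge.length = 0.0
                return tree
            raise TreeShapeError("tree has a polytomy; pass auto_resolve=True")
    return tree


def _dp_optimal_crowns(
    tree: dendropy.Tree, lam_s: float, lam_c: float, min_branch: float
) -> list[dendropy.Node]:
    """Exact optimal delimitation for *fixed* class rates, by tree DP.

    For fixed rates the per-edge cost is ``ln(lambda) - lambda * len`` for
    its class, and the best antichain decomposes over subtrees: a free node
    is either a crown node (its whole subtree joins the within class) or
    lies above the crowns (children are free in turn).
    """

    def cost(length: float, lam: float) -> float:
        if length < min_branch:
            return 0.0
        return float(np.log(lam) - lam * length)

    score: dict[int, float] = {}
    within_sum: dict[int, float] = {}
    choice: dict[int, bool] = {}  # True -> crown here
    for nd in tree.postorder_node_iter():
        w = 0.0
        for child in nd.child_nodes():
            w += within_sum[id(child)] + cost(child.edge.length or 0.0, lam_c)
        within_sum[id(nd)] = w
        if nd.is_leaf():
            score[id(nd)] = 0.0
            choice[id(nd)] = True
            continue
        free = sum(
            score[id(c)] + cost(c.edge.length or 0.0, lam_s)
            for c in nd.child_nodes()
        )
        choice[id(nd)] = w >= free
        score[id(nd)] = max(w, free)
    crowns: list[dendropy.Node] = []
    stack = [tree.seed_node]
    while stack:
        nd = stack.pop()
        if choice[id(nd)]:
            crowns.append(nd)
        else:
            stack.extend(nd.child_nodes())
    return crowns


def _rate_inits(tree: dendropy.Tree, min_branch: float) -> list[tuple[float, float]]:
    lens = np.array(
        [
            nd.edge.length or 0.0
            for nd in _edges(tree)
            if (nd.edge.length or 0.0) >= min_branch
        ]
    )
    inits = []
    for q in (25, 50, 75, 90):
        cut = np.percentile(lens, q)
        lo = lens[lens <= cut]
        hi = lens[lens > cut]
        if lo.size == 0 or hi.size == 0 or lo.mean() <= 0:
            continue
        inits.append((1.0 / hi.mean(), 1.0 / lo.mean()))
    if not inits:
        lam = 1.0 / lens.mean() if lens.size and lens.mean() > 0 else 1.0
        inits.append((lam, lam * 10))
    return inits


def _alternate(
    tree: dendropy.Tree, lam_s: float, lam_c: float, min_branch: float,
    max_iter: int = 50,
) -> tuple[list[dendropy.Node], float, float, float]:
    """Coordinate ascent: optimal delimitation for current rates (tree DP),
    then MLE rates for the delimitation, until the delimitation is stable."""
    prev_key = None
    crowns = [tree.seed_node]
    ll, ls, lc = ptp_loglik(tree, crowns, validate=False, min_branch=min_branch)
    for _ in range(max_iter):
        crowns = _dp_optimal_crowns(tree, lam_s, lam_c, min_branch)
        key = frozenset(id(nd) for nd in crowns)
        ll, ls, lc = ptp_loglik(tree, crowns, validate=False, min_branch=min_branch)
        if key == prev_key:
            break
        prev_key = key
        lam_s = ls if ls > 0 else lam_s
        lam_c = lc if lc > 0 else lam_c
    return crowns, ll, ls, lc


#: exact enumeration is used when the tree admits at most this many
#: delimitations; beyond it the search falls back to hill climbing.
EXACT_SEARCH_LIMIT = 50_000


def _count_delimitations(node: dendropy.Node, limit: int) -> int:
    """Number of antichain covers of the subtree, capped at ``limit``."""
    if node.is_leaf():
        return 1
    total = 1
    for child in node.child_nodes():
        total *= _count_delimitations(child, limit)
        if total >= limit:
            return limit
    return min(total + 1, limit)


def _enumerate_delimitations(node: dendropy.Node):
    if node.is_leaf():
        yield [node]
        return
    yield [node]
    import itertools

    parts = [list(_enumerate_delimitations(c)) for c in node.child_nodes()]
    for combo in itertools.product(*parts):
        yield [nd for sub in combo for nd in sub]


def ptp_ml(
    tree: dendropy.Tree,
    auto_resolve: bool = False,
    min_branch: float = DEFAULT_MIN_BRANCH,
) -> PtpDelimitation:
    """Maximum-likelihood PTP delimitation.

    Small trees (at most ``EXACT_SEARCH_LIMIT`` possible delimitations) are
    solved exactly by enumerating every antichain cover.  Larger trees use
    deterministic coordinate ascent: for fixed class rates the optimal
    delimitation is found exactly by dynamic programming over the tree,
    then the rates are re-estimated from the resulting classes; the
    alternation runs to a fixed point from several quantile-based rate
    initializations and the best local optimum is kept.  Deterministic for
    a fixed tree.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 3:
        raise TreeShapeError("PTP needs at least 3 tips")
    tree = _require_binary(tree, auto_resolve)
    if _count_delimitations(tree.seed_node, EXACT_SEARCH_LIMIT) < EXACT_SEARCH_LIMIT:
        best, best_ll, best_rates = None, -np.inf, (0.0, 0.0)
        for cand in _enumerate_delimitations(tree.seed_node):
            try:
                ll, ls, lw = ptp_loglik(
                    tree, cand, validate=False, min_branch=min_branch
                )
            except DegenerateBranchError:
                continue
            tol = 1e-9 * max(1.0, abs(ll))
            better = ll > best_ll + tol or (
                abs(ll - best_ll) <= tol and best is not None and len(cand) < len(best)
            )
            if best is None or better:
                best, best_ll, best_rates = cand, ll, (ls, lw)
        if best is None:
            raise DegenerateBranchError("no delimitation has a finite likelihood")
        return PtpDelimitation(list(best), best_rates[0], best_rates[1], best_ll)
    best_state = None
    for lam_s0, lam_c0 in _rate_inits(tree, min_branch):
        state = _alternate(tree, lam_s0, lam_c0, min_branch)
        if best_state is None or state[1] > best_state[1]:
            best_state = state
    crown, ll, lam_s, lam_w = best_state
    return PtpDelimitation(list(crown), lam_s, lam_w, ll)


def _available_moves(crown: list[dendropy.Node]):
    splits = [i for i, nd in enumerate(crown) if nd.child_nodes()]
    crown_ids = {id(nd) for nd in crown}
    merge_parents = []
    seen: set[int] = set()
    for nd in crown:
        par = nd.parent_node
        if par is None or id(par) in seen:
            continue
        seen.add(id(par))
        if all(id(c) in crown_ids for c in par.child_nodes()):
            merge_parents.append(par)
    return splits, merge_parents


def bptp_mcmc(tree: dendropy.Tree, cfg: McmcConfig | None = None,
              auto_resolve: bool = False) -> PtpDelimitation:
    """Bayesian PTP via Metropolis-Hastings over delimitations.

    Proposals replace a crown node by its two children (split) or a sibling
    pair of crown nodes by their parent (merge), drawn uniformly over all
    available moves with a Hastings correction.  Support is the post-burn-in
    frequency of each crown subtree; the returned delimitation is the
    maximum-frequency state.  ``n_runs`` independent chains are compared:
    modal MOTU counts differing by more than 10% raise a convergence
    warning (not a failure).
    """
    cfg = cfg or McmcConfig()
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 3:
        raise TreeShapeError("PTP needs at least 3 tips")
    tree = _require_binary(tree, auto_resolve)
    node_key = {id(nd): k for k, nd in enumerate(tree.preorder_node_iter())}

    run_results = []
    for run in range(cfg.n_runs):
        rng = np.random.default_rng((cfg.seed + 1) * 7919 + run)
        crown = [tree.seed_node]
        ll, _, _ = ptp_loglik(tree, crown, validate=False)
        state_counts: dict[frozenset[int], int] = {}
        crown_counts: dict[int, int] = {}
        states: dict[frozenset[int], list[dendropy.Node]] = {}
        burn = int(cfg.iterations * cfg.burn_in)
        n_kept = 0
        for it in range(cfg.iterations):
            splits, merges = _available_moves(crown)
            n_moves = len(splits) + len(merges)
            pick = rng.integers(n_moves)
            if pick < len(splits):
                i = splits[pick]
                nd = crown[i]
                cand = crown[:i] + nd.child_nodes() + crown[i + 1 :]
            else:
                par = merges[pick - len(splits)]
                child_ids = {id(c) for c in par.child_nodes()}
                cand = [nd for nd in crown if id(nd) not in child_ids] + [par]
            try:
                cll, _, _ = ptp_loglik(tree, cand, validate=False)
            except DegenerateBranchError:
                cll = -np.inf
            s2, m2 = _available_moves(cand)
            hastings = n_moves / max(len(s2) + len(m2), 1)
            if np.log(rng.random()) < (cll - ll) + np.log(hastings):
                crown, ll = cand, cll
            if it >= burn:
                n_kept += 1
                key = frozenset(node_key[id(nd)] for nd in crown)
                state_counts[key] = state_counts.get(key, 0) + 1
                if key not in states:
                    states[key] = list(crown)
                for nd in crown:
                    k = node_key[id(nd)]
                    crown_counts[k] = crown_counts.get(k, 0) + 1
        best_key = max(state_counts, key=lambda k: (state_counts[k], sorted(k)))
        run_results.append((states[best_key], crown_counts, n_kept))

    counts = [len(res[0]) for res in run_results]
    if max(counts) - min(counts) > 0.10 * max(max(counts), 1):
        warnings.warn(
            f"bPTP runs disagree in MOTU count: {counts}", RuntimeWarning
        )
    best_crown, crown_counts, n_kept = run_results[0]
    ll, lam_s, lam_w = ptp_loglik(tree, best_crown, validate=False)
    support = {
        crown_tip_set(nd): crown_counts.get(node_key[id(nd)], 0) / n_kept
        for nd in best_crown
    }
    return PtpDelimitation(best_crown, lam_s, lam_w, ll, support)


def nj_tree(m: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a K2P matrix, midpoint-rooted.

    A surrogate input for tree-based delimitation when no externally
    inferred phylogeny is supplied; undefined distances are imputed with
    1.5x the matrix maximum and negative NJ branch lengths clamped to zero.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    d = m.d.copy()
    if np.isnan(d).any():
        fill = np.nanmax(d) * 1.5 if np.isfinite(d).any() else 1.0
        d[np.isnan(d)] = fill
        np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    import io

    sk = skbio_nj(SkbioDM(d, ids=m.ids))
    buf = io.StringIO()
    sk.write(buf, format="newick")
    tree = dendropy.Tree.get(data=buf.getvalue(), schema="newick")
    for nd in tree.preorder_node_iter():
        if nd.edge.length is not None and nd.edge.length < 0:
            nd.edge.length = 0.0
    tree.reroot_at_midpoint(update_bipartitions=True)
    _suppress_unifurcations(tree)
    return tree


def _suppress_unifurcations(tree: dendropy.Tree) -> None:
    tree.suppress_unifurcations()
    for nd in tree.preorder_node_iter():
        if nd.parent_node is not None and nd.edge.length is None:
            nd.edge.length = 0.0
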