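"""Maximum-likelihood tree inference under GTR+Γ.

The search alternates (a) coordinate-wise optimization of branch lengths
and model parameters (bounded Brent passes) with (b) nearest-neighbor
interchange (NNI) sweeps in a fixed edge order, accepting the first
improving rearrangement, until a sweep gains less than ``nni_tol`` log
units. Starting trees come from neighbor joining on p-distances. Support
values come from the standard nonparametric site bootstrap with a reduced
per-replicate search (branch-length pass + one NNI sweep from the full-data
ML tree). All steps are deterministic given the seed and input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .genestats import DistanceMatrix, p_distance_matrix
from .likelihood import LikelihoodEngine, TreeWorkspace
from .msa import GeneAlignment
from .substmodel import GTRGammaParams
from .tree import Node, Tree

__all__ = ["MLResult", "nj_tree", "ml_search", "bootstrap_support", "delta_ml",
           "optimize_branch_lengths", "optimize_parameters"]

BRANCH_MIN = 1e-8
BRANCH_MAX = 10.0


@dataclass
class MLResult:
    tree: Tree
    params: GTRGammaParams
    log_likelihood: float
    converged: bool = True
    trace: list = None  # per-round log-likelihoods of the search


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(d: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining; ties in the Q matrix are broken by the
    lowest (i, j) index pair, negative branch lengths are clamped to 0."""
    n = len(d.ids)
    if n < 3:
        if n == 2:
            root = Node()
            for k, id_ in enumerate(d.ids):
                root.add(Node(id_, max(d.matrix[0, 1] / 2.0, 0.0)))
            return Tree(root)
        raise ValueError("need at least 2 taxa")
    D = d.matrix.astype(float).copy()
    nodes: list[Node] = [Node(i) for i in d.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = np.unravel_index(np.argmin(Q), Q.shape)  # lowest flat index wins ties
        a, b = sorted(best)
        ia, ib = active[a], active[b]
        dij = sub[a, b]
        la = 0.5 * dij + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dij - la
        u = Node()
        ca, cb = nodes[ia], nodes[ib]
        ca.length = max(la, 0.0)
        cb.length = max(lb, 0.0)
        u.add(ca)
        u.add(cb)
        new_d = 0.5 * (D[ia, :] + D[ib, :] - dij)
        D = np.vstack([D, new_d])
        D = np.hstack([D, np.append(new_d, 0.0)[:, None]])
        np.clip(D, 0.0, None, out=D)
        nodes.append(u)
        active = [x for x in active if x not in (ia, ib)] + [len(nodes) - 1]
    # join the last three on a central node (three-point formulas)
    i, j, k = active
    root = Node()
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    for idx, length in ((i, 0.5 * (dij + dik - djk)),
                        (j, 0.5 * (dij + djk - dik)),
                        (k, 0.5 * (dik + djk - dij))):
        nodes[idx].length = max(length, 0.0)
        root.add(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# Coordinate-wise optimization


def _brent(fun, lo, hi, x0):
    """Bounded univariate maximization; returns (x*, f(x*))."""
    res = minimize_scalar(lambda x: -fun(x), bounds=(lo, hi),
                          method="bounded",
                          options={"xatol": 1e-6 * max(abs(x0), 1e-3)})
    return float(res.x), float(-res.fun)


def optimize_branch_lengths(engine: LikelihoodEngine, tree: Tree,
                            n_passes: int = 3, tol: float = 1e-2) -> float:
    """In-place bounded Brent optimization of every branch.

    Each sweep optimizes all branches against partials cached at the start
    of the sweep (then refreshed), iterating up to ``n_passes`` times or
    until a sweep gains less than ``tol`` log units; a sweep that fails to
    improve is rolled back, so the result is monotone.
    """
    ws = TreeWorkspace(engine, tree)
    ll = ws.ll
    nodes = [n for n in tree.postorder() if n.parent is not None]
    for _ in range(n_passes):
        before = ll
        saved = [n.length for n in nodes]
        for node in nodes:
            x, fx = _brent(lambda t, node=node: ws.branch_loglik(node, t),
                           BRANCH_MIN, BRANCH_MAX, node.length)
            if fx >= ws.branch_loglik(node, node.length):
                node.length = x
        ws.refresh()
        ll = ws.ll
        if ll < before - 1e-9:  # stale-partial pathology: roll back
            for n, s in zip(nodes, saved):
                n.length = s
            ws.refresh()
            ll = ws.ll
            break
        if ll - before < tol:
            break
    return ll


def optimize_parameters(engine: LikelihoodEngine, tree: Tree) -> float:
    """Joint optimization of the free GTR+Γ parameters.

    Powell search in transformed coordinates: log exchangeabilities
    (GT fixed at 1), log frequency ratios against A, and log α. Powell
    builds conjugate directions, which matters here because the
    exchangeabilities are strongly correlated.
    """
    params = engine.params.copy()
    has_alpha = params.n_categories > 1

    def unpack(theta):
        params.exchangeabilities = np.concatenate(
            [np.exp(np.clip(theta[:5], -9.0, 9.0)), [1.0]])
        w = np.concatenate([[1.0], np.exp(np.clip(theta[5:8], -9.0, 9.0))])
        params.base_freqs = w / w.sum()
        if has_alpha:
            params.alpha = float(np.exp(np.clip(theta[8], -4.0, 5.0)))

    def negll(theta):
        unpack(theta)
        engine.set_params(params)
        return -engine.loglik(tree)

    w = engine.params.base_freqs
    theta0 = np.concatenate([
        np.log(np.clip(engine.params.exchangeabilities[:5], 1e-4, None)),
        np.log(np.clip(w[1:] / w[0], 1e-4, None)),
        [np.log(engine.params.alpha)] if has_alpha else [],
    ])
    f0 = negll(theta0)
    res = minimize(negll, theta0, method="Powell",
                   options={"xtol": 1e-4, "ftol": 1e-9, "maxiter": 40})
    best = res.x if res.fun <= f0 else theta0
    unpack(best)
    engine.set_params(params)
    return engine.loglik(tree)


# ---------------------------------------------------------------------------
# NNI


def _swap(a: Node, b: Node) -> None:
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def nni_sweep(engine: LikelihoodEngine, tree: Tree,
              current_ll: float | None = None) -> float:
    """One first-improvement NNI sweep over internal edges in deterministic
    postorder; each candidate is scored with its focal branch re-optimized
    against cached partials. Returns the new log-likelihood."""
    ws = TreeWorkspace(engine, tree)
    ll = ws.ll
    for edge_child in tree.internal_edges():
        if len(edge_child.children) != 2:
            continue
        parent = edge_child.parent
        sibling = next(c for c in parent.children if c is not edge_child)
        a, b = edge_child.children
        for keep, out in ((a, b), (b, a)):
            x, fx = _brent(
                lambda t: ws.nni_loglik(edge_child, keep, out, sibling, t),
                BRANCH_MIN, BRANCH_MAX, edge_child.length)
            if fx > ll + 1e-9:
                _swap(out, sibling)
                edge_child.length = x
                ws.refresh()
                ll = ws.ll
                break
    return ll


# ---------------------------------------------------------------------------
# Searches


def _initial_params(aln: GeneAlignment, n_categories: int = 4) -> GTRGammaParams:
    from .likelihood import empirical_base_freqs

    freqs = empirical_base_freqs(aln)
    freqs = np.clip(freqs, 1e-4, None)
    freqs /= freqs.sum()
    return GTRGammaParams(np.ones(6), freqs, alpha=1.0,
                          n_categories=n_categories)


def _alternate(engine: LikelihoodEngine, tree: Tree, optimize_params: bool,
               tol: float = 5e-4, max_iter: int = 15) -> float:
    """Alternate branch-length and parameter passes to joint convergence."""
    ll = optimize_branch_lengths(engine, tree)
    if not optimize_params:
        return ll
    for _ in range(max_iter):
        before = ll
        ll = optimize_parameters(engine, tree)
        ll = optimize_branch_lengths(engine, tree, tol=tol)
        if ll - before < tol:
            break
    return ll


def ml_search(aln: GeneAlignment, start: Tree | None = None, seed: int = 0,
              params: GTRGammaParams | None = None, max_rounds: int = 20,
              nni_tol: float = 0.01, optimize_params: bool = True) -> MLResult:
    """Full ML search: NJ start (unless given), then alternating
    branch/parameter optimization and NNI sweeps to convergence."""
    del seed  # the search is deterministic; kept for interface stability
    if start is None:
        start = nj_tree(p_distance_matrix(aln))
    tree = start.unroot()
    for node in tree.postorder():
        if node.parent is not None and node.length <= 0:
            node.length = BRANCH_MIN * 10
    engine = LikelihoodEngine(aln, params or _initial_params(aln))
    ll = optimize_branch_lengths(engine, tree)
    trace = [ll]
    if optimize_params:
        ll = optimize_parameters(engine, tree)
        ll = optimize_branch_lengths(engine, tree)
        trace.append(ll)
    converged = False
    for _ in range(max_rounds):
        before = ll
        ll = nni_sweep(engine, tree)
        sweep_gain = ll - before
        ll = optimize_branch_lengths(engine, tree)
        trace.append(ll)
        if sweep_gain <= nni_tol:
            converged = True
            break
    if not converged:
        warnings.warn("NNI search did not converge within max_rounds")
    ll = _alternate(engine, tree, optimize_params)
    trace.append(ll)
    return MLResult(tree=tree, params=engine.params, log_likelihood=ll,
                    converged=converged, trace=trace)


def optimize_on_topology(aln: GeneAlignment, topology: Tree,
                         params: GTRGammaParams | None = None) -> MLResult:
    """Branch-length + parameter optimization on a fixed topology, run to
    the same convergence tolerance as the free search."""
    tree = topology.unroot()
    for node in tree.postorder():
        if node.parent is not None and node.length <= 0:
            node.length = 0.05
    engine = LikelihoodEngine(aln, params or _initial_params(aln))
    ll = _alternate(engine, tree, optimize_params=True)
    return MLResult(tree=tree, params=engine.params, log_likelihood=ll)


def delta_ml(aln: GeneAlignment, constraint: Tree, seed: int = 0,
             free: MLResult | None = None) -> float:
    """ΔML = logL(free search) − logL(optimized constraint topology).

    Nonnegative up to optimizer tolerance; 0 when the constraint already is
    the free optimum.
    """
    if set(constraint.tip_names()) != set(aln.ids):
        raise ValueError("constraint tips do not match alignment ids")
    if free is None:
        free = ml_search(aln, seed=seed)
    constrained = optimize_on_topology(aln, constraint)
    return free.log_likelihood - constrained.log_likelihood


def bootstrap_support(aln: GeneAlignment, n_reps: int = 200, seed: int = 0,
                      full: MLResult | None = None) -> MLResult:
    """Nonparametric site bootstrap.

    Sites are resampled with replacement; each replicate re-optimizes
    branch lengths from the full-data ML tree under the full-data model and
    runs one NNI sweep. Support on each internal edge of the full-data tree
    is the percentage of replicates whose tree contains that bipartition.
    """
    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    if full is None:
        full = ml_search(aln, seed=seed)
    engine = LikelihoodEngine(aln, full.params)
    rng = np.random.default_rng(seed)
    target = {}
    all_tips = frozenset(full.tree.tip_names())
    below = full.tree._clade_sets()
    for node in full.tree.postorder():
        if node.parent is None or node.is_leaf:
            continue
        side = below[id(node)]
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        canon = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        target[id(node)] = canon
    hits = {k: 0 for k in target.values()}
    for _ in range(n_reps):
        engine.set_counts(engine.data.bootstrap_counts(rng))
        rep_tree = full.tree.copy()
        ll = optimize_branch_lengths(engine, rep_tree)
        ll = nni_sweep(engine, rep_tree, ll)
        rep_bips = rep_tree.bipartitions()
        for bip in hits:
            if bip in rep_bips:
                hits[bip] += 1
    engine.set_counts(engine.data.counts)
    out = full.tree.copy()
    below = out._clade_sets()
    for node in out.postorder():
        if node.parent is None or node.is_leaf:
            continue
        side = below[id(node)]
        if len(side) < 2 or len(side) > len(all_tips) - 2:
            continue
        canon = min(side, all_tips - side, key=lambda s: (len(s), sorted(s)))
        node.support = 100.0 * hits[canon] / n_reps
    return MLResult(tree=out, params=full.params,
                    log_likelihood=full.log_likelihood,
                    converged=full.converged)
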