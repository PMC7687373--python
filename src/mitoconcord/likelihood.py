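"""Phylogenetic likelihood under GTR+Γ via Felsenstein's pruning algorithm.

Site columns are compressed to unique patterns with multiplicities before
any computation. Gaps, ``N`` and other ambiguity codes are missing data
(partial likelihood 1 in every state). Per-pattern scaling keeps partial
likelihoods in range on large trees; the per-site likelihood is the
equal-weight average over the discrete-Γ rate categories.
"""

from __future__ import annotations

import numpy as np

from .msa import GeneAlignment
from .substmodel import BASE_INDEX, GTREigen, GTRGammaParams
from .tree import Tree

__all__ = ["PatternData", "LikelihoodEngine", "log_likelihood",
           "empirical_base_freqs"]

_MISSING = 4


class PatternData:
    """Unique site patterns of an alignment with multiplicities."""

    def __init__(self, aln: GeneAlignment):
        self.ids = list(aln.ids)
        mat = np.full((len(aln.rows), aln.length), _MISSING, dtype=np.int8)
        for r, row in enumerate(aln.rows):
            for c, ch in enumerate(row):
                mat[r, c] = BASE_INDEX.get(ch, _MISSING)
        cols = np.ascontiguousarray(mat.T)
        patterns, site_to_pattern, counts = np.unique(
            cols, axis=0, return_inverse=True, return_counts=True)
        self.patterns = patterns            # (npat, ntaxa)
        self.site_to_pattern = site_to_pattern.ravel()
        self.counts = counts.astype(float)  # (npat,)
        self.n_sites = aln.length

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    def tip_partial(self, id_: str) -> np.ndarray:
        """(npat, 4) conditional likelihoods at a tip."""
        try:
            row = self.ids.index(id_)
        except ValueError:
            raise KeyError(f"tree tip {id_!r} has no sequence in the alignment")
        states = self.patterns[:, row]
        part = np.zeros((self.n_patterns, 4))
        known = states != _MISSING
        part[known, states[known]] = 1.0
        part[~known] = 1.0
        return part

    def bootstrap_counts(self, rng: np.random.Generator) -> np.ndarray:
        """Pattern multiplicities after resampling sites with replacement."""
        sites = rng.integers(0, self.n_sites, size=self.n_sites)
        new = np.bincount(self.site_to_pattern[sites],
                          minlength=self.n_patterns)
        return new.astype(float)

    def base_freqs(self) -> np.ndarray:
        counts = np.zeros(4)
        for b in range(4):
            counts[b] = ((self.patterns == b) * self.counts[:, None]).sum()
        if counts.sum() == 0:
            return np.full(4, 0.25)
        return counts / counts.sum()


def empirical_base_freqs(aln: GeneAlignment) -> np.ndarray:
    return PatternData(aln).base_freqs()


class LikelihoodEngine:
    """Reusable pruning engine bound to one alignment's pattern data.

    ``set_params`` refreshes the eigensystem; ``set_counts`` swaps pattern
    multiplicities (bootstrap replicates share patterns with the original
    data, only the weights change).
    """

    def __init__(self, aln: GeneAlignment | PatternData,
                 params: GTRGammaParams | None = None):
        self.data = aln if isinstance(aln, PatternData) else PatternData(aln)
        self.counts = self.data.counts.copy()
        self._tip_cache: dict[str, np.ndarray] = {}
        self.set_params(params or GTRGammaParams())

    def set_params(self, params: GTRGammaParams) -> None:
        self.params = params
        self.eigen = GTREigen(params)
        self.rates = params.category_rates()

    def set_counts(self, counts: np.ndarray) -> None:
        self.counts = np.asarray(counts, dtype=float)

    def _tip(self, name: str) -> np.ndarray:
        if name not in self._tip_cache:
            self._tip_cache[name] = self.data.tip_partial(name)
        return self._tip_cache[name]

    def site_log_likelihoods(self, tree: Tree) -> np.ndarray:
        """Per-pattern log-likelihoods (length n_patterns)."""
        K = len(self.rates)
        npat = self.data.n_patterns
        pi = self.params.base_freqs
        scale = np.zeros(npat)
        partials: dict[int, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                continue
            acc = np.ones((K, npat, 4))
            for child in node.children:
                P = self.eigen.transition_matrices(child.length, self.rates)
                if child.is_leaf:
                    cp = self._tip(child.name)  # (npat, 4)
                    down = np.einsum("kij,nj->kni", P, cp)
                else:
                    cp = partials.pop(id(child))
                    down = np.einsum("kij,knj->kni", P, cp)
                acc *= down
            mx = acc.max(axis=(0, 2))
            bad = mx <= 0
            if np.any(bad) and node.parent is None:
                raise FloatingPointError(
                    f"zero likelihood at pattern {int(np.flatnonzero(bad)[0])}")
            mx = np.where(mx > 0, mx, 1.0)
            acc /= mx[None, :, None]
            scale += np.log(mx)
            partials[id(node)] = acc
        root_partial = partials[id(tree.root)]
        site_lik = np.einsum("knj,j->n", root_partial, pi) / K
        if np.any(site_lik <= 0) or not np.all(np.isfinite(site_lik)):
            bad = int(np.flatnonzero((site_lik <= 0) | ~np.isfinite(site_lik))[0])
            raise FloatingPointError(f"non-finite likelihood at pattern {bad}")
        return np.log(site_lik) + scale

    def loglik(self, tree: Tree) -> float:
        return float(self.site_log_likelihoods(tree) @ self.counts)


def log_likelihood(aln: GeneAlignment, tree: Tree,
                   params: GTRGammaParams) -> float:
    """Log-likelihood of an alignment on a tree under GTR+Γ."""
    return LikelihoodEngine(aln, params).loglik(tree)


class TreeWorkspace:
    """Directional partial-likelihood cache for fast branch work.

    For every node v with parent u the cache holds the downward partial
    (data below v, given the state at v) and the π-weighted upward partial
    H[v] (data outside v's subtree, given the state at u), so the
    log-likelihood as a function of one branch length, or of one NNI
    rearrangement across an edge, is a single small contraction:

        L_site(t) = Σ_k 1/K · Σ_ij H[v][k,i] · P_ij(t·r_k) · down[v][k,j]

    Reversibility gives the upward recursion H[c] = (H[u]·P(t_u)) ⊙ Π M[s]
    over c's siblings s, where M[s] = P(t_s)·down[s]. Partials go stale
    when the tree changes; callers refresh after accepting a move.
    """

    def __init__(self, engine: LikelihoodEngine, tree: Tree):
        self.engine = engine
        self.tree = tree
        self.refresh()

    def refresh(self) -> None:
        eng = self.engine
        K = len(eng.rates)
        npat = eng.data.n_patterns
        pi = eng.params.base_freqs
        post = self.tree.postorder()
        down: dict[int, np.ndarray] = {}
        sdown: dict[int, np.ndarray] = {}
        M: dict[int, np.ndarray] = {}
        zero = np.zeros(npat)
        for v in post:
            if v.is_leaf:
                d = np.broadcast_to(eng._tip(v.name), (K, npat, 4))
                sdown[id(v)] = zero
            else:
                d = np.ones((K, npat, 4))
                s = np.zeros(npat)
                for c in v.children:
                    d = d * M[id(c)]
                    s = s + sdown[id(c)]
                mx = d.max(axis=(0, 2))
                mx = np.where(mx > 0, mx, 1.0)
                d = d / mx[None, :, None]
                s = s + np.log(mx)
                sdown[id(v)] = s
            down[id(v)] = d
            if v.parent is not None:
                P = eng.eigen.transition_matrices(v.length, eng.rates)
                M[id(v)] = np.einsum("kij,knj->kni", P, d)
        H: dict[int, np.ndarray] = {}
        sH: dict[int, np.ndarray] = {}
        G: dict[int, np.ndarray] = {}
        for v in reversed(post):  # parents before children
            if v.parent is None:
                continue
            u = v.parent
            if u.parent is None:
                base = np.broadcast_to(pi, (K, npat, 4))
                sbase = zero
            else:
                base = G[id(u)]
                sbase = sH[id(u)]
            h = base
            s = sbase
            for sib in u.children:
                if sib is v:
                    continue
                h = h * M[id(sib)]
                s = s + sdown[id(sib)]
            mx = h.max(axis=(0, 2))
            mx = np.where(mx > 0, mx, 1.0)
            h = h / mx[None, :, None]
            s = s + np.log(mx)
            H[id(v)] = h
            sH[id(v)] = s
            if not v.is_leaf:
                P = eng.eigen.transition_matrices(v.length, eng.rates)
                G[id(v)] = np.einsum("kni,kij->knj", h, P)
        self.down, self.sdown, self.M = down, sdown, M
        self.H, self.sH, self.G = H, sH, G
        first = self.tree.root.children[0]
        self.ll = self._edge_ll(id(first), id(first), first.length)

    def _edge_ll(self, h_key: int, d_key: int, t: float,
                 h=None, sh=None, d=None, sd=None) -> float:
        eng = self.engine
        K = len(eng.rates)
        P = eng.eigen.transition_matrices(t, eng.rates)
        h = self.H[h_key] if h is None else h
        sh = self.sH[h_key] if sh is None else sh
        d = self.down[d_key] if d is None else d
        sd = self.sdown[d_key] if sd is None else sd
        val = np.einsum("kni,kij,knj->n", h, P, d) / K
        val = np.clip(val, 1e-300, None)
        return float(eng.counts @ (np.log(val) + sh + sd))

    def branch_loglik(self, node, t: float) -> float:
        """Log-likelihood with node's branch set to t, all else cached."""
        return self._edge_ll(id(node), id(node), t)

    def nni_loglik(self, edge_child, keep, swap_out, swap_in, t: float) -> float:
        """Log-likelihood of the rearrangement that gives ``edge_child`` the
        children (keep, swap_in) and returns ``swap_out`` to the parent,
        with the focal branch set to t."""
        u = edge_child.parent
        d = self.M[id(keep)] * self.M[id(swap_in)]
        sd = self.sdown[id(keep)] + self.sdown[id(swap_in)]
        eng = self.engine
        K = len(eng.rates)
        npat = eng.data.n_patterns
        if u.parent is None:
            h = np.broadcast_to(eng.params.base_freqs, (K, npat, 4))
            sh = np.zeros(npat)
        else:
            h = self.G[id(u)]
            sh = self.sH[id(u)]
        for sib in u.children:
            if sib is edge_child or sib is swap_in:
                continue
            h = h * self.M[id(sib)]
            sh = sh + self.sdown[id(sib)]
        h = h * self.M[id(swap_out)]
        sh = sh + self.sdown[id(swap_out)]
        return self._edge_ll(0, 0, t, h=h, sh=sh, d=d, sd=sd)
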