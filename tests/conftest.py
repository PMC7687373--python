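"""Shared fixtures: scaled-down simulation configs and independent oracles."""

import itertools

import numpy as np
import pytest
import scipy.linalg

from mitoconcord.simulate import SimConfig, SimElement, default_piranga_like_config
from mitoconcord.substmodel import GTRGammaParams, discrete_gamma_rates, gtr_rate_matrix
from mitoconcord.tree import Node, Tree


def small_tree(n_species: int = 4, cherry: float = 0.01, stem: float = 0.03,
               step: float = 0.02, og_stem: float = 0.12):
    """Ladder of two-individual cherries plus an outgroup; returns
    (tree, species_map, outgroup_name)."""
    species_map = {}

    def make_cherry(i):
        sp = f"sp{i:02d}"
        node = Node(length=stem)
        for j in (1, 2):
            tip = node.add(Node(f"{sp}_i{j}", cherry))
            species_map[tip.name] = sp
        return node

    current = Node(length=step)
    current.add(make_cherry(1))
    current.add(make_cherry(2))
    for i in range(3, n_species + 1):
        parent = Node(length=step)
        parent.add(current)
        parent.add(make_cherry(i))
        current = parent
    root = Node()
    root.add(current)
    og = root.add(Node("outgroup_i1", og_stem))
    species_map[og.name] = "outgroup"
    return Tree(root), species_map, og.name


def small_sim_config(seed: int = 0, n_species: int = 4) -> SimConfig:
    """A miniature dataset (9 tips, 4 elements + spacers) for fast
    end-to-end tests."""
    tree, species_map, outgroup = small_tree(n_species)
    table = [
        SimElement("12S", "rRNA", 400, 0.4),
        SimElement("spacer_12S", "spacer", 60, 1.2),
        SimElement("ND2", "protein", 600, 1.4),
        SimElement("spacer_ND2", "spacer", 60, 1.2),
        SimElement("CytB", "protein", 900, 1.0),
        SimElement("spacer_CytB", "spacer", 60, 1.2),
        SimElement("CR", "control_region", 400, 1.3),
    ]
    params = GTRGammaParams(
        exchangeabilities=np.array([1.0, 8.0, 1.0, 1.0, 12.0, 1.0]),
        base_freqs=np.array([0.30, 0.32, 0.12, 0.26]),
        alpha=0.4, n_categories=4)
    return SimConfig(tree=tree, gene_table=table, params=params, seed=seed,
                     species_map=species_map, outgroup=outgroup)


@pytest.fixture(scope="session")
def default_cfg():
    return default_piranga_like_config(0)


@pytest.fixture
def small_cfg():
    return small_sim_config(0)


def random_resolved_tree(names, rng, min_len=0.01, max_len=0.2) -> Tree:
    """Random binary unrooted topology over the given tips."""
    names = list(names)
    nodes = [Node(n, float(rng.uniform(min_len, max_len))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=float(rng.uniform(min_len, max_len)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    return Tree(root)


def enumeration_loglik(aln, tree: Tree, params: GTRGammaParams) -> float:
    """Independent likelihood oracle: explicit sum over all internal-state
    assignments per site, transition matrices via scipy expm."""
    Q = gtr_rate_matrix(params.exchangeabilities, params.base_freqs)
    rates = discrete_gamma_rates(params.alpha, params.n_categories)
    pi = params.base_freqs
    nodes = tree.postorder()
    P = {id(n): [scipy.linalg.expm(Q * n.length * r) for r in rates]
         for n in nodes if n.parent is not None}
    internal = [n for n in nodes if not n.is_leaf]
    tips = {n.name: aln.row(n.name) for n in nodes if n.is_leaf}
    state_of = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for site in range(aln.length):
        site_lik = 0.0
        for k in range(len(rates)):
            for assignment in itertools.product(range(4), repeat=len(internal)):
                states = {id(n): s for n, s in zip(internal, assignment)}
                contrib = pi[states[id(tree.root)]]
                ok = True
                for n in nodes:
                    if n.parent is None:
                        continue
                    parent_state = states[id(n.parent)]
                    if n.is_leaf:
                        ch = tips[n.name][site]
                        if ch in state_of:
                            contrib *= P[id(n)][k][parent_state, state_of[ch]]
                        # gap/N: sum over tip states = 1, no factor
                    else:
                        contrib *= P[id(n)][k][parent_state, states[id(n)]]
                    if contrib == 0.0:
                        ok = False
                        break
                if ok:
                    site_lik += contrib
        total += np.log(site_lik / len(rates))
    return float(total)
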