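"""Node-wise topological concordance of gene trees against a reference tree.

For every internal node of the reference tree (rooted on the outgroup),
each gene tree is scored as *concordant* (it contains the identical
bipartition, at or above a bootstrap-support floor), *conflicting* (it
contains a sufficiently supported bipartition incompatible with the
reference one), or *uninformative* (neither: unresolved or below the
floor). Two bipartitions A|A' and B|B' are compatible iff at least one of
the four side intersections is empty.

Edges without a recorded support value pass a 0% floor and fail any
positive floor. Scoring can optionally collapse the two individuals per
species to one species-level tip: a gene-tree bipartition maps to species
level only when no species straddles both of its sides, so species-level
non-monophyly renders that bipartition unusable, in line with treating it
as not supporting either resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .tree import Tree

__all__ = ["ConcordanceTable", "bipartitions", "score_node",
           "concordance_table", "render_annotated_tree"]

CONCORDANT = "concordant"
CONFLICTING = "conflicting"
UNINFORMATIVE = "uninformative"


def _canon(side: frozenset, tip_set: frozenset) -> frozenset:
    other = tip_set - side
    return min(side, other, key=lambda s: (len(s), sorted(s)))


def bipartitions(tree: Tree, min_support: float = 0.0) -> set[frozenset]:
    """Nontrivial bipartitions whose support passes the floor, each
    canonicalized as its smaller side."""
    return tree.bipartitions(min_support=min_support)


def _mapped_bipartitions(tree: Tree, min_support: float,
                         species_map: dict[str, str] | None) -> set[frozenset]:
    bips = tree.bipartitions(min_support=min_support)
    if species_map is None:
        return bips
    tip_set = frozenset(tree.tip_names())
    species_set = frozenset(species_map[t] for t in tip_set)
    out: set[frozenset] = set()
    for side in bips:
        sp_side = frozenset(species_map[t] for t in side)
        sp_other = frozenset(species_map[t] for t in tip_set - side)
        if sp_side & sp_other:
            continue  # a species straddles the split
        if len(sp_side) < 2 or len(sp_side) > len(species_set) - 2:
            continue
        out.add(_canon(sp_side, species_set))
    return out


def _compatible(a: frozenset, b: frozenset, tip_set: frozenset) -> bool:
    a2 = tip_set - a
    b2 = tip_set - b
    return not (a & b) or not (a & b2) or not (a2 & b) or not (a2 & b2)


def score_node(ref_bipartition: frozenset, gene_tree: Tree,
               min_support: float = 0.0,
               species_map: dict[str, str] | None = None) -> str:
    """Score one gene tree at one reference bipartition."""
    if not ref_bipartition <= frozenset(
            species_map[t] if species_map else t for t in gene_tree.tip_names()):
        raise ValueError("reference bipartition names tips absent from the gene tree")
    gene_bips = _mapped_bipartitions(gene_tree, min_support, species_map)
    if species_map is None:
        tip_set = frozenset(gene_tree.tip_names())
    else:
        tip_set = frozenset(species_map[t] for t in gene_tree.tip_names())
    canon = _canon(ref_bipartition, tip_set)
    if canon in gene_bips:
        return CONCORDANT
    for bip in gene_bips:
        if not _compatible(canon, bip, tip_set):
            return CONFLICTING
    return UNINFORMATIVE


@dataclass
class ConcordanceTable:
    """Per-node concordance counts at one support floor."""

    threshold: float
    n_genes: int
    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            recs.append({
                "node": row["node"],
                "clade": ";".join(sorted(row["clade"])),
                "concordant": row[CONCORDANT],
                "conflicting": row[CONFLICTING],
                "uninformative": row[UNINFORMATIVE],
                "threshold": self.threshold,
            })
        return pd.DataFrame.from_records(recs)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def counts(self, node: int) -> tuple[int, int, int]:
        row = self.rows[node]
        return row[CONCORDANT], row[CONFLICTING], row[UNINFORMATIVE]


def _reference_nodes(ref_rooted: Tree) -> list[frozenset]:
    """Clades below every internal non-root node with ≥2 tips, in
    deterministic postorder."""
    below = ref_rooted._clade_sets()
    out = []
    for node in ref_rooted.postorder():
        if node.parent is None or node.is_leaf:
            continue
        clade = below[id(node)]
        if len(clade) >= 2:
            out.append(clade)
    return out


def concordance_table(ref: Tree, gene_trees: list[Tree],
                      min_support: float = 0.0,
                      outgroup: str | None = None,
                      species_map: dict[str, str] | None = None) -> ConcordanceTable:
    """Score every gene tree at every reference internal node.

    The reference is rooted on ``outgroup`` (when given) before node
    enumeration, so nodes are clades of the rooted reference. The clade
    separating the outgroup from everything else is contained in every
    gene tree and is scored concordant at any floor (its only edge is the
    outgroup tip edge, which carries no bootstrap value).
    """
    ref_tips = set(ref.tip_names())
    for i, gt in enumerate(gene_trees):
        if set(gt.tip_names()) != ref_tips:
            raise ValueError(f"gene tree {i} tip set differs from reference")
    rooted = ref.reroot_on(outgroup) if outgroup else ref
    tip_set = frozenset(ref_tips)
    if species_map is not None:
        clades = []
        sp_set = frozenset(species_map[t] for t in tip_set)
        for clade in _reference_nodes(rooted):
            sp = frozenset(species_map[t] for t in clade)
            rest = frozenset(species_map[t] for t in tip_set - clade)
            if sp & rest or len(sp) < 2:
                continue  # node below the species level
            clades.append(sp)
        universe = sp_set
    else:
        clades = _reference_nodes(rooted)
        universe = tip_set
    gene_bips = [_mapped_bipartitions(gt, min_support, species_map)
                 for gt in gene_trees]
    table = ConcordanceTable(threshold=min_support, n_genes=len(gene_trees))
    for node_idx, clade in enumerate(clades):
        counts = {CONCORDANT: 0, CONFLICTING: 0, UNINFORMATIVE: 0}
        trivial = len(clade) >= len(universe) - 1
        canon = _canon(clade, universe)
        for bips in gene_bips:
            if trivial:
                counts[CONCORDANT] += 1
                continue
            if canon in bips:
                counts[CONCORDANT] += 1
            elif any(not _compatible(canon, b, universe) for b in bips):
                counts[CONFLICTING] += 1
            else:
                counts[UNINFORMATIVE] += 1
        table.rows.append({"node": node_idx, "clade": clade, **counts})
    return table


def render_annotated_tree(ref: Tree, tables: list[ConcordanceTable],
                          outgroup: str | None = None,
                          species_map: dict[str, str] | None = None) -> str:
    """Plain-text rooted tree with per-node concordance counts.

    Each internal node shows ``[c/x/u @thr]`` blocks, one per table.
    """
    rooted = ref.reroot_on(outgroup) if outgroup else ref
    tip_set = frozenset(rooted.tip_names())
    by_clade: list[dict[frozenset, tuple]] = []
    for tab in tables:
        by_clade.append({frozenset(r["clade"]): (r[CONCORDANT], r[CONFLICTING],
                                                 r[UNINFORMATIVE])
                         for r in tab.rows})
    below = rooted._clade_sets()
    lines: list[str] = []

    def _walk(node, depth):
        pad = "  " * depth
        if node.is_leaf:
            lines.append(f"{pad}{node.name}")
            return
        clade = below[id(node)]
        if species_map is not None:
            clade = frozenset(species_map[t] for t in clade)
        labels = []
        for tab, cl in zip(tables, by_clade):
            if clade in cl:
                c, x, u = cl[clade]
                labels.append(f"[{c}/{x}/{u} @BS>={tab.threshold:g}]")
        lines.append(pad + "+ " + " ".join(labels))
        for child in node.children:
            _walk(child, depth + 1)

    _walk(rooted.root, 0)
    return "\n".join(lines)
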