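"""Per-gene divergence and rate statistics.

These are the summary statistics of a congeneric mitogenome survey: column
identity, mean pairwise identity, uncorrected p-distances, amino-acid
variability under the vertebrate mitochondrial code, relative substitution
rates via regression of one gene's pairwise divergences on a reference
gene's (conventionally CytB), and the across-gene regression of amino-acid
conservation on nucleotide conservation.

"Divergence" is the uncorrected p-distance: intrageneric distances are
small enough that multiple-hit corrections are second order. A
Jukes–Cantor-corrected variant is available via the ``correction`` flag of
:func:`p_distance_matrix`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio.Data import CodonTable

from .msa import GeneAlignment
from .tree import Tree

__all__ = [
    "GeneStats", "DistanceMatrix",
    "percent_identical_columns", "mean_pairwise_identity",
    "p_distance_matrix", "translate", "variable_residue_count",
    "relative_rate", "conservation_regression", "subs_per_site",
    "stats_table",
]


@dataclass
class GeneStats:
    """One report row for a single element.

    ``relative_rate``/``rate_r2`` are ``None`` for the reference gene
    itself; ``var_residues`` is ``None`` for non-protein elements.
    """

    element: str
    align_length: int
    pct_identical: float
    pct_pairwise_identity: float
    subs_per_site: float | None = None
    var_residues: tuple[int, int] | None = None
    relative_rate: float | None = None
    rate_r2: float | None = None
    delta_ml: float | None = None


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over named individuals."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def condensed(self, ids: list[str] | None = None) -> np.ndarray:
        """Upper-triangle entries in a fixed (i<j) order."""
        ids = ids or self.ids
        idx = [self.ids.index(i) for i in ids]
        return np.array([self.matrix[i, j] for i, j in combinations(idx, 2)])

    def write_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, id_ in enumerate(self.ids):
                row = " ".join(f"{x:.6f}" for x in self.matrix[i])
                fh.write(f"{id_:<12} {row}\n")


def _rows(aln: GeneAlignment, ids) -> list[str]:
    if ids is None:
        return aln.rows
    return [aln.row(i) for i in ids]


def percent_identical_columns(aln: GeneAlignment, ids=None) -> float:
    """Percent of columns where every selected row carries the same
    unambiguous base (gap or N anywhere disqualifies the column)."""
    rows = _rows(aln, ids)
    if not rows:
        raise ValueError("empty id subset")
    identical = 0
    for col in zip(*rows):
        first = col[0]
        if first in "-N":
            continue
        if all(c == first for c in col):
            identical += 1
    return 100.0 * identical / aln.length


def _pair_identity(a: str, b: str) -> tuple[int, int]:
    """(matches, comparable) over sites where neither row is gap/N."""
    matches = comparable = 0
    for ca, cb in zip(a, b):
        if ca in "-N" or cb in "-N":
            continue
        comparable += 1
        if ca == cb:
            matches += 1
    return matches, comparable


def mean_pairwise_identity(aln: GeneAlignment, ids=None) -> float:
    """Mean over unordered row pairs of 100·matches/comparable sites."""
    rows = _rows(aln, ids)
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    vals = []
    for a, b in combinations(rows, 2):
        matches, comparable = _pair_identity(a, b)
        if comparable == 0:
            warnings.warn("row pair with no comparable sites skipped")
            continue
        vals.append(100.0 * matches / comparable)
    return float(np.mean(vals))


def p_distance_matrix(aln: GeneAlignment, ids=None,
                      correction: str | None = None) -> DistanceMatrix:
    """Uncorrected pairwise p-distances (optionally ``correction='jc'``)."""
    ids = list(ids) if ids is not None else list(aln.ids)
    rows = [aln.row(i) for i in ids]
    if len(rows) < 2:
        raise ValueError("need at least 2 rows")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            matches, comparable = _pair_identity(rows[i], rows[j])
            if comparable == 0:
                warnings.warn(f"pair ({ids[i]}, {ids[j]}) has no comparable sites")
                continue
            p = 1.0 - matches / comparable
            if correction == "jc":
                if p >= 0.75:
                    raise ValueError("p-distance too large for JC correction")
                p = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            elif correction is not None:
                raise ValueError(f"unknown correction {correction!r}")
            d[i, j] = d[j, i] = p
    return DistanceMatrix(ids=ids, matrix=d)


def _codon_maps(code_id: int) -> tuple[dict, frozenset]:
    if code_id not in _CODON_CACHE:
        try:
            table = CodonTable.unambiguous_dna_by_id[code_id]
        except KeyError:
            raise ValueError(f"unsupported genetic code {code_id}")
        _CODON_CACHE[code_id] = (dict(table.forward_table),
                                 frozenset(table.stop_codons))
    return _CODON_CACHE[code_id]


_CODON_CACHE: dict[int, tuple[dict, frozenset]] = {}


def translate(seq: str, code_id: int = 2) -> str:
    """Translate an in-frame coding sequence.

    A trailing partial codon (1–2 nt, completed by polyadenylation in vivo)
    and a terminal stop are dropped; an internal stop raises, since it
    signals a mis-projected reading frame. Codons containing gaps or N
    translate to ``X``.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    forward, stops = _codon_maps(code_id)
    usable = seq[: len(seq) - len(seq) % 3]
    aa = []
    for i in range(0, len(usable), 3):
        codon = usable[i:i + 3]
        if codon in stops:
            aa.append("*")
        else:
            aa.append(forward.get(codon, "X"))
    if aa and aa[-1] == "*":
        aa.pop()
    joined = "".join(aa)
    if "*" in joined:
        raise ValueError(
            f"internal stop codon at residue {joined.index('*') + 1}; "
            "reading frame is likely mis-projected")
    return joined


def variable_residue_count(aln: GeneAlignment, ids=None,
                           code_id: int = 2) -> tuple[int, int]:
    """(variable, total) amino-acid residues across individuals.

    Each row is ungapped and translated; residues are compared by codon
    column. ``X`` (undetermined) never counts toward variability. Requires
    indel-free coding rows (equal ungapped lengths).
    """
    ids = list(ids) if ids is not None else list(aln.ids)
    proteins = []
    for id_ in ids:
        try:
            proteins.append(translate(aln.ungapped(id_), code_id))
        except ValueError as exc:
            raise ValueError(f"{id_}: {exc}") from exc
    if len({len(p) for p in proteins}) != 1:
        raise ValueError("translated rows differ in length; "
                         "coding indels are not supported")
    total = len(proteins[0])
    variable = 0
    for col in zip(*proteins):
        residues = {c for c in col if c != "X"}
        if len(residues) > 1:
            variable += 1
    return variable, total


def relative_rate(gene_d: DistanceMatrix,
                  ref_d: DistanceMatrix) -> tuple[float, float]:
    """Slope and adjusted R² of OLS of a gene's pairwise distances on the
    reference gene's, over all unordered pairs (intercept included)."""
    if set(gene_d.ids) != set(ref_d.ids):
        raise ValueError("distance matrices cover different individuals")
    if len(gene_d.ids) < 3:
        raise ValueError("need at least 3 individuals")
    ids = list(gene_d.ids)
    y = gene_d.condensed(ids)
    x = ref_d.condensed(ids)
    if np.ptp(x) == 0:
        raise ValueError("reference distances have zero variance")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.rsquared_adj)


def conservation_regression(stats: list[GeneStats]) -> tuple[float, float, float]:
    """Across protein genes, regress % conserved residues on % identical
    nucleotides; returns (slope, adjusted R², two-sided slope p-value)."""
    rows = [s for s in stats if s.var_residues is not None]
    if len(rows) < 3:
        raise ValueError("need at least 3 protein genes")
    x = np.array([s.pct_identical for s in rows])
    y = np.array([100.0 * (1.0 - v / t) for s in rows
                  for v, t in [s.var_residues]])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance in regression inputs")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.params[1]), float(fit.rsquared_adj), float(fit.pvalues[1])


def subs_per_site(tree: Tree) -> float:
    """Total branch length of a gene tree, in substitutions/site."""
    lengths = [n.length for n in tree.postorder() if n.parent is not None]
    if any(l is None for l in lengths):
        raise ValueError("tree is missing branch lengths")
    return float(sum(lengths))


def stats_table(stats: list[GeneStats]) -> pd.DataFrame:
    """Tabular report matching the survey's column set; percentages to one
    decimal, rates to three."""
    recs = []
    for s in stats:
        recs.append({
            "element": s.element,
            "align_length": s.align_length,
            "pct_identical": round(s.pct_identical, 1),
            "pct_pairwise_identity": round(s.pct_pairwise_identity, 1),
            "delta_ml": None if s.delta_ml is None else round(s.delta_ml, 3),
            "subs_per_site": None if s.subs_per_site is None else round(s.subs_per_site, 3),
            "var_residues": ("-" if s.var_residues is None
                             else f"{s.var_residues[0]}/{s.var_residues[1]}"),
            "relative_rate": ("-" if s.relative_rate is None
                              else round(s.relative_rate, 3)),
            "rate_r2": "-" if s.rate_r2 is None else round(s.rate_r2, 3),
        })
    return pd.DataFrame.from_records(recs)
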