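"""Per-gene multiple sequence alignment.

Congeneric mitochondrial genes are nearly indel-free outside the control
region, so a deterministic progressive aligner is sufficient and makes every
run reproducible: pairwise identities (edit distances) define a UPGMA guide
order, and profiles are merged with affine-gap Needleman–Wunsch
(match +1, mismatch −1, gap open −5, gap extend −1). Ties in the dynamic
program are broken in a fixed order (match > gap-in-second > gap-in-first),
and ungapping any output row reproduces its input sequence exactly.

``N`` is treated as missing throughout: it never scores as match or
mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "GeneAlignment",
    "align_gene_set",
    "concatenate",
    "pairwise_align",
    "sum_of_pairs_score",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_phylip",
    "write_phylip",
    "write_partitions",
]

GAP_OPEN = 5.0
GAP_EXTEND = 1.0

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class GeneAlignment:
    """A multiple alignment of one element across individuals.

    Rows are equal-length strings over ``{A,C,G,T,N,-}``; ``ranges`` is
    populated by :func:`concatenate` with the per-element column spans.
    """

    element: str
    ids: list[str]
    rows: list[str]
    ranges: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, id_: str) -> str:
        return self.rows[self.ids.index(id_)]

    def subset(self, ids: list[str]) -> "GeneAlignment":
        return GeneAlignment(self.element, list(ids),
                             [self.row(i) for i in ids], dict(self.ranges))

    def ungapped(self, id_: str) -> str:
        return self.row(id_).replace("-", "")


@njit(cache=True)
def _gotoh(S, gap_open, gap_ext):  # pragma: no cover - exercised via wrapper
    """Affine-gap global alignment over a precomputed column-score matrix.

    Returns (path_a, path_b, length): aligned index pairs with -1 marking a
    gap. State 0=match, 1=gap in B (A advances), 2=gap in A (B advances).
    """
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    tb = np.zeros((3, n + 1, m + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gap_open - (i - 1) * gap_ext
        tb[1, i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -gap_open - (j - 1) * gap_ext
        tb[2, 0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal
            best = M[i - 1, j - 1]
            src = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = 2
            M[i, j] = best + S[i - 1, j - 1]
            tb[0, i, j] = src
            # X: gap in B, A advances
            o = M[i - 1, j] - gap_open
            e = X[i - 1, j] - gap_ext
            if o >= e:
                X[i, j] = o
                tb[1, i, j] = 0
            else:
                X[i, j] = e
                tb[1, i, j] = 1
            # Y: gap in A, B advances
            o = M[i, j - 1] - gap_open
            e = Y[i, j - 1] - gap_ext
            if o >= e:
                Y[i, j] = o
                tb[2, i, j] = 0
            else:
                Y[i, j] = e
                tb[2, i, j] = 2
    # choose end state; prefer match on ties
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = 1
    if Y[n, m] > best:
        best = Y[n, m]
        state = 2
    path_a = np.empty(n + m, dtype=np.int64)
    path_b = np.empty(n + m, dtype=np.int64)
    k = 0
    i, j = n, m
    while i > 0 or j > 0:
        prev = tb[state, i, j]
        if state == 0:
            i -= 1
            j -= 1
            path_a[k] = i
            path_b[k] = j
        elif state == 1:
            i -= 1
            path_a[k] = i
            path_b[k] = -1
        else:
            j -= 1
            path_a[k] = -1
            path_b[k] = j
        k += 1
        state = prev
    return path_a[:k][::-1].copy(), path_b[:k][::-1].copy(), best


def _profile(rows: list[str]) -> np.ndarray:
    """Column base-frequency profile (L, 4); gaps and N contribute nothing."""
    L = len(rows[0])
    prof = np.zeros((L, 4))
    for row in rows:
        for pos, ch in enumerate(row):
            idx = _BASE_INDEX.get(ch, -1)
            if idx >= 0:
                prof[pos, idx] += 1.0
    return prof / len(rows)


def _merge(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Align two alignment blocks profile-to-profile and re-gap their rows."""
    pa = _profile(rows_a)
    pb = _profile(rows_b)
    sa = pa.sum(axis=1)
    sb = pb.sum(axis=1)
    # E[pairwise score] between columns: +1 match, -1 mismatch, missing = 0
    S = 2.0 * (pa @ pb.T) - np.outer(sa, sb)
    path_a, path_b, _ = _gotoh(S, GAP_OPEN, GAP_EXTEND)
    out_a = ["".join(r[i] if i >= 0 else "-" for i in path_a) for r in rows_a]
    out_b = ["".join(r[j] if j >= 0 else "-" for j in path_b) for r in rows_b]
    return out_a, out_b


def pairwise_align(a: str, b: str) -> tuple[str, str]:
    """Global affine-gap alignment of two sequences under the module scores."""
    ra, rb = _merge([a], [b])
    return ra[0], rb[0]


def _edit_distance_matrix(seqs: list[str]) -> np.ndarray:
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            res = edlib.align(seqs[i], seqs[j], mode="NW", task="distance")
            norm = res["editDistance"] / max(len(seqs[i]), len(seqs[j]))
            d[i, j] = d[j, i] = norm
    return d


def align_gene_set(
    seqs: dict[str, str],
    element: str = "",
    guide=None,
) -> GeneAlignment:
    """Progressively align one gene across individuals.

    Merge order follows a UPGMA guide built on normalized pairwise edit
    distances (most-similar first) unless an explicit guide tree is given
    as nested tuples of ids. Deterministic for a fixed input order.
    """
    ids = list(seqs)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences to align")
    for k, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {k}")
    lens = [len(seqs[i]) for i in ids]
    if max(lens) - min(lens) > max(0.2 * min(lens), 10):
        raise ValueError("sequence lengths differ by more than 20%; "
                         "these are unlikely to be one homologous element")

    if guide is None:
        d = _edit_distance_matrix([seqs[i] for i in ids])
        if len(ids) == 2:
            order: tuple = (0, 1)
        else:
            Z = linkage(squareform(d, checks=False), method="average")
            nodes: dict[int, tuple] = {i: i for i in range(len(ids))}
            for k, (a, b, _, _) in enumerate(Z):
                nodes[len(ids) + k] = (nodes.pop(int(a)), nodes.pop(int(b)))
            order = nodes[len(ids) + len(Z) - 1]
    else:
        index = {id_: i for i, id_ in enumerate(ids)}

        def _map(t):
            return index[t] if isinstance(t, str) else tuple(_map(c) for c in t)

        order = _map(guide)

    def _build(node) -> tuple[list[int], list[str]]:
        if isinstance(node, (int, np.integer)):
            return [int(node)], [seqs[ids[int(node)]]]
        left, right = node
        li, lr = _build(left)
        ri, rr = _build(right)
        lr, rr = _merge(lr, rr)
        return li + ri, lr + rr

    got_idx, got_rows = _build(order)
    by_input = sorted(range(len(got_idx)), key=lambda k: got_idx[k])
    rows = [got_rows[k] for k in by_input]
    return GeneAlignment(element=element, ids=ids, rows=rows)


def concatenate(alignments: list[GeneAlignment]) -> GeneAlignment:
    """Append alignments column-wise, recording per-element column ranges."""
    if not alignments:
        raise ValueError("no alignments to concatenate")
    ref_ids = alignments[0].ids
    for aln in alignments[1:]:
        if set(aln.ids) != set(ref_ids):
            missing = set(ref_ids) ^ set(aln.ids)
            raise ValueError(f"id sets differ between alignments: {sorted(missing)}")
    ranges: dict[str, tuple[int, int]] = {}
    offset = 0
    parts: dict[str, list[str]] = {i: [] for i in ref_ids}
    for aln in alignments:
        for id_ in ref_ids:
            parts[id_].append(aln.row(id_))
        ranges[aln.element] = (offset, offset + aln.length)
        offset += aln.length
    rows = ["".join(parts[i]) for i in ref_ids]
    return GeneAlignment(element="concat", ids=list(ref_ids), rows=rows,
                         ranges=ranges)


def sum_of_pairs_score(aln: GeneAlignment) -> float:
    """Sum-of-pairs score of an MSA under the module's affine scheme.

    For each unordered row pair, columns where both rows are gapped are
    dropped, matches score +1, mismatches −1 (N scores 0), and each gap run
    costs open + (len−1)·extend.
    """
    total = 0.0
    n = len(aln.rows)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.rows[i], aln.rows[j]
            in_gap_a = in_gap_b = False
            for ca, cb in zip(a, b):
                if ca == "-" and cb == "-":
                    continue
                if ca == "-":
                    total += -GAP_EXTEND if in_gap_a else -GAP_OPEN
                    in_gap_a, in_gap_b = True, False
                elif cb == "-":
                    total += -GAP_EXTEND if in_gap_b else -GAP_OPEN
                    in_gap_b, in_gap_a = True, False
                else:
                    in_gap_a = in_gap_b = False
                    if ca == "N" or cb == "N":
                        continue
                    total += 1.0 if ca == cb else -1.0
    return total


# ---------------------------------------------------------------------------
# I/O


def read_fasta_alignment(path, element: str = "") -> GeneAlignment:
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return GeneAlignment(element=element, ids=ids, rows=rows)


def write_fasta_alignment(aln: GeneAlignment, path) -> None:
    with open(path, "w") as fh:
        for id_, row in zip(aln.ids, aln.rows):
            fh.write(f">{id_}\n")
            for i in range(0, len(row), 70):
                fh.write(row[i:i + 70] + "\n")


def read_phylip(path, element: str = "") -> GeneAlignment:
    """Read relaxed (whitespace-delimited, one line per taxon) PHYLIP."""
    with open(path) as fh:
        header = fh.readline().split()
        ntax, ncols = int(header[0]), int(header[1])
        ids, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            ids.append(name)
            rows.append(seq.replace(" ", "").strip().upper())
    if len(ids) != ntax or any(len(r) != ncols for r in rows):
        raise ValueError(f"{path}: PHYLIP header does not match contents")
    return GeneAlignment(element=element, ids=ids, rows=rows)


def write_phylip(aln: GeneAlignment, path) -> None:
    width = max(len(i) for i in aln.ids) + 2
    with open(path, "w") as fh:
        fh.write(f" {len(aln.ids)} {aln.length}\n")
        for id_, row in zip(aln.ids, aln.rows):
            fh.write(f"{id_:<{width}}{row}\n")


def write_partitions(aln: GeneAlignment, path) -> None:
    """RAxML-style partition file, 1-based inclusive column ranges."""
    with open(path, "w") as fh:
        for element, (start, end) in aln.ranges.items():
            fh.write(f"DNA, {element} = {start + 1}-{end}\n")
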