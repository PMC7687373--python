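"""Published per-gene summary statistics for the *Piranga* mitogenome survey.

Sixteen non-tRNA elements from 22 congeneric individuals (11 species × 2)
plus a *Cardinalis cardinalis* outgroup: alignment length, % identical
nucleotides and mean pairwise identity within the ingroup, ΔML
(free-vs-constrained gene-tree log-likelihood difference), ML-tree total
branch length, variable/total amino-acid residues, and relative
substitution rate vs CytB with its adjusted R². These printed values are
inputs for desk-scale analyses (e.g. the conservation regression); the
pipeline recomputes the same statistics from sequence data.
"""

from __future__ import annotations

from .genestats import GeneStats

__all__ = ["piranga_gene_stats", "PIRANGA_LENGTH_RANGE"]

#: Published total-genome length range (min, max, mean) across the 22
#: ingroup individuals, bp.
PIRANGA_LENGTH_RANGE = (16_782, 16_814, 16_804)

# element, align_length, pct_identical, pct_pairwise, delta_ml,
# subs_per_site, (variable, total) or None, relative_rate, rate_r2
_ROWS = (
    ("12S", 978, 90.4, 97.6, 1.673, 0.109, None, 0.323, 0.614),
    ("16S", 1604, 90.0, 96.9, 1.014, 0.116, None, 0.398, 0.699),
    ("ATP6", 684, 73.5, 92.1, 17.147, 0.307, (16, 227), 1.014, 0.780),
    ("ATP8", 168, 73.2, 91.9, 9.905, 0.298, (7, 53), 0.914, 0.609),
    ("CR", 1243, 65.5, 88.8, 1.808, 0.422, None, 1.344, 0.698),
    ("CO1", 1551, 77.1, 92.8, 2.576, 0.262, (9, 516), 0.888, 0.843),
    ("CO2", 684, 73.7, 91.4, 0.732, 0.303, (14, 227), 1.111, 0.833),
    ("CO3", 784, 75.6, 92.3, 3.241, 0.281, (11, 261), 0.869, 0.729),
    ("CytB", 1143, 75.3, 92.6, 4.985, 0.287, (33, 380), None, None),
    ("ND1", 978, 68.8, 89.4, 9.005, 0.355, (26, 325), 1.389, 0.874),
    ("ND2", 1038, 63.6, 88.3, 4.216, 0.398, (70, 346), 1.376, 0.833),
    ("ND3", 351, 68.1, 90.0, 3.261, 0.368, (16, 116), 1.495, 0.828),
    ("ND4", 1378, 70.4, 91.2, 11.035, 0.331, (45, 459), 1.124, 0.908),
    ("ND4L", 297, 73.1, 92.6, 3.525, 0.296, (8, 99), 0.883, 0.622),
    ("ND5", 1818, 70.6, 91.3, 2.229, 0.332, (84, 605), 0.974, 0.885),
    ("ND6", 519, 68.0, 90.8, 9.045, 0.372, (33, 172), 0.988, 0.764),
)


def piranga_gene_stats() -> list[GeneStats]:
    """The published per-element statistics as :class:`GeneStats` rows."""
    out = []
    for (el, length, ident, pair, dml, subs, var, rate, r2) in _ROWS:
        out.append(GeneStats(
            element=el, align_length=length, pct_identical=ident,
            pct_pairwise_identity=pair, subs_per_site=subs,
            var_residues=var, relative_rate=rate, rate_r2=r2,
            delta_ml=dml))
    return out
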