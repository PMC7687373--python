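# mitoconcord

Gene-tree/species-tree concordance analysis for congeneric mitochondrial
genomes.

A complete bird mitogenome is one non-recombining molecule, yet its 13
protein genes, two rRNAs and control region are routinely treated as
independent markers. This package reimplements, as a tested pipeline, the
comparative analysis behind that question for a genus-level songbird
dataset (11 *Piranga* species sampled twice, plus a *Cardinalis*
outgroup): extract every non-tRNA element from annotated mitogenomes,
align each element across individuals, compute per-gene divergence and
relative-rate statistics, infer maximum-likelihood gene trees, score each
gene tree's topological agreement with the concatenated-mitogenome tree
node by node, and quantify how much likelihood each gene sacrifices when
constrained to the mitogenome topology.

The core quantities, in the field's standard notation:

* **p-distance** — proportion of differing comparable sites between two
  aligned sequences, uncorrected for multiple hits.
* **relative rate** — the OLS slope of one gene's pairwise p-distances on
  CytB's, over all unordered ingroup pairs (intercept included), with
  adjusted R².
* **GTR+Γ likelihood** — Felsenstein pruning under the general
  time-reversible model with 4-category discrete-gamma rate variation;
  branch lengths in expected substitutions/site. Gene trees come from NNI
  hill-climbing from a neighbor-joining start, with nonparametric site
  bootstrap support.
* **concordance** — at each reference-tree node, a gene tree is
  *concordant* if it contains the same bipartition (at or above a
  bootstrap floor), *conflicting* if it contains a sufficiently supported
  incompatible bipartition, *uninformative* otherwise; tables are produced
  at BS ≥ 0 and BS ≥ 50.
* **ΔML** — log-likelihood of the free gene-tree search minus that of the
  same data constrained to the reference topology (branch lengths and
  model re-optimized), ≥ 0 up to optimizer tolerance.

A synthetic-data generator produces annotated ~16.9 kb genomes along a
known truth tree — published gene lengths, published relative-rate
multipliers, indels confined to the control region and spacers,
stop-free ORFs — so every stage of the pipeline is validated against
ground truth without downloading anything.

## Worked example

```sh
python analysis/01_simulate.py --seed 0          # 23 genomes + truth tree
python analysis/02_run_pipeline.py --seed 0      # full analysis
python analysis/03_published_stats.py            # desk statistics
python analysis/04_rate_recovery.py              # multi-seed recovery
```

`03_published_stats.py` regresses amino-acid conservation on nucleotide
conservation across the 13 protein genes of the published summary table
and prints:

```
OLS: slope=1.226, adjusted R^2=0.689, p=2.73e-04
conserved-residue range: 79.8-98.3%
```

— nucleotide and amino-acid conservation move together (adjusted
R² ≈ 0.69), and the most conserved protein (CO1) is ~98% invariant at the
residue level while the least conserved (ND2) is ~80%.

`04_rate_recovery.py` simulates each ≥1 kb element with its published
rate multiplier and reports the mean regression slope over 10 seeds, e.g.
ND2 (true multiplier 1.376) is recovered at ≈1.22 and 16S (true 0.398) at
≈0.42; every ≥1 kb gene lands within 15% of its generating value, which
is the regime where the slope is a faithful rate estimate.

`02_run_pipeline.py` leaves the full artifact set in `results/pipeline/`:
per-element FASTA and alignments, `<element>.tree.nwk` gene trees with
bootstrap supports, `concat.tree.nwk`, `gene_stats.tsv` (one row per
element: alignment length, % identical, % pairwise identity, ΔML,
substitutions/site, variable residues, relative rate, adjusted R²),
`concordance_bs0.tsv` / `concordance_bs50.tsv` (per node: concordant /
conflicting / uninformative gene-tree counts) and a plain-text annotated
tree rendering. On the synthetic data the concatenated tree matches the
truth topology and raising the support floor from 0 to 50 never increases
a node's concordant count.

The same stages are exposed as a CLI (`mitoconcord run-all`, `extract`,
`align`, `genetree`, `concord`, `deltaml`, `simulate`, `compare`) for use
on any annotated mitogenome set.

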