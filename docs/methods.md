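# Methods

`mitoconcord` reimplements, as one tested pipeline, the comparative
analysis of a congeneric mitogenome survey: per-gene divergence and
relative-rate statistics, maximum-likelihood gene trees, node-wise
concordance of gene trees against the concatenated-mitogenome tree, and
constrained-topology likelihood (ΔML) tests. A synthetic-data generator
reproduces the statistical structure of the survey so that every stage can
be validated against known ground truth without downloading sequence data.

## Genome handling and annotation projection

Mitogenomes are held as plain sequences plus feature lists with 0-based
half-open coordinates (GenBank's 1-based inclusive convention is converted
at the I/O boundary); a feature with `start > end` spans the circular
origin. Feature names are folded to canonical element labels through a
synonym table (COX1 → CO1, COB → CytB, D-loop → CR, …); tRNAs are parsed
and carried through I/O but excluded from all downstream statistics and
trees.

Annotation projection transfers a fully annotated reference's features
onto an unannotated assembly in three steps:

1. one global pairwise alignment of the two genomes. At ~17 kb × ~17 kb we
   use edlib's unit-cost alignment path (exact, linear memory) rather than
   an affine-gap DP over the full matrix; at the >85% identity typical of
   congeners the resulting coordinate map is the same.
2. per-feature boundary refinement: tied optimal alignments place gaps at
   feature boundaries arbitrarily, so each projected feature is re-located
   by a semi-global affine alignment (match +1, mismatch −1, gap open −5,
   extend −1; free end gaps on the genomic window only) of the reference
   feature against a ±30 nt window. Gap costs above the mismatch cost stop
   boundary bases from being shaved off.
3. boundary snapping: where two features abut in the reference, a
   non-coding (spacer/CR) boundary is snapped to its conserved neighbor —
   never the other way round — and protein features are nudged ≤6 nt to
   preserve the reference reading-frame length mod 3 (incomplete stop
   codons, completed by polyadenylation in vivo, are tolerated as 1–2 nt
   partial codons).

On synthetic genomes with indel-bearing control regions and spacers this
recovers every generating coordinate exactly (tested across individuals
and seeds); on real data, boundaries of non-coding elements adjacent to
indels are accurate up to the inherent ambiguity of gap placement.

## Alignment

Per-gene alignments use a deterministic progressive aligner: normalized
pairwise edit distances define a UPGMA guide order, profiles are merged by
affine-gap Needleman–Wunsch (scores as above) with fixed tie-breaking, and
`N` never scores as match or mismatch. Congeneric mitochondrial genes are
nearly indel-free outside the control region, so determinism was favored
over aligner sophistication; the pairwise special case is verified against
an independent affine-gap implementation. Ungapping any output row always
reproduces its input sequence. Concatenation records per-element column
ranges and can emit a RAxML-style partition file.

## Per-gene statistics

* **% identical nucleotides** — share of columns in which every selected
  row carries the same unambiguous base.
* **% pairwise identity** — mean over unordered row pairs of
  matches/comparable sites, sites with gap or `N` in either row excluded.
* **p-distances** — uncorrected proportion of differing comparable sites.
  Divergences within a genus are small enough that multiple-hit
  corrections are second-order; a Jukes–Cantor-corrected variant is
  available via a flag.
* **amino-acid variability** — each row is ungapped and translated under
  the vertebrate mitochondrial code (TGA = Trp, AGA/AGG = stop); a
  trailing partial codon and the terminal stop are dropped, an internal
  stop is an error (it indicates a mis-projected frame). Variable/total
  residue counts are per codon column, `X` ignored.
* **relative rate** — OLS (intercept included) of one gene's ingroup
  pairwise p-distances on the reference gene's (CytB by convention);
  reported as slope and adjusted R². The statistics default to the
  ingroup; the outgroup can be included by flag.
* **substitutions/site** — reported as the total branch length of the ML
  gene tree. This is an interpretation: the survey's column of that name
  is not defined in its source, and its values exceed any pairwise
  distance implied by the identity columns, which total tree length does
  naturally.
* **conservation regression** — across protein genes, OLS of % conserved
  residues (100·(1 − variable/total)) on % identical nucleotides. On the
  published 13-row table this gives slope 1.226, adjusted R² 0.689,
  p = 2.7·10⁻⁴.

## Likelihood model and tree search

Likelihoods use GTR+Γ: six exchangeabilities (GT fixed at 1 for
identifiability), stationary frequencies π, and discrete-gamma rate
variation with 4 equal-probability categories whose rates are
mean-normalized category medians (K = 1 reduces exactly to the
rate-homogeneous model). The generator matrix is scaled to one expected
substitution per site so branch lengths are substitutions/site; its
eigensystem is computed through the π-symmetrized form for stability.
Felsenstein pruning runs over unique site patterns with per-pattern
scaling; gaps and `N` are missing data (partial likelihood 1). The
implementation is tested against an explicit sum over all internal-state
assignments on trees of up to 5 taxa (10⁻⁸ agreement), against the
two-taxon Jukes–Cantor closed form, and for invariance under rerooting
and tip reordering.

The ML search starts from neighbor joining on p-distances (ties broken by
lowest index, negative branches clamped to zero) and alternates:

* **branch lengths** — bounded Brent per branch against cached directional
  partials, sweeping to a 0.01 log-unit tolerance; a sweep that fails to
  improve is rolled back, so progress is monotone.
* **model parameters** — Powell search over (log exchangeabilities, log
  frequency ratios, log α); Powell's conjugate directions matter because
  exchangeabilities are strongly correlated.
* **topology** — first-improvement NNI sweeps in deterministic edge order;
  each candidate is scored with its focal branch re-optimized against
  cached partials, so one candidate costs O(patterns) rather than a full
  tree pass.

The search stops when an NNI sweep gains ≤0.01 log units (default cap 20
rounds), then branch lengths and parameters are polished to a joint 5·10⁻⁴
tolerance. ΔML optimizes the constrained topology to the same tolerance,
which is what makes the self-constraint case return 0 within 10⁻³.

Bootstrap support is the standard nonparametric site bootstrap with a
reduced per-replicate search: resampled pattern weights, branch-length
re-optimization from the full-data ML tree under the full-data model, and
one NNI sweep; support is the percentage of replicates containing each
bipartition of the full-data tree. A degenerate corner follows from the
definition: a strictly invariant alignment yields the identical dataset in
every replicate, so all supports are trivially equal — the no-signal
behavior of the estimator is therefore characterized on iid random data,
where mean internal support stays low. Replicate counts default to the
survey's 200 (gene) and 500 (concatenated); the analysis scripts and
acceptance run use 10–25 replicates, which is enough to exercise the
machinery and calibrate nothing.

The concatenated analysis is unpartitioned under a single GTR+Γ; the
original survey does not state a partition scheme, and this choice is
documented rather than guessed.

## Concordance scoring

For every internal node of the reference tree (rooted on the outgroup),
each gene tree is scored concordant (contains the identical bipartition
with support at or above the floor), conflicting (contains a sufficiently
supported incompatible bipartition; two splits are compatible iff one of
the four side intersections is empty), or uninformative. Edges without a
support value pass a 0% floor and fail any positive floor. Tables are
emitted at floors 0 and 50 by default, and counts always sum to the number
of gene trees.

Scoring can collapse the two individuals per species to one species-level
tip: a gene-tree bipartition maps to species level only when no species
straddles both sides, so species-level non-monophyly makes that split
unusable for either agreement or disagreement. With collapsing on, the
23-tip reference yields the 10 species-level nodes of the original
figure. The node separating the outgroup from the whole ingroup is
contained in every gene tree and scored concordant at any floor (its only
edge is the outgroup tip edge, which carries no bootstrap value).

## Synthetic-data generator

The generator emulates the survey's observables:

* 23 individuals: 11 ingroup species sampled twice (cherries) plus one
  outgroup; the ingroup is a ladder over the cherries so node depths range
  from shallow to deep, exercising low-signal nodes.
* 16 non-tRNA elements at the published alignment lengths, with
  branch-rate multipliers set to the published relative-rate column
  (CytB = 1); 100 nt spacers stand in for tRNA clusters, bringing genomes
  to ~16.9 kb in the standard avian order.
* GTR+Γ with avian-mitochondria-like composition (A 0.30, C 0.32, G 0.12,
  T 0.26) and a strong transition bias (AG 8, CT 12).
* indels only in the control region and spacers (Poisson 0.5 events per
  element copy, geometric lengths of mean 2 nt), spreading total genome
  lengths by a few tens of bp across individuals, as in the real data.
* protein elements stay translatable where it matters: tip branches draw
  codons from the exact 64-codon transition distribution conditioned on
  non-stop outcomes. Internal branches evolve unconditionally — ancestors
  are never translated, and conditioning them would depress protein
  substitution rates. No selection model beyond this.

Two generator settings deserve justification. The published relative rate
is itself a p-distance regression slope, so for the generator's multiplier
column to be meaningful ground truth the simulation must keep p-distances
effectively linear in evolutionary distance. Two effects otherwise bias
slope recovery downward: multiple-hit saturation (worse under strong rate
heterogeneity) and classical regression dilution from binomial sampling
noise in the CytB predictor (worse when true pairwise distances span a
narrow range). The defaults — Γ shape α = 4 and a ladder geometry with
0.014 steps and 0.008 species stems — keep the joint bias within ~11% for
the fastest ≥1 kb gene while matching the published identity levels well
(realized CytB mean pairwise identity 93.0% vs 92.6% published; identical
columns 74.2% vs 75.3%). Within-species divergence is 0.004
substitutions/site and the outgroup stem 0.12, giving an outgroup roughly
as distant as in the real data.

What the generator does not emulate: coalescent gene-tree heterogeneity
(the survey discusses incomplete lineage sorting but performs no
coalescent analysis — per-gene discordant topologies can only be supplied
explicitly as alternative truth trees), selection, base-compositional
heterogeneity among lineages, and sequencing error. Passing recovery tests
on these simulations therefore shows the estimators are correct under the
model they assume, not that real data meet those assumptions.

## Numerical choices and degenerate inputs

Branch lengths are bounded to [10⁻⁸, 10]; NJ's negative branches are
clamped to zero before likelihood work. Pattern likelihoods are clipped at
10⁻³⁰⁰ before logs. Identical-sequence alignments give a zero-length tree
whose log-likelihood equals n·Σ f log f over observed base frequencies.
Alignment inputs whose lengths differ by more than 20% (plus a 10 nt
absolute slack so very short inputs behave) are rejected as unlikely
homologs. All randomness flows from explicit seeds; reruns with the same
inputs and seed produce byte-identical artifacts (stage timings go to a
separate log file for exactly this reason).

## Problem sizes in the shipped runs

The analysis scripts and the acceptance run use the full study-scale
synthetic dataset (23 individuals, 16 elements, 15.2 kb concatenation)
with 10–25 bootstrap replicates; the test suite uses miniature datasets
(9–11 tips, 4 elements) for end-to-end checks and the full scale where
the claim depends on it (rate recovery, concatenated-topology recovery,
species-level node counts). Replicate counts are the only quantity scaled
below the survey's; all statistical claims are about means over ≥10 seeds
where seeds matter.

## Known limitations

* NNI-only topology search can in principle stop in a local optimum that
  SPR-capable software escapes; on congeneric mitochondrial data the
  signal is strong and the truth topology is recovered in the shipped
  simulations.
* ΔML magnitudes depend on the optimizer and model details; they are
  comparable within a run, and the published decimals serve as reference
  points, not targets.
* The reduced bootstrap search (NNI refinement from the full-data tree)
  slightly favors the full-data topology, a bias shared by rapid-bootstrap
  heuristics.
* Uncorrected p-distance slopes systematically understate branch-rate
  ratios once divergence saturates; the JC-corrected flag exists for users
  who need unbiased ratios at deeper scales.
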