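# Methods

## Model and criterion

An unrooted binary tree on *N* taxa has 2*N*−3 branches with non-negative
lengths *x* (substitutions/site, or whatever unit the input distances use).
The path-incidence matrix *A* (one row per unordered leaf pair, one column
per branch) maps lengths to patristic distances, *E*(*D*) = *Ax*.  Given a
distance matrix with observed set Ω and missing set of size *M*, branch
lengths on a fixed topology minimise

RSS(x) = Σ<sub>(i,j)∈Ω</sub> w<sub>ij</sub> (D<sub>ij</sub> − (Ax)<sub>ij</sub>)²,
w<sub>ij</sub> = D<sub>ij</sub><sup>−m</sup>, subject to x ≥ 0.

*m* = 0 (OLS) is the default; *m* = 1 or 2 are available but OLS shows the
least topological bias in least-squares tree fitting.  An observed zero
distance with *m* > 0 would divide by zero; such pairs fall back to unit
weight with a warning.  The solve is Lawson–Hanson active-set NNLS on the
√w-scaled design — exact and deterministic.

Missing pairs contribute nothing to RSS, so at any fit the imputed value of
a masked pair is defined as the fitted patristic distance (its residual is
zero by construction).  The joint problem — over topologies and missing
values — is: minimise the masked RSS of the best tree.

### Identifiability and the non-unique case

If the observed design *A*<sub>Ω</sub> is column-rank-deficient the optimum
is a face, not a point.  The canonical example is a missing distance
between two taxa that end up as sisters: the four-taxon algebra (five path
equations in five unknowns) has determinant zero there, and in general only
the *sums* pendant+internal are pinned, leaving the imputed value a range.
The fit then reports `unique=False`, returns the **minimum-tree-length**
point of the optimal set (a linear program over {x ≥ 0 : A<sub>Ω</sub>x =
fitted values}; the LS criterion has no preference inside the set, and the
shortest-tree representative is the same tie-break used between equal-RSS
topologies), and can report, per masked pair, the exact [lo, hi] interval
of equal-RSS imputations (two more LPs; off by default for speed).  The
rank test is conservative: a rank-deficient design whose optimum happens to
be pinned by the non-negativity boundary would still be flagged.

The minimum-evolution criterion (smallest TL) is computed only as a
diagnostic.  It is unsuitable for imputation: among equal-RSS fills it
always prefers the smallest distance, to the point of assigning 0 to a
masked sister pair.

## Search strategy

1. **Connectivity.**  Imputation is feasible only if the graph whose edges
   are the observed pairs is connected (checked with sparse connected
   components; errors name the isolated groups).
2. **Initial fill.**  Missing D<sub>ij</sub> ← min<sub>k</sub>
   (D<sub>ik</sub> + D<sub>jk</sub>) over taxa k observed against both — an
   upper-bound-flavoured start under the triangle inequality.  If no common
   neighbour exists, the shortest path through observed edges is used.
3. **EM-like alternation.**  Build a tree from the filled matrix (NJ),
   fit branch lengths on observed pairs, replace missing entries with
   patristic values, repeat.  The loop keeps the best fit seen and stops
   when an iteration fails to improve it by `tol` (1e-10), so the recorded
   RSS trajectory is non-increasing; oscillation is cut at the best point.
   Fast, but can stall in local optima across topologies.
4. **Global search.**  For *N* ≤ 8 (configurable), all (2*N*−5)!!
   topologies are enumerated (stepwise addition) and fitted; ties on RSS
   break toward smaller TL, then enumeration order.  For larger *N* the
   missing values are optimised directly: the objective of candidate fill
   *v* is the masked RSS of the tree built from the completed matrix
   (NJ + OLS-NNI inside the objective).  *M* = 1 uses bounded Brent search
   on [0, 2 × fill]; *M* > 1 uses Nelder–Mead (absolute f-tolerance 1e-10,
   x-tolerance 1e-8, ≤ 2000 iterations) from 10 starts: the fill itself,
   then multiplicative U[0.5, 1.5] jitters of it.  Candidate values are
   clamped at 0; builder failures score +∞.  All randomness flows from one
   `numpy` generator seeded by the caller, so runs are reproducible
   bit-for-bit.  The restart count and jitter law are this package's own
   choices — cheap insurance against the local optima the EM path exhibits.

### Tree building

Neighbor joining (Studier–Keppler Q-criterion, lowest-index tie-break)
seeds the topology; negative branch estimates at a join are clamped to zero
with the deficit moved to the sister branch.  OLS-guided NNI hill climbing
then evaluates both rearrangements at every internal branch with the masked
NNLS fit and accepts the best strict improvement per sweep until a local
optimum; RSS never increases and termination is guaranteed.  This NJ+NNI
combination deliberately replaces balanced minimum-evolution programs
(FastME-style): it keeps topology search, branch lengths and imputation on
one coherent least-squares criterion, and on matrices of the kind handled
here the two approaches return the same trees.

## Sequence distances

Pairwise deletion throughout: a column counts for a pair only if both
sequences carry an unambiguous A/C/G/T (ambiguity codes are treated as
gaps).  A pair with zero shared columns is MISSING (this is the missing-gene
scenario).  Models: p-distance, JC69, K80, TN93 — standard closed forms,
TN93 with per-pair empirical base frequencies and both transition classes.
A non-positive logarithm argument (saturation) also yields MISSING rather
than a clipped value, so saturated pairs enter the imputer exactly like
structurally missing ones.  The TN93 estimator here is the standard
pairwise closed form, not a composite simultaneous estimate across all
pairs.

## Simulation design (and what it does not show)

The gene-deletion experiment uses, by default: a balanced 24-taxon true
tree with branch lengths U(0.5, 1.5) × 0.05 substitutions/site; 10
gap-free genes of 300 bp evolved independently under HKY85 (matrix
exponential of the exact generator, normalised to one expected substitution
per site) with per-gene κ evenly spaced on [2, 6.5] and base frequencies
(A, C, G, T) = (0.3, 0.2, 0.2, 0.3); per-taxon deletion of *g* of the 10
genes, uniformly without replacement, replaced by gap blocks; TN93
pairwise-deletion distances; 20 replicates per deletion intensity.  The
κ spacing, frequencies, branch-length law and gene length are this
package's declared choices where the experimental description fixes only
ranges; replicate counts and gene lengths are desk-scale so the whole sweep
runs in minutes on one core, which is why the evaluation is trend- and
property-based rather than a point reproduction of full-scale recovery
percentages.

Pigeonhole structure: with *G* = 10 equal genes, two taxa each retaining
≥ 6 genes must share ≥ 2, so *g* ≤ 4 produces no missing distances;
missing pairs appear from *g* = 5 and dominate by *g* = 9.

At *g* = 9 each taxon keeps a single gene, so the observed-pair graph
decomposes into per-gene cliques and is disconnected with probability ≈ 1 —
no imputation method can bridge taxa with no measured path between them.
The harness then builds the tree on the **largest connected component**
(when it has ≥ 4 taxa) and scores a true-tree bipartition as recovered only
if its restriction to that component is non-trivial and present in the
estimate; replicates whose largest component is smaller score 0.  Recovery
consequently collapses at *g* = 9, which is the honest behaviour of a
distance method on fragmented data.

Not simulated: indels (genes are gap-free, so alignment is exact and the
imputation method is isolated from alignment error), rate heterogeneity
across sites, and likelihood-based reconstruction.  Passing the simulation
tests therefore says nothing about alignment-induced error on real data.

## Numerical choices

- Square-matrix symmetry tolerance on input: 1e-9; rank tolerance 1e-8;
  branch lengths below 1e-12 snapped to 0.
- NNI accepts only strict RSS decreases (> 1e-12), steepest-descent order.
- Exhaustive enumeration capped at N = 8 (10395 topologies at N = 8);
  beyond that the optimizer path is used.
- `mask_random` draws uniformly among masks by rejection until the observed
  graph stays connected.
- Degenerate inputs: N < 3 rejected; polytomies accepted only for
  Robinson–Foulds comparison (they just induce fewer bipartitions);
  missing diagonal entries are invalid.

## Known limitations

- The simplex path is slow when *M* runs into the dozens; the EM path is
  the practical route there and is what the experiment harness uses
  (NJ inner builder, one final NNI refinement pass).
- The non-uniqueness flag is conservative (see above).
- NJ + NNI is a local search; with many missing distances the imputed
  optimum is only as good as the builder's topology.
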