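# Methods

`trimevol` re-implements, as one tested library, the comparative-genomics
workflow used to characterise the fish TRIM (tripartite-motif) gene
repertoire: architecture classification, hypervariability profiling,
positive-selection inference on the B30.2 domain, recombination-aware
segmentation, and MHC-neighbourhood enrichment. This note records the
models, the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that matter.

## Codon substitution model

Selection inference uses the Goldman–Yang codon model with HKY85
exchangeabilities over the 61 sense codons of the universal code (stop
codons excluded from the state space). For codons *i → j* differing at one
position, the instantaneous rate is

q_ij ∝ π_j · κ^[transition] · ω^[nonsynonymous],

with κ the transition/transversion ratio and ω = dN/dS. Multi-nucleotide
changes have rate zero. Equilibrium frequencies π are F3x4 — products of
position-specific nucleotide frequencies estimated from the alignment —
by default (F61 and uniform are options); F3x4 matches the common default
of codon-model software and keeps the simulator and the fitter on the same
model. Frequencies are floored at 1e-8 and renormalised so the matrix stays
reversible when a nucleotide is unobserved at some codon position.

Site models: M0 (one ω), M1a (ω0 < 1, ω1 = 1), M2a (adds ω2 ≥ 1), M7
(ω ~ beta(p, q) on (0,1)) and M8 (beta plus an ωs ≥ 1 class). The beta is
discretised into 10 equal-probability categories represented by their
category means, the conventional treatment. All classes of a mixture share
one time scale: rate matrices are normalised by the mixture-averaged
substitution rate, so a branch length is the expected number of
substitutions per codon for a random site and high-ω classes genuinely
evolve faster.

### Likelihood and optimisation

Per-site likelihoods come from Felsenstein pruning over the 61 states, run
for all ω classes in one batched pass with per-node rescaling against
underflow; identical alignment columns are collapsed into weighted
patterns. Transition matrices use the symmetrised eigendecomposition of the
reversible generator, so P(t) for all branches of a tree is a single
batched matrix product.

The tree topology is fixed: a user-supplied newick, or a neighbor-joining
tree built on Jukes–Cantor-corrected nucleotide distances. Relative branch
lengths are kept and one global scale is re-optimised jointly with the
substitution parameters for each model — a deliberate trade of per-branch
optimisation for desk-scale runtime; with topology and relative lengths
fixed, ω-class estimates are insensitive to this simplification at the
simulation scales used here.

Optimisation is box-constrained L-BFGS-B on log/logit-transformed
parameters (κ and scale on log scale; proportions by stick-breaking logits;
ω0 by logit; ω_pos = 1 + exp(x)), ftol 1e-11, with seeded multi-start
jitter (3 starts by default; the large simulation studies use one start
plus chained initialisation, which proved sufficient there). When an
alternative model is initialised from its nested null fit, one extra start
is placed at an exact boundary embedding of the null solution (p_pos ≈ 0,
ω_pos ≈ 1). This guarantees lnL(alt) ≥ lnL(null) up to ~1e-6 even when the
truth lies on the boundary, which keeps the LRT statistic non-negative;
residual negative 2ΔlnL below 1e-4 is clipped to zero with a warning.

### Tests and site identification

Nested pairs (M0–M1a, M1a–M2a, M7–M8) are compared by 2ΔlnL against a
chi-square with df equal to the difference in free parameter counts (2 for
both M1a–M2a and M7–M8). Because the null lies on the boundary of the
alternative, the chi-square reference is conservative; the type-I error of
the M1a–M2a test measured on null simulations is below the nominal level.

Positively selected sites are identified by empirical Bayes, flagged at
posterior > 0.95 (strict). NEB evaluates class posteriors at the MLEs. BEB
for M2a integrates over the standard 10-point grid prior: p0, p1 on the
triangle grid (equal weight on feasible midpoint pairs, approximating a
uniform Dirichlet), ω0 uniform on (0,1), ω_pos uniform on (1,11), with κ
and branch scale fixed at their MLEs. For M8 the default is NEB; the
optional M8 "BEB" integrates over the p0 and ω_pos grids with the beta
shape fixed at its MLE, and is labelled as such in output — the full
M8 grid adds little at these data sizes and is not published in enough
detail to pin down.

## Recombination segmentation

Breakpoints are sought by comparing a single-phylogeny fit with
segmented-phylogeny fits under the small-sample corrected AIC,
AICc = −2lnL + 2k + 2k(k+1)/(n−k−1), with n the number of nucleotide
columns and, per segment, k = (2·taxa − 3) branch lengths + κ + gamma
shape. Each segment gets its own NJ tree (JC distances) scored under HKY85
with 4 discrete-gamma rate categories (category means of an
equal-probability discretisation), optimising κ, the gamma shape and a
branch scale by Nelder–Mead.

The search is a greedy forward scan on a codon grid (step 3, minimum
segment 10 codons): each round adds the candidate breakpoint that most
improves total AICc and stops when no candidate improves it. This replaces
a genetic-algorithm search with a deterministic procedure adequate for
single- to few-breakpoint histories; large candidate sets are screened
coarsely (every 4th grid point) and refined around the best coarse hit.
Because one extra segment costs ~2·(2n−1) AICc units, spurious breakpoints
on non-recombinant alignments are rare (≤10% of null scans at the
simulation scale used in the tests). Accepted segments can be re-tested
for selection independently (M1a–M2a and M7–M8 per segment), with
positive-site coordinates mapped back to whole-alignment codons — an
independent per-segment treatment rather than a joint partitioned fit with
synonymous-rate variation, which is out of scope.

## Entropy profiling

Column-wise Shannon entropy is computed in bits over the 20 amino acids —
with the hypervariability threshold at 2, only the base-2 reading is
natural (maximum log2(20) ≈ 4.32). Gaps and ambiguity codes (X, B, Z) are
excluded from the frequency denominator; columns above the gap-fraction
threshold (default 0.5) are masked and reported as undefined, never as 0.
Hypervariable calls use strict H > 2, so a perfectly uniform 4-state column
(H = 2 exactly) is not hypervariable. Plug-in entropy is biased downward at
small counts; the tests bound this empirically rather than correcting it,
matching how the published profiles were computed.

## Architecture classification

TRIM classes I–IX are keyed on C-terminal domain content downstream of the
RING/B-box/coiled-coil module, from a canonical lookup table shipped as
editable package data (`data/trim_classes.tsv`). RBCC completeness is
recorded as flags (`missing_RING`, `missing_BBOX`, `missing_CC`) without
blocking classification, since RING or B-box loss is a recurrent event in
fish; proteins with neither RING nor B-box are non-TRIM, and B30.2-only
proteins are flagged rather than inflating class-IV counts. Architectures
outside the table are flagged `novel_combination`; three gain patterns are
named specifically (C-terminal chromodomain, C-terminal RanBD+cyclophilin-A,
and RING–TM–B30.2). Coiled-coils are treated as annotated tokens, not
predicted from sequence. Truncated proteins are paired to their most
similar full-architecture relative ("like" co-orthologue convention) at a
default identity threshold of 0.7 (configurable; ties break to the
lexicographically smallest id and are reported).

## Neighbourhood enrichment

Marker neighbourhoods are ±5 Mb windows (the size of the MHC proper)
around each marker, clipped to chromosome ends and merged. A gene is inside
iff its start coordinate falls in a merged interval (a midpoint rule is
exposed as an option; the published analysis does not define
partial-overlap handling). Tandem runs of same-family genes with
inter-gene gaps ≤ 500 kb (configurable; no published value) collapse to one
occurrence at the cluster midpoint, to avoid pseudo-replication from recent
duplications. The test is a Pearson chi-square on the 2×2 table of
family-vs-other × inside-vs-outside, df = 1, without continuity
correction — the uncorrected statistic reproduces the published p = 0.0035
on the printed genome-wide counts, the corrected one does not. When
collapsing, occurrences are contrasted against raw gene totals, mirroring
the published table construction (62 occurrences vs 24,147 genes).
Coordinates are 0-based half-open internally; 1-based input is accepted
with a dialect flag.

## Synthetic data

The generator produces every input the pipeline consumes:

- **Codon alignments** evolved on a phylogeny under a mixture-ω regime by
  exact matrix-exponential sampling along each branch (no Gillespie
  simulation): site classes i.i.d. from the regime proportions, root states
  from π, no indels, no rate variation beyond the ω mixture. Class labels
  are drawn from a dedicated stream keyed by (n_codons, proportions), so
  the true-class metadata is invariant to the substitution seed; replicate
  studies pass an explicit `class_seed` to vary it.
- **Recombinant alignments** concatenate per-tree simulations over a shared
  leaf set; breakpoints are a function of the segment lengths only.
- **Genome annotations** with uniformly placed background genes and
  tandemly clustered families; a designated family's cluster anchors are
  placed inside marker neighbourhoods with probability
  f·L_in/(f·L_in + L_out), so factor 1 is exactly uniform (giving a
  calibrated null for the chi-square) and factor 0 forbids the family
  inside. The example layout is zebrafish-scale: 25 chromosomes × 60 Mb,
  merged neighbourhoods covering ~24% of the genome (the share observed for
  the real marker set), 2,000 background genes and a 50-gene focal family.
- **Domain tables** realising architecture strings as ordered,
  non-overlapping intervals with plausible domain lengths.

What the generator does *not* emulate — alignment error, indels,
saturation, rate heterogeneity beyond the ω mixture, gene conversion,
assembly artefacts — bounds what green tests show: they validate the
estimators under their own model assumptions, not robustness to real-data
violations of them.

## Simulation scales and reproducibility

The statistical checks use desk-scale designs chosen to keep the full suite
comfortably runnable on one CPU: LRT type-I error over 50 null replicates
(12 taxa, 200 codons), power and parameter recovery over 20 selection
replicates (24 taxa, 400 codons, total tree length ≥ 5, ω_pos = 4,
p_pos = 0.15), breakpoint recovery over 20 single-switch replicates
(200 codons, switch at codon 100) and 20 null scans, and chi-square
calibration over 500 synthetic genomes. `scripts/acceptance.py` re-runs
the same designs at moderately reduced replicate counts (reported in its
output as `n`). All randomness flows from explicit integer seeds; fits are
deterministic given their options.

## Known limitations

- Branch lengths are scaled, not individually re-optimised, under each
  site model; on real data with a poor starting tree this can bias κ and
  the scale (not usually the ω-class ranking).
- The chi-square reference for boundary LRTs is conservative; no
  chi-bar-square mixture correction is applied (the published analyses used
  the same convention).
- The greedy breakpoint scan evaluates one added breakpoint per round and
  can miss closely spaced exchanges that only pay off jointly.
- BEB for M8 is partial (beta shape fixed at the MLE); M8 site lists
  default to NEB.
- The enrichment test treats genes as independent units; collapsing
  mitigates but does not remove spatial dependence of clustered families.
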