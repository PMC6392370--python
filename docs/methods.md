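# Methods

This note records the models, conventions and design choices behind
`barcodeval`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open decisions fell.

## Distance model

Pairwise distances use the Kimura 2-parameter (K80) model. For two aligned
rows, sites where either row carries a gap, `N` or an IUPAC ambiguity code
are excluded pair by pair (*pairwise deletion*). Over the remaining
`n_compared` sites, `P` is the transition proportion (A↔G, C↔T) and `Q`
the transversion proportion, and

d = −½ ln((1 − 2P − Q) √(1 − 2Q)).

Pairwise deletion was chosen over complete deletion because
length-variable spacers (ITS/ITS2) would otherwise lose most of their
columns to a few indel-rich rows; it is also the common choice in
barcoding practice. When the logarithm's argument is non-positive
(saturation) the pair is recorded as *undefined* and excluded from every
mean/range with a warning — no ceiling value is fabricated. Identical rows
return exactly 0 (no floating-point residue). In the equal-substitution
limit (P = p/3, Q = 2p/3) the formula reduces to the Jukes–Cantor
distance, which the tests verify to 1e-12.

## Site statistics

A *variable* site has ≥ 2 distinct unambiguous bases among its non-gap,
non-ambiguous states; a *parsimony-informative* site additionally needs
two such bases in ≥ 2 rows each. Variation consisting only of gaps or
ambiguity codes does not count — indels are tabulated separately, one
event per distinct `(start, end)` gap run across rows, because identical
shared runs plausibly reflect a single mutational origin (counting per row
would inflate events in well-sampled species). Terminal gap runs count
like internal ones. All reported percentages use a single rounding rule —
half-away-from-zero to one decimal — so printed tables are reproducible
exactly.

The *standard exclusion* filter removes outgroups and species sampled only
once before summary statistics and distance partitioning. The same ≥ 2
individuals rule defines the *evaluable* species set that forms the
denominator of every resolution percentage, so all criteria are compared
on identical footing.

## Identification criteria

* **Distance gap** — per species, `min_inter > max_intra` with *strict*
  inequality (a tie fails). Outgroups contribute no distances anywhere;
  the open question of whether a species' minimum interspecific distance
  should include outgroup comparisons was resolved as *no* — outgroups
  serve tree rooting only.
* **Tree-based monophyly** — a species passes when some node's descendant
  tip set equals exactly the species' tips, evaluated on the
  outgroup-rooted tree; for trees without outgroups the unrooted analog
  (either side of a branch) is used. Bootstrap support is available as an
  annotation but never enters the criterion.
* **Best match** — leave-one-out nearest-neighbor identity on the aligned
  matrix (matches / compared unambiguous sites). A heuristic local aligner
  is deliberately not re-implemented: the criterion depends only on the
  identity-ranked top hit, and at the dataset sizes this analysis targets
  (~10²) the exhaustive computation is exact and fast. A rank-1 tie
  containing any heterospecific sequence fails the species — the strict
  reading of "top hit of only a conspecific individual".

## Tree inference

NJ is the exact Saitou–Nei algorithm with the rate-corrected branch-length
formulas, negative estimates clamped to zero, a final three-point solve,
and deterministic tie-breaking (lowest index pair in agglomeration order).
It recovers additive matrices exactly (verified to 1e-9 on random trees).

MP and ML searches start from the NJ topology and hill-climb by
nearest-neighbor interchange, accepting strict improvements until a full
sweep is quiet; random-restart sweep orders (and light random starting
perturbations) are seeded, so the best-of-restarts score is reproducible
and monotone in the restart count. This intentionally does not replicate
the black-box heuristics of desktop phylogenetics suites — the search is
simple, deterministic and testable, and on strong-signal data recovers the
generating topology.

Parsimony uses Fitch counting on bitmask state sets; gaps/N/ambiguity are
missing data (any compatible state at no cost), which makes the score
root-invariant and equal to the exhaustive minimum (tested by brute force
on small instances). Polytomies are folded child-by-child, i.e. scored as
an arbitrary resolution.

Likelihood uses Felsenstein pruning under equal-frequency K80 with
analytic transition probabilities (rate matrix normalized to one expected
substitution per site per unit branch length), site-pattern compression,
and stationary frequencies ¼. Branch lengths are optimized one at a time
by bounded scalar search (tolerance 1e-6, bounds [1e-9, 10]), κ likewise
on [0.05, 100]; cycles of (κ, branches, NNI) stop when the gain is
< 1e-4 nats or after 20 cycles. K80 is the only model on purpose: it
matches the distance model, and model selection is out of scope.

Outgroup rooting places the root on the branch separating all outgroup
tips from all ingroup tips; when no such branch exists the
best-separating branch is used with a logged warning.

## Multi-locus concatenation

Regions are joined on *individual* (not sequence accession, since one
individual's per-region sequences generally have different accessions),
keeping only individuals present in every region (complete-case policy; a
union policy with gap-fill was rejected because it changes per-region
accession counts). Per-region column spans are retained on the result.

## ITS2 derivation

The ITS2 spacer is trimmed from full ITS sequences by motif anchors — the
conserved 3′ flank of the 5.8S gene and 5′ flank of the 28S/26S gene —
searched on the gap-free sequence with a Hamming mismatch budget (default
1). A profile-HMM annotator would be the heavyweight alternative; anchored
trimming is self-contained, configurable and has an exact oracle in the
simulator. Tied best hits and reversed motif order are reported per record
as failures, never silently dropped.

## The simulator

The generator emulates the statistical shape of a dense congeneric
barcoding study:

* **Species tree** — pure-birth (Yule), forward-simulated, with the final
  Exp(nλ) hold time so the expected height is Σₖ₌₂ⁿ 1/(kλ); ultrametric.
* **Individuals** — each species tip becomes a star of tips with
  exponential depths of mean `intraspecific_depth/2`, so a conspecific
  pair's expected path is `intraspecific_depth`. A star, not a coalescent:
  no population model is assumed by the analysis, and the star suffices to
  produce the intra/inter distance structure the pipeline consumes.
* **Calibration** — per region, the species tree is rescaled so the
  expected between-species tip path equals `interspecific_depth`
  (accounting for the within-species depth contribution). The default
  profiles target the per-region distance means of the motivating study
  design: ITS-like 0.0103/0.0705, matK-like 0.0016/0.0474, ITS2-like
  0.0159/0.1026 (intra/inter, substitutions per site), with lengths ~550,
  ~850 and ~235 bp. Twenty-five replicate runs centered within ~1 SD of
  each target; the frozen test bands are target ± ~4 replicate SDs.
* **Sequences** — root drawn uniformly over ACGT, evolved with analytic
  K80 transition matrices (default κ = 2). Deletion events are Poisson per
  branch, scaled so one root-to-tip path expects `indel_rate` events, with
  lengths uniform in the profile's range; events are recorded, so the
  emitted alignment *is* the true alignment and no aligner is needed.
  Insertions are not modeled — for the statistics computed here a deletion
  in one lineage and an insertion in its sister are indistinguishable.
* **Motifs** — when anchor motifs are set (ITS-like profile), layout is
  flank + motif + spacer + motif + flank; motif columns are invariant and
  the spacer is shielded from deletion (substitutions still occur), with
  the remaining columns' substitution rate inflated by `L/(L−n_protected)`
  so whole-sequence divergence still matches the branch lengths. The
  spacer and its per-tip sequence are recorded as extraction truth.
* **Study shape** — defaults: 28 species, 4 individuals each except 5
  singletons, 2 outgroups attached as a distant clade — leaving 23
  evaluable species after the standard exclusion, mirroring the motivating
  design (the simulator's 99 accessions are fewer than the study's 131;
  the evaluable-species arithmetic, not the accession total, is the
  emulated quantity). `enforce_separation=True` additionally floors
  species' pendant branches at 30% of the region depth — the construction
  for *ideal* datasets on which every criterion provably succeeds; it is
  off by default because a Yule tree's most recent splits can otherwise
  legitimately overlap the within-species variation, which is exactly the
  realistic regime.
* **Determinism** — one `SeedSequence` per run, split into named
  substreams per region and operation; identical parameters and seed give
  byte-identical output files.

What the simulator does *not* emulate: alignment error (rows are emitted
pre-aligned), sequencing error and chromatogram artifacts, recombination
or introgression between species, rate variation across sites and
lineages, and insertions. Tests passing on simulated data therefore show
the *analysis* is correct under its own model; they do not certify
identification rates on real sequences, where misalignment and deeper
population structure can only lower resolution.

## Numerical conventions

Distances are reported to 4 decimals and percentages to 1 decimal, both
half-away-from-zero. Histograms of the distance classes use left-closed,
right-open bins of width 0.005 by default and *relative* frequencies per
class. Stochastic searches receive per-cell seeds derived from
(global seed, cell index), so any scoreboard cell can be reproduced in
isolation. Known limitations: NNI hill-climbing can stop in local optima
on weak-signal data (mitigated, not eliminated, by restarts); ML branch
optimization re-evaluates the full pruning per proposal, which is fine at
the ~10²-sequence scale this package targets but would need partial-
likelihood caching well beyond it.

## Problem sizes used in the shipped checks

The test suite and acceptance script size their simulations to make each
check sharp but cheap: pairwise-distance recovery uses two-taxon
alignments of L = 1,000 over 100 replicates; κ recovery an 8-taxon tree at
L = 5,000; NJ exactness 50 random 8-taxon additive matrices; oracle
equivalences ≤ 6-taxon trees (exhaustive parsimony) and 20-sequence
fixtures (identity ranking, monophyly); end-to-end scoreboards an
8-species, 2-region ideal dataset plus the default 28-species shape for
the evaluable-species arithmetic.
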