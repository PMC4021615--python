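# Methods

## Model and statistics

Two rankings of the same N elements are reduced to the relative
permutation π = π₂ ∘ π₁⁻¹ of the second w.r.t. the first.  Under the null
hypothesis the two rankings are independent and uniform, so π is uniform
over S_N.  The mmHG score is the minimum hypergeometric tail
HGT(N, n₁, n₂, b_π(n₁, n₂)) over all cutoff pairs; its p-value is the
probability that a uniform permutation attains a score at least as small.
The mHG statistic is the one-ranking analogue: a fixed binary labeling
with K ones is scanned over all cutoffs n of a single ranking,
min_n HGT(N, K, n, b_n).

Conventions used throughout:

* position 1 of a ranking is the strongest measurement ("top");
* the valid intersection range at a cell is
  max(0, n₂ − N + n₁) ≤ b ≤ min(n₁, n₂); a b at or below the lower
  limit has tail 1, above the upper limit tail 0 — these conventions make
  the neighbour-cell indicator terms of bound B2 well defined at edges;
* all probabilities are carried as natural logs end to end (Table-scale
  inputs reach 1e−137); conversion to linear happens only at reporting;
* every "HGT ≤ s" comparison uses a relative slack of 1e−9 on the log
  values, guarding boundary cells against floating-point noise; one shared
  slack is used for both the qualifying-cell test and the indicator tests
  of B2.

Binomial coefficients use exact log-gamma rather than a Stirling
approximation: equally O(1) per coefficient, and it keeps approximation
error out of reported bounds.

## p-value bounds

* **Bonferroni** — s·N², one test per cutoff pair, capped at 1.
* **B1** — for each cell (n₁, n₂, b) with tail ≤ s, add the fraction of
  permutations realizing exactly that intersection,
  Λ/N! = C(n₁,b) C(N−n₁,n₂−b)/C(N,n₂).  Permutations qualifying at many
  cells are counted repeatedly, so B1 over-counts; per (n₁, n₂) the
  qualifying b form an upper tail ≤ s, which is why B1 ≤ Bonferroni.
* **B2** — the ψ-partition refinement: each qualifying cell's permutation
  set is split five ways; three parts are always already counted by
  previously handled cells; the remaining two (ψ₃, ψ₅ — closed-form
  counts) are added only when indicator tests on three neighbour cells
  show no earlier cell counted them.  Base case n₁ ≤ 1 or n₂ ≤ 1 falls
  back to Λ.  Implemented as a vectorized sweep over n₁ with full
  (n₂, b) tail planes; no memoized recursion is needed because the
  recursion is only through the base case.
* **B3** — a per-cut variant requiring π itself:
  N · min_i (mHG(λ_i) · i) where λ_i marks positions with π(j) ≤ i.
* **B4** — for each (b, n₁) keep only the maximal n₂ whose tail still
  qualifies (the tail is non-decreasing in n₂, so binary search applies;
  the sweep implementation reads the same maximal n₂ off the monotone
  column of a per-n₁ tail plane) and add that single cell's mass.

### The two B4 evaluations

`bound_b4` exposes two evaluation modes.

The default evaluates the sum exactly as defined, over all pairs
1 ≤ b ≤ n₁ ≤ N.  This form has a per-cell counting proof: iterating
b ↦ b_π(n₁, n₂*(b, n₁)) from any qualifying cell converges to a fixed
point, so every permutation with score ≤ s passes *exactly* through some
(n₁, n₂*(b, n₁), b) cell, and a union bound over those cells is valid.

`half_plane=True` (method name `b4sym`) restricts the n₂ search to
n₂ ≥ n₁ and doubles the sum — a shortcut exploiting the (n₁, n₂) symmetry
of the tail that halves the computation.  The published benchmark table
for this bound is reproduced (to well under 1%) by the symmetrized
evaluation, and only by it; the full sum is 15–25% larger at the
benchmark inputs, and unlike the symmetrized form it is never below the
per-cut bound B3 there.  The package therefore reports `b4sym` when the
goal is comparison against the published table (as
`scripts/acceptance.py` does) and keeps the provable full sum as the
default for analysis work.

### Exact and empirical p-values

For N ≤ 10 the p-value is exact: all N! permutations are enumerated in
vectorized blocks (a one-hot cumulative-sum trick yields every b_π table,
and a precomputed (n₁, n₂, b) tail tensor turns scoring into one gather).
Beyond that, `empirical_pvalue` samples uniform permutations (seeded
generator; argsort of uniforms, equivalent to Fisher–Yates) and reports
the hit fraction with a normal-approximation 95% CI.

## Numerical design of the mHG scan

The motif finder evaluates the mHG of tens of thousands of membership
vectors per run, so the per-row scan is O(N): the path pmf is maintained
by exact multiplicative one-draw recurrences (with rescaling through a
log offset below 1e−250), and the tail at a cell is computed only when
its pmf can still beat the running minimum, as pmf · (1 + r + r² + …)
with the term ratio r — truncated when the increment falls below 1e−15
relative.  Cells with b at the valid floor have tail exactly 1 and are
skipped.  The scan is verified against direct log-sum-exp tail evaluation
to ≤ 3e−14 relative error, including maximally enriched rows (an earlier
incremental-tail formulation lost all precision there to cancellation and
was discarded).  A numba kernel runs this loop; an equivalent pure-python
fallback is selected automatically when numba is absent.

Cutoff ties (cells whose tails agree within the shared slack) resolve to
the smallest n (for mmHG: smallest n₁, then n₂).

## The motif finder

Inputs: sequences in ranking order (or a target/background pair, in which
case the list is targets-then-backgrounds and "top" means the target
set); motif width range [k₁, k₂] (default 6–8).

1. a hash-map k-mer index stores, per width, each distinct k-mer's
   occurrence positions and per-sequence presence flags; IUPAC patterns
   are resolved by vectorized position-wise filtering of the distinct
   k-mer table.  The index's enumeration/traversal contract is what
   matters; a generalized suffix tree would satisfy it equally.
2. per width: all k-mers are ranked by mHG of their presence vectors
   (membership = at least one occurrence; occurrence counts are not
   weighted at this stage); the 50 best mutually-diverse k-mers (greedy,
   skipping anything within Hamming distance < 2 of a chosen seed) become
   seeds; each seed undergoes coordinate-ascent IUPAC degeneration
   (all 15 letters per position, left-to-right sweeps, accept only strict
   mHG improvement, up to 3 passes with early stop); the refined
   pattern's matching input words are expanded by greedily adding the
   Hamming-1 neighbour that most improves the set mHG while average
   pairwise identity stays ≥ 0.5·k.
3. each word set becomes a PWM via per-position frequencies over all
   matching windows of all sequences (pseudocount 0.5 per base —
   avoiding zero columns that would annihilate near-miss windows during
   ranking); sequences are re-ranked by best-window PWM score
   (forward-strand by default; both-strand and sum-over-occurrences
   modes behind flags), ties broken by a deterministic key (identifier by
   default, never the input order); the relative permutation of the PWM
   ranking w.r.t. the input ranking is scored with mmHG, and the
   configured bound (default `b4`) plus Bonferroni are reported for the
   returned motifs.

The seed-diversity radius, pass count, expansion similarity threshold,
expansion cap and pseudocount are this package's own concretizations of
choices the method description leaves open; all are exposed in
`FinderConfig`.

## Synthetic benchmark generator

`generate_planted_dataset` emulates the planted-motif benchmark: 500
i.i.d. uniform-ACGT sequences of 100 bp; in each of the top 64, one
concrete word — sampled uniformly from the IUPAC pattern's expansion —
replaces a uniformly chosen window (length is preserved).  GC content,
counts, plant multiplicity and seed are parameters; ground truth records
every planted word and position and is self-validated against the
pattern matcher.  "Variants of a degenerate pattern" is read here as
uniform draws from the pattern's expansion; planting noisy copies of a
consensus instead would concentrate the signal on fewer distinct words
and make recovery easier, so the uniform reading is the conservative one.

Identifier labels are assigned in a seeded shuffled order, deliberately:
if identifiers encode the ranking (seq0001 = best), the identifier
tie-break in PWM ranking degenerates into breaking ties by the partner
list, and the large block of tied low-scoring sequences then fakes
enormous mutual enrichment.  The same caveat applies to real data — with
rank-correlated identifiers, supply a rank-uncorrelated `tie_key` to
`rank_by_pwm`.

What passing planted-recovery tests shows: the pipeline recovers
degenerate patterns whose expansion is rare enough in background
(CTNNNAT, MMMMMMMM: recovered top-1 with margins of 20+ orders of
magnitude).  What they do not show: recovery of patterns that saturate
the background — TNWMNG's 64 words occur in ~78% of random 100-mers, the
planted pattern's own enrichment is then weak (mHG ≈ 2e−6), and
one-position-wider "blurred" patterns genuinely score better under both
the seed statistic and the final mmHG; the top-1 motif is then off by one
position's base set (compatible patterns rank in the top 3).  Real
binding data, with its biased base composition and positional structure,
is not represented by this i.i.d. background.

## Known limitations

* The reported bound is an upper bound on the mmHG p-value of the
  *reported* PWM.  It is not corrected for the de-novo search that
  produced the PWM (tens of thousands of greedily optimized candidate
  patterns): on unplanted null data the best reported bound is routinely
  1e−3–1e−4 at the default 50-seed search depth.  Motif p-values from
  `find_motifs` should be read as ranking scores, not as calibrated
  discovery-level significance; calibrating them would require a
  permutation/re-run null of the whole search.
* Exhaustive p-values stop at N = 10 (10! ≈ 3.6e6); the empirical
  sampler takes over beyond that.
* PWM scores are plain likelihood products without background
  normalization or log-odds correction, exactly as the ranking model
  defines them.
* Tails below ~e−700 (natural log) underflow to −inf inside the fast
  grid sweeps; every comparison the statistics and bounds make operates
  far above that floor.
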