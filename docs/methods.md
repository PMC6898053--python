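# Methods

## Contact definition

A contact is a residue pair whose Cα atoms lie strictly closer than the
cutoff (default 8.0 Å) with a sequence separation of at least 6; closer
pairs merely stabilise local secondary structure and are excluded. Range
classes partition the map by separation: short (6–11), medium (12–23),
long (> 23). Sequence separation is computed on the position within the Cα
trace, not on author residue numbering. This is a deliberate choice: for
chains with numbering gaps the author-number difference would inflate
separations across a break and misclassify pairs that are local in the
actual polymer, whereas the trace index is robust. Residue insertion codes
are rejected outright rather than silently reordered.

## Structural relevance

The relevance of contact *c* is the mean change in reconstruction error it
causes when toggled within `r` sparse baseline subsets (default coverage
0.30, redundancy r = 10). Sign convention: ΔRMSD = RMSD_baseline −
RMSD_toggle when *c* was added to the subset, negated when it was removed,
so positive SR always means the contact improves reconstruction. An
analogous score in TM-score units is computed with the parallel convention
(TM increases for good models, so the differences are flipped relative to
RMSD).

Two implementation choices matter for variance:

* **Seed reuse.** Each toggle reconstruction reuses the engine seed of its
  baseline, so the baseline/toggle difference reflects the contact and not
  the random stream. Redundancy across the `r` baselines then supplies the
  independent replication.
* **Ensemble score.** A reconstruction returns the `top_k = 5`
  lowest-energy models; the reported RMSD/TM is the *mean* of the kept
  models' mirror-resolved scores. The mean was chosen over the best-model
  score to reduce the variance of ΔRMSD estimates.

Per-residue aggregation is reported both as the mean and as the sum of the
incident contacts' SR values; the two conventions answer slightly different
questions (typical information per contact vs total information carried by
a residue) and both are emitted rather than endorsing one. Residues without
contacts are reported with zero relevance and a flag, and excluded from all
downstream statistics.

Subset sizes everywhere use one rounding rule: banker's rounding of
`fraction × count` with a floor of one contact.

## Reconstruction engine

Reconstruction is classical distance geometry, chosen so the scoring loop
is fully self-contained and bit-reproducible with no external binaries:

1. **Bound compilation.** Every pair starts at [4.0 Å, 3.9·L Å] (excluded
   volume; chain-length bound = maximum sequential step × length).
   Sequential pairs get the virtual Cα–Cα bond window [3.7, 3.9] Å,
   next-nearest pairs [5.0, 7.3] Å; contact pairs [3.8 Å, cutoff]. A
   per-residue helix annotation adds canonical (i, i+3) ∈ [4.5, 5.5] and
   (i, i+4) ∈ [5.5, 6.5] windows for every window of residues lying wholly
   in an H run. Strand annotations add no bounds: strand *partners* cannot
   be inferred from a per-residue string, and wrong pairings would be worse
   than none.
2. **Triangle smoothing.** Uppers are tightened to all-pairs shortest paths
   (Floyd–Warshall); lowers are raised by the inverse triangle inequality.
   Inconsistent input (a lower above its smoothed upper) is an error, not a
   warning, since it means the constraint set admits no geometry.
3. **Metrization and embedding.** A trial distance matrix is sampled
   uniformly and independently per pair within the bounds, double-centered
   to a Gram matrix, and projected onto its top three eigenpairs (negative
   eigenvalues clamped). Exact for degenerate lower = upper Euclidean
   input.
4. **Refinement.** Independently sampled trial matrices are far from
   Euclidean, and a pure gradient scheme started there reliably stalls in
   deep local minima (knotted chains). Refinement therefore runs in two
   stages: first, alternating metric projection — clip current distances
   into the bounds, re-embed by classical MDS, repeat (default 50 rounds) —
   which acts as a cheap global conditioner; then L-BFGS minimisation of
   the squared bound-violation energy Σ max(0, l−d)² + max(0, d−u)², with
   early stop once the energy falls below `energy_tol` (default 1e-4 Å²).
   Over the descent phase the energy is non-increasing across accepted
   iterates. Coordinates that already satisfy every bound are returned
   unchanged.

Each reconstruction draws `n_candidates = 20` independent embed+refine runs
from sub-seeds derived deterministically from the run seed and keeps the
five lowest-energy models. Distance information is achiral, so each kept
model is scored together with its point reflection and the better
enantiomer is reported (`mirrored` flag set accordingly).

## Model assessment

Model and native are the same chain at the same length, so superposition
uses residue-index correspondence and the Kabsch algorithm (proper
rotations only); no alignment search is needed or performed. The TM-score
uses d0(L) = 1.24·(L−15)^⅓ − 1.8 (undefined below L = 16, which is an
error) and approximates the score-maximising superposition by the Kabsch
fit followed by iterative-cutoff refinement: repeatedly re-superimpose on
the residues currently within a distance cutoff and keep the best score
seen. This is an approximation to the published exhaustive search; for
same-length, mostly-correct models the two agree closely. Fold-recovery
thresholds are carried as configuration constants: RMSD 4.0 Å and TM-score
0.5.

## Strategies and noise

Selection strategies return exactly `size` contacts (default 30% of the
native map): uniformly random; sorted by SR (most/least relevant, ties
broken by ascending (i, j) so results are independent of input order);
range bins (short, long) and user-annotated feature bins (hbond,
hydrophobic) sampled uniformly within the bin, with `non_*` complements
drawn from outside it. A bin smaller than the requested size raises a
shortfall error naming the deficit rather than silently padding. All
stochastic bins re-sample per replicate.

Noise injection replaces `round(f·k)` members of a k-contact selection by
uniformly drawn residue pairs with separation > 5 that are absent from the
native map, preserving the selection size; fractions are relative to the
selection, not the full map. Validity (non-membership and separation) is
exhaustively checkable and tested.

## Statistics

Group comparisons use the two-tailed Mann-Whitney U test: exact null
enumeration when the combined sample size is ≤ 20 with no ties,
tie-corrected normal approximation with continuity correction otherwise
(the switchover point is a package choice; only the test itself is
prescribed). Notched summaries follow the McGill rule, median ±
1.57·IQR/√n, as the 95% confidence interval around the median. Trend
tables split scored contacts or residues by each boolean feature column and
report n/μ/σ per group with a trend arrow only at p < alpha (default
0.05). No multiple-testing correction is applied by default; a
Benjamini-Hochberg flag exists but is off, so single-feature significance
claims should be interpreted accordingly.

## Synthetic fixtures

The generators emulate small single-domain proteins (the size range of
interest is roughly 56–164 residues) as Cα traces with known ground truth:

* **Helix**: ideal α-helical spiral (radius 2.3 Å, rise 1.5 Å/residue,
  100°/residue; consecutive Cα ≈ 3.83 Å). Deterministic.
* **Bundle**: antiparallel helices packed at ~10 Å axis separation, joined
  by loops built from a Bézier arc walked at exact 3.8 Å chord steps, so
  the native trace satisfies the engine's own sequential bounds. Fixtures
  are self-avoiding (non-bonded pairs ≥ 4.0 Å, a floor set just below the
  3.8 Å contact lower bound) and their maps contain short, medium and
  long-range contacts.
* **Unique-contact bundle**: two compressed spirals (rise 1.0 Å,
  97°/residue, bond kept at 3.8 Å) which — unlike ideal α-helices, whose
  Cα self-distances at separation ≥ 6 all exceed 8 Å — contact themselves
  at separations 6–7, providing redundant short-range contacts. The second
  segment is splayed by 8° so the segments approach only at their free
  ends; axis separation and phase are scanned until exactly one long-range
  pair bridges them. That single contact is the only constraint on the
  segments' relative placement, the synthetic analogue of a uniquely
  informative contact.
* **Coil**: self-avoiding random walk with fixed 3.8 Å steps.

What passing on these fixtures does and does not show: the fixtures have
exact virtual-bond geometry, no side chains, no β-sheets and no
experimental noise, so they validate the *machinery* — bound compilation,
embedding, toggling, aggregation, ordering of informative vs redundant
contacts — under conditions where ground truth is known. They do not
calibrate absolute SR magnitudes for real proteins, which depend on the
reconstruction engine and on the structure; published per-contact values
from other engines are not comparable number-for-number.

## Problem sizes and defaults used in validation

The test and acceptance runs reconstruct bundles of 50–80 residues and
score 30-odd-contact maps at reduced engine settings (4–6 candidates,
500–800 refinement steps, redundancy 3 for full scoring runs) — sizes
chosen so a complete validation pass is a desk-scale computation while
leaving every algorithmic path identical to a full run. Defaults for real
use remain coverage 0.30, redundancy 10, 20 candidates, 2000 refinement
steps, top-5 ensembles.

## Known limitations

* The engine encodes no chirality prior beyond mirror resolution against a
  native; without a native reference, the handedness of a returned model is
  arbitrary.
* Helix-only secondary-structure bounds: β-strand geometry is not
  restrained, so sheet-rich folds reconstruct less precisely.
* Non-contact pairs carry only the generic excluded-volume lower bound;
  the engine does not exploit "no contact observed" as a repulsive
  constraint (a subset's missing contacts may simply be unsampled).
* The coverage default of 30% is a global compromise; the sensitivity
  sweet spot is structure-specific, and per-structure calibration of the
  coverage (e.g. targeting the fold/no-fold boundary) is deliberately not
  automated.
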