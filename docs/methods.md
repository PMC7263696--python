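# Methods

This note documents the models, parameter choices, numerical details and
known limitations of the package.  Nothing here asserts an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Luria–Delbrück model (`recscreen.ld`)

A clone (culture or pinned colony) grows deterministically and
exponentially from `n0` to `nf` cells with no cell death.  Recombination
events arise as a Poisson process with expectation `m` per clone, uniform
over the population increase; with a per-cell per-division rate `mu`,
`m = mu·(nf − n0)`.  An event at a uniformly random point of the growth
founds a recombinant sub-clone of `min(nf, floor(1/u))` descendant cells,
`u ~ Uniform(0,1]`; recombinants have no fitness advantage or disadvantage,
no phenotypic lag, and never revert.  These are the classical assumptions
under which both the Ma–Sandri–Sarkar (MSS) recursion

    p0 = e^(−m),   p_r = (m/r) · Σ_{i=0}^{r−1} p_i / (r − i + 1)

and the Lea–Coulson median relation hold; the underlying screen protocol
specifies no growth model, so adopting the classical one is a modelling
choice, not an inference from data.

The recursion is evaluated with an O(r_max²) dot-product loop in float64;
entries are provably nonnegative and partial sums stay below 1 (checked to
1e-9 in property tests).  Simulation truncates each sub-clone at `nf` and
caps the total recombinant count at `nf`.

Per-stream seeding uses `SeedSequence(entropy=seed, spawn_key=key)`; the
scheme is stable across runs and platforms, and element `i` of a sampled
batch is regenerable in isolation as `simulate_clone(model, child_seed(seed,
i))`.

## Rate estimation (`recscreen.fluctuation`)

Each culture's selective and permissive colony counts are converted to
recombinants per `norm_cells` (default 10⁷) viable cells from the plating
design (counts × dilution / plated volume on each plate).  The default
design is 4 ml cultures, 100 µl of a 10⁵-fold dilution on permissive
plates, 200 µl of a 10²-fold dilution on selective plates, under which the
normalization reduces to `5000 · sel/perm`.

The sample median of the normalized counts (even n: mean of the central
pair — the conventional sample median; the protocol is silent) is converted
to `m̂` by solving `r̃/m − ln m = 1.24` with Brent's method on
[10⁻⁹, 10⁶] to relative tolerance 10⁻⁹ (the left side is strictly
decreasing, so the root is unique).  The rate is `m̂ / norm_cells`,
treating the normalized counts as counts in a pseudo-culture of
`norm_cells` cells.  This convention reproduces the described workflow;
note that because the Lea–Coulson median grows like `m·ln m`, normalizing
counts before solving is not identical to solving at culture scale and
rescaling — recovery experiments in the test suite quantify the resulting
bias (a few percent at 10⁷-cell cultures; ~1.5-fold at 4×10⁸-cell cultures
under the dilution design, still within the 2-fold acceptance band).

Degenerate inputs: a zero median or a non-positive median returns an
indeterminate estimate (NaN rate) rather than raising, so batch processing
continues.  A culture is a **jackpot** when its normalized count exceeds
`norm_cells/2`; a test with more than 50% jackpot cultures is
indeterminate.  This operationalizes "rates could not be determined due to
jackpot cultures" — no printed rule exists, and both constants are module
constants, not tuned values.  Cultures with zero permissive count are
dropped with a warning (their viable density is unknowable); an all-dropped
test raises.

Triage is two-stage: first-pass rate ≥ `rate_cutoff` (default 2×10⁻⁵),
then a one-sided **pooled-variance** Student's t-test (the protocol names
Student's test, not Welch's) of repeated determinate rates against
wild-type replicates at `alpha` (default 0.05).  Strains with an
indeterminate first pass, or too few determinate repeats for a t-test,
report `indeterminate`.

The MSS maximum-likelihood estimator is deliberately not part of the
library (the median method is the headline estimator); it exists only as an
independent oracle in the test suite, censored at a count cap so jackpot
counts enter through the tail probability.

## Colony scoring (`recscreen.pinscore`)

All thresholds are strict inequalities, following the protocol's "greater
than" wording.  Decisions taken where the protocol is ambiguous:

- **Permissive reference mean is per plate**, over circularity-passing
  permissive colonies on that plate.  The alternative (collection-wide
  mean) ignores plate-to-plate pinning and imaging effects that colony-array
  pipelines routinely normalize out.
- **Selective colonies are position-paired**: a selective colony is scored
  only if the permissive colony at the same (plate, row, col) was scored.
  Pairing guarantees recombinant frequency ≤ 1, consistent with published
  maxima of exactly 100%.
- Circularity (4π·area/perimeter², as produced by colony-measurement
  tools) is consumed as a given score; the package never touches images.
- The protocol's two serial selective pinnings are treated as producing one
  final selective scan.

Strains excluded for too few scored permissive colonies (< 10) or for
membership in an exclusion list keep their computed frequency — the list
exclusion exists to remove strains with a confounding secondary *msh3*
mutation from *hit calling*, while their frequencies still belong in
distribution plots.  The 73-strain *msh3* list itself is not part of the
package (it is not printed in the screen publication); the exclusion list
is a plain-text input, one strain per line.

Classification: frequency ≥ 0.87 → hyper; ≤ 0.33 → hypo.  The cutoffs are
configuration (they come from an external cutoff-finding analysis, CLIK,
that is out of scope here), not quantities this package derives.

## Screen simulator (`recscreen.pinsim`)

The generator emulates, per pinned colony: Luria–Delbrück recombinant
accumulation during colony growth (`m = rate · cells_per_colony`); pin
transfer as an **exact hypergeometric** draw of
`round(transfer_fraction · cells_per_colony)` cells without replacement
(at full transfer this reduces exactly to "positive iff any recombinant
exists", a property the binomial approximation lacks); positivity iff ≥ 1
recombinant transfers, else a Bernoulli background channel; truncated-normal
area and circularity observations; a 2% pin-failure rate (absent colonies,
exercising the < 10-colony exclusion) and a 2% artifact rate
(low-circularity blobs, exercising the circularity filter).  Arrays are
1536-density (32×48), each strain a 2×2 quadruplicate of its 384-format
position, `replicates/4` replicate plates.

Parameters with units, defaults, and rationale:

- `cells_per_colony` = 10⁶ cells and `transfer_fraction` = 0.008.  Neither
  is measured anywhere; they were calibrated **once**, before any test was
  written, so that a wild-type rate of 1.14×10⁻⁵ events/cell yields a
  recombinant frequency near the middle of the 0.40–0.60 band spanned by
  the reported wild-type frequencies (46% pilot, 56% screen), given the
  background below.  They are exposed as parameters, not presented as
  robot properties.
- `background_positive_prob` = 0.21, the recombinant frequency reported
  for a recombination-dead strain.  Residual growth and post-pinning
  recombination are not modelled mechanistically; this single channel is
  the only way a dead strain scores 21%.
- `replicates` = 48 (the screen's 48 pinnings per strain);
  `pin_failure_prob` = 0.02; `artifact_prob` = 0.02; area model
  N(400, 60²) px truncated at 1 for colonies and N(5, 3²) truncated at 0
  for empty selective positions; circularity N(0.95, 0.03²) clipped to
  [0, 1] for colonies, N(0.60, 0.10²) for artifacts.  These observation
  values are presentation-scale choices with no anchor in the protocol;
  what matters downstream is that they place true colonies and artifacts on
  opposite sides of the 0.8/50%/10% thresholds with realistic overlap.

Fluctuation-test simulation grows cultures to `culture_cells` (default
4×10⁸ — a 4 ml culture at ~10⁸ cells/ml) and subsamples plates binomially
at the design's plated fractions.

What the generator does **not** emulate: spatial plate effects (edge
growth, neighbor competition), correlated pinning failures, plate-scan
segmentation errors beyond the artifact channel, strain-to-strain growth
differences, and any aging of the arrays between pinnings.  Passing tests
therefore demonstrate correctness of the scoring and estimation machinery
under the assumed statistical structure, not robustness to every real-robot
artifact.

## Integration statistics (`recscreen.screenstats`)

Gene names are uppercased; control rows (WT) are never members of gene
sets; dubious ORFs overlapping validated genes (e.g. YLR235C/TOP3,
YDL162C/CDC9) are kept as distinct genes, exactly as published.  The
overlap p-value is the upper hypergeometric tail summed in log space
(gammaln + logsumexp), so it stays meaningful far below float underflow;
`scipy.stats.hypergeom.sf` serves as an independent cross-check in tests,
and exhaustive subset enumeration verifies exactness on all universes
N ≤ 12.  The default universe for the screen-overlap test is 4500 (the
approximate number of reporter-bearing deletion strains obtained); the
exact universe behind the published overlap p-value is not stated, so the
package reports its p-value together with the universe used rather than
asserting agreement with the published figure.

Frequency-distribution summaries report group/rest/overall medians and
0.05-wide histograms on [0, 1].  The published *msh3*-vs-collection medians
(74%/60%) derive from supplementary data tables not distributed with the
main publication;
the package computes the same contrast from any per-strain frequency table,
and its tests exercise it on simulated collections with an elevated-rate
subgroup.

## Problem sizes in tests and acceptance

Monte-Carlo checks use 10⁵ draws for distributional comparisons (3-SE
bands), 1000 five-culture and 300 hundred-culture simulated fluctuation
tests for estimator recovery, 3000 colonies for simulator calibration
checks, and 200 screen replicates for rate-monotonicity — sizes chosen so
the full suite runs in well under a minute of Monte-Carlo per property
while keeping binomial/empirical standard errors small against the asserted
tolerances.
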