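# Methods

## Overview

divergraft turns a two-clade protein alignment plus complex structures
into ranked functional-divergence calls and chimeric variant designs. The
chain of inference is: per-site substitution counts (parsimony) → a
mixture model separating rate-correlated from rate-independent sites
(Type-I / heterotachy) → a deterministic Conserved-But-Different score
(Type-II) → an interface filter (≤ 5 Å heavy-atom contacts, native or
inferred by superposition) → nested KnockOut/KnockIn site groups and
grafted sequences.

## Substitution counts

For each alignment column and each clade, the signal is the minimum
number of amino-acid replacements needed to explain the observed leaf
states on that clade's induced subtree (Fitch parsimony with the standard
bottom-up set pass). Gaps and `X` are missing data and contribute the
full 20-state set, so they never force a change; a clade with fewer than
two scored leaves at a site yields count 0 and an `insufficient_data`
flag, and flagged sites are excluded from model fitting and from designs.
Unit-cost parsimony counts are invariant to the root position of the
clade subtree and to any bijective relabeling of the amino acids; both
properties are asserted by tests, and counts are checked against
exhaustive enumeration of internal labelings on small trees.

Parsimony counts are a *lower bound* on the true number of substitutions:
multiple hits on one branch and parallel changes collapse. The mixture
model absorbs this through its depth parameters (below), but it means the
method's resolution degrades on trees whose length is concentrated in a
few long branches.

## The Type-I mixture model

Counts `(x_i, y_i)` for site `i` are modeled as draws from a
two-component mixture:

* **Rate-correlated (null):** one rate `λ_i ~ Gamma(α, α)` (mean 1)
  shared by both clades, `x_i | λ_i ~ Poisson(D_A λ_i)`,
  `y_i | λ_i ~ Poisson(D_B λ_i)`. Integrating `λ` out gives the closed
  form `Γ(α+x+y) / (Γ(α) x! y!) · (α/s)^α (D_A/s)^x (D_B/s)^y` with
  `s = α + D_A + D_B`.
* **Rate-independent (Type-I):** each clade draws its own
  `Gamma(α, α)` rate, giving a product of negative-binomial marginals
  `NB(x; α, α/(α+D_A)) · NB(y; α, α/(α+D_B))`.

`θ` (the mixture weight of the independent component) is the coefficient
of functional divergence. `D_A`, `D_B` are the expected per-site counts
on each clade subtree; because `E[count] = D` under both components they
are set by method of moments (the observed means), which stabilizes the
remaining two-parameter fit. `(θ, α)` are estimated by bounded L-BFGS-B
on the log-likelihood (α on a log scale), from a fixed 3 × 3 start grid
(θ ∈ {0.05, 0.3, 0.6} × α ∈ {0.3, 1, 3}); identical `(x, y)` pairs are
aggregated with weights so each likelihood evaluation is linear in the
number of *distinct* count pairs. The fit is deterministic.

Per-site posterior probabilities are
`pp_i = θ f_div / [(1−θ) f_null + θ f_div]`, and the posterior-mean rate
of clade `c` under the divergent component is `(α + x_i^c)/(α + D_c)`.
A site is polarized *slow-in-A/fast-in-B* when `rate_B ≥ r · rate_A`
(default ratio `r = 2`, configurable and recorded in output metadata);
the reciprocal rule gives the other direction, anything else is
unpolarized. The ratio has no canonical value; 2 requires a clear
asymmetry while tolerating posterior shrinkage at small counts.

Both closed-form densities are verified against numerical quadrature
over the gamma rate and checked for normalization; `θ` recovery is
verified on counts simulated from the model itself (|bias| ≤ 0.08 at
2000 sites across θ ∈ {0.1, 0.3, 0.5} × α ∈ {0.5, 2}).

## Type-II (Conserved-But-Different) scoring

A site qualifies when both within-clade counts are ≤ k (default k = 0,
i.e. strictly conserved), each clade has a majority consensus residue
(≥ 70% of non-missing leaves), and the consensus residues differ.
Qualifying sites are ranked by the Grantham chemical distance between the
consensus pair (descending), with ties broken by total count then column
index, so the ordering is deterministic. The Grantham table is embedded
in the source and spot-checked against published landmark values; a
BLOSUM62-derived distance (`s(a,a) + s(b,b) − 2 s(a,b)`) is available as
an alternative metric. This is a transparent deterministic score rather
than a likelihood-based Type-II posterior; it trades statistical
calibration for exact reproducibility and easy auditing.

## Structure stage

Columns are mapped to residues of a chosen chain by global pairwise
alignment (BLOSUM62, affine gaps) of the taxon's ungapped sequence to the
chain sequence; mappings below 90% identity are rejected as a wrong-chain
guard. Contacts use all heavy atoms with an inclusive boundary at the
cutoff (default 5.0 Å); the neighbor search bins partner atoms into cubic
cells of side = cutoff and scans the 27 surrounding cells, with an
all-pairs implementation retained as the test oracle. For the interface
the recipient does not natively form, the donor complex's elongation
factor chain is superposed onto the recipient over matched C-alpha pairs
(closed-form Kabsch with the determinant correction; no outlier-rejection
cycles — a deliberate simplification relative to sequence-guided
alignment tools with rejection iterations), and the same transform
places the donor's partner chain into the recipient frame.

## Variant design

Nested groups: (1) Type-I PP ≥ 0.90; (2) PP ≥ 0.80; (3) PP ≥ 0.80 plus
the top-ranked Type-II sites (default 10). Type-I sites must carry the
direction appropriate to the design (slow in the recipient's clade for
KnockOut of native binding, slow in the donor's clade for KnockIn of
non-native binding); Type-II sites are not direction-filtered. Each
group is intersected with the relevant contact set, giving KO1–3 (native
interface) and KI1–3 (superposed interface); KOKI2/KOKI3 are unions of
the corresponding KO/KI site sets (sites shared by both contribute one
mutation), and the group-1 combination is intentionally not generated.
The CONTROL design takes contact columns with PP < 0.50 that are not
Type-II-qualifying — interface sites with no divergence signal. Grafting
substitutes the donor's residue at each selected column into the
recipient; donor gaps, recipient gaps and identical residues are dropped
with a recorded reason, and positions are reported in ungapped recipient
numbering.

## Synthetic data

The generator produces every input with planted truth, under fixed
default study conditions (the `paperlike` preset):

* 15 + 15 taxa, 400 columns; per clade a random-coalescent *topology*
  with equal branch lengths summing to 5 expected substitutions per site
  (a deep inter-domain split; even lengths keep parsimony counts
  informative where a few very long coalescent branches would saturate
  them), joined by a stem of 0.5 per side.
* Site classes: 30% Type-I (split evenly between slow-in-A and
  slow-in-B — divergent fractions of this order are reported for deep
  two-domain protein families), 5% Type-II, the rest null.
* Null sites share one `Gamma(1, 1)` rate across clades. Type-I sites
  realize the prototype heterotachous contrast: the slow clade evolves at
  `1/√ratio` and the fast clade at `√ratio` times the average rate
  (ratio 10), so every planted site actually displays the pattern being
  planted. Type-II sites switch state exactly once on the stem and
  evolve at rate 0.005 within clades, leaving both clades conserved for
  different residues with ≥ 95% probability per site.
* Substitutions follow a Poisson process per branch with uniform
  replacement over the 19 alternative residues — deliberately simple and
  oracle-checkable; an empirical exchangeability matrix is out of scope
  for the default generator.
* Toy complexes: the elongation-factor chain snakes through a coarse
  cubic grid (spacing ≥ max(14 Å, 2·cutoff + 4.5 Å), which keeps
  coordinates inside PDB fixed-width fields under any rigid motion and
  guarantees the margins below); each planted interface column gets one
  partner atom at cutoff − 0.5 Å from its C-alpha while every other
  partner atom stays ≥ cutoff + 2 Å from all chain atoms, and the
  construction is re-verified numerically before writing. A second file
  holds the same complex under a random rigid motion.
* Assay tables: band-intensity pairs with planted bound fractions and
  multiplicative lognormal noise; CPM replicates as background × fold
  with relative Gaussian noise (15%), two alternating buffer labels, and
  an optional planted gross outlier.

What the generator does **not** emulate: indels, empirical amino-acid
exchangeabilities, among-lineage rate drift within a clade, structural
flexibility, or correlated sites. Passing tests therefore demonstrate
that the pipeline recovers planted signals under its own generative
assumptions, not that it matches any particular real dataset.

## Assay statistics

Bound fraction is `100 · exchange / (EF + exchange)` per lane. CPM values
are normalized by ratio to the mean of the no-EF background reactions.
Outliers are removed by an iterated Grubbs test (two-sided, α = 0.05):
each round removes the single most extreme point if its studentized
deviation exceeds `G_crit(n, α) = ((n−1)/√n)·√(t²/(n−2+t²))` with `t` the
upper `α/(2n)` Student-t quantile on `n−2` df, stopping when nothing
exceeds the threshold or fewer than 3 points would remain. Group
comparisons use the pooled-variance two-sample t statistic with a
one-tailed p-value in the stated direction, starred at p < 0.05 and
p < 0.01; zero pooled variance yields p = 0.5 for equal means, else 0/1
by sign. Buffers are pooled by default, with a `stratify_by` switch for
per-buffer outlier screening.

## Numerical choices and degenerate inputs

* All mixture arithmetic is in log space (`gammaln`, `logaddexp`);
  θ is bounded to [1e-6, 1−1e-6] and α to [1e-3, 1e3] on a log scale.
* Alignment columns are 1-based everywhere; gaps are missing data, never
  a 21st state.
* PDB reading keeps the first-listed alternate-location conformer, model
  1 only, heavy atoms only; waters and HETATM records are skipped.
  A HETATM-only file parses to an empty structure with a warning.
* Kabsch requires ≥ 3 non-collinear pairs and excludes reflections via
  the determinant sign.
* Contact boundary is inclusive (min distance ≤ cutoff is a contact).
* Ties in Type-II ranking and all site-set operations are resolved by
  fixed deterministic keys, so every pipeline output is byte-identical
  across reruns with the same inputs, config and seed.

## Problem sizes

Default test and verification sizes: 400-column, 30-taxon alignments for
pipeline-level checks; 2000-site count tables for parameter recovery;
200 random small trees for the parsimony oracle; 50 toy complexes for
the geometry oracle; 1000 replicate null tables for t-test calibration.

## Known limitations

* θ estimated from sequence-level simulations is biased upward relative
  to the planted Type-I fraction (the deterministic planted contrast is
  sharper than the model's gamma-distributed divergent component, and
  Type-II sites are absorbed into the mixture); per-site posteriors and
  rankings — which drive the designs — are the quantities validated
  against planted truth.
* Fitch counts saturate on long branches; the method loses power on
  clades with few taxa or very uneven trees.
* The Type-II score is a ranking heuristic, not a calibrated posterior.
* Superposition has no outlier rejection, so a partly divergent backbone
  degrades the inferred interface gracefully rather than being trimmed.
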