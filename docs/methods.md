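# Methods

## The traffic model

Lipid distribution driven by hepatic biosynthesis is modelled as a
star-shaped network: an origin (liver) connected to a hub (serum), and the
hub connected to each terminus (CNS compartments, heart, adipose).  Three
presets mirror a two-generation paternal-diet study design: `F1N`
(liver–serum–{brain, heart}; adipose is too small to dissect in
neonates), `F1A` (liver–serum–{cerebellum, right brain, heart, adipose})
and `F2N` (liver–serum–{cerebellum, right brain, heart}).  Custom
networks keep the origin→hub→termini orientation, because axis labels are
directional (pairs of one-letter compartment codes read origin→terminus,
`LS` = liver→serum; codes are the first unused letter of the compartment
name, falling back deterministically to later letters).  Only hub-mediated
axes exist: the model deliberately contains no liver–heart style shortcut
edges, and edges carry no fluxes or rates — presence is interpreted as an
average over the developmental period, not a kinetic quantity.

## Detection and categorisation

A variable is present in a (compartment, phenotype) cell when its signal
is > 0 in ≥ 50% of the cell's samples, evaluated on the exact fraction
(3 of 5 = 0.6 → present; 2 of 5 = 0.4 → absent; exactly 50% passes).
Presence for the study overall is the union over phenotypes ("either
phenotype" reading); per-phenotype presence is what the switch analysis
consumes.  A pooled-evaluation variant (fraction over all samples of a
compartment) is exposed via `detect_presence(..., rule="pooled")` for
sensitivity analysis; per-phenotype is the default.  Positive- and
negative-ionisation-mode blocks are analysed separately end to end, so a
mode column is mandatory; when a compartment (typically adipose) was
profiled both untreated and petrol-washed, negative-mode analysis uses
the washed samples and positive-mode the untreated ones.

Categories, per phenotype:

* **A** = the intersection of presence over all compartments;
* **B(axis)** = present at both axis endpoints, minus A.  B-sets exclude
  A-type variables so that A and B counts partition cleanly;
* **U(c)** = present at c and absent from every *neighbour* of c.  The
  rule is literal: co-presence in two non-adjacent compartments (e.g.
  liver and brain) yields a U assignment in each.  Non-adjacent
  co-presence has no other natural home in an adjacency-based scheme.

These rules guarantee that every detected variable receives at least one
assignment (if it has a present neighbour it is on that B axis or in A;
if not it is U), and that A∩B = ∅ and U(c)∩B(axis∋c) = ∅ — both verified
by an exhaustive oracle over all presence patterns on a 3-node network
and by randomised property tests on the presets.

## Per-axis comparison

The variables "travelling" an axis are those present at both endpoints.
By default this *includes* A-type variables (they demonstrably traverse
every axis); `include_ubiquitous=False` restricts to B-type only, and the
CLI emits both conventions, since published axis counts cannot be audited
against either convention without the underlying raw data.

Two phenotypes' axis lists X, Y are scored with the Jaccard–Tanimoto
coefficient J = |X∩Y|/|X∪Y| (undefined — an error, not 0 or 1 — when both
lists are empty; axis-level code surfaces that case as NaN).  The p-value
uses a subset-resampling null: X′ and Y′ are redrawn independently as
uniformly random subsets of the universe (default X∪Y) with the observed
sizes, and p = P(J(X′,Y′) ≤ J_observed) — the probability of dissimilarity
at least as large by chance.  This tail convention reproduces the
defining worked example: for a two-element list that is a subset of a
three-element list over their union, every redraw gives J′ = 2/3 = J_obs,
so p = 1.  With fixed sizes, J is strictly increasing in the intersection
size k, and k is hypergeometric (population |universe|, successes |X|,
draws |Y|); the `exact` method therefore sums hypergeometric mass over
k ≤ k_obs, which is complete subset-pair enumeration collapsed by
symmetry and tractable at any size — no enumeration cut-off is needed.
The `montecarlo` method (seeded; default 10⁴ draws) simulates actual
subset pairs and exists mainly as an independent check of the exact
route; the test suite additionally cross-checks the exact route against
literal `itertools` enumeration on all universes of size ≤ 5.

A heuristic sometimes attached to this statistic — that p < 0.5 implies
both groups hold unique variables — is not guaranteed under this null and
is not asserted anywhere in the package.

**Re-routing.** For two axes sharing the hub, a variable is re-routed
when it travels `from_axis` in the control phenotype but not the
experimental, and travels `to_axis` in the experimental but not the
control.  All four clauses are required; a variable on both axes in both
phenotypes is excluded.  Routing diagrams serialise (variable, phenotype,
axis) edges as DOT and GraphML.

## Abundance analysis

Per variable and compartment, with E the experimental and C the control
group on the per-mille scale:

* margin change = x̄_E − x̄_C, with a two-tailed two-sample t-test.  The
  classical equal-variance Student's test is the default (Welch's behind
  `equal_var=False`); when both groups are constant the degenerate limits
  p = 1 (equal) or p = 0 (different) are used.
* ENFC = log₁₀(x̄_E/x̄_C) / √((a²+b²)/2) with a, b the sample (n−1) SDs
  on the stored scale.  The measure mixes a log numerator with a raw-SD
  denominator by construction; it is implemented exactly as defined
  rather than made dimensionally tidy, and is exactly antisymmetric under
  group swap.  It is undefined (NaN row, noted) when a group mean is zero
  or both SDs are zero.

Significance uses a per-test threshold α/√N, N the number of variables in
the analysed mode block.  The √N rule is the correction consistent with
the reference threshold pair (586 variables at α = 0.05 → 0.0021 at
2 s.f.); lipid variables are strongly dependent (shared chains and
classes), which is why plain Bonferroni (available as
`correction="bonferroni"`) is not the default.  Tests are per compartment,
not pooled across compartments.  Rows with a missing group or zero group
mean are emitted as not-computable with a reason, never silently dropped:
an all-zero group is a switch-analysis fact, not an abundance estimate.

## Synthetic data

The generator emulates the study conditions: a preset network, two
phenotypes (`NP-NC` control, `LP-HC` experimental) with 8 samples per
(compartment, phenotype) cell by default (the emulated design used ~6–8
per group), and ~500 variables spread over 14 lipid classes with
class-level log-location offsets (TG ≫ PC ≫ minor phospholipids ≫ lyso
species) so that the per-mille composition is realistically dominated by
TGs and PCs.  Per-variable baselines get an extra N(0, 0.8) ln-scale
spread; sample noise is log-normal with σ = 0.25 (ln units), a moderate
biological+technical variability typical of semi-quantitative
direct-infusion profiling; detection dropout zeroes present cells with
probability 0.05 by default.  Each variable draws a category —
A/B/U with weights 0.45/0.35/0.20 — and a corresponding compartment
membership shared by both phenotypes.

Planted structure overrides membership: a re-route sets the control
membership to the `from_axis` endpoints and the experimental membership
to the `to_axis` endpoints; a fold change multiplies the experimental
group's values in one compartment (membership there is forced in both
phenotypes so the comparison is computable).  Because non-planted
memberships are identical across phenotypes, a dropout-free scenario
recovers planted re-routes *exactly* (no false positives or negatives) —
this is a structural property, and the test suite asserts it over 20
seeds.  The manifest records config, per-variable categories and
memberships, and all plants.  Same config + seed ⇒ byte-identical output.

What the generator does **not** model: mass spectra, isotopes, ionisation
efficiency, isobaric overlap, batch/plate effects, and inter-variable
correlation beyond compositional closure.  Passing tests therefore
demonstrate correctness of the set logic and statistics under the stated
noise model, not robustness to instrument artefacts.

## Numerical and design notes

* Signal correction divides each sample by its total analyte signal
  excluding internal standards and scales to 1000 ‰; it is idempotent and
  rank-preserving within a sample, and rejects all-zero samples.
* Species identity is canonical `CLASS(C:D)`; a trailing `(PW)`
  annotation (petrol-washed provenance) and whitespace are stripped into
  flags, not identity.  Sum composition only — no sn-positions, chains,
  masses or adducts.
* An odd total carbon count implies at least one odd-chain fatty acid
  (even-length chains cannot sum to an odd total); the converse is not
  decidable at sum-composition level and is not claimed.
* The DNL (de novo lipogenesis) marker set is user configuration matched
  by exact canonical name; no marker list is hard-coded.
* Monte-Carlo p-values accept either an integer seed or a shared
  `numpy.random.Generator`, so batch comparisons can run on one stream.
* Problem sizes in the test suite (3–6-element universes for enumeration
  checks, ~500–1000-variable simulations, 20 recovery seeds) are chosen
  to make the statistical assertions sharp — 3-binomial-SE bands on 10⁴
  draws — while keeping the default suite fast.

## Known limitations

* The subset-resampling null treats variables as exchangeable; correlated
  presence (e.g. within a lipid class) is not modelled.
* Per-mille normalisation induces compositional dependence between
  variables; with hundreds of variables the induced bias is negligible,
  but analyses of datasets with a few dominant variables should expect
  closure effects (visible as compressed ENFC values).
* The equal-variance t-test on log-normal data is approximate at small n;
  the null false-positive calibration test bounds the practical impact at
  the default noise level.
* Axes are hub-mediated only; direct terminus–terminus exchange, if it
  exists biologically, is invisible to the model.
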