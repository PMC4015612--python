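# Methods

## Model and procedure

`hubmod` tests network modules — a hub node together with all of its
direct interaction partners — for *differential co-expression*: a
change, between biological conditions, in the average correlation
between the hub's expression profile and its partners' profiles. This
is deliberately orthogonal to differential expression; a module can be
strongly dysregulated in this sense while every member keeps an
identical mean level in all conditions.

The pipeline is:

1. **Module extraction.** A node is a hub when the number of its
   interaction partners present in *both* the network and the
   expression matrix is at least `min_partners` (default 5, the
   conventional working definition of a hub in interaction-network
   analysis). Partners without an expression row are dropped before the
   degree is counted; a candidate hub without an expression row is
   excluded with a warning. Modules may overlap — a hub can be another
   hub's partner. For directed microRNA → target networks only source
   nodes are hub candidates.
2. **Correlation profile.** For each module, the hub-partner
   correlation (Pearson by default; Spearman optional for heavy-tailed
   or non-linear data) is computed within each condition over
   pairwise-complete samples. A correlation is undefined when fewer
   than three complete pairs remain or either vector has zero variance
   within the group. A partner undefined in *any* condition is dropped
   module-wide, so observed and permuted statistics are computed on the
   same partner set.
3. **Statistic.** With two conditions: the absolute difference of the
   two condition means of the partner correlations (symmetric in the
   conditions). With three or more: a one-way ANOVA F on the
   correlation values grouped by condition. The F treats the
   correlations as independent observations within groups; partner
   pairing across conditions is ignored — the simplest F consistent
   with testing "is the average correlation equal across groups". Raw
   correlations are averaged (no Fisher-z transform, no absolute
   value), so coherent sign flips register as dysregulation.
4. **Permutation test.** The sample → condition assignment is permuted
   globally — one shuffle applied to every gene simultaneously, group
   sizes preserved — which keeps the gene-gene correlation structure
   intact under the null. One shared, seeded set of B assignments is
   reused across all modules of a run, making module p-values
   comparable and runs reproducible. Sampled mode reports the add-one
   estimate (1 + #{null ≥ obs})/(B + 1), whose floor 1/(B+1) also
   guarantees strictly positive p-values for Fisher combination.
   Exhaustive mode enumerates all distinct assignments (identity
   included; refused above a cap of 10,000 assignments) and reports the
   exact tail fraction.

## Meta-analysis

Hubs present in **all** N result tables are combined; hubs missing
from any table are reported in a side list, not analysed (keeping both
combination rules well defined). Fisher's test uses −2 Σ ln pᵢ against
χ²(2N), with each pᵢ clamped below at its run's permutation floor
1/(Bᵢ+1) — never at an arbitrary epsilon. The rank product assigns
within-dataset ranks ascending by p (ties broken by larger statistic,
then hub ID), takes the geometric mean across datasets, and estimates p
from a pooled permutation null built by independently shuffling each
rank column (default 1000 shuffles); this is the simplest permutation
form of the rank-product family.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_partners` | 5 | minimum expression-covered degree for a hub |
| `method` | pearson | correlation measure (spearman optional) |
| `B` (`--permutations`) | 1000 | sampled-mode permutations; p-floor 1/(B+1) |
| `seed` | required in API | drives all permutations; echoed to the log |
| `alpha` | 0.05 | strict threshold p < alpha for annotation/export |
| `exhaustive_cap` | 10000 | largest enumerable assignment count |
| meta `n_null` | 1000 | rank-product null shuffles per dataset |

## Synthetic data

The generator plants star modules with exact per-condition population
correlations: within condition c the hub is standard normal and each
partner is ρ_c·hub + √(1−ρ_c²)·noise (times `noise_sd`, which leaves
correlations untouched). Sample correlations converge to ρ_c at the
Fisher-z rate 1/√(n−3). Dysregulation is planted only through ρ, never
through mean shifts, isolating the differential-correlation signal. A
unit-variance Student-t (5 df) noise family stresses the Spearman path.

What the generator does **not** emulate: realistic interaction-network
topology (modules are disjoint stars; real hubs share partners),
measurement-level artefacts (batch effects, probe saturation,
missingness patterns), non-Gaussian marginals beyond the t option, and
between-partner correlation beyond what the shared hub induces. Passing
calibration and power tests on these data therefore demonstrates the
statistical machinery is correct and well calibrated under the stated
generative model, not that any particular real dataset will yield
well-calibrated p-values.

## Numerical choices and degenerate inputs

* Zero variance is detected by an exact constant-vector check (max ==
  min) before centring, avoiding spurious correlations from rounding;
  computed coefficients are clipped to [−1, 1].
* F-statistic edge cases: 0/0 → 0 (a fully degenerate null module is
  not evidence of dysregulation); positive/0 → +inf (perfect separation
  dominates every permutation it is compared against).
* Under a permuted labelling a partner can become zero-variance; it is
  dropped for that permutation only. If *no* partner survives a
  permutation, that permutation is counted as ≥ observed —
  conservative, and logged.
* Duplicate gene rows (multiple probes) collapse to the row with the
  highest mean expression: deterministic and standard probe-collapsing
  practice.
* Result tables are totally ordered (p, then hub ID), so serialisation
  is byte-stable; all exports are deterministic.
* Colour ramp: piecewise-linear per RGB channel through red (−1),
  yellow (0), green (+1), channels rounded half-up; undefined
  correlations are grey. A colour-blind-safe blue/grey/orange ramp is
  available (`palette="cb"`).

## Design choices where the design was open

* **Pearson, raw averaging** as the default mirrors the hub-module
  co-expression literature this method descends from; Spearman and a
  z-transform averaging option exist but are off by default.
* **One-way F** (no repeated-measures structure) — documented above;
  a partner-paired F is a possible refinement but changes the null.
* **Module-wide partner dropping** (rather than per-condition
  imputation) keeps the observed and permuted statistics on a common
  partner set.
* **Intersection-only meta-analysis**: combining evidence for a hub
  absent from some dataset would require imputing a p-value or rank;
  we report such hubs separately instead.
* **No built-in multiple-testing correction** in the core result: the
  pipeline thresholds raw p < 0.05 by convention; a Benjamini-Hochberg
  q-value column is available at write-out.
* **Strict p < alpha** for significance in annotation and export.
* Census matching is by exact, case-sensitive symbol; synonym
  resolution is out of scope.

## Study sizes used in tests and the acceptance script

Calibration and recovery are measured at desk scale: type-I error over
500 null modules (5 partners, 20 samples/condition, B = 199), power
and top-ranking over 100 replicates of one planted ρ = 0.8-vs-0.0
module (10 partners, 30 samples/condition, B = 199) among 20 null
modules, the 3-condition F path over 100 replicates (B = 499, chosen
larger so p-value granularity 1/(B+1) rarely ties the planted module
with a null at the floor), and exact-vs-sampled agreement on a
4+4-sample module (70 distinct assignments, B = 5000). These sizes give
binomial standard errors comfortably inside the asserted bounds.

## Known limitations

* Permutation inference assumes exchangeable samples under the null;
  confounded designs (batch aligned with condition) will inflate the
  type-I error.
* The F path inherits ANOVA's sensitivity to unequal within-group
  variances of the correlation values.
* Overlapping modules are tested marginally; no joint or conditional
  inference across modules is attempted, and p-values of overlapping
  hubs are dependent.
* MITAB parsing reads only the primary identifier columns; alternative
  identifiers and aliases are ignored, and the TargetScan/Microcosm
  column layouts are configurable defaults, not guaranteed matches for
  every release.
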