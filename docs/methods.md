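# Methods

`mixshift` implements a quantitative framework for two linked questions
about micropollutants at the sediment–water interface (SWI): how fast do
they dissipate, and how much biology contributes; and does a mixture of
micropollutants shift prokaryotic community composition additively,
synergistically, or antagonistically relative to the compounds applied
singly. All computations run on tabular inputs (concentration time series
and annotated ASV count tables); a synthetic-data generator stands in for
raw measurements so every stage is testable offline.

## Dissipation kinetics

Dissipation of a compound is modelled as first-order decay,
C_t = C_0 · e^(−kt), fitted in its linearised form by ordinary least
squares of ln C on t with all replicate points pooled into one regression
(so the reported n counts points, not timepoints). Zero or negative
concentrations produced by measurement noise are excluded from the log
fit; fewer than three usable points is an error, and a non-positive
estimated rate is flagged non-dissipating with an unbounded half-life.

Derived quantities:

- **DT50 range** (days): ln 2 / (k ± SE), a 1σ band on the half-life.
  Unrounded internally; reported rounded to whole days.
- **CI95 of k**: two conventions. The default *paper* convention used in
  reporting tables is ± z·SE/√n with z = 1.96 — a deliberately narrowed
  comparison interval (the regression SE is divided by √n once more than
  the usual large-sample formula). The *standard* convention (± z·SE) is
  the interval with nominal ~95 % coverage; it is what the coverage
  validation measures, since the narrowed interval is a comparison device
  between conditions, not a coverage statement. Rates are reported to
  3 decimals (half-to-even).
- **Dissipation** D,t % = 100 · (1 − mean C_t / mean C_0) over replicates,
  with a first-order (delta-method) 1σ SD propagated from the replicate
  standard deviations of both means.
- **Biodegradation fraction** B,t % = D_biotic,t % − D_abiotic,t %, the
  loss attributable to biological activity, with the two 1σ errors
  combined in quadrature. Recomputing B from *printed* integer-percent
  dissipation values carries ±1 point of rounding slack, which the tests
  allow.
- Two rates are called *distinct* when their CI95 intervals do not
  overlap.

Bundled reference statistics (`mixshift.refdata`) hold the published
summary values for metformin (MFN), metolachlor (MET) and terbutryn (TER)
in single-compound (ONE) and mixture (MIX) microcosms under biotic and
sterilised (abiotic) regimes: k ± SE with n, CI95 and DT50 ranges, and
day-70 system-wide dissipation. They serve as recomputation oracles and
as generator defaults. One reference row (MET MIX, day 70) is internally
inconsistent as printed — its biotic dissipation is below the abiotic one
yet the biotic fraction is printed positive — so its B is compared by
magnitude only.

## Community statistics

The community module operates on an `AbundanceTable` (integer taxa ×
samples counts, a seven-rank taxonomy, and sample metadata with matrix ∈
{sediment, water}, timepoint ∈ {d0, d70}, condition ∈ {CTRL, MFN, MET,
TER, MIX}, replicate).

- **Prevalence filter**: a taxon is kept only if some replicate group
  (matrix × timepoint × condition) contains it in ≥ 2 samples (default);
  single-replicate detections are treated as spurious. Idempotent.
- **Aggregation**: counts are summed by lineage truncated at the
  requested rank; taxa unassigned at that rank are grouped by their
  deepest assigned lineage under `unclassified <name>`, conserving
  per-sample totals exactly.
- **Alpha diversity**: observed richness, Chao1 (bias-corrected form, so
  it is defined when no doubletons exist), ACE (rare cutoff 10), Shannon
  in natural log, Simpson diversity as 1 − D (the inverse form is
  reported alongside), Pielou J = H/ln S (same log base, so J ∈ [0, 1]),
  Simpson and Camargo evenness, and Good's coverage 1 − F1/N. Undefined
  values (all-zero sample, Pielou with S = 1) are NaN, not errors.
  Camargo evenness, 1 − Σ_{i<j}|p_i−p_j|/S, is implemented in-package;
  the rest are delegated to scikit-bio.
- **Rarefaction**: mean metric over repeated multivariate-hypergeometric
  subsamples without replacement (default 50 draws, seeded); depths
  beyond a sample's total are skipped with a warning.
- **Bray–Curtis** is computed on total-sum-scaled relative abundances by
  default (sequencing depth is a nuisance, not signal); a raw-count mode
  exists. **Dendrograms** first collapse the sample distance matrix to
  between-group means and then cluster the groups by average linkage
  (UPGMA), serialised as Newick.
- **PERMANOVA** is implemented in-package (sequential sums of squares on
  the Gower-centred inner-product matrix; pseudo-F per term against the
  full-model residual) rather than wrapped, because two features the
  analysis needs are not available together in library implementations:
  *strata-restricted permutations* (labels permute only within levels of
  a blocking factor, to neutralise a confounded factor) and *exhaustive
  enumeration* at small n (p = #(F_perm ≥ F_obs)/N including the
  identity). With sampled permutations p = (1 + #(F_perm ≥ F_obs))/(1 +
  n_permutations). Terms are fitted sequentially (order matters, as in
  type-I ANOVA); R² of terms plus residual sums to 1 by construction.
  The pseudo-F agrees with scikit-bio's single-factor implementation to
  machine precision, which the test suite asserts as a cross-check.

## Mixture-effect classification

The core statistic chain, per taxon and stratum (matrix × timepoint),
on relative abundances:

1. Replicate means use the *single-null rule*: when exactly one of three
   replicate values is zero the group is treated as a duplicate (mean of
   the two non-zero values); any other zero pattern averages all values.
   (How multi-null patterns should be handled is not specified by the
   rule's source; the literal single-null reading is implemented.)
2. **Fold change** FC = (mean_sample + 0.001)/(mean_control + 0.001)
   against the CTRL group of the same stratum. The 0.001 pseudo-count
   (0.1 % relative abundance) keeps FC finite and damps noise from taxa
   far below that abundance.
3. **Interaction coefficient** IC = FC − 1; **additive expectation**
   IC_ADD = max(−1, IC_MFN + IC_MET + IC_TER). Summing ICs rather than
   FCs avoids the bias where two decreases (FC 0.4 and 0.6) would sum to
   an apparent no-effect; the −1 floor encodes that a taxon cannot lose
   more than its whole control abundance.
4. **Classification**: each coefficient v gets a conservative relative
   uncertainty band [v − r|v|, v + r|v|] with r = 0.64 by default — the
   third quartile of replicate relative errors of relative abundances, an
   empirical quantity the package recomputes from any table
   (`replicate_relative_error_q3`). Overlapping bands → *additive*;
   disjoint bands with strictly opposite signs → *antagonism (opposing)*;
   otherwise *synergism* if |IC_MIX| > |IC_ADD|, else *antagonism
   (repressing)*. "Exceeds"/"falls short" is interpreted by magnitude for
   sign-compatible pairs; a `signed_rule` flag implements the literal
   signed comparison instead (the two coincide on all published worked
   examples, which the tests pin). IC values of exactly 0 have degenerate
   bands and are sign-compatible with either sign, so a taxon absent from
   all single-compound conditions but present in the mixture classifies
   as synergistic.
5. **Contributor ranking**: per taxon, the compound whose single-compound
   FC is closest to the mixture FC (absolute gap); ties within 1e-9 yield
   binary-combination labels (MFN_MET, …), a three-way tie yields ALL.

Uncertainty bands scale with |IC|, so they never cover zero for a nonzero
coefficient; two near-zero coefficients of opposite sign therefore always
classify as opposing. Interpretation of calls on taxa with negligible
effects in *both* arms should be avoided — the recovery benchmark only
scores taxa with planted, well-separated effects for this reason.

## Synthetic data generator

`SyntheticSpec` describes a full experiment: three compounds with
per-regime rates, water/sediment partitioning fractions (MFN 1.0, MET
0.5, TER 0.2 by default, matching their hydrophilicity ordering), C0 =
17.6 µM, 10 % relative measurement noise, sampling days {0, 15, 30, 50,
70}; biotic series in triplicate, abiotic in duplicate (sterilised
microcosms are run leaner in the emulated design). Transformation-product
chains are generated as sequential first-order compartments (matrix
exponential) for fixture realism only; no validation depends on them.

Community counts: baseline relative abundances are log-normal(0, σ = 2)
(heavy-tailed, like real 16S data), renormalised; the expected abundance
of taxon i in a sample is baseline × matrix multiplier × d70 multiplier ×
exp(condition log-effect). The mixture condition follows a per-taxon
rule: *additive* = exp(sum of the three single-compound log effects);
*synergistic*/*repressing* scale that summed log effect by mix_scale
(> 1 / < 1); *opposing* inverts its sign. Counts are multinomial at a
per-sample log-normal depth (default mean 50 000, σ = 0.1).

Planted effects live on the absolute scale but the analysis observes
relative abundances, so the ground-truth table stores the *expected
relative-abundance* FC/IC values (pseudo-count and compositional
renormalisation included) and the category they imply — a reachable
target for recovery tests, rather than the raw multipliers.

Two factories define the study conditions:

- `default_spec`: 120 taxa structured matrix ≫ time ≫ contamination —
  taxa alternate water/sediment specialists (log-scale matrix multiplier
  ±1.8, SD 0.6), incubation drifts every taxon (±0.55, SD 0.3), condition
  effects are weak and centred (N(0, 0.15)), mixture additive. No
  quantitative effect sizes exist to emulate, so these scales are chosen
  to make the qualitative factor hierarchy unambiguous.
- `interaction_benchmark_spec`: 50 background taxa plus 10 planted taxa
  per category. Additive/repressing/opposing taxa are pinned at 0.4–0.6 %
  baseline (clear of the pseudo-count); synergistic taxa follow the
  emergence regime — rare at baseline (0.004–0.007 %), small single
  effects, mix_scale 3.5 — because that is where synergy is identifiable.
  Synergism and repression are planted in the increase direction only:
  under the −1 floor and multiplicative bands, their decrease-direction
  counterparts converge to the additive band in expectation and are not
  identifiable by any classifier honouring the definitions, so planting
  them would score the generator, not the method. Effect magnitude ranges
  were fixed analytically from the pseudo-count and renormalisation
  arithmetic so the expected-value classification separates with margin.

What the generator does *not* emulate: taxon–taxon interactions
(predation, cross-feeding), overdispersion beyond multinomial sampling
(an optional per-replicate log-normal `replicate_sigma` exists, default
off), chimeras or sequencing error, phase-specific communities coupled to
compound partitioning, and chemistry-accurate transformation kinetics.
Passing recovery tests therefore demonstrates correctness of the
statistic chain under the stated sampling model, not robustness to every
feature of real amplicon data.

## Validation experiments

(`mixshift.experiments`; all pure functions of a seed; problem sizes
chosen to keep the full suite in the low minutes on one core.)

- **Kinetic CI coverage**: 200 noisy decay simulations (k = 0.06/day,
  10 % noise, 5 timepoints × 3 replicates); the true rate should fall in
  the standard CI95 in ≥ 90 % of runs (z = 1.96 with 13 residual df gives
  slightly under nominal 95 %).
- **PERMANOVA type-I error**: 500 null datasets (iid normal features,
  two balanced groups of 10, 999 permutations); rejection rate at
  α = 0.05 should be 0.05 ± 0.02.
- **Enumeration agreement**: at n = 5 the exhaustive-permutation p must
  equal a brute-force oracle that recomputes pseudo-F from within-group
  squared distances over all 120 label permutations.
- **Interaction recovery**: ≥ 90 % of planted synergistic/opposing taxa
  recovered and ≤ 10 % false non-additive calls on planted-additive taxa
  (these thresholds are validation settings of this artifact, not claims
  about any real dataset).
- **Factor ordering**: the sequential R² ordering matrix > time >
  condition should hold in ≥ 95 % of 100 simulated communities.

## Numerical conventions and edge cases

Reporting rounds half-to-even (rates 3 decimals, DT50 and percentages to
integers); internal values stay unrounded. Permutation p-values include
the observed statistic in the numerator and denominator for sampled
permutations. Tie tolerance for contributor ranking is 1e-9 absolute on
FC gaps. All randomness flows through `numpy.random.Generator` seeded
from explicit integers; identical config + seed reruns are byte-identical
(outputs carry the config hash and seed in '#' headers, and the manifest
contains no timestamps).

## Known limitations

Single-compartment first-order kinetics only (no biphasic/DFOP models, no
sorption isotherms). Sequential (order-dependent) PERMANOVA sums of
squares; marginal tests are not implemented. The ±64 % band and the
pseudo-count are tied to the relative-abundance scale; raw-count modes
exist but the defaults assume compositional data. Study-scale dataset
quantities (tens of thousands of ASVs, published R²/F/p and category
percentages) require the original sequencing data and are out of scope;
the validation suite substitutes property-based checks at desk scale.
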