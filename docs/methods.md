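# Methods

`sigkin` quantifies kinship and social structure in managed (zoo) animal
populations from studbook records, predicts individual reproductive success
from that structure, and searches for rearrangements of animals across
institutions that improve predicted population-wide output. This note
documents the models, the parameter choices, and what the synthetic
benchmarks do and do not establish.

## Data model

A studbook is a longitudinal registry: one record per animal (identity, sex,
dam, sire, birth and death dates, natal institution) plus dated transfer
events between institutions. All dates are reduced to integer month indices
relative to a configurable epoch; a day-resolved date rounds to its own
month through day 15 and to the next month after. Dates recorded below
month resolution or flagged uncertain (`"1988"`, `"~Mar 1988"`) exclude the
affected event — the whole individual only when the birth date itself is
uncertain, since age and residency then cannot be anchored. Non-zoo
destinations (suppliers, private owners, unlisted addresses) are recoded to
the `WILD` sentinel; arrivals from `WILD` become immigrant founders with no
recorded parents; animals released to `WILD` or lost to follow-up are
excluded, with every exclusion counted per rule so row accounting always
reconciles. Residency is piecewise constant: the transfer month belongs to
the destination, and two same-month transfers resolve to the last.

## Kinship: the path-additive rule and its classical counterpart

The genealogy is a directed acyclic graph (parent → child). A
kinship-informative path between two individuals ascends zero or more
parent edges and then descends zero or more child edges, never revisiting a
node. Edges are role-labelled: the dam edge and the sire edge are distinct,
so a selfing hermaphrodite's child is joined to its one parent by two
length-1 paths. Each path of length `phi` contributes `k**phi` to the
coefficient of relatedness, `k = 0.5` between parent and child, and
contributions add over paths. This path-additive rule deliberately omits the
classical `(1 + F)` correction for inbred common ancestors; the classical
numerator-relationship value from the recursive kinship-matrix construction
is implemented separately (`wright_relatedness`) and serves as an
independent oracle — the two agree exactly whenever common ancestors are
non-inbred, which the test suite verifies on hundreds of random outbred
pedigrees. Pairwise queries are evaluated by an ancestor-chain join
(enumerate each individual's role-labelled ascent chains once, join on
shared terminal ancestors with disjoint interiors), which is algebraically
identical to enumerating paths but does not traverse descendant subtrees.
The default path-length cap is 8 edges.

Classical coefficients are biased by record-keeping: an individual's mean
relatedness to the population tracks its entry order and documented-ancestor
count, not biology (the `analysis/02` driver quantifies this on synthetic
genealogies). The standard inheritance graph (SIG) avoids the bias by
classifying relatives structurally instead of scalar-izing them.

## Standard inheritance graphs

A SIG reduces the kinship neighbourhood of a focal individual to path
classes keyed by the sex string of the ascent (read focal → ancestor;
`"FM"` is the mother's father) and the descent depth: ascendant classes
(class I: ascent only), lateral classes (class II: ascent then descent) and
descendant classes (class III: descent only). Regardless of inbreeding, a
focal with fully documented ancestors has exactly `2**phi` ascendant paths
at degree `phi` — the child of a full-sib mating has two grandparents but
four grandparental paths — and each ascendant path ends at exactly one
individual of determinate sex, so class-I keys hold one member while
class-II/III keys hold any number of either sex. Focal individuals enter an
analysis only with a complete degree-`d` ascendant set, `d` in {1, 2, 3};
deeper documentation is rare because pedigrees typically reach an
undocumented founder within four generations. The descent cap of class-II/
III enumeration defaults to `d` and is reported with any fitted model.
Lateral paths may not re-enter the focal's own ascent chain, so the focal's
descendants are never double-counted as lateral kin. Classification
preserves relatedness: summing `k**(ascent+descent)` over an individual's
class keys (with path multiplicity) recovers the path-additive coefficient
restricted to the SIG bounds.

## Outcome and covariates

Reproductive success over a window (`r_III`) is the sum of path-additive
relatedness to all descendants born within it — one child contributes 0.5,
one grandchild 0.25 (credited at the grandchild's own birth month) — so
producing sterile versus fecund offspring is weighted differently. Design
matrices hold one row per focal per month of zoo residency with:

* base variables: age (months), sex (female 0, male 1), and female / male /
  total / age-binned group sizes in the focal's zoo (bins at 6 and 24
  months, reflecting juvenile / subadult / adult stages; the focal counts
  itself);
* per SIG class: local kin `alpha` (living members in the focal's zoo),
  non-local kin `beta` (living members elsewhere; `alpha + beta` is global
  kin), and pseudo-kin `gamma` — individuals in the focal's zoo with zero
  path relatedness to it whose sex and age match a living member of the
  class within ±3 months (a tolerance the month resolution makes necessary;
  exact-month matching is too sparse), each counted once per class;
* the outcome: cumulative `r_III` over the next `horizon` months (12 by
  default — the window the group-structure optimizer maximizes; 24 for the
  recovery study). Forecast-mode rows add the focal's past `r_III`
  (`prev_rs`) as a predictor and drop rows where the focal dies inside the
  horizon; current-mode rows keep all months and use social conditions only.

The competing model specifications are: local, non-local, global and pseudo
(one variable set each), `sigma` (`alpha + gamma` summed per class —
kin-blind) and `split` (`alpha` and `gamma` as separate variables —
kin-aware). Models can include or exclude the class-III (descendant)
counts; the benchmark studies exclude them, because a focal's
living-descendant count is a thin proxy for its own reproductive history
and the comparison is meant to isolate social structure — reproductive
history enters explicitly, and only, as `prev_rs` in forecast models.

## Regression trees

The predictor is an ANOVA CART: each node's split maximizes the
between-child sum of squares over every threshold (midpoints of consecutive
distinct values) of every variable, subject to `minsplit = minbucket = 15`
and a complexity gate — a split must improve fit by at least `cp = 0.01` of
the root deviance. Ties break toward the earlier column and smaller
threshold; rows equal to the threshold go left; missing values at
prediction time follow the majority direction recorded at training.
Over-fitting is removed by 10-fold cross-validation over the tree's
cost-complexity (weakest-link) sequence: each fold regrows a tree on the
remaining rows, every complexity level predicts the held-out fold, and each
level's accuracy is the predictive R² of the pooled out-of-fold predictions
(per-fold R² at fold sizes near n/10 is too noisy to rank levels). Two
selection rules are provided: `"best"` takes the highest-accuracy level;
the default `"1se"` takes the simplest level within one standard error of
the best — the standard CART choice, which collapses trees grown on pure
noise to the root leaf in ≥95% of replicates where highest-accuracy
selection keeps spurious splits roughly 10% of the time. External
validation reports both the signed predictive R² (1 − SSE/SST; primary,
and the only variant that can be negative) and the squared Pearson
correlation between predicted and observed outcomes.

## Co-transfer analysis

Same-sex siblings born into a single-paternity litter share identical
kinship structure and age, so co-moving them isolates the kin component of
cohabitation effects. Co-transfer groups are two or more individuals making
their first zoo-to-zoo move in the same month on the same route; members
with any offspring born before the move are excluded. For each member the
analysis counts co-transferred same-sex littermates (same dam, sire, birth
month, sex) and matched non-siblings (same sex, within the pseudo-kin age
tolerance, path-unrelated), and measures subsequent `r_III` from the
transfer to death or data end. Kruskal–Wallis rank-sum tests (tie-corrected,
chi-squared p) compare subsequent success across littermate-count strata
and across matched-non-sibling strata, with counts above 3 pooled, plus a
litter-size-stratified variant. Confound checks use Spearman correlations
of sibling number vs lifetime success and parent vs offspring lifetime
success. Note that parent and offspring lifetime `r_III` are structurally
coupled (a grandchild credits both), so the heritability check is
interpreted against the simulated non-heritable baseline rather than zero.

## Group-structure optimization

The optimizer searches assignments of all living individuals to zoos.
Constraints: no zoo above its historic maximum monthly occupancy over the
trailing ten years, and no occupied zoo below a minimum group size (default
2 — singleton placement of an obligately social species is avoided;
emptying a zoo is allowed). Seed arrangements draw each individual's zoo
with probability proportional to capacity (sampling destinations from the
pool of slots; uniform zoo choice is available but rejects essentially
every draw when capacities are heterogeneous), rejection-sampled until the
constraints hold. Each seed is refined by iterated mutation — a
with-replacement sample of 50 individuals reassigned, redrawn until valid —
and elitist selection among the parent and its five mutants, so per-seed
scores are non-decreasing by construction. Scoring rebuilds every
individual's kin and group covariates as if the arrangement held at the
evaluation month, holding ages and vital states fixed (a static
counterfactual), predicts each individual's 12-month `r_III` with the
fitted kin-blind (sigma) current-conditions model — individuals without a
complete SIG at the model's diameter fall back to a tree on the base
variables so the per-capita mean covers everyone — and averages. The
full-scale search uses 1000 seeds × 40 iterations; the bundled study runs
50 × 10, which already ends strictly above the status-quo prediction on
every synthetic population tried.

## The synthetic studbook generator

The generator is a month-stepped individual-based simulation designed to
reproduce the statistical structure the analysis assumes: two independent
populations of roughly 2800 and 670 individuals over three and two-and-a-half
decades, ~60% of animals with two documented parents (parentage is omitted
from the emitted records with probability 0.38 even though the simulation
knows it), dozens of institutions, immigrant founders treated as unrelated,
and transfers of variable composition — single animals, whole litters, and
same-sex similar-age peer groups.

Females of 12–84 months conceive single-paternity litters (two-month
gestation; fixed sire per litter) at a monthly probability

    base × age_curve × 0.6^(cohabiting siblings)
         × 0.85^(cohabiting matched non-kin)
         × group_multiplier^(group size − 1),

clipped to [0, 1], where "matched non-kin" mirrors the pseudo-kin covariate
(unrelated co-residents matching a living sibling's sex and age within ±3
months). Two further mechanisms give kin and non-kin companions distinct
roles, as in the organism this emulates: a litter requires a co-resident
adult male who is not a close relative of the dam (no shared parent or
grandparent — incest avoidance), and the monthly chance of pairing
saturates with the number of such eligible males
(`1 − (1 − mate_access)^n`). Close male kin therefore crowd breeding
opportunities while unrelated companions supply them — cohabitation effects
that merge destructively when kin and non-kin are summed. Mortality is an
age-graded hazard (higher for pups and the old); unrelated immigrants enter
at a Poisson rate; an optional heritable log-normal fecundity scalar
(default off) provides the positive control for the heritability confound
check.

The recovery parameter set (`recovery_params`) — 20 zoos × 6 founders, 216
months, litter size fixed at the species-typical 3 pups with a
correspondingly higher base rate of 0.09/month — trades some demographic
realism for variance control so the planted effects are expressed above
sampling noise at a population of ~2000. The regional-scale sets
(`north_america_params`, `australasia_params`) keep the 1–5 litter-size
distribution and are calibrated to the target population sizes.

## The benchmark studies and what they show

`sigkin.studies` freezes the study conditions: diameter-1 SIGs, 24-month
outcome, quarterly snapshots, descendant-class predictors excluded, 1-SE
pruning. On independent train/holdout population pairs the kin-aware split
model achieves higher holdout predictive R² than the kin-blind sigma model
in about four replicates of five (measured 33/40 across three seed blocks),
and the fitted split model's first split is a sibling-class count in every
replicate — the planted cohabitation structure is what the model finds.
The absolute R² values (~0.02–0.06) are far below what rich real studbooks
support: a synthetic population whose only predictable structure is the
planted effect is noise-dominated by litter Bernoulli sampling. Passing
these studies therefore shows the pipeline recovers planted kin structure
and preserves the kin-aware/kin-blind ordering; it does not calibrate how
much variance real populations would explain. Diameter-2/3 comparisons are
noisier in both directions (deeper split trees overfit; small holdout
strata can give large negative predictive R²) and are reported by the
analysis drivers but not asserted.

## Numerical and procedural conventions

* Month indices are plain integers and may be negative (founders born
  before the epoch).
* Unknown-sex individuals stay in group-size counts but are never focal
  individuals or SIG members.
* Relatedness ties and tree-split ties break deterministically (documented
  above), so every pipeline stage is reproducible from its seed.
* `k` outside (0, 1], reversed accounting windows, incomplete-SIG focals,
  zero-variance holdout outcomes and over-capacity populations raise
  errors rather than degrade silently.

## Known limitations

* The path-additive rule under-counts relative to the classical coefficient
  only through inbred common ancestors; both are available, and the
  pipeline default is the path rule.
* Pseudo-kin require a living matched relative in the class at the query
  month; a historical-member variant is not implemented.
* The optimizer's counterfactual is static (one evaluation month, ages
  fixed); no demographic projection under the new arrangement.
* Only each individual's first transfer enters the co-transfer analysis.
* The simulator omits dominance hierarchies and reproductive suppression
  beyond the mate-availability mechanism, continuous-time events, and
  marker-based (genomic) relatedness.
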