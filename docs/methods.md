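# Methods

## Data model and standardisation

The unit of replication is the *plot*, nested in a *subsite* (the level at
which coordinates and most covariates exist), nested in a *study area*.
Input is long-format: one record per (plot, survey year, taxon) with an
abundance in survey-method units (point-intercept hits or direct cover).
Only records flagged `control` enter the pipeline.

Standardisation is per plot-year: abiotic and non-vascular records are
removed first, then each remaining vascular record's abundance is divided
by the plot-year vascular total and scaled to percent, so every retained
plot-year sums to exactly 100. Reducing both survey methods to within-plot
proportions is what makes them comparable; the conversion is idempotent.
Plot-years with zero vascular abundance are invalid and rejected with a log
entry.

The morphospecies rule removes any plot-year whose summed relative cover of
records not identified to species exceeds 10% (strictly; exactly 10% is
retained). The rule is read as a *cover* share rather than a record-count
share, matching the cover-centric pipeline; after a plot-year passes,
morphospecies rows are dropped and the remainder renormalised to 100, so
indices operate on identified species only. Whether morphospecies below the
threshold should stay in the denominator is genuinely open; renormalisation
was chosen because it preserves the 100% invariant that the abundance index
relies on.

Eligibility: a plot needs at least two surveys whose first and last years
are ≥5 calendar years apart. Duration is the calendar-year difference of
the endpoint surveys; no within-year dates are used.

## Species classification

Classification uses a zone-occurrence table: per species, a frequency
category (`frequent, scattered, rare, uncertain, introduced, absent`) in
each of the Arctic subzones A–E and the boreal zone. Presence in a zone
means `frequent` or `scattered`; `rare`, `uncertain` and `introduced`
count as absence. Infraspecific rows are merged by taking the most
abundant category per zone under the ordering
`frequent > scattered > rare > uncertain > introduced > absent`
(`uncertain`/`introduced` are placed below `rare` since all three count as
absence; the merge is associative and commutative).

With predicates B (boreal zone), L (Low Arctic D∪E) and H (High Arctic
A∪B∪C), the classes are: Boreal = B∧¬L∧¬H; Boreal-Tundra = B∧L∧¬H;
Arctic = ¬B∧(L∨H); Ubiquitous = B∧L∧H. The two remaining boolean
combinations (no presence anywhere, and boreal + High Arctic without Low
Arctic) match no definition and are surfaced as `Unclassified`; they must
be resolved through a manual-override table before indices are computed —
they are never silently coerced.

## Indices

Turnover uses the endpoint convention: species present only in
intermediate surveys are neither colonisers nor losses. This is the right
convention for a colonisation index (the start value is zero by
construction, so a fitted slope would be dominated by fluctuation), and
the abundance index follows the same convention for consistency; the
package also provides the OLS-slope variant of BAI for comparison, which
equals the end−start rate exactly on two-survey plots.

A plot with no colonisers has no defined colonisation fraction; it is
recorded as BCI = 0 with an explicit `no_colonisers` flag, so the
positive-only subset (BCI > 0 with real colonisers) and the full-range
subset (all plots, zero convention) can be reconstructed unambiguously.
In the full-range binomial model such plots enter as 0 successes of 0
trials and contribute no likelihood, but remain in the data.

Species-level summaries count, per species, the plots where it colonised
(`times_colonised`) and was lost (`times_lost`); the mean annual abundance
change averages over plots where the species occurs at either endpoint —
averaging over all plots would shrink every species toward zero by a
factor that depends on how many plots it happens to miss. For each
colonisation event the summary also records whether the species was
present anywhere in the same subsite at that plot's start year (the
"hidden diversity" signal).

## Null models

The null hypothesis is that class labels are irrelevant to turnover.
Labels are permuted without replacement among all species recorded in a
study area over the whole period (class frequencies preserved; independent
redraws from the pool's boreal proportion are available as a config
option). Per permutation, BCI and BAI are recomputed per plot; the null
BAI is divided by plot duration like the observed index so both share the
%/yr scale. The envelope is the simulated mean ± 2 SD (sample SD, n−1);
flagging is strict (exactly 2 SD is not flagged). One master seed per run
spawns per-study-area substreams deterministically.

For pools of ≤8 species the Monte-Carlo mean and SD are validated in the
test suite against exhaustive enumeration of label placements, within
3 Monte-Carlo standard errors at 999 resamples.

## Covariates

The elevational ("ground") treeline distance for Oro-Arctic subsites is
the hypotenuse of the horizontal distance (km) and the site−treeline
elevation difference (converted from m); Arctic subsites use the
horizontal distance. Distance to treeline is centred by subtracting its
mean. Initial boreal status is the count (for BCI models) or summed
relative cover (for BAI models) of boreal-class species at the first
survey.

Collinearity screening computes pairwise Spearman correlations on
complete pairwise observations, with categorical variables ordinal-coded
according to declared level orderings. For each pair with |ρ| > 0.7
(processed in decreasing |ρ|), the variable lower in a user-declared
keep-priority list is dropped; a conflicted variable with no declared
priority is an error rather than an arbitrary choice. The retained set is
guaranteed to contain no pair above the threshold.

## Models and estimation

Community models regress a plot index on covariates with a subsite random
intercept. Families follow the response: beta with logit link for
positive-only BCI (values shifted by the 0.0001 boundary constant into
(0.0001, 0.9999), so BCI = 1 maps to 0.9999); binomial with logit link for
full-range BCI as boreal colonisers out of total colonisers; Gaussian for
BAI; negative binomial (log link, shape parameterisation, variance
μ + μ²/k) for species-level counts; Gaussian for species mean abundance
change. Species count models filter to species that colonised at least
once, abundance models to species with positive mean change; continuous
traits enter on the log scale.

The random intercept is integrated out per group with adaptive
Gauss–Hermite quadrature (15 nodes; group modes by damped Newton), giving
a marginal likelihood in the fixed parameters. Two backends operate on it:

- **fast** — maximum likelihood (Nelder-Mead then BFGS) with Wald 95%
  intervals from the numerically differentiated Hessian. When the
  random-intercept SD collapses toward zero the likelihood flattens in
  that direction; the SD is floored at 1e-3 (numerically indistinguishable
  below) and a pseudo-inverse covariance is used, flagged in diagnostics.
- **mcmc** — the Bayesian fit: four independent affine-invariant ensembles
  (emcee), 2000 iterations each with the first 400 discarded as warm-up,
  adapt-free stretch moves. Priors: flat on coefficients, half-Student-t
  (3, 0, 2.5) on the random-intercept and residual SDs, gamma(0.01, 0.01)
  on the negative-binomial shape (the weakly informative dispersion prior)
  and on the beta precision. Convergence is summarised by split-R-hat over
  the four chains' walker-mean trajectories; fits exceeding 1.1 are
  returned with a warning and `converged=False`, never silently.

A single-level grouping factor degrades to a fixed-effects fit with a
warning. Pairwise contrasts between categorical levels come from the
joint posterior draws (mcmc) or the Wald covariance (fast), with the
reference level's coefficient identically zero. Effect sizes on log/logit
links are reported as rate ratios via `ModelFit.rate_ratios()`.

Trait filtering scores each record against the mean and SD of the *other*
records of its species × trait (leave-one-out) and removes those beyond
5 SD; with the candidate included in its own reference SD, a single gross
outlier inflates the SD enough to mask itself at realistic record counts
(the maximum attainable z is (n−1)/√n), so the leave-one-out form is the
only self-consistent reading of the rule. Species × trait combinations
with fewer than five surviving records are dropped; means are computed on
the survivors.

## Synthetic data generator

The generator emulates the documented design of the real network: 32
study areas, ~3.5 subsites per area, ~10 plots per subsite (≈1100 plots),
survey pairs 5–28 years apart (shared campaign years within a subsite),
and a 287-species pool in the documented class proportions (16 Boreal,
150 Boreal-Tundra, 14 Arctic, 107 Ubiquitous). Each study area draws a
60-species pool; plot start communities draw ~10 species with Dirichlet
(α = 1) covers. Between surveys, each absent pool species colonises with
probability logit⁻¹(α + β·covariates + γ·boreal); present species go
extinct with probability 0.12; survivors' covers are multiplied by
log-normal noise (σ = 0.4) and renormalised, which induces exactly the
zero-sum coupling the abundance index assumes. The default colonisation
intercept (α = −3.6, ≈1.4 colonisers per plot) was chosen so that roughly
half of the plots experience a boreal colonisation, the prevalence regime
the indices are designed for; the default γ = 0 makes the dynamics
class-exchangeable, the regime in which observed indices should sit inside
the permutation null envelope. Morphospecies and abiotic records are
injected at configurable rates to exercise the filters. A zone-occurrence
table consistent with the generating classes is emitted so the
classification stage can be exercised end-to-end, and the generating
ground truth (classes, per-plot colonisers/losses, coefficients) is
written as JSON.

What the generator does **not** emulate: detection error (species missed
at a survey, which in real data creates artificial turnover), spatially
explicit dispersal, observer and taxonomic drift between campaigns,
climate time series, and unbalanced revisit schedules within a subsite.
Passing tests on synthetic data therefore demonstrate the correctness of
the computations and the calibration of the null under exchangeability —
not robustness to detection error or survey heterogeneity in field data.

## Problem sizes and numerical choices

The test suite runs the calibration check on ≈200 plots with 999
resamples, and parameter-recovery at 50 replicates of 60 subsites × 10
plots (binomial) and 200 species (negative binomial) — sizes at which
interval coverage stabilises while the suite stays fast. The acceptance
script uses the full default network (~1100 plots). Quadrature uses 15
Hermite nodes; Newton mode-finding tolerates 1e-9 with damped steps
clipped at 5; the beta response is clamped to [0.0001, 0.9999]; ties at
exactly 2 SD in the null flag are not flagged.

## Known limitations

- The Wald intervals of the fast backend are asymptotic; at very small
  group counts they can under-cover relative to the MCMC backend.
- The negative-binomial species model is fitted without zero truncation;
  the "colonised at least once" filter is a data filter, not a truncated
  likelihood, so simulation studies that generate many zeros in the
  reference class will show a small downward ratio bias.
- Null-model permutations treat the study-area pool as exchangeable;
  spatially or phylogenetically constrained nulls are out of scope.
- The ordinal codings used for categorical variables in the Spearman
  screen are a declared configuration, not an inference.
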