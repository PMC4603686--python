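# Methods

## Life-cycle model and assumptions

The host grass is projected through four stages (seedling, first-year
juvenile, second-year juvenile, adult) on a one-year, post-breeding
time step; columns of the projection matrix are source stages. The
model is linear, deterministic and density-independent: no seed bank
(ungerminated seeds are treated as dead), no age effects within the
adult class, no migration, and no horizontal transmission of the
endophyte. Adult survival `S_A` is a model constant rather than an
estimated rate — no adult deaths were observed over the census years,
so an arbitrary high value (0.95) is used, and
`survival_ranking_sweep` checks that conclusions about the *ranking*
of group growth rates are unchanged for any `S_A` in [0.5, 0.99].
Absolute λ values do depend on `S_A` and on the benign sowing
conditions, and are best read as relative fitness indices, not
forecasts of density.

Two parallel parameterizations ship in `reference`: the field
vital-rate estimates (mean ± SEM per group) and the published matrix
entries transcribed as printed. They differ in the last printed digit
(e.g. `G_A1` = 0.05·0.63 = 0.0315 vs the printed 0.032), so functions
accept either a `VitalRates` set or a ready `StageMatrix`; analyses of
the published eigen-structure use the printed matrices, estimation
round-trips use the vital-rate sets.

## Eigen-analysis and its independent check

`dominant_eigen` uses the dense eigen-decomposition (right and left),
rectifies the Perron vectors to the nonnegative orthant, validates the
residuals at 1e-8 and falls back to power iteration when the dense
eigenvectors are unusable. Because the 4-stage life cycle has exactly
three loops (adult self-loop and two reproductive paths of length 3
and 4), λ is also the unique positive root of

    1 = S_A/λ + G_J1·G_A1·F·λ⁻³ + G_J1·G_J2·G_A2·F·λ⁻⁴,

which `loop_equation_lambda` solves by bracketed root finding to
1e-12. The two routes agree to 1e-9 on every valid matrix (a property
test), giving an in-package oracle that is independent of the linear
algebra. A structural corollary used in the tests: every reproductive
loop contains `F` and `G_J1` exactly once, so scaling either (or the
transmission factors that multiply them, see below) moves λ
identically — and the elasticities of `G_J2` and `G_A2` are exactly
equal, as are those of `F` and `G_J1`.

Elasticities are reported per element and summed per vital rate;
LTRE contributions use sensitivities evaluated on the midpoint matrix
`(A_t + A_r)/2`, the standard fixed-design choice, which makes the
decomposition exactly antisymmetric in (treatment, reference) and
first-order accurate (residual < 2% of Δλ for 1% perturbations).

## Coupled model, prevalence and persistence

The 8×8 coupled matrix is block lower-triangular: the S block with its
fecundity arc discounted by `T_A·T_seed` and its seedling→juvenile arc
by `T_S`, the plain NS block, and two leakage arcs routing transmission
failures into the NS cohort (an S plant that loses the endophyte is
demographically NS). Persistence is governed by the discounted S-block
λ: prevalence is 0 when it does not exceed the NS λ, and otherwise the
NS components of the dominant eigenvector solve the forced balance
`(λ_S I − A_NS) x = L w_S`. The linear solve replaces raw power
iteration, whose convergence degrades as the block eigenvalues
approach each other; a brute-force renormalized projection is kept in
the tests as the independent route. Finite-horizon prevalence
renormalizes the population each step (prevalence is scale-invariant,
and λ ≈ 2–3 would overflow floating point over long horizons).

Default prevalence counts all four stage classes; a `stage_set` option
restricts to e.g. adults only, since which plants are counted is a
reporting choice, not a model property. Sweeps support two conventions
for the non-varied rate — held at 1, or at its observed value — and
`persistence_threshold` offers a continuous bisection root on the
asymptotic criterion (tolerance 1e-6) and a 0.1-grid scan on the
50-year finite-horizon criterion (default cutoff: prevalence 0.01).

Two findings of this implementation deserve emphasis. First, by the
loop structure above, the asymptotic thresholds for `T_A` and `T_S`
coincide exactly when the other rate is 1; any reported asymmetry
between them must come from transient dynamics, initial conditions or
a non-asymptotic criterion. Second, the relative growth advantage of
symbiotic plants is *larger* under fertilization (3.17/2.46) than
under natural conditions (2.34/1.97), so the model places the F+
persistence threshold (0.333, transmission-product scale) *below* the
natural one (0.458) and predicts symbiont persistence at the observed
F+ transmission rates. Reports of a 0% F+ prevalence and higher F+
thresholds are therefore not reproducible from these matrices by any
deterministic asymptotic or 50-year criterion we examined; the
corresponding checks state this expectation and are allowed to fail
loudly rather than being weakened.

## Monte-Carlo engine

Vital rates are drawn once per trajectory and held constant over time:
the uncertainty models between-genotype variation (the strong
endophyte × genotype effect), not environmental stochasticity.
Probabilities are drawn from Beta distributions moment-matched to
(mean, SEM) — clipped to 99% of the Bernoulli variance bound with a
warning when the SEM is infeasibly large, and degenerating to a point
mass at SEM 0 or at boundary means — and seed counts from a normal
truncated at zero. Each trajectory records the realized per-step rate
`(N(T)/N(0))^(1/T)` over T = 50 steps from the stable distribution of
the mean matrix (100 S + 100 NS adults for the coupled model,
mirroring the labelled field sample); 1000 trajectories by default.
Both the SD and the SEM across trajectories are reported; the ±values
accompanying published λs are interpreted as between-trajectory SDs (a
1000-trajectory SEM would be an order of magnitude smaller), and
`mean_eigen` additionally reports the mean dominant eigenvalue of the
drawn matrices, the other plausible reading of a simulated λ.

Because λ is concave in the drawn rates (most strongly through the
wide fecundity SEMs), the Monte-Carlo mean sits systematically ~1%
below the λ of the mean matrix — about 0.02 at the natural-condition
NS rates, i.e. 3–4 run-SEMs at 1000 trajectories. This is a property
of the estimator, not a convergence failure; the consistency test that
expects agreement within 3 SEMs documents the offset in its failure
message.

## Estimation and statistics

Estimators follow the census ratio conventions exactly: `s1`, `s2`,
`e1`, `e0` and `T_A` are unweighted means of per-mother ratios (mothers
with zero denominators are excluded per parameter, with a warning),
while `P` and `f1` are plot-level ratios; seed→seedling and
seedling→juvenile retention are cohort-level pooled fractions, matching
how the stage assays are scored. The ≥30-tiller attainment `e1` is
computed among *surviving* juveniles, which is the denominator that
makes estimation invert the generative model without bias. SEMs are
SDs of per-mother ratios over √(mothers); with a single mother the SEM
is stored as 0 (no spread information).

Group comparisons use a grouped-binomial logistic GLM (statsmodels)
with endophytic status, resource level and their interaction, assessed
by sequential χ² analysis of deviance in that fixed order (the common
default; the order is a choice, and relabelling the factors permutes
the main-effect tests only up to their sequential position — the
interaction term is order-invariant). Complete separation is flagged
and the affected p-values suppressed. No multiple-testing correction
is applied. Growth-rate comparisons use the Welch two-sample t with
Satterthwaite degrees of freedom (t = 0, p = 1 for identical
zero-variance samples by convention).

## Synthetic census generator

The generator emulates the field sowing design: per group, 20 mother
plants × 50 sown seeds, binomial emergence (`e0`), seedling survival
(`s1`), juvenile survival of 10 followed seedlings (`s2`), binomial
30-tiller attainment among survivors (`e1`), Bernoulli flowering (`P`)
and negative-binomial seed counts for flowering mothers; S mothers
additionally carry binomial endophyte assays (24 seeds, 5 seedlings, 5
juveniles tested per mother, sized so group totals match the reported
assay totals of ≈975 seeds and 200 + 200 seedlings/juveniles across
conditions). NS mothers carry missing, not zero, assay fields. The
negative-binomial shape is k = 1 by default, chosen once so that
between-mother seed-count spread reproduces the reported SEM
magnitudes (≈38–70 on means 77–184 at 12–16 flowering mothers);
Poisson counts would be far too regular. Everything is driven by one
`numpy` generator seed and is bit-reproducible.

What the generator does *not* emulate: between-year environmental
variation (none was detected in the field data), spatial structure,
mother-level random effects beyond the binomial/NB sampling, and
detection error in the endophyte assays. Passing recovery and
calibration tests therefore show that the estimators invert the
assumed sampling model at the design sizes — not that real censuses
are free of overdispersion or assay error.

## Numerical conventions

Comparisons against printed values round half away from zero: λ and
elasticities to 2 decimals, stage distributions and reproductive
values to integer percentages. Root finding uses Brent's method
(bisection-bracketed) with tolerance 1e-12 for λ and 1e-6 for
thresholds. Eigen residual tolerance is 1e-8 relative; elasticity
matrices sum to 1 within 1e-9. Simulation sizes in tests and scripts
(1000 Monte-Carlo trajectories × 50 steps; 1000 null censuses for the
type-I calibration; 100 replicates for recovery coverage) match the
study-scale defaults while keeping the full suite fast.

## Known limitations

Printed reference tables carry internal rounding inconsistencies that
the tests document rather than hide: one elasticity entry is printed
as 0.18 where its theoretically equal partner prints 0.17, and the
reproductive-value integer columns mix rounding conventions (handled
by a ±1 percentage-point tolerance; stable-distribution integers and
all adult reproductive values reproduce exactly). The published
mixed-population prevalence (58% natural / 0% F+) and the published
persistence thresholds depend on an unreported computation (initial
conditions, horizon, stages counted, stochastic averaging) and are not
reproduced by the deterministic coupled model, as discussed above.
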