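# Methods

`coexistkit` implements the quantitative workflow used to characterise
species coexistence in the shrub layer of island *Pinus massoniana*
communities: importance values and dominant-species screening, niche
breadth and overlap along binned soil gradients, overall and pairwise
interspecific association tests, phylogenetic community structure, and
environmental interpretation by ordination and curve regression.  This
note records the models, the defaults and why, the numerical conventions,
and what the synthetic-data generator does and does not emulate.

## Survey model and data contracts

The sampling unit is a 20 m × 20 m plot containing four 5 m × 5 m shrub
quadrats.  Quadrat records carry an individual count (`abundance`) and a
percent cover per (plot, quadrat, species); records with zero abundance
are dropped on load, and duplicate (plot, quadrat, species) keys are an
error rather than being summed — silent aggregation hides data-entry
faults.  Labels are case-sensitive and whitespace-trimmed.

Slope aspect is accepted either as a category name or as a compass
azimuth; azimuths map to the four ordinal categories adret (157.5°–247.5°),
semi-adret (112.5°–157.5°, 247.5°–292.5°), semi-ubac (67.5°–112.5°,
292.5°–337.5°) and ubac (0°–67.5°, 337.5°–360°), each interval closed on
its lower bound and open above, so 0° is ubac.

## Importance values

For species *i* in a plot,

IV% = (relative abundance + relative frequency + relative coverage) / 3,

where each component is the species' share (in %) of the plot total.
Frequency is the number of the plot's quadrats occupied by the species,
normalised across species; abundance and coverage are summed over quadrats
before normalisation (with a fixed quadrat count per plot, summing and
averaging give identical relative values).  The species-level mean IV
averages over **all** plots, counting zero where the species is absent, so
species means sum to 100% and a "share of community importance" reading is
valid.  Dominant species are those with mean IV strictly above the
threshold (default 1%).

## Niche breadth and overlap

A resource gradient is an environmental variable cut into ordered levels;
the packaged scheme uses the published 11-level cuts for pH, total
potassium and available potassium.  Those printed level tables contain
gaps (e.g. pH 4.7–4.8) because the cut points were drawn from observed
values; a value falling in a gap is assigned to the level whose nearest
boundary is closest, ties going to the lower level.  This preserves the
11-level structure without rejecting valid data.  Intervals are half-open
[lo, hi); the first and last levels are open-ended.

With P_ij the proportion of species *i*'s importance value at level *j*
(0·ln 0 := 0):

- Shannon niche breadth  B_S = −Σ_j P_ij ln P_ij, in nats, bounded by ln r;
- Pianka niche overlap  O_ik = Σ_j P_ij P_kj / √(Σ_j P_ij² · Σ_j P_kj²),
  a cosine similarity in [0, 1].

At the "overall level" the 40 plots themselves serve as resource states.
Both indices consume proportions, so they are invariant to joint rescaling
of the raw importance values.

## Association tests

**Overall (variance ratio).**  On the species × plot presence matrix,
VR = S_T²/δ_T² with S_T² the population variance of plot richness T_j and
δ_T² = Σ_i p_i(1−p_i) the summed binomial variances of species occupancy
frequencies.  VR > 1 suggests net positive association.  W = N·VR is
compared with the χ² quantiles at N degrees of freedom; for N = 40 plots
the 90% acceptance interval is (26.51, 55.76) — W inside means the overall
association is not significant at α = 0.05.

**Pairwise (Yates-corrected χ²).**  Each pair's 2 × 2 plot-occupancy table
uses the survey's cell convention — b = both present, c = neither, a and d
= exactly one — giving

χ² = N(|ad − bc| − 0.5N)² / [(a+b)(b+d)(c+d)(a+c)].

The association sign compares the observed joint-presence count b with its
independence expectation (a+b)(b+d)/N, which is convention-proof.  Classes
use the df = 1 critical values: χ² ≥ 6.635 extremely significant
(p < 0.01), ≥ 3.841 significant (p < 0.05).  A zero marginal product (a
species present in every plot, or degenerate co-margins) leaves the
statistic undefined; such pairs are classed "no association" — the only
mechanism the data admit for that class.  Note that the continuity
correction makes the test conservative: under an independent-occupancy
null its realised type-I rate is nearer 2% than the nominal 5%.

**Quantitative (Pearson / Spearman).**  Correlations use plot-level summed
abundances.  Spearman is computed as Pearson on mid-ranks, which equals
the classical 1 − 6Σd²/(N³−N) formula on tie-free data and keeps |r_s| ≤ 1
under ties.  Two-sided p-values use the t approximation with N−2 df; star
classes at 0.05/0.01/0.001.  Zero-variance species yield undefined
correlations, reported as "no association".

**Ecological species groups.**  The published grouping is expert judgment
over an ordination biplot.  The implemented stand-in — labelled heuristic
in its output — clusters species on their signed correlations with the
selected environmental axes (agglomerative, average linkage, Euclidean,
k = 3 by default) and is deterministic.

## Phylogenetic structure (MPD / NRI)

MPD of a plot is the mean patristic distance over unordered pairs of taxa
present (presence-weighted, not abundance-weighted).  The null shuffles
taxa labels on the distance matrix — equivalently, draws the same number
of taxa uniformly from the full pool — 999 times by default.  The index is
reported as

NRI = −(MPD_obs − mean MPD_null) / sd MPD_null,

so positive NRI means phylogenetic clustering; the unnegated standardised
effect size is available via `sign_convention="raw"` because the field's
printed formula sometimes omits the negation while its interpretation
assumes it.  Null standard deviations at or below 1e-12 of the null mean
(a plot holding the entire pool, where only summation order varies) are
flagged degenerate rather than divided by.  NRI is invariant to uniform
scaling of branch lengths, and results are bit-reproducible given (seed,
n_rand).

## Environmental interpretation

**PCA.**  Correlation-matrix PCA (variables standardized with the sample
standard deviation), so eigenvalues sum to the number of variables.
Variable scores are eigenvectors scaled by √eigenvalue; site scores are
the weighted sums of the standardized data.  Eigenvector signs are fixed
by making each component's largest-magnitude loading positive.  An
ordination is conventionally called acceptable when the leading axes
explain more than 40% of total variance.

**RDA with forward selection.**  Redundancy analysis regresses the
species-centred community matrix on standardized predictors; a factor
set's explained fraction is SS(fitted)/SS(total).  Forward selection is
greedy: at each step every unselected factor's conditional contribution is
measured by a pseudo-F

F = ΔSS_explained / (SS_residual / (n − p − 1)),

and tested by unrestricted row permutation of the response with
p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm); the default 499 permutations
give a minimum attainable p of 0.002.  The smallest-p factor (ties broken
by larger F) is added while p ≤ α.  A residual sum of squares below
1e-10·SS_total is treated as an exact fit (F = ∞) and a gain below the
same tolerance as zero, so a perfectly explained response does not promote
further factors through rounding noise.  Ordinal predictors (aspect 1–4,
topographic position 1–3) enter as their codes.  A detrended
correspondence pre-check is deliberately omitted; a linear species
response is assumed.

**Curve families.**  Eleven bivariate families: linear, quadratic, cubic,
compound y = ab^x, power y = ax^b, S-curve y = e^(a+b/x), growth
y = e^(a+bx), exponential y = ae^(bx), logarithmic y = a + b ln x, inverse
y = a + b/x, and logistic y = 1/(1/c + ab^x) with c > 0 enforced.
Families with an exact log-linearization are fitted on the transformed
scale (their R² and regression F-test refer to that scale, the standard
convention); polynomials and the logistic are fitted directly, the
logistic by bounded nonlinear least squares seeded from a compound fit of
1/y − 1/c₀.  The best fit is the highest R² among families with p < 0.05.
On zero-noise data generated from any family, that family attains R² = 1;
where several families coincide on such data (compound, growth and
exponential are reparameterizations of one curve), the tie resolves to the
first in the registration order listed above.  Families whose domain
constraints fail (x > 0 for log/power, y > 0 for log-linearized families,
x ≠ 0 for inverse/S-curve) are skipped with a recorded reason.

**Outlier screening.**  Residuals from an ordinary linear fit are flagged
by the 1.5·IQR rule, with an absolute guard of 1e-8·max(1, |y|_max) so
numerically exact fits flag nothing.  In `replace` mode a flagged point's
y is replaced by the mean y of the non-flagged observations sharing its x
level when at least two exist; otherwise (and always in `eliminate` mode)
the point is dropped.  Every action is itemised in the returned report.

## Synthetic communities

The generator plants known structure so every stage can be tested without
the archived field data.  Expected abundance follows a Gaussian response

λ_is = A_i · exp(−(e_s − μ_i)² / 2σ_i²)

along a single gradient; quadrat counts are Poisson draws of λ_is split
over the plot's quadrats (a gamma-mixture negative-binomial option adds
overdispersion); percent cover is count × per-species size factor ×
lognormal(0, 0.2) noise, capped at 100, keeping the three IV components
distinct but correlated as in real data.  Optima may be evolved by
Brownian motion on a pure-birth (Yule) tree and rescaled to the gradient
range, so narrow environmental filtering yields phylogenetically clustered
plots.  All randomness flows from a single integer seed through one
`numpy` generator, making outputs bit-reproducible.

Defaults mirror the survey design: 40 plots × 4 quadrats, 23 species,
gradient uniform on (0, 1), tolerance σ = 0.2, peak abundance A = 15
individuals per plot.  Planted-pair test scenarios raise A to 25 so a
species at its optimum is reliably sampled — about 25 individuals per
plot, a realistic shrub count.  What the generator does **not** emulate:
spatial autocorrelation between plots, dispersal limitation and island
isolation dynamics, multi-gradient interactions, disturbance, and
observation error in cover estimates.  Passing tests therefore demonstrate
correctness of the statistics and recoverability of planted niche
structure, not robustness to every feature of field data.

## Problem sizes used in the test suite

Calibration suites use 1000 replicates of 10–15 species × 40 plots for the
null association checks, 100 random instances for each brute-force oracle
comparison, 40 seeded replicates for planted-pair sign recovery, 499
permutations for the planted-driver selection, and 199 randomizations for
the clustering check on one simulated 23-species community — sizes at
which every expected effect is decisive while the whole suite stays
fast on a single CPU.

## Known limitations

- The pairwise χ² classes rest on the df = 1 asymptotics; with 40 plots
  and rare species the Yates-corrected test is conservative (see above).
- Forward-selection p-values are marginal per step, not corrected for the
  number of candidate factors.
- The permutation scheme for RDA is unrestricted row permutation; no
  block or spatial restriction is offered.
- The species-group clustering is a labelled heuristic, not a recovery of
  any expert partition.
- Gradient-level niche metrics depend on the published binning; alternate
  bin definitions change B_S (though not its bounds) and, mildly, O_ik.
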