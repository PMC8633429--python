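# Methods

`oakwood` implements the statistical machinery used to study how wood
anatomical traits of co-occurring tree species (the motivating system is
Mexican oaks, sections *Quercus* and *Lobatae*) vary along an aridity
gradient: trait derivation, phenotypic plasticity (RDPI) with
distance-matrix regression, probabilistic species co-occurrence, and
phylogenetic comparative statistics. A synthetic-data generator with known
ground truth stands in for the field data, so every stage is testable
against a recoverable truth.

## Trait derivation

Individual-level inputs are vessel diameter VD (µm, mean equivalent-circle
diameter), vessel frequency VF (mm⁻²), fibre lumen F_L and wall F_W (µm),
wood density WD (g cm⁻³), height H (m) and DBH (cm). Derived variables:

- composition index `S = VA/VF`, lumen fraction `F = VF·VA`,
  vulnerability index `VI = VD/VF`, relative conductivity
  `RC = (VD/2)⁴·VF` (µm⁴ mm⁻², Hagen–Poiseuille-proportional, no viscosity
  constant — the index is relative).
- The product VF·VA mixes mm⁻² with µm²; by default a 10⁻⁶ factor makes F
  a true dimensionless lumen fraction (≈0.1–0.2 is physically
  interpretable); `lumen_fraction_raw=True` gives the raw product for
  exact replication of the mixed-unit index.
- When VA is not measured it is reconstructed as π(VD/2)² and flagged:
  averaging diameters then squaring is not the same as averaging areas, so
  reconstructed VA is biased low relative to a per-vessel mean area. The
  generator's per-vessel mode exists precisely to quantify this (the
  log-scale species-mean correlation of VD and VA stays above 0.99 at
  CV 30%).
- `VF = 0` makes the ratios S and VI undefined; they propagate as missing
  (never zero), while RC and F are exactly 0.

Leaf habit is classified from an annual canopy-foliage series: the series
is linearly interpolated onto a daily grid (cyclically, so the year wraps),
and a day counts as foliated when foliage ≥ 50 % of the series maximum.
The class thresholds are not quantified in the field literature we follow,
so they are explicit configuration: evergreen at ≥ 360 foliated days,
deciduous when the longest leafless spell is ≥ 60 consecutive days,
brevideciduous otherwise. The classification is invariant to uniform
rescaling of the series because the 50 % threshold is relative to the
maximum.

Environment preparation: the UNEP aridity index AI = MAP/PET (humid at
AI ≥ 0.65; finer UNEP classes optional), Hargreaves–Samani potential
evapotranspiration `PET = Σ 0.0023·Ra·(Tmean+17.8)·√(Tmax−Tmin)` over
periods, and an iterative VIF screen that removes the largest-VIF variable
until all VIF ≤ 10 (`VIF_i = 1/(1−R²_i)`). Tie-break: among equal-largest
VIFs — including exact collinearity, where VIF is infinite — the variable
later in input order is removed; this makes a duplicated column lose its
copy and the screen deterministic under variable reordering.

Species means are arithmetic means per species; the log₁₀ option
transforms individual values *before* averaging (the alternative —
transforming species means — is also reachable by calling the transform on
the output, but the individual-level convention is the default because
trait distributions are right-skewed at the individual level).

## RDPI and distance-matrix regression

For one species and trait, RDPI is the mean over all unordered pairs of
individuals growing in *different* plots of the relative distance
`|x_i′j′ − x_ij|/(x_i′j′ + x_ij)`. Within-plot pairs are excluded (the
index compares distinct growing conditions). For nonnegative traits RDPI
lies in [0, 1]: 0 when the trait is invariant, 1 exactly when every
cross-plot pair has one zero member. A 0/0 pair contributes 0. Species
occurring in a single plot have no cross-environment pairs and are
excluded from the RDPI table with a logged reason. RDPI is invariant to
positive rescaling of the trait.

The plot-pair RDPI matrix restricts the pair set to one plot pair per
entry; the scalar RDPI equals the pair-count-weighted mean of the
off-diagonal entries (tested). Section-level matrices are entrywise means
over the section's species, ignoring missing entries (a species absent
from either plot). RDPI values are arcsin-√ transformed before regression.

MRM regresses the unfolded strict lower triangle of the response on those
of the predictors (geographic Euclidean distance on planar coordinates;
environmental Euclidean distance on variables centred and scaled to unit
sample SD). Significance comes from 5000 joint row/column permutations of
the response matrix only (predictors fixed), with the +1 small-sample
correction `P = (#{permuted ≥ observed} + 1)/(n_perm + 1)`, using
|coefficient| per slope and R² for the model. Triangle elements with a
missing value in any matrix are deleted pairwise, and the permuted
response carries its own missingness pattern. The seed is mandatory; the
identity-permutation fit is plain OLS (tested against an unfolded-OLS
oracle).

Between-section RDPI comparisons use the Welch unequal-variance t-test
with Satterthwaite fractional degrees of freedom (both groups constant and
equal gives t = 0, P = 1 by convention).

## Probabilistic co-occurrence

For two species occupying n₁ and n₂ of N plots, the number of shared plots
under independent placement is hypergeometric:
`P(j) = C(n1,j)·C(N−n1,n2−j)/C(N,n2)` on
`max(0, n1+n2−N) ≤ j ≤ min(n1,n2)`. Both exact tails include the observed
value (this is what makes the test conservative); a pair is *positive*
when P(≥ observed) < α, *negative* when P(≤ observed) < α, else *random*
(α = 0.05). Expected co-occurrence is n₁n₂/N. All C(S, 2) unordered pairs
are evaluated by default — no expected-frequency filter, though
`min_expected` exists for compatibility with other implementations —
and species with zero occurrences are excluded with a warning before
pairing. Label percentages are reported at full precision.

## Phylogenetic comparative statistics

Trees are rooted with branch lengths (dendropy handles Newick I/O;
pruning suppresses unifurcations and sums branch lengths). Polytomies are
resolved to zero-length binary branches for contrast-based methods;
disabling auto-resolution raises instead. Tip/table names are reconciled
case-insensitively with spaces and underscores unified, and unmatched
names are listed before failing.

- **PIC**: post-order pass computing `(x_L − x_R)/√(v_L + v_R)`, the
  variance-weighted ancestral value, and the parent branch extension
  `v + v_L·v_R/(v_L + v_R)`. The branch-length bookkeeping is
  data-independent, so randomization tests re-contrast shuffled tip values
  cheaply. PIC through-origin regression is algebraically the Brownian GLS
  fit (tested to 10⁻¹⁰ against dense-matrix GLS).
- **Contrast correlations** use the through-origin formula
  `r = Σxy/√(Σx²Σy²)` with significance on n_tips − 2 df; this form is
  invariant to paired sign flips, so contrast positivization does not
  affect it. The combined table writes raw Pearson below the diagonal and
  PIC correlations above it.
- **PCA** by eigendecomposition of the correlation (standardised) or
  covariance matrix; signs fixed so each component's largest-magnitude
  loading is positive; percent variances sum to 100. The conventional
  exclusion of the redundant VA and S columns is a flag.
- **Blomberg's K**: observed MSE₀/MSE (tip deviation from the GLS
  phylogenetic mean vs the Brownian GLS error) divided by its analytic
  Brownian expectation `(tr C − n/1ᵀC⁻¹1)/(n−1)`. The randomization P is
  one-sided — the proportion of tip shuffles with contrast variance ≤
  observed, +1-corrected, 999 shuffles by default — because signal means
  *lower* contrast variance than random labelling; a two-sided version is
  reported alongside. Under Brownian simulation on a 50-tip tree, mean K
  over 500 traits sits at 1 within ±0.1.
- **PGLS** fixes the Brownian correlation structure (no Pagel's λ). The
  likelihood uses the ML variance (RSS/n); standard errors and t-tests use
  the unbiased variance (RSS/(n−p)). AIC counts k = coefficients + 1
  (variance) — stated because AIC conventions differ. Model selection fits
  one single-predictor model per environmental variable and returns the
  minimum-AIC fit with the full AIC table. On a star phylogeny PGLS and
  OLS coincide exactly.
- **Phylogenetic ANOVA**: the observed F is the ordinary one-way ANOVA
  statistic; the null distribution re-computes F on 1000 traits simulated
  under Brownian motion with the rate estimated from the data by GLS ML.
  Post hoc pairwise t statistics (pooled ANOVA error) get simulation-based
  P-values, Holm-adjusted across pairs.
- **Brownian simulator**: Gaussian increments per branch with variance
  rate × length; all stochastic operations are reproducible given their
  seed, and seeds are never defaulted silently.

## Synthetic-data generator

`simulate_study` emulates the study's sampling frame with defaults fixed
to it: 21 species on a pure-birth tree (scaled to unit height) split into
two sections at the root, three leaf-habit classes assigned by clade with
25 % noise, 33 plots on a linear elevation (650–2738 m) and aridity
(AI 0.78–1.78) gradient with climate variables generated at fixed
correlations to AI (mtdq strongly negative, pwq positive — so the VIF
screen has realistic work), Gaussian-niche occupancy over AI (breadth 0.30
AI units, peak presence probability 0.9; every species is guaranteed its
best plot), and 5 individuals per occupied species-plot cell.

Species-level log₁₀ trait means are Brownian values (rate 0.01 log₁₀²
per unit tree height — giving ~±25 % spread across species, the order
observed among congeners) plus a leaf-habit shift (0.05 log₁₀ units
evergreen vs deciduous) plus an environmental response (0.08 log₁₀ units
per SD of AI, signed per trait: wetter → wider vessels, taller trees,
lighter wood). Individual measurements are lognormal around the
species-plot mean with CV 0.15 (mean-preserving parameterisation);
optionally 50 per-vessel diameters per individual with CV 0.30 are drawn
and averaged, which is what decouples measured VA from π(VD/2)² the way
real sectioning does. One seeded generator drives everything;
regeneration is bit-identical.

What the generator does *not* emulate: spatial autocorrelation beyond the
shared gradient, biotic interactions in occupancy, measurement error
correlated across traits within an individual, and non-Brownian trait
evolution. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of effects under the stated
model, not robustness of the field inferences to these unmodelled
features.

## Numerical choices and problem sizes

- Missing values propagate as missing, never as zero.
- Permutation/simulation P-values always carry the +1 correction, so
  P > 0.
- Degenerate cases: zero-residual PGLS (response ≡ predictor) is flagged
  rather than producing infinite likelihood downstream; both-groups
  constant Welch t returns P = 1; all-zero foliage series and constant
  environmental variables raise.
- Calibration tests run 200 replicates at 199 permutations/simulations
  each (floor(0.05·200)/200 makes the discrete size exactly 0.05 under
  the +1 correction) and judge rejection counts against central 99 %
  binomial bounds; parameter-recovery tests use 50-tip trees and 200
  replicates; the RDPI–effect-size ladder uses 8 species × 8 plots × 30
  replicates per rung. Production defaults remain 5000 MRM permutations,
  999 K randomizations and 1000 ANOVA simulations.

## Known limitations

- PGLS offers no λ/κ/δ transformations or Ornstein–Uhlenbeck residuals by
  design; the Brownian structure is fixed.
- The co-occurrence model ignores space: two widespread species are
  classified random even when interdigitated.
- The VIF screen's later-in-order tie-break is a convention; with near-tied
  VIFs a different input order can retain a different (statistically
  equivalent) variable subset.
- RDPI's [0, 1] bound holds for nonnegative traits only; traits that can
  cross zero need shifting before the index is meaningful.
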