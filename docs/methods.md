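# Methods

This note documents the models implemented in `fsispace`, the defaults and
the reasoning behind them, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Composite index

The index is an entropy-weighted TOPSIS score over 12 indicators in four
dimensions. Two conventions are genuinely open and were fixed as follows:

- **Pooled, not per-year, normalization and weighting.** Min-max bounds and
  entropy weights are computed over all unit-years at once. Per-year
  weighting would re-scale the index each year and make trajectories,
  σ-paths and growth rates incomparable over time; pooled weighting makes
  the index a single panel-wide scale. Both the normalizer and the weight
  step accept any matrix, so a per-year variant is a two-line loop if
  needed.
- **Indicator directions.** The asset–liability ratio (debt burden) and
  average length of stay (longer stays = lower throughput) are cost
  indicators; the other ten are benefit indicators. This follows the
  standard reading of hospital financial analysis: lower leverage and
  shorter stays indicate better solvency and efficiency.
- **Growth indicators in the first panel year** are undefined (no previous
  year); they are back-filled with the unit's earliest computed growth so
  the pooled matrix stays balanced. With 13 years the effect on pooled
  weights is marginal.
- **Degenerate columns** (constant across all unit-years) carry no
  information: they get normalized value 0.5, entropy weight 0, and a flag.

TOPSIS closeness is a relative ranking device: its level depends on the
realized ideal/anti-ideal rows, so the score of a unit is comparable across
units and years within one panel but the *mean level* of the score is not a
calibrated quantity. Tests therefore check rank recovery (Spearman ρ > 0.9
against the latent quality that generated the data), orderings, bounds, and
exact agreement with a step-by-step formula oracle — not score levels.

## Spatial weights

Contiguity weights come from an edge list; economic-distance weights use
1/|xᵢ − xⱼ| (optionally squared, optionally cut off); kNN weights are
row-wise with deterministic lexicographic tie-breaking. All spatial stages
require row-standardized weights, under which the spatial lag is a neighbor
mean, the spectrum lies in [−1, 1], and autoregressive parameters live in
(1/ω_min, 1). The packaged China contiguity list links Hainan to Guangdong
(Qiongzhou Strait); an isolated row would be zero after standardization and
break ML estimation. The edge is declared in the fixture file and editable.
"Institutional distance" matrices are accepted as user input but never
constructed: there is no standard definition to implement.

## Spatial autocorrelation inference

Global and local Moran statistics use permutation inference (999 draws by
default, seeded). The global test's default alternative is **"greater"**
(positive spatial autocorrelation): a sign-adaptive one-sided p-value
("directed", also available) rejects at about twice the nominal rate under
exchangeable data by construction and therefore cannot be calibrated at α;
the fixed-direction test is exact by symmetry, which the calibration suite
verifies (rejection rate 0.05 ± 0.02 over 500 i.i.d. replicates). Local
p-values use conditional permutation (unit i held fixed, the remaining
values redistributed over the other locations) and are directional per
unit; quadrant labels use deviations from the global mean. LISA labels on
real data are reported as diagnostics, not asserted against published
labels, because published classifications depend on an unstated weight
matrix and classification rule.

The Theil index uses natural logarithms and population weights 1/n; the
between/within split is the exact value-share decomposition, and additivity
(between + within = total) holds to 1e-12 as an always-on invariant. On the
packaged 31-province index values with the 11/8/12 east/central/west
grouping the between-group share is ≈ 67%, consistent with the published
finding that regional gaps dominate (≈ 69%; the exact figure depends on
year/pooling choices that are not recoverable).

## Convergence and transition dynamics

- **σ-convergence**: cross-sectional sample SD (ddof = 1) and CV per year.
- **β-convergence**: pooled OLS of ln y_{t+1} − ln y_t on ln y_t (plus
  period-t controls when conditional) with conventional standard errors.
  The implied catch-up speed is −ln(1 + β) per annual transition. The
  published pairing of β = 0.028 (SE 0.012) with a 1.8% speed fits no
  standard convergence-speed formula; the package fixes the convention
  above and reports both numbers.
- **Club convergence** is the Phillips–Sul log-t procedure: relative
  transitions h_it = y_it/mean_i(y_it), cross-sectional variance
  H_t, and the regression of log(H₁/H_t) − 2·log log(t+1) on log t over
  the post-trim sample (trim fraction 0.3) with HAC errors. Clubs are
  grown from the top of the terminal-value ordering (core group maximizing
  the log-t statistic among passing sizes, admission threshold t ≥ −1.65),
  and adjacent clubs merge when they jointly pass. Units supporting no
  club are labelled divergent. On homogeneous panels the procedure returns
  one club in ≥ 95% of replicates; planted two-club panels are recovered
  with terminal means within 0.02.
- **Spatial Markov chains** use pooled k-quantile classes (k = 3 default,
  echoing the three convergence clubs). Each year-pair transition is
  tallied into the matrix conditioned on the class of the unit's spatial
  lag at the start year; the upward-transition probability averages the
  strictly-upward mass over starting classes below the top. Supplying
  explicit cutpoints is supported so simulations with known class encodings
  can be scored exactly.
- **Structural breaks**: global least-squares segmentation by dynamic
  programming over all admissible mean-shift placements (minimum segment
  length 2), with the break count selected by BIC counting (m+1) segment
  means plus m break dates. The DP is verified against exhaustive search
  for series up to length 14. Deliberately out of scope: sup-F asymptotic
  critical values and slope-change segments. Because the reference
  three-phase pattern is a sequence of *growth* regimes, phase boundaries
  are detected on the year-over-year growth of the national mean, where
  they are mean shifts located exactly at the phase starts.
- **Event study**: post-window minus pre-window mean of the national index
  around the event year, against a placebo distribution over all admissible
  alternative event years. With window 1 the estimate equals the dip plus
  the local trend increment, so a planted −0.031 dip on a 0.006/yr trend
  is recovered as ≈ −0.025.

## Spatial econometric models

SAR, SEM and SDM are estimated by concentrated maximum likelihood. For the
lag family, δ̂(ρ) is OLS of y − ρWy on the design and the concentrated
log-likelihood adds T·Σᵢ ln(1 − ρωᵢ) from the eigenvalues of the n×n
weight matrix (panels enter as pooled cross-sections ordered year-major, so
the full weights are kron(I_T, W) and the log-determinant multiplies by T).
The ρ-search is bounded scalar minimization on (1/ω_min, 1) to 1e-10; the
concentrated value is verified against a literal dense-matrix likelihood to
1e-8. SEM concentrates λ through the (I − λW) transform. In the Durbin
design, lags are built for every column whose lag differs from itself —
the intercept and year dummies are invariant under a row-standardized
within-year lag and would duplicate themselves.

Standard errors are asymptotic, from the observed information: the
numerical Hessian of the exact log-likelihood at the ML estimate. This is
the same object as the analytic information matrix with less scope for
hand-derivation errors; simulation shows it slightly optimistic for the
Durbin (θ) terms at n = 31 (≈ 84% coverage at nominal 95%) and well
calibrated for ρ and β (≥ 90% across the board at study scale).

**Panel treatment.** The pipeline default is pooled estimation with year
fixed-effect dummies. A controlled experiment at n = 31 shows the known
inconsistency of spatial-lag ML with time-period fixed effects (ρ̂ biased
by ≈ −0.05 with dummies even under a correctly specified DGP); recovery
experiments therefore use a flat-trend DGP and the no-dummy fit, which is
correctly specified on both sides. Descriptive runs keep the dummies, which
absorb any common year path exactly.

Effects use the LeSage–Pace decomposition; point direct/total effects are
the average diagonal and average row sum of S_r(W) = (I − ρW)⁻¹(Iβ_r +
Wθ_r), computed from traces and row sums without forming S_r per draw, and
additivity (total = direct + indirect) is exact by construction. Effect
standard errors come from 1,000 seeded draws from the asymptotic normal of
(δ, ρ). The placebo test permutes the target column across units within
each year and re-estimates the model (99 draws default, seeded); under the
null its p-values are approximately uniform.

## Synthetic data generator

The generator emulates the statistical structure of the reference setting:
a balanced 31 × 13 panel, an 11/8/12 east/central/west split, a three-phase
upward trend (slopes 0.009, 0.020, 0.006 per year from base 0.458,
phase boundaries after the 6th and 10th years, i.e. 2016 and 2020) with a
one-year −0.031 shock in 2020, regional offsets (+0.149, +0.042, −0.094)
reproducing the published east > central > west ordering, nine covariates
with regional location shifts, and an outcome that responds to covariates
through a spatial Durbin process with ρ = 0.289. The default β/θ pairs are
*solved* from the published direct/total effect magnitudes under the
packaged contiguity weights (a 2×2 linear system per covariate in the
average diagonal/row-sum of the multiplier), so planted truth and published
magnitudes coincide by construction rather than by tuning.

Cross-sectional dispersion follows a V-shaped path (1.00 → 0.76 at 2016 →
0.90 at 2022, matching the published SD ratios): each year's deviations
from the national mean — regional offsets, persistent unit effects, and the
spatial response — are contracted or expanded by g(t). This mirrors
regional gaps that narrow and then re-widen. It also means the default
panel intentionally violates the time-invariance the pooled SDM estimator
assumes; **recovery configurations** (`recovery_config`) set g ≡ 1 and
remove offsets and unit effects so the latent index follows the structural
equation exactly. Focused DGP variants with damped covariate noise are used
where a deterministic signal (phase boundaries, the shock dip, the
dispersion minimum) must be identifiable at n = 31; the full-noise default
buries a 0.01-scale trend signal in 0.02-scale covariate fluctuations, as
real data would.

Raw financial fields are back-generated so each indicator is a noisy
monotone transform of the latent index; the composite-index pipeline then
recovers the latent ranking (Spearman ρ > 0.9). The latent index is mapped
into (0, 1) by a recorded affine map only when it strays outside; tests
compare coefficient estimates against affine-adjusted truth. Everything —
coefficients, trend, shock, offsets, unit effects, dispersion path, affine
map, weight matrix — is stored in the truth record; no recovery test
hard-codes a constant.

What the generator does **not** emulate: measurement error in the raw
fields beyond independent noise, missing data mechanisms, serial
correlation in the outcome noise, within-province heterogeneity, and any
real geography beyond first-order contiguity. Passing recovery tests show
the estimators are correct under the assumed model, not that the published
numbers are reproducible from real data (the underlying panel is not
public).

Smaller purpose-built generators provide clean ground truth for single
estimators: log-AR(1) panels for β-convergence (catch-up rate φ − 1),
club panels converging to specified targets, and neighbor-dependent class
dynamics for the spatial Markov chain (default downward mobility 0.25
keeps the chain mixing so all neighbor environments are visited).

## Reporting conventions

"Average annual growth rate" is the continuous (log) rate
ln(y_T/y_0)/(T−1); the published 2.1% between 0.485 and 0.627 over twelve
transitions holds under this convention (the geometric rate rounds to
2.2%). AIC = 2k − 2·loglik with k counting slope coefficients plus the
spatial parameter. All simulation sizes in the acceptance script (100
recovery replicates, 500 calibration replicates, T = 400 Markov chains)
were chosen to keep Monte Carlo error well below the tolerances being
checked.

## Known limitations

- SDM/SAR ML with time-period fixed effects is biased at small n (no
  Lee–Yu correction is implemented); use the no-dummy fit when the common
  trend is flat or separately removed.
- θ (Durbin-term) standard errors are slightly optimistic at n = 31.
- The log-t clustering uses the common trim and threshold constants
  (0.3, −1.65); no data-driven threshold selection.
- Published LISA labels and the published global Moran's I cannot be
  reproduced exactly because the weight matrix, year and classification
  rule behind them are unstated; the package reports its own values under
  declared choices.
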