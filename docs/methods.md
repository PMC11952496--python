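# Methods

This note documents the models and procedures `cordmap` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Coordinate convention

Template y increases dorsally; the dorsal tips of the dorsal horns sit at
y = +2000 and the ventral tips at y = −2000 arbitrary distance units, the
midline at x = 0, the lateral extremes of the dorsal horns at x = ±2000,
and the dorsal/ventral-horn junction at y = 0. Image readers must declare
row orientation (`y_down`) because pixel row indices grow downward.

## Registration model

Ten named anchors per section drive a separable two-step transform.

*Midline frame.* The rotation pivot is the midpoint of the two midline
anchors; any pivot gives the same final map once the translation fixes the
junction at (0, 0), so the midpoint is chosen for numerical symmetry. The
rotation makes the dorsal-columns base sit vertically above the junction.

*Hemisection stretch.* The y-map is monotone piecewise-linear through five
knots (ventral tip, junction, lateral dorsal horn, dorsal-columns base,
dorsal tip). Both intermediate anatomical controls are knots; if a section's
geometry puts them out of raw-y order relative to their template targets,
the non-mandatory knot involved in the violation is dropped with a warning
and the surrounding segment interpolates linearly. Extrapolation beyond the
terminal knots continues the terminal segment's slope. The x-map is linear
per compartment — lateral dorsal-horn anchor to ±2000 for cells at or above
the junction (frame y ≥ 0), ventral lateral anchor to its zone target below
— with the midline fixed. Cells exactly on the midline are assigned to the
right hemisection (documented tie-break); |x| beyond 1.25 × 2000 is flagged
but kept.

This is the minimal separable linear scheme that sends every anchor exactly
to its target. It inverts perturbations composed of translation, rotation
and axis-aligned scaling exactly; shear is outside the model (the generator
excludes it by default for the same reason). Nonlinear (e.g. thin-plate
spline) warping is deliberately out of scope.

*Intermediate knot targets.* The lateral-dorsal-horn y target (+800
brachial), dorsal-columns-base y target (+1300) and ventral lateral x
target (±1800) vary by segmental zone and are configuration values; the
defaults here were chosen once per zone as plausible geometries. Because
the targets differ across zones, cross-zone statistical comparison is not
meaningful and `overlay_sections` refuses mixed zones unless explicitly
allowed.

## Cumulative birthdating

Design assumptions: one pulse per litter; the litter is the replicate unit
(litter-to-litter variance in conception time dominates embryo-to-embryo
variance); a pulse at embryonic day t labels cells born in [t, t + w]. The
labeling window w defaults to 0.5 days — label availability spans hours and
the pulses are half-day spaced — and is a free parameter.

Construction, per family: embryo fractions → litter means m_{t,ℓ} →
per-timepoint means m_t → percentages p_t = 100·m_t/Σs m_s → litter
cumulative value 100·m_{t,ℓ}/Σs m_s + Σ_{s<t} p_s. The prior-timepoint
addend is a constant per timepoint, so the per-timepoint spread is the
spread of that timepoint's litters only, and the final-timepoint mean is
100 exactly (an algebraic identity, tested to 1e-9). All outputs are
invariant to scaling every embryo's counts by a constant.

Sigmoid fits use all litter-level cumulative points, equally weighted (not
the timepoint means). The 4PL uses the "X is concentration" (non-log-x)
parameterization; initialization Bottom = 0, Top = 100, EC50 = median pulse
day, HillSlope = 10; bounds Bottom ∈ [−10, 50], Top ∈ [50, 120],
EC50 ∈ [x_min − 0.5, x_max + 0.5], HillSlope ∈ [0.5, 200]; five jittered
starts before declaring non-convergence. Flat curves or an EC50 pinned at
the lower bound are flagged degenerate.

The 5PL adds the asymmetry exponent S. Its inflection parameter Xb is not
the half-maximum point, and for strong asymmetry sits well below the pulse
range, so its bounds are wider ([x_min − 4, x_max + 1]); the reported
half-birthdate is instead the numeric root of Y = (Bottom + Top)/2, found
by bracketed bisection to 1e-10. With S = 1 the 5PL reduces to the 4PL and
the two half-birthdates agree. Model selection (`model="auto"`): the 5PL is
used when the 4PL RSS exceeds the 5PL RSS by more than 20% *and* the 4PL
EC50 sits within half a median inter-pulse interval of the first pulse —
the signature of a negligible slow-growth phase.

Note an intrinsic offset, visible in the worked example: because a pulse at
t labels everything born in [t, t + w], the half-birthdate of a wave with
mean μ sits below μ (by roughly w/2 plus a truncation term when the wave
starts before the first pulse). The parameter-recovery tests therefore
compare fits against the oracle defined as the 4PL EC50 of the *noiseless*
closed-form cumulative profile, not against μ.

## Density maps

Bandwidth per axis: h = 4 · 1.06 · min(sd, IQR/1.34) · n^(−1/5), with the
kernel standard deviation h/4 (the internal convention of the classic
bivariate KDE this mirrors; verified against an independent reference run
frozen into the test suite). The grid is 100 × 100 over the data range; by
default it is padded by 3 kernel sds per axis so the Riemann-sum
normalization invariant (∫≈1 within 2%) is testable, and `range_padding=0`
reproduces the strict raw-range convention exactly.

Contour thresholds: per-point densities are read off the grid by bilinear
interpolation (`exact=True` re-evaluates the kernel sum instead; both modes
agree to a few percent); the threshold for fraction q is the empirical
(1 − q)-quantile with linear interpolation between order statistics (stated
to fix tie behavior). Masks therefore nest by construction, and enclosed
fractions are calibrated to ±1 percentage point at n = 5000. Cohort maps
are computed per group (default replicate × pulse day × family); groups
under 20 cells are skipped with a warning; rendering opacity metadata
orders broader levels more transparent. Masks, not polygon traces, are the
output — polygonization is a rendering concern.

## Depth profiles

Pixel profiles: images are thresholded (user-supplied threshold, as in the
original manual workflow — no automatic threshold selection), optionally
multiplied elementwise for two-marker colocalization, and averaged per row
over a sampling rectangle whose width is conventionally about one third of
the dorsal-horn width (warning only). Raw rows are compressed to 80 bins by
assigning row i to bin ⌊i·80/L⌋ and averaging — the mean (not the sum) so
sections of different pixel heights remain comparable; the bin mean equals
the raw mean exactly when L is a multiple of 80. Each replicate's 80-bin
vector is normalized to sum to 1 (interpreted as per-replicate
sum-normalization; cross-genotype column comparisons require
within-replicate proportions). The dorsal-most 56 bins carry the display
flag because lamina VI is excluded from the analysis.

Cell-frequency histograms: 200 bins spanning y ∈ [−2000, +2000],
dorsal-first, per family normalized to 1; outliers are clipped with a
warning. Smoothing is a centered moving average of window 9 bins (the
original figures used a plotting smoother with unstated parameters; the
window is configurable), with edge windows truncated to available bins —
mass is conserved exactly on constant input and up to the edge-truncation
correction otherwise.

## Composition statistics

Counts are restricted to complete sections or complete hemisections
(weight 0.5) so partial tissue cannot distort proportions; the normalized
response is count / sections-collected per replicate. The comparison is an
ordinary two-way ANOVA (cell type × genotype with interaction) on the
normalized counts — proportions are available behind `response=
"proportion"` since figure panels report percentages — followed by Tukey's
test between all genotypes within each cell type, with no additional
across-type correction. Calibration under a Poisson null (base mean 40
counts/section, 3 replicates × 5 sections, 100 seeds) keeps the per-type
false-positive rate ≤ 7% at nominal 5%, and a 3× shift of one type is
detected in ≥ 80% of seeds.

Downsampling a control dataset to a mutant's total keeps round(ρ·n_k) cells
per type (ρ the total ratio), rounding half to even, sampled without
replacement with a seeded generator; the achieved total is reported rather
than forced to the target, since per-type rounding can miss it by up to
half the number of types.

## Synthetic-data generator

What it emulates: (a) sections whose anchors are translation ∘ rotation ∘
per-axis-scaling copies of the template (rotation ±30°, scale 0.8–1.25,
translation ±500 units by default; isotropic unless an anisotropy range is
given; shear excluded because the registration model cannot invert it);
(b) per-family Gaussian settling depths in template space, truncated to the
template extent, with the four default dILB cohorts at progressively dorsal
depths (y means 600/1000/1400/1750, matching progressively later birth);
(c) Gaussian birth waves (default means E11.0–E12.5 at half-day spacing,
sd 0.35 d) sampled through the labeling window with Binomial(200, p) count
noise per embryo, 3 embryos per litter, 4 litters per timepoint, 7 pulses
E10.5–E13.5 — the co-labeling probability is the closed-form Gaussian
interval probability, which the simulator shares with the test oracles to
< 1e-12; (d) two-channel band images with optional salt noise for the
depth-profile fixtures; (e) genotype-dependent multiplicative frequency
shifts with Poisson replicate counts.

What it does not emulate: transcript counts or gene panels, segmentation or
cell-labeling errors, asymmetric or sheared tissue (available behind
options but off by default), EdU dilution, or conception-time uncertainty.
Passing tests therefore demonstrate the correctness of the computational
procedures under the stated generative assumptions — not robustness to the
full messiness of real imaging or spatial-transcriptomics data.

## Problem sizes

Defaults used by the test suite and the demo pipeline were chosen to keep
every check sharp but cheap: 20 seeds for registration recovery and
half-birthdate recovery, 5,000 points for contour calibration, 100 seeds
each for the null-calibration and power checks, 200 family neurons per
simulated embryo. All randomness flows through `numpy.random.default_rng`
seeded from the caller, and identical seeds yield byte-identical tables.
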