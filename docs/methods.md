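# Methods

clotlab simulates and analyses reconstituted blood-clot analogues: clots
mixed from platelet-rich plasma (PRP), packed red blood cells (RBCs) and
platelet-depleted plasma (PDP) over a factorial design of platelet
concentration and RBC volume fraction, then characterised by CT
densitometry, cyclic unconfined compression and histological area
quantification, with the RBC and platelet contributions decoupled by
multiple linear regression. This note records the models, the defaults and
why, the numerical choices, and what the synthetic data can and cannot
show.

## Study design and blending

The default design crosses 3 target platelet concentrations (30, 90,
270 x10^3 platelets/ul) with 5 RBC volume fractions (0, 0.5, 2, 5, 40%)
over 6 donors. Three of the 90 scheduled clots are dropped
(deterministically) to emulate attrition, leaving 87. Blending volumes
follow conservation of platelet number and volume,

    v_prp = C_target * V_total / C_prp,   v_rbc = f_rbc * V_total,
    v_pdp = V_total - v_prp - v_rbc,

treating PDP and packed RBCs as platelet-free. An infeasible recipe raises
rather than clamps: a clamped recipe would silently change composition.
Donor PRP concentrations are drawn uniformly on 460-620 x10^3/ul so that
the most demanding cell of the factorial (270 x10^3/ul at 40% RBC) is
feasible for every donor; reaching it requires C_prp >= 450 x10^3/ul.
Low-RBC clots use 3 ml syringes (8.66 mm bore), the 40% RBC clots 1 ml
syringes (4.78 mm), matching the expectation that high-RBC clots contract
little.

## Contraction model

Platelets drive clot contraction by pulling on fibrin and expelling serum;
RBCs resist volume reduction. The generator parameterises this with an
exponential serum-retention curve

    s(P) = s_min + (1 - s_min) * exp(-k * P),

with s_min = 0.02 and k = 0.017484 per 10^3 platelets/ul (so s(30) = 0.60
and s(270) ~ 0.03: a platelet-poor clot keeps ~60% of its plasma volume, a
platelet-rich one ~3%). RBC volume is conserved, so the retained volume
fraction is r = f + (1 - f) s(P) (with a 0.05% trace-RBC carryover so
nominally RBC-free clots still show sub-percent RBC content) and the
realized RBC content is 100 f / r, capped at 99.9%. Platelet area content
follows a Hill saturation of the platelet amount per retained volume,
phi = 0.95 * raw^1.3 / (raw^1.3 + 929^1.3) with raw = P (1 - f) / r.
Clot diameter scales as the cube root of r times the syringe bore.
Per-clot lognormal jitter (sigma = 0.10) on serum retention and platelet
occupancy represents donor and handling variability.

These constants were tuned once so the realized contents span <1% to >95%
RBC and <1% to >80% platelet across the design — the ranges the factorial
is built to cover. The model is deliberately phenomenological: it conserves
RBC volume and is monotone (RBC content non-decreasing in platelet
concentration at fixed RBC volume), but it does not reproduce every
distributional feature of real cohorts; in particular, measured-area RBC
medians in real MSB sections run higher than a volume-conservation argument
suggests, so median composition here sits lower than in laboratory cohorts
even though the spans match.

## Observable models

All observables are linear in the realized contents, matching the
regression family the analysis fits:

| outcome | model (defaults) | noise |
|---|---|---|
| NCCT density (HU) | 17.32 + 0.35·RBC% + 0.22·plt% | additive N(0, 3 HU) |
| CECT increase (HU) | 76 + 0.49·plt% − 10.23·diameter(mm) | additive N(0, 3 HU) |
| low-strain stiffness (kPa) | −0.26 − 0.001·RBC% + 0.09·plt% | lognormal, sigma=0.15 |
| high-strain stiffness (kPa) | −1.973 + 0.54·RBC% + 10.22·plt% | lognormal, sigma=0.15 |
| hysteresis loss (%) | 80.97 − 0.21·RBC% − 0.35·plt% | lognormal, sigma=0.15 |
| plastic strain (%) | 78.25 − 0.26·RBC% − 0.67·plt% | lognormal, sigma=0.15 |

Mechanical noise is multiplicative and mean-corrected
(y = mu * exp(N(-sigma^2/2, sigma^2))), so OLS point estimates stay
unbiased. The CECT intercept (76 HU) is set so the contrast-penetration
increment is non-negative over the noise-free design support (diameters up
to ~7.3 mm); the phantom generator floors the increment at zero because
contrast cannot reduce attenuation, and with this intercept the floor is
inactive except under noise. The linear stiffness models go negative for
platelet-poor clots — a fitted-intercept artefact; such targets are
projected to the nearest physically realisable feature set before trace
synthesis and flagged (`features_adjusted`).

## Cyclic traces with closed-form characteristics

Sections are compressed to 80% nominal strain (strain = displacement over
the initial 2 mm thickness, compressive positive) at 10%/s for 10 cycles.
The loading branch is sigma(eps) = A·eps + B·eps^5, with (A, B) solved from
a 2x2 linear system equating the continuous-OLS slopes over the 0-10% and
75-80% strain windows (polynomial moments integrated exactly) to the target
secant stiffnesses; B >= 0 and A > 0 guarantee monotone loading. The
unloading branch over x = (eps - eps_0)/(0.8 - eps_0) is the two-parameter
mix

    sigma = sigma_max * (w1·x + (1 − w1)·x^m)          (area coefficient < 1/2)
    sigma = sigma_max * (1 − w1·(1−x) − (1−w1)·(1−x)^m) (otherwise, reflected)

whose linear term keeps every slope finite — so the stress crossing of the
extraction tolerance is sharp and trapezoidal integration is second-order —
while the high power m (8-200) tunes the enclosed area. Given target
hysteresis H and plastic strain eps_p*, the solver fixes the unloading area
to (1 − H/100) times the loading area and shifts the vanishing point eps_0
by a fixed-point iteration (exact crossings via brentq) so that the strain
where stress falls to the extractor's baseline tolerance equals eps_p*
exactly. Peak stresses decay by a softening factor (default 0.95/cycle);
H = eps_p = 0 is special-cased as a fully reversible cycle. Extraction of
a generated trace at 0.1% strain sampling recovers all four features to
well under 0.5% relative (measured: <=0.16% over 200 random feasible
targets); refinement reduces the error monotonically.

Feature extraction itself: nominal stress = force / initial area; cycles
segmented at strain peaks (prominence 5% strain); secant stiffnesses are
free-intercept OLS slopes of stress on strain fraction over the closed
windows of the first loading branch (the 0-10% window fit is not anchored
at the origin — the convention is documented rather than assumed);
hysteresis is 100·(A_load − A_unload)/A_load with trapezoidal areas of the
first cycle; plastic strain is the first strain (walking down from the
peak) where stress falls to baseline + 0.01 kPa, linearly interpolated,
with the baseline taken as the median stress of the initial strain plateau
(0 when the record starts loading immediately). If stress never returns, a
`no_return` flag is set and the minimum strain reported. Only cycle 1
feeds hysteresis and plastic strain; all 10 peak stresses are kept as
diagnostics. A pre-deformed section is excluded via an explicit flag
(`exclude_flagged`), never auto-detected.

## CT phantoms and ROI densitometry

Phantoms are aligned (z, y, x) HU grids, voxel 0.5 x 0.12 x 0.12 mm: a clot
cylinder (uniform at the clot's NCCT density) inside media (10 HU) in a
10 mm tube; the contrast scan adds 340 HU to the media (20-fold diluted
iodixanol scale) and the floored penetration increment to clot voxels,
plus optional voxel noise. The ROI protocol measures three circular ROIs
of half the sample diameter — three such discs cannot be pairwise disjoint
inside one circular cross-section, so they are placed on distinct axial
slices (evenly spaced over the clot extent), each centred on the per-slice
clot centroid and required to inscribe fully. Per-ROI mean HU is averaged
unweighted; the CECT density increase is the CECT minus NCCT density over
identical ROI geometry and may be negative. Voxel-in-disc membership uses
the centre-of-voxel rule. Noise-free phantoms round-trip the generative
densities to machine precision.

## Histology masks and composition

The two stains are modelled as two masks of the same clot (they are
different physical sections): an MSB-like mask (RBC / fibrin+other / white
cells) and a CD42b-like mask (platelet / rest). Contents are component
area over clot cross-sectional area. The normalized composition divides
the RBC and platelet areas by the combined MSB clot area and CD42b
platelet area — implemented exactly as defined even though the denominator
mixes two sections and may double-count platelet-occupied area; the
remainder is "other". Two slices per clot are averaged field-wise when
available. The `exact` mask style allocates pixel counts on a 10,000-pixel
clot disc (contents exact to 0.01%); the `blob` style thresholds a
smoothed Gaussian random field at the content quantile for spatially
correlated patches.

## Statistics

Contents are summarised as median [25th-75th percentile]
(linear-interpolation quantile convention); normality screening is
delegated to standard Shapiro-Wilk. Associations are fitted by simple and
multiple least squares, reported as unstandardised coefficients with
t-based 95% confidence intervals (n − p − 1 degrees of freedom), two-sided
p-values (significance at 0.05, no multiple-testing correction), intercept
and R². Fitting is delegated to statsmodels; the test suite checks it
against an independent normal-equations + t-distribution oracle.

The parameter-recovery study refits each outcome's generative model on 200
replicate cohorts. Point estimation is OLS throughout. For the mechanical
outcomes, whose generative noise is multiplicative (variance proportional
to the squared mean), classical homoskedastic t intervals are not
calibrated (measured coverage 0.77-0.99 across coefficients), so recovery
coverage is scored with heteroskedasticity-consistent HC3 intervals —
chosen over HC1/HC2 by a 2000-replicate calibration (true coverage
0.937-0.968, the variant closest to nominal). Imaging outcomes have
additive noise and keep classical intervals. Two resolution caveats are
applied when scoring a 200-replicate study: bias is tested against
max(5% |beta|, 4 Monte-Carlo SE), since the 5% band for the near-zero
low-stiffness RBC coefficient (|beta| = 0.001) lies far below what 200
replicates can resolve, and observed coverage is required to be consistent
(3 sigma binomial) with a true coverage in [92%, 98%].

## Problem sizes and determinism

Default sizes: 87-clot cohorts; traces of ~16,000 samples per 10-cycle
record at 0.1% strain steps; phantoms of 16 x 88 x 88 voxels; masks of
160 x 160 pixels; 200 replicates for recovery. A full pipeline run takes
about a second on one CPU and the recovery study a few seconds. Every
stage draws from seeds derived from the single run seed; a fixed
configuration reproduces byte-identical output files.

## Limitations

The generator is a calibration harness, not a physiological model: linear
observable models with independent noise (no shear-dependent formation, no
contrast-diffusion kinetics — the 5-minute incubation is a parameter, not
a model), phenomenological contraction, uniform-density clots, aligned
phantoms with no registration error, and label masks in place of a learned
tissue classifier. Passing tests therefore demonstrate that the analysis
machinery is correct and calibrated under known truth — not that the
linear models describe any particular laboratory cohort. Constitutive
(hyperelastic/viscoelastic) fitting and tensile behaviour are out of
scope.
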