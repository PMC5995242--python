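# Methods

`lymphmorph` quantifies lymphatic microvascularization in stained
brightfield histology (TMA-core style images) and relates the resulting
morphometry to risk classification and survival. This note documents the
models, the measurement conventions, the synthetic-data generator that
serves as the test bed, and the numerical choices that were genuinely open.

## Measurement model

**Stain separation.** Each pixel is assigned to the nearest of three
reference colors (stain, counterstained tissue, slide background) by
Euclidean distance in RGB. This is deliberately simple: the package's
synthetic images use a fixed two-color scheme for which nearest-reference
classification is essentially exact, and robustness to real
chromogen/counterstain variation (color deconvolution, illumination
correction) is out of scope. Reference colors are arguments, so a user with
measured stain vectors can substitute them. Tissue area (mm²) is the
non-background pixel count times the pixel area; an image with no tissue is
flagged non-evaluable.

**Vessel extraction and outline closing.** Connected stain components are
treated as vessel walls. A component whose filled interior contains a hole
is an intact ring; the largest hole is its lumen. A component without a
hole is a broken ring: the wall's morphological skeleton is computed, and
skeleton endpoints whose separation does not exceed `max_gap` (default
10 μm) are joined by a straight 2-px chord, after which the interior is
filled. Candidate endpoint pairs are tried from the widest gap downward and
a closure is accepted only if it actually creates a lumen-sized hole. Walls
that cannot be closed are discarded and logged. A parallel, purely
geometric operation (`close_open_outlines`) performs the same closing on
polyline contours with mutual-nearest-endpoint matching (ties broken by
smaller distance, then lower contour index); it is idempotent and is the
normative definition of the closing rule. Chord (straight-line) closing was
chosen over curvature continuation; the gap tolerance is exposed as a
parameter because no principled default exists beyond "a small multiple of
a capillary diameter."

One simplification: the mask-level extractor closes breaks *within* one
connected component. A wall broken in two or more places (several disjoint
arcs of one vessel) is handled by the geometric closer but not reassembled
at mask level; the synthetic generator draws at most one gap per vessel, so
passing tests say nothing about multi-gap walls on real material.

**Lumen-based sizing.** All measurements are taken on the lumen — the
interior of the closed wall excluding wall pixels — so vessel size is
independent of wall thickness. Regions whose lumen longest axis falls
outside 5–200 μm are discarded (large collectors are not considered).
Lengths within one pixel of these bounds are snapped onto the bound: the
cutoff cannot be resolved more sharply than the discretization, and without
the snap a one-sided loss of boundary-grazing vessels appears.

**Descriptor suite.** With A the lumen area, P its perimeter
(Crofton, 4 directions), L and W the maximum and minimum Feret diameters of
the lumen (computed on the convex hull of pixel centers, which is unbiased
for boundary-inclusive rasterization — verified on digital discs of known
diameter), and H the convex hull:

| descriptor | definition | disc value |
|---|---|---|
| roundness | P² / (4πA) | 1 |
| aspect | L / W | 1 |
| perimeter ratio | P / P(H) | 1 |
| deformity | 1 − A / A(H) | 0 |
| shape factor | L² / (4A/π) | 1 |
| branching | endpoint count of the lumen skeleton (min 2) | 2 |

These formulas are the package's normative definitions. A simple tube has
two skeleton endpoints, so `branching = 2` is the unbranched reference.

**Caliber classes.** Vessels are classified by lumen longest axis into
small capillaries (5–15 μm), intermediate capillaries (15–20 μm), large
capillaries (20–50 μm) and small collectors (50–200 μm). Intervals are
half-open at the lower edge — a 15 μm vessel is an intermediate capillary —
a convention fixed here because a deterministic rule is needed at the
boundaries.

**Per-sample quantities.** Per class and in total: density (vessels/mm²),
%SA (lumen area as % of tissue area — wall pixels excluded, consistent with
lumen-based sizing), and the relative shares rel. density and rel. %SA
(per-class % of the total, summing to 100% where the total is positive),
plus per-class medians of every descriptor. A sample with tissue but no
stained vessel is flagged "no lymphatic vascularization"; such samples are
excluded from the statistical layer and carried into survival as their own
stratum.

## Statistical layer

* **Dichotomization.** Continuous variables split at the median; high
  means strictly greater. An all-equal vector is therefore all-low.
* **Contrasts.** Two-sided Mann–Whitney per variable × binary adverse
  factor; exact when both groups ≤ 8 without ties, tie-corrected normal
  approximation otherwise. Significant cells (α = 0.05) are reported with
  the direction of the adverse-minus-reference median difference. No
  multiple-testing correction is applied, by design.
* **Logistic risk model.** Maximum-likelihood logistic regression (IRLS)
  of the binary risk group on 0/1 high-median indicators, low group as
  reference. Backward elimination removes, at each step, the term with the
  largest likelihood-ratio removal p ≥ 0.10. The 0.10 stay threshold keeps
  marginal terms (p ≈ 0.07) in the final table; LR-based removal is the
  surrogate for SPSS-style "conditional" elimination, whose exact statistic
  is not public. Quasi-separated coefficients (|B| > 15) are reported but
  flagged non-estimable. The fitted model is summarised as a multiplicative
  odds equation: a sample's odds multiplier is the product of Exp(B) over
  its high indicators.
* **Heterogeneity.** Per variable: a histogram with ⌈2·N^(1/3)⌉ bins
  (Rice's rule, ceiling convention) with counts normalised to sum to 1, and
  excess kurtosis G2 = m₄/m₂² − 3 using population-normalised central
  moments (the plain fourth standardized moment, not the small-sample
  corrected estimator), with SEK = √(24/n) and Zg2 = G2/SEK. |Zg2| > 2
  flags departure from normality at the 95% level (leptokurtic when
  positive). For the relative variables (rel. density, rel. %SA) zeros are
  discarded before binning, since zero encodes "no vessel", not a measured
  share; N for the bin count is the post-discard size. Under simulated
  normality the |Zg2| > 2 flag fires in roughly 3–5% of replicates at
  n ≈ 200 (the finite-sample kurtosis distribution is slightly
  conservative here).
* **Survival.** Kaplan–Meier with Greenwood standard errors and the
  5-year (60-month) survival read from the step function; one-degree
  log-rank for group comparisons. Cox proportional hazards (Efron tie
  handling) over the pre-treatment binary factors plus the above-median
  total-density indicator, with backward elimination of the covariate with
  the largest Wald p ≥ 0.05 per step. OS is modelled as time to death
  censored at last follow-up. `hr_from_ci` exposes the Wald-symmetry
  identity HR = √(CI_low · CI_high), useful for checking reported
  (HR, CI) triples.

## Synthetic-data generator

The generator emulates the study material so every stage is testable
without any protected patient data.

**Vessel geometry.** A lumen is an ellipse perturbed radially by Fourier
modes 2–8 with amplitudes proportional to an `irregularity` parameter
∈ [0, 1], rescaled so the maximum Feret diameter equals the nominal axis
(within 5%); at irregularity 0.8 outlines are strongly non-round
(roundness > 2). The stained wall (1.5–3 μm, up to 5 μm for collectors) is
drawn outward from the lumen boundary, so ground-truth lumen size is what
the measurement stage should recover. An open-walled vessel has one
contiguous arc removed; the gap is sized as a chord of 2–8 μm — a local
stain discontinuity, never wider than 45% of the vessel axis — rather than
a fixed fraction of the perimeter, because staining defects do not scale
with vessel caliber. The removed fraction never exceeds 0.35 of the
perimeter.

**Core images.** Vessels are packed without overlap into a 1 mm circular
core by bounded rejection sampling (failure raises a packing error),
rendered at 0.5 μm/px (configurable, ≤ 1 μm/px) in a DAB-like brown over
pale counterstained tissue on a white slide, with additive Gaussian pixel
noise (σ = 6 grey levels by default). Lumens are background-colored
(optically empty). No staining artifacts, folds, or scanner color profiles
are simulated — recall measured on these images is an upper bound on real
IHC performance.

**Cohorts.** Default study conditions: 332 samples of 1.571 mm² tissue
(two 1-mm cylinders); 37.9% with no stained vessel; per-sample total
density lognormal with median 40.6 vessels/mm² and log-SD 1.0 (spanning
roughly 1–1000/mm², strongly leptokurtic); 75% small capillaries, the rest
split 8.2 / 12.3 / 4.5% following the relative per-class density scale of
the emulated cohort. Per-vessel descriptors are drawn from parametric
distributions whose class-wise medians grow with caliber (e.g. roundness
medians ≈ 1.5 / 2.7 / 4 / 8). Binary adverse factors use prevalences
(stage M 0.45, age > 18 mo 0.50, unfavourable histology 0.80, MYCN
amplification 0.20, 11q deletion 0.20, high risk 0.45) typical of the
referral setting emulated. By default the risk label is independent of
morphometry; recovery tests plant effects explicitly, so a null model is
the correct answer on default cohorts. Survival times are exponential with
proportional hazards (log-HRs: stage 1.1, MYCN 0.95, age 1.0, high total
density 0.9) on a baseline of 0.0015 events/month, which puts the pooled
5-year EFS near 60–70%; OS uses 0.6× the baseline. A configurable fraction
(default 0.30) of records is censored uniformly before the event time —
censoring is independent of covariates but not of follow-up length, which
is adequate for the estimators exercised here. Everything derives from one
integer seed; equal seeds give byte-identical tables.

**What passing tests show.** Segmentation recovery ≥ 90% with per-class
densities within 10% of truth holds for this noise model and gap model;
logistic/Cox parameter recovery holds at n = 1000–2000 with clean binary
covariates. None of this certifies performance on real D2-40 slides, with
their staining artifacts, touching vessels, and correlated covariates.

## Numerical choices

* Perimeters use the Crofton estimator (4 directions): within ~1% on
  digital discs, where the naive boundary-step perimeter is 3–4% high —
  material because roundness is quadratic in P.
* Feret diameters from the convex hull of pixel centers; the minimum
  Feret is the smallest hull-edge-normal projection width, clamped to ≥ 1
  px to avoid zero widths on 1-px-wide shapes.
* Rice's rule uses ceiling with a 10⁻¹² guard against floating-point
  overshoot at perfect cubes.
* Mann–Whitney switches to the exact distribution only when both groups
  are ≤ 8 and tie-free.
* The pipeline canonicalizes stage-1 tables through their CSV
  representation so fresh and cache-resumed runs are checksum-identical;
  CSV reads use round-trip float parsing.
* Degenerate inputs fail loudly: zero variance (kurtosis), empty groups,
  SE ≤ 0, zero tissue area, < 2 events (Cox), non-positive CI bounds.

## Known limitations

* Nearest-color stain separation will not survive real-world stain
  variability; it is the documented extension point.
* Multi-gap vessel walls are not reassembled at mask level (see above).
* Branching via raw skeleton endpoints can over-count on very irregular
  lumens where skeletonization sprouts spurs; the disc/tube reference
  cases are exact, but absolute branching values on highly deformed shapes
  should be read comparatively.
* The Cox elimination reports the coefficient a covariate had in the model
  from which it was dropped, not a re-fitted marginal estimate.
* The generator's per-vessel descriptor distributions are plausible but
  not fitted to any real per-vessel dataset; only the quantity layer
  (density, class mix, zero fraction, survival scale) is calibrated to the
  emulated study conditions.
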