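# Methods

## The measurement model

A nucleus is represented by its boundary polygon in calibrated μm
(`NucleusShape`). Coordinates stay in the image frame (y down); because
all four size parameters are invariant under reflection, frame
handedness never changes a value, and the stored ring is merely
normalized to positive shoelace orientation for cleanliness. Rings are
cleaned on ingest: repeated closing vertices and consecutive duplicates
dropped, bow-tie (self-intersecting) rings repaired by keeping the
largest simple sub-polygon (segmentation exports occasionally contain
them), unrepairable rings rejected.

The four parameters:

- **Area** — absolute shoelace sum. Exact for polygons.
- **Perimeter** — closed-ring edge-length sum. No curvature or Crofton
  correction is applied; on rasterized input the sub-pixel
  marching-squares contour plus 0.05-pixel decimation keeps the residual
  staircase bias at roughly 1–3%, a known property of the mask path
  (polygon input has no such bias).
- **Maximum Feret diameter** — the polygon diameter, attained at a pair
  of convex-hull vertices, so an all-pairs scan over hull vertices is
  exact.
- **Minimum Feret diameter** — the minimum caliper width, attained
  perpendicular to some hull edge; the minimum over hull edges of the
  farthest-vertex distance to the edge's supporting line is exact. No
  angular discretization is involved in either Feret value; the dense
  angle-sweep appears only as a test oracle.

The hull itself comes from Qhull (scipy); the caliper scans are
implemented here. Record invariants are enforced at construction:
positivity, *F*min ≤ *F*max, the isoperimetric inequality
L² ≥ 4πA, and A ≤ *F*min·*F*max.

## Label-mask ingest

Each positive label is contoured by marching squares at iso-level 0.5 on
its padded binary image, giving sub-pixel vertices, then decimated with
tolerance 0.05 pixel. Border-touching labels are incomplete nuclei and
are excluded by default (`include_border=True` overrides). One isotropic
μm/pixel scalar per image; anisotropic pixels are unsupported (the
scanners this pipeline targets are isotropic at 0.19/0.25/0.5 μm/pixel).
Because masks become polygons before measurement, the mask and GeoJSON
paths share one measurement code path by construction.

## Summaries and quantile conventions

Cases (or pooled variants) are described by the median and quartiles of
each parameter; IQR is always recomputed as Q3 − Q1, never trusted from
input. Two quantile rules are exposed because published small-sample
quartiles depend on the convention: `interp_linear` (h = (n−1)p + 1,
numpy's default) and `spss_haverage` (h = (n+1)p, SPSS's default,
numpy's `weibull`). The default is `interp_linear`. Convention slippage
of exactly this kind is the most plausible source of the handful of
published table entries whose printed IQR differs from Q3 − Q1 by one
final digit; those entries are detected programmatically
(`published.iqr_is_self_consistent`) and excluded from exact regression
comparisons rather than silently tolerated.

Both pooling modes are provided — per-case, and pooling all nuclei of a
variant's cases — since variant-level summaries can be built either way;
pooled-by-variant is used for table-style output. Reference ratios are
elementwise median ratios, reported raw and rounded to one decimal (the
display convention of "times larger than a lymphocyte" tables).

## Classification

The published 8 cut-offs (median and IQR of each parameter) are shipped
as a versioned rule set with strict `>` comparisons, matching their
"> 48.2 μm²" phrasing; a summary exactly at a threshold does not fire.
How the study combined eight rules into one diagnosis is not stated, so
the combination policy is explicit: the default `single_parameter` rests
the call on the maximum-diameter median + IQR rules (maximum diameter is
the most influential parameter in the multivariable model), with
`all_of`, `any_of` and `vote_k` available.

ROC analysis uses the distinct observed scores as candidate thresholds,
positives called by `score > t`; AUC is the tie-aware Mann–Whitney
probability (ties ½), identical to the trapezoidal area. "Highest
sensitivity and specificity" is operationalized as the Youden index,
ties broken toward the smaller threshold (the higher-sensitivity cut).
This in-house implementation exists because the strict-`>`/distinct-
threshold/tie-break conventions are part of the method's definition;
sklearn's ROC is used as an independent cross-check in the tests, never
as the implementation.

The logistic model is a maximum-likelihood fit (statsmodels Logit,
Newton; BFGS fallback when the Hessian is singular or separation is
detected) with Wald 95% CIs and p-values — the output conventions of
mainstream statistics packages. Odds ratios are per raw unit (μm, μm²)
by default; `standardize=True` rescales to per-SD. Complete or
quasi-complete separation is flagged and warned, never silently
returned. Note that per-case medians of the four parameters are nearly
collinear (all driven by overall case size), so multivariable fits on
case-level medians of clean synthetic cohorts are frequently separated
or ill-conditioned; nucleus-level fits are well-behaved.

## Synthetic cohorts

The generator emulates the published per-variant distributions:

- **Area law**: lognormal, calibrated from a printed (median, Q1, Q3)
  triple by μ = ln median, σ = ln(Q3/Q1)/(2 z₀.₇₅), z₀.₇₅ = 0.6744898.
  A lognormal was chosen because every published variant row is
  right-skewed (Q3 − median > median − Q1); the calibration matches the
  quartile ratio exactly and reports the residual asymmetry
  |ln(Q3/m) − ln(m/Q1)| as a diagnostic instead of hiding it (≈ 0.02–0.3
  across the published rows).
- **Shape**: an ellipse sampled at equally spaced polar angles, radius
  modulated by random low-order Fourier modes (2–6, total relative
  amplitude `boundary_noise`, default 0.06), randomly rotated, rescaled
  to the drawn area to machine precision. Radial (star-convex)
  construction guarantees a simple ring at any admissible noise level.
  The eccentricity default per variant is centred on the value whose
  ellipse axis ratio 1/√(1−e²) equals the variant's published
  max/min-Feret median ratio (±0.05).
- **Case heterogeneity**: a per-case multiplicative shift of the area
  median, lognormal with log-SD `case_heterogeneity`, default 0.17 — a
  constant fitted once to the spread of the 14 published per-case
  pleomorphic-ILC area medians (their log-SD) and documented as such.
- **Nuclei per case**: uniform 100–600 by default; the study's per-case
  counts appear only in a supplement not reproduced here, so this is an
  order-of-magnitude guess recorded in the spec defaults.
- **Reference cells**: lymphocyte and normal-epithelium medians are
  never printed in the published tables; `reference_spec` back-derives
  them from the printed lesion-to-reference ratios (≈17.3 μm² and
  ≈23.5 μm²) and is labelled synthetic accordingly.

Perimeter and Feret laws are **not** independently specified; they
emerge from the area law and the shape model. Consequently the generator
reproduces published area medians/IQRs and diameter *ratios* faithfully,
and perimeter/diameter levels only approximately. Real H&E nuclei also
have texture, clustering, segmentation errors and non-stationary
composition that the generator does not model — passing tests show the
*pipeline* is correct and well-calibrated, not that real-slide
performance equals the synthetic numbers.

Determinism: one integer seed drives one `numpy` Generator through the
whole cohort; identically seeded cohorts are byte-identical after
GeoJSON serialization (sorted keys, shortest-round-trip floats).

## Verification choices and problem sizes

- Geometry is checked against independent oracles: all-pairs distances
  and a 3600-angle caliper sweep for the Feret values, an O(n³)
  half-plane test for the hull, Monte-Carlo point-in-polygon (10⁶
  points) and shapely for area/perimeter, closed forms for regular
  n-gons and ellipses.
- AUC is checked against the brute-force pairwise concordance count with
  ties, and against sklearn; the logistic fit against the 2×2
  closed-form odds ratio ad/bc and by parameter recovery within 2 SE.
- Calibration fidelity is asserted pooled over 2000 rendered and
  re-measured nuclei per variant: median within 5%, IQR within 10% of
  the generating law. This check sets `case_heterogeneity = 0` to
  isolate the area law: with a nonzero case shift the pooled law is
  wider by construction (log-scale √(σ² + τ²)), which is a property of
  the cohort model, not a calibration error.
- Discrimination is asserted on a default-parameter cohort of 20 cases
  per arm × 200 nuclei (pleomorphic vs classic score 1): the case-level
  area-IQR ROC must exceed AUC 0.85. These sizes keep the full suite
  around half a minute while leaving comfortable statistical margins.

## Known limitations

- Mask-derived perimeters carry the 1–3% contour bias noted above.
- The rule set's sensitivity/specificity/AUC values published for the
  original 59-case cohort cannot be reproduced without the raw data;
  they are deliberately not asserted anywhere.
- The published multivariable odds ratios are likewise not reproducible
  (feature scale and positive-set definition unstated); only structural
  properties of the logistic fit are tested.
- Anisotropic pixel calibrations, whole-slide pyramidal formats, stain
  handling and nucleus *detection* are out of scope: the pipeline starts
  at boundaries.
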