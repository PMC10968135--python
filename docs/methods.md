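# Methods

## The analysis

The pipeline quantifies ascending-aortic-aneurysm growth and its
hemodynamic correlates from paired surface models of one patient's aorta
(two CT-derived exams, 1–3 years apart) whose walls carry steady
peak-systole pressure and wall-shear-stress fields computed upstream by a
CFD solver. Nothing in this package solves flow; the wall fields are
consumed, not produced.

Per patient the stages are:

1. **Superposition.** The second exam is mapped into the first exam's frame
   by the least-squares rigid motion (Kabsch, SVD of the cross-covariance)
   over three anatomical correspondences: the aortic-annulus point, the
   brachiocephalic-trunk centroid, and the right coronary ostium. Two
   anchoring structures alone leave the rotation underdetermined, so the
   annulus point — defined for every exam by the inflow plane — serves as
   the third pair. Collinear correspondences are rejected.
2. **Region of interest.** The ascending segment is cut out by two plane
   clips: the annulus (inflow) plane, keeping the distal side, and the
   plane anchored at the brachiocephalic centroid, keeping the proximal
   side. The distal plane's orientation is not fully determined by its
   anchor; we orient it along the centerline tangent at the centerline
   point nearest the anchor. Each exam is clipped with its own (superposed)
   landmarks. The angle θ between the annulus plane and the
   brachiocephalic-to-left-main-coronary line is reported descriptively;
   it gates nothing.
3. **Growth call.** Growth is an ROI volume increase of at least 5 %
   between exams, inclusive at the boundary. Volumes are divergence-theorem
   sums over the closed clipped surface, reported in cm³.
4. **Stress metrics.** On the first exam's ROI, ten region statistics:
   area-weighted mean and maximum of relative pressure over faces with
   P ≥ 100 Pa; mean and maximum WSS over faces with τs ≥ 5 Pa and ≥ 7 Pa;
   and the same WSS statistics over the intersections of each high-shear
   region with the high-pressure region. Thresholds are inclusive. An
   empty region yields a *missing* metric — not zero — and the missingness
   (with its n) flows through all cohort statistics, as in real cohorts
   where some patients have no high-pressure/high-shear overlap.
5. **Stress load.** Each baseline metric times Δt (years), in Pa·years,
   models the cumulative burden of wall stress between exams.
6. **Cohort statistics.** Continuous variables: Shapiro–Wilk per group at
   α = 0.05; both groups normal → unpaired two-sample t test (mean ± SD),
   otherwise Mann–Whitney U (median [IQR]). The gate's p-values are
   recorded in every result for audit. Categorical variables: Fisher's
   exact test when a 2×2 table has any expected cell < 5, chi-square
   otherwise. Association: Spearman with average-rank ties. Prediction:
   univariate logistic regression of growth on each annualized metric,
   OR = exp(β₁) with Wald 95 % CI (profile-likelihood CI available via
   `ci="profile"`); optional bidirectional stepwise selection on AIC from
   the null model, deterministic given candidate order. All tests
   two-tailed at α = 0.05, no multiple-testing correction.

## Geometry conventions

* Coordinates in mm, volumes in mm³ internally and cm³ at reporting
  boundaries; fields in Pa.
* Scalar fields live on faces. Vertex-data inputs (VTK `POINT_DATA`) are
  averaged onto faces at read time; thresholding and area weighting are
  then unambiguous.
* Plane clipping splits crossing triangles exactly on the plane (shared cut
  vertices are cached per edge, so two complementary clips produce
  bit-identical cut points and volumes that sum exactly). Every open
  boundary loop is capped by a triangle fan anchored at the loop centroid —
  exact for convex loops and adequate for near-circular vessel cuts. Child
  faces inherit their parent's field values; cap faces carry value 0 and a
  `cap` flag, and all region statistics exclude flagged faces (the cut
  planes are not vessel wall).
* "Maximum diameter" is the maximum over centerline stations of the
  equivalent-area diameter 2·√(A/π) of the cross-section polygon containing
  the station point. The equivalent-area convention is robust to the
  non-circularity of aneurysmal sections; a max-chord convention would read
  systematically larger on elliptical cuts.
* Centerlines are inputs (the synthetic generator emits them analytically);
  no skeletonization is implemented.
* `enclosed_volume` demands a closed, consistently oriented surface and
  raises otherwise; clipping always returns a closed surface.

## Flow-verification formulas

`V = 4Q/(πD²)` (Q in L/min, D in mm, V in m/s), `Re = ρVD/μ ≡ 4ρQ/(πμD)`,
`y⁺ = ρ·y·u_τ/μ` with friction velocity `u_τ = √(τs/ρ)`, and
`GCI = Fs·|ε|/(rᵖ−1)`, `ε = (φᵢ−φᵢ₊₁)/φᵢ₊₁`. Defaults: blood density
1054 kg/m³, dynamic viscosity 3.5 mPa·s, inlet flow 25 L/min (systolic
peak), turbulence intensity 5 %, outlet split 69.1 / 19.3 / 5.2 / 6.4 %
(descending, brachiocephalic, left carotid, left subclavian), refinement
ratio 2.04, safety factor 2. The discretization order p defaults to 2
(second-order upwind upstream solver) and is overridable. The magnitude of
ε is used so the index never goes negative. The y⁺ expression is the
standard friction-velocity form consistent with its symbol list.

## The synthetic generator

**Geometry.** A circular tube swept along a straight ascending segment
(default 80 mm) that bends into a partial arch (radius 30 mm, 100°), with a
short 6 mm root extension below the annulus so the inflow clip plane cuts
interior wall. The aneurysm is a Gaussian radial bulge
`r(s) = r₀(1 + A·exp(−(s−c)²/2w²))`; the default amplitude A = 0.68 on a
30 mm annulus puts the maximum equivalent diameter at 50.4 mm, a typical
moderately dilated ascending aorta. The exact ROI volume is
`π∫r(s)²ds` by adaptive quadrature (the curvature term integrates to zero
around the ring), giving every geometric operation an analytic oracle; at
the default resolution (64 × 160) the faceted mesh sits ~0.2 % below the
analytic volume (inscribed-polygon deficit), well inside the 1 % contract.
Paired exams solve the second exam's bulge amplitude by Brent root-finding
on the analytic volume so the ROI change meets (or infinitesimally exceeds,
never undershoots) the prescribed target, then displace the second exam by
a seeded random rigid motion so registration is genuinely exercised.
Landmark offsets ride on the local radius, so paired exams' landmarks
differ by a fraction of a millimetre — a realistic, slightly imperfect
correspondence.

**Wall fields.** The systolic inflow jet is modelled as a pressure hotspot
decaying as a Gaussian of chordal distance from the impingement point on
the anterior wall, and a ring of elevated WSS around it with low WSS at the
stagnation centre. Both hotspots are normalized so the configured peak
values are attained exactly at some face. Chordal distance approximates
geodesic distance; acceptable while hotspot widths (≈10 mm) stay well below
the vessel circumference (≈160 mm). Optional additive Gaussian noise is
clipped at zero.

**Cohorts.** Defaults encode the study conditions: 14 no-growth and 16
growth patients; inter-exam intervals 1.6 ± 0.7 vs 2.1 ± 0.7 years; ROI
volume changes −4.83 ± 5.86 % vs +12.71 ± 5.20 %; and per-group
means ± SDs for all ten stress metrics. Tabular mode draws each metric from
a left-truncated normal (pressure metrics cannot fall below 100 Pa, shear
metrics below their cutoff) whose **post-truncation** mean and SD are
solved numerically to equal the configured values — naive truncation at the
bound would inflate means by up to ~8 Pa and decalibrate the generator.
Intersection metrics go missing with independent per-patient Bernoulli
rates (3–4 per 30) chosen to match observed per-metric n; only the n is
known, not the mechanism. Metrics are drawn independently within a patient:
the real within-patient correlation structure is uncharacterized, so
passing tests say nothing about joint-metric behaviour. The growth *label*
always comes from applying the ≥ 5 % rule to the sampled volume change
(≈ 93 % of growth-arm patients cross it), while `arm` records the
generative group. Field mode instead samples per-arm jet peak intensities
(from the Pmax and τmax,5 group distributions), builds paired geometries
and fields, and fills the table through the real pipeline — group
separation is then carried only by jet intensity, mirroring the premise
that anatomy-driven jet strength drives wall loads.

## Numerical choices

* Clipping tolerance: vertices within 1e-9 × mesh scale of the plane are
  snapped onto it; degenerate (≤ 1e-12 mm²) faces are dropped at
  construction and after clipping.
* Non-manifold cut loops (a boundary vertex with two outgoing edges) raise
  with the offending vertices named rather than producing a silently
  leaking cap.
* Logistic separation is flagged, not estimated: a fit whose per-SD
  log-odds or its standard error exceeds 25 is reported with
  `separated=True` and no OR.
* Stepwise ties break by candidate order; candidates whose fit separates
  or fails are skipped with a warning.
* Station planes that produce no closed cross-section are skipped with a
  warning; only an all-stations failure is an error.
* The cohort report and manifest are deterministic given the input table
  and config; manifests record SHA-256 checksums of inputs and outputs.

## Problem sizes used in the checks

The test suite and acceptance script run the geometric recovery at
48 × 96 tube resolution (~9 300 faces), metric-oracle equivalence on 100
random fields, generator calibration at n = 1000 per arm, the type-I-error
simulation at 1000 replicates, and detection-frequency comparison against a
2000-replicate Monte-Carlo power oracle over 200 cohort seeds — sizes at
which every tolerance above is comfortably resolved.

## Known limitations

* The ROI distal plane's orientation convention (centerline tangent) and
  the equivalent-area diameter are documented choices; other conventions
  would shift absolute values slightly without changing the pipeline's
  contracts.
* Fields are per-face; maxima are face maxima, which on coarse meshes read
  slightly below a nodal maximum.
* The generator's aorta is circular in section and unbranched (landmarks
  stand in for branch ostia); it emulates volumes, hotspots, and cohort
  statistics, not patient-specific anatomy, branch flows, or pulsatility.
* Time-resolved metrics (TAWSS, OSI) are out of scope: the analysis is a
  steady systolic-peak snapshot.
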