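# Methods

Statistical and numerical specification of the `clusterscan` package. The
README gives the scientific motivation; this document records the exact
model, the defaults and their rationale, the numerical choices, and the
known limitations.

## 1. Study design

A cluster-scanning study of one participant consists of three timepoints —
baseline (`BL`), 3 months (`M3`), 6 months (`M6`) — each comprising 2 days ×
2 sessions/day × 8 scans/session = 32 scans, i.e. 96 scans in total. Every
scan yields one mean-thickness value for the patient-specific **core** ROI
and one for the **control** ROI, giving 192 analysis rows. The two ROI rows
of a scan share that scan's acquisition (and hence its day/session/scan
random effects and its motion score).

## 2. Normative W-scores

For each cortical unit (vertex or parcel), an ordinary-least-squares model
`thickness ~ age + sex` is fit to a normative cohort (default n = 25,
minimum 4 so the design matrix plus residual df is defined). The W-score of
an observed patient value is

```
W = (observed − predicted) / SD_resid
```

with `SD_resid` using the residual degrees of freedom `n − 3` by default
(`n − 1` is available as an option). W behaves like a z-score adjusted for
age and sex: training-cohort W-scores are mean-zero by construction, and a
value 2 residual-SDs below prediction gives W = −2. Cohorts with collinear
covariates (e.g. constant age) are rejected; degenerate units (zero residual
variance) either raise or propagate NaN according to policy.

## 3. ROI definition

- **Core ROI**: vertices with W < −2 (strict inequality) are clustered into
  connected components on the cortical mesh (breadth-first search over the
  edge list). Components smaller than `min_size` (default 1) are dropped;
  components whose majority parcel is not in the allowed parcel set are
  dropped; the core ROI is the union of all retained components. Components
  are named largest-first.
- **Control ROI**: pre/postcentral parcels minus vertices with W < −0.25
  (strict). Vertices with NaN W-scores are left out of the control ROI —
  a unit without a reliable normative fit cannot be certified "near
  normal". An empty control ROI is an error.
- Core and control are disjoint by construction (−2 < −0.25).

The −2 threshold selects clearly atrophic cortex; −0.25 is deliberately
conservative for the control, excluding even mild sub-normality so the
control tracks global/technical effects only.

## 4. Motion quality control

For a rigid-body transform (R, t) between two head positions, the RMS
displacement over a sphere of radius r = 64 mm (approximating the head) has
the closed form

```
RMS² = (r²/5)·tr(AᵀA) + ‖A·c + t‖²,   A = R − I
```

(c the sphere centre, at the origin here). The framewise measure **RMSpm**
is the summed displacement path across a scan divided by scan duration in
minutes. Scans with RMSpm **strictly greater than 10** mm/min are excluded;
exactly 10 is retained. The closed form is verified in the test suite
against Monte-Carlo uniform-ball sampling for 50 random rigid transforms.

## 5. Linear mixed model

For row i (ROI r, timepoint t, scan s in session j of day d):

```
y_i = μ + τ_t + ρ_r + (τρ)_tr + β·RMSpm_i + u_d + v_dj + w_djs + ε_i
u ~ N(0, σ²_day),  v ~ N(0, σ²_sess),  w ~ N(0, σ²_scan),
ε_i ~ N(0, σ²_{stratum(i)}),  stratum = roi × timepoint  (6 strata)
```

Nested random intercepts absorb day-to-day physiological/positioning
variation, session effects, and scan effects shared by the two ROI rows;
the residual strata let the core and control ROIs (and each timepoint) have
their own measurement noise, which balanced data otherwise conflate.

**Estimation.** REML with the residual error variance profiled out. The
parameter vector is θ = (log γ_day, log γ_sess, log γ_scan,
log w₂ … log w₆) — variance ratios relative to σ² and residual stratum
weights relative to the first stratum. The restricted log-likelihood and its
**analytic gradient** are evaluated via Cholesky factorization of V(θ);
optimization is L-BFGS-B from multiple deterministic starting points, with a
consensus rule: an `ABNORMAL` optimizer status is accepted only when an
independent restart reproduces the same optimum. A `fixed_theta` evaluation
path performs pure GLS at user-supplied variances; it backs the exact GLS
oracle tests. Datasets the fixed effects fit exactly (zero residual,
e.g. noise-free synthetic data) short-circuit to OLS with
`singular = True`, zero covariance, and variance components zero.

**Inference.**
- Estimated marginal means (EMMs) per `timepoint × roi` cell are computed
  at the mean motion score. For balanced saturated designs GLS EMMs equal
  raw cell means exactly.
- Pairwise contrasts: the 6 within-ROI timepoint differences, Bonferroni
  adjusted within the family of 6 (α = .05/6 ≈ .008). Interaction
  contrasts: core-minus-control differential declines, family of 3
  (α = .05/3 ≈ .017).
- Denominator degrees of freedom use the **containment** method (92/93 on
  the default design). Wald F-tests for each fixed term and a REML-valid
  likelihood-ratio test between nested *random*-structure models (same
  fixed effects required) are provided.
- `percent_change` reports 100·(EMM_follow − EMM_ref)/EMM_ref rounded to
  one decimal, matching conventional reporting.

### Known limitation: containment df can be liberal

Containment df treats the 192 rows as carrying more information about cell
means than they do when day-level variance dominates: with only 2 days per
timepoint, the effective replication for a timepoint mean is closer to 2
than to 32. In simulations with σ_day comparable to the residual SD, the
null rejection rate of the main-effect F-test reaches ~20% at nominal 5%,
and 95% EMM intervals cover the truth ~92–93% of the time at the default
noise profile (measured 92.4% over 300 seeded replicates). At the default
(study-like) noise profile — day/session SDs well below the scan/residual
SDs — the joint vertex-wise decision rule (main effect p < .05 **and**
Bonferroni-adjusted pairwise p) operates near nominal (~4–5%). Containment
is retained because it is the method's standard choice and is exactly
reproducible; Satterthwaite/Kenward-Roger approximations are a possible
future refinement and the main open design decision.

## 6. Vertex-wise cascade

Per vertex, models are attempted from richest to simplest and the first
that fits stably is kept, recorded as `model_code`: 2 = full nested random
structure, 1 = day-only random intercept, 0 = fixed-effects only (used for
degenerate, e.g. zero-variance, vertices). Outputs per vertex and timepoint
pair: percent change, main-effect p, pairwise p, and a joint significance
flag `p_main < .05 AND p_pair < .05/3`. The cascade is deterministic for a
given input and seed.

## 7. Precision bootstrap and plateau

Given per-scan ROI means at a reference and a follow-up timepoint, the
reference rate is the full-cluster mean difference. For each subsample size
k, B bootstrap draws of k scans from each timepoint yield a mean absolute
percent deviation of the subsampled rate from the reference rate; the
deviation curve is decreasing in expectation in k. The **plateau** is the
first k whose two successive reductions are each < 5% of the preceding
deviation (increases also qualify as "no meaningful reduction"); the curve
needs at least 3 points. For ≤3 scans the bootstrap mean is verified
against exhaustive enumeration.

## 8. Synthetic data generator

Defaults (all overridable through `SyntheticTruth`):

- Cell means (mm): core 1.810 / 1.781 / 1.769, control 2.350 / 2.350 /
  2.337 at BL/M3/M6 — a 0.029 mm (−1.6%) core decline by 3 months and
  0.041 mm (−2.3%) by 6 months against a near-stable control, magnitudes
  typical of progressive focal atrophy over these intervals.
- σ_day = σ_sess = 0.004 mm, σ_scan = 0.010 mm; residual SD 0.012 mm
  (core) / 0.020 mm (control). Scan-to-scan noise dominates day/session
  noise, as observed for fast structural acquisitions; the control ROI is
  noisier because it is anatomically broader.
- Motion: log-normal RMSpm (log-mean log 3, log-SD 0.5 mm/min) with a
  −0.001 mm per (mm/min) effect on measured thickness — motion thins
  apparent cortex slightly.
- Scan-level effects are shared between the core and control rows of the
  same scan, as in real data.
- Vertex maps add spatially smoothed (mesh-neighbour averaged) baseline and
  decline fields; the normative cohort generator produces age/sex
  structures with a known thickness plane so W-score recovery is exact in
  the noise-free limit.

Realism limitations: Gaussian effects throughout (no heavy-tailed motion
spikes or scanner drifts), no within-session autocorrelation beyond the
shared scan effect, linear motion-thickness confound, and a single
participant per dataset. These are deliberate: every generated quantity has
a closed-form expectation the test suite can check.

## 9. Reproducibility

Every stochastic routine takes an explicit seed; derived seeds (per stage,
per replicate) are computed deterministically and kept below 2³¹. Pipeline
runs write a manifest with the seed, config, and per-stage outputs, and are
byte-reproducible for a given seed. `scripts/acceptance.py` recomputes all
headline quantities from the package at run time.
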