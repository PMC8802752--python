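# Methods

This note documents the models, conventions and numerical choices behind
`restiba`, in the order data flows through the pipeline.

## Temporal preprocessing

The input is a spatially normalized, masked 4D BOLD series with repetition
time TR.  Stages apply in a fixed order enforced by provenance flags on the
series object (violations raise rather than silently reorder):

1. **Initial-volume discard** (default 10 volumes) — removes pre-equilibrium
   frames.
2. **Linear detrend** — per-voxel OLS line removal over time.  The per-voxel
   temporal mean removed here is stored on the series: it is the μ the PerAF
   formula needs, and is added back when PerAF is computed.
3. **Nuisance regression** — OLS residual on [intercept | Friston-24 | WM
   mean | CSF mean].  The Friston-24 expansion is, per rigid-body parameter
   p: `[p(t), p(t)², p(t−1), p(t−1)²]`, with the lagged row zero-padded at
   t = 0 (the alternative — duplicating the first row — changes nothing
   detectable downstream; zero-padding is covered by a unit test).
   Collinear columns (e.g. all-zero motion) are dropped greedily
   left-to-right with a logged warning.
4. **Ideal band-pass** 0.01–0.08 Hz — a DFT-domain boxcar retaining bins
   with `low ≤ f ≤ high` inclusive and always zeroing DC.  The boxcar (as
   opposed to a Butterworth filter) matches the volumetric-toolbox
   convention and makes the in-band pass-through, out-of-band rejection and
   fALFF = 1 identities bin-exact.  It is a projection: applying it twice
   equals applying it once, and output energy never exceeds input energy.

The preprocessed-but-unfiltered series is retained alongside the filtered
one: ALFF and fALFF need the full spectrum (their definitions include the
band selection), while PerAF, ReHo and DC consume the filtered series.

**Motion.** Framewise displacement is the Power formulation
`FD(t) = Σ|Δd| + r·Σ|Δθ|` with head radius r = 50 mm (configurable),
FD(0) = 0; its mean enters the group model.  The QC rule excludes a subject
when any volume exceeds 3 mm translation on any axis or 3° rotation about
any axis — strict inequalities, so exactly 3.0 mm is retained.  Rotations
are stored in radians on disk (SPM `rp_*.txt` dialect) and converted to
degrees only for the rule.

**Open point.** Whether WM/CSF signals should come from subject-specific or
template masks is left to the caller: any supplied mask is accepted.

## Metrics

Spectral conventions: the one-sided amplitude at bin k of an n-point series
is `2|X_k|/n` (half that for DC and the Nyquist bin), so a sinusoid of
amplitude A shows amplitude A at its bin.  ALFF is the mean amplitude over
in-band bins; fALFF divides the in-band amplitude sum by the amplitude sum
over all positive frequencies, with the 0 Hz bin excluded from the
denominator — mean intensity is not a fluctuation, and the exclusion makes
fALFF = 1 exact for purely in-band signals.  0/0 is defined as 0.

PerAF is evaluated on the mean-preserving signal: the filtered series plus
the stored pre-detrend voxel mean.  Band-passing removes the temporal mean,
so computing PerAF directly on filtered data would divide by ~0; restoring
the stored mean keeps the printed formula's μ meaningful.  Voxels whose
restored mean is not positive are set to 0 and counted in the log.  Both a
standardized and an unstandardized PerAF branch are carried through
smoothing, since group comparisons are run on both.

ReHo ranks each voxel's filtered series over time (average ranks on ties)
and computes Kendall's W over the K-voxel neighbourhood (K ∈ {7, 19, 27},
default 27).  At mask edges only in-mask neighbours enter and K is reduced
to the actual series count — a documented divergence from the fixed-K
formula that avoids deflating W at the brain edge; interior voxels use the
exact K. W is clipped to [0, 1] at 1e-12 tolerance.

DC thresholds pairwise Pearson correlations at r > 0.25 (strict, positive
side only; anticorrelations never contribute).  Correlations are computed
block-against-all so the full voxel-pair matrix is never materialized, and
results are independent of block size (tested).  Zero-variance voxels
correlate 0 with everything and are logged.  Only the self-correlation is
excluded, not within-neighbourhood pairs.

**Standardization** divides by the global in-mask mean (the "m-map"
convention; the standardized map has in-mask mean exactly 1 and the
operation is idempotent).  The alternative z-score mode (subtract in-mask
mean, divide by in-mask SD) is available as `standardization="zscore"`.
Division was chosen because it is the dominant convention for mALFF/mReHo
maps; both modes are tested.

**Smoothing** is a separable Gaussian with σ = FWHM/(voxel·2√(2 ln 2)) per
axis (4 mm FWHM at 3 mm voxels → σ ≈ 0.566 voxels), run on the full grid
and then re-masked, matching volumetric-toolbox behaviour.  Smoothing
happens strictly after metric computation — smoothing first would inflate
the local correlations ReHo and DC measure — and smoothing twice raises.

## Group inference

Per voxel, OLS on `[intercept, group, mean FD (centred), site dummies]`
with the group contrast; positive t means the reverter-like group exceeds
controls after adjustment.  Continuous covariates are mean-centred (the
group-difference test is invariant to this; it only aids interpretability
of the intercept).  A constant covariate is dropped with a warning.  Sites
must contain both groups — the site-coverage filter (`match_filter_cohort`)
removes subjects at single-group sites and motion-QC failures first, with a
per-subject exclusion log.

Residual smoothness is estimated from the per-voxel standardized GLM
residuals: for each axis, λ = mean squared spatial first difference, and
FWHM = √(4 ln 2 / λ) voxels (floored at half a voxel).  This simple
derivative-variance estimator is known to overestimate FWHM somewhat below
~2 voxels of true smoothness; it is the standard field estimator and the
bias is in the direction that keeps cluster inference usable at desk scale.

Cluster correction Gaussianizes the t map (t → z with matched tail
probability), thresholds each tail at voxel p/2 (two-tailed), clusters with
26-connectivity (configurable 6/18), and assigns each cluster of k voxels
the classical random-field corrected probability

    E[m] = S (2π)^(−2) W^(−3) u² e^(−u²/2),    W = FWHM_geo/√(4 ln 2)
    E[n] = S Φ̄(u) / E[m]
    P(n ≥ k) = exp(−β k^(2/3)),   β = (Γ(5/2)/E[n])^(2/3)
    p_cluster = 1 − exp(−E[m] · P(n ≥ k))

with S the mask size in voxels and u the Gaussian threshold.  Clusters with
p_cluster < 0.05 survive; positive and negative excursions are reported as
separate signed clusters, peaks in mm through the NIfTI affine.

**Calibration.** Over seeded null cohorts (16³ grid, 60 volumes, 10 per
group) the family-wise rate of ≥ 1 surviving cluster sits near the
conservative edge of nominal (the acceptance suite measures it over 200
cohorts).  This is the expected behaviour of Gaussian-random-field cluster
inference when map smoothness is only ~1.3–1.5 voxels FWHM: the
stretched-exponential cluster-size tail overpredicts large null clusters,
so the implied size threshold is somewhat high.  At realistic acquisition
sizes (longer series, larger grids, heavier smoothing) the approximation
improves.  Permutation inference would calibrate tighter and is an explicit
non-goal here.

## Behavioural statistics

Demographic rows use the pooled-variance two-sample t (df = n₁+n₂−2),
accepting raw values or printed (n, mean, SD) summaries — the two agree to
1e-12 on exact summaries.  The 2×2 sex table uses Pearson chi-square
*without* Yates continuity correction; with correction the published p
value is not reproduced.  Partial correlation is the residual method (OLS
of x and y on [1 | covariates], Pearson r of the residuals, p from the t
transform at df = n − 2 − #covariates); it reduces to plain Pearson with no
covariates and matches the closed-form recursion and an independent
library implementation to 1e-8 or better.  FDR is Benjamini–Hochberg
step-up.  Cluster-to-score pairing uses the mean of the (standardized,
smoothed) metric within the cluster mask per subject — the mean rather than
the peak, a deliberate choice for robustness; peak pairing is not
implemented.  Missing scores are dropped pairwise per (region, scale) pair
and logged.

The reverter rule: a subject whose first-visit logical-memory score is
below the education-adjusted normal cutoff, with some later visit at or
above the cutoff and MMSE strictly greater than 24 at that same visit, is a
reverter (earliest qualifying visit reported).  Cutoff values are required
configuration — they come from external education-stratified norms and are
never hard-coded.  Visits with missing scores are skipped and logged.

## Synthetic cohort generator

The generator emulates what the pipeline must be sensitive to, not raw
physiology.  Per subject, the BOLD signal at each in-brain voxel is

    baseline + site offset + Σₛ a·sin(2π fₛ t + φₛ) + ε,

with 3–8 sinusoids (count drawn once per cohort), frequencies uniform in
0.01–0.08 Hz and phases uniform — both drawn independently per voxel — and
per-sinusoid amplitude `a = signal_amp/√n_sin` so total signal power is
independent of the count.  ε is white Gaussian noise scaled by the site's
noise multiplier; sites also add an intensity offset, giving the GLM a real
batch covariate to absorb.  Specs whose band edge reaches the Nyquist
frequency of the requested TR are rejected.  Sinusoids are evaluated with
the second-order recurrence `s(t+1) = 2cos(ωΔt)s(t) − s(t−1)` (exact to
~1e-14, no (voxel × sinusoid × time) tensor).

Planted effects are spheres with a group ratio applied to the
reverter-like group only:

* **amplitude** — multiplies sinusoid amplitude (ALFF/fALFF/PerAF target);
* **synchrony** — region voxels share one latent frequency/phase draw, i.e.
  one latent time course (ReHo target);
* **hub** — an additive latent course shared between the region and a
  random set of distant "partner" voxels (default 15% of brain at weight
  0.7; DC target).  Partner voxels are part of the planted network: they
  acquire elevated DC by construction, so recovery checks compare the hub
  region against non-partner background.

Independent per-voxel frequencies keep background voxel pairs nearly
uncorrelated, which is what lets synchrony and hub effects stand out; the
one cohort-level draw (the sinusoid count) keeps between-subject amplitude
variance low so planted amplitude ratios are recovered accurately
(noiseless region-mean recovery is within a few percent at desk scale).

Motion traces are 6-parameter random walks; translation steps have SD
`severity` mm, rotation steps `severity/50` rad so both contribute
comparably to FD.  Severity 0 gives an identically zero trace.  Behavioural
scores are linear in a supplied per-subject magnitude (the planted
multiplier, or a measured cluster mean) plus optional Gaussian noise; with
zero noise the score/magnitude correlation is exactly 1, which pins down
the partial-correlation machinery.

All randomness flows from one root seed through named integer substreams
(cohort-level draws, per-subject BOLD, motion, scores), so identical
(spec, seed) pairs reproduce every emitted file bit for bit (gzip members
are written with mtime = 0).

**What the generator does not emulate** — hemodynamic response convolution,
cardiac/respiratory physiological noise, scanner drift beyond a linear
trend, spatial autocorrelation of the noise floor, and surface geometry.
Consequently, passing tests demonstrate the correctness and calibration of
the *pipeline machinery* under a known ground truth; they do not certify
performance on real scanner data, whose noise spectrum and spatial
correlation are richer.

## Defaults and problem sizes

| Parameter | Default | Note |
|---|---|---|
| grid | 24×24×24, 3 mm voxels | desk-scale default; acquisition presets 197 vol @ TR 3 s and 976 vol @ TR 0.607 s are accepted |
| volumes / TR | 120 @ 3 s | in-band DFT bins ≈ 23 after discard |
| discard | 10 volumes | |
| band | 0.01–0.08 Hz | |
| ReHo K | 27 | 7/19 available |
| DC threshold | r > 0.25 | binarized; weighted available |
| smoothing | 4 mm FWHM | after metrics |
| voxel/cluster p | 0.05 / 0.05 | two-tailed, GRF |
| noise_sd / signal_amp | 1.0 / 1.0 | "moderate noise" regime |
| sites | 2 (offset 0/+20, noise ×1.0/×1.2) | |

Validation experiments run at reduced sizes chosen for desk-scale
turnaround: null calibration on 16³/60-volume/10-per-group cohorts,
planted-effect power on the 24³ default with 15 per group, and unit oracles
on 6³×40 volumes.  The methods are size-agnostic; nothing in the code
depends on these choices.

## Known limitations

* GRF cluster p values are approximate at low map smoothness (see
  Calibration above); the permutation alternative is out of scope.
* The ReHo edge rule (reduced K) means edge voxels are not comparable
  across masks with different erosions.
* PerAF's mean restoration assumes the stored pre-detrend mean is the
  meaningful μ; if upstream processing already removed the mean, PerAF on
  that series is refused rather than silently computed.
* The generator's site effect is additive/multiplicative only; real
  multi-site data differ in smoothness and spectra as well.
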