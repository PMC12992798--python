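# Methods

This note documents the models behind `mertopo`, the synthetic cohort
generator, the numerical choices, and what passing tests do and do not
establish about real intraoperative data.

## Single-unit features

A segment is a pre-isolated single-unit spike train recorded at one depth
along a microelectrode trajectory; no spike detection or sorting is
performed. Depth-to-target is signed distance in mm along the trajectory
from the planned target (the ventral STN border), positive dorsal of it.

**Firing rate.** `FR = 1 / mean(ISI)` in Hz, computed from the interspike
intervals, not from spike count over duration; the two differ slightly on
finite windows.

**Burst index.** A two-component Gaussian mixture is fitted to the natural
log of the ISIs by expectation–maximization. Bursty trains separate into an
intra-burst (short-ISI) and an inter-burst (long-ISI) component;
`BI = exp(μ_long − μ_short)` is the ratio of the components' geometric-mean
ISIs. A linear-space reading (ratio of the lognormal component means,
including the σ²/2 terms) is available behind `ratio_space="linear"`; with
a common component σ the two agree, and the geometric reading is the
default because it is the natural scale of a mixture fitted in log space.
Numerical choices: 10 EM restarts with means initialised at the 25th/75th
log-ISI percentiles (the first restart) or seeded jitters of them;
variance floor 1e-4 log-units²; weight floor 0.05; fits whose component
means sit within 0.05 log-units, or whose smaller weight falls below the
floor, are flagged degenerate and report BI = 1 — a unimodal ISI
distribution has no burst structure to measure. At least 30 ISIs are
required; below that the mixture is unreliable and the unit's BI is
reported degenerate. The EM is hand-written (1-D, vectorised) and is
cross-checked against scikit-learn's `GaussianMixture` in the test suite.

**Robust CV.** `MAD(ISI) / median(ISI)` with the MAD unscaled (no 1.4826
normal-consistency constant). For exponential ISIs this converges to
`asinh(1/2) / ln 2 ≈ 0.6943`, a closed form used as a test oracle.

**Quality filters.** Segments are retained when duration ≥ 3 s, SNR ≥ 3
with unequivocal single-unit isolation, and the imaging-defined location is
inside STN or SNr. A failing segment is tallied once under the first
failing rule in that order.

## NRMS profiles

Background multi-unit activity is summarised per depth as RMS and
normalised per trajectory by the median of the first five recording sites,
taken dorsal-to-ventral, that last at least 10 s; shorter sites are skipped
and later sites take their place. When fewer than five sites qualify the
median of at least three is accepted; below three the trajectory is
excluded from NRMS analyses (a three-site median retains robustness; fewer
does not). Normalisation is idempotent and scale-invariant. For group
comparison, profiles are resampled onto a common 0.5-mm depth grid by
nearest-depth assignment within ±0.25 mm; empty cells are missing values,
never zeros.

## SEF95 sedation depth

Frontal EEG is cut into non-overlapping 2-s epochs (0.5 Hz resolution);
epochs with any sample beyond ±100 µV or a peak-to-peak excursion beyond
200 µV on any channel are rejected (thresholds configurable; the original
rejection criterion is not standardised). Hann-tapered periodograms are
averaged across epochs and channels, restricted to the 0.5–30 Hz
sedation-monitoring band, and normalised to unit band power — SEF95 is
invariant to the normalisation constant, which is fixed only to make
spectra comparable. SEF95 is the smallest frequency below which 95% of
band power lies, computed from the trapezoidal cumulative of the discrete
spectrum with linear interpolation; this density reading reproduces
analytic spectra exactly (flat on [0.5, 30] Hz → 28.525 Hz; 1/f² →
7.59 Hz) at the cost of smearing a single-bin point mass across its
adjacent half-bins. At least 15 clean epochs (≥ 30 s) are required. The MER
time window is an explicit field of the record; no stimulation-artifact
alignment is attempted.

## Spatial mapping

Coordinates live in a right-handed mm frame with z dorsal-positive.
Trajectories are straight lines `position(d) = target − d·direction`, with
`direction` the dorsal-to-ventral unit vector; an implantation offset
(negative = final electrode deeper than planned) is added to recorded
depths before projection onto the final-electrode line. The STN and SNr
are axis-aligned ellipsoids — a deliberately parametric stand-in for an
imaging-derived atlas; no image registration is performed and no
anatomical accuracy is claimed. STN spans are line–ellipsoid intersection
depths (entry dorsal of exit); tangent and zero-length intersections count
as misses. Trajectories with no STN intersection or an STN chord < 3 mm
are excluded (a chord of exactly 3 mm is kept). Depth alignment shifts
every trajectory so its STN midpoint coincides with the reference midpoint
— half the cohort-mean STN length, i.e. the midpoint of the mean-length
nucleus anchored at exit depth 0; shifting conserves each trajectory's STN
length exactly. Structure classification is the ellipsoid-membership test
with STN taking precedence in overlaps. The sweetspot is a configurable
point in the dorsolateral STN octant; distances are Euclidean. The first
single unit of a trajectory qualifies only if at least two other units lie
within ±2 mm along the track (stray zona-incerta-like isolated units are
skipped); its normalised distance from the dorsal border,
`(entry − depth) / (entry − exit)`, is returned unclipped and may fall
outside [0, 1].

## Group statistics

**Cluster-based permutation test.** At each grid depth a pooled-variance
two-sample t statistic compares the groups; depths with pointwise p < 0.05
form sign-consistent contiguous clusters whose mass is the summed t. The
null distribution of the maximum absolute cluster mass is built from
random relabellings of whole profiles (unpaired; a sign-flip paired mode
exists but group sizes differ in practice, so unpaired is the default),
and cluster p-values are Benjamini–Hochberg corrected across clusters.
Depths where either group has fewer than two finite values never join a
cluster. Default 10,000 permutations (1,000 in the simulation-heavy
tests); the implementation is vectorised across permutations, and 200-run
null simulations in the acceptance suite confirm family-wise error control
near the nominal 5%.

**ANOVA / MANOVA.** One-way ANOVA via sums of squares (scipy), two-way via
an OLS fit with Type-II sums of squares (statsmodels) for the unbalanced
design, MANOVA via Wilks' Λ = det(W)/det(W+B) with Rao's F approximation
(cross-checked against statsmodels and an eigenvalue oracle).

**Effect sizes and power.** For F tests the reported Cohen's d is the f→d
conversion `d = 2√(df₁·F/df₂)`; this single convention covers main
effects, interactions, one-way contrasts and the MANOVA approximation.
Post hoc power for F tests uses the noncentral-F distribution with
λ = f²·N. Correlations report `d = 2|r|/√(1−r²)` and Fisher-z power
`Φ(z√(n−3) − z_crit) + Φ(−z√(n−3) − z_crit)`; two-sample power uses the
normal approximation with `ncp = d√(n₁n₂/(n₁+n₂))` (an equal-allocation
mode, `ncp = d√(N/4)`, is available, since published power values are
sometimes computed under that assumption). Rounding happens only at
presentation: d to 2 dp, power to 2–4 dp, rho to 3 dp.

**Corrections.** Bonferroni `min(1, m·p)`; Benjamini–Hochberg step-up with
monotonicity enforcement (statsmodels).

## Synthetic cohort generator

The generator is the package's test bed: it emulates the statistical
structure of a mixed LA/GA STN-DBS cohort so that every downstream stage
is exercised end-to-end. Defaults (all configurable):

- 25 patients, 11 awake (LA) / 14 sedated (GA); GA propofol rates from a
  truncated normal, mean 3.9, SD 1.8, range 1.0–7.5 mg/kg/h; doses ≤ 4
  count as low-dose. LA patients carry no dose.
- 3 trajectories per hemisphere, vertical lines with 1.2-mm-SD lateral
  jitter through an STN ellipsoid whose central chord is ~5.6 mm, the SNr
  adjacent below. Units are placed on each trajectory's STN∪SNr depth
  support using truncated normals whose *truncated* mean is solved to hit
  the target (LA 2.32 ± 3.01 mm, low-dose GA 2.39 ± 2.94, high-dose GA
  −0.07 ± 2.38): the depth targets describe units retained by the anatomy
  filter, so drawing on an unbounded range and filtering afterwards would
  compress the group differences.
- Firing-rate targets: LA 28.47 ± 14.00 Hz; GA split 23.0 (low) / 18.0
  (high) ± 14.37 Hz so the pooled GA mean matches 21.07 Hz at the emulated
  unit proportions. Burst-index targets are shifted lognormals (support
  ≥ 1): LA 5.59 ± 4.58; GA 10.2/14.7 pooling to ≈ 11.98. Expected BI is
  non-decreasing and FR non-increasing in dose by construction.
- Spike trains are two-regime renewal processes: i.i.d. ISIs from a
  two-component lognormal mixture with common σ = 0.3 (log units), short
  -component weight 0.5, component geometric-mean ratio equal to the
  target BI and overall mean rate equal to the target FR. The common σ
  keeps the mixture identifiable and makes BI analytically targetable;
  extraction recovers condition means within a few percent.
- BI–sweetspot coupling: within each anesthesia condition, unit log-BI
  loads negatively (latent coupling 0.45) on the rank-gaussianised
  distance to the sweetspot, preserving the marginal BI distribution. The
  realised Spearman correlation is ≈ −0.40 (LA) and ≈ −0.30 (GA): the GA
  value is attenuated because high-dose units are both burstier and sit
  ventrally, farther from the dorsolateral sweetspot — an antagonistic
  pathway the real data plausibly share. The coupling is set so the
  correlation is reliably detectable at cohort scale.
- The robust CV is emergent, not a dial: once FR and BI fix the mixture
  shape, MAD/median is determined, so the generator does not take CV
  targets.
- RMS profiles: depths 10 to −5 mm in 0.5-mm steps, lognormal baseline
  around 20 µV, STN plateau ×2.0 and SNr plateau ×1.4, multiplicative
  lognormal noise (σ = 0.12). The STN/SNr elevation is scaled by a dose
  suppression factor: 1 at or below 4 mg/kg/h, decaying as
  `exp(−0.35·(dose − 4))` above — the threshold-like dose response the
  study design probes.
- EEG: 4 channels, 250 Hz, 60 s, ~25 µV RMS colored noise shaped by
  `S(f) = exp(−f/τ)` with τ solved numerically so the band SEF95 equals
  the target; targets follow 26 − 2.2·dose Hz (GA) or 23 ± 1.5 Hz (LA)
  with 1-Hz patient noise. Round-trip error is well under 1 Hz.
- Final electrodes: four contacts at 2-mm spacing on the central
  trajectory, center z placed at the sweetspot z plus a condition-specific
  deviation (LA −0.39 ± 0.91, low-dose −0.16 ± 1.22, high-dose
  −1.55 ± 0.93 mm).
- Low-quality segments (too short, low SNR/multi-unit, outside both
  nuclei) are injected at rates mirroring a realistic exclusion flowchart
  so the quality filters are exercised.

Everything is driven by one `numpy` generator seeded from the cohort seed;
identical (config, seed) gives byte-identical outputs.

**What the generator does not emulate.** No extracellular waveforms (spike
times only), no non-stationarity within segments, no brain shift or curved
trajectories, no hemispheric asymmetry (both hemispheres share one atlas
frame), no EEG artifacts beyond amplitude excursions, no correlation
between a patient's trajectories beyond shared dose, and no anatomically
accurate nuclei. Passing tests therefore demonstrate that the pipeline
recovers known structure of this class — dose-graded suppression,
condition-level feature shifts, spatial gradients — not that it would
reproduce any particular clinical dataset.

## Problem sizes

The simulation-based checks use 25-patient cohorts (~100–150 trajectories,
~900 segments), 1,000 permutations per cluster test, 200 null simulations
for error-rate calibration, and 20 seeds for the qualitative-recovery
suite; these sizes give stable pass/fail behaviour while keeping the full
suite in the minutes range.

## Known limitations

- The ellipsoid atlas and straight trajectories are stand-ins; spatial
  quantities are only as meaningful as the configured geometry.
- The burst index saturates at 1 for unimodal trains; comparisons that mix
  many degenerate units with bursty ones should treat BI = 1 as a floor,
  not a measurement.
- Post hoc power is an observed-effect quantity and inherits all caveats
  of retrospective power analyses; it is reported because the emulated
  study reports it.
- The cluster permutation test assumes exchangeable profiles under the
  null; patient-level clustering of trajectories is ignored (as it is in
  the emulated design).
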