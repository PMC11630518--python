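# Methods

This note records the models, conventions and numerical choices behind
`cofluct`, and what the synthetic-data experiments do and do not establish.

## Signal cleaning

The cleaning chain after parcellation is fixed and logged: per-parcel linear
detrend, zero-phase 4th-order Butterworth band-pass (0.01–0.1 Hz by
default, applied forward–backward so no phase — hence no artificial lag —
is introduced), optional nuisance regression (confound columns plus an
intercept; rank-deficient designs fall back to a pseudoinverse fit with a
warning), then z-scoring. Global-signal regression is never performed; it
would distort both the co-fluctuation amplitude and the lag structure that
the downstream estimators measure.

z-scoring uses the population convention (denominator T). This makes the
time-average of an edge product equal the Pearson correlation exactly,
which the test suite uses as a cross-module identity.

Motion QC uses Power-style frame-wise displacement: the sum of absolute
frame-to-frame differences of the six rigid-body parameters, rotations
converted to arc length on a 50 mm sphere, first frame defined as 0.
Subjects are excluded when mean FD exceeds 0.25 mm or when more than 25% of
frames are spike volumes; both inequalities are strict, and the per-frame
spike cut (default 0.25 mm) is exposed in the configuration because the
literature convention varies. Subjects, not frames, are excluded — there is
no scrubbing or interpolation.

## Edge dynamics

The edge time series of a parcel pair is the frame-wise product of the two
z-scored signals; the RSS over all N(N−1)/2 edges per frame indexes
whole-brain co-fluctuation. For large parcellations the RSS is computed via
the identity `RSS(t)² = ((Σ_i z_i²)² − Σ_i z_i⁴)/2` instead of
materializing the E × T edge matrix; both paths agree to machine precision
and are tested against each other.

Extremum rule: a frame is a trough iff its value is strictly below both
distinct neighbours; runs of equal values collapse to their first frame;
series endpoints are never extrema. Trough-to-trough durations are reported
in TR units (a configuration switch converts to seconds). Subjects with
fewer than two troughs raise a flagged, catchable error rather than being
silently dropped.

"Top and bottom 10%" amplitude conditioning ranks all frames by RSS value
and takes the ceil(0.10·T) largest / smallest (ties broken toward the
earlier frame, selection returned sorted). The alternative reading —
restricting to detected peak/trough frames only — is available behind
`on_extrema=True`.

## Time-delay estimation

The lagged cross-covariance is normalized per lag by the overlap count
(T − |Δ|); an unnormalized sum would bias the extremum toward lag 0. The
lag grid spans ±3 TR by default: hemodynamic lags in this literature span a
few seconds, and the window is configurable because it materially affects
how many pairs are flagged.

Sign conventions, fixed once and used everywhere: `c_ij(Δ)` correlates
parcel i at time t with parcel j at time t+Δ, so a positive peak lag means
i leads j. The TD matrix entry [i, j] stores the lead of parcel j over
parcel i (antisymmetric by construction — each unordered pair is estimated
once and negated), so that column-averaging produces a projection map in
which a parcel that leads the rest of the brain gets a positive value
(positive = early propagation). The per-subject SMN delay is the unweighted
mean of the projection map over SMN parcels.

The sub-TR refinement fits a parabola through the CCF extremum of |c| and
its two neighbours and adds the fractional vertex offset to the integer
peak lag. Anticorrelated pairs contribute through their negative extremum
with the same formula. Degenerate cases are flagged, never dropped: a peak
at the grid boundary or a flat (|curvature| < 1e-12) extremum keeps the
integer-lag estimate, and fractional offsets beyond ±TR/2 are clamped with
a warning. The per-subject boundary fraction is reported so users can see
when the lag window is too narrow.

Known estimator behaviour, measured here and reflected in the tests: on a
single pair with correlation ≳ 0.5 the estimator recovers fractional lags
with median error well below 0.15 TR; at weak pair correlation (r ≲ 0.2,
T = 240) the extremum location is noise-driven and per-pair estimates
scatter by whole lags. Because every pair within a subject shares the same
source realizations, this scatter is correlated across pairs and does not
average out over parcels — per-subject network TD carries an irreducible
SD of roughly 0.3–0.5 s at study conditions. This is why the group analyses
need cohort-scale samples, and why the generator-recovery tests assert
sign and magnitude bands measured from the actual sampling distribution
rather than idealized tolerances.

## Inter-network connectivity

Static FC is the Pearson correlation over the selected frames, with means
and SDs recomputed inside any frame subset (conditional FC is a fresh
correlation, not a reweighting of full-series moments). The SMN–DMN
connection is the unweighted mean of raw r over all 34×23 = 782 cross
pairs; Fisher-z averaging is available as a sensitivity switch but is off
by default. A parcel with zero variance inside a frame subset gets
correlation 0 (flagged) instead of being dropped, keeping the pair count
constant across subjects.

Low-amplitude FC is strongly range-restricted: frames selected for minimal
global co-fluctuation are frames where the shared sources are near zero, so
conditional correlations sit far below the static value for every subject.
Group differences survive this restriction but attenuated — visible in the
worked example and in the generator's group separations.

## Cohort statistics

Classification: patients with HAMD-17 total below 17 are excluded (reason
recorded); remaining patients with item 9 (psychomotor agitation) ≥ 2 are
labelled A-MDD, the rest NA-MDD; controls pass through. Contrasts are OLS
models of the metric on a group indicator plus covariates; the first-named
group is coded 1, so t > 0 means that group is higher. HC contrasts adjust
for age, gender and education; the A-MDD vs NA-MDD contrast additionally
adjusts for the HAMA total and a HAMD "depression sub-dimension" — a
configurable item subset defaulting to items {1, 2, 3, 7} (depressed mood,
guilt, suicidality, work/interests) that by construction never includes
item 9, so the agitation contrast is not self-adjusted. Each metric's three
contrasts form one Benjamini–Hochberg family; families are never pooled
across metrics. Missing phenotype values propagate and are deleted listwise
inside each model, with the per-model n reported.

Agitation regressions take the brain metric as predictor and the item-9
score as outcome on patients only, with gender, age, education and HAMA as
covariates; all continuous variables are mean-centered (which leaves slope,
t and p unchanged) and both the raw and standardized slope are reported.
Severity regroupings use ≥ 24 as "severe" for both HAMA and HAMD-17
(strictness is a documented convention; the cutoffs are configurable).
Education enters as a numeric ordinal over the six levels (0–5).

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes, with
ground truth (true lags, event times, coupling, mixing weights, seeds)
recorded losslessly:

* **Background**: band-limited Gaussian sources — one brain-wide, one per
  network (variance 0.08), one per parcel — occupying 0.01–0.04 Hz, the
  slow portion of the analysis band where resting BOLD carries most of its
  power. Keeping the background slow is what lets the event train govern
  the RSS trough spacing; with broadband background, envelope wiggles set a
  trough-rate floor that no event structure can move.
* **Events**: a Gamma renewal train (shape 3, mean interval per group) of
  random-sign Gaussian bumps (SD 1.2 TR) contributing variance 0.5 per
  parcel, split into a brain-wide common response and network-private
  responses. Intervals are drawn by inverse CDF (one uniform each), and
  event, background and noise draws come from separate RNG substreams, so
  paired cohorts that differ in one generative aspect share all other
  randomness (common random numbers).
* **Coupling**: the stationary-source loading and the DMN's share of the
  common event response are solved in closed form so that the SMN–DMN
  correlation of the raw signals matches the group target while every other
  network pair sits at a common global level (0.40). Infeasible requests
  (coupling too high for the variance budget) raise errors that state the
  feasible bound. Note that band-pass cleaning removes most of the white
  measurement noise (SD 0.15), so correlations measured after cleaning run
  somewhat above the raw-signal targets — uniformly across groups.
* **Lags**: the SMN's composite signal is advanced by an exact spectral
  (FFT phase) shift, so fractional ground-truth lags are exact. The
  measured network TD is the true lead diluted by the zero-lag SMN–SMN
  pairs (×0.85 at the 34-of-214 proportion).
* **Phenotypes**: HAMD item 9 is drawn per group (agitated mass on 2–4,
  non-agitated on 0–1, so classification reproduces the generative labels
  exactly); the remaining 16 items are drawn binomially to hit the group's
  total in expectation, with patient totals raised to the inclusion floor
  of 17 — the generator emulates the post-inclusion analyzed sample, whose
  reported minima are 17. HAMA correlates with HAMD at ≈ 0.5. The default
  cohort is 44 agitated / 75 non-agitated / 94 controls, making the
  agitated share 44/119 = 37.0%.

Group effect magnitudes (SMN leads 1.4 / 0.0 / 0.5 s for A-MDD / NA-MDD /
HC, inter-event intervals 7 / 13 / 13 TR, couplings 0.06 / 0.25 / 0.38)
were fixed once, by calibrating at build time for reliable direction
recovery at 20 subjects per group, and match the reported directions —
agitated patients switch states faster, their SMN leads earlier than the
non-agitated group's, and their SMN–DMN coupling is reduced, most visibly
at low amplitude. The magnitudes are deliberately larger than clinical
effects: the real study needed ~100 subjects per contrast, while the
recovery experiments run at 20/group. Passing these experiments shows the
pipeline recovers known structure of the assumed kind; it does not show
that real BOLD satisfies those assumptions (no hemodynamic response
convolution, no 1/f measurement noise, no spatial autocorrelation within
networks beyond the shared sources, motion summaries drawn independent of
signals).

## Problem sizes used in the checks

The shipped experiments run at: 200 replicates for fractional-lag recovery
(T = 240, SNR 2), 1000 replicates for type-I calibration (n = 30+30 with
two covariates), 50 paired cohorts of 16 subjects for the event-interval
ordering, and 100 cohorts of 20 subjects per group (40 parcels, 240
frames) for end-to-end direction recovery; the full-scale demonstration
cohort uses the default 213 subjects at 214 parcels. These sizes were
chosen as the smallest at which the respective sampling distributions are
tight enough for the assertions to be meaningful.

## Known limitations

* Per-pair TD estimates at weak correlation are noisy by whole lags; only
  network- and cohort-level aggregates are interpretable.
* The projection-map sign convention (positive = early) is fixed here;
  published reports differ in sign conventions, so compare directions, not
  signed values.
* The trough-duration metric counts strict local minima of any depth and is
  therefore sensitive to the fastest spectral component present; its
  between-group differences should be interpreted as rate differences of
  the dominant co-fluctuation process, not literal state lengths.
* The generator's phenotypes are marginally calibrated (totals, item 9,
  HAMA correlation) but items are conditionally independent given severity,
  unlike real rating-scale data.
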