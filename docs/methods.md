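# Methods

`mobispect` implements a frequency-domain digital-phenotyping analysis of
smartphone GPS mobility in mood disorders, together with a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes. This note documents the models, the parameters that matter,
the numerical choices, and the limits of what the synthetic experiments
demonstrate.

## The analysis chain

**Acquisition model.** GPS is duty-cycled: 60 s of 1 Hz sampling
followed by 600 s of silence, i.e. at most
`round(3600/660 × 60) = 327` fixes per hour. Mood is self-reported
daily on four items (depression, mania, fatigue, irritability), each
scored 1 ("not at all") to 5 ("seriously"); the 12:45 prompt is used,
with the 17:00 prompt as fallback. A score above 1 marks a
mood-fluctuation day.

**Preprocessing.** Fixes with reported accuracy above 50 m are
discarded. Positions are projected to meters (equirectangular around a
per-participant reference) and averaged on a 10-s grid anchored at local
midnight; an empty grid bin is missing. A 10-s step between valid bins
is *moving* when the displacement exceeds √10 m, else *stationary*. A
run of missing bins is resolved by the displacement between its flanking
bins: ≥75 m within any 6-minute span (for runs longer than 6 minutes the
linear-motion prorated displacement `d·360/gap` is used) means moving.
Interior gaps up to 60 min are linearly interpolated; each of the 10
stochastic completions adds one zero-mean Gaussian offset per gap run
(sd = the GPS noise scale). A *shared* offset per run, rather than iid
per-bin jitter, was a deliberate choice: iid jitter at realistic GPS
noise exceeds the √10 m/10 s movement threshold bin-to-bin and would
reclassify every imputed stretch as travel and inflate distance sums by
tens of kilometers per day. Longer gaps are copied from the nearest
donor day's same clock bins when one is valid there. A day is analyzed
when at least 6 of its 24 clock hours contain data (one quarter).

**Features.** Eight per participant-day, averaged over the 10
completions: LV = ln(var x + var y + 10⁻⁶ m²) over stationary bins
(population variances; natural log; the 10⁻⁶ m² floor keeps the
degenerate single-point day finite at ln 10⁻⁶ ≈ −13.8); SM/SV = mean and
population variance of per-step speed, using only steps between two
*observed* bins (steps into an imputed stretch measure interpolation,
not motion); NC = number of clusters from greedy sequential clustering
(assign to the nearest running dwell-weighted centroid within 500 m,
else open a new cluster — deterministic and order-stable, unlike
restarted k-means); entropy = Shannon entropy (nats) of cluster dwell,
bounded by ln NC; homestay = stationary dwell fraction at the home
cluster (maximum dwell between 00:00 and 06:00 local — the field's
convention, since "home" is never labeled); TT = moving / (moving +
stationary) time, robust to missingness because the denominator is
classified time rather than 24 h; TD = summed distances between
consecutive valid bins.

**Spectra.** Feature series enter the Fourier transform at hourly
resolution — daily sampling cannot represent the 1-day cycle (Nyquist) —
over 28-day windows by default (56- and 84-day windows are available).
Interior missing hours are linearly interpolated; windows with more than
25% missing are rejected; the mean is removed. Power is the squared DFT
magnitude normalized by series length, one-sided, DC excluded, so the
non-DC power sums to N×variance (Parseval; a rectangular window is the
default, Hann optional). The top five peaks are the highest-power bins
with periods in [2·step, window/2], ties broken toward the longer
period, and a ±2-bin exclusion zone around each accepted peak: an
off-grid tone (e.g. a 9-day cycle in a 28-day window, bin 3.11) spreads
over the rectangular window's main lobe and first sidelobes, and its
shoulder bins must not be double-counted as separate rhythms.

**Consensus.** A peak counts as a whole-day cycle *d* when 1/*d* is the
nearest integer-day frequency and lies within half a frequency bin of
the peak. Plain rounding of periods would map the ~40 sub-2-day noise
bins of an hourly 28-day spectrum onto 1–2-day labels and manufacture
consensus out of noise; the half-bin rule keeps each integer day
attached to the one bin a genuine tone of that period would dominate.
A group carries a consensus period when strictly more than half its
members have it in their top five; summed ranks (lower = stronger)
grade intensity.

**Inference.** Group comparisons use Kruskal-Wallis (3 groups) and
Mann-Whitney U with pooled mid-ranks, two-sided asymptotic p with tie
correction and no continuity correction. Mobility-mood correlations are
Pearson r on window means (daily/weekly/28-day/semiannual windows
anchored at each participant's first day). Before the person-day
logistic models, features are pruned iteratively at VIF > 3 (the column
with the largest VIF is dropped until all pass; infinite VIFs go first).
Day-level models regress the depressed flag (EMA > 1) on female sex,
age, an employee-or-student indicator and the retained features, for
all days / weekdays (Mon–Fri local) / weekends; TT and homestay enter
as fractions. Spectrum models regress a participant-window affective
status on the window's maximum power under four covariate sets (none;
age+sex; +employment; +antidepressants). The window-level status is
"affected on more than half of the window's scored days"; reporting is
per raw power unit, with a per-SD option, since spectral power units
depend on the feature's scale. Wald 95% CIs; α = .05 two-sided; no
multiplicity correction. Person-days are treated as independent —
repeated days within a participant violate this, and a cluster-robust
option exists but is off by default so the headline model matches the
design it reproduces. The Fisher-z sample-size rule is
n = ⌈((z₁₋α/₂ + z_power)/C)²⌉ + 3 with C = ½ln((1+r)/(1−r)); r = 0.5,
α = .05, power = .90 gives n = 38.

## The synthetic cohort

Three groups (defaults 15 controls, 20 bipolar, 27 unipolar) over 28
days, each participant with home/work/other clusters ≥200 m apart, a
lognormal baseline mobility scale, and one fixed timezone (UTC+8, no
daylight saving).

**Latent mood** (daily): controls are baseline + N(0,1) noise; bipolar
adds sinusoids at the configured cycle lengths (default 1, 4 and 9
days, amplitude `bp_amplitude/len(periods)` each, random phases per
participant); unipolar adds a stationary AR(1) drift (φ = 0.75, i.e.
roughly week-long episodes — mean reversion keeps the drift bounded and
lets monthly averages wash out, which a pure random walk would not).
EMA items are fixed-threshold discretizations of latent mood into 1–5;
the lowest cut sits at the normal quantile that makes controls exceed
score 1 on 9% (depression) / 8% (mania) of days, and the patient
baselines (1.2 latent units for depression, 1.4 for bipolar mania) were
chosen so patients fluctuate on roughly 44% / 48% of days — the regime
the analysis operates in.

**Mood→mobility coupling** is multiplicative: one unit of mood elevation
above the person's typical level multiplies excursion rate, away-time
fraction and location diversity by (1−e) with e = (0.30, 0.25, 0.25).
Two deliberate structural choices:

* *Habituation*: coupling acts on the deviation from the person's
  baseline severity, not on absolute severity. Chronic severity is
  absorbed into the person's routine (and into the heterogeneous
  baselines); transient worsening suppresses that day's mobility. This
  is what day-level monitoring measures, and it is why pooled daily
  correlations dominate monthly ones in the generator.
* *Context- and family-specific expression*: spatial range (LV) and
  travel time (TT) respond on weekdays, location diversity (entropy,
  NC) on weekends, and each family sees the day's elevation through its
  own noisy channel (sd 0.4). The remaining features (SM, SV, TD,
  homestay) vary with the person and day only. Independent channels
  make the coupled features correlated mood proxies rather than
  transforms of one scalar — without this, whichever feature is the
  cleanest proxy absorbs the whole multivariable effect and the others'
  partial odds ratios collapse to 1.

Person-level LV baselines spread with sd 2 log-units (activity-space
variances genuinely span orders of magnitude); this heterogeneity is
uncorrelated with mood and is what attenuates between-person (monthly)
correlations relative to pooled daily ones.

**Emission tiers.** The full tier emits raw fixes: a piecewise-linear
path over a stay/excursion schedule (Poisson excursion counts thinned
by mood, guaranteed weekday commutes for workers/students), sampled at
1 Hz during on-cycles, plus isotropic Gaussian noise (sd 5 m) and a
lognormal accuracy field with P(accuracy > 50 m) = 0.05 so the accuracy
gate is exercised. Whole days (5%) and clock hours (2%) drop out.
Because Monte-Carlo experiments at study scale through 1 Hz emission
would be pointlessly expensive, two direct tiers emit day-level
features and hourly LV/entropy series from the same latent process; the
hourly tier carries the group rhythm signal (bipolar: tones of
amplitude 2.0 per cycle over white noise sd 1.0, entropy scaled by
0.15; unipolar: hourly AR(1) drift with ~6 h memory whose flat
low-frequency spectrum stays below the white-noise peaks — a day-level
random walk would pile its power into the lowest one or two bins and
register as a spurious long-period rhythm in a group meant to be
aperiodic).

**Seeding** is hierarchical: one global seed, spawned per participant ×
stream × day, so cohorts of different sizes agree on their shared
prefix and adding a day never reshuffles another day's draws.

## What the synthetic experiments do and do not show

The Monte-Carlo suites (spectral consensus recovery at n = 12 vs 19;
Mann-Whitney power/size on maximum LV power; weekday/weekend logistic
recovery on ~6,600 person-days; daily-versus-monthly correlation
ordering over 50 cohorts of 62 participants) demonstrate that the
pipeline *recovers what the generator injects* at study-scale sample
sizes, and that its tests hold their nominal size when nothing is
injected (the null calibration uses a single-group, uncoupled cohort so
person-day outcomes are exchangeable — with group-level outcome rates
and person-level features both present, the independence-assuming model
is anti-conservative by construction, which is precisely the repeated-
measures caveat above). They do not validate the generator against real
phone data: real cohorts have diurnal rhythms in *every* group (the
aperiodic arm here suppresses them by design so consensus specificity
can be measured), device-dependent noise, and missingness correlated
with state. Effect sizes in the generator are set for clear parameter
recovery, not to reproduce any particular cohort's coefficients.

## Problem sizes and defaults

| Parameter | Default | Why |
|---|---|---|
| duty cycle | 60 s on / 600 s off at 1 Hz | acquisition protocol (≈327 fixes/h) |
| accuracy gate | 50 m | protocol |
| bin width | 10 s | protocol; movement threshold √10 m per bin |
| gap rule | 75 m / 6 min | protocol |
| day validity | ≥6 of 24 h | one-quarter rule |
| imputations | 10, mean-combined | protocol count; combiner unstated, mean chosen |
| cluster radius | 500 m | separates home/work/other at urban scale |
| spectral window | 28 d hourly, rectangular | 1-day cycles need sub-daily sampling; month is the study's strongest span |
| peak rule | top-5 bins, ±2-bin exclusion | leakage control (see above) |
| VIF threshold | 3 | protocol |
| α, CI | .05, Wald 95% | protocol |

Monte-Carlo sizes (20 cohorts for consensus recovery, 200 + 1000
replicates for the rank test, 200 for coverage, 50 cohorts for the
timescale ordering) keep each suite in the tens of seconds while the
binomial error on every reported rate stays below ~2 percentage points.

## Known limitations

* Day-level logistic models ignore within-person correlation (kept to
  match the design being reproduced; `cluster_robust=True` is available).
* The equirectangular projection is a few-kilometer approximation;
  trans-meridian or high-latitude cohorts would need a proper CRS.
* Greedy sequential clustering is order-dependent by construction;
  centroids can drift up to ~one radius from early members.
* The 10-s bin grid anchor (local midnight) and the spectral sampling
  granularity are conventions, not protocol facts.
* Polyserial correlations are not implemented (Pearson is used);
  wavelet/short-time variants and irregular-sampling spectra
  (Lomb-Scargle) are out of scope because interpolation precedes the
  transform.
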