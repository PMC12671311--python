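# Methods

This note documents the models, algorithms and numerical choices behind
`sleepbeat`, and what the synthetic-data experiments do and do not
demonstrate about real recordings.

## Interbeat-interval cleaning

Wearable photoplethysmography produces two characteristic beat errors:
missed beats (two true intervals fused into one long interval) and ectopic
or spuriously split beats (one interval cut into two short ones). The
detector flags beat *i* when its interval deviates from a robust local
expectation — a centered rolling median over 11 beats — by more than a
criterion scaled from the quartile deviation (QD, half the interquartile
range) of successive beat-to-beat differences:

    |x_i − median_local(x)| > max(3.32 · QD_local(Δx), 5 ms)

The 3.32 multiplier converts a QD into an estimate of the maximum expected
beat difference for Gaussian variability. The QD is computed in a rolling
501-beat window rather than globally: nocturnal short-term variability is
deliberately higher than diurnal, and a global scale would reject healthy
night beats. Quartiles are insensitive to the sparse artifacts themselves,
so the criterion is estimated on the corrupted series without masking. The
5 ms floor absorbs sensor quantization on near-regular stretches.
Flagged beats are replaced by linear interpolation (in beat index) between
the nearest unflagged neighbours and marked `interpolated`; timestamps are
untouched, so covered time changes by at most one beat per artifact run.
On the default synthetic streams the detector reaches ≈100% sensitivity at
≈0.2–1% false positives (tested at a 2% injected artifact rate).

## Windowed Poincaré metrics

The cleaned stream is tiled into nonoverlapping 300 s windows anchored at
the recording's first beat time (clock alignment is an arbitrary choice the
data do not pin down; recording alignment is used and stated). A beat
belongs to the window containing the time its interval *ends* (half-open
`[start, end)`); the trailing partial window is discarded. Windows with
five or more interpolated beats are excluded. Per window, with consecutive
interval pairs (x_i, x_{i+1}):

* SD1 = population SD of (x_{i+1} − x_i)/√2 — dispersion perpendicular to
  the identity line of the Poincaré plot (short-term, parasympathetically
  dominated variability);
* SD2 = population SD of (x_{i+1} + x_i)/√2 — dispersion along it
  (long-term variability);
* SDNN = population SD of the intervals.

Population (divide-by-n) SDs keep the successive-difference formulation
exactly equal to the geometric point-to-line-distance definition, which the
test suite verifies to 1e−9 ms against an explicit rotation oracle. The
identity sd1² + sd2² = Var(x_{1..n−1}) + Var(x_{2..n}) (≈ 2·sdnn²) holds by
construction and is asserted as a property.

## Resting filter and normative transform

HR and HRV aggregates use only windows whose mean HR (60000 / mean IBI) is
strictly below 0.55 × (220 − age) bpm — the standard eligibility rule for
photoplethysmography-based HRV. The threshold is computed as
11·(220 − age)/20 so clinically round boundaries (110.0 bpm at age 20) are
represented exactly; applying the rule to night windows as well is the
default and switchable. Published normative HRV tables are not
redistributable, so the normative transform ((value − reference mean) /
reference SD by sex, age band and hour band) takes the table as input; the
package ships an identity table (transform = no-op) and a builder that
derives a table from its own synthetic population.

## Sleep segmentation

Real deployments estimated bed and wake times by eye; the package automates
the same cues. Streams are reduced to 1-minute means and smoothed by a
10-minute rolling median. A minute is a sleep candidate when smoothed
activity falls below the midpoint of the 10th and 90th percentiles of the
day's smoothed activity (a valley cut between the resting and active
clusters — a fixed quantile would sit inside the night cluster whenever the
night is about a third of the record), the smoothed step rate is zero, and
smoothed HR is below the participant-day median. Candidate runs separated
by gaps of ≤20 minutes are bridged (brief arousals, bathroom visits) as
long as candidate minutes keep ≥80% density; the longest surviving block is
the sleep period, and it must last ≥3 h. One hour before and after each
estimated bed/wake time is excluded from all aggregation (2 h removed per
night, exactly); nights shorter than 2 h after trimming are dropped with a
warning. On the default generator the median absolute bed/wake error is
under 3 minutes — real transitions are messier, so this number bounds the
method's noise floor, not its field accuracy.

## Daily features

A participant-day runs from one wake time to the next. Awake aggregates
come from windows fully inside [previous wake + 1 h, bed − 1 h); asleep
aggregates from the night's trimmed bounds; windows straddling a trim zone
count for neither state. Each variable (HR, SD1, SD2, SDNN from resting
kept windows; motion and steps from 1-minute stream means) is reduced to
minimum, mean, maximum, min/mean and max/mean per state — feature names
follow `minimum_sd1_awake` / `sdnn_maximum_ratio_asleep` conventions, with
the mean of motion named `motion_asleep`/`motion_awake`. Sleep duration is
untrimmed wake − bed; awake duration is the time from the previous wake to
bed. Diary stress logs are averaged over the waking span. Missing states
yield NaN, never silent zeros; days with under 4 h of kept windows in a
state are flagged `low_coverage` and excluded from modeling by default.
Static severity scores are binarized strictly (> 3, 3, 4, 17 for
EDSS/MSSS/ARMSS/autonomic questionnaire), with control participants' scores
zeroed first so every control flag is False.

## Within-person normalization and the binary outcome

Each feature and the 1–5 rating are z-scored per participant with the n−1
SD. Columns constant within a participant are recorded as dropped for that
participant and their normalized cells set to 0: a value that never
deviates from the person's own mean has exactly zero within-person
deviation, and poisoning those rows with NaN would silently delete the
participant from every model containing the column. Cells missing in the
input stay NaN. A night is "high quality" when its normalized rating is
strictly positive (ties go to low: "better than the personal average" is
strict). The Shapiro–Wilk check documents why a linear model is not used —
a five-level discrete response fails it at any realistic n.

## Penalized models and the M1/M2/M3 family

The L1 logistic fit minimizes per-observation loss + α·‖β‖₁/n-equivalent
(sklearn C = 1/(α·n), liblinear), making fits invariant to duplicating the
data. The default α = 0.05 was fixed by a null-gradient argument: with
~840 rows the null score of a feature has SD ≈ 0.5/√840 ≈ 0.017, so a
threshold near 3 SDs keeps the expected number of false survivors among ~20
candidates below one. Features with exactly zero L1 coefficient are
dropped; survivors are refit unpenalized for coefficients and Wald p-values
with participant-clustered robust covariance. No post-selection correction
is applied (the refit p-values are anti-conservative under selection; this
caveat is recorded in each fit's metadata). Perfect separation in a refit
is flagged, never silenced.

Family members share this machinery: M1 selects and fits on everyone
jointly; M2 refits M1's selected features per group (patients / controls);
M3 selects and fits per group. Scopes: `.1` night + day, `.2` night only
(asleep-measured features plus sleep duration and the night diary flags),
`.3` day only. Table output reports effects at the P < .10 convention.
Greedy forward selection by participant-grouped cross-validated AUC
(stop when the best addition improves CV AUC by ≤0.01, ties broken
lexicographically) is available both as a standalone operation and as an
alternative family selection mode; it is not the default because forward
selection saturates once several strong features are in the model and then
misses real effects that the penalty retains. For prediction-oriented fits
(model comparison on held-out participants) `choose_penalty_cv` picks α by
participant-grouped CV deviance; the prediction optimum is typically
~5–10× weaker than the selection default.

## Balanced subject-held-out evaluation

Each of 50 splits samples ⌈0.2 · n_participants⌉ participants without
replacement; among their nights the majority class is downsampled (seeded,
without replacement) to exact balance — balancing by row removal rather
than by participant choice preserves subject-wise independence while
guaranteeing equal class counts. Training uses all rows of the remaining
participants. Accuracy, precision and recall are percentages at the 0.5
probability cutoff with high-quality sleep as the positive class; AUC is
pairwise concordance with ties counted ½ (computed by the rank identity,
verified against the O(n²) count). Aggregates are plain means over splits.
Single-class held-out draws are redrawn up to 100 times, then raise.

## Subgroup statistics and sample size

Sleep-quality contrasts average nights within participant first (repeated
nights are not independent), then compare the two groups with the
independent-samples Mann–Whitney U. For combined n ≤ 20 the two-sided p is
exact: all C(n, n₁) reassignments of the pooled values are enumerated and
those with |U − n₁n₂/2| at least the observed deviation counted — midranks
make this tie-safe. Larger samples use the tie-corrected normal
approximation with continuity correction. Pearson correlation matrices are
computed per group on pairwise-complete observations with t-transform
p-values. The sample-size routine returns the smallest n with
z_{(1+c)/2}·√(p(1−p)/n) ≤ h; (0.85, 0.10, 0.95) → 49.

## The synthetic cohort generator

Defaults describe a two-week cohort of 60 participants, about two thirds
patients, bed ≈ 23:00 and wake ≈ 07:00 (SD 45 min), daytime HR 75 bpm with
a 15 bpm nocturnal dip, 1.5× nocturnal HRV gain, a 0.5% per-beat artifact
rate, stress averaging 4/10, and a mean rating of 3.72 with a −0.4-point
deficit for participants with autonomic dysfunction (≈45% of patients, the
questionnaire score being calibrated so that share exceeds the cutoff 17).
The default effect vector on the normalized log-odds scale is the set of
night-and-day model effects the package's model family is designed to
estimate (sleep duration +0.47, waking at night −0.58, nocturnal motion
−0.29, mean SD1 asleep +0.30, mean SD2 asleep −0.47, max SDNN asleep +0.51,
SDNN max-ratio asleep −0.54, …), plus a patient-only nocturnal minimum-HR
effect of +0.45 — a magnitude chosen at the detectability scale of the
recovery experiments and consistent with the between-group swings such
models display.

Two sampling levels share one response model. The stream level integrates
a smooth circadian HR curve (logistic ramps of ~20 min at transitions, slow
AR(1) drift) to beat times, then adds AR(1) (φ = 0.8, 15 ms) plus white
(25 ms) interval noise, both scaled by the nocturnal gain; artifacts are
injected as merges and splits with truth positions recorded; activity is
gamma-distributed around a wake/sleep contrast with optional brief
"bathroom" bouts, and steps are zero during sleep outside those bouts. The
substantial white component is the respiratory-like beat-to-beat
variability real IBI series show; it also sets the detector's
successive-difference scale. At ~100k beats per participant-day the stream
level is meant for small cohorts; the feature level draws the per-day
aggregate table directly from participant-level normal distributions with
the same response model, which is what cohort-scale (60 × 14) modeling
experiments use — beat-level detail is irrelevant to the modeling stage.

Responses: the latent score is the effect vector applied to within-person
z-scored features plus standard logistic noise (noise scale 1.0, so the
configured coefficients *are* the log-odds truth); the label is the
latent's sign; the 1–5 rating is `clip(round(anchor_i + 0.5 · latent))`.
The 0.5 rating scale makes the night-to-night rating SD ≈ 1.0 point — a
realistic diary dispersion. Because clip/round is not mean-preserving, the
generator solves numerically (deterministic quadrature) for the anchor
whose observed mean matches the configured 3.72 and divides configured
rating contrasts (the severity deficit) by the map's local slope so they
appear at full size in the observed ratings; binarizing ratings at the
personal mean then recovers the latent labels for ≈88% of nights.

What the generator does **not** emulate: within-night sleep-stage dynamics
(the night is one stationary regime with optional slow drift), correlations
between features (columns are independent at the feature level, so
collinearity-driven selection instability in real data is untested), wear
gaps and nonwear misclassification, device-specific beat-detection error
structure, and any disease-progression dynamics. Passing recovery tests
therefore demonstrates the correctness and calibration of the pipeline's
machinery under its stated assumptions, not field performance.

## Numerical and design notes

* Timestamps are seconds from the cohort's local midnight of day 0
  throughout; all windows and intervals are half-open.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; identical configs reproduce byte-identical cohorts, splits
  and fits.
* The library's functions and the `examples/` scripts are the interface;
  `run_pipeline` orchestrates the stages and writes CSV outputs plus a
  manifest (config hash, seeds) for provenance. No shell entry point is
  installed — the package is used from Python.
* Problem sizes in the test suite (two-participant stream cohorts, 20
  replicates for recovery experiments, 50 splits) are chosen so the whole
  suite completes in well under a minute while keeping the Monte-Carlo
  margins of the calibration properties meaningful.
* Known limitations: refit p-values carry post-selection optimism; the
  group-specific attribution experiment operates near its statistical
  feasibility boundary (a ~10% false-report rate for one specific null
  feature in a ~19-participant group is inherent to the P < .10 reporting
  convention at the default penalty), so its replicate rate hovers around
  0.9; the evaluation's precision is NaN on splits where no night crosses
  the 0.5 cutoff and is skipped in aggregation.
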