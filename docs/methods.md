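# Methods

This note documents the models, parameters and numerical choices behind
`imikin`, and what the synthetic-data tests do and do not establish.

## Recording model

A trial carries 16 trajectories: two persons (actor, imitator) × eight
trackers (shoulder, elbow, wrist, thumb, index, middle, ring, little),
each with x/y/z position in cm and azimuth/elevation/roll in degrees at
240 Hz. Orientation angles are stored and round-tripped losslessly but no
analysis consumes them; all measures derive from positions. The
coordinate frame is arbitrary but consistent within a trial — every
analysis quantity (speeds, distances) is frame-invariant.

The trial timeline is: image onset → actor go tone 1000 ms later → actor
holds until a return tone 2000 ms after that → imitator go tone 1000 ms
after the actor's return tone → imitator holds until a return tone
2000 ms later. Stimulation is a 3 s train at 3 Hz starting either 333 ms
after image onset (observation) or 1000 ms before the imitator's go tone
(imitation). The opposition task uses a 15 s recording with a 15-pulse
3 Hz train from 5.00 s (last pulse 9.67 s) and 5-s pre/stim/post epochs.

## Preprocessing

*Spike detection* standardizes the per-axis second difference of position
by its trial-and-axis mean and s.d. and flags |z| > 3 (union over axes).
Per-axis detection is the most sensitive reading of "double-differentiated
time-series"; a spike at sample *i* perturbs the second difference at
*i−1, i, i+1*, so detection sensitivity is scored within ±1 sample.
*Repair* replaces samples *i−3 … i+3* by linear interpolation between the
anchors *i−4* and *i+4*; overlapping windows merge rather than stack, and
boundary windows clamp to the nearest valid anchor. Spike repair is
deliberately linear while stimulation-window repair is spline: the two
artifact classes are kept distinct.

*Residual outliers* come from a locally weighted linear smooth (tricube
weights, 5-sample window, first-degree polynomial — statsmodels'
lowess with `frac = 5/n`, no robustness iterations). The outlier
criterion is a configurable residual z threshold, default 3 s.d.;
residuals below 10⁻⁹ of the axis range are treated as numerically zero so
noise-free data are never flagged.

*Stimulation-artifact excision* removes onset ± 25 ms (configurable)
around each known pulse, merges overlapping windows, and reconstructs the
gap with a cubic spline fitted to the remaining samples (`CubicSpline`,
not-a-knot; exact on cubic paths, which the tests verify to 1e-9).
Windows covering more than 50 % of the trial log a warning; more than
90 % is an error. The interpolation report converts samples to ms as
`n / fs × 1000`, rounded half away from zero — integer ms for single runs,
0.1 ms for means — e.g. 53 samples → 221 ms at 240 Hz.

*Filtering* is a fourth-order digital Butterworth low-pass at 12 Hz
applied forward and backward (`scipy.signal.filtfilt`), i.e. zero phase
and squared magnitude. Note that the *digital* (bilinear) design's exact
gain uses the prewarped frequency ratio `tan(πf/fs)/tan(πf_c/fs)`; the
familiar analog form `1/(1+(f/f_c)^{2·4})` matches it within 1 % only
well below Nyquist. The tests assert the exact digital closed form at all
probed frequencies and the analog form at 2 Hz. "Bidirectional
fourth-order" is read literally: the effective magnitude is eighth-order;
users wanting a fourth-order *effective* response should design at order 2.

## Kinematics and exclusions

Speed is the Euclidean norm of `np.gradient` of position (second-order
central differences, one-sided at edges — no phase shift). Segmentation
uses ≥ at onset and < at completion, ties broken toward earlier onset and
later completion. The onset search starts at the go tone (configurable);
"started moving before the starting tone" is operationalized as a
threshold crossing inside a 500 ms pre-go window.

The completion deadline combines two printed constraints that do not
quite agree (a 200 ms tolerance around the return tone vs an 1800 ms
maximum movement time when go → return is 2000 ms): a trial is
`late_finish` if the wrist movement either fails to fall back below
threshold by return tone + 200 ms or lasts longer than 1800 ms.
Exclusion rules fire in the fixed order premature_start → late_finish →
overspeed (any tracker > 250 cm/s anywhere), so each excluded trial has
exactly one primary reason. Retention percentages are data-dependent and
not a fixed property of the method.

## Accuracy and group statistics

Pearson r is computed on the segmented, 120-sample, amplitude-normalized
curves; normalization cannot change r (scale invariance — a test
documents this), it matters only for plotting. The Fisher transform is
the standard `atanh`; |r| = 1 is clipped to 1 − 10⁻⁷ (Z ≈ 8.06) and
logged, and zero-variance curves yield an undefined-correlation signal
whose record is dropped. Whether such trials were dropped or imputed in
the original analyses is unknowable from the text; dropping is the
simplest defensible choice.

The repeated-measures ANOVA uses a general Möbius sums-of-squares
decomposition over marginal means with the participant as random
blocking factor, valid for any number of fully-crossed within factors
(the 4-way design needs it; no installed library fits more than two
within factors with sphericity handling). Against pingouin on 1–2-factor
fixtures it agrees to machine precision in F, Greenhouse–Geisser ε,
Mauchly's W and corrected p. GG correction is applied when Mauchly's
test rejects at 0.05 (`correction="auto"`; "always"/"never" available),
matching report tables that mix integer and fractional degrees of
freedom. Effects with only 1 numerator df need no correction. Hedges'
g_rm uses the repeated-measures denominator with pair correlation and
the small-sample factor `J = 1 − 3/(4(n−1)−1)`.

## Cluster-length permutation test

The null statistic is the **maximum** supra-threshold run length per
permutation. The alternative (recording every run) does not control
family-wise error; the maximum-statistic convention matches the
cluster-based practice the procedure is analogous to. Sign flipping of
each participant's paired difference is the canonical exchangeable null
for a paired design; each permutation flips every participant
independently. p-values use add-one smoothing, so the smallest attainable
value is 1/(N+1) and p ∈ [1/(N+1), 1]. Strict inequality |t| > t₍crit₎
defines runs. With 12 participants, t₍crit₎ = t₀.₉₇₅,₁₁ = 2.201.

A uniform multiplicative effect on speed raises the entire non-normalized
curve, so recovered runs typically span most of the 120 samples and
always cover the PV region; run labels (acceleration / PV / deceleration)
are taken relative to the argmax of the grand-mean curve.

## Synthetic world

Defaults encode the study's stated conditions: 240 Hz, 12 participants,
3 sessions (one stimulation site each), 64 trials per session,
3 sites × 2 stimulation times × 2 meanings × 2 effector classes, 3 Hz
stimulation trains, 15-s opposition recordings. Values the study does not
state were chosen once as field-typical and are configurable: movement
duration 1.2 s (inside the 1.8 s analysis window), peak speeds 25–85 cm/s
from shoulder to fingertips, position noise 0.02 cm (sub-millimetre
electromagnetic-tracker RMS), reaction time 350 ± 40 ms, trial-to-trial
peak-speed CV 8 %, between-participant speed CV 10 %, spike amplitude
5 cm, artifact bursts of 8 cm over ±10 ms per pulse, meaningful and
meaningless gestures split 32/32 per session.

Movements are minimum-jerk reaches; actor–imitator coupling adds to the
shared bell independent smooth shape noise (six envelope-shaped sine
harmonics whose coefficients are projected, in coefficient space, to be
mean-free and bell-orthogonal on the supra-threshold support) scaled to
variance `V_m (1 − ρ′)/ρ′`, giving expected Pearson correlation ρ between
the analysed curves; ρ′ compensates in closed form for the decorrelation
of the two bells' own resampled windows when peak speeds differ. The
noise envelope vanishes where the bell is within twice the segmentation
threshold, so threshold crossings are deterministic. Calibration is
accurate for targets ≳ 0.6 (0.7 → 0.706, 0.9 → 0.903 measured); below
that, speed-curve positivity truncates the required noise variance and
the realized correlation overshoots the target (0.3 → ≈ 0.47). The
default (0.7) is in the accurate regime.

The generator returns ground truth for everything it injects (spike
indices, artifact windows, movement onsets, noiseless peak speeds), which
is what makes detection sensitivity/specificity and effect-recovery tests
possible. What a green test establishes is therefore *internal*
consistency: the pipeline recovers what this generative model planted, at
the stated sizes and noise levels. It does not establish robustness to
real-world phenomena the generator omits: soft-tissue and sensor drift,
heteroscedastic noise, co-articulated multi-joint kinematics, gesture-
specific path shapes, EMG contamination, or behaviourally correlated
exclusions.

Determinism: all randomness flows from `SeedSequence([seed, participant,
session, trial])` (plus fixed stream tags), so outputs are bit-identical
across runs and independent of generation order. The curve-level fast
path (`generate_trial_curves`, `simulate_contrast_cells`) draws the same
statistical world without building 16-channel position files; simulation
studies (type-I calibration at 500 experiments × 1000 permutations,
effect recovery at 100 replicates) use it to stay within minutes of CPU
time. Those replicate counts follow the stated calibration design; the
permutation count per replicate (1000) bounds attainable p at ~0.001,
ample for a 0.05 decision.

## Known limitations

- Coupling targets below ~0.6 are not attainable without violating speed
  positivity (documented overshoot).
- The four-way ANOVA requires a complete balanced design; missing cells
  are an explicit error rather than being imputed.
- The opposition generator moves only the thumb between static
  fingertips; finger-speed magnitudes are therefore lower than thumb
  speeds, unlike real recordings where all digits move.
- Orientation channels are carried but never cleaned or analysed.
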