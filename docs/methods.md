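# Methods

## Event model and parameter definitions

The analysis assumes heel-toe walking recorded as 3-D marker trajectories
at a fixed sampling rate (nominally 100 Hz), with the vertical axis `z`
and the nominal progression axis `x`.  Each gait cycle is delimited by
consecutive heel-z valleys (heel strikes); the single heel-z peak between
them marks mid/late swing, and the toe-z valley shortly after a heel
strike marks foot-flat.  All per-cycle parameters are arithmetic on these
event times and heights (see the README table).  Two conventions matter:

- **Times vs. heights.**  The event symbols are overloaded in the source
  formulas: cycle/swing/double-support durations read event *times*, step
  height reads event *heights*.  Event records carry both, and each
  formula names the field it uses.
- **Literal double-support split.**  `IDS` and `TDS` are computed from
  the *same* foot's toe valley, exactly as the defining formulas state,
  even though double support is anatomically a bilateral quantity.  A
  direct consequence of the formulas is `IDS + TDS = ST` for every cycle
  (the toe valley splits the strike-to-peak interval).  Published cohort
  tables built on the same definitions report much smaller TDS shares;
  those tables cannot be reproduced from the printed formulas alone, and
  this package implements the formulas as printed rather than a
  reconciliation.  The bundled reference table itself contains one known
  internal inconsistency (the unassisted column's TDS/ST cell), which is
  documented, not asserted, in the tests.
- **Step length** is the x-displacement between consecutive heel-z peaks,
  valid for axis-aligned straight walking; turn cycles are excluded
  before it is computed.  The first cycle of a contiguous run (and the
  first after a turn gap) has no step length or velocity.

## Smoothing

Heel- and toe-z signals are smoothed by convolution with a Hanning window
normalized to unit sum — a unit DC gain, so amplitudes of slow components
are preserved; an unnormalized window would rescale the signal.  The
default window is 40 samples at 100 Hz; for other rates a seconds-based
default (0.4 s) keeps the window under half a typical gait cycle, and a
configuration error is raised at 0.5 s or more, where per-cycle extrema
start to merge.  Edges are reflection-padded, which avoids manufacturing
boundary extrema; the even-length default kernel implies a half-sample
phase lag, which cancels in all duration computations and is removed by
event refinement (below).  A Savitzky–Golay low-pass (window 41,
polyorder 3) is available as an alternative; Hanning convolution is the
default because it preserves amplitude without polynomial edge artifacts.

## Event detection

Detection is coarse-to-fine:

1. **Candidates** are local extrema of the heavily smoothed signal over a
   ±10-sample neighborhood with prominence ≥ 2 cm.  The prominence floor
   sits far below the smallest plausible step height (~10 cm) and above
   marker noise; plateau extrema resolve to their first sample; a signal
   with fewer than two valleys raises an "insufficient cycles" error.
2. **Alternation** keeps only the highest peak between two valleys and
   the lowest valley between two peaks (ties keep the earliest event, so
   output is deterministic), trims the series to start and end with a
   valley, and is idempotent.  This is the artifact-rejection rule for
   spurious extrema, e.g. from the turning phase.
3. **Turn exclusion** drops whole cycles overlapping an explicitly
   supplied turn window (from trial metadata).  The window is required
   rather than inferred: locating a turn from marker data is a separate
   problem, and guessing it silently would corrupt the straight-walking
   statistics.
4. **Refinement** re-locates each event on a lightly smoothed copy
   (9-sample Hanning) of the raw signal within ±15 samples, then fits a
   parabola to the raw samples (±3) around the extremum and takes the
   vertex as a sub-sample event time and a noise-averaged height.  The
   heavy kernel spans a third of a typical cycle and displaces extrema of
   asymmetric waveforms by several samples; refinement removes that bias
   (to < 0.05 samples on noiseless synthetic trials) and reduces the
   noise sensitivity of height estimates by roughly half.

Toe valleys are matched per heel cycle: the detected toe-z minimum
nearest the heel strike within [strike, peak] (prominence floor 1 cm).  A
cycle without one is flagged and its double-support split left missing.
The heel-x position at a peak is averaged over ±4 samples — unbiased to
first order and noise-reducing.

## Synthetic gait generator

The generator emulates the *signal structure* the detector assumes, with
every event time known exactly:

- **Heel-z** is a C1 piecewise-cosine "bump train": a narrow raised-cosine
  cup (half-width 0.10 s, depth 2 cm) centred at each heel strike, a low
  2 cm plateau through stance, and a raised-cosine swing bump of the
  commanded step height, symmetric about its peak, which is placed so the
  peak-to-next-strike interval equals `swing_fraction × GCT`.  The cup
  gives each valley a steep, locally symmetric basin: with a perfectly
  flat stance the valley position would be undefined under noise, whereas
  a heel is in reality never resting motionless through stance.
- **Toe-z** has one valley per cycle, `ids_fraction × GCT` after the heel
  strike, with a small late-swing bump (8 cm; any positive amplitude with
  a unique per-cycle valley serves the formulas, which constrain only the
  valley time).  Because the toe valley splits strike-to-peak, the
  generated `TDS` is `(1 − swing_fraction − ids_fraction) × GCT`; the
  scenario's `tds_fraction` field declares the intended anatomical budget
  and is enforced in the feasibility invariant
  `swing + ids + tds < 1`, but the literal-formula TDS follows from the
  other two fractions.
- **Heel-x** advances one step length per cycle via a smooth monotone
  ramp during the rising half of swing, completing 6% of a cycle before
  the heel-z peak and holding — so the step length read at the detected
  peak is exact by construction.
- **Phasing**: right strikes are offset half a right-cycle from the left,
  the standard bipedal alternation.  With unequal left/right cycle times
  the relative phase drifts over a trial; per-cycle parameters are
  unaffected.
- **Turning** rotates the heading by 90° (smooth ramp over the turn
  window) while vertical cycling continues, so turn-phase extrema exist
  and exercise the exclusion logic.
- **Noise** is additive i.i.d. Gaussian per coordinate (default SD
  0.1 cm, a realistic optical-capture jitter scale; sweeps go to 0.3 cm).
  Identical scenarios (including seed) are bit-identical.
- Boundary handling: a full virtual swing bump precedes the first strike
  and follows the last, so boundary valleys have full prominence; the
  surplus boundary peaks are trimmed by the alternation rule.

Scenario defaults are the unassisted Parkinsonian condition of the
reference cohort: 1.29 s cycles, 27% swing fraction, IDS fraction 0.1875,
21.2 cm step height, 93 cm step length, at 100 Hz.

The generator does **not** emulate joint kinematics, ground-reaction
timing, stride-to-stride autocorrelation, freezing episodes, soft-tissue
artifact, or marker dropout beyond NaN gaps.  Passing recovery tests
therefore demonstrates correctness of the event logic and arithmetic
under the stated signal model, not clinical validity on arbitrary real
recordings.

## Statistics

Per-cycle values are pooled across sides and trials within a condition.
Normality is screened per group with Shapiro–Wilk (flagged at p ≤ 0.05; a
constant sample is reported as p = 0); flags are reported, never
auto-switched to a nonparametric test.  Condition pairs are compared with
a two-sided two-sample t-test — Welch's unequal-variance form by default
as the safer choice, with a pooled-variance option for strict classical
reproduction.  No multiple-testing correction is applied, and comparisons
are unpaired; cycles are pooled rather than stratified per subject, so
between-subject variance is not separated from within-subject variance —
a deliberate simplification matching the reporting style the package
mirrors.  Condition velocity is the mean of per-cycle velocities, not
mean SL over mean GCT (the two differ; only the former makes the summary
table internally consistent).  Phase ratios are ratios of condition
means, which makes `IDS/ST = (IDS/GCT)/(ST/GCT)` hold by construction.

The asymmetry index is computed on per-side condition means and reported
in percent with range [−100, 100] (the ×100 in the formula wins over a
[−1, 1] range sometimes quoted alongside it); it is antisymmetric under
side exchange and scale-invariant.

## Validation problem sizes

The test suite and reproduction script use: a 50-scenario sweep (cycle
time 0.9–2.0 s, step height 10–25 cm, step length 40–95 cm, noise SD
0–0.3 cm, 8 cycles per side — 800 cycles), chosen to cover the plausible
clinical range at sub-minute runtime; a 20-cycle-per-side cohort for the
asymmetry recovery; and 1000 null replications at n = 30/group for the
type-I calibration.  Observed performance: at zero noise every cycle's
durations are recovered within 1 sample period and heights/lengths within
0.1 cm; across the noisy sweep ≥ 95% (typically ~99%) fall within 3
sample periods and 0.5 cm.

## Known limitations

- C3D ingestion is not implemented; the CSV schema is the canonical
  interchange format.
- The progression axis is assumed to be `x` before the turn; no
  horizontal-Euclidean fallback is enabled by default.
- Cadence, step width, and joint angles are outside the parameter set.
- Turn windows must come from metadata; there is no automatic turn
  detector.
- Per-subject stratified statistics and per-subject asymmetry averaging
  are not implemented; all pooling is at the cycle level.
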