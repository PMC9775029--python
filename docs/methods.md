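# Methods

This note documents the model behind `nirsrr`, the choices made where the
method leaves room, and what the synthetic benchmarks do and do not show.

## The estimation model

The working assumption is physiological: inhalation and exhalation modulate
cerebral blood volume, so the O2Hb concentration signal carries a slow
baseline wander at the breathing frequency underneath its cardiac
pulsations. The pipeline estimates that frequency:

    OD --MBLL--> O2Hb/HHb --SQI channel selection--> best O2Hb
       --0.05-2 Hz zero-phase FIR--> x(n)
       --normalize, trough detection (Th1, Th2)--> knots K
       --cubic spline through (K, x(K))--> baseline m(n)
       --m - filtfilt(3 s moving average)--> G(n)
       --argmax |FFT(G)| in 0.05-2 Hz, x60--> RR [BPM]

Troughs rather than peaks anchor the spline because the dicrotic notch
perturbs the peak region of each pulse far more than its trough.

### Trough detection thresholds

`Th1 = A*mean(x)` (default `A = 1`) admits only local minima below the
signal mean, screening out dicrotic-notch minima, which sit high on the
pulse downstroke. `Th2` then screens the vector `z` of candidate depths for
motion-artifact outliers. The published description of this stage is
internally inconsistent: discarding values *lower* than
`mean(z) + B*std(z)` would discard essentially every trough (trough values
lie below the mean, and `mean(z)+3*std(z)` lies above nearly all of them),
the opposite of the stage's stated purpose. The default here implements the
evident intent — retain `z >= mean(z) - B*std(z)`, i.e. reject only
abnormally deep troughs — and the literal rule stays available via
`th2_convention="literal"`. Standard deviations use the n−1 denominator;
with fewer than two candidates the screen is skipped; the comparison is
non-strict so zero-variance depth vectors retain everything.

A known property of the `mean ± B·std` form: when several outliers of very
different depths coexist, the deepest inflate the standard deviation and
can mask the shallower ones. This is intrinsic to the rule, not to the
implementation.

### Baseline synthesis and detrending

The spline is a not-a-knot cubic through every retained trough (two knots
degenerate to a line, three to a parabola), evaluated over the full window;
beyond the outer knots the end polynomials extrapolate. The moving-average
detrend uses a uniform kernel of `round(L*fs)` taps applied
forward-backward (zero phase), `L = 3 s` by default — the length with the
lowest error in the empirical regulation. Its measured subtraction
response `|G|/|m|` at 50 Hz:

| f (Hz) | 0.04 | 0.10 | 0.15 | 0.20 | 0.30 | 0.40 | 1.0 |
|--------|------|------|------|------|------|------|-----|
| gain   | 0.05 | 0.26 | 0.51 | 0.75 | 0.99 | 0.98 | 1.0 |

So the stage is not a 0.04 Hz cutoff: at 6 BPM (0.1 Hz) the respiratory
fundamental itself is attenuated to ~26% while its harmonics pass, which
makes the slowest paced rate the least robust operating point of the whole
method. This is a property of the 3 s kernel the method prescribes.

### Spectral estimation

`G` is mean-removed and zero-padded to the next power of two at or above
8× its length (≈0.09 BPM grid for a 50 s window; padding refines argmax
localization, not resolution). The dominant frequency is the magnitude
argmax within the analysis band (0.05–2 Hz, DC excluded; configurable to
`full`). Samples outside the outer trough knots are excluded from the
spectral window: there the "baseline" is an extrapolated end polynomial,
and including it measurably biases the argmax (up to ~0.25 BPM on 50 s
trials) while contributing no information. A plain (rectangular-window)
FFT is retained by design; its leakage can still bias the peak by about
one grid bin when the window holds a non-integer number of breaths, which
is why grid-level accuracy statements use the 0.2 BPM figure rather than a
single bin.

### Band-pass filters

Both FIR stages are Hamming-windowed designs applied forward-backward
(`filtfilt`), so they are exactly zero-phase. The quality-scoring stage
uses the prescribed 208th order, 0.4–3 Hz. The main 0.05–2 Hz stage's
order is a free choice; it is set to `16*fs` taps because the 0.05 Hz edge
needs a long impulse response — at `4*fs` the forward-backward gain at
0.1 Hz (the slowest paced rate) is only 0.05, which destroys 6 BPM trials,
while at `16*fs` it is ≈0.85 and the kernel still fits comfortably inside
a 50 s window. After the window design the taps are mean-subtracted, which
forces an exact DC null (measured rejection far beyond 60 dB) at a
negligible cost in-band.

### Quality index surrogate

The published scoring pipeline is reproduced stage for stage (MBLL →
least-squares detrend → 208th-order 0.4–3 Hz zero-phase FIR → 10 s windows
→ integer 1–5 per window), but its proprietary feature set is not public.
The surrogate features are: finiteness and peak-to-peak sanity bounds
(flat or saturated → 1), the fraction of in-band spectral power
concentrated within ±2 bins of the strongest 0.5–2.5 Hz peak (no cardiac
peak → 2, weak → 3, clear → 4), and the sign of the O2Hb–HHb correlation
(clear peak plus physiological anti-correlation → 5). Window scores
aggregate per channel by mean (median and min are available); ties in
channel selection break toward the lowest channel index; trailing partial
windows are discarded.

## Evaluation metrics

Event-level matching is greedy one-to-one nearest within ±100 ms
(configurable) — localization jitter of a few samples is not a detection
failure. CSI = TP/(TP+FN+FP). Bland–Altman limits use a multiplier of
exactly 2 (not 1.96). Per-subject paired t-tests are two-sided with no
multiple-comparison correction (noted in report metadata); all-zero
differences give t = 0, p = 1, and zero-variance nonzero differences are
flagged degenerate.

## The synthetic generator

The simulator's job is to make every stage falsifiable, so each confounder
the method claims to handle is modelled explicitly:

* **Cardiac pulse** — a per-cycle Gaussian mixture: systolic peak (center
  0.20 of the cycle, σ 0.055), dicrotic bump (0.38, σ 0.06, relative depth
  0.5), diastolic undershoot (0.72, σ 0.10, depth 0.3), mean-removed. The
  saddle between the first two bumps is the dicrotic notch; it sits well
  above the cycle mean (as it does physiologically, high on the
  downstroke), while the undershoot forms a deep trough. That separation
  is precisely what lets `Th1` distinguish the two kinds of local minima —
  an early template with the notch near the baseline level made every
  sub-1 Hz heart rate fail once the filter stopped removing the second
  harmonic.
* **Respiratory wander** — a sinusoid at the commanded rate; under rate
  schedules the frequency is integrated to keep phase continuous.
* **Mayer wave** (0.1 Hz sinusoid) and **slow drift** (0.01 Hz, random
  phase) as low-frequency confounders; **white Gaussian noise**.
* **Motion artifacts** — negative Gaussian excursions of 0.5–1 s (±2σ
  support), amplitude 16× the wander amplitude ±10%, centers at least 5 s
  apart. They model a single event class deliberately: post-filter depth
  heterogeneity (short events lose depth to the 2 Hz edge; events landing
  on a systolic peak start 2 µM-equivalents higher) reintroduces the
  masking limitation of the `mean ± B·std` rule, which is worth
  demonstrating but not manufacturing by default.

Amplitude defaults (µM-equivalent): cardiac 1.5, respiratory 0.25, Mayer
0.08, drift 0.3, noise σ 0.05. Two constraints fix the cardiac:respiratory
ratio: the trough depth below the mean (~0.5 after band-passing) must
exceed the wander amplitude, or troughs riding a respiratory crest rise
above `Th1` and drop out of the spline — the method's own operating
assumption — and the margin must survive the global mean shift a deep
negative artifact induces. The forward optical model (inverse MBLL) uses
tabulated extinction coefficients for 760/850 nm (Prahl compilation), DPF
6.0, source–detector distance 35 mm, all configurable; HHb is generated as
−0.3× the pulsatile O2Hb. Multichannel recordings share one physiology
with per-channel noise scaled by (1 + k/2) so channel selection has a
right answer.

The protocol generator emits the paced-breathing session (60 s rest, five
50 s steps at 6/12/24/12/6 BPM, 30 s rest, five at 9/18/24/18/9 BPM,
repeated once — 1180 s, 20 constant-rate trials); rest-period rates are
drawn uniformly from 12–18 BPM and the subject's heart rate from
0.9–1.3 Hz. All randomness flows from per-call seeded generators with
separate streams for physiology, noise, and artifacts, so an
artifact-free twin of a trial shares its noise bit for bit.

**What the simulator does not model:** hemodynamic (neuronal activation)
responses, heart-rate variability within a trial, respiratory waveform
asymmetry (real breathing is not sinusoidal), non-Gaussian sensor noise,
positive-going or compound motion artifacts, scalp/short-separation
physiology, and optode-specific gain drift. Passing the synthetic
benchmarks therefore demonstrates the algorithm's internal correctness and
its behaviour under the modelled confounders — not field performance on
human recordings.

## Benchmark conditions and observed behaviour

The test suite and `scripts/acceptance.py` use these problem sizes: ten
noiseless 50 s trials (5 paced rates × {50, 100} Hz) for rate recovery; an
8-subject × 20-trial cohort (160 trials) with noise at 10 dB SNR relative
to the respiratory wander; 100 artifact/clean trial pairs with 1–3
injected excursions; 1000 random short signals for the brute-force trough
oracle; 500 Gaussian differences for Bland–Altman coverage.

Under these conditions rate recovery is grid-limited (worst ≈0.1 BPM), the
noisy-cohort mean absolute error is ≈0.05 BPM, and the Th2 screen rejects
artifact troughs with CSI ≈0.94–0.97. Artifact/clean pair agreement sits
at ≈92–96% within the spectral-grid tolerance: a deep excursion blanks the
troughs on its flanks (their local minima disappear on the excursion
slope), the spline bridges a 2–4 s knot gap, and on slow-rate trials
(6–9 BPM, where the moving average has already attenuated the fundamental)
the corrupted wander occasionally flips the argmax to a harmonic. That
residual failure mode is a genuine property of the method at slow rates,
not a simulation artifact.

## Known limitations

* The 6 BPM operating point is fragile by construction (3 s MA response).
* The two-threshold detector assumes one trough per cardiac cycle below
  the signal mean; arrhythmia, very low pulse amplitude, or wander larger
  than the pulse breaks the assumption.
* `Th2` masking under heterogeneous simultaneous artifacts (above).
* The SQI is a surrogate: scores are calibrated to the synthetic fixtures'
  ordering (flat < noise < clean cardiac), not to any published scale.
* RR is assumed quasi-constant per analysis window; windows below 20 s are
  flagged, and no within-window rate tracking is attempted.
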