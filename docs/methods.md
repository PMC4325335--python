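# Methods

`duoscan` is a desk-scale simulator and analysis pipeline for multi-site
real-time fMRI neurofeedback. Two "scanner sites" with grossly different
BOLD amplitudes (e.g. a 3 T and a 7 T system) each run a functional
localizer, calibrate feedback to the subject's *individual maximum* BOLD
response, and then play a joint brain-computer-interface game in which a
virtual sphere is driven by banded, calibrated activation levels exchanged
between the sites through timestamped text files. The package exists to
make the central methodological claim testable in simulation: once signals
are expressed relative to each subject's own maximum, sites with different
absolute signal amplitudes become directly comparable.

## Signal model

The synthetic scanner emits 4D volume series at one volume per TR
(default TR = 2 s). A spherical activation blob (configurable centre and
radius; spatial profile `exp(-d²/2r²)` truncated at radius `r`, i.e. weight
1 at the centre and ≈0.61 at the edge — a smooth partial-volume-like
falloff) rides on a flat baseline intensity (1000 a.u.):

    I(v, t) = B · [1 + w(v) · A · e_b · h(t) / 100] + B·σ/100 · ε + drift

* `A` — the subject's maximal percent signal change at full effort
  (default 2.69%, a realistic sensorimotor amplitude at 3 T; 7 T subjects
  are emulated with 1.6× the 3 T amplitude, matching the observed ≈60%
  group difference between field strengths).
* `e_b ∈ [0, 1]` — per-block effort; an optional controllability map can
  distort intended into realised effort.
* `h(t)` — each block's tapping boxcar convolved with the canonical
  double-gamma HRF (peak delay 6 s, undershoot delay 16 s, dispersions
  1 s, undershoot ratio 1/6, support 32 s), normalised so that one
  full-effort block peaks at exactly 1. Block responses superpose
  linearly.
* noise — i.i.d. Gaussian per voxel per scan, SD in percent of baseline
  (default 0.2%), plus one slow sinusoid (period ≥ 60 s, default 120 s,
  amplitude 0.1%) as drift. There is no autocorrelated physiological
  noise, no motion, and no EPI physics.

A consequence worth knowing: with the canonical 32 s kernel and
consecutive blocks, a block's undershoot overlaps the *next* block's
baseline scans (lags 20–28 s) but not its response window (lags ≥ 34 s).
Per-block percent change is therefore not perfectly linear in amplitude
(relative differences of order 10⁻³). Parameter-recovery checks that
demand 10⁻⁶ accuracy interleave rest blocks so each measured block has a
clean baseline; everything else simply absorbs the leak.

## Localizer and calibration

The localizer is five blocks of twelve scans (2 rest, 2 tapping, 8 rest).
Each arriving volume is smoothed with a 3 mm FWHM Gaussian. Per block,
per voxel, the observed signal at the used scans (block-local baseline
scans 1–3 and response scans 6–8, which straddle the HRF peak) is
expressed as percent change from that block's baseline and correlated
with the identically referenced HRF regressor. The Pearson statistic is
accumulated *incrementally* (growing window) across completed blocks from
running sums, so a map is available after every block; after the last
block it equals a one-shot correlation over the pooled scans to 1e-10.
Constant voxels get NaN, never ±1. The ROI is the largest 6-connected
cluster with r ≥ 0.6 and ≥ 5 voxels (thresholds configurable; the choice
is conventional, not printed in any source); an empty result raises a
localization failure meaning "repeat the measurement".

Calibration defines the 100% reference from the ROI-mean trace. Two
conventions are implemented:

* `window` (default): maximum over blocks of the sliding-window response
  (baseline-window mean subtracted from response-window mean). Because
  the main experiment uses the same 3-scan-mean convention, the HRF
  window attenuation cancels in the relative ratio, which keeps
  calibrated percentages unbiased. This is why it is the default.
* `scan_max`: maximum over all scans of the ROI-mean percent change
  against the run-initial baseline (the rest scans before the first
  tapping block). This is the literal "maximum detected signal" and is
  the convention that recovers the programmed generative amplitude
  exactly; it uses the run-initial baseline because later blocks' local
  baselines sit in the preceding block's undershoot.

Whether the reference should be a single-voxel or ROI-mean maximum is a
genuinely open choice; the ROI-mean trace is used because single-voxel
maxima are noise-dominated at realistic SNR.

## Main experiment, bands and rewards

The main schedule is one 15-scan block per run: 5 baseline scans, 2
tapping scans, 7 rest scans, 1 feedback scan, with the 10 s task cue
presented between blocks (the only partition of the stated segment
lengths that sums to 15). Three tasks (single, cooperation, competition)
are randomly ordered with 20 runs each; per task, each target region (U,
L) appears 10 times. The per-block estimate is the mean of scans 8–10
(6 s of signal immediately after tapping) minus the mean of scans 1–5,
divided by the calibration maximum.

Bands: relative activation < 30% of maximum is *insufficient* (so simply
stopping the task never scores), 30–60% inclusive is *weak* ("L"), and
strictly more than 60% is *strong* ("U"). The boundary convention reads
the banding phrases literally — closed at 30 and 60, open above 60; exact
boundary hits are measure-zero in practice. Relative values are not
clipped before classification; only the sphere position (relative/100) is
clipped to the display field [0, 1].

Rewards per block: *single* — a site is rewarded iff its band matches the
target region. *Cooperation* — both rewarded iff both match, else
neither. *Competition* — among sites whose band matches the target, the
one whose relative level is closest to the band reference (45 for L, the
midpoint of [30, 60]; 80 for U, the midpoint of (60, 100]) wins;
accuracies within 0.01 percentage points count as a tie and reward both.
The tolerance exists because 0.01% of an individual maximum is far below
display resolution and any noise floor; with an exact-equality tie rule,
the ~10⁻³-point amplitude nonlinearity described above would
deterministically decide blocks between otherwise identical performances.
If a partner's exchanged level has not arrived by the feedback scan,
cooperation and competition blocks are scored unsuccessful for both and
flagged `timeout` (the sources are silent here; this is the package's
rule).

## Exchange and logging

Each transmitting channel appends one tab-separated line per trigger scan
(default block-local scan 10): ISO-8601 timestamp, site, block, scan,
then `key=value` pairs in the schema's canonical flag order, floats with
six decimals. Readers poll once per scan with a byte cursor; partial
trailing lines wait for the next poll, malformed lines are reported by
line number and skipped. Timestamps come from a simulated session clock
(fixed epoch + scan index × TR) so that seeded sessions are reproducible
byte for byte; reader latency is zero by default with an optional
injected delay for robustness experiments.

The session log is one TSV row per block (per-site raw %, relative %,
band, success, reward delta, cumulative reward, flags) plus a JSON
summary of per-site and per-task success percentages. The two-site
comparison uses a paired sign-flip permutation test on per-block success
(5000 permutations) rather than a repeated-measures ANOVA: the simulated
comparison needs only exchangeability, and inference machinery for human
cohorts is out of scope.

## Simulated behaviour

Effort policies are simulation devices, not models of human subjects: a
target region maps to an intended effort (defaults 0.45 for L, 0.80 for
U — the band midpoints after window-convention matching) with Gaussian
variability (SD 0.10) and an attention-lapse probability (0.05) that
replaces the draw with a near-zero effort (mean 0.05, SD 0.02). These
defaults produce single-task success rates around 80–90%, a plausible
regime for trained participants; they are deliberately not tuned to any
reported human success rate, which depends on unmodelled behaviour.

## Problem sizes and what passing tests show

Tests and examples run on reduced geometries (16–20 voxels per in-plane
axis, 8–10 slices) with the activation blob scaled accordingly; the
full-protocol defaults (64×64 matrix, 31 slices at 3 T / 20 at 7 T)
remain the configuration defaults. All pipeline mathematics is
resolution-independent, so the reduced grids exercise the same code
paths at a few seconds per session.

Passing tests demonstrate internal correctness of the pipeline —
incremental statistics equal brute-force references, calibration is
exactly invariant to scanner intensity gain, programmed amplitudes and
effort fractions are recovered, schedules and reward rules behave as
specified — under a generative model whose noise is white and whose
subject is stationary. They do not show robustness to motion,
physiological noise, non-stationary baselines, or real human behaviour,
none of which the generator emulates.
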