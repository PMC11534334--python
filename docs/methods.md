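# Methods

`tmreeg` analyzes auditory targeted-memory-reactivation (TMR) experiments in
sleep EEG: spoken cues are re-presented during NREM sleep, and the analysis
asks whether cue-locked slow-wave (SW) activity, fast sleep spindles nested
in the SW up-state, and overnight changes in discrimination behavior differ
between cueing conditions. Because raw recordings of such studies are rarely
shareable, the package is validated end to end on synthetic data with known
ground truth; every detector and statistic is exercised against what was
injected.

## Behavioral model and scoring

The task is a two-alternative reward categorization of 160 artificial words
(4 sets x 40; two sets form the easy, phonotactically familiar "high-PP"
condition, two the difficult "low-PP" condition; half of each set is
rewarded). Encoding presents every word three times (480 trials); the pre-
and post-sleep memory tests present each word once (160 trials).

Scoring uses signal detection theory. Correct responses to rewarded words
are hits, incorrect responses to unrewarded words are false alarms, and

    d' = z(H) - z(FA)        c = -0.5 (z(FA) + z(H))

with z the standard-normal quantile. Rates of 0 and 1 are replaced by
`0.5/n` and `(n-0.5)/n` before the transform (n = trials per category, 40 by
default), so d' is bounded by 2 z(0.9875) ≈ 4.48 at n = 40. Timeout trials
are excluded and n reduced accordingly (their handling is not dictated by
the task; exclusion is the least-assumption choice). Reward points default
to ±10 and never enter the SDT computations.

The behavior simulator draws each response as a Bernoulli trial with a
condition- and presentation-specific accuracy. Defaults: encoding
accuracies (0.50, 0.68, 0.78) for the easy and (0.50, 0.60, 0.70) for the
difficult condition — chance at the first presentation, easy ahead from the
second on; pre-sleep memory accuracies 0.80 / 0.75 (comfortably above the
70%-accuracy ≈ d' 1.05 inclusion level such designs use); and an overnight
accuracy gain of +0.03 for the cued easy condition only, which corresponds
to a d' gain of ≈ 0.22 at that baseline — the magnitude such TMR effects
are reported at. These are study conditions, set once.

## Synthetic sleep EEG

The generator is additive and every component is a pure function of its
seed:

* **Background**: Gaussian noise spectrally shaped to 1/f^β (default β = 1,
  SD 20 µV per channel, 19-channel 10-10 montage, 500 Hz).
* **Cue train**: inter-stimulus intervals uniform on 8 ± 2 s.
* **Slow waves**: one biphasic sine cycle (negative then positive
  half-wave) at 0.75 Hz; the trough sits at the stated time and the
  trough-to-posterior-peak excursion equals the stated amplitude (default
  150 µV), identically on all channels. A cue evokes an SW with
  probability 0.6 at a latency of 0.4–1.6 s; spontaneous SWs occur at
  0.1/s (NREM-like ongoing slow-wave activity — a near-zero baseline would
  make the percent-change density undefined).
* **Spindles**: Hann-windowed sinusoidal bursts (default 13 Hz, 1 s,
  envelope peak = stated amplitude) with a central-parietal amplitude
  topography (maximum at Pz). Injected SWs carry a coupled burst with
  probability 0.8 at a lag of 0.3–0.8 s (envelope peak after trough);
  uncoupled bursts occur at 0.02/s. The cueing-condition manipulation is
  the coupled-spindle amplitude (defaults 14 vs 8 µV for the easy vs
  difficult group in the two-group pipeline).

What the generator does **not** emulate: sleep-stage dynamics and
arousals, spindle frequency drift, SW traveling, realistic inter-channel
correlation of the background (channels are independent noise plus
identical injected events), ocular/muscle artifacts, and any dependence of
behavior on the EEG events. Passing tests therefore demonstrate that the
analysis recovers what its own forward model generates — not that the
detectors are optimal for real recordings.

## Preprocessing

Re-referencing subtracts the mean of the two mastoid channels. Band-passes
are zero-phase (forward–backward) 4th-order Butterworth filters — (0.5, 45)
Hz for wake, (0.5, 35) Hz for sleep analyses. Epochs are half-open
`[t_min, t_max)` windows around cue onset (wake −2–4 s, sleep −2–8 s),
demeaned and linearly detrended; events whose window leaves the recording
are dropped with a warning. Artifact rejection is a deterministic
any-channel peak-to-peak threshold (defaults 150 µV wake, 500 µV sleep), a
reproducible stand-in for visual inspection; the rejection log is kept.

## Time-frequency analysis

Power comes from 7-cycle complex Morlet wavelets on a 0.2 Hz / 10 ms grid
(configurable). The wavelet response is calibrated so a sinusoid of
amplitude *a* reads *a²/2* µV² (the signal's mean squared amplitude);
without this, the L2-normalized wavelet scales power by fs·σ_t·√π per
frequency. Baseline correction subtracts the mean baseline-window power per
channel and frequency ("absolute change", default window −1 to −0.1 s), so
averaging over trials and baseline subtraction commute (asserted in a
test). Time points closer than 2.5 wavelet SDs (σ_t = n_cycles/2πf) to an
epoch edge are flagged invalid rather than silently padded. The wake alpha
analysis averages the 8–13 Hz, 0.7–1.9 s box over Pz/Cz and contrasts
presentations 2 and 3 against presentation 1.

## Slow-wave detection

On the 0.5–3 Hz filtered trace of one channel (default Cz — the
conventional SW-scoring site), every negative local extremum flanked by
positive local extrema whose spacing lies in 0.3–2 s is an event; plateaus
resolve to their midpoint. Two deliberate choices:

* **Amplitude read-out.** A single SW cycle is a broadband transient; any
  0.5–3 Hz zero-phase band-pass attenuates its trough-to-peak excursion by
  ~25%. Amplitude (trough to posterior positive peak) is therefore read
  from the detector's *input* trace at the extrema located on the filtered
  trace, which recovers injected amplitudes within ±2 µV on clean signals.
* **Trough refinement.** The sample minimum of the filtered trace is biased
  ~18 ms by the band-pass's waveform asymmetry and displaced further by
  in-band noise. The trough time is refined as the vertex of a
  least-squares parabola fitted to the input trace over ±0.2 s around the
  sample minimum (clamped between the flanking peaks). This is unbiased on
  clean signals and roughly halves the localization error in noise.

For cue-locked analyses, detection runs on the continuous signal; each
trough is assigned to the most recent cue whose search window contains it,
so overlapping windows never double-count. Per subject, the top 30% of
events by amplitude are kept (⌈0.3 N⌉, ties to the earlier trough). The
density analysis detects over the full peristimulus range (−1.5 to 6 s) —
the baseline bins (−1.5–0 s) must be able to contain troughs — while the
coupling and SW-locked-TFR analyses use the 0–6 s events only. Density is
troughs per trial in 0.5 s bins; percent change is
`(bin / mean(baseline bins) − 1) · 100`, and a zero baseline is flagged
(raw densities returned) rather than divided through.

## Spindle detection

On the 12–16 Hz filtered trace of Pz, the detection "amplitude" is the
Hilbert-envelope magnitude — smooth, standard, and it makes the edge
threshold well-defined. Thresholds are individualized per subject: mean and
SD of the envelope over the concatenated cue windows (−2–8 s). A candidate
needs envelope > mean + 1.25 SD; its boundaries extend to where the
envelope falls below mean + 0.75 SD; candidates separated by < 0.1 s merge
(envelope dips); only durations of 0.5–3 s survive. The spindle peak is the
envelope maximum; spindle amplitude is the mean absolute value of all local
extrema of the filtered trace inside the event.

## SW–spindle coupling and up-state power

A spindle is coupled when its envelope peak falls in the closed interval
[0.3, 0.8] s after some SW trough (the up-state); a spindle qualifying for
several SWs counts once, attached to the SW whose lag is nearest the window
midpoint (0.55 s). The SW-locked TFR segments the recording ±2 s around the
selected troughs (plus 0.5 s padding that is cropped after the transform),
averages Morlet power over segments and subtracts the −2 to −1.5 s
baseline. The group contrast statistic is the mean 11–14 Hz power in the
0.3–0.8 s window (central-parietal channels by default).

## Cluster-based permutation statistics

Pointwise two-tailed t-tests (dependent or independent) at the
cluster-forming alpha (0.05; the cluster alpha and the pointwise alpha are
not separately stated by the convention this follows, so both default to
0.05) threshold the channel × frequency × time grid. Suprathreshold points
cluster through grid adjacency within a channel and a hand-curated
19-channel 10-10 neighbour relation across channels; positive and negative
clusters form separately. A cluster must span ≥ 2 distinct channels (the
"minimum two channels" rule read at cluster level; configurable). The
cluster statistic is the summed t; each tail is compared against the
permutation distribution of its max (min) cluster sum — condition-label
sign flips for paired data (fully enumerated when 2^n ≤ n_perm), group
shuffles otherwise — with p = (b+1)/(n_perm+1) and significance at α/2 per
tail. Zero-variance points get t = 0 (constant data yields no clusters).
Empirical type-I error over 200 null datasets sits within the 99% binomial
band around 0.05 for both designs.

## Validation conventions (synthetic ground truth)

* SW recovery: "SNR 3" means the injected peak deviation (half the
  trough-to-peak amplitude) is 3× the broadband background SD. Sensitivity
  counts injected troughs matched within ±0.25 s (a third of the SW
  period); localization error is the median |Δt| of matches. A strict
  per-event ±50 ms criterion is physically unattainable at this SNR: the
  trough of a 0.75 Hz wave is flat, and in-band noise displaces the sample
  minimum by ~50 ms RMS regardless of absolute scale.
* Spindle recovery: "envelope SNR 5" means the injected envelope peak is
  5× the broadband background SD. Boundary errors are referenced to the
  closed-form times where the noiseless injected Hann envelope crosses the
  detector's edge threshold — the ground truth an ideal edge-threshold
  detector would produce (a Hann envelope is near zero at its support
  edges, so support-referenced boundaries are unattainable for any
  threshold detector).
* Problem sizes: 3 × 30 injected SWs and 20 injected bursts for detector
  recovery; 200 null datasets per design (19 channels × 3 × 10 grid, 15
  subjects, 250 permutations) for type-I calibration; 200 simulated
  sessions for SDT parameter recovery; the two-group pipeline runs 6–8
  subjects per group with 20–30 cues each and 200–500 permutations.

## Known limitations

* Detection channels are fixed single electrodes (configurable), as in the
  procedure this implements; no multi-channel consensus detection.
* The independence of background noise across channels understates real
  EEG spatial correlation, making the cluster test's effective sample size
  per channel optimistic relative to real data.
* ICA-based ocular correction is out of scope; artifact rejection is
  amplitude-based only.
* The synthetic behavior model ties overnight change to condition and
  cueing only; it does not model word-level memory or reward learning.
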