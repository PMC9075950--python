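# Methods

## The task and the data model

Mice lick for water dispensed at a fixed 10-s interval; 20% of trials are
unrewarded and consecutive omissions never occur. Trained animals emit one
rhythmic licking bout (6–8 Hz tongue protrusions) per trial, usually
initiated before the scheduled water time (exploratory, internally timed)
and otherwise triggered by the water itself (reactive/consummatory,
median latency ≈ 360 ms). All analyses run on event times in seconds on a
common session clock: a trial table (start, water time, rewarded flag,
optional optogenetic window), lick-contact times, per-unit spike times,
per-unit per-channel mean spike-peak amplitudes, and per-dendrite calcium
event times. Binary containers are deliberately avoided; a session bundle
is a directory of CSV tables plus YAML config/ground-truth documents.

## Synthetic session generator

The generator is first-class, tested code: it defines the conditions under
which every downstream operation is validated, and emits a ground-truth
record (true bout boundaries and contexts, true unit and dendrite
parameters) for recovery tests.

**Trial structure.** Omissions are drawn from a two-state Markov chain with
P(omit | previous rewarded) = p/(1−p) and P(omit | previous omitted) = 0,
initialized from its stationary distribution. This honours the
no-consecutive-omission constraint while keeping the stationary omission
fraction exactly p (naive resampling after an omission would depress it to
p/(1+p)); the chain's stationary distribution, solved independently from
the transition matrix, is the test oracle. p must lie below 0.5, the
constraint's realizable ceiling.

**Licking.** One bout per trial (with a small no-bout probability,
default 0.05). Exploratory bouts start a Gaussian lead before the scheduled
water time (mean 1.0 s, clipped to [0.2, 1.4] s); reactive bouts follow
water by a Gaussian latency (mean 0.36 s, matching the observed median
response time). Intra-bout inter-lick intervals are uniform on
[100, 175] ms; after water, intervals shrink by the consummatory boost
(default 1.3, reflecting the higher consummatory peak rate). Bout length is
uniform on [12, 28] licks, giving bout durations of roughly 1.6–4 s and a
last lick ~1–3 s after water on rewarded trials. No empirical bout-length
or bout-count distributions are available to fit, so these are plausible
placeholders — flagged as such.

**Spike trains.** Each unit is an inhomogeneous Poisson process sampled by
thinning against the documented intensity upper bound (baseline + tuning
depth + positive ramp amplitudes + water response). The intensity is

λ(t) = baseline + depth·cos(φ(t) − φ₀) [within lick cycles ≤ 300 ms]
     + initiation and termination ramps + water boxcar (1 s),

clipped at zero. Ramps rise linearly from the onset (a time before the
bout's first or last lick) to a signed peak 0.3 s *after* the event and
decay linearly over 1 s. The post-event rise is deliberate: peak Δ rates in
this task occur within 500 ms after lick onset, and an intensity that
snapped back to baseline at the event would make a 0.1-s-lead ramp a
single 100-ms bin that no three-consecutive-increase rule can detect.
Initiation ramps may differ by context (`init_ramp_pre` / `init_ramp_post`)
to model earlier internally-timed engagement.

**Channel footprints.** PCs receive 7–15 channels with peaks at 2–4× the
30 µV noise floor; MLIs/others 1–3 such channels; remaining channels sit
below the floor. The margin (≥ 2× floor) makes footprint classification
exact, which the recovery tests exploit.

**Calcium.** Dendrites fire Poisson events at a 1–2 Hz climbing-fiber
baseline; responsive dendrites add a boxcar boost from the true onset
before each first lick to 0.3 s after it, and around water delivery.
Responsiveness is a region property (task-responsive vs unresponsive
imaged regions).

**Optogenetics.** A configurable fraction of unrewarded trials receives a
stimulus window; the default window [8.4, 14.6] s after trial start
brackets the entire span an exploratory bout can occupy, so full
suppression genuinely silences the trial's licking (a shorter window would
leave tail licks that masquerade as rebounds). In-window licks are deleted
with the suppression probability (survivors get ±30 ms ILI jitter);
rebound bouts appear after offset with the configured probability.

**What the generator does not emulate.** No tongue kinematics, no
raw-voltage or fluorescence synthesis, no spike sorting artifacts, no
bursting or refractory structure (Poisson spiking), no session-to-session
or animal-to-animal variability, no slow drift. Passing tests therefore
demonstrate correctness of the *analysis rules* under the stated
statistical structure, not robustness to every pathology of real
recordings.

## Analysis rules and numerical choices

**Bout segmentation.** A new bout begins when an inter-lick interval
reaches the bout break (default 1.0 s). The rhythmic ILI ceiling (175 ms)
and the isolation criterion (2 s) bracket this unstated gap; 1.0 s sits
unambiguously between them and is exposed in config. Windows are half-open
[lo, hi); a lick exactly at the water time is post-water. Bouts on
omission trials are labeled pre-water (there is no water to react to).

**Entrainment.** Only licks in runs of ≥ 3 consecutive licks with every
ILI in [100, 175] ms (inclusive) enter the phase analysis; spikes in gaps
between retained runs are excluded entirely. Phase is linear interpolation
between consecutive licks, contact = 0 = 2π. The Rayleigh test uses
Wilkie's finite-n approximation p = exp(√(1+4n+4(n²−R_n²)) − (1+2n)),
calibrated by Monte-Carlo (p-values uniform under the null at n = 50 by
KS on 10⁴ replicates) and cross-checked against an independent circular-
statistics implementation. The BH screen is the standard step-up at FDR
0.05 (statsmodels). The circular density uses a wrapped-Gaussian kernel,
σ = 0.3 rad (a von-Mises kernel with κ = 1/σ² is provided as the
alternative reading of a width-0.3 kernel), evaluated on a 360-point grid and
renormalized to unit mass; the suprathreshold mask marks density
> 1.02/2π. Sorting for population displays breaks ties by unit id.

**Baseline rate.** Mean rate over all non-licking periods, i.e. ≥ 2 s from
every lick (mirroring the isolation criterion), requiring > 10 s of such time.

**Initiation ramp rule.** Trial-averaged Δ-rate in 100-ms bins over
[−1.0, +0.5] s around the first lick; positive modulation requires three
consecutive bin-to-bin increases, each exceeding a noise floor of
√2 × median(per-bin SEM) (the SD of a difference of two bin means);
onset = left edge of the first incremented bin of the earliest qualifying
run; the negative rule mirrors it, and when both patterns occur the
earlier-onset one wins (ties favour positive). The noise floor is the
package's operationalization of an "increase" on noisy averaged data: with
strict zero-threshold inequalities, pure iid bin noise produces a
qualifying run in ~59% of stationary units and prepends ≥ 2 spurious bins
to a true run with probability ≥ 1/6 regardless of SNR (P(x₁<x₂<x₃) for
iid noise), which would make the rule useless as a screen. With the floor,
the null modulated rate is ~0.02% (Monte-Carlo, 20k replicates; frozen
regression bound 5%) and onsets of configured ramps are recovered within
one bin in ≳90% of units. When no dispersion estimate exists (SEM absent
or zero — e.g. constructed traces) the rule reduces exactly to the strict
form. Recovery experiments configure ramp amplitude 3·√(baseline/bin),
fixed by a pre-test power analysis: the per-bin increment z-score roughly
equals the amplitude multiplier for a 0.4-s lead, so 2× leaves ~40%
misses while 3× recovers ≳90%.

**Termination rule.** Mean Δ rate in the 300 ms before the last lick,
classified positive/negative when it leaves the ±2 SD band of the 100-ms
bins in the alternative baseline window 1–5 s before the lick. Because a
3-bin mean is compared against single-bin SD, the rule is conservative
(null modulated rate ~0.2%, frozen bound 5%).

**Population onset.** The initiation rule applied to the unit-averaged
Δ-rate trace (≥ 5 units); the onset is reported as the population's lead
on the first lick. Peak Δ rate is the max binned Δ rate in [0, 0.5) s.

**Lick-rate/spike-rate correlation.** Per-trial 1-s bins of lick and spike
counts, trials included only when the first lick falls ≥ 2 s into the
trial and the last lick leaves ≥ 1 s of recorded data; least squares via
scipy.linregress, with an explicit degenerate signal when the lick-rate
spread is zero.

**Calcium rules.** Aligned event rates in 100-ms bins; the reference
distribution for the 3-SD rules is the pre-window baseline [−3, −1) s,
chosen once for symmetry across the region and onset screens. Region
responsiveness: dendrite-averaged peri-water peak (±0.5 s) above baseline
mean + 3 SD, ≥ 5 dendrites per region. Onset: first bin in [−1, +0.5] s
around the first lick above the same threshold, ≥ 20 bouts. Contexts are
aligned separately — on post-water bouts the water response precedes the
first lick and would otherwise read as an early onset. Because the SD is
estimated from 20 skewed Poisson baseline bins, the onset rule
false-alarms on stationary dendrites at ~12% (Monte-Carlo; frozen bound
20%) — a property of the rule, documented rather than patched. The
termination comparison uses the signed-rank test with Pratt zero-handling
and continuity correction (low discrete counts are heavily tied; the
naive test is anticonservative below ~60 paired trials).

**Opto metrics.** Binned lick-rate variance during the stimulus window of
stimulated trials divided by the variance in the *matched time window of
control trials*: normalizing to the unstimulated control condition is the
only reading that yields a ratio of 1 under null stimulation, since the stimulus window deliberately covers the
licking period while the preceding seconds are mostly silent. Rebound
probability counts stimulated trials with a well-separated bout initiation
(≥ 2 s prior non-licking) inside [offset, offset + 2 s).

## Reported problem sizes

Unit tests run on sessions of 20–105 trials; the calibration tests use
10⁴ simulated units (Rayleigh), 10⁵ draws (von-Mises resultant), 300
null panels (BH), 36–50 simulated units (ramp recovery/specificity) and
120 dendrites (calcium specificity); the analysis drivers use 250-trial
sessions with 24 units and 12 dendrites, and a 400-trial opto session.
These sizes put Monte-Carlo noise comfortably inside each stated
tolerance while the whole suite stays fast.

## Known limitations

- Poisson spiking ignores refractoriness and bursting; dispersion-based
  checks would need adjustment on real PC data.
- The ramp rules operate on trial-averaged binned rates; a single-trial
  variant is not implemented.
- The opto-tag test assumes a stationary background rate when computing
  the chance level.
- The channel-count rule thresholds mean peak amplitudes; with access to
  per-channel noise distributions a proper significance test would
  replace the fixed ~30 µV floor.
- Lick-contact times are taken as clean events; no debouncing.
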