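# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `axoprop`.  Units throughout: time in seconds (windows
quoted in ms), distance in µm, voltage in µV, velocity in m/s.

## Device model

The layout couples 8 reservoir modules to 8 microchannels.  Each module
has 2 reservoir electrodes (position within the module is treated as
analysis-irrelevant and unordered) and 5 channel electrodes at 100, 300,
500, 700 and 900 µm from the channel entrance (200 µm pitch, 1 mm channel).
Channel index 0 is the entrance-proximal electrode and the axonal
stimulation site.  Seeding capacity is 200 cells per module, 1,600 per
device.

## Spike detection

Raw traces are high-pass filtered with a second-order Bessel filter,
−3 dB at 200 Hz (`scipy.signal.bessel`, `norm="mag"`, SOS form).  The
filter is applied **causally** by default because the timestamps feed
latency and velocity computations; a zero-phase option (`filtfilt`)
exists but changes absolute latencies and is off by default.

The noise scale σ is estimated robustly: the trace is cut into 100 ms
windows, each window contributes a MAD-based standard deviation
(1.4826 × MAD), and σ is the median across windows.  The within-window
MAD rejects isolated spikes; the across-window median rejects windows
inflated by bursts.  On pure Gaussian noise the estimate is within a few
percent of the true σ; with 10 spikes of 50 σ superimposed it stays
within 10%.

Spikes are negative crossings of −4.5 σ.  Each contiguous sub-threshold
run yields one timestamp at its trough sample; events closer than the
dead time (default 1 ms — deliberately shorter than the 2 ms pair-delay
window so it cannot delete genuine propagation partners) to the previous
accepted event are suppressed.  σ is computed per electrode per
recording.

The "−4.5 StDev of the peak-to-peak noise" threshold convention is
ambiguous on its face; we interpret it as −4.5 robust standard deviations
of the filtered trace, the standard MAD-based reading.

## Burst detection (MaxInterval-style)

Five criteria: a burst opens at the first spike of an inter-spike interval
(ISI) ≤ 20 ms, extends while ISIs ≤ 10 ms, candidates separated by
< 10 ms are merged, and merged candidates with duration < 20 ms or < 4
spikes are discarded.  Merging precedes filtering — the minimum
inter-burst interval is meaningless otherwise.  Burst duration is last
spike − first spike, the only definition computable from timestamps.  A
burst cannot open on a train's final spike.

A property worth knowing: the spikes-in-bursts count is **not monotone**
in the extension ISI.  Relaxing it can absorb a spike into a candidate
that then fails the 4-spike minimum, where the tighter setting split the
cluster into two candidates that re-merged across a short gap into a
valid burst (regression-tested with an explicit counterexample).  The
scan is order-defined, not an optimisation; this is inherent to
sequential MaxInterval semantics.

Eight per-train features feed the correlation analysis: spike rate, burst
rate, % spikes in bursts, mean burst duration, mean spikes/burst, mean
in-burst spike frequency, mean in-burst ISI, mean inter-burst interval
(end-to-start gap).  Undefined means (no bursts; IBI with < 2 bursts) are
NaN, never zero.

## Propagating-spike matching

A propagating spike appears on **all 5** electrodes in order with every
pair delay in [min_delay, 2 ms].  Zero delay would mean infinite
velocity, so the minimum delay is one sample period at 25 kHz (0.04 ms);
the 2 ms maximum implies the 0.1 m/s velocity floor (200 µm / 2 ms).

Matching scans entrance-electrode spikes in time order and extends each
chain by the earliest unconsumed in-window partner on the next electrode,
**backtracking** to the next candidate when a choice dead-ends
downstream.  Chains are emitted only when complete; spike consumption is
injective (a spike seeds or joins at most one event).  Pure greedy
selection without backtracking is not count-optimal: a background spike
that happens to be the earliest in-window partner can strand the chain
one electrode later.  With backtracking, the matcher reproduces the exact
maximum number of disjoint complete chains — computed independently as a
unit-vertex-capacity max-flow — on thousands of randomized device-like
instances (1–3 axons of consistent velocity plus background spikes, up to
12 spikes/electrode), including an adversarially dense regime.  Sustained
near-window spike spacing (~500 Hz) could still create ambiguous
interleavings for any sequential matcher; such rates do not occur in
channel recordings outside the sub-millisecond scale the dead time
already excludes.

**Per-spike velocity.**  The default per-spike mean velocity is the
arithmetic mean of the 4 pairwise velocities, following the per-pair
averaging convention of the field.  Because velocity is the reciprocal of
a noisy delay, this estimator carries a Jensen (convexity) bias of
roughly σ²/d² relative terms per pair — at 0.8 m/s (0.25 ms pair delay)
with 0.05 ms per-electrode jitter that is ≈ +9%.
`MatchParams(mean_mode="harmonic")` computes total distance over total
transit time instead; only the two endpoint jitters enter the
denominator (800 µm scale), making it first-order unbiased (< 1%
observed error in recovery tests).  Ground-truth recovery checks
therefore use the harmonic mode; descriptive analyses default to the
arithmetic convention.

Per-channel summaries average the per-spike means (StDev with ddof 1).
The proximal/distal split assigns each electrode pair by midpoint:
pairs 0–1 and 1–2 (< 500 µm) are proximal, 2–3 and 3–4 distal.  The
velocity histogram spans 0.1–1.2 m/s in 11 half-open 0.1 m/s domains
(the last closed at 1.2); out-of-range velocities go to an overflow
count excluded from the percentages.

## Peri-stimulus analysis

Sessions deliver biphasic pulses (positive-then-negative, 100 µs/phase)
at 1 Hz, 180 trials, at 250/500/1000 mV.  The first 5 ms after each pulse
is blanked (timestamp exclusion, not waveform subtraction — the artifact
is excluded rather than modelled).  Analysis windows default to
{5–15, 15–35, 35–100, 100–300, 300–950} ms, a superset covering the
direct (5–35 ms) and polysynaptic (35–950 ms) splits and the intermediate
decay windows; all configurable.  Window rates pool the selected
electrodes: total spikes / (trials × window length), StDev over per-trial
rates.  Response fidelity is the percentage of trials with ≥ 1 spike in
each of three 10 ms bins partitioning 5–35 ms; multiplicity within a bin
counts once.

Evoked velocity uses the 4 electrodes distal to the stimulation site
(3 pairs); each complete chain is assigned to the direct or late window
by the peri-stimulus time of its first arrival.  Baselines are obtained
by running the identical computation on non-stimulated recordings; when
pre- and post-stimulation baselines exist they are reported separately,
not pooled.

## Correlation statistics

One module (reservoir or channel) at one recording day is one data point.
Activity is normalized per module to its own grand mean over the study,
neutralizing between-culture amplitude differences; normalization is
idempotent and NaN-transparent.  Pearson r with two-sided p from the t
transform; < 3 complete pairs is an error, zero variance is flagged
degenerate.  The activity–velocity table correlates each of the 8
features with channel velocity either pooled over all days or within each
day ("each day separately"); pooled correlations are unweighted across
modules (event-count weighting is exposed upstream but not default).
Condition comparisons (e.g. baseline vs. GABA-A blockade) use the paired
t test on matched electrodes; unpaired electrodes are excluded with a
warning.  Omnibus ANOVA/post-hoc machinery is deliberately out of scope —
stock routines (`scipy`/`statsmodels`/`pingouin`) apply directly to the
tidy outputs.

## Synthetic data: what it emulates, what it does not

Each axon's emission train superposes a homogeneous Poisson process
(tonic) and Poisson-onset bursts whose intra-burst ISIs are uniform
within ±20% of 7 ms, giving ≥ 21 ms duration at the 4-spike minimum —
satisfiable by the burst criteria by construction.  A 2 ms refractory
period thins the merged train so no emission collides within the
detector's dead time.  Arrivals follow the kinematic rule
`arrival_k = emission + position_k / v (+ jitter)`, with optional
distinct proximal/distal velocities split at 500 µm; Gaussian
per-electrode jitter is redrawn (then clipped) to preserve arrival order,
which the matcher assumes.  Each arrival survives independently with
`detection_prob`; a configurable fraction of axons mirrors its emission
train onto one reservoir electrode of its module.  Emissions whose
arrivals would pass the recording end are dropped at generation time so
ground-truth counts match the emitted table exactly.

Stimulation sessions insert, per trial, a direct chain with probability
`p_direct` at a uniform 5–15 ms latency propagating at the evoked
velocity over the 4 recording electrodes, and a polysynaptic chain with
probability `p_late` at a uniform latency in 35–950 ms; spontaneous
background superimposes.  Raw-trace rendering places a negative-leading
biphasic template (~1 ms support) scaled to 40–1,000 µV (log-uniform when
a range is given) in white Gaussian noise, reproducing the observed
SNR band of roughly 2–35, with saturating artifacts at pulse times.

Defaults: 0.5 Hz tonic, 0.1 bursts/s, 6 spikes/burst, 3 axons/channel,
velocities drawn from N(0.55, 0.15) clipped to [0.15, 1.2] m/s (matching
the observed domain occupancy, peak ~0.5–0.6), 0.05 ms jitter, detection
probability 0.95, noise σ 10 µV.  Spontaneous in-channel firing rates are
not quantified in the source data; these are realistic calibration
values, not claims.

Not modelled: biophysical cable properties, axon growth or
age-dependent velocity mechanisms, waveform diversity beyond one
template, electrode impedance differences, bursts coupled across axons.
Consequently, passing recovery tests shows the *analysis* is correct
under the stated statistical structure — not that real recordings satisfy
that structure.

The age-confound generator (`simulate_age_coupled_features`) creates the
maturation pattern directly at the feature level: velocity 0.46 → 0.58 m/s
and burst rate rising linearly with age across 10 recording days, with
independent within-day noise — so pooled feature–velocity correlation is
strongly positive while per-day correlation is null.
`simulate_disinhibition` triples firing/burst rates with lognormal
spread while leaving velocity unchanged up to ±0.02 m/s measurement
noise.

## Problem sizes and determinism

Every stochastic routine consumes a single integer seed through
`numpy.random.default_rng`; identical config + seed reproduces identical
outputs, which the pipeline manifest verifies by content hash.  The test
and acceptance workloads use 60 s single-axon recordings for velocity
recovery (≈ 150–300 events/channel), 1,000 randomized instances for each
oracle-equivalence check, 50 × 180 trials per fidelity point and 20 seeds
for the correlation dissociation — sizes at which the binomial/CLT
tolerances in the tests are meaningful.

## Known limitations

- The matcher is anterograde-only; retrograde propagation would need a
  reversed electrode ordering by the caller.
- No spike sorting: coincident spikes from different axons within one
  sample are collapsed; per-axon attribution of matched events relies on
  velocity separation.
- Peri-stimulus analysis assumes non-overlapping trials (pulse spacing ≥
  trial window); faster protocols require a shortened window scheme.
- The CSV spike format stores doubles with 17 significant digits and must
  be read back with a round-trip float parser (the package's loader does).
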