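# Methods

`meanet` analyses spontaneous activity of developing neuronal cultures
recorded on multi-well micro-electrode array (MEA) plates, in the form the
field's developmental-neurotoxicity (DNT) screens use: repeated 30-minute
recordings of the same 48-well plate across days in vitro (DIV), chronic
compound exposure starting after a DIV 7 baseline, and per-well activity
parameters turned into treatment ratios against solvent (DMSO) controls.
This note documents the models, the estimators, the tunable parameters,
and the choices made where the procedure was genuinely open.

## 1. Detection chain

### Spike detection (optional front end)

The canonical pipeline input is a spike list (electrode, time). When raw
extracellular voltage is supplied instead (12.5 kHz sampling), spikes are
detected by:

1. zero-phase Butterworth band-pass, 200–5000 Hz, order 4 (`sosfiltfilt`);
2. robust noise rms per electrode: median absolute deviation scaled by
   1/0.6745, computed in 10 s windows and summarized by the median across
   windows. The windowed-MAD estimator is insensitive to a sparse minority
   of large spikes (verified: σ recovered within 5% on pure Gaussian noise
   and within 10% with 1% of samples replaced by ±20σ artifacts);
3. threshold crossing at 7 × rms in either polarity; each accepted spike
   is timestamped at the extremum of |v| inside a 2.4 ms pre / 3.6 ms post
   window around the crossing; crossings within the 3.6 ms post-spike
   window are suppressed (dead time).

On pure Gaussian noise the 7σ threshold fires essentially never
(< 0.1 spikes/min over 100 simulated minutes). Electrodes with fewer than
6 spikes/min in the analysis window are excluded from all further
analysis (inclusive threshold: exactly 6.0/min is kept).

### Burst detection (Poisson surprise)

A burst is a cluster of spikes on one electrode that is improbable under
a homogeneous Poisson null at the electrode's mean rate. The surprise of
a candidate run of `n` spikes spanning `T` seconds is

    S = −ln P(X ≥ n),  X ~ Poisson(rate · T),

in natural-log units (nats); the acceptance threshold is S ≥ 10. The mean
rate uses the full observation window, not the span of the spikes: the
window is the observation period. The tail probability is evaluated
through the regularized upper incomplete gamma function, with a
log-domain summation fallback once the tail underflows double precision
(S ≳ 667), so S is exact to ≥ 9 significant digits up to S > 1500.

The search is the classic seed / extend / trim scheme: candidates are
seeded wherever two consecutive inter-spike intervals are below 0.5 × the
mean ISI; the candidate is extended forward while S increases, looking up
to 10 spikes ahead so short dips cannot stop an extension; then spikes
are trimmed from the start while S does not decrease (ties prefer the
shorter burst). Bursts need ≥ 3 spikes. All three knobs (threshold,
minimum spikes, seed factor) are configuration.

An exhaustive oracle (`brute_force_bursts`) scores every contiguous
subsequence and accepts non-overlapping ones greedily by descending S; on
1000 random trains (Poisson background plus planted dense clusters) the
search agrees with the oracle on burst count on ≥ 95% of trains and
recovers ≥ 95% of planted clusters. On homogeneous Poisson trains fewer
than 5% of spikes end up in bursts.

### Network-burst detection

A network burst is a maximal run of well-pooled spikes in which every
consecutive gap is at most a well-adaptive maximum interval, accepted iff
it has ≥ 40 pooled spikes from ≥ ceil(15% of electrodes) distinct
electrodes (3 of 16). The adaptive interval is `C / r_well` with C = 0.25
and `r_well` the pooled spike rate of the well's included electrodes,
clamped to 5–300 ms. The inverse-rate form is this package's documented
dialect: the acquisition software's exact adaptive statistic is
proprietary, and only its dependence on the well mean rate is public.
Participation counts electrodes contributing at least one spike, and the
15% floor is taken over the electrodes that passed the activity filter
(inactive electrodes cannot participate); both choices are configurable.

## 2. The ten well parameters

Computed on the last 20 minutes of each 30-minute recording (the most
stable timeframe); shorter recordings are used in full with a warning.

| parameter | definition |
|---|---|
| n_spikes | pooled spike count over included electrodes |
| n_bursts | total bursts over included electrodes |
| n_network_bursts | network bursts in the well |
| burst_duration_s | mean (end − start) over bursts |
| network_burst_duration_s | mean over network bursts |
| inter_burst_interval_s | mean end-of-burst → next-start gap per electrode, pooled |
| spikes_per_burst | mean spikes per burst |
| spikes_per_network_burst | mean pooled spikes per network burst |
| mean_isi_within_network_bursts_s | mean consecutive pooled-spike interval inside each event, averaged over events |
| synchrony_auc | area under pairwise cross-correlation (below) |

Counts are pooled sums per well rather than per-electrode means — the
later normalization to control makes the scale choice immaterial, and
pooled counts are the simplest auditable convention. Any mean over an
empty set (e.g. network-burst duration in a well without network bursts)
is NaN, never zero, and propagates as missing; a missing raw value makes
that well/parameter's cumulative values missing from that day on.
Nothing is imputed.

**Synchrony.** For each unordered electrode pair (both with ≥ 10 spikes)
the trains are binned at 5 ms; the cross-correlogram over lags |τ| ≤ 100
ms is normalized by √(N_i·N_j), so two identical trains give a zero-lag
peak of exactly 1. The pair score is the normalized correlogram area over
the lag window — equivalently the number of spike pairs whose bin indices
differ by ≤ 20, divided by √(N_i·N_j) — and the well score is the mean
over pairs, clamped to [0, 1]. Under independence the expected pair score
is √(N_i·N_j)·(2L+1)·Δ/T (verified against simulation); strongly
co-bursting wells saturate the clamp at 1, so the score is a
ceiling-limited measure most informative for desynchronizing effects.

## 3. Dose-response statistics

1. **Well inclusion**: wells need ≥ 4 bursting electrodes at the DIV 7
   baseline; a failing well is dropped for the whole experiment.
2. **Cumulative treatment ratios**: per well and parameter, raw values
   are summed over recording days (DIV 7, 10, 14, 17, 21, 24, 28) and
   expressed as % of the sex-matched control mean cumulative value at
   DIV 28. Controls are sex-matched throughout: each sex is normalized to
   its own DMSO wells.
3. **Outlier exclusion**: a value beyond mean ± 2 × sample SD of its
   (parameter, compound, concentration, sex, DIV) group is flagged in a
   single pass (no re-iteration) and removed from every downstream mean
   and test; groups of fewer than 3 values are left untouched. On normal
   groups with the study's condition sizes (12–32) this excludes ≈ 3.7%
   of values. The rule is applied to the ratio values.
4. **Renormalization**: after exclusion the control scaling is recomputed
   so the mean retained-control ratio at DIV 28 equals exactly 100% — an
   identity the pipeline guarantees to machine precision for every
   parameter and sex. The order cumulate → normalize → exclude →
   renormalize is a design choice; it is the only order of the four that
   guarantees the identity exactly.
5. **Benchmark response (BMR)**: the band is the control mean ± the SD of
   retained control ratios pooled across control experiments, per
   (parameter, sex, DIV) (`per_div` mode; a time-averaged half-width is
   available as `time_averaged`). Statistically significant deviations
   smaller than the band are treated as of limited toxicological
   relevance and are not flagged.
6. **ANOVA**: per (parameter, sex, DIV), one-way fixed-effects ANOVA
   across concentrations with Tukey–Kramer comparisons against control
   (studentized-range p-values, valid for unequal group sizes; verified
   to reproduce `statsmodels.pairwise_tukeyhsd` to 1e-8). Per
   (parameter, DIV), two-way concentration × sex ANOVA with interaction,
   Type-II sums of squares (robust to the unbalanced well counts; empty
   cells are dropped with a warning), fitted with statsmodels.
   Sex-specificity at a concentration is the Tukey-adjusted
   male-vs-female contrast within that concentration, adjusted over all
   concentration × sex cells.
7. **Flags and LOEC**: a cell is an effect iff Tukey p ≤ α (0.05) AND the
   deviation of its mean from the control mean exceeds the BMR
   half-width; direction is the sign (excitation/inhibition). The LOEC
   per compound and sex is the lowest concentration with at least one
   significant parameter at any DIV, or "no effect".

No multiple-testing correction is applied across parameters (beyond
Tukey within a family) — deliberately, to mirror the screening
convention the pipeline implements.

### Calibration note

The mean ± 2SD exclusion is not innocent: trimming both groups before a
t-test shrinks the variance estimate and inflates the test's level from
5% to ≈ 9% (measured by simulation at n = 12). The BMR filter restores
calibration, but only if the band half-width is estimated stably: with a
band from a single experiment's 12 control wells the joint flag rate on
null data is ≈ 6%, while with the band from controls pooled across
experiments — which is how the band is defined here, from *pooled*
control experiments — the null flag rate is ≈ 2–3%, below the nominal α.
Practical consequence: derive the BMR from as many pooled control wells
as possible, never from a single plate.

The null flag rate also depends on group size, because the BMR
half-width (one control SD) equals 2.45 / 2.83 / 3.16 standard errors of
a mean difference at n = 12 / 16 / 20 wells per group: the measured
joint null rates (trimmed t-test AND above pooled band) are ≈ 2.6%,
1.1% and 0.4% respectively. At n = 12 the rate estimate from simulated
studies is additionally noise-dominated, because the well-level rate
multipliers are shared by all count parameters of a well, so a single
collective draw can push a whole replicate's cells over the band at
once. The verification suite therefore demonstrates null calibration at
n = 20 wells per condition and sex (within the 12–32 design range) with
the pooled band; at the low end of the design range the procedure should
be considered marginal, which is itself a practically relevant finding
about the mean ± 2SD-then-test convention.

## 4. The synthetic-data generator

The generator emulates what the analysis assumes about sex-separated
developing rat cortical cultures on 48-well, 16-electrode plates; it is a
statistical emulation, not a biophysical model (no membrane dynamics, no
synapses, no pharmacokinetics).

**Development.** Activity is scaled by a raised-cosine ramp from 0 at
DIV 4 (onset) to 1 at DIV 10 (plateau), flat thereafter; only
monotonicity and the endpoints are contractual. Under defaults every
well is active at DIV 7 (ramp value 0.5) and control activity is
statistically stationary from DIV 10 to DIV 28.

**Activity model.** Network-burst events arrive as a homogeneous Poisson
process (default 6/min at plateau). Each event recruits a
Binomial(n_electrodes, 0.6) electrode subset; each recruited electrode
emits a Poisson-count volley at 60 spikes/s over a lognormal duration
(mean 0.25 s, shape 0.4), starting at the event time plus Gaussian onset
jitter (σ = 10 ms). Independent tonic background spiking runs at 0.3
spikes/s per electrode. The implied plateau electrode rate is ≈ 1.2
spikes/s and pooled network-burst events carry ≈ 140 spikes — plausible
for mature cortical cultures on multi-well MEAs, and comfortably above
the 40-spike detection floor. Well-to-well heterogeneity is a lognormal
rate multiplier with CV 0.2 per well, constant across days.

**Sex baseline.** Male wells get ×1.25 network-burst rate and ×0.8
within-burst spike rate on DIV 10–17 only. This reproduces the reported
pattern — more network bursts in males in that window — while leaving
the total firing rate unchanged, so both sexes remain stationary in
well-wide spike counts from DIV 10 on. Both factors and the DIV window
are configuration.

**Compound effects.** A condition is a map from generative knobs
(network-burst rate, within-burst rate, burst duration, recruitment,
background rate, synchrony jitter) to multiplicative factors, applied
only from a hard onset DIV and only to wells of the scoped sex. The hard
onset is the simplest mechanism reproducing effects that appear only
after 1–2 weeks of exposure; gradual accumulation is out of scope.

**Reproducibility.** Every (plate, well, DIV) gets its own RNG stream
derived from `SeedSequence([seed, plate, well, div])` (well-level
multipliers from `[seed, plate, well]`), so identical config + seed gives
byte-identical spike lists and adding wells or days never perturbs
existing ones.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: electrode noise and artifacts, culture
death or detachment, non-Poisson event timing (real cultures show
super-bursts and oscillations), within-burst rate profiles
(accelerating/decelerating volleys), cross-well coupling, plate/edge
effects, and gradual (non-step) exposure dynamics. Real effect sizes and
variances will differ; the generator's role is to make every pipeline
stage verifiable end to end, not to predict compound potencies.

## 5. Problem sizes used in the test suite

The verification suite runs a reduced study chosen once for desk-scale
execution: 6 electrodes/well, 600 s recordings (analysed in full),
network-burst rate 3/min, within-burst volleys of ≈ 15 spikes, 12 wells
per condition × sex cell — the lower end of the study design the
pipeline targets. Under these conditions an injected +50% network-burst-
rate effect with onset DIV 14 in males is recovered (significant and
above-BMR for the network-burst count, flagged sex-specific) at DIV ≥ 17
in well over 80% of replicates, and sham exposures are flagged at below
the nominal α when the BMR band is pooled across control experiments.

## 6. Known limitations

- The adaptive network-burst interval and the synchrony normalization are
  documented dialects of proprietary definitions; absolute parameter
  values are not bit-comparable with vendor software, though the
  normalized treatment ratios largely cancel dialect constants.
- The surprise search is a greedy hill-climber; on adversarial trains it
  can split or merge bursts differently from the exhaustive oracle
  (observed on < 5% of random trains, with no count bias).
- `flag_and_summarize` fits one ANOVA per (parameter, sex, DIV) cell;
  wells recorded repeatedly over days are not modelled longitudinally
  (no mixed effects — deliberately out of scope).
- The synchrony score saturates at 1 for strongly co-bursting wells and
  has little dynamic range for pro-synchrony effects.
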