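# Methods

`thetapop` analyses simultaneously recorded hippocampal (DG–CA3–CA1)
populations around optogenetic perturbation of adult-born dentate granule
cells (abDGCs), and ships a seeded synthetic-session generator that
emulates the statistical structure those analyses assume.  This note
documents the models, the estimators, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Theta segmentation and phase

Raw LFPs are decimated to 1,250 samples/s through an order-8 Chebyshev
type-I anti-alias filter applied forward–backward; the filter's pass band
is normalised to unit DC gain so constant signals pass unchanged.  The
trace is then split into a theta (5–12 Hz) component and the envelope of
slower activity.  The default decomposition is a zero-phase Butterworth
band-pass plus a <5-Hz low-pass whose Hilbert envelope forms the
acceptance threshold; a self-contained cubic-spline sifting decomposition
(`mode="emd"`, intrinsic-mode functions classified by dominant Welch
frequency) is provided as an alternative.  Sifting is stochastic across
implementations and sift parameters, so the band-pass mode is the tested
default and the sifting mode is validated only by the cycle-recovery
property below.

A theta cycle is a span between consecutive troughs whose absolute values
exceed the slow envelope, containing at least one supra-threshold peak,
with trough-to-trough duration in **[71, 200] ms** (≈14 Hz down to 5 Hz).
Phase is piecewise-linear through five anchors — trough −180°, ascending
zero −90°, peak 0°, descending zero +90°, trough +180° — so the **theta
peak is the 0° reference**.  Zero crossings are defined on the theta
component with ties resolved to the earlier sample.  Samples outside
accepted cycles have undefined (NaN) phase and spikes there are excluded
from all phase analyses.  On a clean 8-Hz synthetic trace the segmentation
recovers >95% of generated cycles at 125 ± 1 ms with ~1° RMS phase error;
on a jittered noisy trace the RMS error stays below 10°.

Slow-gamma epochs are intervals where the 30–55-Hz Hilbert envelope
exceeds its mean by 2 s.d.; gamma phase coupling additionally requires
≥200 spikes inside epochs.

## Opto-tag classification

PSTHs are built in bins relative to pulse onset and Z-scored against a
pre-onset baseline binned at the same width.

* **ChR2 (5-ms, 473-nm pulses):** a unit is tagged when some 1-ms bin
  within 10 ms of onset has z > 3 (strict); the latency is the left edge
  of the first such bin; the baseline is the 200-ms pre-onset epoch.  The
  Z-score here is **trial-resolved**: the response probability per event
  is compared with the mean and s.d. of per-event baseline bin counts.
  This is a deliberate design choice: Z-scoring the event-summed counts
  makes z > 3 reachable by Poisson counting noise alone (the summed-count
  tail beyond +3 s.d. is ~0.2–1% per bin, i.e. several percent across a
  10-bin window, at any attainable rate), which is incompatible both with
  a usable false-discovery rate and with the ~0.1% shuffle FDR this
  criterion is known to achieve in practice.  The trial-resolved form
  demands response *reliability* across pulses, detects 100% of
  deterministic short-latency responders, and passes ≤1% of rate-matched
  Poisson units.
* **ArchT (30-s, 561-nm pulses):** z < −2 (summed-count baseline, 4-s
  epoch) in at least 60% of the twenty 800-ms bins covering the 16 s after
  onset; light-suppressed interneurons use 40%.  Both fractions are
  inclusive (12/20 = 60% passes).  A trial-resolved Z is *not* used here:
  a reduction of −2 per-event s.d. from a low baseline is unreachable, and
  detecting a decrease needs the longer summed window.

The false-discovery rate of either criterion is estimated by circularly
shifting each unit's spike train by a uniform random offset (wrapping
within the session) and re-classifying; circular shifts preserve
inter-spike-interval structure, making them a conservative null for
event-locked tests.  Analyses declared laser-off mask spikes inside
[onset, offset + 100 ms].

## Single-unit tuning

Place maps bin the 41-cm arena at ~1.4 cm (30 × 30; 20 × 20 and 10 × 10
for the multi-resolution information variants), smooth spike-count and
occupancy maps separately with a Gaussian kernel of 1.2 bin widths, and
divide.  Bins with <0.1 s raw occupancy count as unvisited.  Positions are
interpolated linearly to spike times; spikes outside the tracked interval
are dropped.  Spatial information per spike is
`Σ P_i (λ_i/λ) log2(λ_i/λ)` with `λ = Σ P_i λ_i`; it is non-negative and
invariant to uniform rate rescaling.  Its null distribution circularly
shifts spike times by ≥20 s relative to position.  Spatial coherence is
the Pearson correlation, on the *unsmoothed* map, between each interior
visited bin and the mean of its available visited 8-neighbours.

Theta (and gamma) coupling is summarised by the circular mean direction
(preferred phase) and mean resultant length of spike-phase unit phasors.
Rate-matched control units are selected greedily by minimal |log-rate
difference| without replacement; the log scale treats rate differences as
multiplicative, which is the natural scale for log-normally distributed
firing rates.

## Cross-correlograms and theta-phase-preserving surrogates

The CCG between a reference and a target train is the conditional
probability P(target spike | lag), over ±160 ms in 0.8-ms bins (400 bins),
normalised by the reference spike count.  Because hippocampal spiking is
theta-modulated, raw CCGs of independent but theta-locked pairs ripple at
theta.  Surrogate target trains move every spike to a uniformly random
accepted cycle (with replacement; an occupancy-weighted option exists) at
the time corresponding to its original phase, exactly conserving the
spike count and the per-spike phase multiset.  The difference CCG
(observed − mean of 500 surrogates) is statistically flat for purely
comodulated pairs (the per-bin surrogate s.d. is retained for that check)
and peaks at the true lag for directly coupled pairs; the
tagged-cell → interneuron motif produces its peak in the 20–40-ms lag
window.  Phase-to-time inverse mapping stays inside the sampled cycle by
construction, so no surrogate spike can acquire undefined phase.

## Population sparsity, silencing responses, co-firing, dimensionality

Population vectors are spike counts of simultaneously recorded principal
cells in half-open windows.  Sparsity uses the Gini index
`S = Σ(2i−N−1)x_i / (N Σx_i)` (ascending order) and, as a
cross-validation, the Hoyer measure
`S = (√N − Σ|x_i|/√(Σx_i²)) / (√N − 1)`.  Both are scale- and
permutation-invariant, rise under count transfers toward richer units,
and are undefined for all-zero vectors — such windows are excluded from
means with the excluded fraction reported.

* **Activation:** Gini in the 100-ms windows immediately before vs after
  each 5-ms pulse, averaged within session to one paired (pre, post)
  value.  The within-session pairing controls for differences in the
  number of recorded cells across days.
* **Silencing:** the 5-s epochs immediately before and during each 30-s
  pulse delimit the conditions; sparsity itself is still estimated on
  ~theta-cycle-long (100-ms) vectors tiling those epochs and averaged per
  condition.
* **Silencing responses:** per-unit Z-scored spike counts in 875-ms bins
  during light, against a 5-s pre-onset baseline, summed over the
  laser-on bins; group traces are displayed smoothed with a three-point
  moving average; an absolute-rate variant divides laser-on/off spike
  totals by the respective durations.
* **Co-firing:** Pearson correlations of per-theta-cycle counts for
  CA3–CA1 cell pairs; zero-variance units are excluded with a count.
* **Dimensionality:** PCA of the mean-centred (never variance-scaled)
  cells × theta-cycles matrix; the estimate is the smallest number of
  components whose cumulative explained variance reaches the target
  (default 80%, sweep over 70–90% supported), and the score divides by
  the number of cells.  Matrices require more than ten simultaneously
  recorded principal cells, and off/on comparisons require identical unit
  sets.  When the two conditions contribute unequal numbers of cycles the
  matrices are subsampled to matched widths before comparison: sample
  top eigenvalues are inflated for narrower matrices, and this estimation
  bias otherwise masquerades as a condition effect.

Both the co-firing and the dimensionality matrices contain the CA3 and
CA1 principal cells; the session-level directional comparisons of
sparsity also use CA vectors.  At the generator's session scale a single
tagged cell is ~3% of the population, so including it would let its own
silenced (all-zero) entry dominate the Gini comparison — an artefact of
small simulated ensembles, not a property of the downstream effect being
tested.

## Estimation statistics

All tests are two-sided.  Permutation tests enumerate the complete
arrangement set when it has at most 2¹⁵ members (sign flips of paired
differences; label reassignments otherwise) and fall back to Monte-Carlo
(default 10,000 draws) with the add-one correction p = (b+1)/(m+1).
Effect sizes are mean/median/paired-mean differences with percentile 95%
bootstrap intervals (default 5,000 resamples; BCa deliberately not the
default, matching estimation-plot convention).  The Watson–Wheeler test
maps pooled circular ranks to uniform scores and refers
`W = 2 Σ (C_g²+S_g²)/n_g` to χ² with 2(k−1) degrees of freedom; ties are
broken by stable ordering and small groups (<10) trigger a warning.
Novelty preference is the percentage of object-exploration time on the
novel object (chance 100/n_objects; 25% with four objects).  No
multiple-testing correction is applied by default (per-comparison
reporting); a Benjamini–Hochberg helper is available.

## The synthetic-session generator

The generator is first-class, tested code; its defaults are the study
conditions for every calibration above.

* **Trajectory:** reflective Ornstein–Uhlenbeck walk in a 41-cm square
  box at 25 frames/s, speeds clipped at 30 cm/s.
* **LFP:** 1,250 samples/s; theta as a frequency-wandering 8-Hz cosine
  (s.d. 0.4 Hz, ~1-s smoothing) with the generating phase retained as
  ground truth (peak = 0°); 1/f background (40 µV RMS); optional
  slow-gamma bursts.
* **Units:** per session 1 tagged abDGC (log-normal rate, median 2.3 Hz),
  8 other DG + 10 CA3 + 14 CA1 principal cells (medians 1.0 Hz in DG and
  1.8 Hz in CA, log-s.d. 0.7), and 6 interneurons (median 12 Hz).
  Principal cells carry Gaussian place fields (s.d. 5–12 cm) and
  von-Mises theta locking; the tagged subpopulation is more strongly
  locked (κ ≈ 0.8–1.5 vs 0.3–0.8) near the descending phase, as in the
  recordings being emulated.
* **Spiking:** inhomogeneous Poisson by thinning of
  `rate(t) = base × place × theta × gain × opto / inhibition`.  The place
  factor is normalised by its mean over the actual trajectory and the
  von-Mises factor `exp(κcos(φ−µ))/I₀(κ)` integrates to one over a cycle,
  so both are rate-preserving.  Thinning (rather than time-rescaling)
  keeps the realised intensity directly comparable to the analytic one.
* **Shared excitability:** all units carry a slow log-normal gain (mean 1,
  log-s.d. 1.2, ~10-s correlation — the timescale of behavioural-state
  fluctuations).  This is what gives simultaneously recorded cells their
  correlated count statistics; its 10-s persistence also means adjacent
  5-s comparison epochs share nearly the same gain, as adjacent epochs of
  a real session do.
* **Light:** 5-ms 473-nm pulses at uniform 0.5–2.5-s inter-stimulus
  intervals (activation) or 30-s 561-nm pulses at uniform 5–22-s
  intervals (silencing).  ChR2-tagged cells emit a near-deterministic
  evoked spike ~3 ms after each blue pulse; ArchT-tagged cells are
  multiplicatively suppressed (gain 0.05) for the pulse duration.
* **Motif:** each tagged-cell spike multiplies every interneuron's rate
  by (1 + 25·drive) in a 20–40-ms lag window; principal cells are
  divisively suppressed by the *pooled* interneuron spiking through a
  fast (80-ms) and a slow (300-ms) integration window, normalised per
  cell to its laser-off mean so unperturbed rates average `base_rate`.
  Low-rate principal cells receive proportionally stronger inhibition
  (weight ∝ (1.5 Hz / base_rate), clipped to [0.3, 3]): the sparsest
  cells are the ones most strongly held down by inhibitory control, so
  disinhibition recruits them preferentially.  An earlier design that
  wired each principal cell to a single interneuron was rejected: it
  injected group-structured correlated variance during laser-off that
  dominated the small-ensemble eigenspectrum.  Because the interneurons
  also carry the shared gain, the pooled divisive term acts as a
  normalisation that partially cancels shared fluctuations; silencing the
  tagged drive weakens it, so principal rates rise, the shared gain
  expresses more fully (co-firing up, dimensionality down) and counts
  equalise (sparsity down), while activating the tagged cell transiently
  deepens it (sparser post-pulse vectors).  The motif and suppression
  gains are free parameters of the generator, chosen once so that these
  directional effects are reproducible across seeds; they are not
  calibrated to any measured effect size.
* **Determinism:** every stream derives from `(rng_seed, key)` via
  `SeedSequence`, with per-unit sub-streams, so a fixed seed reproduces a
  session bit for bit and single units are reproducible in isolation.

### Problem sizes used by the tests and the acceptance script

Theta segmentation is checked on one 600-s clean session; tagging
calibration on 50 deterministic responders, 500 rate-matched Poisson
units (120 pulses) and 40 partially silenced units (20 pulses); surrogate
checks on 20 independent pairs (120 s each, 500 surrogates) plus one
300-s motif pair; statistical calibration on 2,000 null permutation runs
and 500 bootstrap-coverage runs; the directional surface on 20 activation
sessions of 90 s and 20 silencing sessions of 420 s.  These sizes were
chosen so each check is decisive (directional p-values ≤ 0.02 on two
disjoint seed sets) while a full run stays comfortably interactive.

### What the synthetic benchmark does not show

The generator reproduces the *statistical structure* of the recordings —
log-normal rates with a high-rate tagged subpopulation, theta-nested
sparse population vectors, phase locking, light-evoked excitation and
suppression, a 20–40-ms feed-forward lag — not their biophysics.  Passing
tests demonstrate that the estimators recover known ground truth and that
the directional network effects follow from the assumed circuit motif;
they do not validate the motif itself against real tissue, nor calibrate
effect magnitudes, spike-sorting artefacts, non-Poisson firing (bursting,
refractoriness), multi-channel volume conduction, or behavioural
confounds.  Effect magnitudes in the synthetic benchmark are generator
choices, and real sessions are an order of magnitude richer in cell count
than the simulated ensembles.

## Known limitations

* The sifting-based decomposition is a minimal implementation (mirror-
  padded extrema, SD stopping rule, no masked sifts); it recovers clean
  and mildly noisy theta but is not an audited replacement for a mature
  sifting library.
* `read_session` validates structure and time-base alignment but not
  units' physiological plausibility.
* The CCG stores lags at 0.8-ms bin resolution only; sub-bin latency
  estimation is out of scope.
* Waveform-based cell-type classification is consumed as metadata, never
  computed; the optional rate heuristic (mean rate > 5 Hz ⇒ interneuron)
  is provided for convenience and used nowhere in the tests.
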