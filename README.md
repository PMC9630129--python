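# thetapop

Theta-paced analysis of hippocampal ensemble recordings around
optogenetic perturbation of adult-born dentate granule cells (abDGCs).

During exploration, hippocampal principal cells (PCs) in DG, CA3 and CA1
fire sparsely within the ~125-ms frames of individual theta cycles: only
a few cells out of the recorded population are co-active in any one
cycle.  `thetapop` implements the analysis stack used to ask how a small,
optogenetically tagged subpopulation of young granule cells shapes that
population structure:

* **Theta segmentation** — LFP decimation (order-8 Chebyshev-I
  anti-aliasing), theta/slow decomposition, trough-to-trough cycle
  detection with the 71–200-ms duration rule, and per-sample phase by
  piecewise-linear interpolation through cycle anchors (peak = 0°).
* **Opto-tagging** — PSTH-based classification of light-driven units:
  ChR2 (z > 3 within 10 ms of a 5-ms pulse, 1-ms bins) and ArchT
  (z < −2 in ≥60% of 800-ms bins over 16 s of a 30-s pulse), with a
  circular-shift shuffle false-discovery rate.
* **Tuning** — place maps (1.4-cm bins, Gaussian smoothing at 1.2 bin
  widths), Skaggs spatial information `Σ P_i (λ_i/λ) log2(λ_i/λ)` with a
  spike-shuffle null, spatial coherence, theta/gamma phase coupling
  (preferred phase and mean resultant length), rate-matched controls.
* **Surrogate-corrected cross-correlograms** — conditional-probability
  CCGs (±160 ms, 0.8-ms bins) against 500 theta-phase-preserving
  surrogates, isolating spike-time coupling beyond shared theta
  modulation.
* **Population statistics** — Gini and Hoyer sparsity of theta-paced
  population vectors with within-session laser pairing, Z-scored
  silencing responses (875-ms bins, summed over the light period),
  CA3–CA1 co-firing, and PCA dimensionality (components to 80% variance,
  scored per recorded cell).
* **Estimation statistics** — exact/Monte-Carlo two-sided permutation
  tests, bootstrap effect sizes with percentile 95% CIs, the
  Watson–Wheeler circular test, and the novelty-preference index.
* **Synthetic sessions** — a seeded generator of ground-truth recordings
  (trajectory, LFP with known phase, laser schedules, inhomogeneous-
  Poisson spikes with place/theta/opto modulation and a
  tagged-cell → interneuron → principal-cell motif) used to calibrate and
  validate every analysis above.

The sparsity of a population count vector x (ascending, N cells) is

    S_Gini  = Σ_i (2i − N − 1) x_i / (N Σ_i x_i)
    S_Hoyer = (√N − Σ|x_i| / √(Σ x_i²)) / (√N − 1)

both 0 for perfectly even vectors and maximal when one cell holds all
spikes.

## Worked example

Generate a 90-s activation-protocol session (5-ms 473-nm pulses), tag the
light-driven unit, segment theta, and measure the population effect:

```python
import numpy as np
from thetapop import (SimConfig, make_session, classify_all, segment_theta,
                      phase_coupling, activation_sparsity_effect)

cfg = SimConfig(duration=90.0, protocol="activation", rng_seed=7)
session = make_session(cfg)

tags = classify_all(session.spikes, session.laser)
tagged = [t for t in tags if t.label == "chr2_tagged"]
print(f"opto-tagged units: {[t.unit_id for t in tagged]}, "
      f"latency {1e3 * tagged[0].latency:.1f} ms")

cycles = segment_theta(session.lfp)
print(f"theta cycles accepted: {cycles.n_cycles} "
      f"(median duration {1e3 * np.median(cycles.durations):.1f} ms)")

pc = phase_coupling(cycles.phase_of(session.spikes.times(tagged[0].unit_id)))
print(f"tagged-cell theta preference: {pc.preferred_phase:.0f} deg, "
      f"MRL {pc.mrl:.2f} ({pc.n_spikes} spikes)")

d_gini = activation_sparsity_effect(session.spikes, session.laser, cfg.duration)
print(f"CA population Gini change after light pulses: {d_gini:+.4f}")
```

Output:

```
opto-tagged units: ['abdgc_00'], latency 3.0 ms
theta cycles accepted: 713 (median duration 125.6 ms)
tagged-cell theta preference: 113 deg, MRL 0.35 (367 spikes)
CA population Gini change after light pulses: +0.0359
```

The single ChR2-expressing granule cell is recovered by its ~3-ms evoked
response; theta cycles sit at the expected ~125 ms; the cell is
theta-locked (mean resultant length 0.35); and the CA population vectors
in the 100 ms after each pulse are sparser (higher Gini) than in the
100 ms before — the feed-forward sparsification effect.

A command-line interface wraps the same pipeline
(`thetapop simulate|theta|tag|tuning|ccg|sparsity|cofire|dim|run-all|stats`),
reading/writing plain TSV/JSON session bundles; see `thetapop --help`.

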