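# cohear

Analysis pipeline for **coincidence-dependent integration of harmonic
sounds in auditory cortex**, built for the kind of study that combines
mouse vocalization acoustics, two-photon calcium imaging of cortical
populations, extracellular electrophysiology with optogenetics, and go/no-go
psychophysics. Real recordings of this kind are rarely deposited, so the
package ships a first-class synthetic-data module that generates
ground-truthed inputs for every stage, and the test suite verifies each
analysis by parameter recovery against the planted truth.

## What it computes

**Vocal harmonics.** Syllables are detected by amplitude threshold
(10 × baseline SD, bounds at 5 × SD, 15 ms margins), spectrogram contours
are traced (frequency-axis detrending, 3×3 median filter, Frangi ridge
enhancement, flood-fill components, ≥ 7 ms duration), and each 1.4 ms
segment is matched against harmonic templates over a grid of candidate
fundamentals F0 by minimizing

```
EF = sqrt( (1/n) Σ_f ((f·F0 − F_real) / F_real)² )
```

where `f` is the harmonic order assigned to each observed component
frequency `F_real`. Segments with EF < 0.5 are judged harmonic.

**Stimuli.** Harmonic stacks at integer multiples of F0 (e.g. ten tones at
4 kHz F0 up to 40 kHz), temporal-coincidence manipulations (Δonset from
−45 to 45 ms in 15 ms steps applied to the lower half of the stack or to
the fundamental alone), spectral jitter (uniform ± F0/2 per component),
log-spaced pure-tone sets (17 frequencies, 4–64 kHz, three levels), and
block-randomized presentation schedules.

**Imaging responses.** Ring-background subtraction
`F = F_cell − 0.9·F_bg` with a 3% brightness inclusion rule, per-trial
ΔF/F with a 20 a.u. denominator offset, 1 s area-under-curve amplitudes, a
two-criterion significance test (suprathreshold for ≥ 0.5 s in more than
half of trials AND in the trial mean; thresholds 3.3/1.6/2.6 baseline SD
for pyramidal/SOM/PV cells, calibratable by ROC to a 90% true-positive
rate), the coincidence index `CI = (C − S)/(C + S)` and linearity index
`LI = (H − S)/(H + S)` with negative amplitudes clipped to zero, and
CF/BW70 tuning metrics.

**Ensembles and networks.** Max-normalized condition × ROI population
matrices, PCA of ensemble trajectories over Δonset, √N-normalized Euclidean
distance and correlation geometry, NMF clustering (k = 3, best of 100
restarts, pairs below 0.5 coefficient dominance labeled "others"),
cross-F0 membership overlap permutation tests, and trial-to-trial noise
correlations with distance-, SD- and SNR-matched control pairs.

**Electrophysiology and behavior.** PSTHs (10 ms bins, baseline
subtraction), positive-going evoked responses, single-exponential
optogenetic-suppression fits (latency, τ, floor) on 0.5 ms PSTHs, the
equal-variance d′, and psychometric logistic fits on the log-modulus scale
`x = sign(Δ)·log10(1 + |Δ|)` giving the half-max Δonset (behavioral
threshold) and its fractional broadening under cortical inactivation.

## Worked example

```python
import numpy as np
from cohear import ensemble, imaging, synth

cfg = synth.PopulationConfig(
    f0s=(4000.0,),
    n_per_archetype=(("negative_shift", 6), ("positive_shift", 6),
                     ("coincidence", 6), ("nonresponsive", 2)),
    trial_noise_sd=0.1, trace_noise_sd=0.02, seed=0,
)
session = synth.generate_population(cfg)          # traces + ground truth
table = imaging.session_response_table(session.session)

stim = session.stim_table.set_index("stim_id")
table["delta_onset"] = stim.loc[table.stim_id, "delta_onset"].to_numpy()
pm = ensemble.build_population_matrix(table, np.array(cfg.delta_onsets))
clusters = ensemble.nmf_cluster_assign(pm, n_restarts=20, seed=0)
print(clusters.assignments.cluster.value_counts())

roi = int(session.truth.roi[session.truth.archetype == "coincidence"].iloc[0])
grp = table[table.roi == roi].set_index("stim_id")
c, s = grp.loc["h4000_d+0", "amplitude"], grp.loc["h4000_d-30", "amplitude"]
print(f"C = {c:.3f}  S = {s:.3f}  CI = {imaging.coincidence_index(c, s):.3f}")
```

Output:

```
cluster
negative_shift    6
positive_shift    6
coincidence       6
Name: count, dtype: int64
C = 0.501  S = -0.000  CI = 1.000
```

The 18 responsive cells are assigned to the three planted response
archetypes without error, and a coincidence-preferring cell responds only
to the coincident stimulus (S ≈ 0), giving the boundary value CI = 1.

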