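# curtainkit

Quantification toolkit for single-molecule DNA-curtain experiments on
human condensin I and II (CI/CII): the pentameric SMC motor complexes
that compact DNA during mitosis. In a DNA curtain, many λ-DNA molecules
(48,502 bp) are tethered to a lipid bilayer at nanofabricated chromium
barriers, stretched by buffer flow, stained with YOYO-1 and imaged by
TIRF microscopy. Condensin activity appears in kymographs as a bright
punctum of compacted DNA travelling from the free DNA end toward the
barrier. `curtainkit` turns those kymographs — or pre-tracked
trajectories — into the quantities such a study reports:

* **Compaction events** — free-end tracking, piecewise-linear
  change-point segmentation, per-run velocities (μm/s and bp/s),
  processivities with right-censoring (barrier contact within 1 px,
  protein dissociation, DNA breakage, end of record), lag times, and the
  four-way termination taxonomy (reversal / single-step release /
  stall / complete).
* **Censored survival statistics** — Kaplan-Meier product-limit curves
  with Greenwood 95% bands; the *half-life* is the KM median (smallest
  observed event value with S ≤ 0.5); log-rank and Mann-Whitney U
  comparisons (exact for small samples).
* **Loop-extrusion symmetry** — for U-shaped (doubly tethered) DNA, the
  per-frame left/right side-length ratio is fitted against a reaction
  coordinate normalized to [0, 1]; an event is *asymmetric* (one-sided)
  when the fitted slope β falls strictly outside μ ± 5σ of a calibration
  built from known-symmetric events (reference: μ ≈ 0.03, σ ≈ 0.07).
* **Photobleaching step counting** — penalized piecewise-constant
  change-point fits count discrete ≥3σ downward steps to infer how many
  labeled condensins act on a DNA.
* **Biochemical fits** — the quadratic ligand-depletion binding isotherm

      FP(C) = FP_max/(2[DNA]) · ((C+[DNA]+K_d) − √((C+[DNA]+K_d)² − 4·C·[DNA]))

  fitted globally over replicate fluorescence-polarization titrations,
  and ATPase rates from linear fits of the hydrolyzed ADP fraction in
  the linear range, rescaled by [ATP]/[enzyme].
* **A synthetic-data generator** with full ground truth — stochastic
  compaction initiation over a 20-min window, lognormal velocities,
  exponential (memoryless) processivities, competing release hazard,
  stalls and gradual reversals, nucleosome collisions (~3–4 per DNA,
  ~80% unimpeded bypass), two-sided vs one-sided U-loop growth,
  stepwise bleaching traces, and noisy titrations/time courses — so
  every stage of the pipeline is verifiable without raw microscope data.

## Worked example

Run the full synthetic pipeline (simulate → quantify → survival /
symmetry / bleaching / fits) and print the JSON report:

```bash
curtainkit report --seed 1 --out demo_out
```

Selected output (abridged):

```json
{
  "compaction": {
    "n_molecules": 60, "n_events": 57,
    "velocity_median_um_s": 0.155, "velocity_median_bp_s": 699.9,
    "termination_fractions": {"complete": 0.28, "stall": 0.51,
                              "reversal": 0.18, "release": 0.035}
  },
  "survival": {"half_life_um": 8.41, "half_life_kbp": 37.96,
               "n": 57, "n_censored": 23},
  "symmetry": {"frac_symmetric": 0.783,
               "calibration": {"mean": 0.0076, "sd": 0.0708, "k": 5.0},
               "label_accuracy_vs_truth": 1.0},
  "photobleaching": {"histogram": {"1": 26, "2": 13, "3": 1}},
  "biochemistry": {
    "fp": {"true_kd_um": 3.0, "fit_kd_um": 3.0191, "fit_kd_se": 0.1333},
    "atpase": {"fit_basal_rate": 0.8215, "fit_fold": 2.5819}
  }
}
```

Reading this: 57 compaction runs were detected on 60 simulated
molecules; the median detected velocity is 0.155 μm/s (≈700 bp/s under
the 10.75 μm mean extension of flow-stretched λ-DNA); the KM median
processivity is 8.4 μm with 23 of 57 events right-censored; the U-loop
classifier labels 78% of events two-sided with a calibration spread
(σ ≈ 0.07) matching the scale measured on real symmetric events; the
binding fit recovers the ground-truth K_d = 3.0 μM to within one
standard error, and the ATPase fit recovers the basal rate and its
2.5-fold DNA stimulation.

Individual stages are available as subcommands (`curtainkit simulate`,
`quantify`, `survive`, `symmetry`, `bleach`, `fit-fp`, `fit-atpase`)
and as a plain Python API:

```python
from curtainkit import (SimParams, simulate_dataset, segment_trajectory,
                        extract_events, km_estimate, half_life)

trajs, truth = simulate_dataset(SimParams(seed=1, n_molecules=100))
events = [e for t in trajs for e in extract_events(segment_trajectory(t), t)]
curve = km_estimate([e.processivity_um for e in events],
                    [e.censored for e in events])
print(half_life(curve))
```

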