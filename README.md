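# phaselock

Source-space phase-locking-value (PLV) connectivity analysis for
resting-state MEG/EEG, with cluster-based permutation group statistics —
plus a synthetic coupled-oscillator cohort generator so the entire chain
can be validated end-to-end without access to real recordings.

The package targets the kind of study that asks whether a clinical group
(here: frail vs robust older adults) shows altered band-limited
synchronization between brain regions. It covers:

- **Source space** — regular mm-spaced source grids, seed ROIs (explicit
  index sets, sphere unions around MNI coordinates, or labels from an
  atlas volume), resting-state networks as 1.5 cm sphere unions, and the
  spatial adjacency used for clustering.
- **Preprocessing** — 4-s epoch segmentation, zero-phase FIR band-pass of
  epoch windows padded with 2 s of real neighbouring signal, and
  instantaneous phase via the analytic signal.
- **Connectivity** — PLV per source pair,

  `PLV_kl = | (1/T) Σ_t exp(−j(φ_k(t) − φ_l(t))) |`,

  computed per epoch and averaged across epochs; per-subject symmetric
  PLV matrices; seed-to-brain mean-FC vectors (intra-seed pairs excluded)
  and per-network mean-FC scalars.
- **Group inference** — per-source independent-samples t-tests corrected
  by a Monte-Carlo cluster-based permutation test (clusters of spatially
  contiguous suprathreshold sources scored by summed t), and uncorrected
  per-network t-tests.
- **Clinical statistics** — Fisher's exact test for categorical variables,
  Mann-Whitney U (exact by enumeration for small samples, normal
  approximation with tie/continuity corrections otherwise), and
  median [IQR] / n [%] summary tables.
- **Synthesis** — two-group cohorts of narrowband coupled oscillators with
  a closed-form link between the coupling parameter and the expected PLV,
  including a frailty-like hypoconnectivity effect confined to one band
  and one seed-target pair of regions.

## Worked example

Simulate a small cohort in which the frail group loses coupling between a
seed and a contiguous target region in the upper beta band, then run the
seed analysis:

```python
from phaselock.config import validate_config
from phaselock.pipeline import run_pipeline

cfg = validate_config({
    "simulate": {
        "n_robust": 12, "n_frail": 8,
        "grid_shape": [5, 5, 4], "grid_spacing": 10.0,
        "epochs_mean_robust": 10, "epochs_sd_robust": 0,
        "epochs_mean_frail": 10, "epochs_sd_frail": 0, "min_epochs": 10,
        "effect_seed_indices": [0, 1],
        "effect_target_indices": [80, 81, 84, 85, 88, 89],
        "effect_rho_robust": 0.45, "effect_delta_rho": 0.15,
        "effect_band": "upper_beta",
    },
    "bands": [{"name": "alpha_mu", "lo": 8, "hi": 13},
              {"name": "upper_beta", "lo": 20, "hi": 30}],
    "seeds": [{"name": "seed", "laterality": "left", "source_indices": [0, 1]}],
    "cbpt": {"n_permutations": 500},
    "output_dir": "phaselock_out", "rng_seed": 7,
})
report = run_pipeline(cfg)
for c in report.seed_results["seed/upper_beta"]["clusters"]:
    print(c["sign"], round(c["mass"], 1), "p =", round(c["p"], 3), c["sources"])
```

prints

```
positive 44.5 p = 0.002 [80, 81, 84, 85, 88, 89]
negative -2.6 p = 0.828 [59]
positive 2.2 p = 0.972 [14]
negative -2.2 p = 0.974 [94]
```

— one significant positive cluster (robust > frail, i.e. a frail
deficit) whose member sources are exactly the six implanted target
sources, with a cluster mass of 44.5 (the summed t over members) and a
Monte-Carlo p of 0.002 against the max-cluster-mass permutation null;
the remaining single-source clusters are permutation noise, and the same
analysis in the alpha-mu band returns no cluster with p < 0.05.
The `phaselock` command line exposes the same flow
(`phaselock run --config cfg.yaml`, plus `simulate`, `seed-test`,
`rsn-test`, `clinical`, `validate` verbs; exit code 2 flags configuration
errors, 3 a failed stage).

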