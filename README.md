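# flimglia

Metabolic fluorescence-lifetime (NADH-FLIM) analysis of microglial
activation state.

Microglia — the resident immune cells of the central nervous system —
shift their metabolism when they activate, long before their morphology
changes.  That shift is visible in the autofluorescence of NADH: the
free coenzyme decays fast (τ₁ ≈ 400 ps), the protein-bound pool slowly
(τ₂ ≈ 1–3 ns).  A TCSPC FLIM microscope records a photon arrival-time
histogram at every pixel; fitting it with the two-component model

    I(t) = IRF ⊛ [a₁ e^(−t/τ₁) + (1 − a₁) e^(−t/τ₂)],    τₘ = a₁τ₁ + a₂τ₂

gives the free-NADH fraction a₁ and the amplitude-weighted mean lifetime
τₘ.  Surveillant microglia have a shorter τₘ and larger a₁ than
surrounding glia; LPS-induced activation raises τₘ and lowers a₁.

This package is the full analysis chain for such experiments, for
microscopists and analysts who have (or want to prototype against)
time-resolved image stacks plus a co-registered microglial marker
channel (CX3CR1-GFP or Iba1 immunolabel):

* **decay_model** — IRF-convolved bi-exponential forward model, lifetime
  algebra, phasor cross-check;
* **fitting** — SPCImage-style per-pixel pipeline: 5×5 spatial binning,
  photon threshold, bounded Levenberg–Marquardt fits (a fast
  numba-compiled kernel with a numpy reference engine), χ² maps;
* **segmentation** — Otsu marker masking and the
  microglia / non-microglia / background partition;
* **analysis** — pixel → FOV → sample aggregation with a
  pseudoreplication guard, paired/unpaired t-tests and (repeated-measures)
  ANOVA on biological replicates;
* **synthetic_data** — a ground-truth-known generator whose group
  presets are parameterized from published culture, dose-series,
  time-series and brain-tissue group means, so the whole pipeline is
  testable without any external data;
* **io_cli** — plain TIFF + JSON + CSV interchange formats and a
  `flimglia` command-line pipeline (`simulate`, `fit`, `segment`,
  `analyze`, `run-all`).

## Worked example

Simulate a paired vehicle vs LPS (10 ng/mL, 1 h) culture experiment at
reduced scale and run the pipeline end to end, in memory:

```python
import flimglia as fg

design = fg.ExperimentDesign(
    groups={"vehicle": "culture_vehicle_1h", "LPS": "culture_LPS10_1h"},
    n_samples=5,
    n_fovs=5,
    grid=fg.AcquisitionGrid(height=64, width=64),
    seed=42,
)
fov_df, sample_df = fg.run_experiment(design)
print(fg.summarize_group(sample_df).round(2).to_string(index=False))
res = fg.compare_groups(sample_df, "paired_t", parameter="taum")
print(f"paired t ({res.parameter}): t = {res.statistic:.2f}, "
      f"p = {res.p_value:.4f}, significant = {res.significant}")
```

prints

```
  group   compartment  mean_taum  sd_taum  mean_a1_pct  sd_a1_pct  n_samples
    LPS    background     593.33    27.59        77.48       1.06          5
    LPS     microglia     577.43    26.07        78.86       1.29          5
    LPS non_microglia     610.35    28.79        76.16       1.17          5
vehicle    background     577.12    18.24        79.03       1.07          5
vehicle     microglia     553.63    16.86        80.21       0.79          5
vehicle non_microglia     602.03    19.97        78.15       1.26          5

paired t (taum): t = 5.66, p = 0.0048, significant = True
```

Reading the table: fitted microglial τₘ is shorter than non-microglial
τₘ in both groups, LPS raises microglial τₘ (553.6 → 577.4 ps) and
lowers the free-NADH percentage (80.2 → 78.9%), and the paired t-test on
the five biological replicates calls the lifetime shift significant —
the generative presets put the vehicle and LPS microglial means at
548.7 and 566.6 ps, inside one between-sample SD of what the pipeline
recovered.  (The `background` rows are fit-valid ring pixels outside
any cell compartment and are not used in comparisons.)

The same experiment as a shell pipeline, writing TIFF stacks, masks,
maps and CSV summaries:

```bash
flimglia run-all --preset culture_vehicle_1h --preset culture_LPS10_1h \
    --out exp/ --seed 42 --samples 5 --fovs 5 --size 64
```

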