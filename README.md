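# thermolimit

Automated estimation of upper thermal limits from video-tracking data.

Upper thermal limits of small motile animals (zooplankton such as *Daphnia*,
insect larvae, fish fry) are routinely measured as the **time to
immobilisation** — how long an individual keeps swimming when exposed to a
lethal static temperature. Scoring that endpoint by eye is subjective and
drifts within and between observers. `thermolimit` replaces the observer:
given per-individual swimming-velocity time series exported from tracking
software, it detects loss of locomotory function objectively and calibrates
its own detection parameters against experimental biology.

The package is for experimental biologists running acclimation / thermal
tolerance assays with video tracking, and for anyone post-processing
activity traces into censored time-to-event endpoints.

## Method

For a velocity series \(v_t\) (mm/s, sampled at rate \(r\) obs/s), the
detector computes a moving median of width \(w\) observations (robust to
tracking spikes, dropout frames and single-sample pauses) and reports

\[
T_{\mathrm{imm}} = t_0 + \tfrac{1}{r}\,\min\{\, i : \tilde v_i < V_{\mathrm{thresh}} \,\}
\]

where \(\tilde v\) is the smoothed series, \(V_{\mathrm{thresh}}\) (mm/s) the
immobility threshold, and \(t_0\) the time the animal entered its heated
well before recording started. Traces that never cross are **censored**, a
reported outcome rather than an error.

Since \((V_{\mathrm{thresh}}, w)\) are organism- and setup-specific, they are
calibrated by exhaustive grid search (default 100 thresholds × 54 widths =
5400 combinations): for each cell, every subject's \(T_{\mathrm{imm}}\) is
regressed on acclimation treatment (categorical) and body size (continuous),

\[
T_{\mathrm{imm}} \sim \textrm{treatment} + \textrm{size},
\]

and the cell maximising the model \(R^2\) wins — the parameter pair under
which known drivers of thermal tolerance explain the endpoint best. An
interactive model variant, censoring policies, admissibility limits on the
censored fraction and deterministic tie-breaking are described in
[docs/methods.md](docs/methods.md), together with the synthetic-experiment
generator used for verification.

## Worked example

Simulate a five-temperature acclimation experiment (12–28 °C, nine animals
per group, known true immobilisation times), score it at the canonical
detector parameters, and summarise:

```sh
thermolimit simulate --preset validation --seed 1 --out demo/data
thermolimit compute  --tracking demo/data/tracking.csv --meta demo/data/metadata.csv \
                     --v-thresh 0.03 --w 280 --out demo/timm
thermolimit report   --results demo/timm/results.csv --truth demo/data/truth.csv \
                     --out demo/report
```

which logs

```
INFO thermolimit: T_imm for 45 subjects (0 censored); quartiles 1639.7 / 1972.0 / 2597.0 s
INFO thermolimit: recovery vs truth: r=0.9998, bias=-3.2 s, RMSE=13.3 s (n=45)
```

and writes `demo/report/treatment_summary.csv`:

| treatment (°C) | n | mean T_imm (s) | 95% CI (s) |
|---|---|---|---|
| 12 | 9 | 1254.3 | 1080.8 – 1427.8 |
| 17 | 9 | 1759.7 | 1608.1 – 1911.3 |
| 20 | 9 | 1959.0 | 1790.6 – 2127.4 |
| 24 | 9 | 2511.1 | 2350.3 – 2671.9 |
| 28 | 9 | 3079.2 | 2874.7 – 3283.7 |

Warm-acclimated animals stay mobile for longer — the gradient the assay is
designed to resolve — and against the simulator's ground truth the detector
recovers individual immobilisation times to within ~13 s RMSE on ~2000 s
endpoints. Calibration on your own data runs through
`thermolimit optimize --tracking … --meta … --default-grid --out …`, which
exports the full \(R^2\) surface (`surface.csv`), the selected optimum with
its model coefficients, and a surface heatmap. Every command echoes its
effective configuration (`config_echo.yaml`); re-running from the echo
reproduces all outputs byte-identically.

## Input formats

- **Tracking CSV** (long format): `subject_id,time_s,velocity_mm_s`; one row
  per subject × sample; missing velocity (animal not detected) is an empty
  field — never write zero, which means "immobile". Gaps in the time grid
  are refilled as missing samples on read.
- **Metadata CSV**: `subject_id,treatment,body_size_mm,intro_offset_s,block,run`
  (the last four optional). Treatments are categorical labels even when
  numeric-looking.
- **Results CSV**: `subject_id,treatment,body_size_mm,timm_s,censored,n_missing,v_thresh,w`.

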