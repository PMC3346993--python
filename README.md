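# tricalib

Second-order calibration of HPLC-DAD three-way data: quantify analytes
whose chromatographic peaks overlap each other *and* an uncalibrated
sample background, by mathematical rather than chromatographic
separation.

A diode-array detector records a full UV-Vis spectrum at every elution
time, so K injected samples form a data cube `X (time × wavelength ×
sample)`. `tricalib` fits the trilinear model

    x_ijk = Σ_n a_in · b_jn · c_kn + e_ijk

whose essentially unique solution resolves, per chemical species n, an
elution profile `a_n`, a UV spectrum `b_n`, and per-sample relative
amounts `c_n`. Because uniqueness holds even when some species appear
only in the unknown samples, calibration standards and unknowns can be
decomposed jointly and the analytes quantified in the presence of
unmodelled interferents — the *second-order advantage*. The package
provides:

- **`tricalib.datacube`** — the cube + calibration-design data model,
  CSV/YAML directory I/O, average-blank subtraction, time/wavelength
  region selection;
- **`tricalib.simulate`** — a seeded generator of synthetic HPLC-DAD
  studies (overlapping Gaussian peaks, broadband spectra, additive
  noise, baseline, blanks) with exact ground truth;
- **`tricalib.decompose`** — PARAFAC-ALS (alternating least squares,
  optional per-mode nonnegativity) and SWATLD (self-weighted
  alternating trilinear decomposition), plus factor alignment against
  reference spectra;
- **`tricalib.rank`** — chemical-rank estimation via the core
  consistency diagnostic (CORCONDIA);
- **`tricalib.calibrate`** — regression of resolved scores on known
  concentrations through the origin, prediction, recoveries, RMSEP;
- **`tricalib.fom`** — net-analyte-signal figures of merit:
  sensitivity, selectivity, limit of detection (3.3 · s₀ from blank
  estimates);
- **`tricalib.cli`** — a `tricalib` command with `simulate`, `rank`,
  `decompose`, `calibrate`, `fom` and `run` (full pipeline + manifest)
  subcommands.

See `docs/methods.md` for the model assumptions, algorithmic details
and the generator's scope.

## Worked example

The built-in study emulates a two-antibiotic plasma determination: ten
calibration standards of vancomycin + cephalexin only, six "plasma"
samples spiked at known levels but also containing an uncalibrated
interferent, three blanks, 0.5% noise.

```python
import pandas as pd
from tricalib import (FitOptions, align_factors, paperlike_dataset,
                      parafac_als, predict_concentrations, recovery_table)
from tricalib.fom import compute_fom

cube, design, truth = paperlike_dataset(seed=7)          # 151 x 91 x 19
refs = pd.DataFrame(truth.B[:, :2], index=cube.wavelength_axis,
                    columns=list(design.analyte_names))

loadings = parafac_als(cube, FitOptions(n_components=3))  # 2 analytes + 1 interferent
aligned  = align_factors(loadings, refs)
report   = predict_concentrations(aligned, design)
print(recovery_table(report).to_string(index=False))
print(compute_fom(aligned, report.coefficients, design).table.round(4))
```

Output (abridged):

```
              sample  vancomycin_added  vancomycin_predicted vancomycin_recovery_percent ...
              pred01             15.15                 15.25                       100.7
              pred02             20.20                 20.36                       100.8
              pred03             30.30                 30.46                       100.5
              ...
mean_recovery +/- sd                                                          101 +/- 0%
       RMSEP (mg/mL)                                    0.12

            sensitivity  selectivity     lod
vancomycin       0.1986       0.0546  0.0118
cephalexin       0.2744       0.0751  0.0007
```

Reading it: despite elution-profile cosines up to 0.92 between
vancomycin and the interferent present only in the unknowns, every
prediction recovers 100–101% of the spiked concentration; RMSEP is in
concentration units (mg/mL here). Cephalexin's spectrum is the most
distinct in shape, so it is the more selective analyte and has the
lower detection limit. The SWATLD engine (`tricalib.swatld`) gives the
same answers in ~20 sweeps instead of ~170.

The same pipeline runs from the shell:

```sh
tricalib simulate --seed 7 --outdir study/
tricalib rank      --cube study/ --max-components 5 --outdir study_rank/
tricalib calibrate --cube study/ --algorithm swatld --components 3 --outdir study_cal/
tricalib fom       --cube study/ --calibration study_cal/ --outdir study_fom/
```

or all at once with a YAML config and a reproducibility manifest:
`tricalib run --config run.yaml --outdir out/` (see `tests/test_cli.py`
for a complete config example).

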