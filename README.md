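# dadkit

Open analysis of HPLC–DAD (high-performance liquid chromatography with
photodiode-array detection) raw data, for chemists and lab-automation
engineers who need chromatogram analysis outside vendor software: in
screening campaigns, reaction monitoring and closed-loop optimization,
results must be machine-readable, reproducible and produced without
manual integration.

A DAD records a full UV–Vis spectrum at every retention-time point, so
one run is a time × wavelength absorbance matrix `X[t, λ]`, modeled as

    X[t, λ] = Σ_c a_c(t) · s_c(λ) + baseline + noise,

a sum of bilinear compound contributions (elution profile `a_c` ⊗
spectrum `s_c`). `dadkit` implements the full chain on that model:

- **I/O** — canonical open CSV plus ChemStation/LabSolutions-style ASCII
  dialects;
- **preprocessing** — asymmetric-least-squares baseline correction per
  wavelength, robust noise estimation, wavelength trimming;
- **peak detection** — picking, border refinement and trapezoidal
  integration on the wavelength-summed trace;
- **peak purity** — spectral-similarity and PCA rank tests deciding
  whether a window holds one compound;
- **deconvolution** — for impure windows, PCA component counting
  followed by non-negative PARAFAC (trilinear `elution ⊗ spectrum ⊗
  loading` decomposition of the window stacked with pure reference
  windows), which resolves coeluting peaks that single-wavelength
  analysis cannot;
- **quantification** — compound libraries built from calibration runs,
  linear through-origin calibration curves (absolute or relative to an
  internal standard), retention-time correction via the internal
  standard, and campaign-stable tracking of unknown signals;
- **simulation** — a ground-truthed synthetic campaign generator (EMG
  peak shapes, band-built spectra at controlled pairwise correlation)
  and a benchmark harness that scores analysis outcomes into four
  categories: (i) separated and pure, (ii) successfully deconvolved,
  (iii) deconvolution missed the known compound, (iv) purity false
  positive.

## Worked example

Simulate a small campaign, analyze it, and read the peak table:

```bash
cat > spec.json <<'EOF'
{
  "noise_sd": 0.05, "drift": 1.0,
  "runs": [
    {"run_id": "cal_1", "type": "calibration", "compound": "main",
     "concentration": 1.0,
     "compounds": [{"id": "main", "bands": [[230.0, 18.0, 1.0]],
                    "rt": 0.45, "sigma": 0.015, "area": 20.0}]},
    {"run_id": "sample_1", "type": "sample",
     "compounds": [{"id": "main", "bands": [[230.0, 18.0, 1.0]],
                    "rt": 0.45, "sigma": 0.015, "area": 30.0},
                   {"id": "other", "bands": [[330.0, 20.0, 1.0]],
                    "rt": 0.7, "sigma": 0.015, "area": 10.0}]}
  ]
}
EOF
dadkit simulate --spec spec.json --seed 3 --out sim/
dadkit process --manifest sim/manifest.json --out results/
```

`results/peaks_sample_1.csv` then contains (abridged columns):

```
peak,component,retention_time,area,pure,compound,concentration
0,window,0.45,29.584,True,main,1.500
1,window,0.70,9.783,True,unknown_001,
```

The main compound's area (true 30 mAU·min) is integrated to 29.58 and
divided by the calibration slope (≈ 19.7 mAU·min per concentration
unit, fitted from the 1.0-concentration calibration run, which carries
the same small integration bias) to give a concentration of 1.500; the
second compound has no library entry and is tracked as `unknown_001`
with an area but no concentration.

The same pipeline is available as a library:

```python
from dadkit import Campaign, generate_benchmark, analyze_benchmark

bench = generate_benchmark(n=50, level="low", seed=7)
summary, categories, errors, records = analyze_benchmark(bench)
print(summary.counts, summary.median_error_pct)
```

which for this call prints
`{'i': 8, 'ii': 42, 'iii': 0, 'iv': 0} 1.3526...`: 8 cases were
baseline-separated and pure, 42 were deconvolved with the main compound
recovered, and the median relative quantification error over the
deconvolved cases was 1.35%.

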