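# natriq

Quantitative sodium (²³Na) MRI of human calf muscle at 7 T: simulation of
the density-adapted 3D radial acquisition (DA-3DPR), field-inhomogeneity
and partial-volume corrections, phantom-calibrated tissue sodium
concentration (TSC), and test–retest repeatability statistics.

Sodium MRI estimates the tissue sodium concentration — an early marker of
muscle pathology and electrolyte imbalance (e.g. in Addison's disease) —
by comparing corrected muscle signal against agarose calibration phantoms
of known concentration:

```
[Na_invivo] = (I_invivo^corr / I_phan^corr) · [Na_ref],    [Na_ref] = 25 mmol/L
```

where `I_invivo^corr` is the muscle ROI intensity after B0/B1⁺ and
partial-volume (geometric transfer matrix, GTM) corrections, and
`I_phan^corr` is the calibration-curve intensity at the reference
concentration; both are divided by their steady-state relaxation factor
`(1−e^(−TR/T1))·[(Fs/100)e^(−TE/T2s*) + (1−Fs/100)e^(−TE/T2l*)]` so
tissue/phantom relaxation differences cancel. Relaxation parameters come
from inversion-recovery T1 and bi-exponential T2* fits; repeatability is
assessed with two-way ICCs, Bland–Altman limits of agreement, and exact
nonparametric tests (Friedman, Wilcoxon signed-rank and rank-sum with
fully enumerated null distributions).

Because no in-vivo data are deposited, the package ships a digital calf
phantom (muscle compartments, calibration tubes, homogeneous cylinder,
smooth B0/B1⁺ fields, DA-3DPR PSF blurring, complex Gaussian noise
calibrated to SNR ≈ 16) that exercises every stage end to end, plus the
published measurement tables for reanalysis. See `docs/methods.md` for the
models and design choices.

## Worked example

Run the full synthetic quantification chain (simulate → combine → correct
→ GTM → calibrate → TSC) on the healthy digital calf:

```python
from natriq import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(scenario="healthy", matrix=64, seed=20220719))
print(report["tsc"])
print(report["truth"])
print(round(report["mean_muscle_snr"], 1))
```

prints (values in mmol/L):

```
{'GM': 19.957668428780014, 'TA': 13.835170774189288, 'S': 12.617770546079095}
{'GM': 19.9, 'TA': 13.8, 'S': 12.6}
16.8
```

i.e. at the protocol's SNR the pipeline recovers the generative
compartment concentrations within a few tenths of a percent; the
uncorrected values in `report["tsc_uncorrected"]` are 24–39% off, which is
what the B1/PVE corrections remove. The published-table reanalysis is one
call (or `natriq reproduce-paper` on the command line):

```python
from natriq import reproduce_tables
res = reproduce_tables()
print(res["tsc_healthy_mean"])   # {'GM': 19.886..., 'TA': 13.84, 'S': 12.57}
print(res["icc_ck"])             # {'GM': 0.784..., 'TA': 0.818..., 'S': 0.807...}
```

The CLI mirrors the library: `natriq simulate` writes a fixture bundle
(phantom NIfTIs, protocol YAML, measurement CSVs), `natriq run` executes
the pipeline, `natriq reproduce-paper` prints the table reanalysis.

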