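# utecine

Desk-scale simulation and reconstruction of **cardiac-respiratory
self-gated cine UTE (ultra-short echo time) cardiac MRI**, as used for
functional imaging of the mouse heart at high field.

In small-animal cardiac MR, ECG triggering is corrupted by the scanner
itself and echo formation causes flow and susceptibility artifacts.
Center-out radial UTE acquisition addresses both: sampling starts
immediately after excitation (TE ≈ 0.3 ms), and the first sample of
every spoke sits at the k-space origin, so it doubles as a free
navigator recorded once per TR. From that navigator the cardiac and
respiratory motion signals are recovered retrospectively, every spoke is
assigned a cardiac phase, spokes acquired during inspiration are
rejected, and the remainder are binned into cardiac frames and
reconstructed by Kaiser-Bessel convolution gridding. Ventricular
volumes, stroke volume (SV = EDV − ESV), ejection fraction
(EF = 100·SV/EDV), cardiac output (CO = SV·HR) and myocardial mass
(1.05 g/cm³ · myocardial volume) follow by slice summation.

The package provides every stage of that chain plus the ground truth to
validate it, with no scanner data required:

| module      | contents |
|-------------|----------|
| `phantom`   | dynamic analytic ellipse phantom (beating mouse heart) with a closed-form 2-D Fourier transform, exact compartment volumes, rasterization |
| `sequencer` | center-out radial spoke scheduler and sampler, complex Gaussian noise, TE-dependent flow-phase emulation, named protocol presets |
| `selfgate`  | k = 0 navigator extraction, respiratory/cardiac band separation, rate estimation, per-spoke cardiac phase, respiratory gating |
| `recon`     | cardiac-frame binning, ramp density compensation, Kaiser-Bessel gridding with deapodization, brute-force adjoint-NDFT oracle |
| `quant`     | CNR, slice-summation volumetrics, SV/EF/CO, myocardial mass, Teichholz and Simpson echo estimators |
| `pipeline`/`cli` | end-to-end orchestration, YAML configs, HDF5/NIfTI/CSV/JSON persistence, `utecine` command |

Because the phantom's Fourier transform is analytic, every downstream
claim is testable against exact values: the sampler is verified to
1e-10 against the Airy profile of a disk, the gridder to NRMSE < 0.02
against a direct adjoint non-uniform DFT, and the recovered EF/SV/mass
against closed-form ellipse areas.

## Worked example

Protocol arithmetic for the two reference acquisitions:

```bash
$ utecine protocol ute-reference
{
 "scan_time_s": 305.04,
 "scan_time_display": "5 min 5 sec",
 "pixel_um": 128.2051282051282,
 ...
 "navigator_rate_hz": 161.29032258064515
}
$ utecine protocol flash-reference | grep pixel_display
 "pixel_display": "129 μm",
```

246 projections × 200 movie cycles × 6.2 ms TR = 305.04 s per slice
("5 min 5 sec"); the Cartesian comparison protocol's 30 mm FOV over a
232 matrix gives 129.31 → "129 μm" pixels.

Full pipeline on the default phantom (LV cavity contracting from
r = 1.5 mm to 0.8 mm, i.e. ground-truth EF = 1 − (0.8/1.5)² = 71.6%,
480 bpm heart rate, 60 breaths/min, navigator SNR 10, 5 slices):

```python
from utecine import PipelineConfig, run_pipeline
out = run_pipeline(PipelineConfig(seed=1, outdir="demo"))
rep = out["report"]
print(f"HR {rep.heart_rate:.1f} bpm  LV EF {rep.lv.ef:.1f}%  "
      f"SV {rep.lv.sv:.1f} ul  mass {rep.lv.mass:.1f} mg")
```

prints (about one minute of compute):

```
HR 480.0 bpm  LV EF 70.8%  SV 21.9 ul  mass 58.8 mg
```

against analytic ground truth EF 71.6%, SV 22.4 µl, mass 58.5 mg — the
self-gating recovered the 8 Hz cardiac and 1 Hz respiratory rates to
within 0.1%, with a mean absolute cardiac phase error of 0.016. The
output directory holds the raw spokes (`spokes.h5`), the per-spoke
gating table (`gating.csv`), the 16-frame cine (`cine.nii` + JSON
sidecar), the functional report (`report.json`) and a manifest.

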