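# ecgi-bench

How much does torso-signal processing matter for electrocardiographic
imaging (ECGI)?  ECGI reconstructs epicardial (heart-surface) potentials
from body-surface recordings by solving an ill-posed linear inverse
problem, and every lab filters its torso signals differently — moving
averages, notch filters, wavelet baselines, high-pass filters — without an
agreed standard.  `ecgi-bench` is an analysis package for studying the
effect of those choices on a standard epicardial-potential ECGI pipeline,
using fully synthetic torso-tank-style data so that ground truth is always
available.

It is aimed at inverse-ECG researchers and signal-processing
methodologists who want a controlled, reproducible testbed rather than
(or before) experimental tank recordings.

## The pipeline

* **Forward model.**  Torso potentials relate to epicardial potentials by
  `y(t) = A x(t) + n(t)`, with `A` the transfer matrix of a homogeneous
  volume conductor bounded by the epicardium (potential sources) and the
  insulated torso surface.  `A` is assembled by a boundary-element method:
  collocation at mesh vertices, signed triangle solid angles for the
  double layer, analytic `1/r` integrals for the single layer, and a
  row-sum closure that makes constant-potential transfer exact.
* **Processing bank.**  49 variants: raw; seven high-frequency removal
  methods (HFR1–7: one-cycle moving average, Pipberger's cosine-weighted
  two-cycle average, FFT notch, Savitzky–Golay, an 11-tap weighted running
  average, order-7 Butterworth low-pass at 30 and 60 Hz); five
  baseline-drift removal methods (BDR1–5: isoelectric resetting, wavelet
  band-pass 0.5–150 Hz, 3000-ms-frame Savitzky–Golay baseline, cubic
  spline through isoelectric points, order-5 Butterworth high-pass at
  0.5 Hz); all 35 HFR+BDR combinations; and PCA-based signal averaging.
* **Inverse solution.**  Zero-order Tikhonov,
  `min ||A x − y||² + λ²||x||²`, solved in the SVD basis.  λ is selected
  per time instant at the corner (maximum curvature) of the L-curve —
  computed from the exact closed-form curvature of
  (log ‖Ax−y‖, log ‖x‖) — and the median over time is the final λ used at
  every instant.
* **Evaluation.**  SNR-HF and baseline shift of the processed torso
  signals; electrogram amplitude differences and QRS Pearson correlation;
  activation times by minimum dV/dt (truth) and a spatio-temporal
  neighbour-delay blend (reconstructions); activation-map correlation and
  MAE; automated pacing-site detection with a 30-ms neighbourhood rule and
  its localization error.
* **Synthetic data.**  Concentric icosphere meshes (epicardial sphere in
  an ellipsoidal tank), single-site pacing propagated at fixed velocity
  over the mesh edge graph, a biphasic RS electrogram template with
  optional T wave, and three noise classes: power-line interference,
  broadband channel noise, and sub-0.5 Hz baseline drift.

## Worked example

```
$ python analysis/01_simulate_dataset.py --seed 1
epicardium: 162 nodes, mean spacing 12.0 mm
torso: 162 leads
activation spans 0..132 ms from the pacing site
epicardial QRS peak-to-peak (median): 10.0 mV
torso QRS peak-to-peak (median): 2.91 mV

$ python analysis/03_run_study.py --seed 1
49 variants x 5 beats evaluated in 9 s

mean metrics by category:
          amp_abs_diff_mV  qrs_corr_median  at_corr   le_mm
category
BDR                 6.763            0.651    0.884  32.354
HFR                 7.584            0.585    0.962   3.561
HFR+BDR             6.512            0.689    0.971  11.051
RAW                 7.435            0.589    0.901  27.131
SA                  5.345            0.760    0.990  11.036
```

Reading the table: baseline-drift removal (BDR) lowers the selected
regularization parameter and with it the electrogram amplitude error
(6.8 vs 7.4 mV) and improves QRS morphology correlation — but, by letting
more high-frequency noise through to the reconstruction, it *degrades*
pacing-site localization (32 mm vs 27 mm).  High-frequency removal (HFR)
barely changes electrogram amplitude or morphology, yet dramatically
improves activation maps and localization (3.6 mm).  Combining both, or
signal averaging, improves both ends.  `analysis/02_signal_quality.py`
tabulates SNR-HF, baseline shift and median λ per filter, and
`analysis/04_summarize_trends.py` condenses the study table into these
trend statements.

A command-line interface mirrors the scripts:
`ecgi-bench simulate|filter|reconstruct|evaluate|study` (see `--help`).

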