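# Methods

This note documents the models behind `ecgi-bench`, the parameters that
matter, the numerical choices that make runs bit-reproducible, and what
the synthetic data can and cannot say about real recordings.

## Synthetic torso-tank data

**Geometry.**  The epicardium is an icosphere (default subdivision 2,
162 nodes, radius 40 mm; `10·4^n + 2` nodes at level `n`) and the torso an
icosphere scaled anisotropically to semi-axes (120, 160, 100) mm,
emulating a heart suspended in a human-shaped electrolytic tank.  Both
surfaces are closed, consistently outward-wound triangulations; electrode
positions are mesh nodes.  At the default resolution the epicardial
inter-node spacing is ≈12 mm, of the same order as experimental sock
arrays.  Mesh refinement is plain midpoint subdivision (no re-projection
to the sphere), repeated until the mean edge length meets the target.

**Activation.**  Single-site pacing is propagated as shortest-path
distance on the mesh edge graph (Dijkstra) divided by a constant
conduction velocity (default 1 mm/ms, the ventricular order of
magnitude).  Edge-graph distance slightly overestimates true surface
geodesics (paths are restricted to edges); at these mesh resolutions the
error is a few percent and the construction is simple and deterministic.

**Electrogram template.**  A unipolar electrogram is modelled as
`w(t) = −tanh(t/τ)·exp(−t²/2σ²)` — a smooth sigmoid downstroke (the
intrinsic deflection) under a Gaussian envelope, giving a biphasic RS
wave whose steepest downslope sits exactly at the activation time — plus
an optional Gaussian T wave (15 % of QRS amplitude, centred 180 ms after
activation).  Defaults: QRS duration 80 ms (τ = QRS/12, σ = QRS/5),
peak-to-peak 10 mV (the rendered waveform is normalized so this is
exact), cycle length 600 ms.  Lead *i* of every beat is the template
shifted by that node's activation time; beat onsets are spaced by the
cycle length plus Gaussian jitter (default SD 2 ms).  The recording
carries its ground-truth segmentation: per-beat QRS windows (constant
length across beats) and pre-QRS isoelectric windows (20 ms in the 50 Hz
dialect, 17 ms at 60 Hz).

**Noise.**  Three additive classes on the torso signals, each a pure
function of the seed:

| component | default | model |
|---|---|---|
| line interference | 0.05 mV at 50 Hz | per-lead random-phase sinusoid, optional harmonics at amplitude/k |
| channel noise | 0.05 mV SD | i.i.d. Gaussian per lead and sample |
| baseline drift | 1.0 mV total | three random-phase sinusoids with frequencies drawn in [0.1, 0.4] Hz |

The defaults emulate a heavily contaminated ("noisy-tank") recording in
which drift dominates: against the ≈2–3 mV median torso QRS this gives a
raw SNR-HF near 22 dB and a baseline shift of ≈0.34 mV.  Setting all
amplitudes to zero recovers `y = A x` exactly.  Line phase is drawn
independently per lead (tank line pickup is not common-mode after
referencing); drift frequencies are shared across leads, phases are not.

**What the generator does not model:** intramural sources, torso
inhomogeneities, respiration or motion artefacts, electrode contact
failures, and any beat-to-beat physiological variability beyond onset
jitter.  Passing tests therefore demonstrate correctness of the pipeline
and the direction of filtering effects under controlled noise — not
clinical performance.

## Boundary-element forward model

The volume conductor is homogeneous between the epicardium (Dirichlet
surface, potentials imposed) and the torso (Neumann surface, zero normal
current).  Green's second identity collocated at the vertices of both
surfaces gives double-layer blocks (potential kernels) and single-layer
blocks (gradient kernels on the epicardium); eliminating the epicardial
normal gradient through the epicardial single-layer block leaves
`W φ_torso = M φ_epi` and `A = W⁻¹M`.

Numerical choices:

* **Double layer:** signed triangle solid angles by the van
  Oosterom–Strackee arctangent formula, distributed 1/3 per vertex
  (mass-lumped linear interpolation).
* **Single layer:** the analytic closed form for `∫ dS/r` over a plane
  triangle (edge logarithms plus the `−|h||Ω|` height term), also lumped
  1/3 per vertex.  The formula is finite at collocation points lying on
  the element, so same-surface self-blocks need no special quadrature.
* **Diagonal:** each double-layer self-block diagonal is set by the
  row-sum closure ("auto solid angle"), which makes a constant potential
  transfer exactly; row sums of `A` equal 1 to machine precision by
  construction, and this is asserted in tests.
* **Deflation:** the assembled torso-side system is nonsingular for this
  Dirichlet-inner/Neumann-outer problem (the epicardial data pin the
  constant), so rank-1 deflation (adding `1/M` to every entry) is applied
  only if the condition number exceeds 1e12, and an error is raised if the
  system remains singular.
* The tank conductivity (500 Ω·cm) cancels in a potential-to-potential
  transfer and is recorded as metadata only.

Verification: Gauss solid-angle sums (4π interior / 0 exterior) to 1e-9;
the concentric-sphere analytic series for a central-dipole pattern with an
insulated outer boundary is matched to 2.3 % (subdivision 1), 0.21 %
(subdivision 2) and 0.031 % (subdivision 3) relative L2 — monotone in
refinement; `A` is invariant under rigid-body motion of both meshes.

## The processing bank

Window lengths follow the line-frequency dialect: one cycle is 20 ms at
50 Hz and 17 ms at 60 Hz (Pipberger windows 40/33 ms; SNR-HF noise
windows 40/34 ms).  HFR1/HFR2 use the exact integer cycle
(`round(fs/f_line)` samples) so that full-cycle annihilation of the line
frequency is exact in the filter's steady-state interior; Savitzky–Golay
windows round to the nearest odd sample count.  FIR smoothing uses
symmetric reflection padding; Butterworth filters run forward–backward
(zero phase), which doubles their effective attenuation — phase shifts
would bias activation-time placement and break the commutation property.
Choices the underlying methods leave open:

* **HFR3 (notch):** hard-zeroing of FFT bins within ±1 Hz of the line
  frequency and each harmonic up to Nyquist (width configurable).
* **HFR5:** the "11-element weighted running average" ships as normalized
  triangular weights; any user kernel can be substituted.
* **BDR2 (wavelet):** Coiflet with four vanishing moments (`coif2`),
  nominal 20 decomposition levels capped at `log2(n)` for finite records;
  the approximation (sub-0.5 Hz) is dropped, as are detail scales lying
  entirely below 0.5 Hz or entirely above 150 Hz.  Deep levels of a
  finite record are boundary-dominated: the first/last ≈2 s of a record
  are edge-distorted while the interior passband is preserved to <0.1 %.
* **BDR4 (spline):** isoelectric points are the *sample values at each
  isoelectric window's centre* (not window means — averaging a cubic over
  a window adds a curvature term, and point sampling removes a cubic
  drift exactly).  A not-a-knot cubic spline interpolates ≥4 points;
  fewer beats fall back to a single cubic fit.
* **BDR1** subtracts each beat's per-lead isoelectric mean over the beat
  region (regions split at midpoints between QRS onsets).
* **SA (signal averaging):** wavelet baseline removal first, then the
  first principal component across leads is the virtual lead; its QRST
  window is the template; each beat aligns at the cross-correlation peak
  searched within ± half a cycle of its expected position (an unrestricted
  search would lock onto neighbouring beats, since every beat matches the
  template); beats whose aligned window leaves the record are dropped and
  logged.  The residual noise of the average follows `1/√n` measured
  against the wavelet-filtered single-beat noise.

`as_operator` materializes any linear member of the bank (all HFR;
BDR2/3/5; their combinations) as an `n×n` matrix acting on the time axis
by filtering the identity; BDR1/BDR4 (segmentation-dependent) and SA
(alignment is data-driven) are refused explicitly.  Because the
fixed-λ Tikhonov inverse is purely spatial, filter-then-reconstruct and
reconstruct-then-filter agree to machine precision for every such
operator — the commutation property asserted in the acceptance tests.

## Inverse solution

The SVD of `A` is computed once and shared across instants, filters and
λ values.  The λ grid spans `[1e-8, 1e2] × σ_max` with 200 log-spaced
points (configurable).  L-curve curvature is evaluated in closed form:
with `a_i = σ_i²`, `u = λ²`,

    ρ² = Σ β_i² u²/(a_i+u)² + c₀²,    η² = Σ β_i² a_i/(a_i+u)²,

all derivatives of (log ρ, log η) with respect to log λ reduce to the two
sums `S = Σ β² a/(a+u)³` and `Q = Σ β² a/(a+u)⁴`, giving exact curvature
without finite differences (`c₀` is the component of `y` outside the
range of `A`).  The corner is the grid point of maximum signed curvature,
ties broken toward larger λ; a curve with no positive-curvature corner
returns the max-curvature point with a warning.

**Pooling.**  λ is selected at every instant of each beat's QRS window,
and the *median over all analyzed instants* is the single final λ used to
solve every instant.  Per-beat pooling is available
(`reconstruct(..., pool="per-beat")`) but is fragile: a beat whose QRS
happens to coincide with a zero crossing of the drift produces mostly
corner-less L-curves, and its own median can collapse to the grid floor;
the global median lets the rest of the recording outvote those instants.
With global pooling every solution column satisfies the normal equations
at `lambda_median` exactly.

Validated against oracles: solves match direct normal-equation solutions
to 1e-10; residual/solution norms are monotone in λ (exact filter-factor
property); on a severely ill-conditioned test problem with 1 % noise the
L-curve λ falls within a factor of ~4 of the discrepancy-principle λ.

## Evaluation metrics

* **SNR-HF (dB):** after BDR1, the across-lead RMS curve is computed per
  sample; per beat, QRS amplitude = peak of the curve in the QRS window
  (configurable to mean), noise amplitude = RMS over the 40/34 ms pre-QRS
  window; ratios are averaged across beats *before* the 20·log10.  A zero
  noise floor is reported as a capped 300 dB sentinel with a warning.
* **Baseline shift (mV):** mean over leads and beats of the absolute
  isoelectric-window mean.
* **Amplitude:** mean per-lead peak-to-peak in the QRS window; absolute
  difference and relative difference (normalized by the maximum recorded
  per-lead peak-to-peak).
* **QRS morphology:** per-lead Pearson correlation over the QRS window,
  median across leads; zero-variance leads are excluded with a warning.
* **Activation times:** truth maps use minimum dV/dt (central difference,
  no pre-smoothing — smoothing is the filters' job).  Reconstructions use
  a spatio-temporal blend: candidate min-dV/dt times plus pairwise delays
  between mesh-adjacent leads (cross-correlation of windowed derivatives,
  weighted by the normalized correlation peak), merged by regularized
  least squares (delay weight 2.0, configurable).  An isolated artefact
  spike is thereby pulled back toward the times its neighbours imply.
* **Pacing site:** among nodes whose 1-ring neighbours' median activation
  lies within 30 ms of the node's own time, the earliest wins; exact ties
  return the mean of the tied nodes' coordinates; if no node qualifies the
  global minimum is returned with a warning.  Localization error is the
  Euclidean distance to the true pacing node.
* SA produces one beat, which is compared against every unaveraged truth
  beat; BDR1 is applied to the ground-truth epicardial recording before
  all comparisons.

## Study scale and determinism

The default study is desk-scale — 162 epicardial nodes, 162 torso leads,
5 beats at 1000 Hz — chosen so the full 49-variant sweep (filter,
reconstruct, evaluate) completes in ≈10 s and the whole test suite in
about a minute on one CPU.  Trend analyses that involve sub-hertz
baseline methods use 14 beats (≈8.5 s records, the low end of the
experimental 14–31 beat range) so the drift spans several cycles.  Every
stage is a pure function of its configuration including the seed; the
study table is byte-identical across reruns, and per-variant results are
cached on disk so an interrupted sweep resumes where it stopped.

## Known limitations

* Lumped-linear BEM (1/3-per-vertex) trades some accuracy for simplicity;
  the sphere oracle bounds the error at these resolutions but complex
  geometries would warrant full analytically-integrated linear elements.
* The spatio-temporal activation detector is a one-line-description
  reconstruction of that family of methods (candidates + neighbour
  delays + least squares), not a reimplementation of any published
  variant.
* Synthetic electrograms share one template shape across leads; real
  electrograms vary in morphology, fractionation and repolarization.
* The L-curve corner detector inherits the method's known failure mode on
  corner-less curves; the global median is the mitigation, not a cure.
* Only zero-order Tikhonov with L-curve selection is implemented; other
  regularizers and selectors (GCV, CRESO, spatio-temporal priors) are out
  of scope.
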