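# Methods note

This note records the forward models, estimator choices, default
parameters and known limitations of the `qmuscle` package.  Units are
stated with every quantity; all defaults live in `qmuscle.phantom` (shared
physics constants) or at the top of the processing modules (thresholds).

## Common conventions

- Proton frequency 123.2 MHz (3 T).  Chemical shifts in ppm convert to Hz
  by multiplying with the transmitter frequency.
- Noise model: circular complex Gaussian of SD σ per channel added to the
  complex signal; magnitude images are therefore Rician.
- SNR is defined as the mean tissue signal of the first echo/volume
  divided by σ (mean(signal)/SD(noise)).  All noise levels quoted as
  "SNR x" derive σ from this definition on the phantom's muscle mask.
- Random streams: every modality draws from an independent
  `SeedSequence([seed, stream])` child, so maps are bit-reproducible per
  seed and uncorrelated across modalities.
- Every quantitative map carries `valid` and per-voxel `reason` fields;
  exclusion reasons use strict inequalities everywhere (a value exactly at
  a boundary is retained).  First-assigned reason wins at voxel level.

## Synthetic phantom (`qmuscle.phantom`)

Muscles are non-overlapping elliptical cylinders (optionally tilted
fibre axes) on a 64×64×5 grid, 1×1×5 mm voxels.  Default layout: six
lower-leg muscles (TA, TP, PER, SOL, GM, GL) with FF 2–60 %, water T2
28–45 ms, water T1 1000–1400 ms, tensors with MD ≈ 1.4–1.8 µm²/ms.
B1+ is a smooth radial field scaled exactly into the configured range
(default 0.85–1.15 of nominal); the off-resonance field ψ is a tilted
plane plus a Gaussian bump (default amplitude 30 Hz).

Fat constants shared by generator and fitters:

| Constant | Value | Notes |
| --- | --- | --- |
| Main fat shift | −3.4 ppm (−418.9 Hz) | drives the Dixon phase evolution |
| Olefinic fat shift | +0.6 ppm (+73.9 Hz) | survives spectral suppression; handled by DOFS |
| Fat T1 | 371 ms | fingerprint two-compartment model |
| Fat T2 components | 0.56 @ 231 ms, 0.44 @ 83 ms | see "identifiability" below |
| Fat diffusivity | 0.05 µm²/ms (isotropic) | causes the olefinic MD bias |

**Identifiability of the fat T2 constants.** A fat component inside the
15–70 ms water retention window makes the tri-exponential model nearly
degenerate (the water term can trade amplitude with it almost freely, and
the Cramér–Rao bound on T2w explodes).  Both fixed fat components are
therefore placed above 70 ms.  The fitter and generator share the same
constants, as they would share a calibration in practice.

## Dixon fat–water separation (`qmuscle.dixon`)

Model per voxel over echoes TE ∈ {2.75, 3.95, 5.15} ms:
`S = (W + F e^{i2πΔf_fat TE}) e^{i2πψTE} e^{-TE/T2*}` with complex W, F.
Estimation is variable projection: for each candidate (ψ, R2\*) the
complex amplitudes solve a linear system; a coarse grid over ψ (bounded by
the ±1/(2ΔTE) aliasing window) and R2\* (T2\* 5–100 ms) is refined by
coordinate descent.

The fat–water swap ambiguity (a near-equivalent minimum at
ψ ± 1/(2ΔTE) with W and F exchanged) is resolved by:

1. non-maximum-suppressed candidate minima of the per-voxel ψ profile;
2. a minimal-|ψ| prior among near-degenerate candidates (field maps are
   smooth and centred near zero, and at σ = 0 the swap is exactly
   degenerate so only a prior can break it);
3. region growing ordered by residual margin, restricted to "reliable"
   voxels (amplitude ≥ 0.15 × 99th percentile).  Background noise voxels
   are assigned the prior directly and never propagate field values into
   tissue — without this restriction noise bridges between muscles seed
   wrong field branches.

Outputs: FF = F/(W+F)·100 (undefined, not zero, where W+F = 0),
cCSA = (1 − FF/100)·CSA with CSA from label-map voxel counts × in-plane
voxel area.

## Water T2 (`qmuscle.water_t2`)

17 echoes, 9.5 ms spacing.  Free parameters (A_w, T2w, A_f); fat T2s and
weights fixed (table above).  VARPRO over a 60-point logarithmic T2w grid
(3–200 ms) with per-voxel parabolic refinement; inner 2-column linear
solve with a nonnegativity fallback.  The Rician noise floor is removed
before fitting by the second-moment identity `E[|s|²] = s² + 2σ²` with σ
estimated from outside-mask background voxels; without this the floor of
the late echoes is absorbed by the long-T2 fat component and biases T2w.
Exclusions (strict): T2w outside (15, 70) ms, B1+ outside (80, 120) %.

## Water T1 fingerprinting (`qmuscle.fingerprint`)

Sequence: inversion-prepared spoiled GRE, 400 pulses, flips
10 + 50·sin(π(i+1)/n) degrees, TR 12 ms.  Dictionary axes: T1w 600–2000 ms
step 25 ms; FF 0–100 % step 2.5 %; B1 0.70–1.30 step 0.05.  Entries are
two-compartment mixtures (fat T1 371 ms) of the recursion output; because
acquisitions are magnitude images, entries store the **magnitude** of the
signed course, unit normalized, and measured courses are reduced to
magnitude before the inner-product argmax.  Ties break deterministically
toward the lowest T1, then FF, then B1 (C-order layout).  Matching is
invariant to overall signal scale.  FF > 60 % excludes the T1 estimate
(strict).

**Limitation — off-grid B1.**  For truth exactly on dictionary nodes the
match is exact (verified exhaustively over all 18 525 retained nodes) and
robust at SNR 40.  When the true B1 lies between grid planes, however,
the (T1, FF, B1) signal manifold of this sequence class is nearly flat
along a trade-off direction: a B1 offset of half a grid step can be
compensated by ~100–250 ms of T1 and a few FF points with a relative
signal change below typical noise.  Finer B1/FF grids reduce the median
off-grid T1 error (≈250 → ≈40 ms) but do not reach one T1 grid step, and
higher-flip or multi-inversion schedules did not help materially.
Quantitative T1 interpretation therefore assumes B1 close to dictionary
planes (or an external B1 constraint); the continuous-B1 phantom
documents the residual error rather than hiding it.

## Diffusion (`qmuscle.dti`)

- **DOFS**: per diffusion encoding, images at readout shifts
  t_s ∈ {1.1, …, 12.2} ms follow
  `S(t_s) = (W + F e^{i2πΔf_olef t_s}) e^{i(φ0+2πψ t_s)}`.  VARPRO over ψ
  (±60 Hz grid, refined); among residual local minima the water-dominant
  branch is chosen, resolving the ψ → ψ + Δf_olef swap (valid because the
  olefinic fraction is small after spectral suppression of the main peak).
- **Noise/SNR**: non-overlapping 5×5 in-plane patches; eigenspectrum of
  the voxels×volumes matrix with a Marchenko–Pastur bulk criterion
  (range < 4·σ²·√γ); SNR = mean(b0)/σ.
- **b-matrices**: from gradient direction (`b·ggᵀ`) or numerically from a
  sampled waveform via q(t) integration, which captures cross terms
  exactly; the tensor fit consumes per-volume 3×3 b-matrices as given.
- **Tensor fit**: WLLS (weights = signal) initialisation, then 8
  Gauss–Newton steps on `S = S0 exp(−B:D)`.  Metrics from eigenvalues
  clamped at 0: MD = mean, FA = √1.5·‖λ−MD‖/‖λ‖.
- **Timing**: stimulated-echo diffusion time = mixing time + 16.3 ms
  (e.g. TM 100 → 116.3 ms, TM 400 → 416.3 ms).
- **Exclusions** (strict): voxel SNR < 15 or olefinic FF > 10 %;
  muscle-level FF > 50 % or < 50 voxels dominate the voxel rules.

## MRS pH (`qmuscle.mrs`)

Carnosine C2H shift δ (ppm, water-referenced) maps to pH by
`pH = pKa + log10((δ_acid − δ)/(δ − δ_base))`, pKa 6.87, δ_acid 8.52,
δ_base 7.63; water at 4.70 ppm.  Peaks: magnitude maxima in 4.2–5.2 ppm
(water) and 7.5–8.7 ppm (C2H) with three-point parabolic sub-bin
refinement; the C2H peak must exceed 2× the baseline noise SD (estimated
from the far-downfield tail) or pH is reported unavailable.  Muscles with
FF > 30 % (strict) are omitted from pH assessment.

## Statistics (`qmuscle.stats`)

- Per-muscle means over valid voxels; muscles with < 50 valid voxels are
  excluded (muscle-level rule).  Global thigh/leg and muscle-group
  averages are voxel-count weighted, as is the bilateral left/right merge
  (single available side flagged "unilateral").
- `ExclusionLedger` counts every record by exclusion reason;
  `conserved(parameter)` asserts retained + excluded = total.
- Longitudinal change Δ = follow-up − baseline on completers only;
  SRM = mean(Δ)/SD(Δ) with sample SD (n−1); undefined for SD = 0.
- Spearman correlation with qualitative bands (very weak < 0.20 ≤ weak
  < 0.40 ≤ moderate < 0.60 ≤ strong < 0.80 ≤ very strong); for n ≤ 8 the
  two-sided p-value is the exact permutation null of |ρ|.
- Wilcoxon signed-rank and Mann–Whitney U use exact small-sample nulls
  (no ties, n ≤ 12), otherwise the normal approximation.
- Bonferroni-corrected α = 0.05/n rounded to 4 decimals (9 → 0.0056,
  20 → 0.0025).
- Cohort bookkeeping: 18 + 16 + 16 patient exams and 13 control exams,
  (11 thigh + 7 leg) muscles × 2 sides each, gives 2268 segmented muscles
  (1800 patient, 468 control); the diffusion scan (7 lower-leg muscles,
  one side) gives 441.

## Generator scope and limits

The phantom is a validation instrument, not an anatomy simulator: muscle
parameters are piecewise constant, fields are smooth and deterministic,
partial-volume effects and motion are absent, and the generator shares its
forward models (and fat calibration constants) with the estimators.
Recovery errors therefore isolate estimator behaviour (noise propagation,
ambiguity resolution, exclusion logic) rather than model mismatch.  Known
residual gaps: the fingerprint off-grid B1 flatness described above, and
the absence of an automatic detector for corrupted acquisitions (the
ledger supports a generic "corrupted" reason, but flagging is manual).
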