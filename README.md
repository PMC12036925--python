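# qmuscle

Quantitative muscle-MRI processing for longitudinal muscular-dystrophy
imaging studies, with a built-in synthetic phantom for end-to-end
validation.  The package implements the full measurement chain used in
natural-history studies of fat-replacing myopathies (e.g. FKRP-related
limb-girdle muscular dystrophy): fat-fraction mapping, water relaxometry,
diffusion tensor imaging, spectroscopic pH, and the region-of-interest
statistics layer that turns voxel maps into per-muscle longitudinal
biomarkers.

## What it computes

| Module | Quantity | Method |
| --- | --- | --- |
| `qmuscle.dixon` | Fat fraction (FF, %), contractile CSA | Three-point Dixon complex fitting with region-growing field-map disambiguation |
| `qmuscle.water_t2` | Muscle-water T2 (ms) | Tri-exponential fit (free water component + fixed two-component fat) of 17-echo spin-echo decays, Rician floor correction |
| `qmuscle.fingerprint` | Water T1 (ms), FF, B1+ | Dictionary matching of inversion-prepared spoiled-GRE fingerprints on a (T1, FF, B1) grid |
| `qmuscle.dti` | MD, FA, eigenvalues (µm²/ms) | DOFS olefinic fat-water separation across readout shifts, MP-PCA noise/SNR, weighted + nonlinear tensor fit with full b-matrices |
| `qmuscle.mrs` | Intramuscular pH | Carnosine C2H chemical shift via Henderson–Hasselbalch titration |
| `qmuscle.stats` | Per-muscle means, global/group averages, Δ over time, SRM, rank tests | Voxel-count-weighted aggregation, exclusion ledger, exact small-sample nulls |
| `qmuscle.phantom` | Synthetic ground-truth acquisitions | Elliptical-cylinder muscles, smooth B1/off-resonance fields, Rician noise, shared forward models |

Every map carries a validity mask and per-voxel exclusion reasons;
muscle-level results flow through an `ExclusionLedger` that guarantees
`retained + excluded = total` for every parameter.

## Model sketch and notation

- **Dixon**: echoes `S(TE) = (W + F e^{i2πΔf_fat TE}) e^{i2πψTE} e^{-TE/T2*}`
  with fat shift Δf_fat = −3.4 ppm; FF = F/(W+F)·100;
  cCSA = (1 − FF/100)·CSA.
- **Water T2**: `s(TE) = A_w e^{-TE/T2w} + A_f Σ_k p_k e^{-TE/T2f,k}`
  with fixed fat constants shared with the generator; voxels retained for
  T2w in (15, 70) ms and B1+ in (80, 120) % (strict inequalities).
- **Fingerprint**: Bloch recursion of an inversion-prepared spoiled GRE;
  two-compartment water/fat mixing (fat T1 = 371 ms); magnitude
  inner-product matching, scale invariant by construction.
- **DTI**: `S(t_s) = (W + F e^{i2πΔf_olef t_s}) e^{i(φ0 + 2πψ t_s)}` over
  readout shifts t_s separates water from the olefinic fat peak
  (Δf_olef = +0.6 ppm) that spectral fat suppression misses; tensor fit on
  `S = S0 exp(−B:D)` with per-volume 3×3 b-matrices; diffusion time
  = mixing time + 16.3 ms; exclusions SNR < 15, olefinic FF > 10 %,
  muscle FF > 50 %, < 50 voxels.
- **pH**: `pH = pKa + log10((δ_acid − δ)/(δ − δ_base))` with
  pKa = 6.87, δ_acid = 8.52 ppm, δ_base = 7.63 ppm.
- **SRM**: mean(Δ)/SD(Δ) over completers, sample SD.

See `docs/methods.md` for the complete parameter tables, estimator
details and known limitations.

## Worked example

```python
import numpy as np
from qmuscle.phantom import default_config, realize_phantom, generate_dixon_series
from qmuscle.dixon import separate_fat_water
from qmuscle import stats as S

cfg = default_config(seed=11, noise_sigma=0.0)   # 64x64x5, six leg muscles
truth = realize_phantom(cfg)
series = generate_dixon_series(cfg, truth)

result = separate_fat_water(series)
mask = truth.muscle_mask
err = np.abs(result.ff.values[mask] - truth.ff[mask])
print(f"median |FF error| = {np.median(err):.4f} points")
# median |FF error| = 0.0002 points

ledger = S.ExclusionLedger()
records = S.aggregate_muscle(result.ff, truth.label_map,
                             parameter="FF", ledger=ledger)
for r in records:
    print(r.muscle, round(r.value, 2), r.n_voxels, r.reason)
# TA 2.0 650 none
# TP 10.0 650 none
# PER 20.0 640 none
# SOL 30.0 640 none
# GM 45.0 645 none
# GL 60.0 640 none
print(ledger.conserved("FF"))   # True
```

The same phantom feeds the other modalities
(`generate_mse_series`, `generate_fingerprint_series`,
`generate_dti_series`, `generate_spectrum`), so every estimator can be
validated against exact per-voxel ground truth.

A command-line interface covers the file-based workflows:

```bash
qmuscle simulate --seed 2 --out phantom/
qmuscle dixon --echoes phantom/dixon.nii.gz --out ff.nii.gz
qmuscle t2 --mse phantom/mse.nii.gz --b1 phantom/b1_percent.nii.gz --out t2.nii.gz
qmuscle mrs-ph --spectrum phantom/spectrum.json --muscle-ff 10
qmuscle aggregate --map ff.nii.gz --labels phantom/labels.nii.gz \
    --muscles phantom/muscles.json --parameter FF --out table.csv
```

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from freshly simulated phantoms
(about 15 s): Dixon FF median error 0.0002 points noiseless /
0.85 points at SNR 40 with zero fat–water swaps, water-T2 median error
1.73 ms at SNR 50, 100 % exact on-grid fingerprint recovery, MD/FA
median errors 0.023 µm²/ms / 0.020 at SNR 40 with a 99.6 % reduction of
the olefinic MD bias by DOFS, pH round-trip error < 3·10⁻⁵, a simulated
SRM of 0.836 against the generating value 0.8, and the cohort/bookkeeping
constants (2268/1800/468/441 segmented muscles, Bonferroni α 0.0056 and
0.0025, diffusion times 116.3/416.3 ms).

The test suite (`tests/test_acceptance.py`) asserts the corresponding
tolerance criteria; all randomness is seeded and the phantom generator is
bit-reproducible for a given seed.
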