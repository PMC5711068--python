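# imrtqa

Patient-specific IMRT QA analysis for medical physicists: plan-complexity
scoring, chamber-volume dose metrics, and small-field output corrections
for comparing **collapsed** (single-gantry-angle composite) against
**rotated** (planned-angle) absolute-dose verification.

Point-dose IMRT QA measures the dose to an ionization chamber in a solid
water phantom. Many clinics deliver all beams from a single gantry angle
(collapsed delivery) instead of the planned angles (rotated delivery).
Whether that shortcut is trustworthy depends on how modulated the plan is
and how uniform the resulting dose is across the chamber. This package
computes the metrics that quantify exactly that, and ships a toy dose
engine plus plan generator so the whole analysis can be exercised
end-to-end on synthetic cohorts without any clinical data.

## What it computes

**Modulation complexity score** (per segment, beam, plan; 1 = unmodulated,
lower = more complex):

    MCS_plan = Σ_j MCS_beam,j · MU_beam,j / MU_plan
    MCS_beam = Σ_i AAV_i · LSV_i · MU_seg,i / MU_beam

with the aperture area variability `AAV = Σ_a (left_a − right_a) /
Σ_a (max left_a − min right_a)` (per-leaf maxima over the beam's segments)
and the leaf sequence variability `LSV = Π_banks Σ_n (pos_max −
|pos_n − pos_{n+1}|) / ((N−1)·pos_max)` over the N open leaves of each bank.

**Chamber-volume dose metrics** on 3D dose grids, via exact voxel-rank
cumulative DVHs:

- homogeneity index `HI = (D2% − D98%) / D_average` (0 = uniform),
- conformity index `COIN = (V_ch≥RI / V_ch) · (V_ch≥RI / V_shell≥RI)` with
  RI the mean chamber dose and the shell a 1.5 cm Euclidean dilation of the
  chamber contour,
- the fraction of beams whose dose distribution intersects the chamber,
- combined per-beam statistical uncertainty `√(Σ i²)/n` and the percent
  relative RMS difference between paired dose values.

**Small-field correction** (Alfonso-style formalism):

    k_Qclin = (Dw_clin / Dair_clin) / (Dw_ref / Dair_ref)
    D_w     = M · N_D,w · k_Q,Q0 · k_Qclin

converting a chamber reading calibrated in a 10×10 cm² field into dose to
water in the clinical composite field, plus the Monte Carlo efficiency
figure of merit `ε = 1/(T·σ²)`.

**Synthetic study conditions**: a 30×30×17 cm³ virtual water phantom with
0.3 cm voxels, a Farmer-like 0.65 cc cylindrical chamber at isocenter at
8.5 cm depth (100 cm SAD), random multi-beam step-and-shoot plans with a
tunable modulation level, a deterministic divergent-aperture dose engine
(Gaussian penumbra, effective attenuation, inverse square), and noisy
scalar chamber pseudo-measurements.

## Worked example

```python
from imrtqa import SimulationConfig, simulate_patient
from imrtqa.pipeline import run_comparison

case = simulate_patient(SimulationConfig(n_beams=9, n_segments=6, modulation=0.5), seed=3)
report = run_comparison(case)
for mode, m in report.modes.items():
    print(f"{mode:9s} HI={m.hi:.4f} COIN={m.coin:.3f} MCS={m.mcs_plan:.3f} "
          f"k={m.k_qclin:.5f} diff_uncorr={m.diff_uncorrected_pct:+.2f}% "
          f"diff_corr={m.diff_corrected_pct:+.2f}%")
```

prints

```
rotated   HI=0.1931 COIN=0.022 MCS=0.281 k=1.00677 diff_uncorr=+1.30% diff_corr=+0.62%
collapsed HI=0.2122 COIN=0.018 MCS=0.281 k=1.01358 diff_uncorr=+2.27% diff_corr=+0.90%
```

The plan's complexity (MCS 0.281) is identical in both modes — it depends
only on leaf positions and MUs — while the collapsed delivery is less
homogeneous across the chamber (higher HI), its correction factor deviates
further from 1, and applying `k_Qclin` to the pseudo-measurement shrinks
the computed-vs-measured disagreement in both modes.

The same analysis is available from the shell:

```bash
imrtqa run --n-patients 20 --beams 7..19 --modulation 0.5 --seed 42 --out reports/
imrtqa summarize --reports reports/reports.csv --out summary.csv
imrtqa complexity --plan plan.json --out scores.json
imrtqa kfactor --inputs quadruples.csv --out kfactors.csv
```

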