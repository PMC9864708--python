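# capmech

Coronary plaque cap mechanics and vulnerability-change prediction from
segmented vessel cross-sections.

Vulnerable plaques — thin fibrous caps over lipid cores — rupture
mechanically, so both cap geometry and cap stress/strain matter for risk
assessment. Starting from segmented IVUS+OCT-style contours (lumen, outer
wall, lipid and calcification pools, in mm), `capmech`:

* computes morphological risk factors: lumen area (LA), plaque area (PA),
  plaque burden PB = PA/(PA+LA), minimum and mean fibrous-cap thickness on
  100 evenly spaced lumen points (four 25-point quarters);
* recovers the zero-load geometry by per-slice circumferential pre-shrink
  plus a fixed 5% axial pre-shrink, then solves a generalized plane-strain
  anisotropic Mooney–Rivlin finite element model

      W = c1(Ī₁−3) + c2(Ī₂−3) + D1[e^{D2(Ī₁−3)}−1] + (K1/K2)[e^{K2(Ī₄−1)²}−1]

  at systolic pressure to extract cap stress/strain predictors (MaxCapS,
  MeanCapS, MaxCapSn, MeanCapSn);
* scores five ordinal plaque-vulnerability indices (PVI, 1 = least to
  4 = most vulnerable): cap-thickness-based C-PVI and stress/strain-based
  MaxS/MeanS/MaxSn/MeanSn-PVI, with fixed cuts or cuts calibrated against
  C-PVI;
* predicts the binary baseline→follow-up change of each index
  (ΔPVI > 0 vs ≤ 0) with a 50-tree random forest under repeated five-fold
  cross-validation, sweeping all 511 subsets of the nine baseline
  predictors and reporting Acc/Sen/Spe/AUC at the Youden-optimal cutoff.

Patient contour data of this kind are not publicly deposited, so a seeded
synthetic cohort generator produces matched baseline/follow-up slice pairs
with the statistical structure the analysis assumes (right-skewed cap
thickness, rare morphology-linked progression, class-imbalanced outcomes).

## Worked example

```python
import numpy as np
from capmech import CohortSpec, generate_cohort, morphology
from capmech.pipeline import MechanicsSettings, slice_mechanics

pair = generate_cohort(CohortSpec(seed=1, n_pairs=1))[0]
m = morphology(pair.baseline)
print(f"LA={m.LA:.2f} mm^2  PB={m.PB:.3f}  MinCapT={m.MinCapT:.3f} mm")

rec = slice_mechanics(pair.baseline,
                      settings=MechanicsSettings(element_size=0.35))
print(f"circ_shrink={rec['circ_shrink']:.3f}  "
      f"MaxCapS={rec['MaxCapS']:.1f} kPa  MaxCapSn={rec['MaxCapSn']:.3f}")
```

prints

```
LA=7.77 mm^2  PB=0.599  MinCapT=0.796 mm
circ_shrink=0.118  MaxCapS=138.3 kPa  MaxCapSn=0.147
```

i.e. this slice has a 60% plaque burden with a comfortably thick 0.80 mm
cap (C-PVI 1); the fitted 11.8% circumferential pre-shrink makes the
pressurized model match the imaged lumen, and the cap sees a peak of
~138 kPa of principal Cauchy stress and ~15% principal Green–Lagrange
strain at systole.

The numbered drivers under `analysis/` run the full study on the synthetic
cohort: `01_generate_cohort.py` → `02_morphology.py` →
`03_cap_mechanics.py` (slow stage: two FE models per pair) →
`04_score_pvi.py` → `05_predict_changes.py`, writing tables under
`results/`. The same stages are available as a CLI
(`capmech synth|morph|preshrink|solve|pvi|predict|run`).

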