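# threecb

Three-compartment breast (3CB) imaging is a dual-energy mammography technique
that decomposes every pixel of a compressed-breast X-ray into thicknesses of
lipid, water, and protein.  Malignant lesions carry a distinctive
compositional signature — a lipid deficit and a relative water/protein excess
against their surrounding tissue, widening with distance from the lesion
border — which is invisible to morphology-based reading and to conventional
computer-aided detection (CAD).  This package implements the full analysis
chain for studying how much that compositional information adds to CAD's
malignancy predictions, on simulated cohorts with known ground truth
(clinical 3CB images are identifiable patient data and not public).

It is aimed at researchers in quantitative breast imaging and medical-image
statistics who want a reproducible, desk-scale testbed for dual-energy
material decomposition, ring-based compositional radiomics, and
risk-reclassification statistics.

## The model

Per pixel, with effective linear attenuation coefficients `mu_{m,E}` (cm⁻¹)
for material `m` at beam energy `E`, measured line attenuations `A_LE`,
`A_HE` and known compressed thickness `T` (cm):

```
mu_l,LE t_l + mu_w,LE t_w + mu_p,LE t_p = A_LE
mu_l,HE t_l + mu_w,HE t_w + mu_p,HE t_p = A_HE
      t_l +        t_w +        t_p     = T
```

solved by a single precomputed 3×3 inverse (`solve_lwp`).  Downstream:

* **Features** — each lesion ROI and its three 2-mm concentric outer rings
  (0–2, 2–4, 4–6 mm by Euclidean distance transform) yield 9 statistics ×
  4 regions × 3 maps = 108 compositional features.
* **Model** — a small feed-forward network maps the 108 features plus the CAD
  probability to a probability of malignancy (patient-grouped 60/20/20
  split, seeded random hyperparameter search, early stopping).
* **Added value** — AUC with 1000-round bootstrap CIs, integrated
  discrimination improvement IDI = IS + IP, and net reclassification
  improvement over BI-RADS risk bins 3/4a/4b/4c&5 (2, 10, 50, 95 %
  borders).
* **Signatures** — per-lesion `median(lesion) − median(ring k)` contrasts,
  compared malignant-vs-benign and triple-negative-vs-receptor-positive with
  Welch's unequal-variance t-test.

The synthetic-data module (`phantom_sim`) generates the cohorts: textured
breast phantoms with pathology-specific lesion gradients, dual-energy
acquisitions, and a binormal CAD surrogate calibrated to a chosen operating
AUC, including per-pathology misses.  See `docs/methods.md` for the full
model description and design rationale.

## Worked example

```python
from threecb import (SimConfig, CadConfig, default_attenuation_model,
                     generate_phantom, forward_project, solve_lwp)
from threecb.pipeline import build_cohort, added_value_experiment
from threecb.model import SearchConfig

# one phantom, noiseless round trip
model = default_attenuation_model()
phantom = generate_phantom(SimConfig(), seed=0)
acq = forward_project(phantom, model, noise_sigma=0.0)
lwp = solve_lwp(acq, model, phantom.breast_mask)
print(abs(lwp.lipid - phantom.lipid_map).max())   # ~1e-13 cm

# full added-value experiment on a 350-patient cohort
cohort = build_cohort(350, seed=0)
res = added_value_experiment(350, seed=0, cohort=cohort,
                             search_config=SearchConfig(budget=6))
print(f"CAD alone      AUC {res['auc_cad']:.3f}")
print(f"CAD + 3CB      AUC {res['auc_combined']:.3f}")
```

prints (seed 0):

```
7.37188088351104e-14
CAD alone      AUC 0.627
CAD + 3CB      AUC 0.805
```

The CAD surrogate operates near its configured AUC of 0.69 on the held-out
test partition; adding the 108 compositional features lifts test AUC by
+0.10 to +0.40 depending on the cohort seed (the lesion gradients are the
configured malignant/benign signature medians).  Zeroing the compositional
features returns performance to the CAD baseline, confirming the gain comes
from composition.

A command-line interface covers the file-based workflow:

```bash
threecb simulate --n-patients 20 --seed 1 --out cohort/
threecb decompose --le cohort/P00000/le.tif --he cohort/P00000/he.tif \
    --thickness cohort/P00000/thickness.tif --model cohort/model.json --out lwp/
threecb features --cohort cohort/ --out features.csv
threecb train --features features.csv --seed 1 --out model.json
threecb evaluate --features features.csv --model model.json --seed 1 --out report.json
threecb signatures --cohort cohort/ --out signatures.csv
```

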