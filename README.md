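# y90dose

Voxel-based absorbed-dose calculation for ⁹⁰Y microsphere selective internal
radiation therapy (SIRT), aimed at medical physicists comparing dosimetry
methods in the liver, the lung, and at the liver–lung interface.

After radioembolization, post-therapy imaging gives a per-voxel activity map
`A_ijk` (Bq) on a grid co-registered with a CT-derived density map `ρ_ijk`
(g/cc).  With no biological clearance, the cumulated disintegrations are
`N_ijk = A_ijk · T½ / ln 2` (T½ = 64.1 h).  The package implements four
voxel-based dosimetry methods (VBDM) that turn `N_ijk` into absorbed dose
(Gy):

| Engine | Dose model |
|--------|------------|
| `LD`   | local deposition: `D = N · E_avg / (ρ · ΔV)`, with `E_avg` = 0.937 MeV per decay |
| `SK`   | soft-tissue kernel: `D = N ⊗ K`, K the 4.8 mm voxel kernel in 1.04 g/cc reference tissue |
| `SKD`  | density-corrected kernel: `D = (N ⊗ K) · 1.04 / ρ` |
| `RT`   | reference transport: kernel summation along radiological (density-scaled) paths |

`RT` is the package's deterministic reference engine: it reduces exactly to
the equilibrium (local-deposition) dose in uniform media of any density and
reproduces the stretching of the β range in low-density lung (11 mm in soft
tissue → 44 mm at 0.26 g/cc), which is what separates the engines at the
liver–lung interface.

On top of the engines the package provides:

* a **slab interface study** (`run_interface_study`): a two-compartment
  liver/lung phantom with Gaussian PSF blurring (0/10/20 mm FWHM) and lung
  shunt fractions (1/10/20 %), reporting central-axis dose profiles, percent
  differences from the unblurred reference, and the intervals where each
  engine stays within ±10 % of the truth;
* **VOI analysis** (`mean_dose`, `dvh`, `interface_exclusion`,
  `sensitivity_fit`): mean doses and cumulative DVHs for tumor, non-tumoral
  liver (NL), and right lung (RL), remainder VOIs excluding 1–3 cm around
  the liver–lung interface, and the original-vs-remainder cohort regression;
* a **synthetic phantom generator** (`generate_phantom`, `generate_cohort`):
  deterministic SPECT/CT-like "patients" (density, activity, masks, blurred
  counts) so the whole pipeline runs and is tested without patient data.

## Worked example

```python
from y90dose import SlabSpec, run_interface_study
from y90dose.interface import TRANSPORT_AWARE

study = run_interface_study(SlabSpec())
for fwhm in (0.0, 10.0, 20.0):
    liver = study.noncompliance_depth("liver", fwhm)
    lung = study.noncompliance_depth("lung", fwhm, engines=TRANSPORT_AWARE)
    print(f"FWHM {fwhm:4.0f} mm: liver accurate beyond {liver:.0f} mm, "
          f"lung beyond {lung:.0f} mm")
print(f"deep-lung SK error: {study.band_mean_pd('SK', 20.0, 0.20, 45, 60):.1f} %")
```

prints

```
FWHM    0 mm: liver accurate beyond 4 mm, lung beyond 27 mm
FWHM   10 mm: liver accurate beyond 5 mm, lung beyond 34 mm
FWHM   20 mm: liver accurate beyond 11 mm, lung beyond 43 mm
deep-lung SK error: -75.0 %
```

i.e., with a 20 mm FWHM imaging resolution, every engine is within 10 % of
the truth deeper than ~11 mm into the liver; the transport-aware engines
(RT, LD, SKD) reach 10 % accuracy only ~40 mm deep into the lung; and the
soft-tissue kernel without density correction underestimates the deep-lung
dose by the equilibrium ratio 0.26/1.04 ≈ −75 %, so it should not be used
for lung dosimetry.

A command-line interface mirrors the library:

```bash
y90dose phantom --n 17 --seed 7 --out-dir cohort/
y90dose compute --activity act.nii.gz --density rho.nii.gz --engine skd --out dose.nii.gz
y90dose simulate-interface --out-dir results/interface/
y90dose voi-report --dose dose.nii.gz --liver liver.nii.gz --lung rl.nii.gz --out report.json
```

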