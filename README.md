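# cnvquant

Quantitative monitoring of **corneal vascularization** from en-face
angiography images.

Corneal neovascularization — pathological ingrowth of blood vessels into
the normally avascular cornea — is followed in the clinic and in animal
models with two imaging modalities: dye-free anterior-segment **OCT
angiography (OCTA)** and dye-based **indocyanine green angiography
(ICGA)**. Deciding whether an anti-VEGF treatment is working requires an
objective, repeatable measurement of how much vasculature is present at
each visit and how much grew or regressed between visits.

`cnvquant` implements that measurement chain as a tested, reusable
pipeline, aimed at researchers running longitudinal vascularization
studies (e.g. suture-induced vascularization in rabbit with anti-VEGF
treatment arms):

* **preprocessing** — repair of bright motion-artefact lines along the
  fast-scan axis, median denoising, optional background flattening and
  PSF-compensating sharpening;
* **registration** — automated rigid alignment (translation + rotation)
  of consecutive follow-up scans by phase correlation plus a bounded
  rotation search, and construction of the *common overlay region* on
  which all comparisons are made;
* **segmentation** — vessel binarization (global Otsu for OCTA, local
  mean for ICGA) with a multiscale Hessian tubularity gate;
* **quantification** — the core statistics;
* **stats** — Bland-Altman limits of agreement, Pearson correlation,
  paired/Welch t-tests, exact Wilcoxon signed-rank, group summaries;
* **synthetic** — a ground-truthed simulator of whole studies, so every
  stage is verifiable against known truth without any data download.

## The statistics at the core

For a binary vessel mask $V$ on a region of interest $R$ (pixel sets),

$$\mathrm{VD} = 100\cdot\frac{|V \cap R|}{|R|}\ (\%)$$

is the **vessel density**. For two consecutive visits $a$ (earlier) and
$b$ (later), with $b$ rigidly warped into $a$'s frame and $C$ their
common overlay region,

$$\mathrm{VGD} = 100\cdot\frac{|b\setminus a| - |a\setminus b|}{|C|}
= \mathrm{VD}_b\big|_C - \mathrm{VD}_a\big|_C\ (\%)$$

is the **vessel growth density**: positive for growth, negative for
regression. The pixelwise partition of $C$ into grown / regressed /
persistent vessels is exported as a change map. **Repeatability error**
is the signed VD difference between two same-session scans of the same
region; its smallness relative to between-visit VGD is what makes VGD
a meaningful longitudinal statistic. Method agreement between OCTA and
ICGA measurements of the same vasculature is assessed with Bland-Altman
limits of agreement (mean difference ± 1.96 SD) and Pearson correlation.

## Worked example

Simulate a six-animal study (saline / aflibercept-like / ranibizumab-like
arms, sub-conjunctival and topical routes, 4 weekly visits, both
modalities, duplicate same-session scans), then quantify it end-to-end:

```python
import numpy as np
from cnvquant import (SimulationConfig, generate_study, PipelineConfig,
                      run_quantify, run_compare_modalities)

config = SimulationConfig(seed=7).scaled(animals_per_drug_arm=1,
                                         animals_per_control_arm=1)
manifest, truth = generate_study(config, "demo_study")
result = run_quantify(manifest, PipelineConfig(), base_dir="demo_study",
                      out_dir="demo_study/out")

octa = result.table.data[result.table.data.modality == "OCTA"]
print(octa.groupby(["arm", "week"])["vessel_density_pct"].mean().round(2))

pooled = run_compare_modalities(result.table)["pooled"]
ba = pooled["bland_altman"]
print(f"OCTA vs ICGA growth: mean diff {ba['mean_diff']:+.2f}%, "
      f"LOA [{ba['loa_low']:.2f}, {ba['loa_high']:.2f}]%, "
      f"r = {pooled['pearson']['statistic']:.3f}")
rep = np.abs(result.repeatability.repeatability_error_pct)
print(f"same-session repeatability |error|: {rep.mean():.2f}%")
```

Output:

```
arm          week
aflibercept  1       12.29
             2       25.65
             3       14.72
             4       10.98
ranibizumab  1       10.84
             2       21.15
             3       11.18
             4       18.01
saline       1       11.19
             2       24.53
             3       28.71
             4       32.07
Name: vessel_density_pct, dtype: float64
OCTA vs ICGA growth: mean diff +0.29%, LOA [-1.64, 2.22]%, r = 0.999
same-session repeatability |error|: 0.07%
```

Reading the numbers: vessels grow from the limbus for two weeks
(densities rise to ~21-26% of the corneal disk), then treatment starts.
The saline controls keep growing; the aflibercept-like arm regresses and
stays regressed; the ranibizumab-like arm regresses and rebounds at week
4. OCTA- and ICGA-derived growth densities of the same vasculature agree
to a fraction of a percentage point with near-perfect correlation, and
the same-session repeatability error is two orders of magnitude smaller
than typical between-visit change — the property that makes the growth
statistic trustworthy.

The same flow is available from the shell:

```bash
cnvquant simulate --out study --seed 7
cnvquant quantify --manifest study/manifest.csv --out study/out
cnvquant compare --measurements study/out/measurements.csv --out study/out/stats.json
cnvquant report --measurements study/out/measurements.csv --stats study/out/stats.json --out study/report
# or everything at once:
cnvquant all --out run1 --seed 7
```

## Layout

```
src/cnvquant/
  io_formats.py      images, study manifests, measurement tables
  synthetic.py       ground-truthed study simulator
  preprocessing.py   motion-line repair, denoising, flattening, sharpening
  registration.py    rigid transforms, warping, pairwise registration
  segmentation.py    vessel binarization
  quantification.py  vessel density, growth density, repeatability
  stats.py           Bland-Altman, correlation, t-tests, Wilcoxon
  pipeline.py        orchestration (quantify / compare / report)
  cli.py             command-line interface
docs/methods.md      model, parameters, numerical choices, limitations
```
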