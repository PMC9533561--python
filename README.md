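# spatialtme

Distance-banded spatial quantification of the tumor immune microenvironment
from segmented multiplex-immunofluorescence cell tables.

## The problem

Multiplex (multispectral) immunofluorescence stains many immune markers on
one tissue slide; commercial image-analysis software then segments cells
and calls per-marker positivity, producing one table row per cell.  For
paired surgical cohorts — e.g. a primary colorectal tumor and its liver
metastasis from the same patient — the scientific questions are spatial:

* How dense is each immune phenotype (cells/mm²) in the **tumor center**
  (TC), the **invasive front** (TF — tissue within 150 µm outside the
  tumor boundary) and the **peritumoral region** (PT — tissue ≥ 150 µm
  away)?
* Do those regional densities differ between paired lesions, between
  regions, or between clinical subgroups (number of liver metastases 1 vs
  >1, metastasis diameter < 3 vs ≥ 3 cm)?
* How do CD68/CD163 **macrophage colocalization subtypes**
  (CD68⁺CD163⁺, CD68⁺CD163⁻, CD68⁻CD163⁺) redistribute between lesions?
* Is a lesion **immune-inflamed**, **immune-excluded** or an **immune
  desert**, judged by where its CD8⁺ T cells sit relative to the tumor
  boundary?

`spatialtme` implements this pipeline starting from the segmented-cell
table: tumor-boundary estimation from tumor-compartment cell positions,
signed-distance banding at a configurable width *w* (default 150 µm, with
TC ⇔ d < 0, TF ⇔ 0 ≤ d < w, PT ⇔ d ≥ w), pooled density quantification
(Σcounts/Σareas over the 3–5 imaged fields per lesion), macrophage
subtyping, immunotype calling (inflamed ⇔ d_TC ≥ t; excluded ⇔ d_TC < t ≤
d_TF; desert otherwise, with threshold *t* reported in every output), and a
Wilcoxon battery — paired signed-rank tests within patients/lesions and
rank-sum (Mann–Whitney U) tests for independent subgroups, both with exact
small-sample null distributions.

Because cohorts of this kind are rarely public, the package ships a
first-class synthetic-data generator (`spatialtme.synthdata`) that emulates
a 17-patient paired cohort — region-dependent Poisson cell intensities on
the true TC/TF/PT zones of a generative tumor mask, an elevated immune
band inside 150 µm, configurable CD68/CD163 joint-positivity, clinical
covariates — with the ground truth written to a sidecar file so recovery
can be tested end to end.

## Worked example

```bash
spatialtme simulate --seed 7 --out cohort/
spatialtme run --cohort cohort/ --out results/
spatialtme report --results results/
```

prints (seed 7, default 17-patient preset):

```
significant contrasts (p < alpha) per family:
  clinical_subgroup        6 / 48
  cross_lesion            20 / 36
  immunotype_contrast      0 / 40
  overall                  7 / 12
  region_contrast         38 / 48
immunotype calls:
  metastasis  desert          1
  metastasis  excluded        9
  metastasis  inflamed        7
  primary     excluded        7
  primary     inflamed        10
```

Reading this: most region contrasts are significant because the generator
places a 3× denser immune band at the invasive front; the cross-lesion
family picks up, among others, the peritumoral CD163 excess of metastases;
the immunotype contrasts are null here because the default preset couples
no marker to the immunotype regimes; and the immunotype calls split
lesions by whether the cohort-median CD8 threshold is exceeded in the
tumor center (inflamed) or only at the front (excluded).  `results/` holds the tidy tables
(`densities.csv`, `macrophages.csv`, `macrophage_heatmap.csv`,
`immunotypes.csv`, `battery.csv`) plus a `provenance.json` with the exact
configuration.

The same analysis is available as a library:

```python
from spatialtme import SynthConfig, simulate_cohort, run_pipeline
cohort, truth = simulate_cohort(SynthConfig(seed=7))
results = run_pipeline(cohort)
results["battery"].query("family == 'cross_lesion' and marker == 'CD163'")
```

## Layout

| module | role |
| --- | --- |
| `spatialtme.cellio` | cell-table dialect, validation, lesion merging, cohort I/O |
| `spatialtme.geometry` | tumor-boundary estimation, signed distances, TC/TF/PT partition |
| `spatialtme.quantify` | phenotype definitions, density tables, macrophage subtyping |
| `spatialtme.immunotype` | inflamed / excluded / desert classification |
| `spatialtme.stats` | exact Wilcoxon signed-rank & rank-sum tests, comparison battery |
| `spatialtme.synthdata` | synthetic paired-cohort generator with ground truth |
| `spatialtme.pipeline`, `spatialtme.cli` | end-to-end runner and `spatialtme` command |

See `docs/methods.md` for the model, parameter and design details.
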