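# nucoloc

Per-nucleus quantification of nucleolar colocalization in multi-channel
fluorescence microscopy.

Many chromatin and ribosome-biogenesis factors (the motivating case is
KANSL2, a subunit of the NSL histone-acetyltransferase complex) shuttle
between the nucleoplasm and the nucleolus depending on transcriptional
state and cell-cycle phase. Deciding *how nucleolar* such a protein is,
cell by cell, requires an objective pixel-level statistic rather than a
visual call. `nucoloc` implements that analysis end to end:

1. **Nuclei segmentation** from the DAPI channel by local Otsu
   thresholding (gated by the global Otsu level) with size and shape
   filters — touching clusters are excluded, not split.
2. **Per-cell colocalization score**: for each nucleus mask, the
   Pearson correlation coefficient of raw pixel intensities between the
   query-protein channel *K* and a nucleolar-marker channel *G* (UBF,
   fibrillarin, ...):

   $$R=\frac{\sum_i (K_i-\bar K)(G_i-\bar G)}
            {\sqrt{\sum_i (K_i-\bar K)^2\,\sum_i (G_i-\bar G)^2}}$$

   computed over mask pixels only, on raw intensities. *R* = 1 for
   ideal colocalization, −1 for ideal anti-colocalization, and is
   invariant to channel gain and offset.
3. **Control calibration**: a positive control (the marker structure
   detected twice, independently) and a negative control (marker vs
   DAPI, which is depleted inside nucleoli) bracket the assay's dynamic
   range.
4. **Cell-cycle stratification** from the PCNA pattern: mid-S cells
   show foci at the nuclear periphery and around nucleoli; G1/G2 cells
   are homogeneous; ambiguous cells are discarded.
5. **Group statistics**: Welch *t* for two conditions, one-way ANOVA
   followed by Dunnett's many-to-one or Tukey's all-pairs procedure for
   more, with figure-style star annotations.

Because raw micrographs from such studies are rarely deposited, the
package ships a first-class **synthetic field generator**
(`nucoloc.simgen`) that renders fields of elliptical nuclei with bright
nucleolar disks, tunable query enrichment *f*, Gaussian/Poisson noise
and optional channel bleed-through — together with full ground truth
and a closed-form oracle for the expected coefficient of a two-level
image pair, so every stage of the pipeline is verifiable.

## Worked example

Simulate two conditions — strong nucleolar enrichment (*f* = 1.0,
emulating untreated cells) and weak enrichment (*f* = 0.2, emulating
RNA-polymerase-I inhibition, which disperses nucleolar factors) — then
segment, score and compare:

```python
import numpy as np
from nucoloc import (SimulationConfig, generate_field, segment_nuclei,
                     score_cells, two_group_test, p_to_stars)

records = {}
for name, f, seed in [("untreated", 1.0, 1), ("pol1_inhibited", 0.2, 2)]:
    cfg = SimulationConfig(n_nuclei=12, enrichment=f, noise_sigma=8.0, seed=seed)
    field, truth = generate_field(cfg)
    labels = segment_nuclei(field.channels["dapi"])
    records[name] = score_cells(field, labels, condition=name)
    rs = [r.pearson_r for r in records[name]]
    print(f"{name}: n={len(rs)} mean r = {np.mean(rs):.3f} +/- {np.std(rs, ddof=1):.3f}")

res = two_group_test([r.pearson_r for r in records["untreated"]],
                     [r.pearson_r for r in records["pol1_inhibited"]],
                     names=("untreated", "pol1_inhibited"))
print(f"Welch t = {res.statistic:.2f}, p = {res.p_raw:.2e} ({p_to_stars(res.p_raw)})")
```

Output:

```
untreated: n=12 mean r = 0.937 +/- 0.003
pol1_inhibited: n=12 mean r = 0.536 +/- 0.020
Welch t = 67.96, p = 2.54e-16 (****)
```

All 12 nuclei per field are recovered; the mean per-cell coefficient
drops from 0.94 to 0.54 when the enrichment fraction falls from 1.0 to
0.2, and the two conditions are separated far beyond the *p* ≤ 0.0001
star level. The same run is available from the shell:

```bash
nucoloc simulate --seed 1 --n-nuclei 12 --out field.tif
nucoloc segment field.tif --out labels.tif
nucoloc score field.tif labels.tif --out cells.csv
nucoloc run --config run.yaml     # full multi-condition pipeline
```

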