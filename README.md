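# marrowmap

In-situ quantification of bone-marrow haematopoiesis from segmented 3D
microscopy coordinates.

Blood production happens at discrete microanatomical "production sites" in
the marrow: strings of erythroid progenitors (CFU-E) decorating single
sinusoids with budding erythroblast clusters, common lymphoid progenitors
(CLPs) near arterioles surrounded by maturing B-cell stages, and focal
neutrophil and monocyte/dendritic-cell progenitors with clustered progeny on
distinct sinusoids — while multipotent stem and progenitor cells (HSPCs)
stay dispersed as single cells enriched near megakaryocytes.  `marrowmap`
implements the analysis pipeline that makes those statements quantitative:
it consumes cell-spot and vessel-surface tables exported from imaging
software (one row per segmented cell with 3D coordinates in µm) and
produces distance analyses, enrichment calls, production-site censuses and
clonality classifications.  It is aimed at groups doing whole-mount marrow
confocal imaging who want the full statistical treatment without the
original commercial tool chain.

## What it computes

* **Radius-corrected gap distances.**  All distances are surface-to-surface:
  for cells *a*, *b* with centres $x_a, x_b$ and radii $r_a, r_b$,
  $d_{\text{gap}} = \lVert x_a - x_b\rVert - r_a - r_b$; vessels are capsules
  (polyline + radius), so the cell–vessel gap subtracts both the lumen
  radius and the cell radius.  Gaps ≤ 0.5 µm count as direct contact.  Per-
  type mean radii come from a built-in catalogue of 22 measured stage
  diameters (e.g. CFU-E 12.67 ± 1.88 µm).
* **Empirical random-placement null.**  Pseudo-cells of each type are drawn,
  at the observed per-type frequencies, from the positions of *all*
  segmented haematopoietic cells (~50,000–80,000 per 35-µm optical slice),
  150 replicates by default; observed distance distributions are tested
  against the pooled null (Student's *t* if both samples pass Shapiro–Wilk
  normality, Mann–Whitney otherwise) and called *enriched* (closer) or
  *depleted* (farther).
* **Production-site detection.**  CFU-E in sinusoid contact are single-linked
  (≤ 10 µm surface gap, one sinusoid chain) into strings of ≥ 3; terminal
  erythroid cells within 50 µm attach to their nearest string; B stages
  within 150 µm attach to their nearest CLP; myeloid sites form around
  sinusoid-anchored GP/MDP progenitors.  Censuses report sites per mm² of
  projected marrow area and per-site output.
* **Confetti clonality.**  Green (dump-channel) cells are discarded; sites
  are classified monoclonal / oligoclonal / unlabelled from their YFP/RFP/CFP
  composition; the same-colour distance statistic is tested against a null
  that permutes colours over fixed coordinates (add-one permutation p).
* **Vessel morphometry** (length, largest diameter, branch points — a branch
  is where two or more lumens connect) and the daughter-cell separation
  classifier (> 50 µm two hours after division).
* **A synthetic marrow generator** that emulates a 35-µm sternal optical
  slice with ground truth for every stage, used to validate the entire
  pipeline end-to-end (see `docs/methods.md`).

## Worked example

```python
import numpy as np
from marrowmap import (GeneratorConfig, build_volume, nearest_gap,
                       distance_to_vessels)
from marrowmap.catalog import HSPC_TYPES
from marrowmap.sites import (SiteParams, detect_cfu_e_strings,
                             assemble_erythroid_sites, detect_b_sites)

scene = build_volume(GeneratorConfig(), seed=1)   # 2.0 x 1.25 mm x 35 µm slab
params = SiteParams()
strings = detect_cfu_e_strings(scene.cells, scene.vessels, params)
sites = assemble_erythroid_sites(strings, scene.cells, params)
b_sites = detect_b_sites(scene.cells, scene.vessels, params)
hspc = scene.cells[scene.cells["cell_type"].isin(HSPC_TYPES)]
gaps = nearest_gap(hspc, hspc)
```

Output of the accompanying print statements:

```
scene: 51255 cells, 48 vessel segments
erythroid: 10 CFU-E strings, 7.6 CFU-E per string, mean late-erythroblast cluster 32.4 cells
B: 10 CLP-anchored sites, 18.0 pre B per CLP
HSPC dispersion: median nearest-progenitor gap 127.7 um over 53 HSPCs
pre CFU-E sinusoid contact: 60%
Confetti-labelled fraction: 7.16%
```

Reading it: the detector re-found all ten planted CFU-E strings on their
sinusoids (≈ 8 cells per string; the one-scene cluster mean of 32 cells
fluctuates around the configured 40 with only ten clusters); each CLP
carries ≈ 16 pre B within 150 µm; HSPCs sit > 100 µm from their closest
fellow progenitor; 60 % of pre CFU-E touch a sinusoid; and 7.2 % of all
cells carry a Confetti colour (7.3 % expected).

The same stages are scriptable from a shell:

```sh
marrowmap simulate --preset steady_state --seed 7 --out run/
marrowmap analyze  --cells run/cells.csv --vessels run/vessels.csv --out run/
marrowmap sites    --cells run/cells.csv --vessels run/vessels.csv --out run/
marrowmap clonality --cells run/cells.csv --membership run/site_membership.json --out run/
marrowmap report   --run-dir run/
```

Presets (`steady_state`, `phlebotomy_d2`, `gcsf_sternum`, `gcsf_tibia`,
`aged`) alter production-site numbers and compositions only — they encode
anatomical endpoints of the stress models, not their biology.

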