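# Methods

This note documents the models and procedures implemented in `marrowmap`,
the defaults and why they were chosen, and the limits of what the synthetic
validation shows.

## Coordinate model and distances

Cells are points with radii in a continuous, right-handed µm frame with the
origin at a corner of the analysed slab; all distances are 3D (never
projected).  The analysed tissue is an axis-aligned slab — x–y extent ×
35 µm, the depth to which whole-mount staining is uniform — whose y-extreme
planes stand in for the endosteal bone surfaces.  This slab idealisation is
a modelling choice: real sternal marrow has curved cortical boundaries, and
nothing downstream depends on the endosteal geometry beyond a distance to a
plane.

The elementary statistic is the **gap distance**: centre distance minus the
radii of both participants (cell–cell) or minus lumen radius and cell
radius (cell–vessel).  Both radii are subtracted because contact semantics
require it: two touching cells should read ≈ 0, not one radius.  Negative
gaps (interpenetrating segmentations) are preserved, never clamped.
"Direct contact" is gap ≤ 0.5 µm rather than exactly 0 because segmentation
jitter makes the exact boundary brittle.  When a record lacks a measured
radius the catalogue mean radius for its stage is substituted; the
catalogue holds the 22 measured stage diameters (means ± s.d.).

Vessels are **capsules** — an ordered polyline with one radius — so
point-to-surface distances are exact (point-to-segment minimisation)
without meshes or voxel transforms.  A **branch** is a junction where two
or more lumens join a third, i.e. a node of degree ≥ 3 in the graph whose
edges are segments and whose nodes are shared polyline endpoints; a
degree-2 junction is a lumen continuation, and segment chains through such
junctions are merged into one vessel before morphometry.  Vessel length is
polyline arc length; the reported diameter is the largest along the vessel.

Nearest-neighbour queries use a brute-force vectorised scan up to 1,500
targets and a kd-tree above that; because the correction subtracts
per-target radii, the kd-tree candidate set is widened by the target-radius
spread so the radius-corrected minimum is exact, and tests assert equality
with all-pairs scans.

## Empirical random-placement null

The null asks: would this cell type sit closer to (or farther from) a
structure if its members were random haematopoietic cells?  Candidate
locations are the positions of *all* segmented haematopoietic cells in the
window (48,964–81,248 per slice in the data this emulates) — not uniform
points, so the null inherits the true cell-density field.  Per replicate,
each type's observed count is drawn **without replacement** (a random cell
set should not duplicate positions; across replicates draws are
independent), pseudo-cells get the type's catalogue radius, and the
identical distance code path as the observed data is applied.  The default
is 150 replicates, the midpoint of the 100–200 range used in the emulated
workflow.

The observed-vs-null comparison pools all observed gaps against all null
gaps (matching per-cell dot plots; per-replicate medians are retained for
diagnostics) and dispatches on normality: Shapiro–Wilk at α = 0.05 on both
samples → two-tailed unpaired Student's *t*; otherwise two-tailed
Mann–Whitney.  The named normality test is our stand-in; only the
normality-gated dispatch itself is prescribed.  "Enriched" requires p ≤ α
*and* observed median below the null median; "depleted" the reverse.  Under
complete spatial randomness the type-I error of this call is ≈ α
(calibration is asserted in the acceptance suite within binomial 99%
bounds over 100 runs).

## Production-site detection

* **Erythroid.**  CFU-E in direct sinusoid contact are single-linked under a
  10 µm surface gap, restricted to pairs sharing a sinusoid chain;
  components of ≥ 3 cells are strings.  Contact membership considers every
  chain within tolerance, not only the nearest, because where two sinusoids
  cross a cell on one surface is nearly equidistant to both.  The 10 µm
  linkage (≈ one CFU-E diameter) is an explicit stand-in: the in-vivo
  strings are contiguous but no linkage distance is published, so the
  parameter is exposed in `SiteParams`.  Early/late erythroblasts,
  reticulocytes and RBC within 50 µm (the median distance for random
  cells) of any string member attach to the nearest string, ties to the
  lowest string id; late erythroblasts are then grouped into clusters by
  the same single-linkage rule.
* **B.**  Every CLP seeds a candidate site; pre-pro B, pro B and pre B
  within 150 µm attach to their nearest CLP.  Arteriole proximity is
  reported as an attribute, never used as a filter, so a mislocalised CLP
  still shows up (with its anomaly visible) instead of silently vanishing.
* **Neutrophil / monoDC.**  A site is a sinusoid-anchored focal progenitor
  (GP, resp. MDP) plus immature progeny (PN, resp. monocytes and cDC)
  within 50 µm; progenitors without sinusoid contact are reported as
  unanchored.  The formal supplementary definitions of these sites are not
  in the available text, so the rules codify the published summary
  (focal progenitor + clustered progeny on a distinct sinusoid) with all
  thresholds exposed for re-tuning.
* **Census.**  Site density divides counts by the x–y projected marrow area
  in mm² — the natural 2D normalisation for a thin optical slab — and
  per-site output is summarised as mean ± s.e.m.

Sites of one lineage partition their members by construction
(nearest-anchor assignment), and erythroid/neutrophil/monoDC anchors are
checked to be distinct vessels.

## Confetti clonality

The four-colour reporter labels ~7.3 % of cells irreversibly; shared colour
proxies shared clone.  GFP shares the imaging dump channel, so green cells
are discarded before any clonal analysis and only YFP/RFP/CFP count.  A
site with ≥ 2 labelled members in one colour is monoclonal, in ≥ 2 colours
oligoclonal, otherwise unlabelled — the ≥ 2 minimum is ours (one labelled
cell carries no clonal information), and the ≥ 2-colour reading of
"oligoclonal" is a documented stand-in for an undefined term.  The
same-colour distance test statistic is the median gap from each progeny
cell to the nearest focal cell of its own colour; the null permutes colour
labels over fixed coordinates, preserving per-colour counts (asserted every
replicate), with the add-one two-sided rank p so p is never 0.  For small
inputs all distinct colour arrangements can be enumerated exactly (each is
equally likely under uniform permutation of a multiset).

## Synthetic marrow generator

The generator produces scenes with the statistical structure the analysis
assumes, plus ground truth (site membership, clone ids, placement process,
contact labels) for every cell.  Defaults encode the study conditions of a
steady-state young sternal segment:

| parameter | default | basis |
|---|---|---|
| volume | 2000 × 1250 × 35 µm (2.5 mm²) | per-segment HSPC densities of the imaged segments |
| background pool | 50,000 CSR cells | inside the observed 48,964–81,248 per-slice range |
| vessels | 40 sinusoids (r ≈ 9 µm), 8 arterioles (r ≈ 5 µm), persistent random walks | sinusoid-dominated marrow vasculature |
| HSPC counts | 53 across 7 types | per-segment means of the mapped populations |
| HSPC repulsion | soft core, scale 120 µm, weight 4 | reproduces the observed > 100 µm median dispersion |
| CFU-E strings | 10 sites; sizes gamma on [3, 23], mean 8, s.d. 4 | measured string-size range/mean |
| late clusters | 1 per site; gamma on [19, 96], mean 40, s.d. 15 | measured range and mean (±4 read as s.e.m.; s.d. chosen to match the range) |
| B sites | 10 CLPs; 2 ± 1 / 3 ± 2 / 16 ± 8 stage counts in 150 µm | measured per-CLP composition |
| pre CFU-E | 30 per scene, 60 % sinusoid contact | measured contact fraction (count raised to make per-scene fractions measurable) |
| Confetti | 7.3 % labelled, equal colour weights | reporter recombination fraction |

Mechanisms are ours where only endpoints are published: HSPC dispersion is
sequential rejection sampling with a Strauss-like soft core (hard floor at
half the scale, exponential penalty within the scale) plus bounded
exponential biases toward megakaryocytes and away from arterioles — with
scale and bias weights at 0 it reduces exactly to CSR, which the
calibration tests exploit.  Size distributions are discretised gammas
clipped to the published range, with the raw mean adjusted by root finding
so the clipped, rounded distribution hits the published mean exactly.
String members are laid along a sinusoid's arc at one-diameter spacing with
a contiguity cap so consecutive surface gaps stay below the linkage
distance; clusters are dart-thrown with a 0.8-diameter minimum separation
inside a ball sized for ~15 % packing; CLP anchors are chosen by
farthest-point greedy selection over arteriole-surface candidates at
≥ 320 µm spacing (twice the capture radius plus margin, so nearest-CLP
assignment is unambiguous); site footprints of all lineages keep ≥ 120–150
µm apart and anchor vessels are never shared.  Clone policy: string members
draw from ≥ 2 clones per string (oligoclonal), each erythroblast cluster
inherits the single clone of its nearest string member (monoclonal), B and
myeloid progeny share their focal progenitor's clone with fixed
probabilities; labelling is Bernoulli per *clone*, so monoclonal structures
are labelled all-or-none, as an irreversible recombination event upstream
implies.

Everything is deterministic in (config, seed): one seed sequence is spawned
into fixed per-stage streams, and identical runs produce byte-identical
tables.

### What the synthetic validation does and does not show

Passing recovery tests shows the detectors invert the generator's
construction rules at realistic densities, noise levels and crowding — with
crossing vessels, a 50,000-cell background and boundary clipping — and that
the statistical machinery is calibrated under its null.  It does **not**
show robustness to real segmentation pathology (missed or doubled spots,
stage misclassification, vessel over-segmentation), to marrow-mask geometry
beyond a slab, or to production sites that violate the planted separations
(e.g. two strings sharing a sinusoid).  The spacing constraints the
generator enforces are what make exact recovery achievable; real tissue
need not respect them, and the exposed `SiteParams` thresholds are the
knobs to re-tune against annotated real data.

## Statistical procedures

Two-proportion comparisons use the Pearson chi-square on the 2×2 table with
Yates continuity correction (df = 1, two-sided); the correction is the
default because it reproduces the published transplant comparison
(4/5 vs 1/73 → P = 1.96 × 10⁻⁹) exactly, and an uncorrected mode is
available.  The marker screen operationalises the imaging-panel rule — a
marker must be uniformly expressed in ≥ 1 HSPC type at ≥ 10³ fluorescence
over background and absent from ≥ 1 type — with "uniform" as ≥ 90 % of
events positive and "absent" as ≤ 10 % (the fractions are ours; no
published values exist).  Daughter-cell separation uses a strict > 50 µm
threshold at the queried time, with linear interpolation permitted only
between adjacent frames.

## Numerical choices and problem sizes

Contact tolerance 0.5 µm; string linkage 10 µm; nearest-assignment ties to
the lowest site index; degenerate zero-length polylines are skipped with a
warning; permutation p-values use the add-one convention; kd-tree queries
are exactness-guarded as described above.  The test suite and the
acceptance script run 20 default scenes (~51,000 cells each) for the
recovery measurements, 100 CSR runs for null calibration, and exhaustive
enumeration on ≤ 6-cell toys for the permutation oracle — sizes chosen so a
full validation completes in a few minutes on one CPU while keeping the
recovery standard errors a few percent of the recovered means.

## Known limitations

Single-slab, single-time-point analysis only: no tracking of sites across
time points, no inference of stress state from one scene, no parametric
point-process statistics (the null is purely empirical), no voxel-space or
mesh computation, and no lineage-tree reconstruction from Confetti colours.
Presets alter site numbers and compositions only; they are anatomical
endpoints, not simulations of haemorrhage, infection, G-CSF or ageing.
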