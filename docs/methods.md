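# Methods

`organquant` implements the quantitative machinery used to link the partial
epithelial–mesenchymal transition (p-EMT) state of head-and-neck squamous
cell carcinoma (HNSCC) keratinocytes to their pattern of invasion in 3D
organ cultures. This note documents each model, its assumptions, the
tunable parameters, and the design choices made where the procedure was
genuinely open.

## The nine-gene p-EMT score

Input is a long-format qPCR table of cycle thresholds (Ct) for nine p-EMT
marker genes plus the reference gene GAPDH, across ≥ 2 keratinocyte
populations. The chain is:

1. ΔCT = CT_gene − CT_GAPDH per (population, gene, replicate), reference
   matched within the same (population, replicate) block. Replicate ΔCTs
   are averaged per (population, gene) *before* the exponential transform —
   standard ΔCT practice; the aggregation order is our choice since only
   n = 3 replication is implied by the data layout.
2. EXP = 2^(−ΔCT) × 100.
3. Per gene, the cohort extremes EXP_min/EXP_max (taken over the
   per-population aggregated values, not individual replicates) define
   N_val = (100·EXP_min − EXP_max)/99; subtracting N_val maps each gene's
   cohort range onto an exact 100-fold span:
   (EXP_max − N_val) = 100·(EXP_min − N_val).
4. The nine normalized values are averaged per population, and the cohort
   of averages is converted to the range 0.1–10. The conversion is
   implemented as linear min–max mapping with endpoints 0.1 and 10 — the
   single interpretation consistent with a bounded score; the population
   with the maximal raw mean scores exactly 10, the minimal exactly 0.1.
   The conversion is applied jointly across all samples passed in one call
   (e.g. control and TGF-β-treated conditions together, if supplied
   together).

Default panel: PDPN, VIM, PAI1, LAMC2, TGFBI, THBS1, MMP1, MMP10, ITGA5.
The panel is configurable; "THBS1" is used for the thrombospondin-1 gene
throughout. Degenerate cases are handled explicitly: a gene whose cohort
extremes coincide contributes 0 for every population (the formula's own
limit; it carries no discrimination) with a warning, and a cohort in which
every population has the identical raw mean is scored 5.05 everywhere with
a warning.

Properties the implementation guarantees (and tests): scores lie in
[0.1, 10]; shifting *every* gene's Ct by a common constant leaves all
scores unchanged (joint rescaling of EXP cancels in the min–max
conversion); shifting one gene's Ct by c multiplies that gene's normalized
values by exactly 2^(−c) (the N_val step is affine-equivariant per gene);
raising one population's expression of any panel gene never lowers that
population's score. Note that a *single-gene* Ct shift does change the
intermediate raw means non-uniformly across populations, and with > 2
populations can move the interior scores — this is a property of the
printed formulas themselves, since the min–max conversion only removes
transforms common to all genes.

## Image quantification

Images are calibrated 3-channel rasters (cytokeratin = tumor
keratinocytes, PDPN, DAPI = nuclei), oriented air-side up: row 0 is the
top of the section, the epithelial sheet occupies the top rows, invasion
proceeds downward. Orientation is a documented input contract.

* **Segmentation**: Otsu or fixed threshold on the cytokeratin channel
  (mask = intensity ≥ t); the threshold used is echoed to the provenance
  log, since the original workflow used interactive thresholding whose
  value is otherwise unrecorded.
* **Sheet vs islands**: 8-connected components; the largest component
  touching the top border is the epithelial sheet (no such component is an
  orientation error); every other component with area ≥ `min_island_area`
  (default 25 px²) is a detached island. The area floor suppresses
  single-pixel noise.
* **Depth**: the sheet base row is the *median* over columns of the
  sheet's lowest occupied row — robust to finger-like protrusions of the
  front. Per-island depth = (deepest island pixel − base row) × µm/px,
  clamped at 0; image depth = maximum over islands, 0 with none.
* **Nuclei per island**: Otsu threshold of the DAPI channel restricted to
  the island, 8-connected components, area ≥ `min_nucleus_area` (default
  9 px²). Deliberately simple (no watershed); adequate for well-separated
  nuclei and documented as replaceable.
* **LWR**: per-cell length-to-width ratio from the eigenvalues of the
  second central moments of the mask pixel set (the moment-equivalent
  ellipse); LWR ≥ 1, rotation-invariant. 1 ≈ cuboidal epithelial cell,
  higher ≈ elongated mesenchymal-like.
* **Marker intensity**: plain arithmetic mean of a channel over a mask
  (e.g. PDPN over the keratinocyte mask); area- or cell-number-normalized
  variants are left to the caller.

Images are processed at native resolution; doubling µm/px doubles reported
depths and quadruples µm² areas while leaving pixel-domain quantities
unchanged (tested).

## Invasion grading

* **Invasion index** = total island area (µm²) × island count × image
  depth (µm); zero whenever either factor is zero.
* **SPOI** (single pattern of invasion) = n_singular / n_clustered, where
  singular means < 15 nuclei and clustered ≥ 15; recorded as 0 when no
  singular island exists. With singular islands but zero clustered ones
  the ratio is undefined; we report the singular count with an explicit
  `spoi_undefined_flag` — monotone in singular count and never silently
  aggregated.
* **WPOI** (worst pattern of invasion), grades 1–5 with precedence
  5 > 4 > 3 > 2 > 1 ("worst wins"): 5 if any island lies ≥ 1000 µm from
  the tumor mass; 4 if any singular detached island exists; 3 if any
  detached island exists (all clustered); 2 if the invasion front shows
  ≥ 1 finger-like protrusion; 1 for a broad pushing front. An island with
  exactly 15 nuclei is clustered (the SPOI dichotomy decides the boundary;
  the verbal grade definitions leave 15 unassigned) and contributes to
  grade 3 — one convention everywhere. The 1 mm rule is implemented as
  island-to-sheet distance (nearest-pixel Euclidean); the grade-1/2
  distinction, visual in origin, is operationalized as 8-connected sheet
  components below the base contour with vertical/horizontal extent ≥ 2
  (config-exposed). Grading with uncalibrated distances raises, because
  grade 5 is undecidable without µm.
* **Experiment aggregation**: arithmetic mean and SEM over image fields;
  the sampling design is nine fields per independent experiment (triplicate
  images at center, quarter-left, quarter-right of the gel) collapsing to a
  single sample point; a different field count warns. SPOI fold change
  (with fibroblasts / without) is undefined when the denominator mean is 0
  and is flagged rather than propagated.

## Statistics

Pearson r with two-sided p from t = r·√((n−2)/(1−r²)) on n−2 df, plus the
OLS best-fit line, for every correlation plot; paired Student's t (zero
differences → p = 1 by convention; zero-variance nonzero differences → an
explicitly infinite t with p = 0); the transcription-factor screen runs the
same correlation per TF against an invasion phenotype, ranks by |r|, and
appends a Benjamini–Hochberg q column for reference only (ranking uses raw
|r|; the per-TF r/p are what the analysis reports).

Outlier identification is an iterative two-sided Grubbs test at α = 0.05:
repeatedly flag the single most extreme point whose statistic
|x − x̄|/s exceeds the critical value, recompute, stop when none exceeds
(or < 3 points remain). Flags are returned; removal is the caller's
decision, and is applied only where requested (fold-change comparisons).
This is a deliberate, simpler stand-in for GraphPad Prism's default ROUT
outlier method, which is proprietary in its tuning and is a non-goal here;
the substitution matters only for borderline points. The test's measured
false-flag rate on null normal samples (n = 20) is ≈ 0.05, i.e. the
nominal α.

TGF-β responsiveness is called from pSMAD3 densitometry fold change
(treated/control) at a default threshold of 1.5 — below the 2–4-fold
stimulation typical of responsive lines and above the ≈ 1-fold of
non-responders; config-exposed.

## Synthetic data generator

The generator exists because no images or expression tables are publicly
deposited for this workflow; every downstream stage is validated against
synthetic inputs with exactly known ground truth.

* **Organ images**: epithelial sheet as a full-width slab at the top;
  detached islands as discs at specified depths/radii; nuclei as disjoint
  3 px-radius discs separated by ≥ 2 px so counts are unambiguous; optional
  finger protrusions (15×5 px, aspect 3) for grade-2 fronts; an optional
  far island placed so its rasterized top edge sits exactly the requested
  distance below the sheet for grade-5 fixtures (≥ 1000 µm, which needs a
  correspondingly tall image). Foreground 1.0 / background 0.0 with
  additive Gaussian noise clipped to [0, 1] — the simplest intensity model
  that exercises thresholding. Default calibration 1 µm/px, overridable;
  no pixel size is implied by the rendering. Islands that would touch each
  other or the sheet are refused, never merged. The sidecar stores the
  *rendered* per-island pixel areas, depths and Euclidean distances, so
  parameter-recovery tests compare against the true rasterized geometry,
  and the expected SPOI/WPOI/invasion-index are computed from those records
  by the grading module's own rule functions (self-consistency by
  construction, verified by test).
* **Ct tables**: each population has a latent p-EMT level in [0, 1]; at
  noise 0 every panel gene's Ct is baseline − level × dynamic range
  (defaults 30 and 5 cycles), GAPDH fixed at 20 — so a higher latent level
  always means higher expression of every panel gene. Replicate noise is
  Gaussian in Ct cycles; the simulated dataset default is 0.2 cycles,
  a typical qPCR replicate spread.
* **Cell masks**: filled ellipses at random orientation with requested
  major/minor ratios (50 cells per population in the simulated dataset,
  matching the measurement design); the end-to-end dataset couples
  elongation to the latent p-EMT gradient (ratio = 1 + 2 × level + jitter)
  so the LWR–score correlation is positive by construction.
* **Densitometry**: four responders with fold change uniform in [2, 4] and
  two non-responders at fold 1, mirroring the six-population cohort
  structure with two non-responsive lines.
* **TF matrix**: 40 transcription factors, one built as
  r·z + √(1−r²)·ε on the standardized phenotype (default r = 0.95), the
  rest independent standard normals.

What the generator does *not* emulate: realistic histology texture,
stain bleed-through, touching/overlapping nuclei, out-of-focus blur,
irregular island shapes, or segmentation ambiguity at the sheet boundary.
Passing the recovery suites therefore demonstrates correctness of the
*rules and measurements*, not robustness of Otsu-plus-components
segmentation on real micrographs — on real data the thresholds
(`min_island_area`, `min_nucleus_area`, fixed vs Otsu) are the knobs to
revisit, and a watershed nuclei counter may be needed.

## Problem sizes and numerical choices

The validation suites use 480×420 px images with up to six islands
(radii 22–32 px chosen so the requested nuclei counts pack with the
mandated spacing), 50-image random sweeps for parameter recovery, 20-seed
rank-recovery runs, 1000-rep null simulations for the Grubbs false-flag
rate, and 500-rep power simulations for the TF screen (n = 6 populations,
39 null TFs) — sizes at which every stochastic property is stable while
the whole suite runs in well under a minute of compute per suite.
Stochastic assertions compare Monte-Carlo estimates against their expected
bounds with a 3σ binomial envelope; all simulations are seeded and
reproducible. Ties in the Grubbs iteration resolve to the first maximal
deviation (order-invariance is tested); all p-values are two-sided.

## Known limitations

* WPOI 1 vs 2 depends on a protrusion heuristic for what is a visual
  criterion; borderline fronts may grade differently than a pathologist.
* The 1 mm WPOI-5 rule is island-to-sheet by default ("between tumor
  islands" is ambiguous); island-to-island distances can be derived from
  the island table if wanted.
* Nuclei counting assumes separable nuclei; dense overlapping chromatin
  will undercount.
* The score's 0.1–10 conversion is cohort-relative: scores are not
  comparable across separately scored cohorts.
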