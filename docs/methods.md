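# Methods

## What the package models

The package analyses an organoid-based chemosensitivity platform with three
arms that meet in a clinical comparison:

1. an **imaging arm**: 3D confocal stacks of thick organoid sections
   (40–120 μm, 5 μm z-steps) segmented into nuclei and cells, from which
   per-cell intensity readouts are computed;
2. an **assay arm**: 96-well viability screens of drug-treated organoids,
   summarized as dose-response fits and vehicle-normalized viability
   reductions that feed a threshold classifier;
3. a **clinical arm**: small-cohort concordance between assay calls and
   CA19-9-encoded patient response, and survival prognosis by the
   stroma-to-tumor marker ratio.

No imaging or clinical dataset is bundled beyond small synthetic fixtures;
the synthetic-data module is the substrate for every test.

## Synthetic organoid volumes

`generate_volume` emulates a single organoid: nuclei are quasi-spheres
(mean radius 4 μm, log-normal dispersion 0.1 clipped to ±50 %) placed by
rejection sampling inside a spherical shell, flattened in z when the section
is thinner than the shell diameter, with a minimum center distance
(default 2× mean nucleus radius) and a bounded retry budget (10,000
candidate draws, then an explicit packing error). Each nucleus carries a
cytoplasmic corona of 1.8× its radius. Channel amplitudes are log-normal
per cell; CK-19 is reduced to 5 % in fibroblasts and α-SMA to 5 % in tumor
cells, and apoptotic cells carry 6× annexin A5. Depth attenuation is
`exp(-attenuation_per_um · z)` with default 0 so segmentation oracles are
exact; nonzero attenuation is used only for penetration-profile tests.
Voxels default to (0.5, 0.5, 5.0) μm (x, y, z), mirroring spinning-disk
stacks with 5 μm steps.

Where coronas of nearby cells would overlap, each voxel is owned by the
nearest eligible nucleus (distance normalized by corona radius), giving a
deterministic partition; the recorded per-cell ground-truth maxima are taken
from the rendered array over owned voxels and are therefore exact by
construction. Intensities are quantized to uint16 before ground truth is
recorded, so oracle comparisons are integer-exact.

What the generator deliberately does *not* emulate: optical PSF and
photobleaching, acquisition noise, Matrigel autofluorescence texture,
multi-organoid fields, nucleus shape irregularity. Passing phantom oracles
therefore demonstrates correctness of the geometry-and-bookkeeping pipeline
(segmentation, attribution, averaging), not robustness to real microscope
noise — the latter is out of scope for this package's claims.

## Segmentation

Nuclei: Gaussian smoothing of DAPI (σ = 1 voxel in x/y, scaled by the
anisotropy ratio in z), Otsu threshold, removal of objects under a physical
minimum volume (default 65 μm³ ≈ a 2.5 μm-radius sphere — a speckle filter,
not a biological constant), then a distance-transform watershed computed
with physical voxel spacing. Seed maxima are taken on a lightly smoothed
distance transform (the coarse 5 μm z-step otherwise produces exact
symmetric plateau ties that double-seed a nucleus) and merged so that no two
seeds lie within the minimum seed separation (default 6 μm) in physical
distance; the merge keeps the first seed in (z, y, x) scan order, making the
result deterministic.

Cells: the cytoplasmic mask is the Otsu- (or user-) thresholded sum of the
cytoplasmic channels unioned with the nucleus mask. Mask voxels in
components containing at least one nucleus are partitioned by nearest-seed
assignment — the Voronoi partition under Euclidean distance with physical
spacing, computed from the seed distance transform's index field. This is
the same partition a seeded watershed on the distance-to-seed image produces
when flood paths are unobstructed, but it is free of flood-ordering
artifacts through narrow mask corridors and is exactly reproducible.
Mask components with no seed become additional *anucleate* cell labels
(after the same minimum-volume filter), which is how the enumerated cell
count can exceed the nucleus count. Membrane-proximal signal lies inside
the grown cell region, so per-cell maxima include membrane-localized
staining.

## Quantification

* **ACI** — each cell contributes the maximum voxel intensity of a
  cytoplasmic channel over its region (raw per-voxel maximum, no smoothing);
  the ACI is the arithmetic mean over cells of those maxima.
* **ANI** — mean Ki-67 intensity over a nucleus' voxels, averaged over
  nucleated cells. Nuclear boundaries come from thresholding, so the ANI
  agrees with the generative ground truth approximately (≈1 % on phantoms)
  while maxima agree exactly.
* **Concordance** — `100·min(n_nuclei, n_cells)/max(n_nuclei, n_cells)`,
  reported to one decimal. The count pairs (2349, 2260), (2162, 2098) and
  (1983, 2127) map to 96.2, 97.0 and 93.2 under this formula in either
  argument order.
* **Depth profiles** — mean above-floor intensity per z-bin (bin width a
  multiple of the z-step, default 5 μm), with a configurable low-signal
  flag per bin.
* **Group comparisons** — Welch's two-sided t-test for two groups, one-way
  ANOVA beyond; all-constant equal-mean input returns p = 1 by convention
  rather than NaN.

## Dose-response and the threshold classifier

The viability model is a descending four-parameter logistic
`v(d) = bottom + (top − bottom)/(1 + (d/IC50)^hill)` fitted by bounded
nonlinear least squares (`scipy.optimize.curve_fit`; start values from the
midpoint-nearest dose; bounds keep IC50 within three decades of the dose
range, hill in [0.1, 10], bottom in [−0.5, 0.9], top in [0.1, 2]). A flat
response (range < 0.05) or non-convergence raises an explicit fit failure,
never a silent result. Noiseless curves are recovered to three significant
figures. With triplicates and 10 % multiplicative CV the *single-run*
estimator scatter of the free 4-parameter fit is large (relative error up
to ~40 % in occasional seeds at 24 wells); recovery is therefore asserted
on the 50-seed aggregate (geometric mean within 20 %, median relative error
under 20 %). This is a property of the estimator at that design, not of the
implementation; weighted fits do not materially reduce it.

Viability reduction is `100·(1 − mean(treated)/mean(vehicle))` per plate,
vehicle-well mean per model × regimen (mean-of-replicates, not
per-replicate calls). Negative reductions (stimulated growth) are preserved
in reports and floored at 0 only for classification. At threshold τ the
three dose binaries give responder (all 1) / nonresponder (all 0) /
intermediate, and the any-dose rule gives effectiveness; categories are
monotone non-increasing in τ by construction. The threshold matrix spans
τ ∈ {10, 20, 30, 40} % with a binary collapse (intermediate → responder).
Inflection detection reports the L1 change of the
(responder, intermediate, nonresponder) count vector across adjacent
thresholds and selects the *upper* threshold of the maximal-change pair —
the bar at which the category mass has just shifted — with ties broken
toward 30 %; identical counts across the grid mean no inflection and the
default 30 % is returned.

## Clinical statistics

CA19-9 encodes clinical response: a strict post- vs pre-neoadjuvant
decrease (no magnitude threshold by default; one is configurable). Records
are excluded when the baseline is under the normal-range cutoff (default
35 U/mL, the standard clinical reference value, configurable), when no
neoadjuvant therapy was given, or when values are missing; exclusion never
alters the classification of retained records. Clinical GA maps to the
ex vivo GEM/PAC arm, clinical FFX to ex vivo FFX; records treated with both
regimens contribute a pair per arm.

Exact McNemar uses the doubled smaller binomial tail capped at 1 (mid-p
available, not default). Fisher's exact test is two-sided by probability
ordering (the sum over same-margin tables whose hypergeometric probability
does not exceed the observed one), which yields 1/56 ≈ 0.0179 for the
5/5-vs-0/3 landmark table. The prognosis analysis dichotomizes the
α-SMA/CK-19 ratio at 1.0 (exact ties join the >1.0 group with a warning;
the reference cohort has none), counts alive/dead at the 32-month landmark
(patients censored before the landmark are excluded from the 2×2 and
reported separately), and runs the log-rank test on the full curves via
lifelines. Percentages for match rates are printed to one decimal with
truncation (16/21 → 76.1), the convention of the clinical summary they
mirror.

The packaged cohort fixtures are synthetic reconstructions: 21 models with
the reference exclusion lists and match counts (GA 3/4, FFX 7/8, overall
16/21 at τ = 30 %), and an 8-model prognosis cohort with the 5-vs-3
landmark split. The discordant-pair structure forced by those counts is
b = 2, c = 0, giving an exact McNemar p of 0.5 on this fixture. Numeric
CA19-9, survival and reduction entries are simulated, so only count-level
results are meaningful on these files.

## Determinism and numerical conventions

Every generator takes one integer seed and is bit-reproducible; the
pipeline's `summary.json` is written with sorted keys and fixed precision
(6 decimals) so reruns with the same seed are byte-identical (the config
hash covers analysis parameters, not the output location). Segmentation is
fully deterministic: seed ordering by (z, y, x), Voronoi ties resolved by
the distance transform's fixed scan order. Percentages are reported to one
decimal, ratios to two. Degenerate inputs return conventions rather than
errors where a convention exists (p = 1 for no discordant pairs, no events,
or an all-zero Fisher table; infinite doubling time for nonpositive growth)
and typed errors where none does (empty tables for ACI/ANI, zero counts for
concordance, zero vehicle mean).

## Problem sizes

Tests and the acceptance script use phantoms of 1–50 cells in shells of
18–55 μm radius (stacks up to ~280×280×12 voxels × 5 channels), triplicate
plates of 7 dose levels over 50 seeds, 100-profile random cohorts for the
classifier oracle, and 100 simulated 400-patient cohorts for log-rank
power; these sizes were chosen to exercise every code path while keeping a
full run in the tens of seconds.

## Known limitations

* Segmentation is tuned for the phantom regime (roughly spherical nuclei,
  clean background); it is a contract-level reproduction of a commercial
  pipeline, not a general-purpose segmenter, and carries no learned model.
* The ANI oracle is approximate (thresholded nuclear boundaries), unlike
  the exact maxima oracle.
* The log-rank implementation covers two groups only, per the prognosis
  design.
* Drug-synergy modeling, colocalization, spectral unmixing and tissue
  microarray quantification are out of scope.
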