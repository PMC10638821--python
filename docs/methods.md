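# Methods

## Problem and model

`celiaq` quantifies the three histologic hallmarks of celiac disease in duodenal
biopsy cross-sections — villus blunting, crypt hyperplasia and intraepithelial
lymphocytosis — and condenses them into one continuous score. The inputs are a
five-class tissue mask (villous epithelium VE, crypt epithelium CE, lamina propria
LP, submucosa including Brunner's glands, white space) and a per-cell table with
CD3 status and compartment. Three surrogate features are computed per specimen:

* **VE/LP area ratio** — surrogate for villus height; falls with blunting.
* **CE/VE area ratio** — surrogate for crypt hyperplasia; rises with crypt
  expansion.
* **%CD3 VE** — CD3+ intraepithelial lymphocytes per 100 villous enterocytes; the
  IEL convention of the modified Marsh scheme (> 40 is the classical cut-off).

The machine learning score is affine:

```
MLS = 0.872 − 1.03·(VE/LP) + 0.20·(CE/VE) + 3.92·(%CD3 VE / 100)
```

Modified Marsh sub-grades 3a/3b/3c map to 3.0/3.333/3.666 on a numeric grid
(printed 3-decimal constants, not thirds, so conversion boundaries are exact); a
continuous MLS converts back to an ordinal grade by nearest grid value, with exact
midpoints resolved to the lower (less diseased) grade — the conservative call, a
package choice since no convention dictates it.

**%CD3 scale.** The scorer takes %CD3 on the percent scale and divides by 100
internally. With the coefficient +3.92, percent-scale input would produce scores
two orders of magnitude off the Marsh grid (3.92 × 41.9 ≈ 164), while the
proportion scale lands severe-disease feature medians at ≈ 2.5 — squarely in the
Type-3 range — so the proportion scale is the only consistent reading and is
asserted at the interface.

**%CD3 denominator.** "Per 100 enterocytes" is interpreted as CD3-negative
epithelial cells (the IEL counting convention), the default; an `all_cells` mode
is provided because "percent CD3-positive cells" is also a defensible reading.
The active mode is recorded in output metadata, and values may exceed 100.
CD3+ cells in the lamina propria are never counted — the synthetic generator
deliberately seeds LP with CD3+ lymphocytes so tests can prove the exclusion.

Features with a zero denominator (e.g. a biopsy fragment with no lamina propria)
are carried as missing with a reason code, never as zero; scoring such a specimen
raises an error naming the missing feature.

## Model fitting

`fit_mls` is ordinary least squares with intercept (statsmodels), reporting R²,
the overall F statistic with (3, n−4) degrees of freedom and two-sided coefficient
p-values. Noise-free data generated on the published plane is interpolated back to
the published constants at machine precision; under Gaussian residual noise
(σ = 0.5, n = 200) every coefficient is recovered within 3 standard errors in
essentially all seeded repetitions. The original training cohort is not public, so
its specific R² is not a reproducible quantity; parameter recovery on synthetic
cohorts is the package's fitting contract instead.

## Synthetic specimens

The generator emulates a 2-D mucosal cross-section: a 120 µm submucosal band at
the bottom; above it a mucosal band of depth `crypt_depth_um` of lamina propria
pierced by straight crypt tubes (crypt epithelium); villi as parallel fingers with
rounded, sinusoidally perturbed tips (±5% height) rising from the surface. The
luminal tissue border carries a 30 µm epithelial band (VE), computed by Euclidean
distance from the background so band thickness is uniform along villus sides,
tips and the inter-villus surface. Crypt mouths pierce the surface band. Default
canvas is 520 × 800 px at 2 µm/px.

Per-Marsh-type defaults (villus height / crypt depth / crypt width, µm; IEL per
100 enterocytes):

| Type | villus | crypt depth | crypt width | IEL |
|------|--------|-------------|-------------|-----|
| 0    | 400    | 130         | 45          | 15  |
| 1    | 380    | 150         | 45          | 55  |
| 2    | 400    | 260         | 50          | 55  |
| 3a   | 250    | 300         | 55          | 60  |
| 3b   | 120    | 350         | 58          | 60  |
| 3c   | 30     | 400         | 60          | 60  |

These are design values calibrated only to the *qualitative* ordering of the
disease spectrum — the published cohort's feature medians depend on real cases and
are not targeted. Type 1 is architecturally near-normal; it receives marginally
blunter villi and deeper crypts than Type 0 (within normal biologic variation for
lymphocytosis-only biopsies) so that cohort medians order strictly rather than by
coin flip. Lengths are jittered ±5% per specimen, the IEL target ±15%, all from a
single seeded generator per specimen.

Epithelial nuclei sit on a jittered hexagonal grid with 12 µm pitch restricted to
the epithelial bands; each is CD3+ with probability r/(100+r), so the
positives-per-100-negatives ratio targets r. LP lymphocytes (all CD3+) are placed
at 800/mm² with a minimum-separation grid so nuclei never fuse. Every generated
cell lies, by construction, on a mask pixel of its recorded compartment.

**What the generator does not emulate:** real stain texture and nucleus-size
variation, tissue folds and artifacts, biopsy orientation effects, focal
(patchy) lymphocytosis, 3-D sectioning geometry, and true villus/crypt length
measurement (areas are the only surrogates, as in the scoring model). Passing
tests therefore demonstrate the correctness of the *pipeline contract* — masks and
cell tables in, features and scores out — not classifier performance on real
whole-slide images.

## Pseudo-IHC rendering and the segmentation stand-in

Renders composite pale per-class base tints with Beer–Lambert attenuation by two
stains (hematoxylin discs of radius 3 µm on every nucleus; DAB discs of 5 µm on
CD3+ cells) using the standard H-DAB optical-density vectors. Renders are
deterministic given (specimen, seed); Gaussian noise is available but off by
default.

The segmentation stand-in replaces a commercial CNN classifier and nuclei
plug-in, which cannot be redistributed; it is rule-based and deterministic so the
downstream scoring is exercised end to end:

1. **Unmixing** with the published H-DAB stain matrix (scikit-image), rescaled to
   base-10 OD units and clipped at zero.
2. **Tissue classification** of unstained pixels by nearest base tint (Euclidean
   RGB, max distance 60; uncovered pixels raise an error with a count). Pixels
   under stain are filled from the nearest unstained *tissue* pixel within one
   nucleus diameter (stain sits on cells, cells sit in tissue; without the tissue
   preference, cells on the luminal edge of the band drain into white space),
   falling back to the nearest unstained pixel of any class. Connected components
   below 200 µm² are merged into their dominant neighbour class.
3. **Nuclei detection** by Laplacian-of-Gaussian blobs on the hematoxylin channel
   (σ spanning 0.85–1.35 of the nucleus radius/√2), kept when the OD at the peak
   exceeds the hematoxylin threshold (default 0.30). A cell is CD3+ iff the mean
   DAB OD within 2 µm of the centroid exceeds the DAB threshold (default 0.45);
   the small measuring radius avoids contamination from a neighbour's DAB disc.
   The compartment is the mask class at the centroid pixel (no area voting), and
   detections are emitted in row-major scan order so ties are deterministic.
   Crowded or scale-saturated blobs are flagged in the log.

Both OD thresholds are calibrated on the package's own noise-free renders; real
IHC would need pathologist-set values, which is exactly the knob the
`SegmentationConfig` exposes. On noise-free renders the stand-in achieves
per-class IoU ≥ 0.95, nuclei recall/precision ≥ 0.99, CD3-call accuracy ≥ 0.99,
and end-to-end MLS within 0.25 of truth-mode scores (the %CD3 ratio is the most
sensitive term: compartment calls at band boundaries move single cells between
numerator and denominator).

## Paired-biopsy response analysis

The packaged 28-pair pre/post gluten-restriction cohort (checksummed CSV) carries
each pair's Marsh grades and continuous MLS. The response rule: *improved* iff the
numeric Marsh transform decreased, *worsened* iff it increased, else *unchanged*.
A pair is *aligned* when improvement is accompanied by an MLS decrease, worsening
by an increase, or no change by |ΔMLS| ≤ tol. The source table never states the
rule operationally; this one is reverse-engineered from its verdicts (all 27
improvers have ΔMLS < 0 and are aligned; the single unchanged pair has
ΔMLS = +1.03 and is not), and the 27/28 outcome is insensitive to any tol in
(0, 1.03). Default tol = 0.333, one Marsh sub-step; it is configurable and
reported in output. Percentages are rounded half-up to one decimal (27/28 →
96.4); medians use the standard mid-rank rule (the 28-pair pre-biopsy median
computes to 2.725, matching the printed 2.72 at its precision).

Group comparisons (`group_compare`) compute the pooled-variance Student t-test
from first principles (Welch via flag), the 95% CI of the mean difference, group
medians, and eta² = t²/(t²+df) — checked against an independent from-scratch
computation to 1e-10 in the tests.

The per-feature direction audit counts, among improved pairs, whether each
surrogate moved in the recovery direction (VE/LP up, CE/VE down, %CD3 VE down);
pairs with a missing feature are excluded and reported.

## Numerical and design choices

* Coordinates are 0-based (row, column) = (y, x) everywhere; masks are 8-bit PNG
  with a JSON sidecar (class map, pixel size, provenance), cells are CSV — so
  exports from third-party segmentation tools can enter at the features stage.
* Areas are pixel counts × (pixel size)²/10⁶ mm²; ratios are pixel-size invariant.
* `to_ordinal` ties go to the lower grade; MLS is never clamped (negative scores
  are legitimate post-treatment values).
* Every pipeline artifact embeds seed, config hash and package version; rerunning
  a configuration reproduces byte-identical outputs.
* Problem sizes in the test-suite and acceptance script (cohorts of 20 specimens
  per type, 12–20 rendered specimens for the segmentation checks, 200-row
  regression cohorts over 20 seeds) are the package's chosen verification scale;
  they keep every generated quantity's sampling error well inside the asserted
  margins.

## Known limitations

* The stand-in classifier only understands the generator's tint conventions (or
  user-supplied tint rules); it is a pipeline-contract test vehicle, not a tissue
  classifier for real WSI.
* Geometry is a parallel-finger cross-section: no branching villi, no oblique
  sections, no Brunner-gland substructure (submucosa is one class).
* The %CD3 denominator ambiguity (negatives vs all nuclei) is resolved by
  convention, not by evidence; both modes are implemented.
* Published cohort-level feature medians and the original confusion-matrix counts
  depend on the undeposited 116-sample image set and are out of reach; the
  package verifies ordering properties on its own synthetic cohorts instead.
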