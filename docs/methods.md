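# Methods

This note documents the models, conventions and numerical choices behind each
stage, what the synthetic data does and does not emulate, and the known
limitations.

## Synthetic seed scenes

Seeds are rendered as ellipses with an optional low-order radial cosine
perturbation: the outline in normalized elliptical coordinates is
r(θ) = 1 + ρ·cos(mθ) with amplitude ρ ∈ [0, 0.2] (default 0) and m = 8
lobes. This family was chosen because its geometry has closed forms usable as
measurement oracles: length 2a(1+ρ), width 2b, area πab(1 + ρ²/2) — exactly
πab for ρ = 0. Seeds are placed without touching (bounding-circle test; a
spec that cannot be placed after a bounded number of draws is rejected), so
the segmenter never needs to split merged objects — matching the imaging
protocol the phenotyping stage assumes, in which up to 20 seeds are scattered
sparsely on white paper, 15 + 5 across two replicate images per genotype.

The calibration card is rendered as a dark frame around a 6×4 grid of patches
with the classic 24-patch nominal sRGB values; its physical width (109 mm)
provides the mm-per-pixel scale. A global color cast can be applied as a 3×3
matrix plus offset in *linearized* sRGB, optionally followed by an
encoded-domain gamma perturbation and per-channel Gaussian pixel noise. All
randomness flows from a single integer seed per call, so fixtures are
bit-reproducible.

Not emulated: photorealistic seed texture (pericarp gloss, creases, the
ventral groove), shadows, lens distortion, defocus, and storage-time effects
on the seeds. Consequently, passing tests validate the measurement and
calibration *logic*, not robustness to real-camera artifacts; on real images
the segmentation threshold and the card detector are the components most
likely to need tuning.

## Phenotyping

**Card detection and calibration.** The card is the dominant dark connected
component on the near-white background (Otsu threshold on mean intensity;
a component must span ≥ 5% of the image to qualify — zero candidates raise
card-not-found, several raise ambiguous-card). Patch colors are sampled as
the median of the central 36% of each patch cell. The correction is an affine
map (3×3 matrix + offset) fitted by least squares in linearized sRGB from
measured to nominal patch values and applied to the whole image in the same
domain. An affine map in linear RGB exactly inverts any planted affine cast;
it only approximates a gamma perturbation, which is why the gamma knob
defaults to off and is meant as a stress test.

**Segmentation.** Lightness Otsu threshold (card region excluded), 3×3
morphological opening, connected components, minimum-area filter 2 mm².
Contours are traced by marching squares at the 0.5 level and smoothed with a
5-vertex circular moving average before measurement. The smoothing is the
perimeter-bias control: raw marching-squares polygons overestimate the
perimeter of smooth digitized outlines by ~5–6%, which would push the
circularity of a perfect circle to ≈ 0.89; after smoothing a r = 100 px
circle measures sCi ≈ 0.993 and sRg ≈ 1.002. Area and perimeter are computed
on the same smoothed polygon and the convex hull on its vertices, which makes
sSo ≤ 1 and sRg ≥ 1 hold by construction. Seed length/width come from the
minimum-area rotated bounding rectangle (rotating calipers over the hull),
projected area from the pixel count; both scale by the card-derived
mm-per-pixel factor.

**Roundness normalization.** Roundness is reported as 4A/(πL²) so that a
circle scores exactly 1 and an ellipse with a = 2b scores b/a = 0.5; the
un-normalized A/L² variant would place the circle at π/4 and contradict the
convention that non-circular shapes score below unity.

**Color descriptors.** All four spaces are reported on a single 8-bit scale:
RGB as-is; HSV with hue 0–360° mapped to 0–255 and S, V scaled to 0–255;
CIE L\*a\*b\* (D65, sRGB) with L\* 0–100 mapped to 0–255 and a\*, b\* offset
by +128; YCrCb in full-range BT.601 (JPEG convention, Cr/Cb offset +128).
A 1-px erosion removes the boundary ring before sampling, since edge pixels
mix seed and background color. Mean descriptors use a single-pass 3σ
exclusion applied per channel independently (a pixel can be excluded for one
channel and kept for another). Dominant colors use a deterministic Lloyd
iteration with k = 3 in each space's own 3-D coordinates: initial centroids
are the pixels at the 10th/50th/90th percentile of the projection onto the
pixel cloud's first principal axis; clusters are ranked by pixel count with
ties broken by descending mean luminance of the member pixels; when fewer
than three distinct colors exist (or a cluster empties), the lowest-ranked
non-empty centroid is duplicated into the empty slots with count 0.
Determinism was a hard requirement here — results must be bit-reproducible
across runs — which is why the iteration is written out rather than delegated
to a library k-means with randomized restarts. Whether dominant clustering is
run per space (as here) or once in a reference space with converted centroids
is a genuinely open design point; per-space was chosen because it treats the
four spaces symmetrically.

**Aggregation.** The per-genotype trait vector is the unweighted mean of each
of the 55 descriptors over all detected seeds pooled across the genotype's
images, so image order and the 15/5 split are irrelevant.

## RIL simulation

Genotypes follow a two-state Markov chain per chromosome: map distance d cM
converts to a single-meiosis recombination fraction by Haldane
(r = (1−e^(−2d/100))/2, no interference), corrected to the selfed-RIL
effective switch frequency R = 2r/(1+2r). Marginals are P(±1) = ½. The same
R(d) is used by the scan's conditional expectations, so the scan model is
correctly specified for the simulator — by design, since the tests measure
the scan's statistical behavior, not model misspecification. Phenotypes are
y = Σaᵢxᵢ + Σeⱼx₁ⱼx₂ⱼ + N(0, σ²) with x at the marker nearest the requested
position; with Var(x) = 1 the effect for a requested PVE is
a = σ·√(PVE/(1−PVE)). Default population size is 114 lines on 21 chromosomes
at 5 cM spacing (120 cM each); the real map's per-chromosome marker density
is not knowable from the study conditions, so these defaults are explicit
configuration, not inference.

## QTL scans

A regression (Haley–Knott-style) likelihood is used throughout:
LOD = (n/2)·log₁₀(RSS₀/RSS₁). It is deterministic, fast, and exactly equal to
the single-marker ANOVA LOD at marker positions; a full EM mixture refinement
would change almost nothing at marker density ≤ 5 cM and is out of scope.

Cofactor selection is stepwise forward–backward linear regression on
mean-imputed marker codes with P_entry = 0.001 and P_exit = 0.002 (capped at
n/10 cofactors); candidates collinear with the current model are skipped. At
each scan position (1 cM walk, marker positions always included in the grid)
the phenotype is adjusted by all selected cofactors *except* the two markers
flanking the current interval, and regressed on E[x | flanking genotypes]
computed from the Markov chain (missing flank → the other flank alone; both
missing → line dropped at that position). Peaks are local maxima with
LOD > 2; peaks within 10 cM merge to the higher one (the scan keeps nearby
distinct optima separate beyond that radius, as repeat loci on one
chromosome are a real phenomenon); support intervals are LOD−1 drops;
PVE = 100·(1 − RSS₁/RSS₀) at the peak. Classes: LOD in (2, 3] significant,
LOD > 3 highly significant (boundary at 2 exclusive). Names follow the
gene-symbol-catalog pattern Q.\<trait\>-\<chrom\>, with ordinal suffixes
(.2, .3 …) for repeated trait×chromosome pairs in peak order.

The epistasis scan walks a 5 cM grid, excludes same-chromosome pairs closer
than 20 cM (linkage produces spurious product terms there), fits
{1, x₁, x₂, x₁x₂} against {1, x₁, x₂}, and reports pairs with interaction
LOD ≥ 5 and interaction PVE ≥ 5%; surviving pairs within 20 cM per locus of
a stronger pair are suppressed (2-D local maximum).

Statistical behavior under the default study conditions (verified by the
test suite): a planted 20%-PVE additive QTL at n = 200 with 5 cM markers is
recovered within ±5 cM at LOD > 3 in ≥ 90% of replicates; a planted 15%-PVE
interaction at n = 300 is reported in ≥ 80%; pure-noise genome scans at
n = 114 over 21 chromosomes average well under 0.5 highly significant peaks,
and additive-only traits produce essentially no false epistatic pairs. The
replicate tests use 20 seeded replicates and 3-chromosome genomes for the
power checks (the power of a local test does not depend on the number of
unlinked chromosomes) and the full 21-chromosome genome for the null rates.

## Trait similarity

Locus sets use exact peak identity after rounding to 3 decimals (tolerance
0 cM by default): observed cross-trait overlaps in this kind of scan are
exact-position, because co-mapping traits share the same peak grid point.
A union–find unification with positive tolerance is available for rerun
jitter. Ochiai = |A∩B|/√(|A|·|B|), defined as 0 when either set is empty.
Clustering is agglomerative with UPGMA (average) linkage on d = 1 − S —
the default a general-purpose paleo/ecology statistics package would apply —
with single/complete available; determinism comes from presenting traits in
lexicographic order. Traits with no QTLs attach at maximal distance 1 rather
than being dropped, so the tree always has one leaf per trait. Output is
Newick with branch lengths from merge-height differences.

## Prioritization

Marker physical coordinates and gene→KO assignments are *inputs* (TSV): the
upstream steps that produce them in a real study — aligning marker sequences
to a genome assembly and running KO-assignment services — are external
pipelines, and what this package owns is the filter cascade. Intervals span
min(flank starts)–max(flank ends), 1-based inclusive; gene overlap is
any-overlap (≥ 1 bp), the inclusive reading of "genes in marker-limited
sites". Expression filtering keeps genes whose *maximum* TPM over seed-tissue
samples is ≥ 1 (max, not mean: a gene expressed in any seed sample counts as
seed-expressed); it applies only to coat-color QTLs by default — pigment
genes must act in the seed, while size/shape genes may act anywhere in the
plant — with a config override to apply it everywhere. When several sources
assign KOs to one gene the union is kept. The synthetic fixtures plant
candidates satisfying every filter plus decoys failing exactly one filter
each, so the expected output is known by construction, and the test suite
checks exact set equality against an independent brute-force triple loop.

## Pipeline and reproducibility

One YAML config holds every threshold under a named key whose default equals
the method's standard value (LOD 2/3/5, PVE 5%, steps 1/5 cM, TPM 1, 3σ,
k = 3, min area 2 mm², locus tolerance 0); any override is echoed into the
run log. All stage outputs are written to one run directory with a SHA-256
manifest; identical config + seed reproduces byte-identical files. The demo
run plants shared loci across traits so the similarity stage has structure to
recover, plus one epistatic pair.

## Known limitations

- The segmenter assumes non-touching seeds on a white background; no
  watershed splitting is attempted.
- The affine color correction cannot invert nonlinear casts (strong gamma,
  vignetting).
- Shape indices are reliable only above ~50 px of seed length; at lower
  resolution perimeter quantization dominates.
- The scan assumes homozygous RILs (no dominance, two genotype classes) and
  fixed LOD thresholds; permutation-based genome-wide thresholds are not
  implemented.
- Printed cM positions are treated as opaque coordinates; no map-offset
  convention is inferred.
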