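# Methods

This note records the models, rules and numerical choices behind
`astroseg`, in the order the pipeline applies them, together with what the
synthetic benchmark does and does not establish.

## Noise model and estimation

All detection assumes additive noise of unknown standard deviation σ on an
otherwise piecewise-smooth image. σ is estimated from second differences of
adjacent pixels, `(2c − l − r)/√6`, pooled horizontally and vertically and
scaled by 1.4826× the median absolute value. The combination has unit
variance under i.i.d. noise, cancels linear ramps exactly (so shading
gradients do not inflate σ), and the median makes it insensitive to bright
objects covering a minority of pixels. Degenerate geometries with no
interior pixels (e.g. 2×2) fall back to first differences. The estimator is
calibrated for roughly symmetric noise; strongly clipped or heavily
Poisson-limited data will bias it low.

## Detection: locally significant regions

Candidates are upper-threshold components — the nested family of connected
components of `I ≥ t` across occupied intensity levels. Components are
4-connected by default (8-connected via `connectivity=2`); 4-connectivity
prevents diagonal leakage between thin parallel branches. Images with more
than a bounded number of distinct values are binned for component
enumeration (256 bins in `build_component_tree`, 128 in `detect_regions`,
both configurable); scores are always computed on raw intensities, so
binning only quantizes *which* nested candidates exist, by less than the
noise scale in practice.

A candidate region R is scored against its boundary ring B (pixels within
`ring_width = 2`, Chebyshev, outside R, inside the image; the ring is
purely geometric):

    z_raw = (mean(R) − mean(B)) / (σ·√(1/|R| + 1/|B|))

`score_region` reports exactly this. Selection in `detect_regions`
additionally subtracts a null term: because R is *selected* to lie above a
threshold and B below it, even pure noise shows a positive gap. For an
i.i.d. normal neighborhood split at its upper-p quantile,
p = |R|/(|R|+|B|), the expected gap is `φ(z_p)·(1/p + 1/(1−p))·σ`.
Subtracting it recenters pure-noise candidates near zero while true
contrast passes through; the conditional null variance is smaller than the
unconditional standard error used, so the test is conservative. With the
default α = 0.001 (one-sided normal quantile ≈ 3.09), the measured fraction
of 128×128 pure-noise images containing any detection is below 1%.

Per root-to-leaf chain, the highest-scoring candidate at or above z(α)
wins; ties go to the larger region; overlapping selections are resolved by
score. At σ = 0 any contrasted candidate scores +∞ and the tie rule returns
the largest, which is why noiseless objects are recovered exactly
(IoU = 1). Scoring is vectorized per level, with ring statistics from a
Chebyshev maximum-filter over the label raster; this equals the
per-candidate geometric ring unless two same-level components lie within
2·ring_width of each other, in which case each shared ring pixel is
attributed to one of them.

Area bounds: min 5 px for mitochondria, 50 px for cell fragments. The
pipeline caps cell candidates at a quarter of the field of view (config
`max_area_cell`, 0 = use the cap): without a cap the statistically
strongest candidate on a noisy field is a near-global background component.

## Linkage

Brightest path = max-bottleneck path: among 8-connected pixel paths between
two fragment boundaries, maximize the minimum intensity; the reported edge
weight is the path's mean intensity including both terminal pixels. The
bottleneck value is found with a widest-path Dijkstra; the concrete path is
then the deterministic BFS-shortest route inside the bottleneck-optimal
subgraph (lexicographic neighbor order). An exact "maximum mean among
bottleneck ties" would require mean-optimal simple-path search, which is
not tractable; bottleneck optimality itself is exact and oracle-tested.
Searches are restricted to the pair's bounding box dilated by
`envelope = 50` px (None disables).

The linkage is the maximum-weight spanning tree (Kruskal, ties to
lexicographically smallest node pairs) — equivalently a minimum spanning
tree after inverting brightness to a cost. Tree edges below
`min_link_weight` (default: half the area-weighted mean fragment interior
intensity) are cut; each remaining component becomes one cell mask
containing its fragments plus the 1-px linking-path corridors.

After assembly, the mask is completed by hysteresis: 8-connected pixels
strictly above the background median + `mask_fill_sigma`·σ (default 2) that
touch the mask are annexed. The significance-optimal threshold otherwise
sheds the dimmest distal pixels of 1–2 px processes, which are too small to
survive as independent fragments. At σ = 0 the step is a no-op (strict
inequality at the background level). Setting `mask_fill_sigma = 0` disables
it.

## Branch hierarchy

Skeletonization uses topology-preserving thinning (scikit-image
`skeletonize`) rather than the raw medial axis, which sprouts spurs on
rasterized ribbons. Local full width at a skeleton pixel is `2·EDT − 1`:
the Euclidean distance transform measures to the nearest *background pixel
center*, half a pixel beyond the mask boundary, and the −1 makes a
5-px-wide bar measure 5 and a radius-10 disk measure ≈ 19.

Branch decomposition: skeleton pixels of 8-degree ≥ 3 are junctions;
8-adjacent junction pixels merge into one node. Endpoint spurs shorter than
`spur_len = 3` px are pruned (two rounds). Inter-junction pieces shorter
than their own mean width + 2 px are absorbed into the junction: where two
children meet a parent a few pixels apart, the piece between the meeting
points is the interior of a single branchpoint, not a branch — branch
structure below the local width is unresolvable.

Classification rule table (defaults in pixels; scale physically via
`pixel_size`):

| rule | parameter | default |
|---|---|---|
| soma = mask component of `EDT ≥ θ_soma·max(EDT)` holding the EDT peak | `theta_soma` | 0.6 |
| branches wholly inside the soma are absorbed (not counted) | — | — |
| SOMA_PRIMARY: soma-incident and mean width ≥ θ_primary·soma width | `theta_primary` | 0.35 |
| TERMINAL: distal `l_tip` skeleton px of each non-primary leaf end away from the soma | `l_tip` | 5 |
| FINE: remaining segment mean width ≤ θ_fine | `theta_fine` | 3 px |
| SECONDARY: everything else | — | — |

Branch mean width is measured over skeleton pixels *outside* the soma
region, so a thin process entering the wide soma is not promoted to
primary. `branch_counts` reports SOMA_PRIMARY as 1 (the soma) plus the
number of primary branches; TERMINAL counts tip segments.

Territories: every mask pixel is assigned its geodesically nearest typed
segment by iterated 8-neighborhood minimum-label propagation inside the
mask (chessboard metric, ties to the lower segment id); soma pixels are
typed SOMA_PRIMARY outright. The chessboard metric differs from exact
Euclidean geodesics by at most a factor √2 locally, well below the width of
the territories involved.

## Mitochondria

Detection reuses the region detector on the organelle channel with pixels
outside the cell mask set to the background median (σ estimated on the
unsuppressed image); detections are clipped to the mask. Each mitochondrion
takes the branch type holding the plurality of its pixels in the territory
map, ties resolved toward the finer type (terminal > fine > secondary >
soma/primary). Per-type counts and arithmetic mean sizes are reported only
for secondary, fine and terminal; soma/primary assignments increment
`excluded_mito_count`, so reported + excluded = detected on every run.
Sizes are pixel counts, with µm² = px·pixel_size² in the tables.

## Organization metrics

Distances are center-to-center with no edge correction (border somas keep
their observed neighbors). k = 9 is the default neighbor count for the
multi-neighbor mean. Cluster areas: maximum projection of a stack,
isotropic Gaussian blur of radius 1.0 (0 disables), user-supplied threshold
(the measurement is defined on interactively thresholded images, so no
auto-threshold is provided), 8-connected components, areas *strictly*
greater than `min_area = 500` px, descending. The KS statistic is the exact
sup-distance between the two empirical CDFs, evaluated at all sample
points; p-values are out of scope.

## Synthetic benchmark

The generator emulates a cultured astrocyte at roughly 0.2–0.3 µm/px on a
512×512 16-bit canvas: a soma disk (radius 12 px), 4–5 primary trunks
(width 9 px, length 55–80 px), two secondary children per trunk (5 px,
40–60 px), and two fine grandchildren per secondary (rendered 1–2 px,
25–40 px), grown as tortuous polylines (≤ 12° bend per 3-px step). Children
attach at their parent's distal endpoint, so every level transition sits at
a branchpoint — the hierarchy the classifier infers is branchpoint-
delimited by construction. A collision system forbids any contact between
ribbons other than a child touching its own parent at the attachment
(1-px moat, whole-arbor restart if a subtree cannot be placed), because a
single accidental contact creates a spurious junction that corrupts the
ground-truth topology. Intensities default to background 100 and
foreground 240 (both channels), so the stress condition — noise
sd 28 = contrast/5 — stays clear of the zero clip.

Mitochondria are ellipses elongated along their host branch, clipped to the
cell raster (organelles live in the cytoplasm); the clipped pixel set is
the ground-truth size. Placement: secondary/fine hosts mid-branch (30–70%
of arc length, additionally at least `tip_length + 7` px from the end so
the organelle stays out of the terminal compartment), terminal mitochondria
half a tip-length from the leaf end, soma mitochondria inside the disk.
Placements keep a 1-px gap and must remain one 4-connected piece after
clipping, so each is detectable as a single region.

Rendering is constant-intensity with additive seeded pseudo-normal noise.
What the benchmark does **not** emulate: the point-spread function and
focal blur, Poisson photon statistics, intensity falloff along processes,
autofluorescence texture, overlapping neighbor cells, and 3-D structure.
Passing the round-trip tests therefore demonstrates that the algorithms
recover what they are defined to recover under the stated noise model — not
performance on real micrographs, where the detector's σ estimate and the
width thresholds would need checking against the instrument's scale.

## Problem sizes and determinism

The test suite and the acceptance script verify: linkage optimality on 100
random graphs (≤ 8 nodes) and bottleneck optimality on 100 random 5×5
grids against brute-force/threshold-connectivity oracles; false-positive
calibration on 200 pure-noise 128×128 fields; branch-type recovery on 20
zero-noise arbors (≥ 90% agreement observed ≈ 99.9%); mitochondrial
count/size recovery exact at zero noise and within ±10%/±15% aggregated
over 20 arbors at 5σ contrast; geometry oracles on 50 random point sets;
and bit-identical outputs for repeated runs. These sizes keep the full
verification under a few minutes on one CPU while leaving each statistical
check comfortably powered.

All randomness — generator geometry, placements, rendering noise — flows
from explicit integer seeds through `numpy.random.default_rng`; the
pipeline itself is deterministic, so a config plus a seed reproduces every
output file byte for byte.
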