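# Methods

## The measurement

Anterior vertebral compression (VC) quantifies the loss of anterior height
of one vertebral body against its two vertical neighbours. With anterior
heights `Ha_upper`, `Ha_target`, `Ha_lower` (each the Euclidean distance
between the two anterior — left, on a lateral view — corner vertexes of a
body),

```
VC (%) = (ref − Ha_target) / ref × 100,        ref = (Ha_upper + Ha_lower) / 2
```

The neighbour-mean reference is the default; a max-neighbour reference is
available via `compute_vc(..., denominator="max")` since the clinical
literature uses both conventions. The formula is a pure ratio, so pixel
spacing cancels and measurements on the standardized 512 × 512 grid need no
spacing metadata. VC is negative whenever the target is taller than the
reference — which is not an error: a healthy body adjacent to a collapsed
one measures negative by construction, and such triplets are deliberately
kept in regression training sets.

The underlying assumption is that the two flanking bodies are an adequate
surrogate for the target's pre-fracture height. The pipeline does not try
to decide whether a measured compression is a fracture; it reports the
number.

## Phantom generator

`spinevc.phantom` renders a vertical stack of convex quadrilateral bodies
(anterior side left) on a square canvas, with exact corner coordinates,
anterior heights and VC values as ground truth.

* Geometry defaults: 4 bodies of 96 × 120 px with a 12 px gap on a 512 px
  canvas — proportions of a collimated lateral lumbar view after
  standardization. Compression lowers the upper-left corner by the
  requested fraction of the body height (anterior wedging, the dominant
  osteoporotic pattern); it shortens the anterior edge without breaking
  convexity. Per-body in-plane tilt is available.
* The whole stack is translated by a random sub-pixel offset. Grid-aligned
  polygon edges are a rasterization knife-edge (the pixel row a boundary
  falls into becomes ambiguous) that real anatomy never exhibits; the
  common offset leaves every height and every VC unchanged.
* Rendering: body intensity 0.7, background 0.3, additive Gaussian noise
  (σ = 0.03 of dynamic range by default) — enough contrast structure for
  CLAHE and for small segmentation training runs to be meaningful.
* Corpus conditions used by the training builders and the acceptance
  script: each interior vertebra is independently wedged with probability
  1/2 by a fraction drawn uniformly from 0–50%, spanning the clinically
  reported range from incidental to severe compression.
* Degradations (`degrade_mask`) produce masks violating exactly one
  accurate-segmentation condition: a bridge merging two bodies
  (condition 1), a circular fillet replacing a corner with a smooth arc
  (condition 2), or deletion of an interior body (condition 3).

What the phantom does **not** emulate: ribs, pedicles, endplate curvature,
osteophytes, projectional overlap, exposure gradients, or genuinely
ambiguous boundaries. Passing phantom tests therefore demonstrates that the
algorithms are correct on well-posed inputs — not that clinical accuracy at
any particular level is achieved. Quantities obtained on phantoms
(e.g. Dice ≈ 0.99) are upper bounds that clinical data would lower.

### Resolution analysis behind the default body size

A binary mask localizes each polygon edge only to within one pixel
(~U(−0.5, 0.5) px error after the subpixel refinement's half-pixel
correction). The VC error is roughly `(δ_target + δ_ref)/ref × 100` for
height errors δ; with reference heights ≥ ~70 px this stays comfortably
inside the 1.5-percentage-point consistency budget the phantom suite
enforces, which motivates the 96 px default body height. Empirically the
maximum |error| over 4000 random triplets is < 1 pp.

## Preprocessing

CLAHE (`skimage.exposure.equalize_adapthist`) with a normalized clip limit
(default 0.02) on an 8 × 8 tile grid, applied to the original raster
*before* resizing so the tile size tracks the acquisition resolution.
Standardization scales the long side to 512 (bilinear for images,
nearest-neighbour for masks so they stay binary), pads the short side
symmetrically with zeros, and records the affine (scale, row/col offsets);
the inverse maps standardized coordinates back to original pixels to
within 0.5 px. Constant images pass through CLAHE unchanged (degenerate
histogram). Intensities are normalized to [0, 1] before network input.

## Segmentation networks

One symmetric encoder/decoder topology hosts all three variants; only the
convolution block differs:

* **block** = two 3 × 3 conv → BN → ReLU units;
* **residual** variants add a 1 × 1-projected shortcut from block input to
  block output;
* the **recurrent** variant applies its second unit's kernel `time_steps`
  times (default 2), re-adding the unit input at each step
  (`x_t = f(w·x_{t−1} + x_0)`, kernel and BN shared across steps).

So `unet` = plain blocks, `resunet` = + shortcut, `r2unet` = + shortcut and
recurrence. Two useful identities follow by construction and are asserted
in tests: `r2unet` with one time step has exactly `resunet`'s parameter
count, and with the shortcut disabled it *is* `unet` (identical weights
give identical outputs). Encoder levels halve the grid with 2 × 2 max
pooling; decoder levels upsample 2 ×, halve channels with a 3 × 3 unit and
concatenate the skip feature map; a 1 × 1 convolution plus sigmoid yields
the per-pixel foreground probability, binarized at 0.5.

Training choices left open by the architecture description and fixed here:
binary cross-entropy loss, Adam optimizer at the documented learning rate
(0.001, batch 5), He initialization, default width 32 channels at the top
level, depth 4 for 512-px inputs. All exposed in `SegModelConfig` /
`TrainParams`. Reference hyperparameters for full-scale runs are batch 5,
200 epochs, lr 0.001; the scaled-down experiments in the test suite use
20 training phantoms at 128 × 128, depth 3, 8 base filters, 30 epochs —
problem sizes chosen so the whole suite trains networks from scratch on a
single CPU while still demonstrating generalization (held-out Dice ≈ 0.99
against an acceptance floor of 0.8).

## MRDN regressor

Input: a triplet crop, aspect-pad-resized to 128 × 128 (six pooling stages
require divisibility by 64). Stem: six 3 × 3 conv → BN → ReLU → 2 × 2
max-pool layers, channels doubling from 16 with a cap (default 128) to
keep the parameter count in check. Then one multi-scale residual dilated
block (MRDB): 1 × 1 bottleneck, four *parallel* 3 × 3 dilated convolutions
at rates 2/4/8/16 (receptive spans 5–33 px), channel concatenation
(4 × bottleneck width), a closing 3 × 3 convolution back to the stem
width, and a single residual addition of the block input at the very end.
Global average pooling and a linear unit output the scalar VC in percent.
The block count is configurable (`n_mrdb`, default 1).

Training: mean squared error, Adam, reference hyperparameters batch 8,
up to 150 epochs, lr 0.01. The `CompressionRegressor` estimator
standardizes targets internally for optimization — a reparametrization of
the linear head, inverted at prediction time — which makes the stated
learning rate well-scaled regardless of the target units. The scaled-down
experiment (200 training crops, 40 epochs, 8 stem channels) reaches
held-out MAE ≈ 2–3 pp against an acceptance ceiling of 5 pp.

## Division and the accurate-segmentation filter

Components are 4-connected (bodies are separated by background gaps;
8-connectivity would bridge diagonal near-contacts), labelled 1..n by
centroid row. Speckle below 1% of the median component area is discarded.
The three conditions are operationalized as:

1. *merge*: any component taller than 1.8 × the median component height;
2. *corners*: vertex detection must succeed on every body;
3. *adjacency*: any vertical bbox gap larger than 1.0 × the median height.

The first failing condition is reported; thresholds are keyword
arguments. Passing masks yield the n − 2 sliding triplets (k, k+1, k+2),
each cropped to the joint bounding box plus a 4 px margin with all other
components zeroed.

## Vertex detection and subpixel refinement

Coarse corners: on the convex hull of a component's pixels, the point
farthest from the centroid in each diagonal quadrant, with ties broken
toward the sharper hull angle. A hull vertex with interior angle above
150° is too blunt to be a corner; a missing or blunt quadrant raises a
corner-detection error, which is precisely how rounded/degraded bodies
trip condition 2 (a disk has no corners, by design).

Refinement: total-least-squares lines are fitted to the boundary pixels
along each of the four edges between coarse corners (excluding a 2.5 px
margin near the corners), shifted half a pixel outward because boundary
pixel centres sit inside the true edge, and intersected; intersections
moving more than 3 px from the coarse corner fall back to it. This reduces
corner error from ~1 px to ~0.3 px and VC error accordingly.

The left/right split uses the line through the *upper and lower* body
centres for all three bodies (the middle body reuses the same line — the
simplest consistent choice); vertexes are assigned by the sign of the
cross product, and anything other than a 2/2 split is a partition error.

## Evaluation statistics

Confusion counts are exact integers; sensitivity, specificity, accuracy
and Dice follow the standard pixel definitions, with zero-denominator
scores reported as NaN (not 0) so aggregates stay honest. MAE/MSE/RMSE are
computed on percent units. Bland–Altman uses differences
(predicted − manual), sample SD (ddof = 1) and 1.96 × SD limits of
agreement; Pearson correlation uses `scipy.stats.pearsonr` with NaN on
zero variance.

## Determinism

Every stochastic component (phantom sampling, weight initialization,
batch shuffling) is driven by an explicit integer seed through
`numpy.random.default_rng`; identical configurations reproduce bit-identical
phantoms, training runs (on one device) and pipeline output tables.

## Known limitations

* The numpy engine trains on a single CPU; it is suitable for the phantom
  experiments here, not for full-scale clinical training runs.
* Binary-mask geometry cannot beat ~0.3 px corner accuracy; heavily
  collapsed bodies (short reference heights) amplify this in the VC ratio.
* The condition thresholds (1.8 ×, 1.0 ×, 150°) are one consistent
  operationalization of qualitative screening rules; clinical deployment
  would tune them on real failure modes.
* Anatomical level naming (T8…L5), Cobb angle and kyphotic angulation are
  out of scope.
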