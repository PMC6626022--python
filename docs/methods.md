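# Methods

This note documents the models and numerical choices behind `mmscope`,
what its synthetic validation does and does not show, and the design
decisions taken where several reasonable options existed.

## Imaging-modality model

Brightfield frames of a mother-machine device are predominantly bright
with sparse dark structures (channel walls, cells); phase-contrast
frames invert that arrangement. The per-frame statistic is the
*uncorrected* sample skewness G₁ = m₃/m₂^{3/2} of the flattened pixel
values; at megapixel sample sizes the small-sample bias correction is
irrelevant. Classification uses only the sign (positive → phase,
negative → brightfield); G₁ = 0 ties to brightfield because only the
positive branch is evidence of phase contrast. The statistic is
invariant under positive affine intensity maps and flips sign under
reflection, so normalisation of the input is immaterial. Per-frame
decisions within one imaging area are reconciled by majority vote (one
acquisition has one modality); disagreement is logged.

## Channel detection

Walls are enhanced with a multi-scale Frangi ridge filter (brightfield;
dark-ridge polarity, scales {1, 1.5, 2, 2.5, 3} px — walls are a few
pixels wide at the reference magnification) or Sobel gradient magnitude
(phase). The response is binarised with Li's minimum cross-entropy
threshold, components outside 500–50 000 px² are dropped, survivors are
dilated (disk, radius 2 px) to close small wall gaps, hole-filled, and
the interiors taken as fill minus dilated outline.

Cells inside a channel also respond to the ridge/edge filter and can
slice its interior into fragments; all fragments within one filled
component are therefore treated as a single channel interior and the
slice gaps closed morphologically (disk of radius = dilation radius + 2).

Each interior's axis joins its two farthest-apart pixels; regions are
kept when the axis length lies in 100–400 px and the perpendicular
extent in 5–40 px. Every length-dimensioned parameter above is
multiplied by a single user-facing scale factor (areas by its square) so
one knob adapts the pipeline to a different magnification.

Channels are ordered left-to-right by their centroid projection
orthogonal to the mean axis direction. The pitch is a *divisor-aware*
median of consecutive separations: each separation is first divided by
its rounded multiple of the smallest separation, so that one or two
missed channels cannot inflate the estimate (a plain median fails
already for three channels with one interior gap). Interior gaps of
≈ m·pitch receive m−1 stamped copies of the mean channel shape —
the pixelwise majority (> 50 %) of the detected interiors after
translation to a common centroid and rotation to the common axis angle.
No extrapolation happens beyond the outermost detections, since there is
no evidence a stamped channel there would lie in the field of view.
Final masks are dilated by 3 px: deliberately slightly generous masks
keep channel recall near 1 so no cell pixels are lost to the next stage
(at a small, accepted cost in channel precision). Fewer than three
detected channels make the pitch unidentifiable; such frames raise
`FrameRejected` and are skipped, with tracking linking across the gap's
neighbours.

## Bacteria detection

Cells are darker than their channel background in both modalities, so
each channel crop is inverted and its slowly varying background removed
with a rolling ball of radius 10 px (≈ 2 cell widths: large enough not
to erode cells, small enough to track the channel profile). This makes
segmentation independent of where a cell sits along the channel and of
smooth illumination gradients. A scale-normalised LoG bank
(σ ∈ {1.5 … 3.5} px, response −σ²∇²G∗I, maximum-projected over σ) turns
rods of varying width into uniform positive blobs; the image mean is
subtracted first because the discrete LoG kernel does not sum exactly
to zero and would otherwise leak a DC bias into every response.

One Li threshold per frame is computed over the pooled responses of all
channels. This is essential for empty channels: their noise response
falls below a threshold anchored by occupied channels, whereas a
per-channel threshold would always split noise into spurious objects.
Watershed markers are the connected regions of distance transform
≥ 3 px from the mask background; the watershed floods the inverted
response under 4-connectivity (deterministic tie-breaks). Regions are
then filtered to width 2–15 px and area 20–2 000 px².

The second splitting stage targets abutting cells: each region's
skeleton path is traced (longest path between endpoints) and a cut is
declared where, within a 3-px window, the local width (distance
transform) falls below median − 2·MAD *and* the local intensity falls
below median − 2·MAD, both statistics pooled over all initially
detected cells of the frame. The conjunction is deliberate: a dim patch
without a waist, or a waist without dimming, is a single cell. Two
guards suppress false cuts: a cap-sized margin (2 × median width) at
both skeleton ends, where rods are naturally narrow and dim, and a
post-hoc merge of any child smaller than the minimum cell area back
into its neighbour. Region pixels are assigned to the nearest skeleton
segment, so children always partition the parent exactly.

## Tracking

The whole-field drift between consecutive frames comes from
phase-correlation template matching; the Pearson correlation of the
overlap at the estimated shift is reported, and below 0.3 the shift
falls back to (0, 0) with a warning (two structureless images correlate
near zero). Channels are linked when each is the other's nearest
neighbour after shift correction — a deliberately conservative rule
that prefers no link to a wrong link.

Bacteria tracking enumerates, per channel, all combinations of
per-cell events between consecutive frames: each previous cell lyses
(0 children), persists (1) or divides m times (2^m consecutive
children, m ≤ 2 per interval — more than 4-fold growth between frames
is implausible at typical imaging cadence and the cap bounds the
combinatorics). Assignments never cross along the channel axis (cells
cannot pass each other in a dead-end channel) and new cells enter only
at the open end; these two physically forced constraints collapse the
hypothesis space enough for exhaustive scoring. Which end is the dead
end cannot be inferred from a single frame, so it is a configuration
flag (default: the low-projection end, matching the synthetic
geometry); on real data it should be set from the device orientation.

Each hypothesis scores as a product of per-cell terms
p_area · p_centroid · p_event:

* p_area = exp(−½((ΣA_children/A_parent − 1)/σ_A)²), σ_A = 0.2; for
  divisions the n-th root is taken (a per-division geometric mean) —
  the functional form of the "normalised by the number of divisions"
  rule is a design choice; the root keeps every term in (0, 1].
* p_centroid = exp(−½((d − n_div·L/2)/σ_c)²) with d the mean child
  displacement from the (shift-corrected) parent centroid, L the median
  cell length of the previous frame and σ_c = L/2: each division is
  expected to displace centroids by about half an average cell length.
  The Gaussian form itself is a design choice; only the L/2 expectation
  is structural.
* p_event: priors 0.90 / 0.07 / 0.03 for no-change / division / lysis
  (configurable; division and lysis are rare at hourly cadence).

Lysed cells contribute their prior only; new cells contribute no term.
The arg-max hypothesis is applied; ties break deterministically by
fewest non-trivial events, then fewest divisions, then lexicographic
assignment. Persisting cells keep their global lineage id; offspring
and newcomers get fresh ids. Tracking links consecutive accepted frames
only — there is no gap-closing beyond a rejected frame's neighbours and
no whole-track smoothing.

## Quantification

Length and width are the major/minor axis lengths of the second-moment
ellipse of the mask (the standard region-property definitions; note the
moment ellipse of a perfect rectangle of length a has major axis
≈ 1.15 a). A skeleton-geodesic length is available behind a flag for
strongly curved cells. Fluorescence is reported as mean-over-mask minus
background, background being the mean fluorescence of the cell's own
channel minus all cell masks — same channel, same frame, so local
illumination cancels; a fully occupied channel borrows the pooled empty
area of the frame's other channels (with a warning). The mean (not
median) background keeps the measurement exactly linear in the input
plane. All outputs are in pixels; physical calibration is a CSV-level
multiplier left to the user, since pixel size is acquisition metadata.

## Synthetic fixtures

The generator renders what the pipeline *relies on*, not optics:
channels as closed dark wall outlines (brightfield) or a bright-on-dark
scheme (phase) at a regular pitch, cells as capsules darker than their
channel background, a linear illumination ramp, Gaussian sensor noise
(default σ = 5 % of the cell/background contrast), rigid inter-frame
drift, and per-cell dynamics: linear growth (3 px/frame), division at a
length threshold into two half-length children with a 1-px gap, and
scheduled lysis (the cell is present up to the scheduled frame and gone
from it on). Cell positions are persistent: growth pushes cells toward
the open end only, and a lysed cell leaves a gap rather than letting
neighbours slide back — the physically correct behaviour, and the one
that makes lysis identifiable for the tracker. Default geometry:
8 channels of 150×12 px at 40 px pitch in a ~250×420 px frame, two
cells per channel with initial lengths U(25, 40) px, i.e. 10–20 cells
per frame. Identical spec and seed give bit-identical output.

Not modelled: point-spread functions, phase halos, cell crowding and
mechanical interactions, focus drift, filamentation. Passing the
synthetic suite therefore demonstrates the correctness of the
algorithmic chain under controlled conditions, not performance on any
particular real dataset; the published-scale numbers on real
acquisitions are outside what this repository can recompute.

## Validation protocol and problem sizes

`scripts/acceptance.py` recomputes two headline numbers at desk scale,
chosen as the package's own standard problem sizes:

* detection-efficiency proxy: 10 series × 3 frames at the default
  geometry (≈ 480 ground-truth cells pooled), full pipeline, a cell
  counting as detected when detections cover ≥ 50 % of its area;
* channel-tracking proxy: 50 consecutive-frame pairs with integer drift
  uniform on [−15, 15] px, ground-truth channel sets as input, shift
  estimation + mutual-NN matching, scored against the known identity.

The 50 % overlap convention is the standard object-detection criterion;
it is exposed as a parameter since other conventions exist.

## Known limitations

* The dead-end orientation flag must be set correctly for real data.
* Curved or branched channels, and channels open at both ends, are out
  of scope.
* Filamentous cells defeat the median/MAD split statistics (the MAD
  collapses when most cells are abnormal).
* The hypothesis scorer compares consecutive frames only; a detection
  error in one frame can propagate a relabelling into the next.
* Fluorescence is not corrected for photobleaching or flat-field.
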