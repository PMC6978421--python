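# Methods

## The growth model

A mycobacterial cell elongates only at its two poles. The **old pole**
(inherited from the mother) grows at the fast rate from birth. The **new
pole** (created at the last division) follows a continuous bilinear law with
four parameters — offset `c`, pre-changepoint speed `v_slow`, post-changepoint
speed `v_fast`, and the changepoint time `t_NETO` measured from pole birth:

    L(t) = c + v_slow · min(t, t_NETO) + v_fast · max(0, t − t_NETO)

The law is continuous at the changepoint by construction and non-decreasing
whenever both speeds are non-negative. Each pole carries its own clock: the
changepoint is drawn independently of the division time, so for a minority of
poles it falls after the next division. Lineage bookkeeping therefore carries
a pole's parameters and age across divisions rather than resetting them.

Default population parameters (mean ± SD, drawn from independent normals
truncated at zero by resampling):

| species | lag (h) | interdivision (h) | v_slow (µm/h) | v_fast (µm/h) |
|---|---|---|---|---|
| *M. smegmatis* | 2.9 ± 0.8 | 3.6 ± 0.7 | 0.15 ± 0.06 | 0.61 ± 0.13 |
| *M. tuberculosis* | 6.2 ± 2.2 | 16.3 ± 3.1 | (as Msm) | (as Msm) |

Elongation speeds are not published for *M. tuberculosis*; its preset borrows
the *M. smegmatis* speeds, which affects only trajectory shape, not timing
statistics. No presets are provided for *M. abscessus* or *M. marinum*
because only their asymmetry-ratio averages (not absolute times) are
published; they are supported via custom `PopulationParams`. Truncation is by
resampling, not clipping, to avoid a point mass at zero; the truncation is
mild for every printed parameter (the most affected, the Mtb lag, is 2.8 SD
from zero). Lag and interdivision time are drawn independently — whether they
are correlated within cells is unknown; the assumption is explicit and the
sampler takes the two distributions separately so a correlated variant could
be substituted.

**Wag31 accumulation.** Polar recruitment of the wall-synthesis scaffold
Wag31 (DivIVA) at a new pole follows an asymptotic exponential,
`I(t)/I_f = 1 − (1 − i₀) e^(−t/τ)`, with defaults i₀ = 10% of the final
level and τ = 2.4 h. Evaluated at the mean lag (2.9 h) this puts the level
at ≈73% of final at take-off. The photo-converted Wag31 pool is modelled as
pure conservation bookkeeping — the total is fixed (photobleaching neglected)
and splits evenly across all poles at equilibrium — because no kinetic law
for the relocalization is established; per-pole signal halves at each
division as the pole count doubles.

**Wall-age partitioning.** The lineage simulator tracks cell-wall material as
1D segments on a material axis. Material never moves once synthesized; poles
prepend/append segments tagged with the synthesizing generation (the
founder's endowment is generation 0). Division splits the segment list at a
plane a configurable fraction (default 0.5, symmetric) of the cell length
from the old pole. At the *M. smegmatis* means, one deterministic cycle gives
an old-pole daughter that is 72.5% newly synthesized wall and a new-pole
daughter that is 28.5% new — verified against a 1-nm brute-force
discretization of the same growth law (agreement < 0.2%).

## Synthetic imaging

Rendered stacks emulate two instrument classes: AFM-like height maps
(default 30 nm pixels, bright capsule on dark background, 13-min frames) and
phase-contrast-like images (dark rod on bright background; 65 nm pixels
would be typical, the pixel size is a free parameter). Cells are capsules
(capped rods, default width 0.5 µm) on a shared axis. Choices that matter:

- **Material is immobile in the lab frame.** Growth only advances the pole
  tips, so cell bodies, the multiplicative surface texture riding on them
  (emulating the wave-troughs, scars and blebs that make the surface
  trackable; amplitude 6%, correlation length 0.12 µm), and the fiducial
  bumps all stay put. This is what makes surface structures usable as
  fiducial markers.
- **Division snap.** At each division the two sibling subtrees are displaced
  apart along the axis by `snap_nm` total (default 100 nm), split ±snap/2 —
  only the total separation is characterized experimentally, so an even
  split is assumed.
- **Sub-resolution junctions.** A ~100 nm inter-sibling gap is far below
  optical resolution — that is precisely why snapping, not a visible gap, is
  what timestamps division. Neighbours closer than `junction_resolution_um`
  (default 0.2 µm) render as one continuous rod, so the junction region is
  flat and does not flicker frame to frame; texture ownership in overlap
  regions is split at a fixed seam so the texture field never morphs. After
  division the siblings' inner poles grow back toward each other and the
  model lets their material intervals interpenetrate slightly rather than
  modelling mechanical pushing; the rendered chain is correspondingly a few
  tens of nm shorter than the summed cell lengths late in a movie.
- Fiducial ownership follows the *inherited material* (birth segments), so a
  sibling whose pole regrows past the division plane never captures a
  fiducial on the other side.
- Coordinates: frame origin top-left, 0-based pixel indices, physical
  positions measured at pixel centers; annotations (per-frame cell extents,
  fiducial tracks, division events) are embedded ground truth in nm.

What the generator does **not** emulate: optical point-spread functions,
AFM tip convolution, cell bending or rotation, crowded-colony mechanics, and
uneven illumination. Passing tests therefore demonstrate correctness of the
algorithms under idealized rod geometry and Gaussian noise, not robustness
to every artifact of real micrographs.

## Fitting

**Bilinear changepoint fit.** For a fixed changepoint the model is linear in
the other three parameters, so the fit profiles the changepoint over every
interior sample time (excluding the first/last two points) with closed-form
least squares, then polishes the best three candidates with Nelder–Mead over
all four parameters (xatol 1e-6, fatol 1e-8, ≤2000 iterations per restart).
The changepoint is constrained to `[t₂, t_{n−2}]` to avoid boundary
degeneracy — a pole whose changepoint falls outside the observation window
is reported as "no changepoint detected", never extrapolated. Slopes are
unconstrained during optimization (the fit may describe a slowdown);
classifying a pole as biphasic requires `v_fast > v_slow` post hoc. Ties
between restarts break toward the earliest changepoint. On noiseless data
the generative parameters are recovered to < 1e-4; across 200 noisy
trajectories the mean estimates are unbiased within Monte-Carlo error.

**Model selection.** Old poles are linear, new poles biphasic, but no
selection rule is published; BIC with a Gaussian likelihood (k = 3 vs 5
parameters including the noise variance) and a margin of 2 is used: the
bilinear model must undercut the linear BIC by more than the margin. The
false-changepoint rate on genuinely linear data at 50 nm noise is ~5%
(≤10% across 500 simulations). Both RSS values are floored at a
machine-scale epsilon so two numerically perfect fits tie and parsimony
keeps the line.

**Asymptotic exponential.** `I(t) = I_f − (I_f − I_0) e^(−t/τ)` via
Levenberg–Marquardt (trust-region with τ > 0), τ's 95% confidence half-width
from the linearized covariance, adjusted R² reported. A flat trace leaves τ
unidentifiable and is flagged as non-converged rather than raised.

## Image pipeline

- **Registration**: translation-only phase cross-correlation of consecutive
  frames (subpixel by upsampled matrix multiplication), cumulative drift
  removed against frame 0. Rotation is out of scope (synthetic cells are
  rendered without rotation).
- **Segmentation**: global Otsu (or fixed) threshold, connected components,
  removal of objects below 0.2 µm². Siblings in end-to-end contact merge
  into one label by design; separating them is the division detector's job.
- **Division detection**: for each consecutive frame pair, the axial profile
  is tiled into 20-pixel body windows (pole caps and inter-cell gaps are
  excluded by an intensity mask at 75% of body height); each tile's rigid
  displacement is estimated once by normalized 1D cross-correlation with
  parabolic subpixel refinement, with the lag search bounded at ±0.25 µm to
  reject aliased peaks on weakly textured windows. For each candidate plane
  the median displacement of the up-to-three tiles nearest the plane on
  either side is compared (using the nearest tiles keeps a snap from being
  diluted by unrelated cells further along a chain); the frame statistic is
  the maximum divergence over planes. An event is called where that
  statistic exceeds the median plus `threshold_factor` (default 3) times the
  robust MAD scale of the non-candidate frame pairs; the noise scale is
  floored at 0.1 pixel, the practical accuracy of subpixel correlation, so a
  few unusually quiet pairs cannot push the threshold below what the
  estimator can resolve. The quiet-frame median (slow growth common to every
  pair) is subtracted from the reported separation. On rendered ground truth
  the estimate is 101 ± 2 nm for a 100 nm snap, with zero false positives
  across 50 static stacks.
- **Pole measurement**: the pole tip is the subpixel half-maximum crossing
  of the axial profile on the chosen side; the reference fiducial (nearest
  usable one) is re-localized by quadratic peak interpolation around its
  track position. Reported length = |tip − fiducial| plus accumulated
  handoff offsets, so the curve is continuous when the reference changes;
  frames with no usable fiducial yield NaN, never interpolation. Static-cell
  repeatability at default settings is a few nm SD, comfortably inside the
  ~50 nm precision the measurement concept is specified to.
- **Wall-age map**: per-frame binary masks summed pixelwise; inter-frame
  drift above 2 pixels triggers a warning (with the maximum drift found)
  since the method presumes a colony that does not move.

## Problem sizes

The test suite and the acceptance script use 200 trajectories per
parameter-recovery experiment (100 for the slow-growing species, whose
trajectories are twice as long), 200 fluorescence traces, 10,000 Monte-Carlo
(lag, interdivision) draws, 30-frame rendered stacks, and 50 replicate
static stacks for the false-positive check. These sizes put every
Monte-Carlo standard error well below the effect sizes being checked while
keeping a full run in the minutes range on one CPU.

## Known limitations

- The axial measurement is a straight-line projection; bent cells and
  curved-centerline geodesics are not handled.
- The division detector assumes registered input; it warns but still runs on
  drifting stacks.
- Sibling junction mechanics (pushing) are not modelled; see the rendering
  notes above.
- The automated pole/fiducial localizer replaces what was historically a
  manual measurement; it is validated only against synthetic ground truth.
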