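# Methods

`sarcoquant` quantifies a sarcolemma-localised target protein (typically
dystrophin) in every myofibre of a transverse skeletal-muscle section imaged
in two fluorescence channels: a *membrane* (fibre-identification) channel —
spectrin or laminin — and a *target* channel.  This note records the model
behind each stage, the parameters that matter, what the synthetic sections do
and do not emulate, and the numerical choices made where the design was open.

## Fibre recognition

The membrane channel of a transverse section shows myofibres as closed
polygonal rims.  Recognition proceeds in six steps:

1. **Tissue detection.** The membrane channel is smoothed
   (`tissue_smooth_um`, default 1.0 µm) and thresholded at
   `tissue_intensity_fraction` (default 0.15) of the median rim intensity,
   unioned with the rim network, hole-filled, and eroded by
   `tissue_erosion_um` (1.5 µm) to retract the smoothing glow past the
   outermost rims.  Anchoring the threshold on the rim level rather than on
   the image histogram keeps the mask correct whether background fills most
   of the frame (whole-slide scans) or almost none of it (crops).  A frame
   whose histogram is a single noise mode — Otsu class separation below twice
   the estimated noise SD — yields an empty mask and zero fibres.
2. **Rim network.** The membrane channel is ridge-enhanced with a Sato
   tubularity filter at `ridge_scale_um` (1.0 µm ≈ the rim width).  Thin
   bright rims respond; flat cytoplasm and broad bright plateaus (folded
   tissue) do not — this distinction later drives the fold rejection.  The
   response is binarised with a tile-local Gaussian threshold floored at half
   the global Otsu value (`threshold_method="local"`; a purely global
   variant is available), because illumination varies across whole slides.
3. **Candidates.** The network is closed morphologically
   (`closing_radius_um`, 1.0 µm) and candidate interiors are the connected
   components of tissue minus the closed network.  Components larger than
   the maximum fibre area containing two or more distance-transform maxima
   (at least `watershed_min_distance_um` apart) are split by watershed —
   the fallback for fused interiors.
4. **Structure filters.** A candidate is rejected when it touches the image
   border (completeness and area are undefined there); its area falls below
   `min_area_um2` (200 µm²: erythrocytes, axon profiles, vessel lumina,
   intrafusal profiles) or above `max_area_um2` (15 000 µm²: connective
   expanses); its solidity falls below `min_solidity` (0.80: irregular
   connective shapes, spindle interiors riddled with intrafusal profiles);
   its interior membrane-channel mean reaches `fold_intensity_fraction`
   (0.6) of the rim level (folded tissue is bright across its whole
   footprint); or its interior mean sits below `min_interior_fraction`
   (0.10) of the rim level above background (enclosed spaces with no
   cytoplasmic signal at all — interstitial pockets — are not fibres).
5. **Rim completeness and the 20 % rule.** The traced candidate boundary is
   sampled at ≈1 px arc steps.  A sample is *supported* when, within
   `rim_band_um` (1.0 µm) **outward** along the boundary normal, the maximum
   membrane intensity exceeds a threshold *and* the binarised rim network is
   present.  The intensity threshold adapts per candidate — half the median
   band maximum, floored at half the section-wide level — because rim
   intensities vary severalfold between fibres and a dim fibre's intact rim
   must not read as a gap.  The network condition excludes diffuse bright
   regions without ridge response (patch edges) from counting as rims.  The
   outward-only band must stay shorter than the interstitial spacing;
   otherwise the intact rim of the *neighbouring* fibre reads as support for
   a disrupted one.  Fibres missing less than `gap_exclusion_fraction`
   (default 20 %) of their rim are retained, their traced closure standing
   in for the reconstructed rim; fibres missing at least that fraction are
   rejected (`gap_gt_threshold`) on the reading that they are severely
   damaged or degenerating.  The measure-zero boundary case of exactly 20 %
   missing is assigned to rejection, giving a total ordering.
6. **Labels.** Accepted fibres are relabelled 1..N in raster order of their
   centroids, and each interior is expanded outward by `boundary_snap_um`
   (1.2 µm, equidistantly, so neighbours never overlap) to place the label
   boundary on the rim centreline rather than the network's inner edge.  The
   snap distance was calibrated against the measured offset between the
   binarised network's inner edge and the true rim centreline on synthetic
   sections; with it, ring means recover true rim intensities to <0.4 %
   noise-free.

Either spectrin or laminin may serve as the membrane channel; the logic is
identical, and the rim band is symmetric enough to tolerate the small
biological offset between a subsarcolemmal and a basal-lamina marker.

## Compartments and quantification

Per accepted fibre, the sarcolemma ring spans `b_in_um` (0.5 µm) inside to
`b_out_um` (0.5 µm) outside the (snapped) boundary, the outward part split
equidistantly where neighbouring rings would meet; the cytoplasm is the
interior eroded by `erosion_um` (1.5 µm).  Distances are measured from the
label boundary, which runs between pixel centres, so every physical radius
carries a +0.5 px offset against centre-to-centre distance transforms.  Ring
and cytoplasm are disjoint by construction; a fibre too small to survive the
erosion gets an empty cytoplasm and a flag rather than a substituted value.

All means are plain arithmetic means over the masks — bit-identical to an
explicit per-pixel loop on integer images.  The per-fibre record carries the
uncorrected ring mean of the target channel (the headline statistic, in
arbitrary units), the cytoplasm mean and their difference (`corrected_target`,
which may legitimately be negative and is flagged, not clipped), the
membrane-channel ring mean, the interior area (pixel count × pixel area), and
the minimum Feret diameter (rotating calipers on the convex hull of the
boundary).  Whole-section summaries use the *uncorrected* means: absolute
intensities are the comparable quantity across sections, and normalising to
the membrane marker is deliberately not a default output — membrane markers
are themselves elevated in dystrophic muscle, so the ratio underestimates
sarcolemmal target levels there (a flagged helper exists for explicit use).

The *legacy ROI* emulation reproduces the older operator-driven protocol: a
fixed-size uniform random sample of fibres (default 40 per sample), and per
fibre the maximum intensity over a sarcolemmal portion minus the minimum over
a cytoplasmic portion, summarised as mean ± SEM.  Background subtraction is
the default only here, matching how that protocol reported its values.

## Statistics

Section summaries use the sample SD (n−1), SEM = SD/√n and
CV% = 100·SD/mean; `cv_from_sem` exposes the identity
CV% = 100·SEM·√n/mean used to check printed summary tables for internal
consistency.  Distribution curves are fixed-width histograms over [0, max]
(64 bins by default; the binning is a presentation choice) expressed as
absolute and cumulative fibre-count percentages.  Group comparisons take the
unweighted average of section means per group (a section is one biological
observation regardless of its fibre count), report fold change and percent
reduction (rounded to integer percent for reporting), and test pooled
per-fibre values with a two-sided Mann-Whitney U, or one-way ANOVA across
three or more groups.  The bundled published per-section summaries
(`sarcoquant.published`) reproduce the reported Becker-muscular-dystrophy
reductions of 29 % and 14 % versus paediatric controls under exactly this
convention; the corresponding Duchenne reductions compute to 78 % and 69 %
against printed values of 83 % and 70 %, so the averaging convention behind
those two printed numbers is not recoverable from the published table and
they are not asserted anywhere.  Two published rows repeat the SEM in the CV
column and several others differ by 0.01 from the SEM-derived value; the
seven rows that are exactly self-consistent are the ones checked.

## Synthetic sections

The generator provides ground truth the real method can never have: per-fibre
true rim intensities, true gap fractions, and a full distractor inventory.

**Geometry.** Fibres are Voronoi cells of a maximal Poisson-disc point
process (mean cell area ≈ 1.6 r² for minimum distance r, measured
empirically), each shrunk by `interstitial_margin_um` and filtered to
`fibre_area_range_um2` (800–4500 µm², a paediatric fibre-size range).  Cells
clipped by the image frame are not rendered — a scanned section lies inside
the frame, and a clipped cell would carry an artificial straight rim along
the border.  Ground truth flags fibres adjacent to any unrendered region
(`on_tissue_edge`): a rim gap facing open surround has no bounding neighbour
rim and genuinely reads as tissue-edge damage.

**Rims.** The rim cross-section is a flat plateau of width `rim_width_um`
(1.5 µm) centred on the cell outline with Gaussian shoulders
(`rim_edge_sigma_um`, 0.25 µm).  A plateau — rather than a pure Gaussian —
makes the mean intensity over the rim footprint equal the drawn per-fibre
intensity, which is what turns the ground truth into an exact bookkeeping
oracle; the shoulders stand in for diffraction blur.  Gaps are carved as 1–3
arcs with Dirichlet-distributed lengths at uniform positions; each retained
arc is shrunk by half a rim width at its free ends before stamping so the
rendered support ends at the drawn arc boundary, and the *actual* removed
fraction (after merging overlapping arcs) is what ground truth records.
Default gap incidence is 1 % of fibres, the rate reported for real sections;
an optional `gap_assignment="spaced"` keeps gapped fibres non-adjacent.

**Interstitial margin.** The default margin is 3 µm (boundary-to-boundary
6 µm) — wider than real endomysium.  This is a deliberate idealisation: at
0.5 µm pixels, rims 2 µm apart are optically inseparable, and in real tissue
adjacent fibre membranes effectively share one rim, so a single fibre's
disruption is not locally decidable.  The wider margin makes each fibre's rim
individually attributable, which is what lets the 20 % rule be validated
*exactly* against ground truth.  The consequence — that the generator does
not model shared-wall ambiguity — is the main thing passing tests do *not*
show about real sections, and whole-slide deployments should expect the
completeness measurement to be optimistic wherever fibres truly abut.

**Intensities and noise.** Per-fibre rim intensities are drawn from named
distributions; defaults are lognormal with mean 18 000 au, CV 0.20 for the
target channel and mean 20 000 au, CV 0.10 for the membrane channel, on a
16-bit range with a 600 au background — matching the scale and ~20 % CV of
published control-section summaries.  A 12-bit option (0–4095) mirrors older
camera hardware.  Cytoplasm sits at `cytoplasm_intensity_fraction` (0.25) of
the fibre's rim level.  Noise is Poisson on the signal (gain 4 au/photon)
followed by additive Gaussian read noise with σ = 2 % of the dynamic range —
a standard sCMOS model.  Values are clipped to the dynamic range (with a
warning on overflow) and quantised to integers.

**Distractors.** Five kinds, each rendered in a fibre-free pocket carved out
of the tessellation, with footprints recorded: *vessel* (thick-walled annulus
with a sub-minimum lumen), *nerve bundle* (cluster of sub-minimum rimmed
profiles), *spindle* (capsule outline enclosing intrafusal profiles that
spoil the interior's solidity), *connective patch* (irregular diffuse region
with no closed rims, always larger than any fibre), and *fold* (a patch at
rim-level intensity across its whole interior).  Their abundance and
morphology are plausibility-driven defaults, not fitted to data.

**Determinism.** One `numpy` generator seeded from the spec drives every
draw; the same spec yields bit-identical images and ground truth.

## Validation metrics

A detected fibre matches a true fibre when its centroid falls inside the true
polygon.  Recall is computed over tissue-interior true fibres whose gap
fraction is below the exclusion threshold — fibres the protocol *requires*
rejecting are not detection misses — and precision counts every accepted
object that matches no true fibre against the pipeline.  On sections of
roughly 630 interior fibres under default noise and distractors, measured
recall and precision are 100 % across seeds; the rim-gap rule classifies
every fibre with true gap ≤ 18 % or ≥ 22 % correctly (the 18–22 % band is
excluded as measurement tolerance; per-fibre completeness error is
about ±0.01 SD, worst case ≈ 0.03).

## Problem sizes

The validation suite and the reproduction script use: a 3328² px detection
section (0.5 µm/px, ≈ 630 interior fibres), a 1536² px noise-free gap-rule
section with gaps uniform on [0, 0.35], a 1536² px default-noise recovery
section, and ten 1024² px sections spanning mean rim intensities
3000–22 000 au for the legacy-concordance check.  These sizes exercise every
code path at whole-slide-like fibre counts while keeping a full run in the
order of a minute or two.

## Known limitations

- No shared-wall model (see above); no fibre-type mosaics, oblique or
  longitudinal sections, 3-D stacks, or photorealistic histology.
- Revertant (sporadically target-positive) fibres are not distinguished —
  the method quantifies each fibre but does not classify it.
- Intensities are arbitrary units end-to-end; nothing is normalised on I/O,
  so cross-experiment comparisons inherit the staining and acquisition
  variability that the section-level CVs quantify.
- The rim-reconstruction of retained fibres keeps the traced closure as the
  boundary; no geometric in-painting of the missing arc is attempted beyond
  the morphological closure of the network.
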