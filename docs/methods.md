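# Methods

## Rectangular-duct flow model

The channel is modelled as fully developed, incompressible, Newtonian
laminar flow in a rectangular duct of width 2W (x ∈ [−W, W]), height 2H
(y ∈ [−H, H]) and length L, driven by a constant axial pressure gradient.
The solution is the standard double-cosh eigenfunction series; the series
amplitude c₁ = (1/μ)·dp/dz is normalised through the prescribed flow rate
via the mean velocity u_m = Q/(4WH), with the normalisation denominator

1 − (192/π⁵)(W/H) Σ tanh((2n+1)πH/2W)/(2n+1)⁵.

For wide channels this bracket is small (≈9.4×10⁻³ at W/H = 10) and the
implementation guards it with a positive floor, raising an
ill-conditioned-geometry error rather than dividing by a vanishing number.
Series terms are evaluated with overflow-safe cosh ratios (exp-difference
form once the argument exceeds 30), truncated at `n_terms = 500` or when a
term's relative contribution falls below 10⁻¹² — doubling the terms changes
peak WSS by <10⁻⁴ relative.  Wall shear stress on the cell-bearing bottom
wall (y = −H) is the termwise-differentiated series, reported as a
magnitude.  Q = 0 short-circuits every flow quantity to zero.

The axial pressure distribution uses the laminar friction-factor
correlation λ·Re = 96·(1 − 1.3553/α + 1.9467/α² − 1.7012/α³ + 0.9564/α⁴ −
0.2537/α⁵), α = W/H ≥ 1 (inputs auto-oriented), with Re = ρ·u_m·Dh/μ and
the standard hydraulic diameter Dh = 4A/P.  Gauge pressure is linear in z:
p(z) = P_out + (L−z)·dp/dz.  A raised outlet reservoir contributes ρgh,
plus an optional outlet-tube friction term μQL_tube·32/(πD⁴); the
coefficient is kept as written in the source correlation and exposed as a
named constant (`TUBE_FRICTION_COEFF = 32`; the classical Hagen–Poiseuille
coefficient would be 128, but the term is sub-pascal at these flow rates
either way, and it is reported separately so callers can confirm that).

**Viscosity.**  The library default is culture medium at 37 °C,
μ = 0.00072 Pa·s.  The published condition table for this chip (0.14 /
0.014 Pa peak WSS; 47.1 / 4.71 Pa ΔP; 3971.1 / 3928.7 Pa inlet gauge) is
internally consistent only under μ ≈ 1.0×10⁻³ Pa·s — both WSS and ΔP are
linear in μ, and the stated 0.00072 Pa·s yields values ≈28% lower.  We
verified with an independent finite-difference Poisson oracle (401×41
grid; agreement 0.07% on velocity and centreline WSS) that the series
itself is correct as printed, so the discrepancy lies in the tabulated
viscosity, not the model.  Test fixtures and the acceptance script
therefore pin μ = 1.0×10⁻³ Pa·s; library users get the physically stated
default unless they override it.

**Validation.**  The finite-difference oracle lives in the test suite only
(`tests/fd_oracle.py`), never in the library path.  Tests check pointwise
velocity agreement (<1%), centreline WSS (<2%), flow-rate recovery by
quadrature (<0.5%), a global force balance (ΔP·A vs the line integral of
wall shear, within 5% — the friction correlation is itself approximate),
and degree-1 homogeneity in Q and μ (hypothesis property tests).

## Segmentation and per-cell measurement

The object hierarchy mirrors CellProfiler practice.  Nuclei (primary
objects) are segmented from the DAPI channel by minimum-cross-entropy (Li)
thresholding, hole filling and 8-connected labelling, dropping components
below `min_nucleus_px` (default 50 px).  No declumping is applied by
default; an optional distance-transform watershed declump flag exists.

Whole cells (secondary objects) are grown from the nuclei inside the actin
foreground.  The foreground mask is the Li threshold of the actin channel
after light Gaussian smoothing (σ = 1 px), followed by a 3×3 closing
(edge-padded, so the image frame is not eroded) and hole filling — the
smoothing and closing keep shot noise from punching gaps in the cortical
actin network, whose enclosed interiors the hole filling recovers.  Every
foreground pixel is then assigned to exactly one nucleus by seeded
watershed on the distance to the *seed centroids*.  Using the centroid
point landscape (rather than distance to the nucleus boundary) keeps the
inter-cell boundary midway between nuclei regardless of nuclear shape; on
synthetic monolayers the 99th-percentile boundary displacement against
ground truth is 1 px.  Seed pixels are always included in their own cell;
seeds falling outside the foreground are flagged.

Cytoplasm (tertiary) is the per-cell set difference cell ∖ nucleus.  The
membrane ring is cell ∖ (cell eroded `ring_px` = 3 times with the 3×3
8-connected structuring element, each object eroded independently); a cell
eroded to extinction keeps its whole footprint as the ring and is flagged.
A 9×9 square therefore yields exactly a 72-px ring.  Cells touching the
image border are excluded from per-cell records.

Shape measures come from `skimage.regionprops` (area scaled by
pixel_size², second-moment eccentricity) plus circularity 4πA/P² and its
reciprocal compactness.  The junctional ratio is mean-based — mean
membrane VE-cadherin over mean whole-cell VE-cadherin — which is invariant
to cell size and to any positive rescaling of the channel; the
integrated-intensity variant is also emitted for comparison.

## Junction metrics

Line profiles across junctions use bilinear interpolation at unit spacing,
averaged over a configurable perpendicular width; colocalization along the
profile is the Pearson correlation of the two channel sequences (NaN, with
a warning, for zero-variance input).

Inter-cell boundaries are pixel pairs with differing nonzero labels; the
VE-cadherin band is the thresholded foreground within a Chebyshev search
radius (default 5 px) of any boundary pixel, with each band pixel assigned
to its nearest boundary edge (label pair).  Band coverage is the fraction
of boundary pixels within 1 px of the band.

Stain width is band area divided by medial-axis length (axis links 1,
diagonal links √2).  This area/length estimator is orientation-robust on a
raster — a ribbon of width w measures w whether it runs along an axis or a
diagonal, and a 1-px ribbon measures 1 — where the naive 2×(medial-axis
EDT) over-counts discrete ribbons by about one pixel and varies with
orientation.

Protrusions (VE-cadherin fingers, or filopodia when run on the actin mask)
are skeleton branches escaping a baseline corridor around the boundary
(Chebyshev radius ⌈baseline_w/2⌉ + 2; baseline_w defaults to the measured
stain width, and the 2-px margin absorbs small segmentation offsets).
Length is the geodesic arc from the corridor exit to the farthest skeleton
tip plus the exit's own clearance beyond the band half-width, so the
reported quantity is tip-to-band-edge distance and is insensitive to the
corridor radius.  Candidates not connected to the corridor skeleton
(isolated specks: noise, cytoplasmic puncta) are discarded, as are
candidates reaching within 8 px of the image frame — the segmented
boundary is least reliable there, mirroring the usual exclusion of
border-touching objects — and records under `min_len` = 3 px.  These
skeleton-based measures are algorithmic surrogates for measurements that
are usually made by hand; they are validated against the synthetic
generator's ground truth only, and no equivalence with manual measurement
is claimed.

## Synthetic monolayer generator

The generator emulates a confocal field of a confluent HUVEC monolayer.
Cell geometry is a Voronoi tessellation of minimum-distance-sampled seeds
after one Lloyd relaxation step; the minimum seed distance
(0.75·√(mean cell area), floor 3 px) keeps every region above ~0.4× the
mean area so no cell is smaller than its nucleus.  Elongated phenotypes
are produced by anisotropic coordinate scaling (`aspect`).  Nuclei are
ellipses of randomized orientation and mild elongation, all sharing one
target area (15% of the mean cell area — endothelial nuclei vary far less
in size than their cells) and centred on the Lloyd-relaxed generators,
which sit within a pixel or two of the region centroids.  Actin has a
cytoplasmic baseline, a 1-px-radius cortical rim along every boundary and
the frame, and 3–8 random chords per cell as stress fibers.  VE-cadherin
has a cytoplasmic level plus a junctional band drawn as all pixels within
Euclidean distance band_width/2 of the boundary centreline — thresholding
at half the nominal width gives the drawn band its true perpendicular
width at any boundary orientation.

Phenotypes: *continuous* renders the band at the membrane intensity;
*fingers* adds spikes perpendicular to each edge (direction from the
edge's principal axis; Poisson-distributed counts at `finger_density` per
boundary pixel, restricted to the central 60% of the edge), with drawn
length measured from the band's outer edge to the spike tip — the same
quantity the detector reports — drawn ~Normal(mean 10 px, sd 2 px)
truncated at 1 px; *disrupted* attenuates the band to
max(membrane·δ, cytoplasm) (δ = `disruption_factor`, default 0.2, i.e. the
band sinks to the cytoplasmic level) and scatters bright cytoplasmic
puncta.  δ = 1 with zero puncta reproduces the continuous rendering
exactly.  Noise is Poisson resampling followed by additive Gaussian,
clipped at zero — the standard fluorescence approximation; there is no
PSF/optics simulation, no 3-D stack and no time dependence.

The ground truth records the label maps, per-finger drawn lengths, the
nominal band width, and a per-cell "true" junctional ratio computed from
the noise-free rendering with the true cell labels and the same 3-px ring
definition the pipeline applies — so pipeline error is attributable to
segmentation, not to the truth's own discretization.  All randomness flows
from one `numpy` Generator seeded by `rng_seed`; identical specs render
bit-identically.

**What passing tests show.**  On these synthetics the pipeline recovers
≥95% of interior cells one-to-one (IoU > 0.7), per-cell junctional ratios
within 5% (noise-free) / 10% (SNR ≥ 5) of truth for ≥90% of cells, drawn
finger lengths within 2 px and band widths within 0.5 px, and separates
the phenotypes (disrupted < continuous junctional ratio; fingers >
continuous finger length) in ≥95% of paired seeded runs.  Real confocal
data differ in ways the generator does not model — uneven illumination,
out-of-focus light, staining variability, nuclear declumping, genuinely
irregular cell outlines — so these numbers bound algorithmic error, not
end-to-end accuracy on micrographs.

## Problem sizes and defaults

The generator's default render is 1024×1024 px at 0.16 µm/px with ~90
cells (a 40×/63× confocal field).  The validation suite exercises the same
code on 512×512 fields with 40 cells (recovery tests; ~19 interior cells
per field) and 384×384 fields with 24 cells across 20 paired seeds per
phenotype (separability), sizes at which the full suite completes in about
a minute while every per-cell statistic still aggregates dozens of cells.
Default band width is 5 px (0.8 µm), within the ~0.5–2 µm range of
junctional VE-cadherin stains; finger length defaults to 10 ± 2 px
(1.6 ± 0.3 µm).  Intensity defaults put membrane VE-cadherin at 5× the
cytoplasmic level on a 16-bit-like scale with background 5.

## Known limitations

- The duct model assumes fully developed steady flow: no entrance effects,
  pulsatility, compliance or non-Newtonian rheology.
- The friction-factor correlation is an engineering fit; its ΔP differs
  from the exact series force balance by a few percent.
- Secondary segmentation assumes one cell per nucleus and a foreground
  that encloses cell interiors (cortical actin); heavily fragmented or
  sub-confluent fields will violate both.
- Protrusion detection reports actin stress fibers crossing the corridor
  as "filopodia" on synthetic images, since the generator does not draw
  dedicated actin filopodia; on the VE-cadherin channel this ambiguity
  does not arise.
- Junction metrics within 8 px of the image frame are deliberately not
  reported.
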