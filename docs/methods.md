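# Methods

## Problem

X-ray micro-CT renders a soil column as a stack of greyscale cross-sections.
Root material of different plants attenuates X-rays almost identically, so
when several plants share a column their roots appear with the same
intensities, and whenever two root cross-sections touch, the boundary between
them is faint or absent: the sections coalesce into one blob. Thresholding
can separate root from soil but cannot say whose root is whose. `rhizotrace`
treats each root cross-section as a moving target tracked top-down through
the stack and adds a shape-based collision mechanism so that material stays
assigned to its plant of origin through contacts.

## Tracking model

Each tracked target owns a level-set function per slice: a signed field phi,
negative inside the object, positive outside, whose zero crossing is the
interface. All active functions evolve simultaneously under a multi-phase
exclusion rule — an interface may not move onto a location already interior
to another function; a candidate update there has its sign switched back to
positive — so interiors are pairwise disjoint by construction. Contacts
between targets of *different* plants are detected as shared-negative or
8-adjacent interiors; same-plant contacts are ordinary merges and are not
collisions.

While a target is free of contact, the outline of its interface is recorded
each slice as a 2D point set (each record replacing the last). When a
cross-plant collision opens, the most recent record — captured before the
contact — is frozen and reused for the whole interaction, under the
assumption that a root cross-section's shape is approximately constant while
the contact lasts. Every collision slice, the frozen outline is rigidly
aligned to the current interface with the iterative closest point algorithm,
and interface points are classified against the aligned (predicted) region:

* points **outside** the predicted region mean growth — the front evolves
  normally;
* points strictly **inside** mean the front has been pushed inwards by the
  neighbour — the field is authorized to push back and reclaim pixels of its
  predicted region that are currently interior to the other field, switching
  the other function's sign there;
* where **both** predicted shapes claim a pixel, neither front can be
  pushed: the pixel is frozen at its pre-resolution owner.

The collision closes on the first slice the interiors are neither
overlapping nor 8-adjacent and at least `separation_margin` (default 2 px)
apart; shape recording then resumes. A pair that separates and re-touches
produces a distinct second event. Three or more plants at one locus are
resolved pairwise in ascending target-id order.

Target lifecycle: a tracker group per plant is seeded from user-supplied
points (several seeds per plant allowed); a target whose interior splits into
several 8-connected components spawns same-plant children with parent links;
same-plant targets that touch merge into the lower id; a target terminates
when its interior vanishes or its appearance diverges from its reference for
`term_patience` (default 3) consecutive slices. There is deliberately no
minimum target size. Tracking is single-direction top-down and fully
deterministic.

## Numerical scheme

The level-set evolution is morphological rather than PDE-based: the interior
is a binary mask advanced by unit dilation/erosion steps, up to `max_iter`
(default 10) per slice, with a 3x3 majority-vote smoothing pass as the
curvature term; phi is recovered as a signed Euclidean distance transform
when the continuous field is needed (sign conventions and the extracted
zero-crossing are identical to a narrow-band scheme at this resolution, and
the update cost per slice is a few milliseconds at 320x320). A stationary
front is left untouched by the smoothing term.

The speed function is region competition: a pixel joins the interior when
its intensity is strictly closer to the appearance model's foreground mean
than to the background level, and a boundary pixel leaves when strictly
closer to background. The background level is the median intensity outside
all tracked interiors (soil dominates a cross-section, making the median
robust even with bright neighbour material nearby). A deadband of half a
histogram bin guards the comparison, so binning noise cannot move a front on
a uniform slice.

The appearance model is a normalized intensity histogram (default 64 bins
over the dtype range) of the target region, compared with the
Jensen-Shannon divergence (base-2; symmetric, bounded in [0, 1], zero iff
equal). A converged expansion whose histogram diverges from the reference
beyond `divergence_threshold` (default 0.1) is rejected and the region
reverts to its pre-growth extent. The reference is refreshed every free
slice and frozen during collisions, mirroring the frozen shape record. At
the seed slice the gate is bypassed (a histogram estimated from a few seed
pixels is too noisy to judge the first full-region expansion) and the model
is rebuilt from the converged region.

ICP alternates KD-tree nearest-neighbour correspondence with the closed-form
least-squares (SVD) rigid fit, reflections rejected; initialization matches
centroids, and stops after `icp_max_iter` (50) rounds or when the RMS
residual improves by less than `icp_tol` (0.05 px). The RMS residual is
non-increasing across iterations. Interface contours are extracted by
marching squares and resampled to one point per pixel of arc length. Three
in-collision refinements stabilize the alignment, each adopted after
benchmarking on held interaction scenarios: the alignment is warm-started
from the previous slice of the same collision (centroid initialization
biases a straddling front's fit toward the junction); only interface points
carrying image-gradient support above a quarter of the object/background
contrast are used as alignment targets (the ownership dividing line inside a
coalesced blob has no image evidence); and a collided field is capped at a
`collision_growth_margin` (6 px) dilation of its predicted region, with
interior components disconnected from the predicted region dropped — keeping
each level set locked near its recorded shape, which is the point of the
mechanism. An optional trimmed-correspondence mode (`icp_trim`) exists but
is off by default.

## Synthetic phantoms

The generator emulates interacting root cross-sections as constant-radius
discs on a random walk down the stack: per slice each disc advances exactly
`step` = 6 px along a heading perturbed by a uniform draw in +/-`max_turn` =
16 deg, reflecting specularly off the walls of a 320x320 px frame (the
violating velocity component is flipped before moving, so consecutive
centres are always exactly one step apart and discs stay wholly inside the
frame). Defaults: 2 discs of radius 20 px, 500 slices, 12 independent
stacks per suite (per-stack streams spawned from one seed). Initial centres
are uniform, at least one diameter apart; initial headings uniform. Discs
may interpenetrate freely; ground-truth labels assign contested pixels to
the nearer centre (ties to the lower index). Rendering draws foreground 200,
background 50 on an 8-bit scale with Gaussian noise of sd 10 — values chosen
so the appearance model is exercised non-trivially — and the pre-noise
foreground is pixel-identical to the truth labels. The truth also logs
contact episodes (centre distance within one diameter plus an 8-adjacency
allowance).

What the phantoms do not emulate: branching, radius change along the root,
soil texture, partial-volume and reconstruction artefacts, or any intensity
difference between plants. Passing the phantom benchmark therefore shows
identity maintenance under coalescence of same-appearance targets; it says
nothing about segmentation quality against realistic soil backgrounds.

## Evaluation

A one-time plant-to-root assignment is fixed at the seed slice by maximum
overlap (Hungarian matching). Label accuracy is the fraction of
truth-foreground pixels carrying the correct plant label. Identity is
audited on clean slices (outside truth contact episodes, where the
attribution is unambiguous): a *swap* is a change in the truth root a
plant's material majority-overlaps between consecutive clean slices, and
each interaction is flagged successful when both involved plants carry the
same truth-root identity immediately after the episode as immediately
before. Plants with no labelled pixels on some clean slice are reported as
lost.

## Capability boundary and known limitations

Benchmarked on independent 12-stack suites (150 slices per stack, both
modes), the shape-constrained tracker preserved plant identity through every
interaction whose minimum centre separation stayed at or above roughly
14 px — including long contacts and contacts in which the pair's relative
bearing rotated by more than 90 degrees — while the unconstrained baseline
swapped or lost a tracker in essentially every interacting stack. The
constrained tracker still fails on *deep coalescence*: events in which the
two discs pass through or slide around each other while almost fully
merged (minimum centre separation below roughly 11 px). In that regime the
two targets have identical shape, identical intensity distribution and
interchanged positions, so no cue available to a per-slice shape-and-
appearance tracker distinguishes the outcomes; resolving it would require a
motion model or target-level data association, which is deliberately outside
this tracker's design (next-slice initialization is the previous interior;
there is no motion prediction). Under the generator's random-walk defaults
such deep events occur at a rate of a few tenths per 150-slice stack, so a
12-stack suite usually contains several; the acceptance suite reports them
honestly rather than excluding them.

Other known limitations: the U-shaped-root case (two plants' trackers
picking up opposite ends of one root and meeting in the middle) is inherent
to top-down tracking and not addressed; upward-oriented roots would need
direction alternation, which is out of scope; real μCT artefacts are not
modelled by the phantoms.

## Parameters

| name | default | unit | role |
| --- | --- | --- | --- |
| `max_iter` | 10 | px/slice | front advance budget per slice |
| `curvature_passes` | 1 | — | majority-smoothing passes per slice |
| `n_bins` | 64 | — | appearance histogram bins |
| `divergence_threshold` | 0.1 | bits | JS-divergence gate and termination test |
| `term_patience` | 3 | slices | consecutive appearance rejections before termination |
| `separation_margin` | 2 | px | boundary distance ending a collision |
| `collision_growth_margin` | 6 | px | allowed extent beyond the predicted shape in collision |
| `icp_max_iter`, `icp_tol` | 50, 0.05 | —, px | ICP stopping rule |
| `seed_radius`, `seed_max_iter` | 3, 40 | px, px | seed-slice initialization |
| `shape_constraint` | on | — | disable for the baseline comparison |

Simulator: `n_roots` 2, `radius` 20 px, `step` 6 px, `max_turn` 16 deg,
`frame` 320x320 px, `n_slices` 500, `n_stacks` 12, `fg_intensity` 200,
`bg_intensity` 50, `noise_sd` 10 (8-bit scale), `rng_seed` 0.

The acceptance script (`scripts/acceptance.py`) measures simulator fidelity
on one full 500-slice stack and runs the two-mode comparison on 12 stacks of
150 slices — the per-slice mechanics are depth-independent, and the shorter
stacks keep the double suite a desktop-scale computation.
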