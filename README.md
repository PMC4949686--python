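# rhizotrace

Separating the root systems of multiple plants in X-ray micro-CT image
stacks.

Roots of different plants grown in one soil column attenuate X-rays almost
identically, so in the reconstructed greyscale stack their cross-sections
share the same intensities — and when roots of two plants touch, their
cross-sections coalesce into a single blob with no visible boundary.
Thresholding can separate *root* from *soil* but cannot say *whose* root is
whose. `rhizotrace` is for root-phenotyping researchers who need per-plant
root architectures from multi-plant soil columns: it tracks every root
cross-section top-down through the stack and keeps material assigned to its
plant of origin through contacts.

## Method

Each tracked cross-section owns a level-set function φ (negative inside,
positive outside; the zero crossing is the interface). All functions evolve
simultaneously under a multi-phase exclusion rule: an interface may not move
onto a location interior to another function — a candidate update there has
its sign switched back to positive — so interiors never overlap, and a
collision between plants is detected the moment two interiors meet. Region
growth is driven by intensity (region competition against a background
level) and gated by an appearance model: the Jensen–Shannon divergence

JSD(P, Q) = H((P+Q)/2) − (H(P)+H(Q))/2

between the candidate region's intensity histogram Q and the target's
reference histogram P, with base-2 entropy H.

While a target is free, its interface outline is recorded each slice as a
point set. When cross-sections of different plants collide, the last
pre-collision record is frozen and, on every slice of the interaction,
rigidly aligned to the current interface with the iterative closest point
algorithm (ICP). Interface points **outside** the aligned region mean growth
and evolve normally; points **inside** mean the front is being pushed
inwards by the neighbour, authorizing it to *push back* — reclaim predicted
pixels from the colliding function, switching that function's sign there.
Where both predicted shapes claim a pixel, neither front moves. A built-in
phantom generator (discs of radius 20 px stepping 6 px per slice with
bounded random turns in a 320×320 frame) provides exact per-pixel ground
truth for benchmarking identity maintenance under coalescence.

## Worked example

```bash
python examples/05_compare_modes.py
```

prints, for one generated 150-slice stack containing a root-root contact:

```
1 contact episode(s) in 150 slices
shape constraint ON : accuracy 99.8%, swap slices 0, interactions kept 1/1
shape constraint OFF: accuracy 89.5%, swap slices 12, lost plants [2], interactions kept 0/1
```

With the collision mechanism active, 99.8 % of all root pixels carry the
correct plant label and both trackers exit the interaction on their own
roots. In baseline mode (exclusion only, no shape constraint) the trackers
mis-assign material during the contact: plant 2's tracker is squeezed out
(`lost plants [2]`) and 12 audited slices show a tracker majority-overlapping
the wrong root. The other scripts in `examples/` demonstrate the phantom
generator, plain two-plant tracking, ICP motion recovery and the push-back
rule in isolation, each printing the numbers it computes.

The same pipeline is available from the shell:

```bash
rhizotrace simulate --config sim.yaml --out phantoms/
rhizotrace track --stack phantoms/stack_01/images.tif --seeds seeds.yaml --out tracked/
rhizotrace evaluate --result tracked/ --truth phantoms/stack_01/ --out metrics.json
```

where `seeds.yaml` assigns seed points (slice, row, col) to plants:

```yaml
plants:
  1: [[0, 283, 163]]
  2: [[0, 292, 43]]
```

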