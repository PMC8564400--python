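# Methods

## Lattice model

Patterns are flat-top regular hexagons of edge length *L* (μm) on a
triangular lattice of centers with spacing *s* = √3·*L* + *D*, where *D* ≥ 0
is the perpendicular gap between facing flat edges. Axial integer
coordinates *(q, r)* address patterns internally; exported tables carry both
*(q, r)* and a 1-based serial id (row-major over the odd-q offset layout)
for joins in external tools. Derived distances are closed-form:
apothem (√3/2)·*L*; *l₁* = apothem + *D* and *l₂* = *l₁* + √3·*L*, the
distances from a pattern center to the closest and farthest edge of a
nearest neighbor; *r₁* = *s* + *L* and *r₂* = √3·*s* + *L*, covering-circle
radii for the first and second neighbor rings. The *r₂* convention contains
every second-ring center but deliberately not the far ring's full hexagons
(that would need 2·*s* + *L*); neighbor shells are therefore defined by
lattice hop distance, with the circles as a geometric gloss. Both radii are
configurable.

For *L* = 55, *D* = 70 the exact values are *l₁* = 117.631 μm and
*l₂* = 212.894 μm; at one-decimal printed precision these appear as 117.6
and 212.8 (truncation — note that round-half-up would print 212.9).

Point-in-pattern queries are boundary-inclusive; a point on a shared
boundary (possible only at *D* = 0) goes to the hexagon with the lowest
serial id. Points in the gap map to the `OUTSIDE` sentinel (pattern id −1
in files).

## Synthetic circuits

The generator emulates the occupancy statistics of mature (≈DIV 21)
hippocampal cultures on the 55/70 μm honeycomb; its defaults are the
observed values, not free dials:

| parameter | default | meaning |
|---|---|---|
| `p_soma_inside` | 0.643 | probability a soma lands inside a hexagon |
| `rpa_count_dist` | {1: .45, 2: .312, 3: .14, 4: .068, 5: .03} | number of dendrite-occupied patterns (RPAs); mass on {1, 2} = 0.762 |
| `axon_coverage_mean` | 6.7 | mean patterns covered per axon |
| `p_synapse_given_contact` | 0.9 | probability a co-occupancy forms a synapse (>90% observed) |
| `density` | — | plating range 39.5–78.9 cells/mm² when used |
| `min_soma_separation_um` | 15 | soma exclusion radius (≈ one soma diameter) |

The axon-coverage distribution is a negative binomial (r = 5) shifted to
support 1–25 and renormalized, with its success probability solved once so
the truncated mean is exactly 6.7; the same parameterization places 0.808
of the mass below 10 patterns, matching the observed histogram without a
second knob. No parametric forms are published for these histograms, so
the categorical RPA distribution and the negative-binomial family are this
package's choices, exposed in the config.

Placement draws each soma inside a uniformly chosen hexagon with
probability `p_soma_inside`, otherwise uniformly in the gap within the
array footprint, with bounded retries against the separation constraint.
Dendrites occupy the soma pattern plus draws from its first neighbor
shell; a cell whose soma sits in the gap draws RPAs from all hexagons
within *l₁* (+ one edge length) of the soma — such cells tend to form more
RPAs, as observed. Axon territory is the set of distinct patterns visited
by a nearest-neighbor random walk from the soma pattern until the coverage
target is reached; this reproduces the locality of entrapped axons
(long but never far from the cell body) without a mechanistic growth-cone
model. All randomness descends from one seed through named substreams
(placement, growth, color, synapse), so identical parameters and seed give
byte-identical outputs.

Boundary effects: cells whose soma pattern lies on the array border have
fewer than 6 shell-1 neighbors, so their RPA count is truncated at the
available pool; on the 60×54 recovery lattice this biases the mass on
{1, 2} upward by ≈0.01, within the 3-SE acceptance band at n = 5000.

The generator emulates occupancy statistics only. It does not model
neurite morphology, fluorophore optics, astrocyte contamination, or the
temporal dynamics of axon escape; conclusions from passing tests are about
the analysis pipeline, not about biology upstream of the occupancy table.

One deliberate mismatch to published motif profiles: real neural circuits
under-represent certain reciprocal triad classes (a wiring rule), whereas
the geometric contact rule here makes reciprocal dyads common — two
neighboring cells frequently each reach the other's dendritic territory.
The simulator therefore reproduces occupancy and fragmentation statistics,
not the motif-class rarities of biological networks.

## Rendering and registration

`render_image` rasterizes the pattern channel (filled hexagons) plus one
channel per fluorophore: soma discs at full color intensity, dendrite
patterns at 0.55×, and axons as thin straight traces from the soma to each
covered pattern center at 0.8× (the walk's visit order is not part of the
annotation contract, so traces are star-shaped rather than path-shaped —
sufficient for registration fixtures). Pixel rows run top-down while μm
*y* runs up; positive rotations are counter-clockwise on screen.

Rotation estimation windows the image (Hann), takes the 2D power spectrum,
masks the DC region, and reads the angle of the strongest first-order
peak, averaging all peaks in the same radial band (weights = peak power,
angles folded into [−30°, +30°) by the 60° lattice symmetry) after
per-axis quadratic sub-pixel refinement. A flat or structureless spectrum
(peak-to-median power ratio < 20) raises a no-lattice error. Measured
round-trip accuracy on rendered fixtures is ≤ 0.2°.

Detection cross-correlates the derotated image with a synthesized hexagon
template (zero-normalized, scores in [−1, 1]); local maxima with score
≥ 0.5 (configurable) separated by ≥ 0.8·*s* become centers, refined to
sub-pixel by a 3-point quadratic fit (≈0.3 px residual at 0.4 px/μm).
Indexing rounds center positions to axial coordinates, refines the
translational offset by least squares over two passes, and chooses the
integer lattice shift maximizing overlap with the in-bounds index set.

## Connectome and metrics

`build_graph` applies the contact rule deterministically: edge *i* → *j*
iff axon(*i*) ∩ dendrite(*j*) ≠ ∅, with the shared patterns kept as edge
evidence. Autapses are dropped by default (the path machinery presupposes
distinct nodes); multiple shared patterns collapse to one unweighted edge.
Label noise belongs to the simulator, whose `p_synapse_given_contact < 1`
thins the truth graph relative to the reconstruction.

Shortest paths use per-source BFS with path-count (σ) accumulation along
layers. Conventions for the fragmented directed graphs these cultures
produce:

* **Closeness.** The textbook *N*/Σ*d* diverges or zeroes out when any
  node is unreachable, which would zero nearly every node in a fragmented
  culture. We use reachable-set closeness: the number of nodes reachable
  from *n* divided by the summed distances to them, exactly 0 for an
  isolated node. A driver cell one hop from its entire reachable set
  scores exactly 1, matching how such cells are reported.
* **Betweenness** is directed, endpoint-excluding and unnormalized,
  computed from σ\_st(n) = σ\_sn·σ\_nt on shortest-path-compatible triples.
* **Eccentricity** of a node reaching nothing is 0; network radius and
  diameter are the min/max over nodes with finite positive eccentricity.
* **Density** is reported as |E|/N (the per-node edge budget reading of
  D = k/N) with the standard directed density |E|/(N(N−1)) alongside as
  `density_std`.

Hub tags: integrator (k_in ≥ 5) and distributor (k_out ≥ 5) hubs —
published cut-offs are "4 or 5 depending on the network", so the threshold
is configurable; pacemaker = distributor with top-decile closeness;
bottleneck = top-decile positive betweenness; connector = bottleneck with
k_out ≥ 4. Quantile thresholds adapt per network.

## Motif census

All 64 labeled 3-node digraphs are grouped by canonical code (minimum
6-bit adjacency signature over the 6 node permutations) into 16 classes,
13 weakly connected. Numbering is deterministic: ascending edge count,
ties by canonical code, then anchored so the feedforward triangle is
class 5 and the 3-cycle class 6. The ordinal positions of the remaining
classes are a convention of this package; cross-study comparisons should
key on canonical codes (the gallery from `hexconn.viz.plot_motif_gallery`
shows each representative). Triads are induced subgraphs; the census is a
vectorized lookup over all C(N, 3) triplets, O(N³) but comfortable at the
tens-to-hundreds-of-nodes scale of these cultures.

## Verification choices

Centralities are checked against an independent brute-force oracle that
enumerates all simple paths: exhaustively for every digraph on ≤ 4 nodes
(4,369 graphs) plus seeded samples of 5-node digraphs, and against
networkx betweenness; the census against a permutation-search isomorphism
oracle and conservation (Σ counts + disconnected = C(N, 3)). Simulator
parameter recovery runs one 5,000-cell circuit on a 60×54 lattice
(≈62 cells/mm², inside the plating range) with a 3-standard-error band.
Qualitative network structure (several segments plus isolated cells,
largest-segment diameters in the 3–8 range) is reproduced with 60
annotated cells on a 20×20 array — the annotated-cell count emulates the
sparsity of stochastic multicolor labeling, where only color-discriminable
cells are traced, not the plating density.

## Known limitations

* The registration stage assumes the nominal lattice parameters and image
  scale are known; it fits translation and rotation, not *L*, *D* or
  px/μm.
* Detection is tuned for binary-ish pattern channels with additive noise;
  uneven illumination and tile stitching artifacts are out of scope.
* The simulator's color model is a Dirichlet composition per cell and
  ignores intensity variation across compartments of one cell.
* Metrics are unweighted; contact counts are exported as edge evidence but
  not used as weights.
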