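# Methods

This note records the models implemented in `iplconnect`, the assumptions
behind them, the tunable parameters with their defaults, what the synthetic
generator does and does not emulate, and the numerical choices made where
the underlying workflow left the design open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Annotation model and coordinates

A volume is a stack of `slice_count` image planes. Slice indices are
0-based; XY coordinates are in pixels with the origin at top-left, and all
conversions to physical units happen only at output boundaries. Physical
position of a circle centre is `(x·s, y·s, Σ thickness of slices above)`
with `s` the pixel size (default 2.18 nm/px, the TEM mosaic sampling of the
workflow this models). Slice thickness defaults to a uniform 70 nm — the
low end of the 70–90 nm microtomy range — and can be overridden per slice.
Skipped slices (lost sections) carry no annotations but still occupy
physical depth, so depth is invariant to which *other* slices are skipped.

Location links may bridge up to `max_gap` = 6 slices, enough to survive the
worst single loss contemplated here (a five-section refacing loss).
Duplicate links are rejected at load rather than silently deduplicated, on
the view that a duplicate row is evidence of an upstream bug.

**Arbor diameter** is the maximum pairwise XY distance between circle
centres (radii excluded). The measurement underlying published arbor
figures is not defined precisely enough to tell centre-to-centre from
centre+radius or convex-hull extent; centre-to-centre was chosen as the
simplest rule and the difference is at most two process radii.

**Contact census.** Postsynaptic/presynaptic counts cover all *directed*
links (chemical synapses, ribbon synapses, cistern contacts) touching the
cell's children, so that the conservation law Σ presynaptic = Σ
postsynaptic = number of directed links holds exactly; cistern contacts are
additionally reported under their own key. Undirected contacts (gap
junctions, adjacency) count once per link for each endpoint cell.

**Interchange format.** Five CSV tables plus `volume.json`, UTF-8, header
rows mandatory, integers bare, floats with a `.` decimal. `structure_links.csv`
carries an optional `channel` column so that co-released transmitters
(dopamine vs glutamate from the same axonal cell; GABA vs peptide) remain
distinguishable in motif catalogs; files without the column load with an
empty channel. The writer emits a canonical sorted form, so save → load →
save is byte-identical and the round trip is testable by byte comparison.

## Circuit graph analyses

Every structure link becomes one edge between the parent cells (a true
multigraph; parallel contacts are preserved). Chemical synapses, ribbons
and cistern contacts are directed pre → post; gap junctions and adjacency
are undirected and stored once under canonical node order.

**Chains.** A chain is a maximal simple directed path over synaptic edges;
a "stage" is an edge, not a cell (the worked six-stage example numbers six
arrows). Interior nodes may be restricted by a filter (an
`amacrine_interior` filter is provided), but the default is unrestricted:
the six-stage reference chain itself passes through a bipolar cell interior
node, so an amacrine-only default would be unable to reproduce it.
Maximality means no synaptic edge extends the path at either end without
repeating a cell or violating the interior filter. Longest-path search is
exponential in general; enumeration is a depth-first search bounded at
`max_depth` = 12 edges (paths at the bound are reported even if extendable),
which is tractable at desk scale. Parallel edges between the same cell pair
are collapsed to one hop — otherwise the path count grows multiplicatively
with synapse multiplicity for no analytic gain — and the lexicographically
smallest edge key is kept as the witness. Gap junctions and adjacency edges
never contribute stages.

**Alternating chains** restrict the same enumeration to cells labelled
GABA+ or glycine+ with consecutive labels differing; the census is grouped
by alternation count (= edges). Single cells do not count as chains.

**Motif taxonomy.** Motifs are classified at cell-class level on the class
digraph induced by directed edges: *reentrant* (an edge within one class),
*reciprocal* (edges both ways between two classes), *looping* (a directed
cycle over ≥ 3 distinct classes), *simple chain* (a maximal repeat-free
directed class path). Cell-level witness edges are retained. Class-level
classification is invariant under any cell relabelling that preserves
classes.

**Motif catalog.** A focal cell's repertoire is the set of distinct
(partner class, contact type [+ channel], direction) triples, with
direction ∈ {in, out, coupled}. `channel_split` defaults to on because
co-released transmitters from one partner class are biologically distinct
motifs. Gap junctions and adjacency count as "coupled" motifs; the focal
class itself is a partner class when self-coupled.

**Fictive adjacency.** Two cells are apposed on a slice when any circle of
one comes within ε of touching a circle of the other (centre distance ≤
r_a + r_b + ε in physical units); a pair is reported when apposed on ≥
`min_slices` consecutive slices, and is *fictive* iff no structure link of
any type joins the cells. Defaults: ε = 30 nm (about two membranes plus a
cleft) and `min_slices` = 3; neither threshold is given by the source
workflow, and both are exposed as CLI flags. Volume-level skipped slices do
not break a run of apposed slices — a lost section is no evidence against
apposition, mirroring how tracing bridges skips.

## Rendering

Each linked circle pair becomes a closed conical frustum (n-gonal, default
`n_sides` = 16) in physical nm. A circle with exactly two links is tilted
from the XY plane by half the angle between its incoming and outgoing
segments, about the normal of the plane through the three centres; circles
with one or ≥ 3 links stay XY-parallel, since the tilt rule is defined only
for the two-link case. Rims share angular offsets to avoid twisted
frusta. With equal radii and no tilt the lateral area is the prism formula
`2 n r sin(π/n) h`, converging to `2πrh`. Whether the original renderer
merged coincident rims at branch points is undocumented; a `weld` option
merges coincident vertices on request (default off). Unlinked annotations
render as isolated disks with a logged warning.

## Phenotyping

**Gaussian overlap.** The "normal distribution overlap" statistic is
operationalized as the equal-z threshold `t = (σ₂μ₁ + σ₁μ₂)/(σ₁+σ₂)`;
the misclassification probability of each class is its Gaussian tail beyond
t. The two tails coincide by construction. This choice is the simplest rule
under which the published bounds (≤ 0.015 ON→OFF, ≤ 0.02 OFF→ON for
glycine 63±13 vs 15±7) hold; the exact rule behind those published bounds
is unstated, so they are verified as inequalities only. Equal means make
the threshold undefined and raise an error.

**Clustering.** Channels are standardized, projected onto the principal
components explaining ≥ 95% of variance, and clustered with seeded
k-means. `mode="isodata"` — the mode named by the source workflow —
iteratively splits clusters whose mean within-cluster SD exceeds 1.5× the
median within-cluster SD and merges centroid pairs closer than 0.5× the
median inter-centroid distance (both configurable; the workflow names
isodata without parameters). Clustering is deterministic given the seed,
and permuting input rows permutes labels only.

**Density profiles.** All retinal gap junctions share a 12–13 nm
pentalaminar zone; heterocellular junctions additionally carry broad
flanking cytoplasmic density, thicker on the amacrine side (~10 nm on the
bipolar face, > 15 nm on the amacrine face). The classifier estimates a
baseline from the profile tails (median, with a MAD noise scale), requires
the central peak to rise ≥ 5 noise-scales above baseline (else *unknown*),
and measures flank extent outward from the nominal membrane faces at
± 6.5 nm as the region above 25% of the central contrast. Both flanks wider
than 5 nm and mutually asymmetric ⇒ heterocellular (thicker side
reported); thin flanks ⇒ homocellular. Measuring flanks from a data-driven
central edge instead double-counts the shoulder where band tails and flank
plateaus overlap; the fixed-face rule exploits the near-constant
pentalaminar width.

**Image fusion.** Overlay fusion works in HSV: hue and saturation from the
molecular overlay, value (brightness) from the TEM image, so a neutral-gray
overlay pixel leaves the TEM pixel exactly unchanged and the value channel
of the output equals the TEM input bit-exactly. Alpha blending is the
standard convex combination, clipped to the 8-bit range. All rasters are
8-bit per channel.

## Connectivity statistics

Sample SDs use the n−1 denominator, matching the mean ± 1 SD convention of
the figures being reproduced. The placement test's null is per-contact
placement probability proportional to class cell counts — the source
workflow does not state its null, so this choice is declared here and the
published tail bounds (< 1.3×10⁻⁶ for nanoribbons, < 5.6×10⁻³ for veto
synapses) are treated as qualitative anchors only; the per-class counts
behind them were never printed, so exact reproduction is impossible. The
test is one-sided because the claims are directional (concentration in one
class). The tail is super-uniform under the null up to binomial
discreteness. No multiple-testing machinery is provided; the use case is a
pair of isolated tests.

## Synthetic generator

The generator emits the *stated world* of the analyses at 1:10 scale: a
68-cell census preserving the class proportions of the 16.5 TB source
volume (284 bipolar cells, 167 GABA+ and 118 glycine+ amacrine cells, …),
wiring rules that realize the documented AII amacrine repertoire (rod
bipolar ribbon drive, OFF-pathway chemical output, heterocellular coupling
with ON cone bipolar cells, dual-transmitter axonal-cell input, axonal
nanoribbons confined to ON cone bipolar cells, veto synapses on bipolar
axons), a planted six-stage chain on reserved cells with no other wiring
(so it is provably maximal), planted apposed-but-unconnected pairs, and
skipped sections.

Signatures are truncated normals clipped to [0, 255]. Glycine parameters
are the published ones (ON 63±13, OFF 15±7, rod 5±3, uncoupled ON 31±7);
AGB parameters are a numeric translation of the published qualitative
ordering — OFF strong (120±25), coupled ON about half of OFF (60±15), rod
near zero (5±3), uncoupled ON the strongest of all (210±15). The
uncoupled-ON value was revised once, from 180±20, after the first
translation failed to reproduce the documented fact that the four bivariate
clusters are distinct: at 180±20 the tiny uncoupled cohort merged into the
OFF cluster under the prescribed clustering pipeline.

Spatial layout is stylized, not anatomical. Cells occupy vertical "soma
columns" on private lanes of a 12 µm grid inside a 250 µm disc; each cell
lays its lateral arbor out on a private pair of adjacent slices, reaching
two diametrically opposite tips so that the planted arbor diameter (AII
67±6 µm; other classes plausible desk-scale values) is exact. Because
lanes never overlap and lateral excursions of different cells never share
slices, no incidental apposition can persist for ≥ 3 consecutive slices;
with the default `min_slices` = 3, the only detectable appositions are the
planted pairs (which span 12 slices at circle separation just under
touching). Cells carrying planted apposition columns drop out of the arbor
ground truth, since the columns extend them beyond their planted arbor.
Contact children carry no circle geometry of their own. Smoothed random
process trajectories, varying calibres, glial wrapping and realistic
spatial statistics are *not* emulated — a green recovery test establishes
that the analyses invert the generator's planted structure, not that they
would segment real micrographs.

Everything is drawn from one seeded generator; the same config yields
byte-identical interchange tables.

## Test scale and runtime

Property suites use 100–150 random graphs of ≤ 12 nodes against brute-force
oracles, 10³ random tilt triples, 10⁵-draw Monte-Carlo checks, and
full-pipeline generator runs on a sample of seeds (placement-statistic
checks across 100 seeds reuse the deterministic census rather than
regenerating every volume). The whole suite runs in well under a minute on
one CPU.

## Known limitations

- Chain enumeration reports node-paths; parallel-synapse multiplicity is
  deliberately not expanded into distinct chains.
- The isodata split/merge heuristics are simple and can under-split a tiny
  cluster adjacent to a large one; class-recovery accuracy on the default
  cohort is ≥ 95% at the tested seeds but the uncoupled-ON cohort (n≈16 of
  500) is sometimes absorbed rather than isolated.
- The density-profile classifier assumes the profile is centred on the
  membrane pair and that the pentalaminar width is near-constant.
- Arbor diameter ignores process radii (centre-to-centre rule).
- The fictive-adjacency thresholds (ε, `min_slices`) are package defaults,
  not measured constants.
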