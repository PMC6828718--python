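# Methods

## The medium

`actinet` treats a two-dimensional projection of an actin-bundle network
as an excitable medium. The bundles form the conductive substrate; the
voids between them are inert. Excitation is modelled with the two-variable
FitzHugh–Nagumo (FHN) reduction of Hodgkin–Huxley membrane kinetics,

```
du/dt = c1 · u (u − a)(1 − u) − c2 · u v + I + D_u ∇²u
dv/dt = b (u − v)
```

where `u` is the fast trans-membrane potential and `v` the slow recovery
variable. The cubic has stable fixed points at `u = 0` (rest) and `u = 1`
(excited) and the unstable excitation threshold at `u = a`. The coupling
term `−c2·u·v` supplies the slow negative feedback that turns a
supra-threshold kick into a travelling pulse with a refractory tail.

Integration is explicit Euler on the conductive nodes only, with the
five-point Laplacian restricted to the mask: flux terms toward void or
off-grid neighbours are dropped, which is exactly the mirror (no-flux)
condition `∂u/∂n = 0` on all internal and external boundaries. Void nodes
carry no state and read as zero.

### Parameters

| name | default | meaning |
| ---- | ------- | ------- |
| `dt` | 0.015 | Euler time step (model time units) |
| `dx` | 2 | lattice node spacing; the Laplacian divides by `dx²` |
| `D_u` | 1 | conductance of the passive current spread |
| `a` | 0.13 | excitation threshold of the cubic |
| `b` | 0.013 | recovery rate (sets the refractory time scale `~1/b`) |
| `c1` | 0.26 | activation (cubic) coefficient |
| `c2` | 0.1 | excitability control |
| `I` | 0 | external stimulation current |

`c2` is the experiment dial: 0.1 is fully excitable; 0.107–0.108 are
sub-excitable (wavefronts survive only along favourable geometry); beyond
roughly 0.13 the medium no longer propagates. Values outside 0.09–0.13
trigger a config warning. With these defaults the single-node system has,
besides the rest state, a pair of interior equilibria; spatially this
manifests as slow, robust pulses rather than fast spikes — wave speed is
roughly 0.2 space units per time unit (about 1 lattice node per 600
iterations). All run lengths below were chosen with that scale in mind.

A logical True at an input site is delivered as a supra-threshold kick:
`u` is set to 1.0 on the conductive nodes of a radius-5 disc for one step
(amplitude, radius, duration and `set_u`/`add_I` mode are configurable).
The underlying model only requires that an input "excites the channel";
the specific footprint is a package choice and the propagation behaviour
is insensitive to it as long as the kick exceeds the threshold across a
few nodes.

### Numerical choices

* Double precision throughout; fixed-step Euler (no adaptive stepping).
* The production loop is a compiled (numba) kernel; `fhn.step` is the
  plain-numpy reference implementation of the same update, and the test
  suite asserts bit-identical agreement between the two over run prefixes
  with both stimulus modes.
* Derivatives are evaluated at the pre-step fields; `set_u` stimuli
  overwrite after the update.
* Non-finite fields abort the run with step and site diagnostics (checked
  every 256 steps inside the kernel, every step in `fhn.step`).
* Single-node dynamics agree with an adaptive high-order integrator
  (DOP853, rtol 1e-10) to better than 1e-3 max-abs error over 10⁴ steps
  for c2 in {0.09, 0.1, 0.107}.

## Templates

Real input: an 8-bit RGB (or grayscale) image is thresholded channel-wise
— a pixel is conductive iff `r > 40`, `g > 19` and `b > 19`, all strict.
The green condition is applied like the others but each threshold is
independently configurable. Non-8-bit data is rejected rather than
rescaled, so thresholds always refer to the 0–255 scale.

Synthetic stand-ins emulate regularly spaced aster-based bundle networks:
aster centres on a jittered square lattice (pitch `spacing`, default 40
nodes; jitter fraction 0.15), joined by straight bundles of width 5 to
orthogonal neighbours with probability 0.9 and diagonal neighbours with
probability 0.4. One integer seed drives all stochastic elements, making
generation a pure function of the recipe. Engineered fixtures (straight
channel, Y-junction, cross, seven-channel junction) draw exact geometries
and label their arm endpoints; junction generators verify that deleting
the hub leaves one connected component per arm and reject degenerate
(blobbed) geometries. Bundles narrower than 3 nodes are rejected because
they quench wavefronts under the default parameters. Component analysis
uses 8-connectivity so thin diagonal bundles stay connected.

What the generator does **not** emulate: intensity variation along
bundles, curved or branching bundles, bundle-width dispersion, imaging
noise, and the specific geometry of any real micrograph. Tests passing on
these synthetic networks therefore demonstrate properties of the method
(propagation, annihilation, monotonicity, gate statistics), not agreement
with any particular real network's gate map.

## Measurements

* Electrode potential: `p = Σ (u − v)` over conductive nodes within
  Euclidean distance < 2 of the electrode — the 3×3 neighbourhood. The
  distance-2 reading is maximal-consistent: Chebyshev gives the same set,
  Manhattan would drop the diagonals.
* Activity: count of conductive nodes with `u > 0.1` (strict), reported
  as a fraction A of all conductive nodes.
* Frequency matrix: per-node count of steps with `u > 0.1`, max-normalised
  at the end of the run (all-zero maps stay zero); high-frequency domains
  are 8-connected components with normalised frequency strictly above
  0.72, discarding components below 5 nodes (speckle guard, configurable).
* Frames: every 150th step, sites with `u > 0.04` rendered as wavefront
  over the conductive template.

### Spike detection and alignment

The model itself does not define a spike; the detector is declared, not
inferred: a spike is an above-threshold (`p > 0.5`) local maximum of the
electrode potential, with maxima within a 300-iteration refractory window
of the previous spike merged into it. The 0.5 threshold sits well below a
wavefront passage (p of order the neighbourhood size) and well above
numerical ripple on every fixture examined; both knobs are configurable.

Spikes recorded under the three input pairs are aligned into events:
spikes closer than 200 iterations are simultaneous (one event); a spike
within the window of two candidate events joins the nearer (earlier on a
tie); retained events must be more than 1000 iterations apart — an event
inside that guard interval of the previous one is discarded as an echo of
the same wave passage rather than merged (merging would contradict the
simultaneity window). The behaviour between the two windows is not fixed
by the model description; this discard rule is the package's choice.

## Gate readouts

* **Structural**: on a labelled junction fixture, each output arm's
  response vector is whether any node in its endpoint's 3×3 neighbourhood
  ever exceeded `u > 0.1` during the run for each input pair. Geometry
  where the (1,1) input excites no output is flagged non-functional.
* **Frequency**: a node is near a pair's output domains if within the
  co-location radius (default 10 nodes) of any domain node; each gate's
  placements are the connected regions matching its response vector.
* **Activity**: the mean of A over steps after the settle window
  (defaults: 8·10⁴ iterations at c2 = 0.1, 10⁵ at c2 = 0.107, the onset
  of the activity limit cycle) is tested against interval rules
  `A ∈ [lo, hi] ⇒ True`. The shipped rule sets are worked examples read
  off one particular network; on other networks they are starting points,
  which is why `activity_gates` reports the induced truth table rather
  than asserting it.
* **Spiking**: every aligned event at every electrode is classified by
  its response vector; the census tabulates per-electrode counts, with
  mean, sample standard deviation (ddof = 1; the convention is the
  package's choice) and median across electrodes recomputable from the
  table. The hierarchy orders gates by total discovery count, grouping
  gates whose totals differ by less than 5% of the grand total.
* **Compound**: electrode pairs whose events co-occur within the
  simultaneity window and realise AND + XOR (half-adder) or SELECT + XOR
  (Toffoli-style pair).

## Problem sizes and what the shipped runs show

The demo pipeline runs 14.2·10⁴ iterations on 256×256 aster networks
(about 14 000 conductive nodes) with 30 farthest-point-sampled
electrodes, electrodes 7 and 17 doubling as inputs x and y. At the
package's wave speed each run amounts to roughly one traversal of the
network, so per-electrode gate counts are small (grand totals of order
10–30 per network); select gates dominate because electrodes reachable
from one input spike identically under the two input pairs that share
that input, while xor requires accidental co-timing of the two
uncorrelated single-input runs plus silence under (1,1) — across seeded
networks the select total strictly exceeds the xor total in every run
examined. Channel fixtures use 400×7-node channels (single-front
traversal within 2.9·10⁵ iterations). The excitability sweep uses 10⁵
iterations per c2 on a fixed 256×256 network. The reproduction script
(`scripts/acceptance.py`) runs the census on three seed-derived networks;
the test suite's hierarchy check covers ten.

## Known limitations

* Wave speed in iterations is a consequence of the printed parameter set
  with the `dx²`-scaled Laplacian; richer per-electrode censuses require
  either longer runs or denser electrode placement.
* The activity-interval rule sets and any specific domain map depend on
  the underlying template; only their mechanics are portable.
* 2-D lattices only; isotropic homogeneous `D_u`; ideal noiseless
  electrodes.
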