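# actinet

Boolean logic from excitation waves on actin-bundle networks.

Self-assembled networks of actin-filament bundles are a candidate
substrate for unconventional, collision-based computing: the bundles
conduct travelling excitations, and the presence/absence and interaction
outcomes of wavefronts can encode logic. `actinet` simulates this regime
and discovers the logic it supports. It is aimed at researchers in
unconventional computing and excitable-media modelling who want a
reproducible desk-scale version of the experiment: image in (or synthetic
network in), gate census out.

## What it does

1. **Templates** — threshold an RGB micrograph of a bundle network into a
   binary conductive mask (`r > 40`, `g > 19`, `b > 19`, strict), or
   generate synthetic stand-ins: jittered aster lattices and engineered
   fixtures (straight channels, Y-junctions, a seven-channel junction)
   with labelled arm endpoints.
2. **Dynamics** — integrate the two-variable FitzHugh–Nagumo system on
   the conductive nodes (explicit Euler, Δt = 0.015; five-point Laplacian
   with no-flux boundaries, Δx = 2; D_u = 1, a = 0.13, b = 0.013,
   c1 = 0.26):

   ```
   du/dt = c1·u(u − a)(1 − u) − c2·u·v + I + D_u ∇²u
   dv/dt = b·(u − v)
   ```

   `c2` sets the excitability (0.1 fully excitable, 0.107–0.108
   sub-excitable). A logical True at an input site is a supra-threshold
   kick of u.
3. **Readouts** — four schemes map dynamics to two-input Boolean gates:
   *structural* (which junction arms the wavefronts reach), *frequency*
   (max-normalised per-node excitation-frequency maps; domains above
   0.72 act as spatial outputs), *activity* (intervals of mean network
   activity as logical True) and *spiking* (per-electrode spike trains
   aligned across the input pairs 01/10/11 into 3-bit response vectors,
   classified as or / select / xor / and-not / not-and / and, tabulated
   into a per-electrode census with a gate-frequency hierarchy).

## Worked example

```
$ actinet demo --seed 1 --out demo_run
wrote demo_run: 15 select / 0 xor gates; hierarchy select_x > select_y > {not_and, and_not} > {or, xor, and}
```

This generates a seeded 256×256 aster network (~14 000 conductive
nodes), places 30 electrodes by farthest-point sampling (electrodes 7
and 17 double as the inputs x and y), simulates the three input pairs
for 142 000 iterations each at c2 = 0.1, and runs all four analyses.
The printed line is the spiking census headline: 15 of the 19 gate
events discovered across the 30 electrodes are select gates (the output
copies one input — the wave from that input reaches the electrode, the
other input's wave does not), while no xor gate appears: xor needs the
two single-input waves to arrive co-timed while the dual-input run stays
silent there, which is rare. That select ≻ … ≻ xor ordering is the
robust qualitative finding; exact counts vary with the network seed.

`demo_run/report.json` holds the full bundle: the manifest with every
parameter, the structural/frequency/activity reports, the Table-shaped
census with per-gate mean/sd/median across electrodes, and any
half-adder (and + xor) or Toffoli-style (select + xor) electrode pairs.
`traces_01.csv` etc. carry the per-step electrode potentials and network
activity.

The same pieces are scriptable: `actinet mask` / `synth` / `simulate` /
`gates`, or from Python:

```python
from actinet import fhn, gates, template

mask = template.generate_network(
    template.NetworkRecipe(kind="y_junction", shape=(96, 96)))
result = gates.structural_truth_table(
    mask, fhn.SimulationParams(n_steps=90_000))
print(result.functions)   # {'z': <GateLabel.OR: 'or'>}
```

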