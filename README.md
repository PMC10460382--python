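# gcwmorph

Label-free multiphoton quantification of **gas cell walls (GCWs) in bread
dough**: polarized second-harmonic-generation (SHG) fusion, starch-granule
segmentation, autofluorescence-envelope delimitation, and morphometrics —
together with a ground-truthed synthetic-microscopy simulator that makes
every stage testable.

## The science

During proving, dough lamellae between gas bubbles thin toward rupture; the
proportion and placement of starch granules in these walls governs their
mechanics. Multiphoton microscopy images the two solid phases without
labels: SHG from crystalline amylopectin reports starch granules, and
two-photon endogenous fluorescence (EF) reports the gluten network; gas is
dark in both. A single linear polarization excites only the amylopectin
shells parallel to it — each granule shows two lobes — so channels acquired
at 0°/45°/90°/135° with backward and forward detection are **summed** into
a complete granule outline (for a `cos²` angular response the four-angle
sum is exactly uniform).

From the fused SHG and the EF envelope the pipeline measures, per wall:

* **Starch areal fraction** — starch pixels over envelope pixels on five
  slices spanning 6 µm of depth, mean ± SD;
* **Granule size distribution** — Max-Feret diameter *d* of each granule on
  a representative slice, spherical volume *V = πd³/6*, and wheat A/B/C
  typing (A > 15 µm, B 5–15 µm, C < 5 µm) by number and by volume;
* **Wall dimensions and type** — L × W × D and the string (partially
  ruptured; depth ≈ width, well under the stack) vs intact (spans the
  stack) classification.

Analysis is deliberately 2D: the axial optical elongation makes granule
z-extents unreliable, hence the spherical assumption on in-plane Feret
diameters. `docs/methods.md` details the model, parameters and
limitations.

## Worked example

Simulate a string-type wall with 50% target starch fraction, quantify it,
and print the report:

```bash
gcwmorph simulate --config cfg.yaml --out-dir sim
gcwmorph quantify --stack sim/stack.tif --config cfg.yaml --out-dir quant
gcwmorph report quant/report
```

with `cfg.yaml`:

```yaml
simulate:
  seed: 11
  shape: [40, 192, 192]
  target_starch_fraction: 0.5
  wall: {kind: string, length_um: 28.0, width_um: 9.0, depth_um: 10.0, z_offset_um: 5.0}
```

prints:

```
granules on representative slice: 5
starch fraction: 50.0% +/- 2.3%
wall L x W x D: 33.0 x 9.4 x 12.5 um (string)
class number shares: A: 0.0%, B: 40.0%, C: 60.0%
class volume shares: A: 0.0%, B: 90.9%, C: 9.1%
```

The simulator recorded a ground-truth areal fraction of 0.519 for this
seed, so the pipeline estimate (0.500) recovered it within 0.02. The wall
is correctly typed as a string (depth 12.5 µm ≈ width, well under the
20 µm stack), B-type granules dominate the volume share while C-types
dominate counts, and the report files (`report_granules.csv`,
`report_summary.json`) hold the per-granule table and the full summary.

The same analysis is available as a library:

```python
from gcwmorph import simulate_stack, quantify_stack
from gcwmorph.simulate import SimulationParams, WallGeometry

params = SimulationParams(shape=(48, 256, 256), target_starch_fraction=0.55, seed=1)
wall = WallGeometry("string", 38.0, 10.0, 11.5, z_offset_um=6.0)
result = simulate_stack(params, wall)
report = quantify_stack(result.stack).report
print(report.starch_fraction_mean, report.wall_class)
```

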