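# cardiomorph

Automatic segmentation and cardiac-mechanics analysis of 4D light-sheet
fluorescence microscopy (LSFM) recordings of the developing zebrafish heart.

Zebrafish embryos (2–5 days postfertilization) are a standard model for
early cardiac development: the tg(cmlc2:gfp) line makes the myocardium
fluoresce, so an LSFM z-stack shows a bright muscular shell around a dark,
blood-filled two-chamber lumen. Quantifying how that lumen changes over the
heartbeat — per chamber — gives the core indices of cardiac function:

- **EDV / ESV** — end-diastolic / end-systolic volume, the maximum and
  minimum of the chamber volume V(t) over one cycle;
- **SV = EDV − ESV** — stroke volume;
- **EF = 100 · SV / EDV** — ejection fraction.

Manually outlining the lumen on hundreds of 2D slices per time point is the
bottleneck. cardiomorph replaces it with a **U-net**: an encoder–decoder
convolutional network trained on hand-segmented slices that emits a binary
intracardiac mask per slice, validated against reference masks with the
**Dice coefficient** 2|A∩B|/(|A|+|B|). The single connected lumen is then
separated into atrium and ventricle by binary morphology — erode the 3D
mask until it fractures at the narrow atrioventricular canal, dilate the two
seeds back, intersect with the original mask — and each chamber's volume
trace yields its mechanics report. A cardiac-period estimator (normalized
autocorrelation with sub-sample refinement and a ±δ phase-lock window)
supports binning free-running acquisitions into one canonical cycle.

Because no public LSFM heart recordings accompany this problem, the package
ships a first-class **synthetic phantom**: a 4D beating two-chamber heart
with depth attenuation, PSF blur, shot-like noise, a trabeculated (rough)
ventricular wall, and — crucially — exact closed-form volume oracles,

    V(t) = (4/3) π a b c̄ (1 + α sin(2πt/T + φ)),

so every stage of the pipeline can be verified quantitatively: a designed
modulation amplitude α implies EF = 200α/(1+α) percent, recoverable from
the masks to within a fraction of a point.

## Worked example

Simulate a 4-dpf heart at the fast 4 μm profile, split the ground-truth
lumen into chambers, and report mechanics:

```bash
cardiomorph simulate --preset 4dpf --seed 0 --out demo/sim --pitch 4 --frames 20
```

```python
from cardiomorph import stacks_io, chamber_split, mechanics
from cardiomorph.containers import CineSequence

maps = stacks_io.read_cine_masks("demo/sim", kind="truth")
lumen = CineSequence([m.lumen() for m in maps], maps.frame_interval, maps.period)
chambers, iters = chamber_split.split_cine(lumen)
for label in (1, 2):
    r = mechanics.chamber_mechanics(chambers, label, dpf=4)
    print(f"{r.chamber}: EDV {r.edv:.4g} ESV {r.esv:.4g} SV {r.sv:.4g} um3, EF {r.ef:.1f}%")
```

prints

```
atrium: EDV 6.006e+05 ESV 2.429e+05 SV 3.576e+05 um3, EF 59.5%
ventricle: EDV 6.723e+05 ESV 4.038e+05 SV 2.684e+05 um3, EF 39.9%
```

The atrium was designed with α = 3/7 (EF = 60%) and the ventricle with
α = 1/4 (EF = 40%); both are recovered to ~0.5 points from voxelized masks,
and the atrial stroke volume lands at ≈3.6 × 10⁵ μm³. The total lumen
volume averages ≈9.5 × 10⁵ μm³ over the cycle, the scale of a 4-dpf heart.

The full pipeline — simulate → train the U-net on randomized phantom
slices → segment → split → mechanics → Dice evaluation — runs from one
JSON config:

```bash
cardiomorph run --config examples/run_config.json
```

See `examples/` for short scripts exercising each capability, including
period estimation (`examples/estimate_period.py`) and training/evaluating
the segmentation network (`examples/train_and_segment.py`).

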