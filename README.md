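# dks — deep keypoint stadiometry for ASD closure planning

`dks` is a research tool for interpretable, measurement-based treatment
suggestion in atrial septal defect (ASD) assessment from transthoracic
echocardiography (TTE).  Instead of mapping images directly to a class
("black-box" classification), it

1. **localizes anatomical keypoints** in the three standard views —
   parasternal short-axis of the aorta (PSSAX, 3 points), subxiphoid
   long-axis of the two atria (SXLAX, 4 points) and apical four-chamber
   (A4C, 4 points) — with a multiscale-supervised stacked hourglass network
   (MSHNet) refined by a fully convolutional multi-scale fusion network
   (RegNet), with auxiliary anatomical-aware pair/triplet supervision (AAS);
2. **measures** defect diameters, rims and septum length in millimetres by
   converting keypoint pixel distances through each frame's measuring
   scale (the *stadiometry* step); and
3. **decides** between transcatheter and surgical closure by evaluating an
   explicit Boolean rule set over the measurements, suggesting an occluder
   waist diameter (max defect diameter of the three views + 4 mm, rounded
   up into the device catalogue, default 8–32 mm).  Every decision carries
   a per-condition trace that a clinician can audit and override.

Keypoints are regressed as Gaussian heatmaps (peak 1, σ = 2 px encode
default) supervised at 1/8, 1/4 and 1/2 of the input resolution with a
summed per-scale MSE; decoding is argmax plus quarter-pixel refinement.
The networks run on a small self-contained numpy autodiff framework
(`dks.nnet`) — no GPU or deep-learning framework required.

Because clinical TTE datasets are private, the package ships a synthetic
echo-like generator (`dks.synthgen`) producing sector-shaped speckled
frames with a bright septum band interrupted by a defect gap, exact
analytic keypoints, randomized mm-per-pixel scale, and labels derived by
applying the decision rules to the true geometry.  Every stage is therefore
trainable and testable offline; see `docs/methods.md` for the model,
parameter and generator details and for what the synthetic results do and
do not show.

## Worked example

```python
from dks.synthgen import simulate_cases
from dks.stadiometry import measure_case
from dks.decision import decide

case = simulate_cases(5, 7, class_mix=0.6, image_size=128)[0]
m = measure_case(case.keypoints, case.scales)   # ground-truth keypoints
res = decide(m.to_dict())
print(res.plan, res.suggested_size_mm)
print(res.trace_table())
```

prints

```
transcatheter 24
measurement               value  cmp threshold  result
rim_wall_mm               10.33  >=       5.00  PASS
rim_svc_mm                 9.45  >=       5.00  PASS
rim_ivc_mm                11.11  >=       5.00  PASS
rim_roof_mm                9.01  >=       5.00  PASS
rim_mitral_mm              5.87  >=       5.00  PASS
septum_length_mm          33.04  >       24.00  PASS
```

The maximum defect diameter over the three views is 19.39 mm, so the
suggested occluder waist is the smallest catalogue size ≥ 23.39 mm, i.e.
24 mm; all five rims clear the 5 mm sufficiency threshold and the septum
(33.04 mm) can seat the device, so transcatheter closure is suggested.  Had
any condition failed (or no device fit), the plan would be surgical and the
failing row would read FAIL.

The same flow runs from the shell:

```bash
dks simulate --n 100 --seed 0 --class-mix 0.6 --image-size 64 --out data/
dks train --view A4C --manifest data/manifest.csv --seed 0 --out ckpt/
dks run --manifest data/manifest.csv --checkpoints ckpt/ --out results/
dks decide --measurements m.json            # rule trace for one case
```

`dks train` reports the best validation PCK@0.1 (fraction of keypoints
within 0.1 × the scale-bar length of ground truth); ablation flags
`--no-msh/--no-aas/--no-regnet` reproduce the vanilla-hourglass baselines.

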