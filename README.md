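# perfmap

Automated preoperative perforator mapping from CT angiography for DIEAP-flap
breast reconstruction planning.

In a DIEAP (deep inferior epigastric artery perforator) flap procedure the
surgeon harvests lower-abdominal skin and fat perfused by small perforator
arteries that pierce the rectus abdominis muscle and its anterior fascia.
Choosing the right perforator before surgery requires knowing, for each
candidate vessel, (i) the length of its intramuscular course — shorter than
4 cm is preferred, because it bounds the dissection — and (ii) where it
emerges through the fascia relative to the umbilicus. Radiologists read
these off CTA maximum-intensity projections by hand; `perfmap` computes them
automatically.

## What the package does

Given a CTA-like volume and rectus muscle masks (all arrays are `(z, y, x)`
with Z the axial slice index and anterior at low Y), the pipeline runs:

1. **Anatomical priors** (`perfmap.anatomy`) — intensity windowing for vessel
   enhancement, anterior skin sheet extraction, umbilicus detection as the
   deepest midline skin indentation, anterior rectus fascia derived
   morphologically from the muscle masks, and a candidate-vessel mask.
2. **Centerlines** (`perfmap.centerline`) — 3D thinning of each candidate
   component, ordering along the graph-diameter path (side branches at
   bifurcations are discarded), endpoint re-extension through the mask, and
   physical path lengths

   `L(c) = Σ_i ‖p_{i+1} − p_i‖₂`  (consecutive physical points, mm),

   with the endpoint straight-line distance as a control for ordering
   failures.
3. **Centerline-guided prompted segmentation** (`perfmap.prompting`) — per
   axial slice, positive point prompts refined to the brightest voxel within
   a 5-voxel radius (the contrast-filled lumen) and negative prompts ringed
   just outside the vessel; a pluggable single-mask backend segments each
   slice independently and the 2D outputs are stacked to 3D. Shipped
   backends: a ground-truth oracle and a deterministic threshold
   region-grower; foundation-model adapters can implement the same
   two-method interface.
4. **Evaluation** (`perfmap.evaluate`) — DSC, IoU, average surface distance,
   Hausdorff distance and its 95th-percentile variant, inference time per
   centerline; MAE/MdAE/RMSE/IQR error statistics; and model comparison by
   MANOVA (Wilks' λ), per-metric one-way ANOVA, and Tukey HSD.
5. **Quantification** (`perfmap.quantify`) — intramuscular path length (the
   centerline restricted to the muscle mask), the fascial emergence point
   (direct fascia intersection, else nearest approach within 20 voxels along
   Y), and the umbilicus offsets `(|Δz|·s_z, |Δx|·s_x)` in mm.
6. **Training losses** (`perfmap.losses`) — Dice, cross-entropy and Skeleton
   Recall Loss (soft recall of the prediction on the dilated ground-truth
   skeleton, which penalises broken tubular continuity), combined as
   `w_d·L_Dice + w_s·L_SRL + w_ce·L_CE`; the shipped optimised profile is
   `(0.5, 0.33, 0.17)`.

A synthetic phantom generator (`perfmap.phantom`) builds CTA-like cases with
layered abdominal anatomy and parametric perforator curves whose
intramuscular arc lengths and emergence points are known analytically, so
every stage is testable without clinical data.

## Worked example

```
python examples/04_clinical_report.py
```

runs the whole pipeline on a self-generated phantom (seed 1) with the
region-growing backend and prints:

```
id     intramusc straight   vert  horiz  flags
cl00        44.6     62.5   18.0   29.6  LONG, central
cl01        25.4     48.2   18.0   20.8  short, central
cl02        23.2     43.9    8.0   21.6  short, central
cl03        22.3     53.3    2.0   11.2  short, central
cl04        22.4     53.2    9.0   30.4  short, central
```

One perforator has an intramuscular course over 4 cm (flagged `LONG`, i.e.
a longer dissection); the others are surgically preferable. `vert`/`horiz`
are the mm offsets of each vessel's fascial emergence point from the
umbilicus. The phantom's analytic truth for these five vessels is
22.2/22.5/22.0/25.4/44.8 mm, so the recovered lengths are accurate to well
under a millimetre on average. `examples/01–03` and `05` demonstrate the
individual stages (phantom generation, centerline extraction, prompted
segmentation scoring, backend comparison statistics).

The same workflow is available from the shell:

```
perfmap run --phantom --backend region-grow --seed 1 --out runs/demo
perfmap phantom --out case/ --seed 7
perfmap evaluate --pred pred.nrrd --gt gt.nrrd --out metrics.json
```

Exit codes: 0 success, 2 validation error, 1 runtime failure.

## Scope

Foundation-model inference and fine-tuning (SAM-family, nnInteractive) are
deliberately out of scope: backends are adapters behind one interface, and
only classical reference backends ship here. Muscle masks are inputs, not
computed. See `docs/methods.md` for the model, parameter defaults, numerical
choices and limitations.
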