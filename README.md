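# dropcascade

Image analysis for droplet-microfluidics crystallization experiments:
cascaded binary U-Net segmentation, K-Means binarization and object
counting, per-droplet content classification, and first-order kinetics of
the amorphous-calcium-carbonate (ACC) to crystal transformation.

## The problem

In a droplet-microfluidics screen, thousands of ~170 µm aqueous droplets
each act as an independent micro-batch crystallizer.  ACC forms instantly
in every droplet; over hours, some droplets transform to a crystalline
polymorph — vaterite (spherical habit) or calcite (rhombohedral habit) —
visible as a tiny high-contrast inclusion of only a few pixels.  Measuring
the transformation rate means classifying the contents of every droplet in
hundreds of large time-lapse frames, which is infeasible by hand.

Direct multi-class segmentation fails here because of extreme feature
imbalance: crystals occupy ≤3 px while droplets and the textured chip
background dominate.  The cascade sidesteps this:

1. **U-Net 1** segments droplets from the raw RGB frame.
2. The binarized droplet mask is **overlaid** on the frame — every pixel
   outside a droplet is blacked out, removing background contrast.
3. **U-Nets 2 and 3** independently segment vaterite and calcite on the
   overlaid image, where the tiny targets are no longer drowned out.
4. Probability maps are binarized by two-cluster **K-Means** on pixel
   intensity, objects are counted by connected components, and each droplet
   (delimited by the minimum enclosing circle of its mask component) is
   classified by the crystal centroids that fall inside it.  A droplet
   contains ACC exactly when it contains no crystal.

Pooling counts over locations gives a time series N_ACC(t), fitted with an
exponential-plateau model

    N_ACC(t) = A·e^(−kt) + C            (count or ratio form)

where k (min⁻¹) is the first-order transformation rate of the labile
droplet population and C is the inert plateau.  The ACC half-life is finite
only if the plateau of the ratio form lies below 0.5; otherwise the latest
observation with ACC fraction > 0.5 gives an empirical lower bound.

Very large frames are handled by a cut-and-resize step (at most two cuts
per axis, to limit reconstruction seam artifacts), with the per-tile
predictions merged back to full-frame masks.

The U-Nets and their training loop (Adam on binary cross-entropy, with
hand-written backpropagation) are implemented in NumPy inside the package;
a built-in synthetic scene generator with exact ground truth makes the
entire pipeline testable end to end without any experimental data.

## Worked example

`examples/fit_kinetics.py` simulates 12 locations × 16 timesteps of ~55
droplets under a known rate of 0.027 min⁻¹ with a 10% labile population,
assembles the pooled ACC series and fits the ratio-form model:

```
simulated 660 droplets over 16 timesteps (true rate 0.027/min)
fitted ratio model: 0.106 * exp(-0.0265 t) + 0.898
ACC fraction at t=360 min: 0.898 (~90% of droplets still amorphous)
half-life under fitted model: unreachable
24-h ACC fraction 0.678 -> half-life > 1440 min
```

The fitted rate (0.0265 min⁻¹) recovers the generating rate to ~2%; the
plateau of 0.898 means ~90% of droplets remain amorphous after six hours,
so the half-life cannot be reached under the fitted model and is instead
bounded below by a 24-hour count (443 of 653 droplets still ACC → fraction
0.678 → half-life > 24 h).

Other examples: `examples/simulate_scene.py` (scene generation and ground
truth), `examples/count_and_classify.py` (counting and per-droplet
classification), `examples/train_cascade.py` (training the cascade on
synthetic tiles; droplet IoU ≈ 0.97 on held-out scenes).

A thin CLI exposes the same pipeline for shell use:

```
dropcascade simulate --config config.yml --out data/
dropcascade train    --config config.yml --data data/ --out models/
dropcascade predict  --config config.yml --data data/ --models models/ --out pred/
dropcascade analyze  --counts pred/counts.csv --out analysis/
```

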