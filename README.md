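# spintrack

Planar rotation analysis of optically trapped ellipsoidal cells from video.

When an elongated cell — the motivating case is a human sperm head held in
optical tweezers — rotates in the image plane, its projected outline is an
ellipse whose major-axis orientation α(t) encodes the rotation.  `spintrack`
turns a grayscale video into a rotation-rate measurement:

1. crop a region of interest around the trap center (or track a swimming
   cell's centroid),
2. segment the cell head — with a nested encoder–decoder network (U-Net++
   topology) trained on a hybrid cross-entropy / soft-Dice loss, or with
   classical baselines (intensity clustering, Chan–Vese level set, Otsu),
3. fit an ellipse to the mask boundary and extract the orientation
   α ∈ [0°, 180°),
4. unwrap the 180° axis ambiguity by the minimal-increment rule
   Δ ∈ (−90°, 90°], and
5. compute the forward-difference angular speed

       Ω(k) = |α(k+1) − α(k)| / (2π) · fps    [revolutions / s]

   plus summary statistics and Welch two-sample t-tests between cells or
   conditions.

Segmentation quality is scored by IoU = |S∩T|/|S∪T| and
Dice = 2|S∩T|/(|S|+|T|).  A synthetic-video generator renders a rotating
elliptical head (length 4–5 µm, width 2.5–3.5 µm) over a complex, blob-noisy
background with *exact* ground-truth masks and orientations, so the entire
pipeline is testable without microscopy data.  The network, its
backpropagation and the Adam optimiser are implemented directly on NumPy
arrays (`spintrack.nn`) and gradient-checked in the test suite.

## Worked example

```python
from spintrack import (FrameStack, NoiseModel, PipelineConfig, SynthParams,
                       generate_sequence, run_rotation_pipeline)

params = SynthParams(
    omega_true=2.0, fps=163.0, seed=5,
    background_noise=NoiseModel(gaussian_sd=0.0, blob_count=0, blob_intensity=0.0),
    psf_sigma_px=0.5,
)
frames, truth = generate_sequence(params, n_frames=163)
result = run_rotation_pipeline(FrameStack(frames, fps=163.0),
                               PipelineConfig(method="threshold"))
s = result.summary
print(f"mean Omega: {s.mean:.4f} rev/s over {s.n} frame pairs")
print(f"median / IQR: {s.median:.4f}  [{s.q25:.4f}, {s.q75:.4f}] rev/s")
```

prints

```
mean Omega: 1.9999 rev/s over 162 frame pairs
median / IQR: 2.0160  [1.8594, 2.1769] rev/s
```

i.e. a clip generated at 2.0 rev/s is recovered to 0.005%; the per-frame
spread (IQR) reflects rasterization jitter of the fitted orientation, which
averages out over frames.  The `examples/` directory walks through each
capability: synthesis, rotation measurement, training, group comparison and
the segmentation benchmark.  The same flows are available from the shell:

```sh
spintrack synth --omega 2 --n-frames 163 --seed 7 --out-dir clip/
spintrack rotate --in clip/frames.tif --method threshold --fps 163 --out-dir results/
spintrack train --epochs 10 --seed 0 --out model.npz
spintrack compare results_a/speed.csv results_b/speed.csv
spintrack benchmark --model model.npz --n-frames 30
```

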