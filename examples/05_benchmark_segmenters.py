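"""Benchmark classical segmentation methods on labelled synthetic frames.

Scores each method by mean IoU and Dice against the truth masks, in the
layout of a model-comparison table.  On blob-noisy frames the intensity-only
methods (clustering, thresholding) lose ground because bright background
structure is indistinguishable from the cell by intensity alone; run
examples/03 first if you want to add the trained network to the comparison.
"""

from spintrack import benchmark_segmenters, generate_training_set, kmeans_segment, levelset_segment, threshold_segment

pairs = generate_training_set(n_images=10, seed=33, image_size=120)

result = benchmark_segmenters(
    pairs,
    {
        "Clustering": kmeans_segment,
        "Level set": lambda f: levelset_segment(f, iterations=60),
        "Threshold": threshold_segment,
    },
)
print(result)
print("\n(higher IoU/Dice = better overlap with the truth mask; time is informational)")
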