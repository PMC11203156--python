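"""Enhance a noisy OCT-like volume and show what each guarantee means.

Builds a small synthetic time series, derives the reference histogram from
its volumes, runs the enhancement chain on the first timepoint and prints
the intensity statistics before and after.
"""

import numpy as np

from octrack import (
    PhantomConfig,
    build_reference_histogram,
    generate_scene,
    normalize_intensity,
    preprocess_volume,
)

scene = generate_scene(PhantomConfig(shape=(48, 80, 80), n_organoids=5, days=(1, 3, 5), seed=11))
volumes = list(scene.volumes.values())

ref = build_reference_histogram(volumes, p_norm=95.0)
print(f"reference 95th percentile (from {len(volumes)} volumes): {ref.p95_ref}")

vol = volumes[0]
normed = normalize_intensity(vol, ref)
print(f"after normalization, volume p95 = {np.quantile(normed.data, 0.95):.1f} "
      f"(anchored to the reference, so intensity is comparable across days)")

pre = preprocess_volume(vol, ref)
mask = scene.labels[min(scene.labels)].labels > 0

def rel_contrast(a):
    return (a[mask].mean() - a[~mask].mean()) / a.max()

print(f"output dtype: {pre.data.dtype}, range {pre.data.min()}..{pre.data.max()}")
print(f"organoid/background contrast raw: {rel_contrast(vol.data.astype(float)):.3f}, "
      f"preprocessed: {rel_contrast(pre.data.astype(float)):.3f}")
print("higher contrast after the chain means organoids stand out more for segmentation")
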