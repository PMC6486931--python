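"""Spatial and spatio-temporal Haralick texture of a phantom lesion.

The spatial GLCM pairs each lesion voxel with its 26 neighbours; the
spatio-temporal GLCM pairs the same voxel's intensity at two time points
of the enhancement (pre/peak/post), so its energy measures how uniformly
the lesion takes up contrast over time.
"""

import mplesion as mp
from mplesion.texture import glcm_3d, haralick13, temporal_glcm

config = mp.PhantomConfig(n_patients=1, seed=5)
study, _ = mp.make_cohort(config)[0]
std = mp.standardise_study(study)
lesion = study.annotation == 1

spatial = haralick13(glcm_3d(std.dce_peak, lesion))
print("spatial texture of the peak-contrast volume:")
print(f"  energy={spatial['energy']:.4f}  entropy={spatial['entropy']:.2f}  "
      f"contrast={spatial['contrast']:.1f}")

for a, b in (("dce_pre", "dce_peak"), ("dce_pre", "dce_post"), ("dce_peak", "dce_post")):
    h = haralick13(temporal_glcm(getattr(std, a), getattr(std, b), lesion))
    print(f"temporal {a} vs {b}: energy={h['energy']:.4f} entropy={h['entropy']:.2f}")

# Higher temporal energy means more voxels share the same (before, after)
# intensity pair, i.e. homogeneous contrast uptake; heterogeneously
# enhancing lesions spread mass across the matrix and lose energy.
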