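"""Compute one subject's lFCD and FOCA maps through the full subject-level
branch: volume dropping, nuisance regression, band-pass (lFCD only), the
statistic, whole-brain-mean normalization and 8 mm smoothing.
"""

import numpy as np

from lifespan_localfc import PipelineConfig, compute_subject_maps, default_spec, generate_subject

spec = default_spec(seed=7)
vol, motion = generate_subject(spec, age=70.0, subject_seed=0)
wm, csf = spec.tissue_masks()
cfg = PipelineConfig()  # r=0.6, tSNR 50, 0.01-0.08 Hz, FWHM 8 mm

for statistic in ("lfcd", "foca"):
    m = compute_subject_maps(vol, motion, wm, csf, statistic, cfg)
    inside = m.values[m.mask]
    decl = m.values[spec.effect_regions[0].index(spec.grid_shape)].mean()
    rise = m.values[spec.effect_regions[1].index(spec.grid_shape)].mean()
    print(f"{statistic:4s}: in-mask mean {inside.mean():.3f} "
          f"(normalized), declining-region mean {decl:.2f}, "
          f"rising-region mean {rise:.2f}")

# At age 70 the declining region's coherence has fallen to ~0.43 and the
# rising region's has grown to ~0.57; with the r=0.6 growth threshold the
# rising region therefore shows a much larger normalized lFCD, and a higher
# FOCA, than the declining one.
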