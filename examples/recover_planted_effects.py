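"""End-to-end validation: simulate a 100-subject cohort, run the whole
pipeline, and check that the group GLM recovers the planted age effects.
"""

import json

from lifespan_localfc import default_spec, recover_planted_effects

spec = default_spec(n_subjects=100, seed=1)
report = recover_planted_effects(spec, statistic="lfcd", coef="age")
print(json.dumps(report, indent=2))

# "sign" is the sign of the mean age-coefficient t-value over the planted
# region's voxels and should match the sign of the planted slope;
# "cluster_overlap" is True when an FDR-surviving >30-voxel cluster
# touches the region.
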