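"""Densify a sparse scanpath: rescale durations, replicate, jitter, rasterize.

A two-fixation scanpath (the sparsest the eye tracker produced) becomes a
duration-weighted cloud of jittered points, and its fixation map marks every
pixel within 10 px of an original fixation.
"""

import numpy as np

from gazeattr import AugmentationParams, render_fixation_map, replicate_and_jitter, rescale_durations
from gazeattr.types import Fixation, Scanpath

sp = Scanpath(
    fixations=[Fixation(40, 40, 120.0), Fixation(80, 60, 480.0)],
    participant_index=0,
    image_id="img_000",
    group_label="TD",
)
params = AugmentationParams()  # rescale to [1, 100], jitter and radius 10 px

scaled = rescale_durations(sp, params)
print(f"durations {[f.duration for f in sp.fixations]} ms -> scaled {scaled.tolist()}")
# the shortest fixation maps to 1 replica, the longest to 100

aug = replicate_and_jitter(sp, image_shape=(128, 128), params=params, rng=np.random.default_rng(0))
xy = aug.xy()
print(f"augmented length {len(aug)} = sum of scaled durations {scaled.sum()}")
print(f"max |shift| from source fixations: {max(np.abs(xy[:1] - [40, 40]).max(), np.abs(xy[1:] - [80, 60]).max()):.0f} px (<= 10)")

fixmap = render_fixation_map(sp, (128, 128), radius=params.fixmap_radius)
print(f"fixation map marks {int(fixmap.sum())} pixels "
      f"(two radius-10 disks; a single centered disk covers 317 lattice points)")
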