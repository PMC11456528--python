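"""Correct depth-dependent intensity loss on a synthetic cell cluster.

Builds a 40-section phantom pair in which both channels lose signal
exponentially with depth (30% retained at the bottom), then divides the
signal of interest by the per-section non-zero mean of the reference
channel.  The raw depth profile shows the attenuation; the corrected
profile is flat because the shared loss cancels in the ratio.
"""

import numpy as np

from stacknorm import (
    AttenuationModel,
    PhantomSpec,
    depth_profile,
    generate_pair,
    section_means,
    ssin_normalize,
)

spec = PhantomSpec()  # 40 sections, 128x128, 8-bit, depth-uniform SOI
model = AttenuationModel.exponential_to(0.3, spec.shape[0])
ns, soi, truth = generate_pair(spec, model)

raw = depth_profile(soi)
normalized = ssin_normalize(soi, section_means(ns))
post = depth_profile(normalized)

print(f"raw profile:  top section {raw.percent_of_max[0]:.1f}% of max, "
      f"deepest {raw.percent_of_max[-1]:.1f}%")
print(f"post profile: top section {post.percent_of_max[0]:.1f}% of max, "
      f"deepest {post.percent_of_max[-1]:.1f}%")
print(f"max deviation from flat after correction: "
      f"{np.abs(post.percent_of_max - 100).max():.2e} percent points")
# The raw profile drops to ~30% at the deepest section (pure imaging
# artifact); after normalization every section reads 100%, i.e. the
# depth gradient was methodological, not biological.
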