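"""Orthogonal mean-projection heatmaps before and after normalization.

A membrane-receptor-like phantom concentrates its signal in a top cap
and peripheral annulus.  The side-view (xz) projection of the raw stack
mixes that true localization with depth attenuation; after
normalization the artifact is gone while the shell contrast remains.
"""

from pathlib import Path

from stacknorm import (
    AttenuationModel,
    PhantomSpec,
    generate_pair,
    section_means,
    snip_heatmap,
    ssin_normalize,
)

out = Path("example_output")
out.mkdir(exist_ok=True)

spec = PhantomSpec(soi_pattern="top_shell")
model = AttenuationModel.exponential_to(0.3, spec.shape[0])
ns, soi, truth = generate_pair(spec, model)

pre = snip_heatmap(soi, out=out / "snip_pre.png")
post = snip_heatmap(
    ssin_normalize(soi, section_means(ns)), out=out / "snip_post.png"
)

half = spec.shape[0] // 2
for label, pset in [("pre ", pre), ("post", post)]:
    rows = pset.xz.mean(axis=1)
    print(f"{label}: xz top-half/bottom-half row-mean ratio = "
          f"{rows[:half].mean() / rows[half:].mean():.3f}")
truth_rows = truth.soi_base.mean(axis=(1, 2))
print(f"ground truth ratio (from the unattenuated pattern) = "
      f"{truth_rows[:half].mean() / truth_rows[half:].mean():.3f}")
print(f"figures written to {out}/")
# Pre-normalization the ratio is inflated by depth loss; after
# normalization it matches the ground-truth anatomy of the phantom.
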