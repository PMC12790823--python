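"""Expression denoising via reconstruction.

The decoder's output replaces each spot's noisy profile with a spatially
informed reconstruction; marker genes become cleaner inside their domain.
"""

import numpy as np

from stgap import (
    FixtureSpec,
    TrainConfig,
    adaptive_radius,
    build_radius_graph,
    embed_and_denoise,
    generate_fixture,
    normalize_expression,
    partition_graph,
    select_hvg,
    train,
)

spec = FixtureSpec()
ds_raw, truth = generate_fixture(spec)
ds = select_hvg(normalize_expression(ds_raw), 200)
g = build_radius_graph(ds.coords, adaptive_radius(ds.coords))
p = partition_graph(g, spot_batch_size=256, seed=0)
model, _ = train(ds, g, p, TrainConfig(epochs=100, seed=0))
assign = embed_and_denoise(ds, g, p, model)

X, Xh = ds.dense(), assign.denoised
marker = 0  # a domain-0 marker gene
inside = truth == 0
for name, M in (("raw", X), ("denoised", Xh)):
    contrast = M[inside, marker].mean() - M[~inside, marker].mean()
    cv = M[inside, marker].std() / max(M[inside, marker].mean(), 1e-9)
    print(f"{name:9s} marker gene: in-domain minus out-of-domain mean "
          f"{contrast:.2f}, in-domain CV {cv:.2f}")
# The denoised profile keeps the in/out contrast while shrinking the
# within-domain coefficient of variation: technical noise is smoothed using
# spatial context.
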