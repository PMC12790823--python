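"""Simulate a tissue section with planted domains and preprocess it.

Builds a 2000-spot jittered grid with 4 contiguous expression domains,
normalizes counts and selects variable genes — the inputs every later stage
consumes.
"""

from stgap import FixtureSpec, generate_fixture, normalize_expression, select_hvg

spec = FixtureSpec()  # 50x40 grid, K=4 bands, 200 genes, Poisson counts
ds_raw, truth = generate_fixture(spec)
print(f"section: {ds_raw.n_spots} spots x {ds_raw.n_genes} genes, "
      f"{spec.n_domains} planted domains")
print(f"mean total counts per spot: {ds_raw.dense().sum(1).mean():.1f}")

ds = normalize_expression(ds_raw, target_sum=1e4, apply_log1p=True)
ds = select_hvg(ds, n_top=200)
print(f"after normalization + HVG: {ds.n_genes} genes, "
      f"log1p-scaled (max value {ds.dense().max():.2f})")
# Each spot's counts now sum to the same depth pre-log, so expression
# differences reflect composition, not sequencing depth.
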