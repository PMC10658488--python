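"""Generate one synthetic vessel network and read off its morphology.

Builds a single 1 x 1 mm (256 px at 4 um/px) vasculogenesis-like mask and
prints the six morphological metrics used everywhere downstream. Coverage
is an area fraction; lengths and diameters are in micrometres.
"""

from vnqi import GeneratorConfig, generate_mask, measure

config = GeneratorConfig(n_seed_points=120, connect_prob=0.85, rng_seed=7)
mask = generate_mask(config)
metrics = measure(mask)

print(f"mask: {mask.pixels.shape} px at {mask.pixel_pitch} um/px")
print(f"vessel coverage        {metrics.vessel_coverage:8.3f}  (fraction of field)")
print(f"total vessel length    {metrics.total_vessel_length:8.0f}  um")
print(f"segment count          {metrics.segment_count:8d}")
print(f"branchpoint count      {metrics.branchpoint_count:8d}")
print(f"mean segment length    {metrics.mean_segment_length:8.1f}  um")
print(f"mean segment diameter  {metrics.mean_segment_diameter:8.1f}  um")
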