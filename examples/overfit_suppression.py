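"""Suppressing correlated high-resolution artefacts (over-fitting).

Over-fitting stabilises noise identically into both half maps, so it
correlates like signal and inflates the FSC. This script plants such an
artefact in a low-resolution sector, well above that sector's true
truncation frequency, and shows that filtering pulls the region's FSC
in the planted band back down.
"""

import splitfilter as sf

spec = sf.PhantomSpec(seed=0)
truth, sector_masks = sf.generate_phantom(spec)
mask = sf.ring_mask(spec)
pair = sf.make_half_pair(truth, spec.noise_sigma, seed=5, mask=mask)

sector, band = 2, (0.25, 0.35)  # sector truncated at 0.05 cycles/voxel
planted = sf.plant_correlated_artefact(
    pair, sector_masks[sector], band, amplitude=spec.noise_sigma, seed=99
)

result = sf.run_filter(planted)
box = spec.box_size
band_shells = slice(int(band[0] * box), int(band[1] * box) + 1)
before = sf.masked_region_fsc(planted, sector_masks[sector])[band_shells].mean()
after = sf.masked_region_fsc(result, sector_masks[sector])[band_shells].mean()

print(f"sector truncated at {spec.subunit_truncations[sector]} cycles/voxel; "
      f"artefact planted in band {band[0]}-{band[1]} cycles/voxel")
print(f"masked FSC in the planted band: {before:.3f} before, {after:.3f} after")
print("\nThe artefact correlates like signal (high FSC before filtering) but "
      "its voxel values fall below the global noise maximum at those "
      "resolutions, so the filter strips it - the mechanism that breaks the "
      "feedback loop of local over-fitting during iterative refinement.")
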