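"""Read off the filter's per-voxel resolution assignment on a phantom.

The six sectors of the phantom are truncated at known frequencies
(0.0125 ... 0.35 cycles/voxel). After filtering, each voxel carries the
index of the highest shell at which its signal beat the noise bound —
an implicit local resolution map. This script compares the per-sector
median assignment with the known truncation shells.
"""

import numpy as np

import splitfilter as sf

spec = sf.PhantomSpec(seed=0)
truth, sector_masks = sf.generate_phantom(spec)
mask = sf.ring_mask(spec)
pair = sf.make_half_pair(truth, spec.noise_sigma, seed=11, mask=mask)
result = sf.run_filter(pair)

box = spec.box_size
print(f"schedule terminated at shell {result.schedule.terminated_at}")
print("sector  truncation(c/v)  true shell  median assigned shell")
for i, (trunc, smask) in enumerate(zip(spec.subunit_truncations, sector_masks)):
    median = np.median(result.assigned_resolution1[smask.interior])
    print(f"{i:6d}  {trunc:15.4f}  {trunc * box:10.1f}  {median:12.1f}")

print("\nThe assignment tracks the truncation ordering. Sectors truncated at "
      "0.05-0.1 cycles/voxel read high: at this box size their truncation "
      "kernels are wider than a sector, so neighbouring density leaks into "
      "the estimate (see docs/methods.md).")
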