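"""Filter a synthetic half-map pair and inspect the shared statistics.

Builds the default six-sector phantom, adds independent Gaussian noise
to make a half-map pair, runs the two-pass filter and prints the
per-shell scalars the two half-sets share: FSC, C_ref, the signal
fraction P_S and the noise bound used at each cutoff.
"""

import numpy as np

import splitfilter as sf

spec = sf.PhantomSpec(seed=0)
truth, sector_masks = sf.generate_phantom(spec)
mask = sf.ring_mask(spec)
pair = sf.make_half_pair(truth, spec.noise_sigma, seed=1, mask=mask)

result = sf.run_filter(pair)
sched = result.schedule

print(f"schedule: {len(sched.shells)} shells, terminated at shell "
      f"{sched.terminated_at} ({sched.termination_reason})")
print("shell   fsc   cref    P_S   noise_bound")
for s in sched.shells[::4]:
    bound = result.bounds.get(s.shell_index)
    print(f"{s.shell_index:5d}  {s.fsc:5.2f}  {s.cref:5.2f}  {s.p_signal:5.2f}"
          f"   {bound.used:8.3f}" if bound else "")

interior = mask.interior
err_before = np.sqrt(np.mean((pair.half1.data[interior]
                              - (truth.data * mask.data)[interior]) ** 2))
err_after = np.sqrt(np.mean((result.filtered_half1.data[interior]
                             - (truth.data * mask.data)[interior]) ** 2))
print(f"\nRMS error vs ground truth inside the mask: "
      f"{err_before:.3f} before filtering, {err_after:.3f} after")
print("The filter removes most of the noise while the schedule table above "
      "is the only information the two half-sets ever exchanged.")
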