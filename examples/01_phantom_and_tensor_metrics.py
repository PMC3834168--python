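"""Build the standard crossing/bending/splitting phantom and fit the tensor.

Prints the fitted FA/MD/AD/RD inside each designed bundle. The two crossing
bundles are designed with different anisotropy (FA ~0.77 vs ~0.49), which is
what makes the crossing hard for deterministic tracking.
"""

import numpy as np

import tractbench as tb
from tractbench import tensor

spec, gt = tb.make_standard_phantom(snr=20.0, rng_seed=0)
dwi = tb.simulate_dwi(spec, gt)
eigs = tensor.eigendecompose(tensor.fit_tensor(dwi))
maps = tensor.scalar_maps(eigs)

print(f"phantom grid {spec.shape} at {spec.voxel_mm} mm, SNR {spec.snr}")
print(f"{'bundle':<12}{'FA':>6}{'MD':>7}{'AD':>7}{'RD':>7}  (1e-3 mm^2/s)")
for name, bt in gt.bundles.items():
    pure = bt.fraction > 0.99
    for other, ob in gt.bundles.items():
        if other != name:
            pure &= ~ob.mask
    if not pure.any():
        continue
    print(f"{name:<12}{maps.fa[pure].mean():6.2f}{maps.md[pure].mean():7.2f}"
          f"{maps.ad[pure].mean():7.2f}{maps.rd[pure].mean():7.2f}")
print("\nFA is unitless in [0, 1]; the high-FA bundle should read ~0.77 "
      "(prints as 0.8) and the low-FA bundle ~0.49.")
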