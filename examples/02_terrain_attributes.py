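"""Derive the full terrain-attribute stack from a DTM.

Slope/aspect come from the Zevenbergen-Thorne polynomial fit, catchment
area from D-infinity routing on the pit-filled surface, and PSIR from a
clear-sky geometric insolation model; TWI = ln(A/tan b) and the LSF
erosion index follow from area and slope.
"""
import numpy as np

import biocrust as bc

dtm = bc.generate_dtm(bc.SceneConfig(seed=1))
stack = bc.compute_terrain_stack(dtm)

for name, r in stack.as_dict().items():
    v = r.values[r.mask]
    print(f"{name:12s} min {v.min():12.3f}  mean {v.mean():12.3f}  "
          f"max {v.max():12.3f}")
# Northernness spans ~0-2 (south- to north-facing), PSIR is annual
# insolation in Wh/m2/yr (south-facing cells receive the most), and TWI
# is highest along convergent hollows where the catchment area grows.
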