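"""Quantify a synthetic western blot with the fixed-ROI densitometry chain.

A rectangle of fixed size measures each band; the same-size region directly
below it provides the background; each band is normalized to its loading
control and then to the average of the wild-type lanes.
"""

import numpy as np

from centroquant import BandROI, measure_lanes, normalize_bands

# synthetic blot scan: two lanes of bound protein plus loading controls
blot = np.zeros((60, 80))
blot[5:11, 5:15] = 100.0    # lane 1 (WT) band
blot[11:17, 5:15] = 40.0    # background region below it
blot[5:11, 25:35] = 70.0    # lane 2 (mutant) band
blot[11:17, 25:35] = 40.0
blot[30:36, 5:15] = 100.0   # loading controls
blot[30:36, 25:35] = 100.0

rois = [
    BandROI("1", "band", 5, 5, 10, 6),
    BandROI("1", "loading", 5, 30, 10, 6),
    BandROI("2", "band", 25, 5, 10, 6),
    BandROI("2", "loading", 25, 30, 10, 6),
]
records = normalize_bands(measure_lanes(blot, rois), wt_lanes=["1"])
cols = ["lane", "raw_mean", "background_mean", "net", "loading_net",
        "ratio", "normalized"]
print(records[cols].to_string(index=False))
print()
print("lane 2 net = 70-40 = 30; ratio = 30/100 = 0.3; "
      "normalized = 0.3 / 0.6 = 0.5 of WT binding")
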