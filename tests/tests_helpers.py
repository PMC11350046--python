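"""Shared fixture builders used across test modules."""

import numpy as np

from tauhcn.ultra import VesicleMap


def simple_map(coords, sid="s") -> VesicleMap:
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    return VesicleMap(
        synapse_id=sid, coords=coords, diameters=np.full(n, 40.0),
        is_dcv=np.zeros(n, bool),
        active_zone=np.array([[0.0, 0.0], [500.0, 0.0]]),
        presyn_area=0.35,
    )
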