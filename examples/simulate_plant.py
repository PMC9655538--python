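"""Grow one synthetic plant and inspect its exact ground truth.

The simulator extends each root tip day by day; treatment multipliers scale
the elongation and branching rates. Printed lengths are exact polyline arc
lengths — the oracle every downstream measurement is checked against.
"""
import numpy as np

from rootscreen.plate_core import PlantId, PlateGeometry
from rootscreen.synth_plate import SimParams, simulate_root_system

geom = PlateGeometry(n_holes=1)
params = SimParams(rng_seed=3)

for treatment in ("Amb-Ctl", "HT-Ctl"):
    truth = simulate_root_system(params, PlantId("demo", 0), day=14,
                                 geom=geom, treatment=treatment)
    print(f"{treatment} at 14 days after inoculation:")
    print(f"  primary root        {truth.length_primary_cm:6.2f} cm")
    print(f"  1st-order laterals  {truth.length_lat1_cm:6.2f} cm "
          f"({truth.n_lat1} roots)")
    print(f"  2nd-order laterals  {truth.length_lat2_cm:6.2f} cm "
          f"({truth.n_lat2} roots)")
    print(f"  total               {truth.length_total_cm:6.2f} cm, "
          f"depth {truth.depth_cm:.1f} cm, "
          f"mean branching angle {truth.branching_angle_deg:.0f} deg")

# The high-temperature multipliers slow every rate, so the heat-stressed
# plant should be a strictly smaller root system than the ambient one.
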