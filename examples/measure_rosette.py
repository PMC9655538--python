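"""Segment a synthetic rosette image and compare to its rendered truth.

The segmentation is the platform's published operating point: HSV box
thresholds (hue 21-222 deg, saturation >= 0.11, value >= 0.17) followed by
the two cluster-size cleanup passes. The measured projected leaf area
should match the rendered truth to well within 3%.
"""
from rootscreen.plate_core import PlateGeometry
from rootscreen.shoot_pheno import measure_shoot_image
from rootscreen.synth_plate import render_rosette_image

geom = PlateGeometry(n_holes=1)
img, true_area, _ = render_rosette_image(n_leaves=8, leaf_area_mm2=250.0,
                                         geom=geom, rng=42)
meas, mask = measure_shoot_image(img, geom, dai=14)

print(f"rendered true area : {true_area:8.2f} mm^2")
print(f"measured area      : {meas.projected_leaf_area_mm2:8.2f} mm^2 "
      f"({meas.n_plant_pixels} plant pixels)")
err = abs(meas.projected_leaf_area_mm2 - true_area) / true_area * 100
print(f"relative error     : {err:8.2f} %")
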