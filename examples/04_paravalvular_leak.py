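"""Quantify diastolic paravalvular leakage for the two implant analogues.

Post-implant presets seal the occluder except for leak channels: two
wide gaps between the native leaflets and the stent frame (calcific
case) versus three narrow commissural gaps (fibrocalcific case). A
constant 90/0 mmHg aortic/ventricular pressure pair drives the
regurgitant flow; the leak volume is the plane flux integrated over the
500 ms diastolic window.
"""

from stenoflow import make_scenario, pvl_volume, run_flow

volumes = {}
for preset in ("CAS_post_pvl", "FAS_post_pvl"):
    sc = make_scenario(preset, rng_seed=0)
    flow = run_flow(sc, duration=10.0, output_stride=1000, drive="constant")
    plane = [p for p in sc.measurement_planes if p.label == "AA'"][0]
    volumes[preset] = pvl_volume(flow, plane, steady=True)
    gaps = ", ".join(f"{g['location_tag']} {g['width'] * 1e3:.1f} mm"
                     for g in sc.geometry.gap_channels)
    print(f"{preset}: gaps [{gaps}] -> {volumes[preset]:.4f} ml/beat")

ratio = volumes["CAS_post_pvl"] / volumes["FAS_post_pvl"]
print(f"leak ratio CAS/FAS = {ratio:.1f}: the wide leaflet-stent gaps "
      "pass several times the regurgitant volume of the narrow "
      "commissural gaps")
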