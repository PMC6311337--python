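"""Plan both pubic-body screws on one synthetic hemipelvis.

Generates the default hemipubis phantom (symphyseal body, superior
ramus, obturator foramen, tubercle), places the virtual reconstruction
plate along the pelvic brim and reports every corridor parameter:
insertion angles (degrees), screw lengths (mm) and the safe-region
pattern seen along the obturator-tangential screw.
"""

from pubicorridor import (PipelineConfig, PubisPhantomSpec,
                          analyze_hemipelvis, generate_pubis_phantom)

mesh, landmarks = generate_pubis_phantom(PubisPhantomSpec())
result = analyze_hemipelvis(mesh, landmarks, PipelineConfig())

flat = result.to_flat_dict()
print("inner screw (site M, 6.5 mm lateral of the tubercle edge):")
print(f"  insertion-plane MIA {flat['inner_plane_MIA_deg']:.2f} deg "
      "(medial obliquity of the OM plane)")
print(f"  MAIA {flat['inner_MAIA_deg']:+.2f} deg, "
      f"MPIA {flat['inner_MPIA_deg']:+.2f} deg, "
      f"L1 {flat['inner_L1_mm']:.2f} mm at maximal antversion")
print("outer screw (site L, 19.5 mm lateral):")
print(f"  MAIA {flat['outer_MAIA_deg']:+.2f} deg, "
      f"MPIA {flat['outer_MPIA_deg']:+.2f} deg, "
      f"L2 {flat['outer_L2_mm']:.2f} mm")
print("obturator-tangential screw (lateral safety bound):")
print(f"  MIA {flat['tangential_MIA_deg']:.2f} deg, "
      f"APIA {flat['tangential_APIA_deg']:+.2f} deg, "
      f"L0 {flat['tangential_L0_mm']:.2f} mm")
print(f"safe-region pattern: {flat['region_pattern']}")
print()
print("Positive angles are anterior, negative posterior; any screw more")
print("lateral than the tangential direction would breach the obturator.")
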