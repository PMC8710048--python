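"""Generate a synthetic sorghum-like plant and render its six calibrated
silhouettes (five side views at 72-degree turntable steps plus one top
view), then print the ground-truth leaf angles the rest of the pipeline
will try to recover."""

import leafangle3d as la

model = la.generate_plant(n_leaves=5, seed=42)
rig = la.default_rig()
masks = la.render_silhouettes(model, rig)

print(f"plant seed {model.seed}: {len(model.leaves)} leaves, "
      f"stem {model.stem_polyline[-1][2]:.0f} mm tall")
for cam, mask in zip(rig, masks):
    view = "top" if cam.view_kind == "top" else f"side {cam.turntable_angle:.0f} deg"
    print(f"  {view:>12}: {int(mask.sum())} foreground px")

print("\nground truth (theta = insertion angle from the stem axis,")
print("phi = direction around the stem; leaf 1 is the lowest):")
for rec in la.ground_truth_angles(model):
    print(f"  leaf {rec.leaf_index}: theta {rec.theta:5.1f} deg  "
          f"phi {rec.phi:5.1f} deg  junction {rec.junction_height:5.1f} mm")
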