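"""Full pipeline on one synthetic plant: carve the visual hull from the
six silhouettes, check reprojection concordance, skeletonize, segment
stem and leaves, and measure each leaf's insertion angles.  The printed
comparison against the generator's ground truth shows the measurement
error of the geometry pipeline itself."""

import leafangle3d as la

model = la.generate_plant(n_leaves=5, seed=42)
rig = la.default_rig()
masks = la.render_silhouettes(model, rig)

res = la.reconstruct_and_measure(masks, rig, resolution=128, plant_id="demo")

print(f"carved {res.grid.count} voxels at 128^3 "
      f"(voxel size {res.grid.voxel_size:.1f} mm)")
print(f"reprojection concordance per view: "
      + ", ".join(f"{s:.3f}" for s in res.qc.per_view)
      + f"  (QC {'pass' if res.qc.passed else 'FAIL'} at threshold {res.qc.threshold})")
print(f"skeleton: {res.skeleton.n_nodes} nodes, "
      f"stem base confidence {res.base.confidence:.2f}")
print(f"segmented {len(res.segmentation.leaves)} leaves "
      f"+ {len(res.segmentation.stem_nodes)} stem nodes\n")

truth = la.ground_truth_angles(model)
print("leaf  theta_meas  theta_true   error   (top leaf shares the apex")
print("                                        whorl and is least reliable)")
for r in res.records:
    t = truth[r.leaf_index - 1]
    print(f"  {r.leaf_index}     {r.theta:7.1f}    {t.theta:7.1f}  "
          f"{abs(r.theta - t.theta):6.2f}")
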