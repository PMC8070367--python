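"""Geometric featurization of one phantom: occupancy grids, bony anatomy,
flattening, and truncated SVD.

Each structure becomes a 96 x 96 x 48 occupancy bitmap over the planning
image's bounding box (flattened to 442,368 {0,1} features); the CT above
1300 HU gives a bony-anatomy context volume of the same shape. Truncated
SVD compresses the sparse occupancy matrix to a handful of components.
"""

import numpy as np

from rtname import dim_reduce, synthetic, voxelize

rng = np.random.default_rng(1)
cfg = synthetic.CohortConfig(disease="prostate", other_structures_range=(4, 6), seed=1)
series, sset = synthetic.generate_phantom("prostate", "DEMO", rng, cfg)
box = voxelize.compute_bounding_box(series)
print(f"image bounding box: {box.min_corner} .. {box.max_corner} mm")

rows = []
for rec in sset.records:
    vol = voxelize.rasterize_structure(rec, box)
    vec = voxelize.flatten(vol)
    rows.append(vec)
    if rec.true_label != "other":
        print(f"  {rec.true_label:12s} occupies {int(vec.sum()):5d} / {vec.size} voxels")

bone = voxelize.extract_bony_anatomy(series, box)
print(f"bony anatomy (>1300 HU): {int(bone.bits.sum())} voxels")
print(f"structure+bone concatenation length: "
      f"{len(voxelize.concat_structure_and_bone(rows[0], voxelize.flatten(bone)))}")

X = np.vstack(rows).astype(np.float32)
k = min(6, len(rows))
model = dim_reduce.fit_truncated_svd(X, k=k, seed=1)
reduced = dim_reduce.transform(model, X)
print(f"SVD: {X.shape} -> {reduced.shape}; singular values "
      f"{np.round(model.singular_values, 1)}")
print("Each structure is now a short dense vector ready for a classifier.")
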