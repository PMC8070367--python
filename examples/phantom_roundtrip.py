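"""Generate one synthetic CT phantom, write it as DICOM, and read it back.

Shows that the writer/reader pair is lossless: physician-given structure
names survive byte-for-byte and contour coordinates round-trip within
1e-3 mm, which is what makes the DICOM layer safe to put underneath the
featurization pipeline.
"""

import tempfile
from pathlib import Path

import numpy as np

from rtname import dicom_io, synthetic

rng = np.random.default_rng(0)
cfg = synthetic.CohortConfig(disease="prostate", other_structures_range=(3, 5), seed=0)
series, sset = synthetic.generate_phantom("prostate", "DEMO", rng, cfg)
print(f"phantom: {series.voxels.shape} voxels at {series.spacing} mm, "
      f"{len(sset.records)} structures")

with tempfile.TemporaryDirectory() as tmp:
    manifest = dicom_io.write_synthetic_dicom(series, sset, tmp)
    print(f"wrote {len(manifest['ct_files'])} CT slices + {manifest['rtstruct_file']}")
    back_series = dicom_io.read_ct_series(tmp)
    back = dicom_io.read_structure_set(Path(tmp) / manifest["rtstruct_file"], back_series)

worst = 0.0
for orig, got in zip(sset.records, back.records):
    assert orig.given_name == got.given_name  # names are verbatim
    for c0, c1 in zip(orig.contours, got.contours):
        worst = max(worst, float(np.abs(c0.points - c1.points).max()))
print(f"names verbatim: yes | worst coordinate error: {worst:.2e} mm (tolerance 1e-3)")
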