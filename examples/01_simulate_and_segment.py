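"""Render a synthetic confocal stack and recover its planted lipid bodies.

Plants five Gaussian lipid bodies of known oxidised/reduced ratio in a
two-channel stack, detects them (Otsu threshold on the combined lipid
signal, 26-connected components) and compares each measured ratio and
volume with the generator's analytic expectation.
"""

import numpy as np

import symbiolipo as sl

spots = [(10.5, 10.5), (10.5, 23.3), (23.3, 10.5), (23.3, 23.3), (16.9, 16.9)]
truth = sl.ImageGroundTruth(
    bodies=[
        sl.PlantedBody(center_um=(4.0, y, x), radius_um=2.0, true_ratio=r, peak_reduced_intensity=1000.0)
        for (y, x), r in zip(spots, [0.8, 1.2, 1.6, 2.0, 2.5])
    ],
    shape=(16, 128, 128),
    voxel_size_um=(135.0 / 512.0, 135.0 / 512.0, 0.5),
)
stack = sl.generate_image(truth, seed=7)
mask = truth.cell_mask()

threshold = sl.compute_detection_threshold(stack, mask)
rois = sl.segment_lipid_bodies(stack, mask)

print(f"detected {len(rois)} of {len(truth.bodies)} planted bodies "
      f"(Otsu threshold {threshold:.0f})")
print(f"{'measured ratio':>15} {'true ratio':>11} {'volume µm³':>11} {'expected':>9}")
for roi, body in zip(
    sorted(rois, key=lambda r: r.ratio), sorted(truth.bodies, key=lambda b: b.true_ratio)
):
    volume = roi.area_um2 * stack.voxel_size.z_um
    print(f"{roi.ratio:15.3f} {body.true_ratio:11.1f} "
          f"{volume:11.2f} {body.expected_volume_um3(threshold):9.2f}")

# The ratio column is the per-body lipid-peroxidation readout: it matches the
# planted truth exactly in noise-free data because the oxidised channel is a
# fixed multiple of the reduced channel inside each body. Volumes agree with
# the analytic isophote expectation to within a few percent of discretisation.
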