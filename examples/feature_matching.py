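"""Feature detection and epipolar-verified matching between two views.

Renders two adjacent views of a synthetic wound scene, detects
scale-invariant keypoints (difference-of-Gaussians extrema with orientation
histograms and 128-D gradient descriptors), matches them with the ratio
test, and filters the matches with fundamental-matrix RANSAC. The surviving
inliers are the raw material of the 3D reconstruction.
"""
import numpy as np

from woundmap import (make_scene, match_descriptors, ransac_fundamental,
                      render_images)
from woundmap.features import detect_and_describe

scene = make_scene("cylinder", 2.0, n_cameras=20, seed=7)
views = render_images(scene, resolution=960)[:2]

ka, da = detect_and_describe(views[0])
kb, db = detect_and_describe(views[1])
print(f"keypoints: {len(ka)} / {len(kb)} in the two views")

matches = match_descriptors(da, db, ratio=0.8,
                            image_a=views[0].id, image_b=views[1].id)
F, verified = ransac_fundamental(matches, ka, kb, seed=7)
n_in = int(verified.inlier_mask.sum())
print(f"putative matches: {len(matches.pairs)}; epipolar inliers: {n_in}")

xa = np.array([[ka[i].x, ka[i].y] for i, _, _ in verified.inlier_pairs()])
xb = np.array([[kb[j].x, kb[j].y] for _, j, _ in verified.inlier_pairs()])
res = np.abs(F.epipolar_residual(xa, xb))
print(f"median epipolar residual of inliers: {np.median(res):.2e} "
      "(each inlier satisfies x'^T F x ~ 0)")
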