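"""Mask volumetrics and inter-reader Dice agreement on synthetic contours.

Digitizes a 10 mm-radius sphere (analytic volume 4188.79 mm^3), then
emulates independent reviewers by perturbing the contour boundary until the
pairwise Dice score drops to the study's inter-user level (~0.875), and
reports average agreement and variability (1 - mean Dice).
"""

import math

from gliotrack import agreement_report, dice, make_ellipsoid_mask, mask_volume, perturb_mask_to_dice

sphere = make_ellipsoid_mask((10, 10, 10), (1, 1, 1), frame_id="gold")
analytic = 4 / 3 * math.pi * 10**3
vol = mask_volume(sphere)
print(f"digitized sphere volume: {vol:.0f} mm^3 "
      f"(analytic {analytic:.0f}, error {100 * abs(vol - analytic) / analytic:.2f}%)")

groups = []
for k in range(5):
    reviewer = perturb_mask_to_dice(sphere, target=0.875, tolerance=0.02, seed=k)
    print(f"reviewer {k}: Dice vs gold = {dice(sphere, reviewer):.3f}, "
          f"volume {mask_volume(reviewer):.0f} mm^3")
    groups.append([sphere, reviewer])

report = agreement_report(groups, percent=True)
print(f"mean inter-reader Dice: {report.mean_score:.1f}%  "
      f"-> variability {report.variability:.1f}%")
# Boundary flips are balanced (adds ~ removes), so reviewer volumes stay
# close to the gold standard even at Dice ~0.875 — volume is much more
# stable than voxel-wise overlap, which is why longitudinal volumetry works.
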