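"""Extract per-region facial temperature from a registered thermal frame.

Builds a synthetic face scene with the published pre-stimulus right-cheek
count level, refines the nostrils, lays out the five measurement regions and
averages raw 14-bit thermal counts per region.
"""

from fearsense import define_rois, detect_nostrils, session_ft
from fearsense.synthetic import default_face_features, gen_face_scene

features = default_face_features()
levels = {
    "middle_forehead": 15101.48,
    "left_eye": 15119.34,
    "right_eye": 15112.23,
    "left_cheek": 15105.64,
    "right_cheek": 15116.71,  # published pre-stimulus right-cheek mean
}
visible, thermal, truth = gen_face_scene(
    features, roi_levels=levels, noise_sd=5.0, seed=2
)

nostrils, nose_center = detect_nostrils(visible, features.nose_box)
print(f"nostrils at x = {nostrils[0].x:.1f}, {nostrils[1].x:.1f}; "
      f"nose centre ({nose_center.x:.1f}, {nose_center.y:.1f})")

rois = define_rois(features)
result = session_ft([thermal], rois)
print("session mean raw counts per region:")
for name, mean in result.per_roi_mean.items():
    print(f"  {name:16s} {mean:9.2f}  (commanded {levels[name]:.2f})")
print(f"  all regions      {result.all_regions_mean:9.2f}")
print("(counts are the 14-bit sensor scale; a fear response lowers them by")
print(" tens of counts, e.g. the published right-cheek drop of ~79)")
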