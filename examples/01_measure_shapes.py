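"""Measure seed and pod shape descriptors from synthetic images.

Renders a dark elliptical seed and a curved pod on a light background,
binarizes each with the protocol's threshold methods (maximum entropy for
seeds, Huang for pods), extracts the object and prints the twelve
calibrated shape descriptors.
"""

from phenoprop import morphometry as mm
from phenoprop.synthetic_data import generate_pod_image, generate_seed_image

SCALE = 50.0  # pixels per cm

seed_img, seed_meta = generate_seed_image(axes_px=(120, 70), noise_sd=4.0, seed=1)
pod_img, pod_meta = generate_pod_image(220, 40, curvature=0.004, noise_sd=4.0, seed=2)

for name, img, method in [("seed", seed_img, "max_entropy"), ("pod", pod_img, "huang")]:
    records = mm.measure_image(img, scale=SCALE, method=method, min_area_px=50)
    print(mm.records_to_frame(records, image_id=name).round(3).to_string(index=False))

print(
    "\nThe seed was rendered with a 120x70 px ellipse (true AR about 1.71)\n"
    "and the pod with curvature 0.004/px, which lowers its solidity below 1:\n"
    "curved pods occupy less of their convex hull than straight ones."
)
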