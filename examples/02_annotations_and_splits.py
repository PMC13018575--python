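"""From a lumen mask to a padded YOLO-style training label, plus data splits.

The tight bounding box of the mask is padded by 10% of its extent per side
(so the full contour sits inside), clipped to the image, then converted to
normalized center/size fractions - the one-line-per-box text format object
detectors train on.
"""

import carotidseg as cs

img, mask = cs.make_phantom(cs.default_transverse_spec(seed=0))
h, w = mask.shape

box = cs.mask_to_padded_box(mask, pad_frac=0.1)
nbox = cs.pixel_to_normalized(box, w, h)
print(f"padded box: left={box.left} top={box.top} "
      f"width={box.width} height={box.height}")
print(f"label line: {nbox.class_id} {nbox.xc:.6f} {nbox.yc:.6f} "
      f"{nbox.w:.6f} {nbox.h:.6f}")

cs.write_labels([nbox], "/tmp/example_label.txt")
back = cs.read_labels("/tmp/example_label.txt")[0]
print("round trip (up to 6-decimal formatting):",
      max(abs(back.xc - nbox.xc), abs(back.yc - nbox.yc),
          abs(back.w - nbox.w), abs(back.h - nbox.h)) < 1e-6)

# Holdout + 5-fold split arithmetic for the two published dataset sizes:
for n in (1100, 84):
    split = cs.partition_dataset(n, holdout_frac=0.1, k=5, seed=0)
    print(f"n={n}: development {len(split.development)}, "
          f"holdout {len(split.holdout)}, "
          f"fold sizes {[len(f) for f in split.folds]}")
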