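"""Region vocabularies and the anatomical landmark table.

Prints the CT (17-class) and MRI (18-class) output vocabularies and the
cranio-caudal landmark pair delimiting a few regions.
"""

from bodyregion import build_vocabulary, landmark_table

for modality in ("CT", "MRI"):
    vocab = build_vocabulary(modality)
    print(f"{modality}: {len(vocab.output_classes)} output classes, "
          f"{len(vocab.internal_classes)} internal (incl. transitional abdomen_chest)")

print("\nLandmark intervals (top -> bottom along the patient z axis):")
for iv in landmark_table():
    if iv.region in ("knee", "abdomen", "spine_lumbar"):
        print(f"  {iv.region:14s} {iv.top_landmark!r} -> {iv.bottom_landmark!r}")

# The landmark pair is what an annotator aligns the thin 3D bounding box to;
# every slice whose centre falls between the two landmarks gets that label.
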