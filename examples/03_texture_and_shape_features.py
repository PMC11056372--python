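"""Extract the 26-value feature vector (20 GLCM texture statistics + ABCD
shape/colour descriptors) for one benign and one malignant lesion.

Prints the descriptors most relevant to the clinical ABCD signs: asymmetry,
border irregularity, colour variance, diameter, area and roundness, plus two
texture statistics that separate noisy malignant texture from smooth nevi.
"""

from dermoscan import extract_feature_vector, generate_dataset, preprocess_pipeline

samples = generate_dataset(1, 1, seed=12)
vectors = {}
for s in samples:
    gray = preprocess_pipeline(s.image)
    vectors[s.spec.label] = extract_feature_vector(s.image, gray, s.truth_mask)

show = [
    "asymmetry_index", "border_irregularity", "color_variance",
    "diameter", "area", "roundness", "contrast", "entropy",
]
print(f"{'feature':24s} {'benign':>10s} {'malignant':>10s}")
for name in show:
    print(f"{name:24s} {vectors['benign'][name]:10.3f} {vectors['malignant'][name]:10.3f}")
# asymmetry_index is the percent of lesion area unmatched when folded across
# its principal axes; border_irregularity is 1 for a circle; GLCM contrast and
# entropy rise with the speckled internal texture of the malignant class.
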