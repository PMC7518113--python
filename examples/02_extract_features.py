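"""Extract the 80 per-lesion radiomic features from images and contours.

Each lesion yields 72 spatial features (9 first-order statistics, 60 GLCM
texture statistics at offsets 1..15, and the binary-texture trio AR/CDD/DD)
plus 8 morphological features in physical units.
"""

from gbradiomics import CohortConfig, extract_feature_table, generate_cohort

cohort = generate_cohort(CohortConfig(n0=5, n1=5, seed=2))
table = extract_feature_table(cohort)

print(f"feature table: {table.shape[0]} lesions x {table.shape[1] - 2} features")
cols = ["label", "IMean", "Cont14", "Homo13", "DD", "Maj.Len", "Eq.Dia", "Sol"]
print(table[cols].round(3).to_string())
# Cont14/DD capture the uneven, centrally clustered bright echoes of
# cholesterol polyps; Maj.Len and Eq.Dia are the lesion's physical size in cm
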