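"""Generate a synthetic two-class gallbladder-polyp cohort and write it to disk.

Builds the default cohort — 58 cholesterol polyps (class 0) and 41 tubular
adenomas (class 1) at 0.02 cm/px — and saves one 8-bit PNG plus one contour
JSON per lesion together with a manifest CSV.
"""

from gbradiomics import CohortConfig, generate_cohort, write_cohort

config = CohortConfig(seed=1)
cohort = generate_cohort(config)
manifest = write_cohort(cohort, "scratch/example_cohort")

n0 = sum(lesion.label == 0 for lesion in cohort)
print(f"generated {len(cohort)} lesions ({n0} cholesterol polyps, {len(cohort) - n0} adenomas)")
print(f"manifest: {manifest}")
example = cohort[0]
print(
    f"first lesion: id={example.contour.lesion_id}, "
    f"sampled major axis {example.true_params['maj_len_cm']:.2f} cm, "
    f"{example.true_params['n_foci']} hyperechoic foci"
)
# class-0 lesions carry punctate bright foci (the cholesterol-crystal proxy);
# class-1 lesions are larger, more irregular, and texturally homogeneous
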