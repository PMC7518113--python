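"""Two-stage feature selection, replayed on the published clinical table.

Stage 1 keeps significant features and collapses each GLCM type to its
best-Fv representative; stage 2 keeps, per family, features at or above the
family medians of both Fv (Fisher inter-intraclass variance ratio) and F
(pooled z-score separation).  Replaying stage 2 on the summary table of the
original 99-lesion clinical cohort reproduces its published thresholds and
final 8-feature set.
"""

from gbradiomics import family_medians, second_stage_select
from gbradiomics.reference import reference_stage1_records

records = reference_stage1_records()
fv_sp, f_sp = family_medians(records, "spatial")
fv_mo, f_mo = family_medians(records, "morphological")
print(f"spatial family thresholds:       Fv >= {fv_sp:.3f}, F >= {f_sp:.3f}")
print(f"morphological family thresholds: Fv >= {fv_mo:.3f}, F >= {f_mo:.3f}")

kept = second_stage_select(records)
print(f"retained {len(kept)} features:")
for r in kept:
    print(f"  {r.feature:8s} ({r.family}): Fv={r.Fv:.3f}, F={r.F:.3f}")
# the retained set is the published one: Cont14, Ener8, Homo13, Entr6, DD
# (spatial) and Maj.Len, Eq.Dia, Per (morphological)
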