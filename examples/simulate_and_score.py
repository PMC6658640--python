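"""Simulate a small synthetic cohort, measure uptake and assign scores.

Each synthetic study contains a liver, a thoracic-aorta blood pool and
one focal lesion, rendered under the three reconstruction settings
(earl_lower 7 mm, earl_upper 5 mm, qclear 4 mm effective FWHM). SUVmax-
based Deauville scores are printed per setting; watch how borderline
lesions drop a score under the smoother EARL settings.
"""

from petharmony import CohortConfig, generate_cohort
from petharmony.deauville import classify_response, score_study
from petharmony.suv import measure_study

cohort = generate_cohort(CohortConfig(n_studies=6, seed=7))
print("study      true lesion SUV  DS(qclear)  DS(earl_upper)  DS(earl_lower)")
for study in cohort:
    meas = measure_study(study.volumes, study.masks, study.meta)
    scores = score_study(meas, metric="suv_max")
    row = [scores[p].score for p in ("qclear", "earl_upper", "earl_lower")]
    print(
        f"{study.study_id}      {study.true_uptakes['lesion_1']:5.2f}"
        f"        {row[0]}            {row[1]}               {row[2]}"
        + ("   <- discordant" if len(set(row)) > 1 else "")
    )
print(
    "\nScores of 4-5 mean non-responder (lesion hotter than liver);"
    "\ndiscordant studies are typically downscaled by the EARL settings."
)
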