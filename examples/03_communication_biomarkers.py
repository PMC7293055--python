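"""Compute call and text biomarkers from one participant's event log.

Text features are distribution summaries of inter-message gaps (overall
and per direction) plus the across-contact variability of those gap
features; call features are counts, the missed and phone-idle shares,
and inter-call gap summaries.
"""

from phenomarker import CohortConfig, generate_cohort
from phenomarker.comm import call_biomarkers, text_biomarkers

cohort = generate_cohort(CohortConfig(n_participants=5, accel_days_cap=0.01,
                                      seed=11))
rec = max(cohort, key=lambda r: len(r.texts))

tb = text_biomarkers(rec.texts)
print(f"{rec.participant_id} (SIAS {rec.sias}):")
print(f"  texts: {tb.total_texts}, median gap {tb.gaps_all[1] / 3600:.2f} h, "
      f"outgoing median gap {tb.gaps_outgoing[1] / 3600:.2f} h")
print(f"  across-contact SD of per-contact mean gap: "
      f"{tb.contact_variability[0] / 3600:.2f} h")

cb = call_biomarkers(rec.calls)
print(f"  calls: {cb.total_calls}, missed {cb.pct_missed:.0%}, "
      f"during idle {cb.pct_idle:.0%}, distinct contacts {cb.n_contacts}")
# Higher-severity participants tend to reply later (longer outgoing gaps)
# and miss more calls, per the generator's planted slopes.
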