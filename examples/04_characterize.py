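"""Characterize a cohort: demographics, windowed concurrent diagnoses,
drug classes, the EKG any-code query, and inpatient length of stay.

Concurrent conditions use the closed window (-1, +1) days around the
index date; treatments and procedures use (-1, +14).
"""

from amiclaims import (
    CONDITION_WINDOW,
    TREATMENT_WINDOW,
    build_cohort,
    demographics,
    drug_class_table,
    load_ami_codelist,
    los_summary,
    multi_code_any,
    windowed_items,
)
from amiclaims.cohort import QueryPeriod
from amiclaims.resources import EKG_CODE_SET, load_drug_classes
from amiclaims.simulate import GeneratorConfig, generate

bundle = generate(GeneratorConfig(n_persons=20_000), seed=7)
codelist = load_ami_codelist()
period = QueryPeriod.years(2014, 2017)
cohort = build_cohort(bundle, codelist, period, "any_healthcare")
inpatient = build_cohort(bundle, codelist, period, "inpatient")

d = demographics(cohort)
print(f"cohort n={d.size}, mean age {d.mean_age:.1f} (SD {d.sd_age:.1f}), "
      f"male {d.male_pct}%, 65+ {d.bin_pcts['65+']}%")

top = windowed_items(cohort, bundle.diagnoses, CONDITION_WINDOW, top_n=5)
print("\ntop concurrent diagnosis codes (window -1..+1 days):")
print(top.table.to_string(index=False))

print("\ncardiac drug classes (window -1..+14 days, top-100 products):")
print(drug_class_table(cohort, bundle.drugs, TREATMENT_WINDOW, load_drug_classes())
      .to_string(index=False))

n_ekg, pct_ekg = multi_code_any(cohort, bundle.procedures, TREATMENT_WINDOW, set(EKG_CODE_SET))
print(f"\nany EKG code in window: {n_ekg} persons ({pct_ekg}%)")

los = los_summary(inpatient, bundle.admissions)
print(f"inpatient LOS: mean {los.mean:.1f} (SD {los.sd:.1f}), median {los.median:.0f} "
      f"(IQR {los.iqr[0]:.0f}-{los.iqr[1]:.0f}), bands "
      + ", ".join(f"{k}: {v:.1%}" for k, v in los.band_props.items()))
# Percentages exceed 100% summed because items are not mutually
# exclusive; LOS bands reflect the configured 69.9/17.8/5.4/6.9 split.
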