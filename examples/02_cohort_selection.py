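"""Condition-string rules and the three cohort gates.

A study enters the analysis cohort when head-and-neck cancer is its unique
investigated condition, it was not withdrawn/terminated, and it is open to
all sexes.
"""

from hncmeta import (
    SynthParams,
    generate_registry,
    hnc_condition_index,
    is_hnc_condition,
    select_cohort,
)

for name in ["cancer of the larynx", "breast cancer", "laryngeal cancer",
             "Head and Neck Neoplasms", "hypertension"]:
    print(f"{name!r:40s} HNC condition: {is_hnc_condition(name)}")
# "laryngeal cancer" is False: the region string list carries "larynx" in
# full, and substring matching is literal — the MeSH terms usually rescue
# such studies.

print("\nindex of ['cancer of the larynx', 'breast cancer']:",
      hnc_condition_index(["cancer of the larynx", "breast cancer"]))

bundle, _ = generate_registry(SynthParams(n_studies=1000, seed=2))
report = select_cohort(bundle)
print(f"\nscreened {report.n_screened} studies")
print(f"  HNC as unique condition : {report.n_hnc_unique}")
print(f"  - withdrawn/terminated  : {report.n_excluded_status}")
print(f"  - single-sex            : {report.n_excluded_single_sex}")
print(f"  = included cohort       : {report.n_included}")
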