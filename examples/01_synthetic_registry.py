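"""Generate a seeded synthetic registry and inspect its planted truth.

The generator emits AACT-shaped tables with known per-study labels, so the
whole pipeline can be exercised without downloading a registry snapshot.
"""

from hncmeta import SynthParams, generate_registry

bundle, truth = generate_registry(SynthParams(n_studies=500, seed=1))

record = next(iter(bundle))
print("example study:", record.nct_id)
print("  title:      ", record.brief_title)
print("  conditions: ", record.conditions)
print("  status:     ", record.overall_status, "| type:", record.study_type)

print("\nplanted S/G categories (all 500 studies):")
print(truth["sg_category"].value_counts().to_string())
print("\nplanted HPV mention rate:", round(truth["hpv_mention"].mean(), 3))
# The category counts approximate a realistic cohort: ~5% treat sex/gender
# as an analytical variable, ~55-60% mention it only in eligibility text.
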