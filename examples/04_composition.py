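"""Structural composition analytics on a scored synthetic screen.

Element presence summary, a fluorine atom-count histogram, and the
association between chlorine content and the airborne-persistence score.
"""

from exposcreen import (
    SyntheticConfig,
    atom_count_histogram,
    element_score_association,
    generate_reference_fixture,
    generate_screening_set,
    presence_summary,
    run_pipeline,
)

reference, _ = generate_reference_fixture(n=148, seed=42)
records = generate_screening_set(SyntheticConfig(n_chemicals=1000), seed=7)
result = run_pipeline(records, reference)

summary = presence_summary(result.scored)
print("element presence (percent of structures containing >= 1 atom):")
print(summary.to_string(index=False))
mw = summary.attrs["mw"]
print(f"molecular weight: median {mw['median']:.0f}, mean {mw['mean']:.0f} g/mol")
print()

print("fluorine atom-count histogram (containing structures only):")
print(atom_count_histogram(result.scored, "F"))
print()

assoc = element_score_association(
    result.scored, result.scored["s_apc"], "Cl", n_bins=10
)
print("mean Cl atoms per structure by S_APC score bin:")
print(assoc.to_string(index=False))
print()
print("The association profile shows how halogenation tracks with the")
print("airborne-persistence percentile score across the screened set.")
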