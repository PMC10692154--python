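"""Symmetry-label consistency across members of a composition.

Members of the same unique composition should normally agree on their point
group; a disagreement (here a histidine-kinase dimer annotated C2 in one
entry and asymmetric in two others) flags a curation or detection issue.
"""

from complexkit import reference_examples
from complexkit.identity import IdentifierRegistry, eligibility, group_unique, mark_preferred
from complexkit.symmetry import consistency_by_composition, symmetry_frequency

bundle = reference_examples()
preferred = mark_preferred(bundle.assemblies)
eligible = [a for a in preferred if eligibility(a)[0]]
uniques = group_unique(eligible, IdentifierRegistry())

freq = symmetry_frequency(eligible)
print("label histogram:", freq["histogram"])
print(f"cyclic fraction among symmetric assemblies: {freq['cyclic_fraction']:.2f}")
print()
report = consistency_by_composition(uniques, bundle.assemblies)
for comp in report.compositions:
    flag = "consistent" if comp.is_consistent else "INCONSISTENT"
    print(f"{comp.md5[:10]}… members={comp.histogram} -> {flag}")
print()
print(f"{report.n_inconsistent}/{report.n_assessed} multi-member compositions disagree "
      f"({report.fraction_inconsistent:.1%}).")
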