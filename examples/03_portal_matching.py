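"""Matching compositions against a Complex Portal catalogue.

An exact match takes the portal's recommended name outright; a composition
with one extra component becomes an extended match; and a composition
covering two disjoint portal definitions maps to both accessions.
"""

from complexkit import reference_examples
from complexkit.identity import IdentifierRegistry, eligibility, group_unique, mark_preferred
from complexkit.portal import match_unique

bundle = reference_examples()
preferred = mark_preferred(bundle.assemblies)
eligible = [a for a in preferred if eligibility(a)[0]]
uniques = group_unique(eligible, IdentifierRegistry())

for u in uniques:
    match = match_unique(u, bundle.portal)
    if match is None:
        continue
    entries = ",".join(e for e, _ in u.members)
    extras = ", ".join(f"{l} ({c})" for l, c in match.extra_components) or "-"
    print(f"{entries}: kind={match.kind}  portal={'|'.join(match.complex_acs)}  extras={extras}")
print()
print("The nucleosome entry maps to two portal accessions at once because its")
print("mapped components exactly cover two disjoint curated complexes.")
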