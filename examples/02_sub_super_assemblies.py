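"""Sub-assembly / super-assembly detection.

Haemoglobin (2x alpha + 2x beta) is a strict sub-assembly of the
haemoglobin-IsdB receptor complex, which adds two receptor copies.
"""

from complexkit import AssemblyInstance, IdentifierRegistry, PolymerComponent
from complexkit.identity import group_unique
from complexkit.relations import build_relation_graph, is_subassembly


def assembly(entry, spec):
    comps = [
        PolymerComponent(entry, i + 1, "protein", n, uniprot_accessions=(acc,))
        for i, (acc, n) in enumerate(spec.items())
    ]
    return AssemblyInstance(entry, 1, comps)


hb = assembly("7jy3", {"P69905": 2, "P68871": 2})
isdb = assembly("7pch", {"P69905": 2, "P68871": 2, "Q8NX66": 2})
lysozyme = assembly("6kd1", {"P00698": 1})

uniques = group_unique([hb, isdb, lysozyme], IdentifierRegistry())
by_entry = {u.members[0][0]: u for u in uniques}

print("haemoglobin ⊂ haemoglobin-IsdB:",
      is_subassembly(by_entry["7jy3"], by_entry["7pch"]))
print("lysozyme ⊂ haemoglobin-IsdB:  ",
      is_subassembly(by_entry["6kd1"], by_entry["7pch"]))

graph = build_relation_graph(uniques, mode="strict")
for sub, sup, data in graph.edges(data=True):
    print(f"edge: {sub[:10]}… -> {sup[:10]}…  added={data['added_components']}")
print()
print("Strict mode requires shared components to keep equal stoichiometry;")
print("the edge direction points from the contained composition outward.")
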