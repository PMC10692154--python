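# complexkit

Canonical composition identity, persistent accessions, Complex Portal
mapping, and automated human-readable naming for macromolecular assemblies.

## The problem

A structural archive such as the PDB stores many independently deposited
structures of the same biological assembly: adult haemoglobin, for example,
appears in hundreds of entries, each describing "two alpha chains and two
beta chains" in its own words. Without a standard notion of *which assembly
this is*, the same complex cannot be found, counted, or compared across
entries. `complexkit` implements an archive-scale pipeline that:

1. reduces every assembly to a **canonical composition** — each polymer
   component labelled by its external reference and copy number,

   | component          | label                                  |
   |--------------------|----------------------------------------|
   | protein (UniProt)  | `P68871_1`                             |
   | RNA (Rfam)         | `RF00177_1`                            |
   | antibody           | `antibody_<entry>_<entity>_<stoich>`   |
   | protein (unmapped) | `protein_<entry>_<entity>_<stoich>`    |
   | RNA (unmapped)     | `RNA_<entry>_<entity>_<stoich>`        |
   | DNA                | `DNA_<entry>_<entity>_<stoich>`        |
   | DNA/RNA hybrid     | `DNA/RNA_<entry>_<entity>_<stoich>`    |

   ordered canonically, joined by commas and content-addressed with an md5
   digest, so the digest depends only on the component multiset;
2. mints one persistent `PDB-CPX-<serial>` accession per digest in an
   append-only registry — once assigned, never changed;
3. selects each entry's **preferred assembly** (the smallest assembly
   containing all of the entry's polymeric entities);
4. detects **sub-/super-assembly** relations (one composition's component
   set a strict subset of another's, with equal — or optionally bounded —
   stoichiometry on shared components);
5. matches compositions against the **Complex Portal** exactly, with extra
   components, or as combinations of several disjoint portal complexes;
6. assigns a **human-readable name** by a decision tree: curated names,
   portal names, ribosome detection and naming (rRNA Rfam families plus a
   ribosomal-protein fallback), shared GO cellular-component terms, UniProt
   recommended names for single-protein assemblies (with generic labels for
   extras), antibody/entity names for unmapped proteins, Rfam family names,
   and generic nucleic-acid names;
7. reports **point-group symmetry consistency** across the members of each
   unique composition (disagreements flag curation problems).

Chimeric entities (one chain mapping to several UniProt accessions) exclude
an assembly from identification. Identity is implicitly species-scoped:
UniProt accessions are species-specific and unmapped labels embed the entry,
so homologous assemblies from different organisms never merge.

A first-class synthetic-archive generator (`complexkit.synth`) produces
seeded snapshots with machine-readable ground truth for every stage, so the
entire pipeline is testable without network access, alongside a fixed
replica bundle of well-documented archive cases.

## Worked example

```python
from complexkit import AssemblyInstance, IdentifierRegistry, PolymerComponent
from complexkit.identity import canonical_key, group_unique

def hb(entry):
    return AssemblyInstance(entry, 1, [
        PolymerComponent(entry, 1, "protein", 2, uniprot_accessions=("P69905",)),
        PolymerComponent(entry, 2, "protein", 2, uniprot_accessions=("P68871",)),
    ])

key = canonical_key(hb("6kat"))
print(key.composition_string)   # P68871_2,P69905_2
print(key.md5_hex[:12])         # 015ef1985e73

uniques = group_unique([hb("6kat"), hb("7jy3")], IdentifierRegistry())
print(uniques[0].accession, uniques[0].members)
# PDB-CPX-100001 [('6kat', 1), ('7jy3', 1)]
```

Both entries share one composition string, hence one digest and one
accession. The `examples/` directory holds one narrative script per
capability (identity, relations, portal matching, naming, symmetry, the full
pipeline); each prints what it computes and what the numbers mean. For
instance, `examples/06_full_pipeline.py` generates a 107-assembly synthetic
archive and prints:

```
assemblies in snapshot: 107
unique compositions:    71
named fraction:         0.944
portal matches:         10 (exact 5)
sub-assembly fraction:  0.042
symmetry inconsistent:  5/26
```

## Command line

A thin CLI wraps the library: `complexkit run --config run.yaml` executes
the whole release-style pipeline (snapshot → unique_assemblies.tsv,
relations.tsv, portal_mapping.tsv, names.tsv, symmetry_report.tsv,
stats.json, with the registry updated append-only), and per-stage
subcommands (`identify`, `relate`, `portal-map`, `name`, `symmetry`,
`fixtures`) run the stages individually. Exit codes: 0 success, 1 input
validation failure, 2 registry integrity/locking failure.

## File formats

Snapshots are one TSV row per (entry, assembly, entity) with columns
`entry_id assembly_id entity_id polymer_type uniprot rfam is_antibody
entity_name uniprot_name go_cc taxonomy_id copies symmetry` and an optional
trailing `seq_length`; a structurally equivalent hierarchical JSON form is
also read. Portal catalogues are TSV with pipe-separated
`ACCESSION(stoichiometry)` participant tokens (the public complextab dialect
is accepted). Curated names are two-column TSV (md5, name). The registry is
an append-only two-column TSV plus a JSON sidecar carrying the next serial.

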