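# Methods

## Canonical composition identity

An assembly is a multiset of polymer components with copy numbers. Each
component is labelled by the strongest external reference available:
UniProt accession for proteins, Rfam family for RNA, an `antibody_` label
for ANARCI-style antibody annotations without a UniProt mapping, and
type/entry/entity labels for everything unmapped. Labels carry the
stoichiometry as a trailing `_<copies>` field.

Three normalisation rules make the digest a pure function of the component
multiset:

* **Merging.** Components mapping to the same accession across several
  deposition entities are merged with summed stoichiometry before
  labelling — identity should reflect the molecule, not entity bookkeeping.
* **Ordering.** Labels sort mapped-first, lexicographically within each
  class. Some total order is mandatory for hash stability; mapped-first
  matches the convention of writing recognisable accessions before
  entry-specific placeholders.
* **Separator.** Labels are joined with a bare comma, no whitespace, before
  hashing; whitespace-sensitive digests are fragile across serialisations.

The md5 of the composition string is the content address. A collision would
require two distinct composition strings with equal md5 — negligible at
archive scale and irrelevant to adversarial concerns here.

Unmapped labels embed the entry and entity id, so compositions containing
unmapped components are never shared between entries. This is deliberate:
without an external reference there is no evidence that two unmapped chains
are the same molecule. A consequence worth knowing: unique groups containing
unmapped components always have exactly one member.

## Persistent accessions

The registry maps md5 → `PDB-CPX-<serial>`, append-only: an assignment is
never changed or removed, serials strictly increase, and duplicate md5s or
accessions on load raise an integrity error. Serials start at 100001 with no
zero-padding (configurable). Within a run, *new* compositions are assigned
in sorted composition-string order rather than input order, so two runs over
row-shuffled copies of the same snapshot produce byte-identical registries.
The trade-off is that serial allocation depends on which snapshots were seen
in which order across runs — the persistence contract (an md5 keeps its
accession forever) is what the design guarantees, not schedule-independent
serial numbering. A lock file enforces a single writer per registry;
concurrent runs fail fast instead of merging.

## Preferred assemblies

One entry may declare several candidate quaternary structures. The preferred
assembly is the smallest (fewest total polymer chains) among those
containing every polymeric entity of the entry at least once, ties broken by
lowest assembly id. If no assembly is complete, the one covering the most
entities wins under the same tie-breaks. Only preferred, non-chimeric
assemblies enter unique-assembly identification.

## Sub- and super-assemblies

Composition *a* is a sub-assembly of *b* when *a*'s component-identity set
is a strict subset of *b*'s. Whether stoichiometry participates in the
subset test is genuinely open; both documented examples (haemoglobin inside
the haemoglobin-IsdB receptor complex; the bare versus factor-bound
ribosome) preserve shared stoichiometry, so the default **strict** mode
requires equal copy numbers on shared components, and a **relaxed** mode
(shared copies of *a* ≤ those of *b*) is available as a flag. Components
compare by canonical identity, so unmapped components only ever match
themselves. All direct pairwise relations are stored; a transitive-reduction
view is derived on demand.

## Complex Portal matching

Matching uses only UniProt-mapped protein components. An **exact** match
requires the accession-with-stoichiometry multiset to equal a portal
complex's participants with nothing else present (ties broken to the lowest
portal accession). Otherwise a greedy largest-coverage-first sweep consumes
portal complexes whose participants are sub-multisets of the remaining
mapped components: one consumed complex plus leftovers is an
`exact_plus_extras` match, two or more (their coverage is disjoint by
construction) is a `multi_portal` match. Greedy cover is sufficient for the
documented cases and cheap; full set-cover optimisation is a known
non-feature. Leftovers are categorised as protein / DNA / RNA / antibody /
peptide / unmapped; "peptide" means a protein shorter than 20 residues when
the snapshot carries a sequence length, otherwise the component stays
"protein". Shared-participant stoichiometry must match exactly by default;
a relaxation flag accepts portal stoichiometry ≤ assembly stoichiometry.
Portal entries with non-UniProt participants (small molecules, RNA) are
matched on their UniProt subset and flagged `partial_definition`.

## Naming decision tree

Rules apply in fixed precedence: curated name (keyed by md5) → portal exact
→ portal extended/multi → ribosome → shared GO CC term → single-UniProt
rules → antibody/entity names → Rfam family names → generic nucleic names →
unnamed. Curated names outrank automation because the curated list exists to
correct it; GO sits below portal and ribosome naming because a shared
compartment-like term is weaker evidence than an exact curated composition.
Both choices are configuration, not hard-coded behaviour.

Details that matter:

* **Ribosomes.** Primary route: ≥1 rRNA component mapped to a configured
  rRNA Rfam family *and* ≥1 ribosomal protein (case-insensitive name
  patterns, default "ribosomal protein"/"ribosome"). Fallback route, only
  when no rRNA mapping exists at all: ≥1 unmapped RNA plus ≥1 ribosomal
  protein; the unmapped RNA is then presumed to be the rRNA and does not
  count as extra bound RNA. Subunits come from the family → SSU/LSU map
  (5S and 5.8S count as LSU); in the fallback they are inferred from
  30S/50S-style protein names, defaulting to both. Names follow the
  subunit content — "30 S ribosomal subunit", "50 S ribosomal subunit",
  "70 S ribosome" (40 S/60 S/80 S for eukaryote-style taxa, default
  prokaryotic when taxonomy is absent) — appending " and tRNA" when a
  component maps to the tRNA families RF00005/RF01852 and " and RNA" when
  other RNA is bound.
* **GO naming.** Only allow-listed complex-describing CC terms are eligible
  (never compartments like "cytoplasm"); the term must be present on every
  component; among several qualifying terms the most specific wins — fewest
  annotated components archive-wide, then alphabetical.
* **Single-UniProt rules.** All components one accession → the UniProt
  recommended name, regardless of stoichiometry. One accession plus generic
  extras → comma-joined protein name and extra labels with a trailing
  "complex" ("Interleukin-17A, IG-heavy chain, IG-light lambda chain,
  peptide complex"). Portal-extended and ribosome names join with " and "
  instead — the two joining styles mirror the two naming conventions the
  archive uses.
* **Unmapped protein assemblies.** Antibody present → entity names joined
  with " and ", category `antibody`. Otherwise entity names; a single
  shared name across several entities is categorised `entity_common_name`,
  a single-entity or multi-name assembly `unmapped_protein`.
* **Nucleic assemblies.** All components Rfam-mapped → family names from a
  shipped table (overridable). Otherwise generic "DNA" / "RNA" / "DNA/RNA
  hybrid"; multi-component all-nucleic assemblies get the same generic
  names (flagged choice — the convention is only explicit for
  single-component assemblies).

Unnamed is a valid outcome; mixed mapped/unmapped heteromers typically land
there.

## Symmetry consistency

Point-group detection is an upstream input, not recomputed. Labels are
normalised to uppercase Schoenflies strings with "asymmetric" ≡ "C1";
missing labels are excluded rather than presumed asymmetric. Frequency
tables report per-label counts and cyclic/dihedral fractions over symmetric
(non-C1) labels. Consistency is assessed per unique composition with ≥2
labelled members: consistent iff all labels agree. Because "compositions" and
"member assemblies" are both defensible denominators, the report exposes
both countings.

## Synthetic archive generator

`FixtureConfig` fixes archetype counts, a symmetry-noise rate and a seed;
one seeded PRNG drives all draws and the same seed reproduces identical
bytes. The defaults produce 71 unique compositions over ~110 assemblies
covering every naming category, planted portal matches of all three kinds,
curated sub/super pairs and chimeric excludes; by construction ≈94 % of
unique compositions are namable, and each multi-member fully mapped group
has a 6 % chance of carrying one perturbed symmetry label (≈6 % inconsistent
groups in expectation, mirroring an archive-scale inconsistency rate).
Synthetic accessions use reserved namespaces (`UPnnnnn`, `CPX-9nnnnn`).

What the generator emulates: composition archetypes, external mappings,
stoichiometry, portal definitions, curated overrides, symmetry labels,
multi-assembly entries (to exercise preferred-assembly selection). What it
does not: sequences, coordinates, experimental metadata, the long-tailed
size distribution of real archives, partially wrong external mappings, or
real accession semantics. Passing tests on synthetic archives therefore
demonstrate the pipeline's logic and determinism, not the coverage numbers
one would obtain on a real archive; the replica bundle
(`reference_examples()`) covers fidelity to real, documented cases.

## Numerical and procedural choices

* Problem sizes: tests use archives of ~70–80 unique compositions and a
  1000-assembly sample for hash-invariance properties — large enough to
  exercise every branch while keeping the full suite in a few seconds.
* Determinism: every output table has a total sort order; stats JSON is
  key-sorted; writes are temp-file-then-rename so failures never leave
  partial outputs.
* Degenerate inputs: empty snapshots yield empty outputs and exit 0;
  validation failures abort before any registry mutation; an unparseable
  symmetry label is counted as "other" with a warning rather than dropped.

## Known limitations

* Greedy multi-portal cover can miss an optimal decomposition when portal
  definitions overlap heavily.
* Ribosomal-protein recognition is name-pattern-based and multilingual or
  unconventional entity names will evade it.
* The GO allow-list ships small; real deployments should extend it from an
  ontology slim.
* Cross-species merging of homologous assemblies is out of scope by design.
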