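import hashlib
import random
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from complexkit import identity
from complexkit.models import AssemblyInstance, EligibilityError, PolymerComponent


def protein(entry="1abc", entity=1, acc="P68871", copies=1, **kw):
    accs = kw.pop("accessions", (acc,) if acc else ())
    return PolymerComponent(
        entry_id=entry, entity_id=entity, polymer_type="protein",
        copies=copies, uniprot_accessions=accs, **kw,
    )


def nucleic(ptype, entry="1abc", entity=1, copies=1, rfam=None):
    return PolymerComponent(
        entry_id=entry, entity_id=entity, polymer_type=ptype,
        copies=copies, rfam_accession=rfam,
    )


@pytest.mark.parametrize(
    "component,expected",
    [
        (protein(acc="P68871", copies=1), "P68871_1"),
        (nucleic("RNA", rfam="RF00177"), "RF00177_1"),
        (protein("5mv4", 1, None, 1, is_antibody=True), "antibody_5mv4_1_1"),
        (protein("7rx0", 2, None, 1), "protein_7rx0_2_1"),
        (nucleic("RNA", "1un6", 2), "RNA_1un6_2_1"),
        (nucleic("DNA", "8b1t", 4), "DNA_8b1t_4_1"),
        (nucleic("DNA/RNA", "8e8j", 3), "DNA/RNA_8e8j_3_1"),
    ],
)
def test_component_label_grammar(component, expected):
    """Each component kind labels by its own production, character-exact."""
    assert identity.component_label(component) == expected


def test_chimeric_component_has_no_label():
    chimera = protein(accessions=("P68871", "P69905"))
    with pytest.raises(EligibilityError):
        identity.component_label(chimera)


@pytest.mark.parametrize(
    "label,expected",
    [
        ("P68871_2", ("mapped", "P68871", 2)),
        ("RF00177_1", ("mapped", "RF00177", 1)),
        ("antibody_5mv4_1_1", ("antibody", "5mv4_1", 1)),
        ("DNA/RNA_8e8j_3_1", ("DNA/RNA", "8e8j_3", 1)),
    ],
)
def test_parse_label_inverts_grammar(label, expected):
    assert identity.parse_label(label) == expected


def test_haemoglobin_composition_string_and_digest():
    asm = AssemblyInstance("6kat", 1, [
        protein("6kat", 1, "P69905", 2),
        protein("6kat", 2, "P68871", 2),
    ])
    key = identity.canonical_key(asm)
    assert key.composition_string == "P68871_2,P69905_2"
    assert key.md5_hex == hashlib.md5(b"P68871_2,P69905_2").hexdigest()


def test_mapped_labels_sort_before_unmapped():
    asm = AssemblyInstance("1uty", 1, [
        nucleic("DNA", "1uty", 2),
        protein("1uty", 1, "P12345", 1),
    ])
    assert identity.canonical_key(asm).composition_string == "P12345_1,DNA_1uty_2_1"


def test_same_accession_entities_merge_with_summed_stoichiometry():
    asm = AssemblyInstance("2abc", 1, [
        protein("2abc", 1, "P11111", 2),
        protein("2abc", 2, "P11111", 1),  # same molecule, different entity
    ])
    assert identity.canonical_key(asm).composition_string == "P11111_3"


def _random_components(rng, entry):
    pool = [f"P{n:05d}" for n in range(8)]
    comps = []
    n = rng.randint(1, 5)
    for entity in range(1, n + 1):
        kind = rng.choice(["protein", "rna", "dna", "unmapped"])
        copies = rng.randint(1, 4)
        if kind == "protein":
            comps.append(protein(entry, entity, rng.choice(pool), copies))
        elif kind == "rna":
            comps.append(nucleic("RNA", entry, entity, copies, rfam=f"RF{rng.randint(1, 5):05d}"))
        elif kind == "dna":
            comps.append(nucleic("DNA", entry, entity, copies))
        else:
            comps.append(protein(entry, entity, None, copies))
    return comps


def _multiset_oracle(components):
    """Brute-force component identity multiset, independent of labelling."""
    counts = Counter()
    for c in components:
        if c.polymer_type == "protein" and c.uniprot:
            ident = ("uniprot", c.uniprot)
        elif c.polymer_type == "RNA" and c.rfam_accession:
            ident = ("rfam", c.rfam_accession)
        else:
            ident = (c.polymer_type, c.is_antibody, c.entry_id, c.entity_id)
        counts[ident] += c.copies
    return frozenset(counts.items())


def test_digest_depends_only_on_component_multiset():
    """1000 random assemblies, each shuffled 5 ways: md5 grouping equals the
    brute-force multiset grouping and permutations never change the digest."""
    rng = random.Random(42)
    by_oracle = {}
    by_md5 = {}
    for i in range(1000):
        entry = f"{1000 + i:04d}"
        comps = _random_components(rng, entry)
        digests = set()
        for _ in range(5):
            shuffled = list(comps)
            rng.shuffle(shuffled)
            key = identity.canonical_key(AssemblyInstance(entry, 1, shuffled))
            digests.add((key.md5_hex, key.composition_string))
        assert len(digests) == 1, "permutation changed the canonical key"
        md5, comp_string = digests.pop()
        by_oracle.setdefault(_multiset_oracle(comps), set()).add(md5)
        by_md5.setdefault(md5, set()).add(_multiset_oracle(comps))
    assert all(len(v) == 1 for v in by_oracle.values()), "equal multisets, different md5"
    assert all(len(v) == 1 for v in by_md5.values()), "different multisets, same md5"


@settings(max_examples=100, deadline=None)
@given(st.permutations(list(range(6))), st.data())
def test_canonical_key_is_permutation_invariant(order, data):
    copies = data.draw(st.lists(st.integers(1, 5), min_size=6, max_size=6))
    comps = [
        protein("3abc", 1, "P00001", copies[0]),
        protein("3abc", 2, "P00002", copies[1]),
        protein("3abc", 3, None, copies[2]),
        nucleic("RNA", "3abc", 4, copies[3], rfam="RF00005"),
        nucleic("DNA", "3abc", 5, copies[4]),
        nucleic("DNA/RNA", "3abc", 6, copies[5]),
    ]
    base = identity.canonical_key(AssemblyInstance("3abc", 1, comps))
    permuted = identity.canonical_key(
        AssemblyInstance("3abc", 1, [comps[i] for i in order])
    )
    assert base == permuted


class TestRegistry:
    def test_minting_and_idempotence(self):
        reg = identity.IdentifierRegistry(first_serial=100487)
        key = identity.canonical_key(
            AssemblyInstance("1uty", 1, [protein("1uty", 1, "P12345", 1), nucleic("DNA", "1uty", 2)])
        )
        acc = identity.assign_identifier(key, reg)
        assert acc == "PDB-CPX-100487"
        assert identity.assign_identifier(key, reg) == acc
        assert reg.next_serial == 100488

    def test_persistence_round_trip(self, tmp_path):
        reg = identity.IdentifierRegistry()
        for md5 in ("a" * 32, "b" * 32, "c" * 32):
            reg.assign(md5)
        path = tmp_path / "reg.tsv"
        reg.save(path)
        reloaded = identity.IdentifierRegistry.load(path)
        assert reloaded.assignments == reg.assignments
        assert reloaded.next_serial == reg.next_serial

    def test_duplicate_md5_is_an_integrity_error(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text("aa\tPDB-CPX-100001\naa\tPDB-CPX-100002\n")
        from complexkit.models import RegistryIntegrityError

        with pytest.raises(RegistryIntegrityError):
            identity.IdentifierRegistry.load(path)

    def test_duplicate_accession_is_an_integrity_error(self, tmp_path):
        path = tmp_path / "reg.tsv"
        path.write_text("aa\tPDB-CPX-100001\nbb\tPDB-CPX-100001\n")
        from complexkit.models import RegistryIntegrityError

        with pytest.raises(RegistryIntegrityError):
            identity.IdentifierRegistry.load(path)


class TestPreferredAssembly:
    def test_smallest_complete_assembly_wins(self):
        hexamer = AssemblyInstance("1e94", 1, [protein("1e94", 1, "P0A7B8", 6)])
        dodecamer = AssemblyInstance("1e94", 2, [protein("1e94", 1, "P0A7B8", 12)])
        assert identity.select_preferred_assembly([dodecamer, hexamer]) == 1

    def test_single_assembly_entry(self):
        only = AssemblyInstance("1abc", 3, [protein(copies=2)])
        assert identity.select_preferred_assembly([only]) == 3

    def test_incomplete_assemblies_are_skipped_when_a_complete_one_exists(self):
        # four assemblies: two complete (sizes 6 and 8), two partial
        full6 = AssemblyInstance("4xyz", 1, [
            protein("4xyz", 1, "P1", 4), protein("4xyz", 2, "P2", 2)])
        full8 = AssemblyInstance("4xyz", 2, [
            protein("4xyz", 1, "P1", 4), protein("4xyz", 2, "P2", 4)])
        part1 = AssemblyInstance("4xyz", 3, [protein("4xyz", 1, "P1", 1)])
        part2 = AssemblyInstance("4xyz", 4, [protein("4xyz", 2, "P2", 1)])
        assert identity.select_preferred_assembly([full8, part1, full6, part2]) == 1

    def test_fallback_to_best_coverage_when_nothing_is_complete(self):
        a = AssemblyInstance("5xyz", 1, [protein("5xyz", 1, "P1", 1)])
        b = AssemblyInstance("5xyz", 2, [
            protein("5xyz", 2, "P2", 1), protein("5xyz", 3, "P3", 1)])
        assert identity.select_preferred_assembly([a, b]) == 2

    def test_empty_input_is_a_usage_error(self):
        with pytest.raises(ValueError):
            identity.select_preferred_assembly([])


def test_eligibility_counts_chimeras(default_bundle):
    from conftest import identify

    preferred = identity.mark_preferred(default_bundle.assemblies)
    flagged = [a for a in preferred if not identity.eligibility(a)[0]]
    want = sum(
        1 for g in default_bundle.truth.groups.values() if g.excluded
    )
    assert len(flagged) == want
    ok, reason = identity.eligibility(flagged[0])
    assert not ok and "chimeric" in reason


def test_group_unique_members_and_counts(ref_bundle, ref_uniques):
    by_string = {u.key.composition_string: u for u in ref_uniques}
    hb = by_string["P68871_2,P69905_2"]
    assert sorted(hb.members) == [("6kat", 1), ("7jy3", 1)]
    # grouping never merges distinct truth groups and never splits one
    from conftest import truth_by_md5

    truth_by_md5(ref_bundle, ref_uniques)  # asserts internally


def test_composition_classes_match_brute_force(default_uniques):
    stats = identity.composition_statistics(default_uniques)
    brute = {"protein_only": 0, "protein_nucleic": 0, "nucleic_only": 0}
    for u in default_uniques:
        types = {c.polymer_type for c in u.components}
        if types == {"protein"}:
            brute["protein_only"] += 1
        elif "protein" in types:
            brute["protein_nucleic"] += 1
        else:
            brute["nucleic_only"] += 1
    for k, v in brute.items():
        assert stats[k] == v
    assert (
        stats["monomeric"] + stats["homomeric"] + stats["heteromeric"]
        == stats["n_unique"]
    )


def test_stoichiometry_variability_flags_mixed_homomer_groups(ref_uniques):
    table = identity.homomer_stoichiometry_variability(ref_uniques)
    assert table["Q8N5Z0"] == [2, 4]  # dimer group plus one tetramer annotation
    assert table["P0A7B8"] == [6]  # the dodecamer was not the preferred form
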