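import pytest

from complexkit import naming
from complexkit.identity import IdentifierRegistry, group_unique
from complexkit.models import AssemblyInstance, CuratedNameMap, PolymerComponent
from conftest import truth_by_md5


def protein(entry, entity, acc=None, copies=1, uniprot_name=None, name="",
            antibody=False, go=(), tax=562, seq_length=None):
    return PolymerComponent(
        entry_id=entry, entity_id=entity, polymer_type="protein", copies=copies,
        uniprot_accessions=(acc,) if acc else (), is_antibody=antibody,
        entity_name=name, uniprot_name=uniprot_name, go_cc_terms=tuple(go),
        taxonomy_id=tax, seq_length=seq_length,
    )


def rna(entry, entity, copies=1, rfam=None, name="", tax=562):
    return PolymerComponent(
        entry_id=entry, entity_id=entity, polymer_type="RNA", copies=copies,
        rfam_accession=rfam, entity_name=name, taxonomy_id=tax,
    )


def _unique(entry, components):
    [u] = group_unique([AssemblyInstance(entry, 1, components)], IdentifierRegistry())
    return u


CFG = naming.NamingConfig()


class TestRibosomeDetection:
    def test_rrna_plus_ribosomal_protein(self):
        comps = [
            rna("6v3e", 1, rfam="RF00177"),
            protein("6v3e", 2, "P0A7V0", uniprot_name="30S ribosomal protein S2"),
        ]
        call = naming.detect_ribosome(comps, CFG)
        assert call.is_ribosome and call.subunits == {"SSU"}

    def test_no_rna_means_no_ribosome(self):
        comps = [protein("1abc", 1, "P1", uniprot_name="50S ribosomal protein L2")]
        assert not naming.detect_ribosome(comps, CFG).is_ribosome

    def test_fallback_unmapped_rna_plus_ribosomal_protein(self):
        comps = [
            rna("8rbf", 1, name="large subunit rRNA"),
            protein("8rbf", 2, "P60422", uniprot_name="50S ribosomal protein L2"),
        ]
        call = naming.detect_ribosome(comps, CFG)
        assert call.is_ribosome and call.subunits == {"LSU"}

    def test_fallback_never_fires_when_rrna_is_mapped(self):
        comps = [
            rna("5j7l", 1, rfam="RF00177"),
            rna("5j7l", 2, name="mRNA"),  # unmapped RNA present too
            protein("5j7l", 3, "P0A7V0", uniprot_name="30S ribosomal protein S2"),
        ]
        call = naming.detect_ribosome(comps, CFG)
        assert call.subunits == {"SSU"}  # from the mapped family, not names
        assert call.has_other_rna

    def test_trna_families_are_recognised(self):
        comps = [
            rna("6bok", 1, rfam="RF00177"),
            rna("6bok", 2, rfam="RF01852"),
            protein("6bok", 3, "P0A7V0", uniprot_name="30S ribosomal protein S2"),
        ]
        assert naming.detect_ribosome(comps, CFG).has_trna


class TestRibosomeNames:
    @pytest.mark.parametrize(
        "subunits,trna,other,style,expected",
        [
            ({"SSU", "LSU"}, True, True, "prokaryotic-style", "70 S ribosome and tRNA and RNA"),
            ({"SSU", "LSU"}, False, False, "prokaryotic-style", "70 S ribosome"),
            ({"SSU"}, False, False, "prokaryotic-style", "30 S ribosomal subunit"),
            ({"LSU"}, False, False, "prokaryotic-style", "50 S ribosomal subunit"),
            ({"SSU", "LSU"}, False, False, "eukaryotic-style", "80 S ribosome"),
            ({"SSU"}, True, False, "eukaryotic-style", "40 S ribosomal subunit and tRNA"),
        ],
    )
    def test_name_templates(self, subunits, trna, other, style, expected):
        from complexkit.models import RibosomeCall

        call = RibosomeCall(True, frozenset(subunits), trna, other, style)
        assert naming.ribosome_name(call) == expected

    def test_non_ribosome_is_a_usage_error(self):
        from complexkit.models import RibosomeCall

        with pytest.raises(ValueError):
            naming.ribosome_name(RibosomeCall(False))


class TestCommonGoName:
    def test_shared_allowlisted_term_names_the_complex(self):
        go = (("GO:0016591", "DNA-directed RNA Polymerase II"),)
        comps = [protein("2c35", 1, "P20433", go=go), protein("2c35", 2, "P34087", go=go)]
        assert naming.common_go_name(comps, CFG) == ("GO:0016591", "DNA-directed RNA Polymerase II")

    def test_component_without_terms_blocks_naming(self):
        go = (("GO:0000786", "nucleosome"),)
        comps = [protein("5ay8", 1, "P68431", go=go), protein("5ay8", 2, "P62805")]
        assert naming.common_go_name(comps, CFG) is None

    def test_non_allowlisted_terms_are_ignored(self):
        go = (("GO:0005737", "cytoplasm"),)
        comps = [protein("1abc", 1, "P1", go=go), protein("1abc", 2, "P2", go=go)]
        assert naming.common_go_name(comps, CFG) is None

    def test_most_specific_term_wins(self):
        shared = (
            ("GO:0000786", "nucleosome"),
            ("GO:0000502", "proteasome complex"),
        )
        comps = [protein("1abc", 1, "P1", go=shared), protein("1abc", 2, "P2", go=shared)]
        counts = {"GO:0000786": 5, "GO:0000502": 500}
        got = naming.common_go_name(comps, CFG, counts)
        assert got == ("GO:0000786", "nucleosome")


class TestDecisionTree:
    def test_curated_name_overrides_everything(self, ref_bundle, ref_uniques):
        clock = next(u for u in ref_uniques if u.key.composition_string == "O08785_1,Q9WTL8_1")
        curated = CuratedNameMap(entries={clock.md5_hex: "curator's choice"})
        from complexkit import portal

        match = portal.match_unique(clock, ref_bundle.portal)
        res = naming.name_assembly(clock, match, curated, CFG,
                                   portal_names={"CPX-3225": "CLOCK-Bmal1 transcription complex"})
        assert res.name == "curator's choice" and res.category == "curated"

    def test_homomer_takes_uniprot_recommended_name(self):
        u = _unique("1bcf", [protein("1bcf", 1, "P0ABD3", 24, uniprot_name="Bacterioferritin")])
        res = naming.name_assembly(u, None, None, CFG)
        assert res.name == "Bacterioferritin" and res.category == "uniprot"

    def test_single_uniprot_with_generic_extras(self):
        u = _unique("5hi4", [
            protein("5hi4", 1, "Q16552", 2, uniprot_name="Interleukin-17A", tax=9606),
            protein("5hi4", 2, copies=2, name="IG-heavy chain", antibody=True, tax=9606),
            protein("5hi4", 3, copies=2, name="IG-light lambda chain", antibody=True, tax=9606),
            protein("5hi4", 4, copies=2, name="HAP peptide", seq_length=12, tax=9606),
        ])
        res = naming.name_assembly(u, None, None, CFG)
        assert res.name == "Interleukin-17A, IG-heavy chain, IG-light lambda chain, peptide complex"
        assert res.category == "uniprot"

    def test_antibody_only_assembly(self):
        u = _unique("12e8", [
            protein("12e8", 1, copies=2, name="IG-heavy chain", antibody=True),
            protein("12e8", 2, copies=2, name="IG-light kappa chain", antibody=True),
        ])
        res = naming.name_assembly(u, None, None, CFG)
        assert res.name == "IG-heavy chain and IG-light kappa chain"
        assert res.category == "antibody"

    def test_unmapped_homomer_uses_entity_name(self):
        u = _unique("1ivi", [protein("1ivi", 1, copies=2, name="dihydrolipoamide dehydrogenase")])
        res = naming.name_assembly(u, None, None, CFG)
        assert res.name == "dihydrolipoamide dehydrogenase"
        assert res.category == "unmapped_protein"

    def test_rfam_only_assembly_takes_family_name(self):
        u = _unique("2gis", [rna("2gis", 1, rfam="RF00162", name="SAM-I riboswitch")])
        res = naming.name_assembly(u, None, None, CFG)
        assert res.name == "SAM riboswitch" and res.category == "rfam"

    @pytest.mark.parametrize(
        "ptype,expected",
        [("DNA", "DNA"), ("RNA", "RNA"), ("DNA/RNA", "DNA/RNA hybrid")],
    )
    def test_generic_nucleic_names(self, ptype, expected):
        comp = PolymerComponent(
            entry_id="6c8m", entity_id=1, polymer_type=ptype, copies=2,
        )
        u = _unique("6c8m", [comp])
        res = naming.name_assembly(u, None, None, CFG)
        assert res.name == expected and res.category == "nucleic_generic"

    def test_mixed_mapped_and_unmapped_heteromer_stays_unnamed(self):
        u = _unique("9xyz", [
            protein("9xyz", 1, "P1", uniprot_name="A"),
            protein("9xyz", 2, "P2", uniprot_name="B"),
            protein("9xyz", 3, name="orphan chain"),
        ])
        res = naming.name_assembly(u, None, None, CFG)
        assert res.name is None and res.category == "unnamed"

    def test_determinism(self, ref_bundle, ref_uniques):
        from complexkit import portal

        portal_names = {c.complex_ac: c.recommended_name for c in ref_bundle.portal}
        for u in ref_uniques:
            match = portal.match_unique(u, ref_bundle.portal)
            first = naming.name_assembly(u, match, ref_bundle.curated, CFG, portal_names=portal_names)
            second = naming.name_assembly(u, match, ref_bundle.curated, CFG, portal_names=portal_names)
            assert first == second


def test_category_soundness(ref_bundle, ref_uniques):
    from complexkit import portal

    portal_names = {c.complex_ac: c.recommended_name for c in ref_bundle.portal}
    for u in ref_uniques:
        match = portal.match_unique(u, ref_bundle.portal)
        res = naming.name_assembly(u, match, ref_bundle.curated, CFG, portal_names=portal_names)
        if res.category == "complex_portal":
            assert match is not None
        if res.category == "uniprot":
            accs = {c.uniprot for c in u.components if c.uniprot}
            assert len(accs) == 1
        if res.category == "go":
            assert res.evidence and res.evidence[0].startswith("GO:")
        assert (res.category == "unnamed") == (res.name is None)


def test_naming_statistics_breakdown(default_bundle, default_uniques):
    from complexkit import portal

    truth = truth_by_md5(default_bundle, default_uniques)
    portal_names = {c.complex_ac: c.recommended_name for c in default_bundle.portal}
    go_counts = naming.go_term_component_counts(default_uniques)
    for u in default_uniques:
        match = portal.match_unique(u, default_bundle.portal)
        res = naming.name_assembly(u, match, default_bundle.curated, CFG,
                                   portal_names=portal_names, go_counts=go_counts)
        u.name, u.naming_category = res.name, res.category
    stats = naming.naming_statistics(default_uniques)
    want = {}
    for t in truth.values():
        want[t.category] = want.get(t.category, 0) + 1
    got = {k: v["unique_assemblies"] for k, v in stats["categories"].items()}
    assert got == want
    assert stats["named_fraction"] >= 0.90
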