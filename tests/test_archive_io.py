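import random

import pytest

from complexkit import archive_io
from complexkit.models import SnapshotValidationError
from complexkit.synth import FixtureConfig, generate_archive


@pytest.fixture()
def snapshot_paths(tmp_path):
    bundle = generate_archive(FixtureConfig(seed=7))
    return bundle, bundle.write(tmp_path)


def test_snapshot_round_trip_is_byte_identical(snapshot_paths, tmp_path):
    _, paths = snapshot_paths
    instances = archive_io.read_snapshot(paths["snapshot"])
    out = tmp_path / "rt.tsv"
    archive_io.write_snapshot(instances, out)
    assert out.read_bytes() == paths["snapshot"].read_bytes()


def test_row_order_does_not_change_parsed_content(snapshot_paths, tmp_path):
    _, paths = snapshot_paths
    instances = archive_io.read_snapshot(paths["snapshot"])
    shuffled = list(instances)
    random.Random(0).shuffle(shuffled)
    out = tmp_path / "shuffled.tsv"
    archive_io.write_snapshot(shuffled, out)
    reread = archive_io.read_snapshot(out)

    def as_set(insts):
        return {
            (a.entry_id, a.assembly_id, a.symmetry_label, frozenset(a.components))
            for a in insts
        }

    assert as_set(reread) == as_set(instances)


def test_direct_field_mapping(tmp_path):
    rows = "\t".join(archive_io.SNAPSHOT_COLUMNS) + "\n" + "\t".join(
        ["6kat", "1", "1", "protein", "P68871", "", "0",
         "Hemoglobin subunit beta", "Hemoglobin subunit beta",
         "GO:0005833=haemoglobin complex", "9606", "2", "C2"]
    )
    path = tmp_path / "one.tsv"
    path.write_text(rows + "\n")
    [asm] = archive_io.read_snapshot(path)
    assert asm.entry_id == "6kat" and asm.assembly_id == 1
    [comp] = asm.components
    assert comp.uniprot_accessions == ("P68871",)
    assert comp.copies == 2
    assert comp.go_cc_terms == (("GO:0005833", "haemoglobin complex"),)
    assert asm.symmetry_label == "C2"


def _write_rows(tmp_path, rows):
    header = "\t".join(archive_io.SNAPSHOT_COLUMNS)
    path = tmp_path / "bad.tsv"
    path.write_text(header + "\n" + "\n".join("\t".join(r) for r in rows) + "\n")
    return path


def test_uniprot_on_dna_component_is_rejected(tmp_path):
    row = ["1abc", "1", "1", "DNA", "P68871", "", "0", "duplex", "", "", "", "1", ""]
    path = _write_rows(tmp_path, [row])
    with pytest.raises(SnapshotValidationError, match="non-protein"):
        archive_io.read_snapshot(path)


def test_missing_mandatory_column_names_the_column(tmp_path):
    path = tmp_path / "short.tsv"
    path.write_text("entry_id\tassembly_id\n1abc\t1\n")
    with pytest.raises(SnapshotValidationError, match="entity_id"):
        archive_io.read_snapshot(path)


def test_validate_snapshot_counts_every_seeded_defect(tmp_path):
    # seven distinct invariant violations in one snapshot
    rows = [
        # 1: copies = 0
        ["1aaa", "1", "1", "protein", "P00001", "", "0", "x", "", "", "", "0", ""],
        # 2: duplicate entity within assembly
        ["1aab", "1", "1", "protein", "P00002", "", "0", "x", "", "", "", "1", ""],
        ["1aab", "1", "1", "protein", "P00003", "", "0", "y", "", "", "", "1", ""],
        # 3: rfam on a protein
        ["1aac", "1", "1", "protein", "P00004", "RF00005", "0", "x", "", "", "", "1", ""],
        # 4: uniprot on DNA
        ["1aad", "1", "1", "DNA", "P00005", "", "0", "x", "", "", "", "1", ""],
        # 5: antibody flag on RNA
        ["1aae", "1", "1", "RNA", "", "", "1", "x", "", "", "", "1", ""],
        # 6: malformed rfam accession
        ["1aaf", "1", "1", "RNA", "", "RFX1", "0", "x", "", "", "", "1", ""],
        # 7: bad entry code
        ["TOOLONG", "1", "1", "protein", "P00006", "", "0", "x", "", "", "", "1", ""],
    ]
    path = _write_rows(tmp_path, rows)
    instances = archive_io.read_snapshot(path, validate=False)
    report = archive_io.validate_snapshot(instances)
    assert len(report.errors) == 7


def test_portal_catalog_parses_participants(tmp_path):
    path = tmp_path / "portal.tsv"
    path.write_text(
        "complex_ac\trecommended_name\tparticipants\n"
        "CPX-3225\tCLOCK-Bmal1 transcription complex\tQ9WTL8(1)|O08785(1)\n"
        "CPX-1\twith small molecule\tP11111(2)|CHEBI:15422(1)\n"
    )
    complexes = archive_io.read_portal_catalog(path)
    assert len(complexes) == 2
    clock = complexes[0]
    assert clock.complex_ac == "CPX-3225"
    assert clock.participant_dict == {"Q9WTL8": 1, "O08785": 1}
    assert not clock.partial_definition
    assert complexes[1].partial_definition  # CHEBI participant dropped


def test_portal_catalog_rejects_zero_stoichiometry(tmp_path):
    path = tmp_path / "portal.tsv"
    path.write_text("complex_ac\trecommended_name\tparticipants\nCPX-2\tx\tP1(0)\n")
    with pytest.raises(ValueError, match="stoichiometry"):
        archive_io.read_portal_catalog(path)


def test_portal_catalog_round_trip(snapshot_paths):
    bundle, paths = snapshot_paths
    complexes = archive_io.read_portal_catalog(paths["portal"])
    want = {
        c.complex_ac: tuple(sorted(c.participant_dict.items())) for c in bundle.portal
    }
    got = {
        c.complex_ac: tuple(sorted(c.participant_dict.items())) for c in complexes
    }
    assert got == want


def test_json_snapshot_equivalent_to_tsv(tmp_path, snapshot_paths):
    import json

    bundle, paths = snapshot_paths
    doc = {"entries": []}
    by_entry = {}
    for asm in bundle.assemblies:
        by_entry.setdefault(asm.entry_id, []).append(asm)
    for entry_id, asms in by_entry.items():
        doc["entries"].append(
            {
                "entry_id": entry_id,
                "assemblies": [
                    {
                        "assembly_id": a.assembly_id,
                        "symmetry": a.symmetry_label,
                        "components": [
                            {
                                "entity_id": c.entity_id,
                                "polymer_type": c.polymer_type,
                                "copies": c.copies,
                                "uniprot": list(c.uniprot_accessions),
                                "rfam": c.rfam_accession,
                                "is_antibody": c.is_antibody,
                                "entity_name": c.entity_name,
                                "uniprot_name": c.uniprot_name,
                                "go_cc": [list(t) for t in c.go_cc_terms],
                                "taxonomy_id": c.taxonomy_id,
                                "seq_length": c.seq_length,
                            }
                            for c in a.components
                        ],
                    }
                    for a in asms
                ],
            }
        )
    path = tmp_path / "snapshot.json"
    path.write_text(json.dumps(doc))
    from_json = archive_io.read_snapshot(path)
    from_tsv = archive_io.read_snapshot(paths["snapshot"])
    key = lambda insts: {
        (a.entry_id, a.assembly_id, a.symmetry_label, frozenset(a.components))
        for a in insts
    }
    assert key(from_json) == key(from_tsv)


def test_curated_names_round_trip(tmp_path, snapshot_paths):
    bundle, paths = snapshot_paths
    curated = archive_io.read_curated_names(paths["curated"])
    assert curated.entries == bundle.curated.entries
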