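"""Reading and writing archive snapshots, portal catalogues and name lists.

Snapshot format
---------------
A snapshot is one row per (entry, assembly, entity): UTF-8 TSV with header

    entry_id  assembly_id  entity_id  polymer_type  uniprot  rfam
    is_antibody  entity_name  uniprot_name  go_cc  taxonomy_id  copies
    symmetry  [seq_length]

``uniprot`` holds zero or more semicolon-separated accessions (more than one
marks a chimeric entity); ``go_cc`` holds pipe-separated ``GO:NNNNNNN=name``
pairs; ``symmetry`` is the per-assembly point-group label, repeated on every
row of the assembly; ``seq_length`` is an optional trailing column.  A
structurally equivalent hierarchical JSON form (entries > assemblies >
components) is read from ``.json`` paths.

Complex Portal catalogues are accepted both as the minimal three-column TSV
(complex_ac, recommended_name, participants) and in the public "complextab"
dialect; participant tokens are ``ACCESSION(stoichiometry)`` joined by ``|``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .models import (
    AssemblyInstance,
    CuratedNameMap,
    PolymerComponent,
    PortalComplex,
    SnapshotValidationError,
    ValidationReport,
)

PathLike = Union[str, Path]

SNAPSHOT_COLUMNS = [
    "entry_id",
    "assembly_id",
    "entity_id",
    "polymer_type",
    "uniprot",
    "rfam",
    "is_antibody",
    "entity_name",
    "uniprot_name",
    "go_cc",
    "taxonomy_id",
    "copies",
    "symmetry",
]
OPTIONAL_COLUMNS = ["seq_length"]

_RFAM_RE = re.compile(r"^RF\d{5}$")
_ENTRY_RE = re.compile(r"^[0-9a-z]{4}$")
_PARTICIPANT_RE = re.compile(r"^(?P<acc>[^()|\s]+)\((?P<stoich>\d+)\)$")


# ---------------------------------------------------------------------------
# snapshot parsing


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in {"1", "true", "yes", "y"}


def _parse_go(raw: str) -> tuple[tuple[str, str], ...]:
    terms = []
    for token in raw.split("|"):
        token = token.strip()
        if not token:
            continue
        go_id, _, go_name = token.partition("=")
        terms.append((go_id.strip(), go_name.strip()))
    return tuple(terms)


def _component_from_row(row: dict) -> PolymerComponent:
    uniprot_raw = (row.get("uniprot") or "").strip()
    accessions = tuple(a.strip() for a in uniprot_raw.split(";") if a.strip())
    tax_raw = (row.get("taxonomy_id") or "").strip()
    len_raw = (row.get("seq_length") or "").strip()
    return PolymerComponent(
        entry_id=row["entry_id"].strip(),
        entity_id=int(row["entity_id"]),
        polymer_type=row["polymer_type"].strip(),
        copies=int(row["copies"]),
        uniprot_accessions=accessions,
        rfam_accession=(row.get("rfam") or "").strip() or None,
        is_antibody=_parse_bool(row.get("is_antibody", "")),
        entity_name=(row.get("entity_name") or "").strip(),
        uniprot_name=(row.get("uniprot_name") or "").strip() or None,
        go_cc_terms=_parse_go(row.get("go_cc") or ""),
        taxonomy_id=int(tax_raw) if tax_raw else None,
        seq_length=int(len_raw) if len_raw else None,
    )


def _rows_to_instances(rows: Iterable[dict]) -> list[AssemblyInstance]:
    """Group rows into AssemblyInstance objects, preserving first-seen order."""
    instances: dict[tuple[str, int], AssemblyInstance] = {}
    for row in rows:
        inst_key = (row["entry_id"].strip(), int(row["assembly_id"]))
        component = _component_from_row(row)
        symmetry = (row.get("symmetry") or "").strip() or None
        if inst_key not in instances:
            instances[inst_key] = AssemblyInstance(
                entry_id=inst_key[0],
                assembly_id=inst_key[1],
                symmetry_label=symmetry,
            )
        inst = instances[inst_key]
        if symmetry and inst.symmetry_label is None:
            inst.symmetry_label = symmetry
        inst.components.append(component)
    return list(instances.values())


def read_snapshot(path: PathLike, validate: bool = True) -> list[AssemblyInstance]:
    """Read an archive snapshot (TSV, or hierarchical JSON for ``.json``).

    With ``validate=True`` (default) a snapshot violating any field invariant
    raises :class:`SnapshotValidationError`; pass ``validate=False`` to obtain
    the parsed instances for inspection with :func:`validate_snapshot`.
    """
    path = Path(path)
    if path.suffix == ".json":
        instances = _read_snapshot_json(path)
    else:
        instances = _read_snapshot_tsv(path)
    if validate:
        report = validate_snapshot(instances)
        if not report.ok:
            raise SnapshotValidationError(report)
    return instances


def _read_snapshot_tsv(path: Path) -> list[AssemblyInstance]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SNAPSHOT_COLUMNS if c not in df.columns]
    if missing:
        raise SnapshotValidationError(
            ValidationReport(errors=[(str(path), f"missing mandatory column: {c}") for c in missing])
        )
    return _rows_to_instances(df.to_dict(orient="records"))


def _read_snapshot_json(path: Path) -> list[AssemblyInstance]:
    """Hierarchical form: {"entries": [{"entry_id", "assemblies": [...]}]}."""
    doc = json.loads(path.read_text())
    rows: list[dict] = []
    for entry in doc.get("entries", []):
        for asm in entry.get("assemblies", []):
            for comp in asm.get("components", []):
                row = {
                    "entry_id": entry["entry_id"],
                    "assembly_id": str(asm["assembly_id"]),
                    "symmetry": asm.get("symmetry", "") or "",
                    "entity_id": str(comp["entity_id"]),
                    "polymer_type": comp["polymer_type"],
                    "uniprot": ";".join(comp.get("uniprot", [])),
                    "rfam": comp.get("rfam", "") or "",
                    "is_antibody": "1" if comp.get("is_antibody") else "0",
                    "entity_name": comp.get("entity_name", ""),
                    "uniprot_name": comp.get("uniprot_name", "") or "",
                    "go_cc": "|".join(f"{i}={n}" for i, n in comp.get("go_cc", [])),
                    "taxonomy_id": str(comp.get("taxonomy_id") or ""),
                    "copies": str(comp["copies"]),
                    "seq_length": str(comp.get("seq_length") or ""),
                }
                rows.append(row)
    return _rows_to_instances(rows)


def write_snapshot(instances: list[AssemblyInstance], path: PathLike) -> None:
    """Write instances in canonical TSV form (stable column order)."""
    rows = []
    any_length = any(c.seq_length is not None for a in instances for c in a.components)
    for inst in instances:
        for comp in inst.components:
            row = {
                "entry_id": comp.entry_id,
                "assembly_id": inst.assembly_id,
                "entity_id": comp.entity_id,
                "polymer_type": comp.polymer_type,
                "uniprot": ";".join(comp.uniprot_accessions),
                "rfam": comp.rfam_accession or "",
                "is_antibody": "1" if comp.is_antibody else "0",
                "entity_name": comp.entity_name,
                "uniprot_name": comp.uniprot_name or "",
                "go_cc": "|".join(f"{i}={n}" for i, n in comp.go_cc_terms),
                "taxonomy_id": "" if comp.taxonomy_id is None else comp.taxonomy_id,
                "copies": comp.copies,
                "symmetry": inst.symmetry_label or "",
            }
            if any_length:
                row["seq_length"] = "" if comp.seq_length is None else comp.seq_length
            rows.append(row)
    columns = SNAPSHOT_COLUMNS + (["seq_length"] if any_length else [])
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# validation


def validate_snapshot(instances: list[AssemblyInstance]) -> ValidationReport:
    """Check every field invariant; the report lists all violations found."""
    report = ValidationReport()
    seen_keys: dict[tuple[str, int], str] = {}
    for inst in instances:
        loc = f"{inst.entry_id}/assembly {inst.assembly_id}"
        if inst.key in seen_keys:
            report.errors.append((loc, "duplicate (entry_id, assembly_id) pair"))
        seen_keys[inst.key] = loc
        if not inst.components:
            report.errors.append((loc, "assembly has no components"))
        seen_entities: set[int] = set()
        for comp in inst.components:
            cloc = f"{loc}/entity {comp.entity_id}"
            if comp.entity_id in seen_entities:
                report.errors.append((cloc, "duplicate entity_id within assembly"))
            seen_entities.add(comp.entity_id)
            if not _ENTRY_RE.match(comp.entry_id):
                report.errors.append((cloc, f"entry_id not a 4-char lowercase PDB code: {comp.entry_id!r}"))
            if comp.polymer_type not in ("protein", "DNA", "RNA", "DNA/RNA"):
                report.errors.append((cloc, f"unknown polymer_type: {comp.polymer_type!r}"))
            if comp.copies < 1:
                report.errors.append((cloc, f"copies must be >= 1, got {comp.copies}"))
            if comp.entity_id < 1:
                report.errors.append((cloc, f"entity_id must be positive, got {comp.entity_id}"))
            if comp.rfam_accession is not None:
                if comp.polymer_type not in ("RNA", "DNA/RNA"):
                    report.errors.append((cloc, "rfam accession on a non-RNA component"))
                elif not _RFAM_RE.match(comp.rfam_accession):
                    report.errors.append((cloc, f"malformed Rfam accession: {comp.rfam_accession!r}"))
            if comp.polymer_type != "protein" and (comp.uniprot_accessions or comp.uniprot_name):
                report.errors.append((cloc, "UniProt fields on a non-protein component"))
            if comp.is_antibody and comp.polymer_type != "protein":
                report.errors.append((cloc, "is_antibody set on a non-protein component"))
            if comp.entry_id != inst.entry_id:
                report.errors.append((cloc, "component entry_id differs from assembly entry_id"))
    return report


# ---------------------------------------------------------------------------
# Complex Portal catalogue

_COMPLEXTAB_ALIASES = {
    "#complex ac": "complex_ac",
    "complex ac": "complex_ac",
    "recommended name": "recommended_name",
    "identifiers (and stoichiometry) of molecules in complex": "participants",
}


def read_portal_catalog(path: PathLike) -> list[PortalComplex]:
    """Read a Complex Portal catalogue (minimal TSV or complextab dialect).

    Participants that are not plain molecule accessions (e.g. ``CHEBI:...``
    small molecules) are dropped and the complex flagged partial_definition.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    renames = {c: _COMPLEXTAB_ALIASES.get(c.strip().lower(), c) for c in df.columns}
    df = df.rename(columns=renames)
    for col in ("complex_ac", "recommended_name", "participants"):
        if col not in df.columns:
            raise ValueError(f"portal catalogue missing column: {col}")
    complexes: list[PortalComplex] = []
    for lineno, row in enumerate(df.to_dict(orient="records"), start=2):
        participants: list[tuple[str, int]] = []
        partial = False
        for token in str(row["participants"]).split("|"):
            token = token.strip()
            if not token:
                continue
            m = _PARTICIPANT_RE.match(token)
            if not m:
                raise ValueError(f"{path}:{lineno}: malformed participant token {token!r}")
            acc, stoich = m.group("acc"), int(m.group("stoich"))
            if stoich < 1:
                raise ValueError(f"{path}:{lineno}: participant stoichiometry must be >= 1: {token!r}")
            if ":" in acc:  # CHEBI/URS/... — not a UniProt accession
                partial = True
                continue
            participants.append((acc, stoich))
        if not participants:
            continue  # nothing mappable; skip with no entry
        complexes.append(
            PortalComplex(
                complex_ac=row["complex_ac"].strip(),
                recommended_name=row["recommended_name"].strip(),
                participants=tuple(participants),
                partial_definition=partial,
            )
        )
    return complexes


def write_portal_catalog(complexes: list[PortalComplex], path: PathLike) -> None:
    rows = [
        {
            "complex_ac": c.complex_ac,
            "recommended_name": c.recommended_name,
            "participants": "|".join(f"{a}({n})" for a, n in c.participants),
        }
        for c in complexes
    ]
    pd.DataFrame(rows, columns=["complex_ac", "recommended_name", "participants"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# curated names & symmetry tables


def read_curated_names(path: PathLike) -> CuratedNameMap:
    """Two-column TSV (composition md5, curated name), no header required."""
    entries: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[1].strip():
            raise ValueError(f"{path}:{lineno}: expected 'md5<TAB>name'")
        if parts[0].strip().lower() == "md5":
            continue
        entries[parts[0].strip()] = parts[1].strip()
    return CuratedNameMap(entries=entries)


def write_curated_names(curated: CuratedNameMap, path: PathLike) -> None:
    lines = [f"{md5}\t{name}" for md5, name in sorted(curated.entries.items())]
    Path(path).write_text("md5\tname\n" + "\n".join(lines) + ("\n" if lines else ""))
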