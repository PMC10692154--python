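"""Canonical composition identity for macromolecular assemblies.

Every eligible assembly is reduced to an ordered list of component labels:

=====================  ==============================================
component              label
=====================  ==============================================
protein with UniProt   ``<accession>_<stoichiometry>``        (P68871_1)
RNA with Rfam          ``<accession>_<stoichiometry>``        (RF00177_1)
antibody (unmapped)    ``antibody_<entry>_<entity>_<stoich>``
protein (unmapped)     ``protein_<entry>_<entity>_<stoich>``
RNA (unmapped)         ``RNA_<entry>_<entity>_<stoich>``
DNA                    ``DNA_<entry>_<entity>_<stoich>``
DNA/RNA hybrid         ``DNA/RNA_<entry>_<entity>_<stoich>``
=====================  ==============================================

Labels are joined into a composition string whose md5 digest is the stable
content address of the composition; a persistent ``PDB-CPX-`` accession is
minted once per digest and never reassigned.  Because UniProt accessions are
species-specific and unmapped labels embed entry/entity, identity is
implicitly scoped to a species: homologous assemblies from different
organisms never share a digest.
"""

from __future__ import annotations

import hashlib
import json
import re
from pathlib import Path
from typing import Optional, Sequence, Union

from .models import (
    AssemblyInstance,
    CompositionKey,
    EligibilityError,
    PolymerComponent,
    RegistryIntegrityError,
    UniqueAssembly,
)

PathLike = Union[str, Path]

ACCESSION_PREFIX = "PDB-CPX-"
DEFAULT_FIRST_SERIAL = 100001

_UNMAPPED_PREFIXES = ("antibody_", "protein_", "RNA_", "DNA_", "DNA/RNA_")

#: Full grammar of emitted labels; inverted by :func:`parse_label`.
LABEL_RE = re.compile(
    r"^(?:"
    r"(?P<acc>[A-Za-z][A-Za-z0-9]+(?:-\d+)?)"
    r"|(?P<type>antibody|protein|RNA|DNA|DNA/RNA)_(?P<entry>[0-9a-z]{4})_(?P<entity>\d+)"
    r")_(?P<stoich>\d+)$"
)


def component_label(component: PolymerComponent, copies: Optional[int] = None) -> str:
    """Emit the canonical label for one component.

    ``copies`` overrides the component's own stoichiometry (used when copies
    of the same accession are merged across entities).
    """
    if component.is_chimeric:
        raise EligibilityError(
            f"chimeric entity {component.entry_id}/{component.entity_id} has no canonical label"
        )
    n = component.copies if copies is None else copies
    if component.polymer_type == "protein":
        if component.uniprot:
            return f"{component.uniprot}_{n}"
        if component.is_antibody:
            return f"antibody_{component.entry_id}_{component.entity_id}_{n}"
        return f"protein_{component.entry_id}_{component.entity_id}_{n}"
    if component.polymer_type == "RNA":
        if component.rfam_accession:
            return f"{component.rfam_accession}_{n}"
        return f"RNA_{component.entry_id}_{component.entity_id}_{n}"
    if component.polymer_type == "DNA":
        return f"DNA_{component.entry_id}_{component.entity_id}_{n}"
    if component.polymer_type == "DNA/RNA":
        return f"DNA/RNA_{component.entry_id}_{component.entity_id}_{n}"
    raise ValueError(f"unknown polymer type {component.polymer_type!r}")


def parse_label(label: str) -> tuple[str, Optional[str], int]:
    """Invert :func:`component_label` into (kind, mapping, stoichiometry).

    ``kind`` is ``mapped`` for accession labels, else the unmapped type;
    ``mapping`` is the accession for mapped labels and ``entry_entity`` for
    unmapped ones.
    """
    m = LABEL_RE.match(label)
    if not m:
        raise ValueError(f"not a canonical component label: {label!r}")
    if m.group("acc"):
        return ("mapped", m.group("acc"), int(m.group("stoich")))
    return (m.group("type"), f"{m.group('entry')}_{m.group('entity')}", int(m.group("stoich")))


def label_identity(label: str) -> str:
    """The label with its stoichiometry stripped — the component identity."""
    return label.rsplit("_", 1)[0]


def eligibility(assembly: AssemblyInstance) -> tuple[bool, Optional[str]]:
    """Assemblies containing chimeric entities are excluded from identification."""
    for comp in assembly.components:
        if comp.is_chimeric:
            return (
                False,
                f"entity {comp.entity_id} of {comp.entry_id} is chimeric "
                f"({';'.join(comp.uniprot_accessions)})",
            )
    return (True, None)


def _label_sort_key(label: str) -> tuple[int, str]:
    mapped = not label.startswith(_UNMAPPED_PREFIXES)
    return (0 if mapped else 1, label)


def canonical_key(assembly: AssemblyInstance) -> CompositionKey:
    """Reduce an assembly to its canonical composition key.

    Components mapped to the same accession are merged with summed
    stoichiometry before labelling, so identity reflects the molecule rather
    than deposition entity bookkeeping.  Labels are ordered mapped-first,
    lexicographically within each class; the md5 digest is taken over the
    comma-joined string with no whitespace.
    """
    ok, reason = eligibility(assembly)
    if not ok:
        raise EligibilityError(reason)
    mapped_copies: dict[str, int] = {}
    unmapped_labels: list[str] = []
    for comp in assembly.components:
        accession = comp.uniprot if comp.polymer_type == "protein" else None
        if accession is None and comp.polymer_type == "RNA":
            accession = comp.rfam_accession
        if accession:
            mapped_copies[accession] = mapped_copies.get(accession, 0) + comp.copies
        else:
            unmapped_labels.append(component_label(comp))
    labels = [f"{acc}_{n}" for acc, n in mapped_copies.items()] + unmapped_labels
    labels.sort(key=_label_sort_key)
    composition_string = ",".join(labels)
    digest = hashlib.md5(composition_string.encode("utf-8")).hexdigest()
    return CompositionKey(labels=tuple(labels), composition_string=composition_string, md5_hex=digest)


# ---------------------------------------------------------------------------
# preferred assembly


def select_preferred_assembly(assemblies: Sequence[AssemblyInstance]) -> int:
    """Choose the preferred assembly of an entry.

    The preferred assembly is the smallest one (fewest polymer chains, i.e.
    lowest total copy count) containing every polymeric entity of the entry;
    ties break to the lowest assembly_id.  If no assembly contains all
    entities, the one covering the most entities wins under the same
    tie-breaks.
    """
    if not assemblies:
        raise ValueError("select_preferred_assembly requires at least one assembly")
    entries = {a.entry_id for a in assemblies}
    if len(entries) > 1:
        raise ValueError(f"assemblies belong to several entries: {sorted(entries)}")
    all_entities: set[int] = set()
    for a in assemblies:
        all_entities |= a.entity_ids
    candidates = [a for a in assemblies if a.entity_ids >= all_entities]
    if not candidates:
        best_coverage = max(len(a.entity_ids) for a in assemblies)
        candidates = [a for a in assemblies if len(a.entity_ids) == best_coverage]
    best = min(candidates, key=lambda a: (a.total_copies, a.assembly_id))
    return best.assembly_id


def mark_preferred(assemblies: Sequence[AssemblyInstance]) -> list[AssemblyInstance]:
    """Set ``is_preferred`` across a snapshot and return the preferred ones."""
    by_entry: dict[str, list[AssemblyInstance]] = {}
    for a in assemblies:
        by_entry.setdefault(a.entry_id, []).append(a)
    preferred: list[AssemblyInstance] = []
    for entry_assemblies in by_entry.values():
        chosen = select_preferred_assembly(entry_assemblies)
        for a in entry_assemblies:
            a.is_preferred = a.assembly_id == chosen
            if a.is_preferred:
                preferred.append(a)
    return preferred


# ---------------------------------------------------------------------------
# persistent identifier registry


class IdentifierRegistry:
    """Append-only md5 → ``PDB-CPX-`` accession registry.

    Once assigned, a mapping is never changed or removed; accessions strictly
    increase with assignment order.  Persisted as a two-column TSV plus a JSON
    sidecar carrying ``next_serial``.
    """

    def __init__(self, first_serial: int = DEFAULT_FIRST_SERIAL):
        self.assignments: dict[str, str] = {}
        self._order: list[str] = []  # md5s in assignment order
        self.next_serial = first_serial

    @staticmethod
    def sidecar_path(path: PathLike) -> Path:
        return Path(str(path) + ".meta.json")

    @classmethod
    def load(cls, path: PathLike, first_serial: int = DEFAULT_FIRST_SERIAL) -> "IdentifierRegistry":
        reg = cls(first_serial=first_serial)
        path = Path(path)
        if not path.exists():
            return reg
        seen_acc: set[str] = set()
        max_serial = first_serial - 1
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#") or line.startswith("md5\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise RegistryIntegrityError(f"{path}:{lineno}: expected 'md5<TAB>accession'")
            md5, acc = parts[0].strip(), parts[1].strip()
            if md5 in reg.assignments:
                raise RegistryIntegrityError(f"{path}:{lineno}: duplicate md5 {md5}")
            if acc in seen_acc:
                raise RegistryIntegrityError(f"{path}:{lineno}: duplicate accession {acc}")
            if not acc.startswith(ACCESSION_PREFIX):
                raise RegistryIntegrityError(f"{path}:{lineno}: malformed accession {acc!r}")
            reg.assignments[md5] = acc
            reg._order.append(md5)
            seen_acc.add(acc)
            max_serial = max(max_serial, int(acc[len(ACCESSION_PREFIX):]))
        reg.next_serial = max_serial + 1
        sidecar = cls.sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            if meta.get("next_serial", reg.next_serial) < reg.next_serial:
                raise RegistryIntegrityError("sidecar next_serial lags behind assigned accessions")
            reg.next_serial = meta.get("next_serial", reg.next_serial)
        return reg

    def assign(self, md5_hex: str) -> str:
        existing = self.assignments.get(md5_hex)
        if existing is not None:
            return existing
        accession = f"{ACCESSION_PREFIX}{self.next_serial}"
        self.assignments[md5_hex] = accession
        self._order.append(md5_hex)
        self.next_serial += 1
        return accession

    def save(self, path: PathLike) -> None:
        path = Path(path)
        lines = [f"{md5}\t{self.assignments[md5]}" for md5 in self._order]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
        self.sidecar_path(path).write_text(
            json.dumps({"next_serial": self.next_serial}, indent=0) + "\n"
        )


def assign_identifier(key: CompositionKey, registry: IdentifierRegistry) -> str:
    """Return the persistent accession for a composition, minting if unseen."""
    return registry.assign(key.md5_hex)


# ---------------------------------------------------------------------------
# unique-assembly grouping


def group_unique(
    assemblies: Sequence[AssemblyInstance],
    registry: Optional[IdentifierRegistry] = None,
) -> list[UniqueAssembly]:
    """Group eligible preferred assemblies into unique compositions.

    One :class:`UniqueAssembly` per distinct md5; members enumerate every
    contributing (entry, assembly) pair.  When a registry is supplied, new
    compositions receive accessions in sorted composition-string order so the
    registry is independent of input row order.  Returned groups are sorted by
    composition string.
    """
    groups: dict[str, UniqueAssembly] = {}
    for asm in assemblies:
        key = canonical_key(asm)
        grp = groups.get(key.md5_hex)
        if grp is None:
            grp = UniqueAssembly(key=key, components=list(asm.components))
            groups[key.md5_hex] = grp
        grp.members.append(asm.key)
        grp.taxonomy_ids |= {
            c.taxonomy_id for c in asm.components if c.taxonomy_id is not None
        }
    uniques = sorted(groups.values(), key=lambda u: u.key.composition_string)
    if registry is not None:
        for u in uniques:
            u.accession = assign_identifier(u.key, registry)
    return uniques


def classify_unique(u: UniqueAssembly) -> dict[str, object]:
    """Composition-class flags for one unique assembly."""
    types = {c.polymer_type for c in u.components}
    if types <= {"protein"}:
        composition_class = "protein_only"
    elif "protein" in types:
        composition_class = "protein_nucleic"
    else:
        composition_class = "nucleic_only"
    identities = {label_identity(lbl) for lbl in u.key.labels}
    total = sum(int(lbl.rsplit("_", 1)[1]) for lbl in u.key.labels)
    if len(identities) > 1:
        multiplicity = "heteromeric"
    elif total > 1:
        multiplicity = "homomeric"
    else:
        multiplicity = "monomeric"
    proteins = [c for c in u.components if c.polymer_type == "protein"]
    mapped = [c for c in proteins if c.uniprot]
    return {
        "composition_class": composition_class,
        "multiplicity_class": multiplicity,
        "any_uniprot_mapped": bool(mapped),
        "all_uniprot_mapped": bool(proteins) and len(mapped) == len(proteins),
    }


def composition_statistics(uniques: Sequence[UniqueAssembly]) -> dict[str, int]:
    """Archive-style composition breakdown over unique assemblies."""
    stats = {
        "n_unique": len(uniques),
        "protein_only": 0,
        "protein_nucleic": 0,
        "nucleic_only": 0,
        "monomeric": 0,
        "homomeric": 0,
        "heteromeric": 0,
        "any_uniprot_mapped": 0,
        "all_uniprot_mapped": 0,
    }
    for u in uniques:
        flags = classify_unique(u)
        stats[flags["composition_class"]] += 1
        stats[flags["multiplicity_class"]] += 1
        if flags["any_uniprot_mapped"]:
            stats["any_uniprot_mapped"] += 1
        if flags["all_uniprot_mapped"]:
            stats["all_uniprot_mapped"] += 1
    return stats


def homomer_stoichiometry_variability(
    uniques: Sequence[UniqueAssembly],
) -> dict[str, list[int]]:
    """Distinct stoichiometries observed per single-accession protein group.

    Groups whose composition is a single UniProt accession are keyed by that
    accession; the value lists the distinct copy numbers seen across unique
    compositions (length > 1 flags a stoichiometry-variable protein).
    """
    seen: dict[str, set[int]] = {}
    for u in uniques:
        if len(u.key.labels) != 1:
            continue
        label = u.key.labels[0]
        if label.startswith(_UNMAPPED_PREFIXES):
            continue
        acc, stoich = label.rsplit("_", 1)
        comps = [c for c in u.components if c.polymer_type == "protein"]
        if not comps:
            continue
        seen.setdefault(acc, set()).add(int(stoich))
    return {acc: sorted(v) for acc, v in seen.items()}
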