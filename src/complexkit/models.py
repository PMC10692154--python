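"""Core domain types for assembly identity, matching and naming.

The vocabulary follows PDBe practice: a PDB *entry* declares one or more
*assemblies* (candidate quaternary structures); each assembly is a bag of
polymer *components* (deposition entities) with copy numbers; assemblies
sharing a canonical composition form one *unique assembly* that receives a
persistent ``PDB-CPX-`` accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

POLYMER_TYPES = ("protein", "DNA", "RNA", "DNA/RNA")

#: Naming categories a unique assembly may receive (Table-4-style vocabulary).
NAMING_CATEGORIES = (
    "uniprot",
    "unmapped_protein",
    "nucleic_generic",
    "complex_portal",
    "ribosome",
    "antibody",
    "entity_common_name",
    "go",
    "curated",
    "rfam",
    "unnamed",
)


@dataclass(frozen=True)
class PolymerComponent:
    """One polymer entity within one assembly, with its external mappings.

    ``uniprot_accessions`` holds zero or more UniProt accessions; more than
    one marks a chimeric entity, which excludes the whole assembly from
    unique-assembly identification. ``copies`` is the stoichiometry of the
    entity within the assembly.
    """

    entry_id: str
    entity_id: int
    polymer_type: str
    copies: int
    uniprot_accessions: tuple[str, ...] = ()
    rfam_accession: Optional[str] = None
    is_antibody: bool = False
    entity_name: str = ""
    uniprot_name: Optional[str] = None
    go_cc_terms: tuple[tuple[str, str], ...] = ()
    taxonomy_id: Optional[int] = None
    seq_length: Optional[int] = None

    @property
    def is_chimeric(self) -> bool:
        return len(self.uniprot_accessions) > 1

    @property
    def uniprot(self) -> Optional[str]:
        """The single UniProt accession, or None if unmapped or chimeric."""
        if len(self.uniprot_accessions) == 1:
            return self.uniprot_accessions[0]
        return None


@dataclass
class AssemblyInstance:
    """One deposited assembly of one PDB entry."""

    entry_id: str
    assembly_id: int
    components: list[PolymerComponent] = field(default_factory=list)
    symmetry_label: Optional[str] = None
    is_preferred: bool = False

    @property
    def key(self) -> tuple[str, int]:
        return (self.entry_id, self.assembly_id)

    @property
    def total_copies(self) -> int:
        return sum(c.copies for c in self.components)

    @property
    def entity_ids(self) -> frozenset[int]:
        return frozenset(c.entity_id for c in self.components)


@dataclass(frozen=True)
class PortalComplex:
    """A Complex Portal definition: participants with stoichiometry."""

    complex_ac: str
    recommended_name: str
    participants: tuple[tuple[str, int], ...]  # (UniProt accession, stoich)
    partial_definition: bool = False  # non-UniProt participants were dropped

    @property
    def participant_dict(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for acc, n in self.participants:
            out[acc] = out.get(acc, 0) + n
        return out


@dataclass
class CuratedNameMap:
    """Manually curated names keyed by composition md5."""

    entries: dict[str, str] = field(default_factory=dict)

    def get(self, md5_hex: str) -> Optional[str]:
        return self.entries.get(md5_hex)


@dataclass
class ValidationReport:
    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass(frozen=True)
class CompositionKey:
    """Canonical composition of an assembly: ordered labels, string, digest."""

    labels: tuple[str, ...]
    composition_string: str
    md5_hex: str


@dataclass(frozen=True)
class PortalMatch:
    """How a unique composition maps onto the Complex Portal catalogue."""

    kind: str  # exact | exact_plus_extras | multi_portal
    complex_acs: tuple[str, ...]
    extra_components: tuple[tuple[str, str], ...] = ()  # (label, category)


@dataclass(frozen=True)
class NameResult:
    name: Optional[str]
    category: str
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class RibosomeCall:
    is_ribosome: bool
    subunits: frozenset[str] = frozenset()  # subset of {"SSU", "LSU"}
    has_trna: bool = False
    has_other_rna: bool = False
    kingdom_style: str = "unknown"  # prokaryotic-style | eukaryotic-style


@dataclass
class UniqueAssembly:
    """An equivalence class of assemblies with identical canonical composition."""

    key: CompositionKey
    accession: Optional[str] = None
    members: list[tuple[str, int]] = field(default_factory=list)
    components: list[PolymerComponent] = field(default_factory=list)
    name: Optional[str] = None
    naming_category: str = "unnamed"
    portal_matches: list[PortalMatch] = field(default_factory=list)
    taxonomy_ids: set[int] = field(default_factory=set)

    @property
    def md5_hex(self) -> str:
        return self.key.md5_hex


class SnapshotValidationError(ValueError):
    """A snapshot violates its schema or field invariants."""

    def __init__(self, report: ValidationReport):
        self.report = report
        lines = "; ".join(f"{loc}: {rule}" for loc, rule in report.errors[:10])
        more = "" if len(report.errors) <= 10 else f" (+{len(report.errors) - 10} more)"
        super().__init__(f"snapshot invalid: {lines}{more}")


class RegistryIntegrityError(RuntimeError):
    """The persistent identifier registry is internally inconsistent."""


class EligibilityError(ValueError):
    """Operation applied to an assembly excluded from identification."""
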