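"""Automated human-readable naming of unique assemblies.

Names are assigned by a decision tree over the evidence attached to an
assembly's components, in fixed precedence order:

1. manually curated name (keyed by composition md5) — authoritative;
2. Complex Portal exact match — the portal recommended name;
3. Complex Portal extended / multi-portal match — portal name(s) plus the
   generic names of the extra components, joined with " and ";
4. ribosome naming (subunit detection via rRNA Rfam families, with an
   unmapped-RNA + ribosomal-protein fallback);
5. a Gene Ontology cellular-component term shared by every component,
   restricted to an allow-list of complex-describing terms;
6. single-UniProt rules: homomers and monomers take the UniProt recommended
   name; a single mapped protein with generic extras takes
   "<protein>, <extra>, ... complex";
7. all-unmapped protein assemblies take antibody and/or entity names;
8. all-Rfam nucleic assemblies take Rfam family names;
9. remaining nucleic-acid-only assemblies are named generically
   (DNA / RNA / DNA/RNA hybrid).

An assembly matching none of the rules stays unnamed — a valid outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .identity import component_label
from .models import (
    CuratedNameMap,
    NameResult,
    PolymerComponent,
    PortalComplex,
    PortalMatch,
    RibosomeCall,
    UniqueAssembly,
)
from .portal import PEPTIDE_MAX_LENGTH, categorize_extra

# ---------------------------------------------------------------------------
# configuration

DEFAULT_RRNA_FAMILIES: dict[str, str] = {
    # small subunit
    "RF00177": "SSU",  # bacterial 16S
    "RF01959": "SSU",  # archaeal 16S
    "RF01960": "SSU",  # eukaryotic 18S
    "RF02542": "SSU",  # microsporidian SSU
    # large subunit
    "RF02541": "LSU",  # bacterial 23S
    "RF02540": "LSU",  # archaeal 23S
    "RF02543": "LSU",  # eukaryotic 28S
    "RF00001": "LSU",  # 5S
    "RF00002": "LSU",  # 5.8S
}

#: tRNA families; their presence appends " and tRNA" to ribosome names
DEFAULT_TRNA_FAMILIES = ("RF00005", "RF01852")

DEFAULT_RIBOSOMAL_PROTEIN_PATTERNS = ("ribosomal protein", "ribosome")

#: GO CC terms eligible for whole-complex naming (complex/machine terms only,
#: never compartments like "cytoplasm")
DEFAULT_GO_ALLOWLIST = (
    "GO:0000786",  # nucleosome
    "GO:0000502",  # proteasome complex
    "GO:0005833",  # haemoglobin complex
    "GO:0009522",  # photosystem I
    "GO:0009523",  # photosystem II
    "GO:0016591",  # DNA-directed RNA polymerase II, holoenzyme
    "GO:0033178",  # proton-transporting two-sector ATPase complex
    "GO:0005666",  # RNA polymerase III complex
    "GO:0005665",  # RNA polymerase II, core complex
)

#: human-readable names for Rfam families used when an assembly consists
#: exclusively of Rfam-mapped nucleic components
DEFAULT_RFAM_NAMES: dict[str, str] = {
    "RF00162": "SAM riboswitch",
    "RF00005": "tRNA",
    "RF01852": "tRNA",
    "RF00177": "16S ribosomal RNA",
    "RF02541": "23S ribosomal RNA",
    "RF00001": "5S ribosomal RNA",
    "RF00010": "RNase P RNA",
    "RF00028": "group-I intron",
    "RF00029": "group-II intron",
    "RF00234": "glmS ribozyme",
}

#: taxonomy ids given eukaryotic-style (40 S/60 S/80 S) ribosome names
DEFAULT_EUKARYOTE_TAXA = (
    9606, 10090, 10116, 4932, 559292, 3702, 7227, 6239, 7955, 9913,
)


@dataclass
class NamingConfig:
    rrna_families: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RRNA_FAMILIES))
    trna_families: tuple[str, ...] = DEFAULT_TRNA_FAMILIES
    ribosomal_protein_patterns: tuple[str, ...] = DEFAULT_RIBOSOMAL_PROTEIN_PATTERNS
    go_allowlist: tuple[str, ...] = DEFAULT_GO_ALLOWLIST
    rfam_names: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_RFAM_NAMES))
    eukaryote_taxa: tuple[int, ...] = DEFAULT_EUKARYOTE_TAXA
    peptide_max_length: int = PEPTIDE_MAX_LENGTH

    @classmethod
    def from_yaml(cls, path) -> "NamingConfig":
        doc = yaml.safe_load(open(path)) or {}
        kwargs = {}
        for key in (
            "rrna_families",
            "trna_families",
            "ribosomal_protein_patterns",
            "go_allowlist",
            "rfam_names",
            "eukaryote_taxa",
            "peptide_max_length",
        ):
            if key in doc:
                value = doc[key]
                kwargs[key] = tuple(value) if isinstance(value, list) else value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# ribosome detection and naming


def _is_ribosomal_protein(component: PolymerComponent, config: NamingConfig) -> bool:
    if component.polymer_type != "protein":
        return False
    haystack = f"{component.uniprot_name or ''} {component.entity_name}".lower()
    return any(p.lower() in haystack for p in config.ribosomal_protein_patterns)


def _subunit_from_protein_names(
    components: Sequence[PolymerComponent], config: NamingConfig
) -> frozenset[str]:
    """Infer subunits from ribosomal protein names when no rRNA is mapped."""
    subunits = set()
    for c in components:
        if not _is_ribosomal_protein(c, config):
            continue
        text = f"{c.uniprot_name or ''} {c.entity_name}".lower()
        if "30s" in text or "40s" in text or "small" in text:
            subunits.add("SSU")
        if "50s" in text or "60s" in text or "large" in text:
            subunits.add("LSU")
    return frozenset(subunits) if subunits else frozenset({"SSU", "LSU"})


def detect_ribosome(
    components: Sequence[PolymerComponent], config: Optional[NamingConfig] = None
) -> RibosomeCall:
    """Decide whether a component list is a ribosomal assembly.

    Primary route: at least one rRNA component mapped to a configured rRNA
    Rfam family together with at least one ribosomal protein.  Fallback route
    (only when no rRNA mapping exists): at least one unmapped RNA together
    with at least one ribosomal protein; the unmapped RNA is then presumed to
    be the rRNA and does not count as additional bound RNA.
    """
    config = config or NamingConfig()
    rrna_families = {
        c.rfam_accession
        for c in components
        if c.polymer_type == "RNA" and c.rfam_accession in config.rrna_families
    }
    has_ribo_protein = any(_is_ribosomal_protein(c, config) for c in components)
    has_unmapped_rna = any(
        c.polymer_type == "RNA" and not c.rfam_accession for c in components
    )
    has_trna = any(
        c.rfam_accession in config.trna_families
        for c in components
        if c.polymer_type == "RNA"
    )
    taxa = {c.taxonomy_id for c in components if c.taxonomy_id is not None}
    if taxa:
        kingdom = (
            "eukaryotic-style"
            if taxa & set(config.eukaryote_taxa)
            else "prokaryotic-style"
        )
    else:
        kingdom = "prokaryotic-style"

    if rrna_families and has_ribo_protein:
        subunits = frozenset(config.rrna_families[f] for f in rrna_families)
        has_other = any(
            c.polymer_type == "RNA"
            and c.rfam_accession not in config.rrna_families
            and c.rfam_accession not in config.trna_families
            for c in components
        )
        return RibosomeCall(True, subunits, has_trna, has_other, kingdom)
    if not rrna_families and has_unmapped_rna and has_ribo_protein:
        has_other = any(
            c.polymer_type == "RNA"
            and c.rfam_accession
            and c.rfam_accession not in config.trna_families
            for c in components
        )
        return RibosomeCall(
            True, _subunit_from_protein_names(components, config), has_trna, has_other, kingdom
        )
    return RibosomeCall(False, frozenset(), has_trna, False, kingdom)


def ribosome_name(call: RibosomeCall) -> str:
    """Name a ribosomal assembly from its subunit content and bound RNAs."""
    if not call.is_ribosome:
        raise ValueError("ribosome_name called on a non-ribosome")
    euk = call.kingdom_style == "eukaryotic-style"
    if call.subunits == {"SSU", "LSU"}:
        name = "80 S ribosome" if euk else "70 S ribosome"
    elif call.subunits == {"SSU"}:
        name = "40 S ribosomal subunit" if euk else "30 S ribosomal subunit"
    else:
        name = "60 S ribosomal subunit" if euk else "50 S ribosomal subunit"
    if call.has_trna:
        name += " and tRNA"
    if call.has_other_rna:
        name += " and RNA"
    return name


# ---------------------------------------------------------------------------
# GO common-term naming


def common_go_name(
    components: Sequence[PolymerComponent],
    config: Optional[NamingConfig] = None,
    term_component_counts: Optional[dict[str, int]] = None,
) -> Optional[tuple[str, str]]:
    """A GO cellular-component term shared by every component, if any.

    Only allow-listed complex-describing terms qualify.  When several terms
    qualify, the most specific wins: fewest annotated components archive-wide
    (per ``term_component_counts``), tie broken alphabetically by term name.
    Returns (GO id, term name) or None.
    """
    config = config or NamingConfig()
    if not components:
        return None
    allow = set(config.go_allowlist)
    shared: Optional[dict[str, str]] = None
    for comp in components:
        terms = {i: n for i, n in comp.go_cc_terms if i in allow}
        if shared is None:
            shared = terms
        else:
            shared = {i: n for i, n in shared.items() if i in terms}
        if not shared:
            return None
    assert shared is not None
    counts = term_component_counts or {}

    def specificity(item: tuple[str, str]):
        go_id, go_name = item
        return (counts.get(go_id, 0), go_name, go_id)

    go_id, go_name = min(shared.items(), key=specificity)
    return go_id, go_name


def go_term_component_counts(
    uniques: Sequence[UniqueAssembly],
) -> dict[str, int]:
    """Archive-wide count of components annotated with each GO CC term."""
    counts: dict[str, int] = {}
    for u in uniques:
        for comp in u.components:
            for go_id, _ in comp.go_cc_terms:
                counts[go_id] = counts.get(go_id, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# the decision tree


def _extra_display_name(component: PolymerComponent, config: NamingConfig) -> str:
    category = categorize_extra(component, config.peptide_max_length)
    if category == "DNA":
        return "DNA"
    if category == "RNA":
        return "RNA"
    if category == "peptide":
        return "peptide"
    if category == "antibody":
        return component.entity_name or "antibody"
    if category == "protein":
        return component.uniprot_name or component.entity_name or "protein"
    if component.polymer_type == "DNA/RNA":
        return "DNA/RNA hybrid"
    return component.entity_name or "protein"


def _dedupe(names: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for n in names:
        if n and n not in seen:
            seen.add(n)
            out.append(n)
    return out


def name_assembly(
    unique: UniqueAssembly,
    portal_match: Optional[PortalMatch] = None,
    curated: Optional[CuratedNameMap] = None,
    config: Optional[NamingConfig] = None,
    portal_names: Optional[dict[str, str]] = None,
    go_counts: Optional[dict[str, int]] = None,
) -> NameResult:
    """Run the naming decision tree for one unique assembly.

    ``portal_names`` maps Complex Portal accessions to recommended names (only
    needed when a portal match is supplied); ``go_counts`` carries archive-wide
    GO term component counts for the specificity tie-break.
    """
    config = config or NamingConfig()
    portal_names = portal_names or {}
    comps = sorted(unique.components, key=lambda c: (c.entry_id, c.entity_id))

    # 1. curated override
    if curated is not None:
        curated_name = curated.get(unique.md5_hex)
        if curated_name:
            return NameResult(curated_name, "curated", (unique.md5_hex,))

    # 2-3. Complex Portal
    if portal_match is not None:
        base_names = _dedupe(
            [portal_names.get(ac, ac) for ac in portal_match.complex_acs]
        )
        if portal_match.kind == "exact":
            return NameResult(base_names[0], "complex_portal", portal_match.complex_acs)
        extra_names = []
        by_label: dict[str, PolymerComponent] = {}
        for c in comps:
            if not c.is_chimeric:
                by_label.setdefault(component_label(c).rsplit("_", 1)[0], c)
        for label, _category in portal_match.extra_components:
            comp = by_label.get(label.rsplit("_", 1)[0])
            extra_names.append(
                _extra_display_name(comp, config) if comp is not None else label
            )
        parts = base_names + _dedupe(extra_names)
        return NameResult(" and ".join(parts), "complex_portal", portal_match.complex_acs)

    # 4. ribosome
    call = detect_ribosome(comps, config)
    if call.is_ribosome:
        return NameResult(ribosome_name(call), "ribosome", ("ribosome-rule",))

    # 5. shared GO cellular-component term
    go_hit = common_go_name(comps, config, go_counts)
    if go_hit is not None:
        go_id, go_name = go_hit
        return NameResult(go_name, "go", (go_id,))

    protein_comps = [c for c in comps if c.polymer_type == "protein"]
    mapped = [c for c in protein_comps if c.uniprot]
    accessions = {c.uniprot for c in mapped}

    # 6. single-UniProt rules
    if len(accessions) == 1:
        anchor = next(c for c in comps if c.uniprot)
        protein_name = anchor.uniprot_name or anchor.entity_name
        extras = [c for c in comps if not (c.polymer_type == "protein" and c.uniprot)]
        if not extras:
            if protein_name:
                return NameResult(protein_name, "uniprot", (anchor.uniprot,))
        else:
            extra_names = _dedupe([_extra_display_name(c, config) for c in extras])
            if protein_name:
                name = ", ".join([protein_name] + extra_names) + " complex"
                return NameResult(name, "uniprot", (anchor.uniprot,))

    # 7. all-unmapped protein assemblies: antibody and/or entity names
    if protein_comps and not mapped and len(protein_comps) == len(comps):
        names = _dedupe([c.entity_name for c in comps if c.entity_name])
        if names:
            has_antibody = any(c.is_antibody for c in comps)
            category = "antibody" if has_antibody else (
                "entity_common_name" if len(names) == 1 and len(comps) > 1 else "unmapped_protein"
            )
            return NameResult(" and ".join(names), category, tuple(names))

    nucleic = [c for c in comps if c.polymer_type in ("DNA", "RNA", "DNA/RNA")]
    if nucleic and len(nucleic) == len(comps):
        # 8. all components mapped to Rfam
        rfams = [c.rfam_accession for c in comps]
        if all(rfams):
            names = _dedupe(
                [config.rfam_names.get(f, c.entity_name or f) for f, c in zip(rfams, comps)]
            )
            return NameResult(" and ".join(names), "rfam", tuple(rfams))
        # 9. generic nucleic-acid names
        types = {c.polymer_type for c in comps}
        generic = {"DNA": "DNA", "RNA": "RNA", "DNA/RNA": "DNA/RNA hybrid"}
        name = " and ".join(sorted(generic[t] for t in types))
        return NameResult(name, "nucleic_generic", tuple(sorted(types)))

    return NameResult(None, "unnamed", ())


def naming_statistics(uniques: Sequence[UniqueAssembly]) -> dict:
    """Category breakdown over named unique assemblies (Table-4 style)."""
    by_category: dict[str, dict[str, int]] = {}
    named = 0
    for u in uniques:
        row = by_category.setdefault(
            u.naming_category, {"unique_assemblies": 0, "member_entries": 0}
        )
        row["unique_assemblies"] += 1
        row["member_entries"] += len(u.members)
        if u.name is not None:
            named += 1
    total = len(uniques)
    return {
        "categories": {k: by_category[k] for k in sorted(by_category)},
        "n_unique": total,
        "n_named": named,
        "named_fraction": (named / total) if total else 0.0,
    }
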