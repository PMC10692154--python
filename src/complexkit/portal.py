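"""Matching unique compositions against the Complex Portal catalogue.

Three match kinds are produced, tried in order:

``exact``
    the assembly's UniProt-mapped components (with stoichiometry) equal a
    portal complex's participants and nothing else is present;
``exact_plus_extras``
    one portal complex's participants form a sub-multiset of the assembly's
    mapped components and the leftovers are categorised generically;
``multi_portal``
    two or more portal complexes with disjoint participant coverage are
    found by a greedy largest-coverage-first sweep.

By default shared participants must match stoichiometry exactly; pass
``relaxed_stoichiometry=True`` to accept portal stoichiometry <= assembly
stoichiometry for extended matches.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .identity import component_label
from .models import PolymerComponent, PortalComplex, PortalMatch, UniqueAssembly

PathLike = Union[str, Path]

#: proteins shorter than this (when a length is known) count as peptides
PEPTIDE_MAX_LENGTH = 20

EXTRA_CATEGORIES = ("protein", "DNA", "RNA", "antibody", "peptide", "unmapped")


def _mapped_counts(components: Sequence[PolymerComponent]) -> dict[str, int]:
    """UniProt accession -> summed stoichiometry over protein components."""
    out: dict[str, int] = {}
    for c in components:
        if c.polymer_type == "protein" and c.uniprot:
            out[c.uniprot] = out.get(c.uniprot, 0) + c.copies
    return out


def categorize_extra(
    component: PolymerComponent, peptide_max_length: int = PEPTIDE_MAX_LENGTH
) -> str:
    """Generic category of a leftover component for extended portal matches."""
    if component.polymer_type == "DNA":
        return "DNA"
    if component.polymer_type == "RNA":
        return "RNA"
    if component.polymer_type == "protein":
        if component.is_antibody:
            return "antibody"
        if component.seq_length is not None and component.seq_length < peptide_max_length:
            return "peptide"
        if component.uniprot:
            return "protein"
        return "unmapped"
    return "unmapped"  # DNA/RNA hybrids and anything else


def match_exact(
    unique: UniqueAssembly, catalog: Sequence[PortalComplex]
) -> Optional[PortalMatch]:
    """Exact composition match: participants equal, no other components."""
    mapped = _mapped_counts(unique.components)
    if not mapped:
        return None
    if any(
        not (c.polymer_type == "protein" and c.uniprot) for c in unique.components
    ):
        return None  # unmapped or non-protein components present
    hits = [c for c in catalog if c.participant_dict == mapped]
    if not hits:
        return None
    best = min(hits, key=lambda c: c.complex_ac)
    return PortalMatch(kind="exact", complex_acs=(best.complex_ac,))


def _is_submultiset(
    participants: dict[str, int], pool: dict[str, int], relaxed: bool
) -> bool:
    for acc, n in participants.items():
        have = pool.get(acc, 0)
        if relaxed:
            if have < n:
                return False
        elif have != n:
            return False
    return True


def match_extended(
    unique: UniqueAssembly,
    catalog: Sequence[PortalComplex],
    relaxed_stoichiometry: bool = False,
    peptide_max_length: int = PEPTIDE_MAX_LENGTH,
) -> Optional[PortalMatch]:
    """Greedy extended match: cover mapped components with portal complexes.

    Portal complexes are consumed largest-coverage-first (total participant
    stoichiometry, tie-break lowest accession) so coverage is disjoint.
    Leftover components — mapped proteins not covered, unmapped proteins,
    antibodies, peptides and nucleic acids — are categorised as extras.
    Only called when :func:`match_exact` found nothing.
    """
    pool = _mapped_counts(unique.components)
    matched: list[PortalComplex] = []
    while True:
        candidates = [
            c
            for c in catalog
            if c.participant_dict
            and _is_submultiset(c.participant_dict, pool, relaxed_stoichiometry)
        ]
        if not candidates:
            break
        best = min(
            candidates,
            key=lambda c: (-sum(c.participant_dict.values()), c.complex_ac),
        )
        matched.append(best)
        for acc, n in best.participant_dict.items():
            pool[acc] -= n
            if pool[acc] <= 0:
                del pool[acc]
    if not matched:
        return None
    extras: list[tuple[str, str]] = []
    covered = {}
    for c in matched:
        for acc, n in c.participant_dict.items():
            covered[acc] = covered.get(acc, 0) + n
    consumed: dict[str, int] = {}
    for comp in unique.components:
        if comp.polymer_type == "protein" and comp.uniprot:
            acc = comp.uniprot
            used = min(comp.copies, covered.get(acc, 0) - consumed.get(acc, 0))
            used = max(used, 0)
            consumed[acc] = consumed.get(acc, 0) + used
            leftover = comp.copies - used
            if leftover > 0:
                extras.append(
                    (component_label(comp, copies=leftover), categorize_extra(comp, peptide_max_length))
                )
        else:
            extras.append((component_label(comp), categorize_extra(comp, peptide_max_length)))
    kind = "multi_portal" if len(matched) >= 2 else "exact_plus_extras"
    return PortalMatch(
        kind=kind,
        complex_acs=tuple(c.complex_ac for c in matched),
        extra_components=tuple(extras),
    )


def match_unique(
    unique: UniqueAssembly,
    catalog: Sequence[PortalComplex],
    relaxed_stoichiometry: bool = False,
    peptide_max_length: int = PEPTIDE_MAX_LENGTH,
) -> Optional[PortalMatch]:
    """Try an exact match first, then the extended/greedy cover."""
    match = match_exact(unique, catalog)
    if match is not None:
        return match
    return match_extended(
        unique,
        catalog,
        relaxed_stoichiometry=relaxed_stoichiometry,
        peptide_max_length=peptide_max_length,
    )


def export_mapping(
    uniques: Sequence[UniqueAssembly], path: PathLike
) -> None:
    """Write the public mapping TSV (one row per matched unique assembly).

    Rows are sorted by accession; the file is written atomically (temp then
    rename) so an I/O failure never leaves a partial file behind.
    """
    rows = []
    for u in uniques:
        for m in u.portal_matches:
            rows.append(
                {
                    "pdb_complex_accession": u.accession or "",
                    "md5": u.md5_hex,
                    "complex_portal_accessions": "|".join(m.complex_acs),
                    "match_kind": m.kind,
                    "extra_components": "|".join(
                        f"{label}:{cat}" for label, cat in m.extra_components
                    ),
                }
            )
    rows.sort(key=lambda r: (r["pdb_complex_accession"], r["md5"]))
    df = pd.DataFrame(
        rows,
        columns=[
            "pdb_complex_accession",
            "md5",
            "complex_portal_accessions",
            "match_kind",
            "extra_components",
        ],
    )
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    try:
        df.to_csv(tmp, sep="\t", index=False, lineterminator="\n")
        os.replace(tmp, path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise
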