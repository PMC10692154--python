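"""End-to-end release-style pipeline: identify → relate → map → name → report.

A run reads one snapshot, selects preferred assemblies, drops chimeric ones,
groups unique compositions, assigns (or reuses) persistent accessions from
the registry, detects sub/super-assembly relations, maps compositions to the
Complex Portal, names everything, and writes symmetry and composition
statistics.  Outputs are deterministic: identical inputs plus registry yield
byte-identical files, and a re-run mints no new accessions.

The registry is guarded by a single-writer lock file; concurrent runs fail
fast with an integrity error rather than merging.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import archive_io, identity, naming, portal, relations, symmetry
from .models import RegistryIntegrityError, UniqueAssembly

PathLike = Union[str, Path]

OUTPUT_FILES = (
    "unique_assemblies.tsv",
    "relations.tsv",
    "portal_mapping.tsv",
    "names.tsv",
    "symmetry_report.tsv",
    "stats.json",
)


@dataclass
class RunConfig:
    snapshot: PathLike
    registry: PathLike
    out_dir: PathLike
    portal_catalog: Optional[PathLike] = None
    curated_names: Optional[PathLike] = None
    naming_config: Optional[PathLike] = None
    relation_mode: str = "strict"
    portal_relaxed_stoichiometry: bool = False
    first_serial: int = identity.DEFAULT_FIRST_SERIAL

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)


class _RegistryLock:
    def __init__(self, registry_path: Path):
        self.lock_path = Path(str(registry_path) + ".lock")

    def __enter__(self):
        self.lock_path.parent.mkdir(parents=True, exist_ok=True)
        try:
            fd = os.open(self.lock_path, os.O_CREAT | os.O_EXCL | os.O_WRONLY)
        except FileExistsError:
            raise RegistryIntegrityError(
                f"registry is locked by another run: {self.lock_path}"
            )
        os.write(fd, str(os.getpid()).encode())
        os.close(fd)
        return self

    def __exit__(self, *exc):
        self.lock_path.unlink(missing_ok=True)
        return False


def _atomic_write_df(df: pd.DataFrame, path: Path) -> None:
    tmp = path.with_name(path.name + ".tmp")
    try:
        df.to_csv(tmp, sep="\t", index=False, lineterminator="\n")
        os.replace(tmp, path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise


def _atomic_write_text(text: str, path: Path) -> None:
    tmp = path.with_name(path.name + ".tmp")
    try:
        tmp.write_text(text)
        os.replace(tmp, path)
    except BaseException:
        tmp.unlink(missing_ok=True)
        raise


def run_pipeline(config: RunConfig) -> dict:
    """Execute one release-style run; returns the stats dictionary.

    Raises :class:`SnapshotValidationError` on invalid input (no registry
    mutation happens in that case) and :class:`RegistryIntegrityError` on a
    corrupt or locked registry.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    registry_path = Path(config.registry)

    # 1. inputs (snapshot validation precedes any registry mutation)
    assemblies = archive_io.read_snapshot(config.snapshot)
    catalog = (
        archive_io.read_portal_catalog(config.portal_catalog)
        if config.portal_catalog
        else []
    )
    curated = (
        archive_io.read_curated_names(config.curated_names)
        if config.curated_names
        else None
    )
    naming_config = (
        naming.NamingConfig.from_yaml(config.naming_config)
        if config.naming_config
        else naming.NamingConfig()
    )

    with _RegistryLock(registry_path):
        registry = identity.IdentifierRegistry.load(
            registry_path, first_serial=config.first_serial
        )

        # 2. preferred assemblies, eligibility, unique grouping
        preferred = identity.mark_preferred(assemblies)
        eligible, excluded = [], []
        for asm in preferred:
            ok, reason = identity.eligibility(asm)
            (eligible if ok else excluded).append((asm, reason))
        eligible_assemblies = [a for a, _ in eligible]
        uniques = identity.group_unique(eligible_assemblies, registry)

        # 3. relations
        graph = relations.build_relation_graph(uniques, mode=config.relation_mode)
        accession_of = {u.md5_hex: u.accession or u.md5_hex for u in uniques}
        relation_df = pd.DataFrame(
            relations.relation_rows(graph, accession_of),
            columns=["sub_accession", "super_accession", "sub_md5", "super_md5", "added_components"],
        )

        # 4. portal matching
        portal_names = {c.complex_ac: c.recommended_name for c in catalog}
        for u in uniques:
            match = portal.match_unique(
                u,
                catalog,
                relaxed_stoichiometry=config.portal_relaxed_stoichiometry,
                peptide_max_length=naming_config.peptide_max_length,
            )
            u.portal_matches = [match] if match else []

        # 5. naming
        go_counts = naming.go_term_component_counts(uniques)
        for u in uniques:
            result = naming.name_assembly(
                u,
                u.portal_matches[0] if u.portal_matches else None,
                curated,
                naming_config,
                portal_names=portal_names,
                go_counts=go_counts,
            )
            u.name = result.name
            u.naming_category = result.category

        # 6. symmetry
        frequency = symmetry.symmetry_frequency(eligible_assemblies)
        consistency = symmetry.consistency_by_composition(uniques, assemblies)

        # 7. outputs
        _write_uniques(uniques, out_dir / "unique_assemblies.tsv")
        _atomic_write_df(relation_df, out_dir / "relations.tsv")
        portal.export_mapping(uniques, out_dir / "portal_mapping.tsv")
        _write_names(uniques, out_dir / "names.tsv")
        _write_symmetry(consistency, out_dir / "symmetry_report.tsv")

        stats = {
            "input": {
                "n_assemblies": len(assemblies),
                "n_entries": len({a.entry_id for a in assemblies}),
                "n_preferred": len(preferred),
                "n_eligible": len(eligible_assemblies),
                "n_excluded_chimeric": len(excluded),
            },
            "composition": identity.composition_statistics(uniques),
            "naming": naming.naming_statistics(uniques),
            "portal": {
                "n_matched": sum(1 for u in uniques if u.portal_matches),
                "n_exact": sum(
                    1 for u in uniques if u.portal_matches and u.portal_matches[0].kind == "exact"
                ),
                "n_exact_plus_extras": sum(
                    1
                    for u in uniques
                    if u.portal_matches and u.portal_matches[0].kind == "exact_plus_extras"
                ),
                "n_multi_portal": sum(
                    1 for u in uniques if u.portal_matches and u.portal_matches[0].kind == "multi_portal"
                ),
            },
            "relations": relations.summarize(graph),
            "symmetry": {
                "frequency": frequency,
                "n_assessed": consistency.n_assessed,
                "n_inconsistent": consistency.n_inconsistent,
                "fraction_inconsistent": consistency.fraction_inconsistent,
                "n_members_assessed": consistency.n_members_assessed,
                "n_members_inconsistent": consistency.n_members_inconsistent,
            },
        }
        _atomic_write_text(
            json.dumps(stats, indent=2, sort_keys=True) + "\n", out_dir / "stats.json"
        )

        # 8. registry persisted last, append-only
        registry.save(registry_path)
    return stats


def incremental_update(config: RunConfig) -> dict:
    """Re-run over a new snapshot against an existing registry.

    Previously seen compositions keep their accessions; only novel
    compositions mint new ones.  (Identical to :func:`run_pipeline`; the
    registry semantics make every run incremental.)
    """
    return run_pipeline(config)


def _write_uniques(uniques: list[UniqueAssembly], path: Path) -> None:
    rows = []
    for u in uniques:
        flags = identity.classify_unique(u)
        rows.append(
            {
                "accession": u.accession or "",
                "md5": u.md5_hex,
                "composition_string": u.key.composition_string,
                "n_members": len(u.members),
                "members": "|".join(f"{e}_{a}" for e, a in sorted(u.members)),
                "composition_class": flags["composition_class"],
                "multiplicity_class": flags["multiplicity_class"],
                "all_uniprot_mapped": int(flags["all_uniprot_mapped"]),
                "taxonomy_ids": "|".join(str(t) for t in sorted(u.taxonomy_ids)),
            }
        )
    rows.sort(key=lambda r: r["accession"])
    df = pd.DataFrame(
        rows,
        columns=[
            "accession",
            "md5",
            "composition_string",
            "n_members",
            "members",
            "composition_class",
            "multiplicity_class",
            "all_uniprot_mapped",
            "taxonomy_ids",
        ],
    )
    _atomic_write_df(df, path)


def _write_names(uniques: list[UniqueAssembly], path: Path) -> None:
    rows = [
        {
            "accession": u.accession or "",
            "md5": u.md5_hex,
            "name": u.name or "",
            "category": u.naming_category,
        }
        for u in uniques
    ]
    rows.sort(key=lambda r: r["accession"])
    df = pd.DataFrame(rows, columns=["accession", "md5", "name", "category"])
    _atomic_write_df(df, path)


def _write_symmetry(report, path: Path) -> None:
    rows = [
        {
            "accession": c.accession or "",
            "md5": c.md5,
            "n_labelled_members": len(c.member_labels),
            "labels": "|".join(f"{k}:{v}" for k, v in c.histogram.items()),
            "is_consistent": int(c.is_consistent),
        }
        for c in report.compositions
    ]
    rows.sort(key=lambda r: r["accession"])
    df = pd.DataFrame(
        rows, columns=["accession", "md5", "n_labelled_members", "labels", "is_consistent"]
    )
    _atomic_write_df(df, path)
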